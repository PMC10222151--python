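"""k-mer counting, genomic signatures, and the k4freq distance.

The genomic signature of a genome X is the vector of relative
frequencies f_w(X) = X_w / S_X over all 4^k words w, where X_w is the
sliding-window occurrence count of w and S_X = sum_w X_w. The k4freq
distance between two genomes is the plain Euclidean distance between
their k=4 signatures:

    Eu(X, Y) = sqrt( sum_w (f_w(X) - f_w(Y))^2 )

Counts are held sparsely (sorted integer word codes + counts) so the
same counting core serves both the dense small-k signatures (k = 4, 6)
and the exact-match distance at k = 14, where a dense 4^k table per
genome would be wasteful.

Counting conventions: windows never span a contig boundary; any window
containing a non-ACGT base is skipped (and tallied), so ambiguity codes
neither match nor invent composition; only the deposited strand is
counted unless ``strand_mode="both"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from phagesig.io_formats import SequenceRecord

BASES = "ACGT"

# base -> 2-bit code lookup over the full byte range; -1 marks non-ACGT
_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHV",
    "TGCAANYRSWMKVHDB",
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerCounts:
    """Sparse occurrence counts of all k-words observed in one genome.

    ``codes`` are the 2-bit-packed integer encodings (A=0, C=1, G=2,
    T=3, lexicographic) of the observed words, strictly increasing;
    ``counts`` are the matching occurrence counts X_w > 0.
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray
    total: int
    skipped_windows: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(self.codes) != len(self.counts):
            raise ValueError("codes and counts length mismatch")
        if self.total != int(self.counts.sum()):
            raise ValueError("total does not equal sum of counts")

    def as_dict(self) -> dict[str, int]:
        """Decode to {word: count}; intended for small k (tests, display)."""
        return {decode_kmer(int(c), self.k): int(n) for c, n in zip(self.codes, self.counts)}

    def __len__(self) -> int:
        return len(self.codes)


@dataclass(frozen=True)
class SignatureVector:
    """Dense relative-frequency vector over all 4^k words.

    Index order is lexicographic over A<C<G<T (i.e. by the 2-bit code),
    fixed so vectors are bit-comparable across runs.
    """

    k: int
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        if len(self.frequencies) != 4**self.k:
            raise ValueError(f"expected 4^{self.k} entries, got {len(self.frequencies)}")

    def __len__(self) -> int:
        return len(self.frequencies)


def encode_kmer(word: str) -> int:
    code = 0
    for ch in word:
        b = _CODE_LUT[ord(ch)]
        if b < 0:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer")
        code = (code << 2) | int(b)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def _contig_window_codes(contig: str, k: int) -> tuple[np.ndarray, int]:
    """Codes of all valid k-windows of one contig and the skipped-window count."""
    n_windows = max(len(contig) - k + 1, 0)
    if n_windows == 0:
        return np.empty(0, dtype=np.int64), 0
    base = _CODE_LUT[np.frombuffer(contig.encode("ascii"), dtype=np.uint8)].astype(np.int64)
    invalid = base < 0
    # windows with any invalid base, via cumulative sum of the bad mask
    cs = np.concatenate(([0], np.cumsum(invalid)))
    bad_window = (cs[k:] - cs[:-k]) > 0
    codes = np.zeros(n_windows, dtype=np.int64)
    for j in range(k):
        codes = (codes << 2) | base[j : j + n_windows]
    skipped = int(bad_window.sum())
    return codes[~bad_window], skipped


def count_kmers(
    record: SequenceRecord | str,
    k: int,
    strand_mode: str = "forward",
) -> KmerCounts:
    """Sliding-window k-mer counts of a genome.

    Each contig is counted independently (no window spans a contig
    junction) and the counts aggregated. ``strand_mode="both"`` also
    counts the reverse complement of every contig, doubling the number
    of windows. A genome with every contig shorter than k yields
    total = 0 (the caller decides whether that is an error).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    contigs = (record,) if isinstance(record, str) else record.contigs
    if strand_mode == "both":
        contigs = tuple(contigs) + tuple(reverse_complement(c) for c in contigs)

    all_codes: list[np.ndarray] = []
    all_counts: list[np.ndarray] = []
    skipped = 0
    for contig in contigs:
        codes, n_skip = _contig_window_codes(contig, k)
        skipped += n_skip
        if codes.size:
            u, c = np.unique(codes, return_counts=True)
            all_codes.append(u)
            all_counts.append(c)

    if not all_codes:
        return KmerCounts(k=k, codes=np.empty(0, dtype=np.int64), counts=np.empty(0, dtype=np.int64), total=0, skipped_windows=skipped)

    codes = np.concatenate(all_codes)
    counts = np.concatenate(all_counts)
    u, inv = np.unique(codes, return_inverse=True)
    merged = np.bincount(inv, weights=counts).astype(np.int64)
    return KmerCounts(k=k, codes=u, counts=merged, total=int(merged.sum()), skipped_windows=skipped)


def signature(counts: KmerCounts) -> SignatureVector:
    """Relative-frequency signature f_w = X_w / S over the canonical 4^k order."""
    if counts.total == 0:
        raise ValueError("no countable k-mers: cannot build a signature from an empty count")
    freqs = np.zeros(4**counts.k, dtype=np.float64)
    freqs[counts.codes] = counts.counts / counts.total
    return SignatureVector(k=counts.k, frequencies=freqs)


def k4freq_distance(sig_x: SignatureVector, sig_y: SignatureVector) -> float:
    """Euclidean distance between two genomic signatures of equal k.

    Bounded by sqrt(2) since each signature sums to one; zero iff the
    signatures are identical.
    """
    if sig_x.k != sig_y.k:
        raise ValueError(f"signature k mismatch: {sig_x.k} vs {sig_y.k}")
    return float(np.linalg.norm(sig_x.frequencies - sig_y.frequencies))
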