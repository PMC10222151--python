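"""Exact long-k-mer match similarity (SIM) and distance (DSW, "k14exact").

For two genomes with k-mer occurrence totals S_X <= S_Y (X the smaller),

    SIM(X, Y) = sum_{w : Y_w > 0} X_w / S_X
    DSW(X, Y) = 1 - SIM(X, Y)

i.e. the occurrence-weighted fraction of the smaller genome's words that
occur at least once in the larger one. At k = 14 a match is effectively
never random between bacterial-scale genomes (< 2% expected random hits
for a 5 Mb genome), so DSW = 0 means X is inserted verbatim in Y (a
prophage in a chromosome) and DSW = 1 means the genomes share no k-word.

Counts stay sparse throughout: at k = 14 the word space (4^14 ~ 2.7e8)
dwarfs any genome, and a dense table per genome would be enormous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from phagesig.kmer_signatures import KmerCounts


@dataclass(frozen=True)
class ExactMatchResult:
    """One query/target exact-match measurement (X is the smaller-total genome)."""

    query_id: str
    target_id: str
    k: int
    s_x: int
    s_y: int
    sim: float
    dsw: float


def _assign_roles(counts_a: KmerCounts, counts_b: KmerCounts) -> tuple[KmerCounts, KmerCounts]:
    """Return (X, Y) with S_X <= S_Y; ties keep the first argument as X."""
    if counts_a.k != counts_b.k:
        raise ValueError(f"k mismatch: {counts_a.k} vs {counts_b.k}")
    if counts_a.total == 0 or counts_b.total == 0:
        raise ValueError("no countable k-mers: SIM is undefined for an empty count")
    if counts_b.total < counts_a.total:
        return counts_b, counts_a
    return counts_a, counts_b


def sim(counts_a: KmerCounts, counts_b: KmerCounts) -> float:
    """Occurrence-weighted fraction of the smaller genome's k-mers present in the larger.

    Presence in Y is a plain membership test (Y_w > 0); multiplicity in
    Y does not matter, while the query side is weighted by X_w / S_X.
    """
    x, y = _assign_roles(counts_a, counts_b)
    # y.codes is sorted; membership by binary search
    present = np.zeros(len(x.codes), dtype=bool)
    if len(y.codes):
        pos = np.searchsorted(y.codes, x.codes)
        in_range = pos < len(y.codes)
        present[in_range] = y.codes[pos[in_range]] == x.codes[in_range]
    matched = int(x.counts[present].sum())
    return matched / x.total


def dsw_distance(counts_a: KmerCounts, counts_b: KmerCounts) -> float:
    """DSW = 1 - SIM; in [0, 1], symmetric under the size-based role rule."""
    return 1.0 - sim(counts_a, counts_b)


def exact_match(
    query_counts: KmerCounts,
    target_counts: KmerCounts,
    query_id: str = "query",
    target_id: str = "target",
) -> ExactMatchResult:
    """Full SIM/DSW record for one genome pair."""
    x, y = _assign_roles(query_counts, target_counts)
    s = sim(query_counts, target_counts)
    return ExactMatchResult(
        query_id=query_id,
        target_id=target_id,
        k=query_counts.k,
        s_x=x.total,
        s_y=y.total,
        sim=s,
        dsw=1.0 - s,
    )


def expected_random_match_rate(k: int, genome_length: int) -> float:
    """Probability a fixed k-word occurs in an i.i.d. uniform genome of given length.

    With n = max(L - k + 1, 0) windows each matching with probability
    4^-k, the at-least-once probability is 1 - (1 - 4^-k)^n. This is the
    expected SIM between two unrelated random sequences, and the basis
    for choosing k: at k = 14 a 5 Mb genome gives ~1.8%, below the 2%
    random-match ceiling, while k = 13 gives ~7%.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if genome_length < 0:
        raise ValueError("genome_length must be >= 0")
    n = max(genome_length - k + 1, 0)
    if n == 0:
        return 0.0
    # -expm1(n*log1p(-p)) is exact where (1-p)^n underflows naive evaluation
    return -math.expm1(n * math.log1p(-(4.0**-k)))


def smallest_k_for_rate(genome_length: int, max_rate: float = 0.02, k_max: int = 32) -> int:
    """Smallest k whose expected random-match rate is below *max_rate*."""
    if not 0 < max_rate < 1:
        raise ValueError("max_rate must be in (0, 1)")
    for k in range(1, k_max + 1):
        if expected_random_match_rate(k, genome_length) < max_rate:
            return k
    raise ValueError(f"no k <= {k_max} achieves rate < {max_rate} at length {genome_length}")
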