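"""Shared fixtures and independent brute-force oracles.

The oracles recompute k-mer statistics by plain string slicing and
dictionary arithmetic, independent of the integer-encoded production
path, so agreement between the two is a real check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from phagesig import SequenceRecord, SyntheticConfig, simulate

BASES = "ACGT"


def naive_counts(seq: str, k: int) -> tuple[dict[str, int], int]:
    """(word -> count, skipped windows) by string slicing on one contig."""
    counts: dict[str, int] = {}
    skipped = 0
    for i in range(max(len(seq) - k + 1, 0)):
        w = seq[i : i + k]
        if set(w) <= set(BASES):
            counts[w] = counts.get(w, 0) + 1
        else:
            skipped += 1
    return counts, skipped


def naive_record_counts(record: SequenceRecord, k: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    skipped = 0
    for contig in record.contigs:
        c, s = naive_counts(contig, k)
        skipped += s
        for w, n in c.items():
            counts[w] = counts.get(w, 0) + n
    return counts, skipped


def naive_euclidean(counts_x: dict[str, int], counts_y: dict[str, int], k: int) -> float:
    """Direct summation of (f_w(X) - f_w(Y))^2 over every one of the 4^k words."""
    sx = sum(counts_x.values())
    sy = sum(counts_y.values())
    acc = 0.0
    for word in itertools.product(BASES, repeat=k):
        w = "".join(word)
        acc += (counts_x.get(w, 0) / sx - counts_y.get(w, 0) / sy) ** 2
    return math.sqrt(acc)


def naive_sim(seq_a: str, seq_b: str, k: int) -> float:
    """SIM by dictionaries: X is the smaller-total sequence (ties -> first)."""
    ca, _ = naive_counts(seq_a, k)
    cb, _ = naive_counts(seq_b, k)
    sa, sb = sum(ca.values()), sum(cb.values())
    if sb < sa:
        cx, cy, sx = cb, ca, sb
    else:
        cx, cy, sx = ca, cb, sa
    return sum(n for w, n in cx.items() if w in cy) / sx


def random_dna(rng: np.random.Generator, length: int, probs=None) -> str:
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=probs)])


@pytest.fixture(scope="session")
def small_dataset():
    """A scaled-down synthetic study shared by pipeline-level tests."""
    config = SyntheticConfig(
        seed=5,
        n_groups=3,
        genomes_per_group=6,
        genome_length=20_000,
        phage_length=5_000,
        n_lysogenic=12,
        n_lytic=12,
        prophage_hosts_per_phage=2,
    )
    return simulate(config)
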