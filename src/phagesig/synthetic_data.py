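"""Synthetic genome generator for end-to-end testing.

Emulates the compositional structure the distance methods rely on:

* host "genera" — groups of genomes drawn from a shared base
  composition (order 0) or transition matrix (order 1), with groups
  spread across a realistic GC range so hexamer signatures separate;
* ameliorated (lysogenic-like) phages — drawn from their host group's
  composition, and additionally integrated as prophages into a few host
  strains of the group, since a temperate phage physically resides in
  host chromosomes (this is what the exact-match distance detects);
* divergent (lytic-like) phages — composition pulled away from the host
  group toward a phage-specific alien composition;
* far-outlier hosts (extreme GC) that density clustering should reject
  as noise;
* genome pairs over disjoint k-word alphabets sharing no exact k-mer.

Every generator is a pure function of its config/seed; the same seed
reproduces byte-identical sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from phagesig.io_formats import AssociationTable, SequenceRecord

_BASE_ARR = np.frombuffer("ACGT".encode(), dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``composition_divergence`` is the mixing weight pulling lytic-like
    phage composition away from the host group (0 = indistinguishable
    from ameliorated phages). ``prophage_hosts_per_phage`` is how many
    host strains of its group each lysogenic-like phage is integrated
    into as a prophage.
    """

    seed: int = 0
    n_groups: int = 3
    genomes_per_group: int = 20
    genome_length: int = 200_000
    phage_length: int = 50_000
    markov_order: int = 0
    composition_divergence: float = 0.35
    n_lysogenic: int = 50
    n_lytic: int = 50
    prophage_hosts_per_phage: int = 3
    n_outliers: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.markov_order not in (0, 1):
            raise ValueError("markov_order must be 0 or 1")
        if not 0.0 <= self.composition_divergence <= 1.0:
            raise ValueError("composition_divergence must be in [0, 1]")


def _group_compositions(n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Base compositions for the host groups, spread over GC 35-65%.

    Groups are placed at evenly spaced GC contents (the dominant axis of
    real inter-genus compositional variation) with a small seeded skew
    between the two members of each base pair, so no two groups share a
    signature even at equal GC.
    """
    if n_groups == 1:
        gcs = np.array([0.5])
    else:
        gcs = np.linspace(0.35, 0.65, n_groups)
    comps = np.empty((n_groups, 4))
    for i, gc in enumerate(gcs):
        at_skew, gc_skew = rng.uniform(-0.05, 0.05, size=2)
        a = (1 - gc) / 2 + at_skew
        c = gc / 2 + gc_skew
        comps[i] = (a, c, gc - c, 1 - gc - a)
    if comps.min() <= 0.01:
        raise ValueError("degenerate group composition; reduce skew or group count")
    return comps


def _random_sequence(length: int, probs: np.ndarray, rng: np.random.Generator) -> str:
    idx = rng.choice(4, size=length, p=probs)
    return _BASE_ARR[idx].tobytes().decode("ascii")


def _markov1_sequence(length: int, trans: np.ndarray, rng: np.random.Generator) -> str:
    """Order-1 chain started from the uniform distribution."""
    cum = np.cumsum(trans, axis=1)
    u = rng.random(length)
    idx = np.empty(length, dtype=np.int8)
    state = int(rng.integers(4))
    for i in range(length):
        state = int(np.searchsorted(cum[state], u[i]))
        state = min(state, 3)
        idx[i] = state
    return _BASE_ARR[idx].tobytes().decode("ascii")


def _group_models(config: SyntheticConfig, rng: np.random.Generator):
    """Per-group sequence models: composition vectors, plus transition matrices at order 1."""
    comps = _group_compositions(config.n_groups, rng)
    if config.markov_order == 0:
        return comps, None
    # rows biased toward the group composition, with seeded row-wise noise
    trans = np.empty((config.n_groups, 4, 4))
    for g in range(config.n_groups):
        for s in range(4):
            row = comps[g] * rng.uniform(0.6, 1.4, size=4)
            trans[g, s] = row / row.sum()
    return comps, trans


def _draw_from_model(length: int, comp: np.ndarray, trans: np.ndarray | None, rng: np.random.Generator) -> str:
    if trans is None:
        return _random_sequence(length, comp, rng)
    return _markov1_sequence(length, trans, rng)


def make_host_groups(config: SyntheticConfig) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Generate host genomes for each group, plus optional outlier hosts.

    Returns (records, genome id -> group label). Outlier hosts (group
    label "outlier") get an extreme GC-80% composition far from every
    group, the kind of genome DBSCAN should leave unclustered.
    """
    rng = np.random.default_rng(config.seed)
    comps, trans = _group_models(config, rng)
    records: list[SequenceRecord] = []
    groups: dict[str, str] = {}
    for g in range(config.n_groups):
        label = f"group{g + 1}"
        for j in range(config.genomes_per_group):
            gid = f"host_g{g + 1}_{j + 1:03d}"
            seq = _draw_from_model(config.genome_length, comps[g], None if trans is None else trans[g], rng)
            records.append(SequenceRecord(id=gid, contigs=(seq,), role="host"))
            groups[gid] = label
    outlier_comp = np.array([0.08, 0.40, 0.40, 0.12])
    for j in range(config.n_outliers):
        gid = f"host_outlier_{j + 1:03d}"
        seq = _random_sequence(config.genome_length, outlier_comp, rng)
        records.append(SequenceRecord(id=gid, contigs=(seq,), role="host"))
        groups[gid] = "outlier"
    return records, groups


def insert_prophage(host: SequenceRecord, phage: SequenceRecord, position: int, contig_index: int = 0) -> SequenceRecord:
    """Splice the phage sequence into a host contig at *position*.

    Pure function: returns a modified copy (same id) and leaves the
    inputs untouched. By construction every k-window of the phage
    (k <= phage length) occurs in the product, so DSW(phage, product) = 0.
    """
    if not 0 <= contig_index < len(host.contigs):
        raise IndexError(f"contig index {contig_index} out of range for {host.id!r}")
    target = host.contigs[contig_index]
    if not 0 <= position <= len(target):
        raise ValueError(f"position {position} out of range [0, {len(target)}] in contig {contig_index} of {host.id!r}")
    phage_seq = "".join(phage.contigs)
    new_contig = target[:position] + phage_seq + target[position:]
    contigs = host.contigs[:contig_index] + (new_contig,) + host.contigs[contig_index + 1 :]
    return SequenceRecord(id=host.id, contigs=contigs, role=host.role)


def make_phages(
    config: SyntheticConfig,
    hosts: list[SequenceRecord],
    host_groups: dict[str, str],
) -> tuple[list[SequenceRecord], AssociationTable, list[SequenceRecord]]:
    """Generate lysogenic-like and lytic-like phages against existing hosts.

    Lysogenic-like phages are drawn from their group's composition
    (amelioration) and integrated as prophages into
    ``prophage_hosts_per_phage`` randomly chosen host strains of the
    group. Lytic-like phages mix the group composition with a
    phage-specific alien composition at weight ``composition_divergence``
    and are never integrated. Returns (phages, associations,
    updated hosts); the input host list is not modified.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    comps, trans = _group_models(config, np.random.default_rng(config.seed))

    group_labels = [f"group{g + 1}" for g in range(config.n_groups)]
    members: dict[str, list[int]] = {lab: [] for lab in group_labels}
    updated = list(hosts)
    for i, h in enumerate(updated):
        lab = host_groups.get(h.id)
        if lab in members:
            members[lab].append(i)

    phages: list[SequenceRecord] = []
    assoc_rows = []
    pending: dict[int, list[tuple[int, SequenceRecord]]] = {}

    for p in range(config.n_lysogenic):
        g = p % config.n_groups
        label = group_labels[g]
        pid = f"phage_lyso_{p + 1:03d}"
        seq = _draw_from_model(config.phage_length, comps[g], None if trans is None else trans[g], rng)
        phage = SequenceRecord(id=pid, contigs=(seq,), role="phage")
        phages.append(phage)
        assoc_rows.append((pid, "phage", label, "lysogenic"))
        idx_pool = members[label]
        n_carry = min(config.prophage_hosts_per_phage, len(idx_pool))
        if n_carry:
            for i in rng.choice(idx_pool, size=n_carry, replace=False):
                pos = int(rng.integers(0, len(updated[int(i)].contigs[0]) + 1))
                pending.setdefault(int(i), []).append((pos, phage))

    # Positions are chosen in original host coordinates; applying them from
    # highest to lowest keeps every prophage contiguous (a later insertion
    # can never split an earlier one).
    for i, insertions in pending.items():
        host = updated[i]
        for pos, phage in sorted(insertions, key=lambda t: t[0], reverse=True):
            host = insert_prophage(host, phage, pos)
        updated[i] = host

    alien_base = np.array([0.10, 0.15, 0.15, 0.60])
    for p in range(config.n_lytic):
        g = p % config.n_groups
        label = group_labels[g]
        pid = f"phage_lytic_{p + 1:03d}"
        alien = alien_base * rng.uniform(0.7, 1.3, size=4)
        alien = alien / alien.sum()
        mix = (1 - config.composition_divergence) * comps[g] + config.composition_divergence * alien
        seq = _random_sequence(config.phage_length, mix, rng)
        phages.append(SequenceRecord(id=pid, contigs=(seq,), role="phage"))
        assoc_rows.append((pid, "phage", label, "lytic"))

    assoc = AssociationTable(
        pd.DataFrame(assoc_rows, columns=["element_id", "role", "host_group", "lifestyle"])
    )
    return phages, assoc, updated


def make_disjoint_pair(
    k: int,
    lengths: tuple[int, int] = (10_000, 10_000),
    seed: int = 0,
) -> tuple[SequenceRecord, SequenceRecord]:
    """Two genomes guaranteed to share no k-word (DSW = 1 at this k).

    One genome is built over {A, C}, the other over {G, T}; every
    k-word of one then uses letters absent from the other. A final
    brute-force intersection of the two k-word sets verifies the
    guarantee before returning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if min(lengths) < k:
        raise ValueError(f"both lengths must be >= k={k}")
    rng = np.random.default_rng(seed)
    seq_a = "".join(np.array(["A", "C"])[rng.integers(0, 2, size=lengths[0])])
    seq_b = "".join(np.array(["G", "T"])[rng.integers(0, 2, size=lengths[1])])
    words_a = {seq_a[i : i + k] for i in range(len(seq_a) - k + 1)}
    words_b = {seq_b[i : i + k] for i in range(len(seq_b) - k + 1)}
    if words_a & words_b:
        raise RuntimeError("disjoint-pair construction failed verification")
    return (
        SequenceRecord(id="disjoint_a", contigs=(seq_a,), role="host"),
        SequenceRecord(id="disjoint_b", contigs=(seq_b,), role="host"),
    )


@dataclass
class SyntheticDataset:
    """One fully generated study: hosts (with prophages), phages, truth labels."""

    config: SyntheticConfig
    hosts: list[SequenceRecord]
    host_groups: dict[str, str]
    phages: list[SequenceRecord]
    associations: AssociationTable


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate hosts and phages in one call (the CLI `simulate` backend)."""
    hosts, groups = make_host_groups(config)
    phages, assoc, hosts_updated = make_phages(config, hosts, groups)
    return SyntheticDataset(
        config=config,
        hosts=hosts_updated,
        host_groups=groups,
        phages=phages,
        associations=assoc,
    )
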