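"""Life-cycle inference: group distances, ROC thresholding, classification.

The working premise: a temperate (lysogenic) phage ameliorates toward —
and often physically resides in — the genomes of its host group, so its
genomic distance to that group is short; an obligately lytic phage's
composition drifts freely and it shares no long exact words with host
chromosomes, so its distance is long. A distance threshold separating
the two classes is learned from labelled phage-host pairs by building
the ROC curve of the "lysogenic iff distance <= t" rule and taking the
candidate threshold closest to the ideal classifier at (FPR, TPR) =
(0, 1). The same distances rank phages by expected breadth of reactivity
with strains of a host group, and screen plasmids for cross-cluster
(horizontal-transfer-like) associations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from phagesig.exact_match import dsw_distance
from phagesig.host_clustering import HostCluster
from phagesig.io_formats import AssociationTable, SequenceRecord
from phagesig.kmer_signatures import KmerCounts, count_kmers, k4freq_distance, signature

METHODS = ("k4freq", "k14exact")
DEFAULT_K = {"k4freq": 4, "k14exact": 14}


@dataclass(frozen=True)
class GroupDistance:
    """Mean (+/- sample sd) distance of one element to all genomes of a host group."""

    element_id: str
    host_group: str
    method: str
    mean: float
    sd: float
    n_hosts: int
    min: float = math.nan

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_hosts < 1:
            raise ValueError("n_hosts must be >= 1")


@dataclass(frozen=True)
class ROCResult:
    """ROC curve over candidate thresholds of the rule `lysogenic iff d <= t`."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    best_threshold: float
    best_point: tuple[float, float]
    class_mean_midpoint: float


@dataclass(frozen=True)
class LifecycleCall:
    """Per-element verdict; lysogenic iff mean distance <= threshold."""

    element_id: str
    host_group: str
    method: str
    mean_distance: float
    threshold: float
    call: str


def _pair_distance(elem: KmerCounts, host: KmerCounts, method: str) -> float:
    if method == "k4freq":
        return k4freq_distance(signature(elem), signature(host))
    return dsw_distance(elem, host)


def _counts_for(records: Sequence[SequenceRecord], k: int, strand_mode: str) -> dict[str, KmerCounts]:
    out = {}
    for rec in records:
        c = count_kmers(rec, k=k, strand_mode=strand_mode)
        if c.total == 0:
            raise ValueError(f"genome {rec.id!r} has no countable {k}-mers")
        out[rec.id] = c
    return out


def distance_table(
    elements: Sequence[SequenceRecord],
    hosts: Sequence[SequenceRecord],
    method: str = "k4freq",
    k: int | None = None,
    strand_mode: str = "forward",
) -> pd.DataFrame:
    """All element x host pairwise distances as a tidy table.

    Counts each genome once, then evaluates every pair; columns are
    query_id, target_id, method, k, distance.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    k = DEFAULT_K[method] if k is None else k
    ecounts = _counts_for(elements, k, strand_mode)
    hcounts = _counts_for(hosts, k, strand_mode)
    if method == "k4freq":
        esigs = {i: signature(c) for i, c in ecounts.items()}
        hsigs = {i: signature(c) for i, c in hcounts.items()}
    rows = []
    for e in elements:
        for h in hosts:
            if method == "k4freq":
                d = k4freq_distance(esigs[e.id], hsigs[h.id])
            else:
                d = dsw_distance(ecounts[e.id], hcounts[h.id])
            rows.append((e.id, h.id, method, k, d))
    return pd.DataFrame(rows, columns=["query_id", "target_id", "method", "k", "distance"])


def group_mean_distance(
    element: SequenceRecord,
    hosts: Sequence[SequenceRecord],
    method: str = "k4freq",
    k: int | None = None,
    host_group: str = "",
    strand_mode: str = "forward",
) -> GroupDistance:
    """Distance of one element to every genome of a host group, summarized.

    The spread is the sample standard deviation (n-1 denominator), zero
    for a single-host group.
    """
    if len(hosts) == 0:
        raise ValueError("empty host group")
    table = distance_table([element], hosts, method=method, k=k, strand_mode=strand_mode)
    return summarize_distances(table, element.id, host_group or "group", method)


def summarize_distances(table: pd.DataFrame, element_id: str, host_group: str, method: str) -> GroupDistance:
    d = table.loc[table["query_id"] == element_id, "distance"].to_numpy()
    if d.size == 0:
        raise ValueError(f"no distances for element {element_id!r}")
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return GroupDistance(
        element_id=element_id,
        host_group=host_group,
        method=method,
        mean=float(d.mean()),
        sd=sd,
        n_hosts=int(d.size),
        min=float(d.min()),
    )


def roc_threshold(distances: Sequence[float], labels: Sequence[str]) -> ROCResult:
    """Learn the lytic/lysogenic distance threshold from labelled examples.

    Positive class is lysogenic (short distance); candidates are the
    midpoints between consecutive sorted unique distances plus sentinels
    below the minimum and above the maximum; AUC is the trapezoid area
    under the (FPR, TPR) curve; the best threshold minimizes the
    Euclidean distance to (0, 1), ties going to the smallest threshold.
    """
    d = np.asarray(distances, dtype=np.float64)
    lab = np.asarray(labels, dtype=object)
    if d.shape[0] != lab.shape[0]:
        raise ValueError("distances and labels length mismatch")
    bad = set(lab) - {"lytic", "lysogenic"}
    if bad:
        raise ValueError(f"unknown label(s): {sorted(bad)}")
    pos = lab == "lysogenic"
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: both lysogenic and lytic examples are required")

    u = np.unique(d)
    pad = max(u[-1] - u[0], abs(float(u[0])), 1e-6)
    candidates = np.concatenate(([u[0] - pad], (u[:-1] + u[1:]) / 2.0, [u[-1] + pad]))

    # predicted lysogenic when distance <= t
    tpr = np.array([(d[pos] <= t).mean() for t in candidates])
    fpr = np.array([(d[~pos] <= t).mean() for t in candidates])

    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))

    dist2 = fpr**2 + (1.0 - tpr) ** 2
    best_idx = int(np.lexsort((candidates, dist2))[0])

    return ROCResult(
        thresholds=candidates,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        best_threshold=float(candidates[best_idx]),
        best_point=(float(fpr[best_idx]), float(tpr[best_idx])),
        class_mean_midpoint=float((d[pos].mean() + d[~pos].mean()) / 2.0),
    )


def classify(gd: GroupDistance, threshold: float) -> LifecycleCall:
    """Hard lytic/lysogenic call: lysogenic iff mean distance <= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    call = "lysogenic" if gd.mean <= threshold else "lytic"
    return LifecycleCall(
        element_id=gd.element_id,
        host_group=gd.host_group,
        method=gd.method,
        mean_distance=gd.mean,
        threshold=threshold,
        call=call,
    )


def threshold_scale_warning(method: str, threshold: float) -> str | None:
    """Heuristic guard against mixing method-specific thresholds.

    k4freq distances live near 0 (threshold ~0.026 scale) while k14exact
    distances live near 1 (threshold ~0.955 scale); a threshold on the
    wrong side of 0.5 almost certainly belongs to the other method.
    """
    if method == "k4freq" and threshold > 0.5:
        return f"threshold {threshold} looks like a k14exact-scale value but method is k4freq"
    if method == "k14exact" and threshold <= 0.5:
        return f"threshold {threshold} looks like a k4freq-scale value but method is k14exact"
    return None


def reactivity_rank(
    group_distances: Sequence[GroupDistance],
    threshold: float | None = None,
    interactions: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Rank elements of one host group by ascending mean distance.

    Short distances flag candidate broadly-reactive phages; with a
    threshold, elements in the "lysogenic area" (mean <= threshold) are
    marked. Ties are broken by element id.
    """
    if not group_distances:
        raise ValueError("no group distances to rank")
    methods = {g.method for g in group_distances}
    if len(methods) > 1:
        raise ValueError(f"mixed methods in ranking: {sorted(methods)}")
    groups = {g.host_group for g in group_distances}
    if len(groups) > 1:
        raise ValueError(f"mixed host groups in ranking: {sorted(groups)}")
    rows = sorted(group_distances, key=lambda g: (g.mean, g.element_id))
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(rows) + 1),
            "element_id": [g.element_id for g in rows],
            "host_group": [g.host_group for g in rows],
            "method": [g.method for g in rows],
            "mean_distance": [g.mean for g in rows],
            "sd": [g.sd for g in rows],
            "n_hosts": [g.n_hosts for g in rows],
        }
    )
    if threshold is not None:
        df["below_threshold"] = df["mean_distance"] <= threshold
    if interactions is not None:
        df["observed_interactions"] = [interactions.get(e, 0) for e in df["element_id"]]
    return df


def association_screen(
    elements: Sequence[SequenceRecord],
    clusters: Sequence[HostCluster],
    hosts: Sequence[SequenceRecord],
    method: str = "k4freq",
    k: int | None = None,
    annotations: AssociationTable | None = None,
    strand_mode: str = "forward",
) -> pd.DataFrame:
    """Distance of every element to every host cluster, with HGT flags.

    One row per element x cluster (mean, sd, min over cluster members).
    When *annotations* supply each element's annotated cluster label,
    rows are marked associated/same-cluster, and a non-associated row
    whose mean falls below the associated-element mean of that cluster
    is flagged as a candidate horizontal transfer.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    k = DEFAULT_K[method] if k is None else k
    host_by_id = {h.id: h for h in hosts}
    for cl in clusters:
        missing = [m for m in cl.member_ids if m not in host_by_id]
        if missing:
            raise KeyError(f"cluster {cl.cluster_id} references unknown host(s): {missing}")
    cluster_names = {cl.cluster_id: (cl.label or f"cluster{cl.cluster_id}") for cl in clusters}
    if annotations is not None:
        known = set(cluster_names.values())
        for e in elements:
            try:
                g = annotations.host_group_of(e.id)
            except KeyError:
                continue
            if g not in known:
                raise KeyError(f"element {e.id!r} annotated to unknown cluster {g!r}")

    table = distance_table(elements, hosts, method=method, k=k, strand_mode=strand_mode)
    dist = table.set_index(["query_id", "target_id"])["distance"]

    rows = []
    for e in elements:
        annotated = None
        if annotations is not None:
            try:
                annotated = annotations.host_group_of(e.id)
            except KeyError:
                annotated = None
        for cl in clusters:
            d = np.array([dist[(e.id, m)] for m in cl.member_ids])
            name = cluster_names[cl.cluster_id]
            rows.append(
                {
                    "element_id": e.id,
                    "cluster": name,
                    "method": method,
                    "k": k,
                    "mean": float(d.mean()),
                    "sd": float(d.std(ddof=1)) if d.size > 1 else 0.0,
                    "min": float(d.min()),
                    "n_hosts": int(d.size),
                    "annotated_cluster": annotated,
                    "is_annotated": annotated == name,
                }
            )
    df = pd.DataFrame(rows)

    assoc_mean = (
        df.loc[df["is_annotated"]].groupby("cluster")["mean"].mean()
        if df["is_annotated"].any()
        else pd.Series(dtype=float)
    )
    df["candidate_hgt"] = [
        (not r.is_annotated)
        and r.cluster in assoc_mean.index
        and r.mean < assoc_mean[r.cluster]
        for r in df.itertuples()
    ]
    return df
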