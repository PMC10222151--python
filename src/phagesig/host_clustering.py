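"""Host-genome clustering on hexamer signatures (PCA + DBSCAN).

Bacterial genomes are embedded by their k = 6 relative-frequency
signatures, projected with PCA, and density-clustered with DBSCAN
(defaults eps = 0.50, MinPts = 10). Genomes falling in no dense region
are labelled noise and are normally dropped before phage/plasmid
screening, since a host group needs enough coherent members for a mean
distance to be meaningful.

The DBSCAN neighbourhood radius only has meaning on a fixed scale, so
by default each retained principal component is standardized to unit
variance before clustering (``scale="unit-variance"``); pass
``scale="none"`` to cluster on the raw PCA scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA

from phagesig.io_formats import SequenceRecord
from phagesig.kmer_signatures import count_kmers, signature

#: DBSCAN label for genomes in no dense region.
NOISE = -1


@dataclass(frozen=True)
class HostCluster:
    """One signature-coherent group of host genomes."""

    cluster_id: int
    member_ids: tuple[str, ...]
    label: str | None = None

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class ClusteringReport:
    """Outcome of one PCA + DBSCAN run over a host collection."""

    n_components_used: int
    explained_variance: np.ndarray
    eps: float
    min_pts: int
    scale: str
    clusters: list[HostCluster]
    noise_ids: tuple[str, ...]
    embedding: np.ndarray = field(repr=False)
    genome_ids: tuple[str, ...] = field(repr=False, default=())

    @property
    def n_noise(self) -> int:
        return len(self.noise_ids)

    @property
    def n_genomes(self) -> int:
        return sum(len(c) for c in self.clusters) + self.n_noise

    def membership(self) -> dict[str, int]:
        """genome id -> cluster id (NOISE for unclustered genomes)."""
        out = {gid: NOISE for gid in self.noise_ids}
        for cl in self.clusters:
            for gid in cl.member_ids:
                out[gid] = cl.cluster_id
        return out

    def to_dict(self) -> dict:
        return {
            "n_components_used": self.n_components_used,
            "explained_variance": [float(v) for v in self.explained_variance],
            "eps": self.eps,
            "min_pts": self.min_pts,
            "scale": self.scale,
            "clusters": [
                {"cluster_id": c.cluster_id, "label": c.label, "members": list(c.member_ids)}
                for c in self.clusters
            ],
            "noise": list(self.noise_ids),
        }


def hexamer_matrix(
    records: Sequence[SequenceRecord],
    k: int = 6,
    strand_mode: str = "forward",
) -> tuple[list[str], np.ndarray]:
    """Stack genome signatures into an (n_genomes, 4^k) matrix.

    Rows follow the input record order; columns follow the canonical
    lexicographic word order, so the matrix is bit-stable across runs.
    """
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for rec in records:
        counts = count_kmers(rec, k=k, strand_mode=strand_mode)
        if counts.total == 0:
            raise ValueError(f"genome {rec.id!r} has no countable {k}-mers")
        ids.append(rec.id)
        rows.append(signature(counts).frequencies)
    return ids, np.vstack(rows)


def _sign_fix(components: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each component so its largest-magnitude loading is positive."""
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1.0
            scores[:, i] *= -1.0
    return components, scores


def cluster_hosts(
    matrix: np.ndarray,
    genome_ids: Sequence[str],
    eps: float = 0.50,
    min_pts: int = 10,
    n_components: int = 2,
    scale: str = "unit-variance",
) -> ClusteringReport:
    """PCA-project signature rows and DBSCAN-cluster the embedding.

    Genomes are sorted by id before clustering so the partition does not
    depend on input order; clusters are numbered 0, 1, ... by decreasing
    size (ties by smallest member id). With fewer genomes than MinPts
    every genome is noise (a warning case, not an error).
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[0] != len(genome_ids):
        raise ValueError("matrix rows must match genome_ids")
    if scale not in ("unit-variance", "none"):
        raise ValueError(f"unknown scale mode {scale!r}")
    order = np.argsort(np.asarray(genome_ids, dtype=object))
    ids_sorted = [genome_ids[i] for i in order]
    mat = matrix[order]

    n_components = min(n_components, mat.shape[0], mat.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(mat)
    _, scores = _sign_fix(pca.components_, scores)

    embedding = scores.copy()
    if scale == "unit-variance":
        sd = embedding.std(axis=0)
        sd[sd == 0] = 1.0
        embedding = embedding / sd

    if mat.shape[0] < min_pts:
        labels = np.full(mat.shape[0], NOISE)
    else:
        labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(embedding)

    clusters: list[HostCluster] = []
    for raw_id in sorted(set(labels) - {NOISE}):
        members = tuple(ids_sorted[i] for i in np.flatnonzero(labels == raw_id))
        clusters.append(HostCluster(cluster_id=int(raw_id), member_ids=members))
    # renumber by decreasing size, ties broken by smallest member id
    clusters.sort(key=lambda c: (-len(c), c.member_ids[0]))
    clusters = [
        HostCluster(cluster_id=i, member_ids=c.member_ids, label=c.label)
        for i, c in enumerate(clusters)
    ]
    noise_ids = tuple(ids_sorted[i] for i in np.flatnonzero(labels == NOISE))

    return ClusteringReport(
        n_components_used=n_components,
        explained_variance=pca.explained_variance_ratio_.copy(),
        eps=eps,
        min_pts=min_pts,
        scale=scale,
        clusters=clusters,
        noise_ids=noise_ids,
        embedding=embedding,
        genome_ids=tuple(ids_sorted),
    )


def label_clusters(report: ClusteringReport, labels: dict[int, str]) -> ClusteringReport:
    """Attach user-supplied names (e.g. genus-style labels) to clusters."""
    report.clusters = [
        HostCluster(cluster_id=c.cluster_id, member_ids=c.member_ids, label=labels.get(c.cluster_id, c.label))
        for c in report.clusters
    ]
    return report


def drop_noise(
    report: ClusteringReport,
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], list[str]]:
    """Restrict *records* to non-noise cluster members.

    Returns (kept records, noise ids) so the caller can log what was
    removed; an all-noise clustering yields an empty collection.
    """
    keep = {gid for c in report.clusters for gid in c.member_ids}
    kept = [r for r in records if r.id in keep]
    noise = [r.id for r in records if r.id not in keep]
    return kept, noise
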