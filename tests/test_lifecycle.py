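"""Group distances, ROC thresholding, classification, ranking, screening."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from phagesig import (
    GroupDistance,
    SequenceRecord,
    association_screen,
    classify,
    group_mean_distance,
    reactivity_rank,
    roc_threshold,
)
from phagesig.host_clustering import HostCluster
from phagesig.io_formats import AssociationTable
from phagesig.lifecycle import distance_table

import pandas as pd

from conftest import random_dna


def _gd(element="p", mean=0.02, group="g", method="k4freq", **kw):
    return GroupDistance(element_id=element, host_group=group, method=method, mean=mean, sd=0.0, n_hosts=1, **kw)


# --- group mean distances -------------------------------------------------

def test_group_mean_matches_direct_summation():
    rng = np.random.default_rng(12)
    phage = SequenceRecord("p", (random_dna(rng, 2_000),), role="phage")
    hosts = [SequenceRecord(f"h{i}", (random_dna(rng, 5_000),)) for i in range(4)]
    gd = group_mean_distance(phage, hosts, method="k4freq", host_group="g")
    table = distance_table([phage], hosts, method="k4freq")
    d = table["distance"].to_numpy()
    assert gd.mean == pytest.approx(d.sum() / len(d), abs=1e-15)
    assert gd.sd == pytest.approx(np.sqrt(((d - d.mean()) ** 2).sum() / (len(d) - 1)), abs=1e-15)
    assert gd.n_hosts == 4
    assert gd.min == pytest.approx(d.min(), abs=0)


def test_group_mean_single_host_sd_zero():
    rng = np.random.default_rng(13)
    phage = SequenceRecord("p", (random_dna(rng, 1_000),), role="phage")
    host = SequenceRecord("h", (random_dna(rng, 3_000),))
    gd = group_mean_distance(phage, [host], method="k14exact", k=8)
    assert gd.sd == 0.0
    assert gd.n_hosts == 1


def test_group_mean_empty_group_rejected():
    phage = SequenceRecord("p", ("ACGTACGT",), role="phage")
    with pytest.raises(ValueError, match="empty host group"):
        group_mean_distance(phage, [])


def test_distance_table_schema_and_cardinality():
    rng = np.random.default_rng(14)
    elements = [SequenceRecord(f"p{i}", (random_dna(rng, 500),), role="phage") for i in range(3)]
    hosts = [SequenceRecord(f"h{i}", (random_dna(rng, 1_500),)) for i in range(2)]
    table = distance_table(elements, hosts, method="k14exact", k=6)
    assert list(table.columns) == ["query_id", "target_id", "method", "k", "distance"]
    assert len(table) == 6
    assert (table["k"] == 6).all()
    assert table["distance"].between(0, 1).all()


# --- ROC thresholding -----------------------------------------------------

def test_roc_perfect_separation_by_hand():
    roc = roc_threshold([0.01, 0.02, 0.04, 0.05], ["lysogenic", "lysogenic", "lytic", "lytic"])
    assert roc.auc == 1.0
    assert roc.best_threshold == pytest.approx(0.03)
    assert roc.best_point == (0.0, 1.0)
    assert roc.class_mean_midpoint == pytest.approx((0.015 + 0.045) / 2)


def test_roc_identical_distance_multisets_auc_half():
    d = [0.01, 0.02, 0.03, 0.01, 0.02, 0.03]
    lab = ["lysogenic"] * 3 + ["lytic"] * 3
    roc = roc_threshold(d, lab)
    assert roc.auc == pytest.approx(0.5)


def _pair_count_auc(distances, labels):
    """Mann-Whitney probability that a lysogenic distance < a lytic one."""
    lyso = [d for d, l in zip(distances, labels) if l == "lysogenic"]
    lytic = [d for d, l in zip(distances, labels) if l == "lytic"]
    wins = sum((a < b) + 0.5 * (a == b) for a, b in itertools.product(lyso, lytic))
    return wins / (len(lyso) * len(lytic))


def test_roc_auc_matches_pair_counting_oracle_and_sklearn():
    rng = np.random.default_rng(21)
    for _ in range(10):
        d = np.round(rng.random(30), 2)  # duplicates likely
        lab = np.where(rng.random(30) < 0.5, "lysogenic", "lytic")
        if len(set(lab)) < 2:
            continue
        roc = roc_threshold(d, lab)
        assert roc.auc == pytest.approx(_pair_count_auc(d, lab), abs=1e-12)
        # independent library cross-check: score = -distance for lysogenic-positive
        skl = roc_auc_score((lab == "lysogenic").astype(int), -d)
        assert roc.auc == pytest.approx(skl, abs=1e-12)


def test_roc_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(22)
    d = rng.random(40)
    lab = np.where(rng.random(40) < 0.4, "lysogenic", "lytic")
    base = roc_threshold(d, lab).auc
    assert roc_threshold(np.exp(3 * d), lab).auc == pytest.approx(base, abs=1e-12)
    assert roc_threshold(d**3 + 5, lab).auc == pytest.approx(base, abs=1e-12)


def test_roc_single_class_rejected():
    with pytest.raises(ValueError, match="ROC undefined"):
        roc_threshold([0.1, 0.2], ["lytic", "lytic"])


def test_roc_best_threshold_found_by_exhaustive_scan():
    rng = np.random.default_rng(23)
    d = np.concatenate([rng.normal(0.02, 0.006, 25).clip(0.001), rng.normal(0.04, 0.008, 25).clip(0.001)])
    lab = ["lysogenic"] * 25 + ["lytic"] * 25
    roc = roc_threshold(d, lab)
    pos = np.array(lab) == "lysogenic"

    def point(t):
        return ((d[~pos] <= t).mean(), (d[pos] <= t).mean())

    best = min(
        roc.thresholds,
        key=lambda t: (point(t)[0] ** 2 + (1 - point(t)[1]) ** 2, t),
    )
    assert roc.best_threshold == best


# --- classification -------------------------------------------------------

@pytest.mark.parametrize(
    "mean,threshold,expected",
    [
        (0.019, 0.026, "lysogenic"),
        (0.030, 0.026, "lytic"),
        (0.026, 0.026, "lysogenic"),  # boundary goes to lysogenic
    ],
)
def test_classify_threshold_rule(mean, threshold, expected):
    call = classify(_gd(mean=mean), threshold)
    assert call.call == expected
    assert call.threshold == threshold


def test_classify_monotone_in_distance():
    calls = [classify(_gd(mean=m), 0.026).call for m in np.linspace(0.001, 0.1, 50)]
    flips = [i for i in range(1, 50) if calls[i] != calls[i - 1]]
    assert calls[0] == "lysogenic" and calls[-1] == "lytic"
    assert len(flips) == 1  # lysogenic never reappears past the threshold


def test_classify_invalid_threshold_rejected():
    with pytest.raises(ValueError):
        classify(_gd(), 0.0)


# --- reactivity ranking ---------------------------------------------------

def test_reactivity_rank_sorts_and_flags():
    gds = [_gd("A", 0.03), _gd("B", 0.01), _gd("C", 0.02)]
    df = reactivity_rank(gds, threshold=0.026, interactions={"B": 9, "A": 1})
    assert list(df["element_id"]) == ["B", "C", "A"]
    assert list(df["rank"]) == [1, 2, 3]
    assert list(df["below_threshold"]) == [True, True, False]
    assert list(df["observed_interactions"]) == [9, 0, 1]


def test_reactivity_rank_ties_break_by_element_id():
    df = reactivity_rank([_gd("z", 0.02), _gd("a", 0.02)])
    assert list(df["element_id"]) == ["a", "z"]


def test_reactivity_rank_mixed_methods_rejected():
    with pytest.raises(ValueError, match="mixed methods"):
        reactivity_rank([_gd("A", method="k4freq"), _gd("B", method="k14exact")])


# --- association screening ------------------------------------------------

@pytest.fixture(scope="module")
def screen_setup():
    rng = np.random.default_rng(31)
    hosts = [SequenceRecord(f"h{i}", (random_dna(rng, 4_000),)) for i in range(5)]
    clusters = [
        HostCluster(cluster_id=0, member_ids=("h0", "h1", "h2"), label="cl0"),
        HostCluster(cluster_id=1, member_ids=("h3",), label="cl1"),
        HostCluster(cluster_id=2, member_ids=("h4",), label="cl2"),
    ]
    # e0/e1 random plasmids annotated to cl0; e2 is annotated to cl0 but is a
    # verbatim chunk of the foreign cluster cl1's host -> k14exact distance 0
    # there; e3 is cl1's own (random) plasmid, establishing cl1's associated mean.
    elements = [
        SequenceRecord("e0", (random_dna(rng, 1_000),), role="plasmid"),
        SequenceRecord("e1", (random_dna(rng, 1_000),), role="plasmid"),
        SequenceRecord("e2", (hosts[3].contigs[0][500:1_800],), role="plasmid"),
        SequenceRecord("e3", (random_dna(rng, 1_000),), role="plasmid"),
    ]
    annotations = AssociationTable(
        pd.DataFrame(
            [
                ("e0", "plasmid", "cl0", None),
                ("e1", "plasmid", "cl0", None),
                ("e2", "plasmid", "cl0", None),
                ("e3", "plasmid", "cl1", None),
            ],
            columns=["element_id", "role", "host_group", "lifestyle"],
        )
    )
    return elements, clusters, hosts, annotations


def test_screen_cardinality_and_groupby_oracle(screen_setup):
    elements, clusters, hosts, annotations = screen_setup
    df = association_screen(elements, clusters, hosts, method="k14exact", k=14, annotations=annotations)
    assert len(df) == len(elements) * len(clusters)
    # independent recomputation of one cell from the raw pairwise table
    raw = distance_table(elements, hosts, method="k14exact", k=14)
    cell = raw[(raw["query_id"] == "e0") & raw["target_id"].isin(["h0", "h1", "h2"])]["distance"]
    got = df[(df["element_id"] == "e0") & (df["cluster"] == "cl0")].iloc[0]
    assert got["mean"] == pytest.approx(cell.mean(), abs=1e-15)
    assert got["is_annotated"]


def test_screen_flags_foreign_cluster_insertion(screen_setup):
    elements, clusters, hosts, annotations = screen_setup
    df = association_screen(elements, clusters, hosts, method="k14exact", k=14, annotations=annotations)
    row = df[(df["element_id"] == "e2") & (df["cluster"] == "cl1")].iloc[0]
    assert row["min"] == 0.0
    assert row["mean"] == 0.0
    assert row["candidate_hgt"]
    # annotated rows are never HGT-flagged
    assert not df[df["is_annotated"]]["candidate_hgt"].any()


def test_screen_unknown_annotation_cluster_rejected(screen_setup):
    elements, clusters, hosts, _ = screen_setup
    bad = AssociationTable(
        pd.DataFrame([("e0", "plasmid", "nope", None)], columns=["element_id", "role", "host_group", "lifestyle"])
    )
    with pytest.raises(KeyError, match="nope"):
        association_screen(elements, clusters, hosts, annotations=bad)


def test_screen_cluster_with_unknown_host_rejected(screen_setup):
    elements, _, hosts, _ = screen_setup
    bad = [HostCluster(cluster_id=0, member_ids=("ghost",))]
    with pytest.raises(KeyError, match="ghost"):
        association_screen(elements, bad, hosts)
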