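"""Map integration, Table-style statistics, multi-locus classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from clovermap.integrate import (classify_multilocus, infer_homeologs,
                                 integrate, map_stats)


def _map(group, ids, pos, seg="biparental", suffix=""):
    return pd.DataFrame({
        "group": group, "locus_id": [i + suffix for i in ids],
        "marker_id": ids, "position_cm": pos,
        "seg_class": seg, "distorted": False})


def test_identical_parental_maps_integrate_to_themselves():
    ids = [f"A{k}" for k in range(6)]
    pos = [0.0, 5.0, 12.0, 20.0, 31.0, 40.0]
    m1 = _map("P1-LG1", ids, pos, suffix="_P1")
    m2 = _map("P2-LG1", ids, pos, suffix="_P2")
    res = integrate(m1, m2)
    assert len(res.fallback) == 0
    out = res.map_df
    assert list(out["locus_id"]) == ids  # anchors merged, emitted once
    np.testing.assert_allclose(out["position_cm"], pos, atol=1e-9)


def test_lg6a_style_fallback_formula():
    """2 shared anchors only: n = 24 + 22 - 2 = 44 loci and length =
    (97.6 + 120.5) / 2 = 109.05 cM by the fallback formula."""
    ids1 = [f"A{k}" for k in range(24)]
    ids2 = [f"B{k}" for k in range(22)]
    # two shared bi-parental anchors, everything else parent-specific
    ids2[0], ids2[1] = ids1[0], ids1[1]
    pos1 = np.linspace(0, 97.6, 24)
    pos2 = np.linspace(0, 120.5, 22)
    seg1 = ["biparental" if i in (ids1[0], ids1[1]) else "female"
            for i in ids1]
    seg2 = ["biparental" if i in (ids1[0], ids1[1]) else "male"
            for i in ids2]
    m1 = _map("P1-LG6a", ids1, pos1, seg=seg1)
    m1.loc[m1.seg_class == "biparental", "locus_id"] += "_P1"
    m2 = _map("P2-LG6a", ids2, pos2, seg=seg2)
    m2.loc[m2.seg_class == "biparental", "locus_id"] += "_P2"
    res = integrate(m1, m2, min_anchors=3)
    assert len(res.fallback) == 1
    fb = res.fallback.iloc[0]
    assert fb.n_loci == 44
    assert fb.length_cm == pytest.approx(109.05, abs=1e-9)


def test_integrated_positions_track_truth(small_dataset):
    from clovermap.config import PipelineConfig
    from clovermap.pipeline import _build_parent_map
    from clovermap.testcross import split_parental
    from tests.conftest import strip_suffix

    table, truth = small_dataset
    cfg = PipelineConfig()
    p1, p2 = split_parental(table)
    map1, _ = _build_parent_map(p1, cfg, "P1")
    map2, _ = _build_parent_map(p2, cfg, "P2")
    res = integrate(map1, map2)
    tru = truth.loci.set_index("locus_id")
    for g, sub in res.map_df.groupby("group"):
        if len(sub) < 5:
            continue
        tpos = [tru.loc[strip_suffix(l), "pos_cm"] for l in sub["locus_id"]]
        rho = abs(spearmanr(sub["position_cm"], tpos).statistic)
        assert rho >= 0.99, g


def test_conservation_of_locus_counts(small_dataset):
    from clovermap.config import PipelineConfig
    from clovermap.pipeline import _build_parent_map
    from clovermap.testcross import split_parental

    table, truth = small_dataset
    cfg = PipelineConfig()
    p1, p2 = split_parental(table)
    map1, _ = _build_parent_map(p1, cfg, "P1")
    map2, _ = _build_parent_map(p2, cfg, "P2")
    res = integrate(map1, map2)
    for r in res.correspondence.itertuples():
        sub = res.map_df[res.map_df["group"] == r.group_p1]
        if not len(sub):  # fallback group
            continue
        n1 = (map1["group"] == r.group_p1).sum()
        n2 = (map2["group"] == r.group_p2).sum()
        n_shared = (sub["locus_id"].map(
            lambda l: not l.endswith(("_P1", "_P2")))
            & (sub["seg_class"] == "biparental")).sum()
        assert len(sub) == n1 + n2 - n_shared


# --- map statistics --------------------------------------------------------

def test_map_stats_density_matches_printed_table_convention():
    """Totals behave like the study tables: 1059 loci / 2322.9 cM -> 2.19
    cM per locus, and 1743 / 2511.3 -> 1.44."""
    rows = []
    for k in range(1059):
        rows.append(("LG1", f"l{k}", k * (2322.9 / 1058)))
    df = pd.DataFrame(rows, columns=["group", "locus_id", "position_cm"])
    df["marker_id"] = df["locus_id"]
    df["seg_class"] = "female"
    df["distorted"] = False
    stats = map_stats(df)
    total = stats[stats.group == "Total"].iloc[0]
    assert total.n_loci == 1059
    assert total.length_cm == pytest.approx(2322.9, abs=0.01)
    assert total.density == pytest.approx(2.19, abs=0.005)
    assert 2511.3 / 1743 == pytest.approx(1.44, abs=0.005)


def test_single_locus_group_stats_degenerate():
    df = pd.DataFrame({"group": ["LG9"], "locus_id": ["only"],
                       "marker_id": ["only"], "position_cm": [0.0],
                       "seg_class": ["female"], "distorted": [False]})
    stats = map_stats(df)
    row = stats[stats.group == "LG9"].iloc[0]
    assert row.length_cm == 0.0 and row.largest_gap_cm == 0.0


def test_largest_gap_reports_flanking_pair():
    df = pd.DataFrame({"group": "LG1", "locus_id": list("abc"),
                       "marker_id": list("abc"),
                       "position_cm": [0.0, 2.0, 21.1],
                       "seg_class": "female", "distorted": False})
    stats = map_stats(df)
    row = stats[stats.group == "LG1"].iloc[0]
    assert row.largest_gap_cm == pytest.approx(19.1)
    assert row.largest_gap_pair == "b|c"


def test_fallback_groups_contribute_to_totals():
    df = pd.DataFrame({"group": "LG1", "locus_id": list("ab"),
                       "marker_id": list("ab"), "position_cm": [0.0, 10.0],
                       "seg_class": "female", "distorted": False})
    fb = pd.DataFrame([("LG6a", 44, 109.05, 2)],
                      columns=["group", "n_loci", "length_cm", "n_shared"])
    stats = map_stats(df, fallback=fb)
    total = stats[stats.group == "Total"].iloc[0]
    assert total.n_loci == 46
    assert total.length_cm == pytest.approx(119.05)
    fbrow = stats[stats.group == "LG6a"].iloc[0]
    assert fbrow.density == pytest.approx(109.05 / 44)


# --- homeologs and multi-locus classes ------------------------------------

def test_homeolog_pairing_prefers_more_shared_markers():
    df = pd.DataFrame({
        "group": ["LG1a"] * 5 + ["LG1b"] * 5 + ["LG2a"],
        "locus_id": [f"m{k}a" for k in range(5)]
        + [f"m{k}b" for k in range(5)] + ["m0c"],
        "marker_id": [f"m{k}" for k in range(5)] * 2 + ["m0"],
        "position_cm": 0.0, "seg_class": "female", "distorted": False})
    pairing = infer_homeologs(df)
    assert len(pairing) == 1
    row = pairing.iloc[0]
    assert {row.group_a, row.group_b} == {"LG1a", "LG1b"}
    assert row.n_shared_markers == 5


def test_no_multilocus_markers_empty_pairing(caplog):
    df = pd.DataFrame({"group": ["LG1a", "LG2a"], "locus_id": ["x", "y"],
                       "marker_id": ["x", "y"], "position_cm": 0.0,
                       "seg_class": "female", "distorted": False})
    pairing = infer_homeologs(df)
    assert len(pairing) == 0


def test_multilocus_type_and_location_classes():
    integrated = pd.DataFrame({
        "group": ["LG3a", "LG3b", "LG4a", "LG4a", "LG1a", "LG2a"],
        "locus_id": ["w1a", "w1b", "w2a", "w2b", "w3", "w4"],
        "marker_id": ["w1", "w1", "w2", "w2", "w3", "w4"],
        "position_cm": [0, 0, 0, 5, 0, 0],
        "seg_class": ["female"] * 4 + ["biparental", "biparental"],
        "distorted": False})
    pairing = pd.DataFrame([("LG3a", "LG3b", 3)],
                           columns=["group_a", "group_b",
                                    "n_shared_markers"])
    p1 = pd.DataFrame({"group": ["P1-LG1"], "locus_id": ["w3_P1"],
                       "marker_id": ["w3"], "position_cm": [0.0],
                       "seg_class": ["biparental"], "distorted": [False]})
    p2 = pd.DataFrame({"group": ["P2-LG9"], "locus_id": ["w3_P2"],
                       "marker_id": ["w3"], "position_cm": [0.0],
                       "seg_class": ["biparental"], "distorted": [False]})
    corr = pd.DataFrame([("P1-LG1", "P2-LG2", 5)],
                        columns=["group_p1", "group_p2", "n_anchors"])
    bands = {"w1": 2, "w2": 2, "w3": 1, "w4": 1}
    out = classify_multilocus(p1, p2, integrated, bands, pairing, corr)
    out = out.set_index("marker_id")
    assert out.loc["w1", "location_class"] == "homeologous"
    assert bool(out.loc["w1", "type_i"])
    assert out.loc["w2", "location_class"] == "same"
    # w3 is bi-parental with placements on non-corresponding groups: Type II
    assert bool(out.loc["w3", "type_ii"])
    assert not bool(out.loc["w4", "type_ii"])
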