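"""Integration of the two parental-specific maps and map statistics.

Bi-parental loci appear on both parental maps (as locus_id + '_P1'/'_P2')
and serve as anchors: corresponding groups are matched by shared anchors,
each parental map is rescaled by monotone piecewise-linear interpolation
through the mean anchor positions, and the rescaled loci are merged.  A
group with fewer than ``min_anchors`` shared loci cannot be integrated and
is reported with the fallback statistics
n = n_P1 + n_P2 - n_shared and length = mean of the parental lengths.

Also computes per-group map statistics (locus count, length, density =
length/n, distortion %, largest gap), multi-locus Type I/II classification,
and homeologous-group inference from shared multi-locus marker names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ssr import round_half_up

log = logging.getLogger(__name__)

__all__ = [
    "IntegratedMap",
    "integrate",
    "map_stats",
    "classify_multilocus",
    "infer_homeologs",
]

_ANCHOR_SUFFIXES = ("_P1", "_P2")


def _base_id(locus_id: str) -> str:
    for suf in _ANCHOR_SUFFIXES:
        if locus_id.endswith(suf):
            return locus_id[: -len(suf)]
    return locus_id


@dataclass
class IntegratedMap:
    """Integrated map plus fallback statistics for non-integrable groups."""

    map_df: pd.DataFrame              # group, locus_id, marker_id, position_cm,
                                      # seg_class, distorted, origin
    fallback: pd.DataFrame            # group, n_loci, length_cm, n_shared
    correspondence: pd.DataFrame      # group_p1, group_p2, n_anchors


def _match_groups(map_p1: pd.DataFrame, map_p2: pd.DataFrame) -> pd.DataFrame:
    """Greedy 1:1 correspondence between parental groups by shared anchors."""
    a1 = map_p1[map_p1["seg_class"] == "biparental"].copy()
    a2 = map_p2[map_p2["seg_class"] == "biparental"].copy()
    a1["base"] = a1["locus_id"].map(_base_id)
    a2["base"] = a2["locus_id"].map(_base_id)
    counts = (a1.merge(a2, on="base", suffixes=("_p1", "_p2"))
              .groupby(["group_p1", "group_p2"]).size().reset_index(name="n"))
    counts = counts.sort_values(["n", "group_p1", "group_p2"],
                                ascending=[False, True, True], kind="mergesort")
    used1: set[str] = set()
    used2: set[str] = set()
    rows = []
    for r in counts.itertuples():
        if r.group_p1 in used1 or r.group_p2 in used2:
            continue
        used1.add(r.group_p1)
        used2.add(r.group_p2)
        rows.append((r.group_p1, r.group_p2, int(r.n)))
    return pd.DataFrame(rows, columns=["group_p1", "group_p2", "n_anchors"])


def _interp(x: np.ndarray, xa: np.ndarray, ya: np.ndarray) -> np.ndarray:
    """Piecewise-linear through anchors with linear end extrapolation."""
    y = np.interp(x, xa, ya)
    if len(xa) >= 2:
        lo_slope = (ya[1] - ya[0]) / max(xa[1] - xa[0], 1e-9)
        hi_slope = (ya[-1] - ya[-2]) / max(xa[-1] - xa[-2], 1e-9)
        left = x < xa[0]
        right = x > xa[-1]
        y[left] = ya[0] + (x[left] - xa[0]) * lo_slope
        y[right] = ya[-1] + (x[right] - xa[-1]) * hi_slope
    return y


def integrate(map_p1: pd.DataFrame, map_p2: pd.DataFrame,
              min_anchors: int = 3) -> IntegratedMap:
    """Combine two parental maps through their shared bi-parental anchors.

    Parental group pairs with >= ``min_anchors`` shared anchors are merged:
    the P2 coordinate axis is flipped if the anchor orders disagree, each
    locus is transformed through the anchor-mean piecewise-linear map, and
    anchors are emitted once at their mean position.  Pairs with fewer
    anchors go to ``fallback``; groups with no correspondence pass through
    unchanged with a warning.
    """
    corr = _match_groups(map_p1, map_p2)
    out_rows: list[pd.DataFrame] = []
    fb_rows = []
    matched1 = set(corr["group_p1"])
    matched2 = set(corr["group_p2"])

    for r in corr.itertuples():
        sub1 = map_p1[map_p1["group"] == r.group_p1].copy()
        sub2 = map_p2[map_p2["group"] == r.group_p2].copy()
        sub1["base"] = sub1["locus_id"].map(_base_id)
        sub2["base"] = sub2["locus_id"].map(_base_id)
        shared = (sub1[sub1["seg_class"] == "biparental"]
                  .merge(sub2[sub2["seg_class"] == "biparental"],
                         on="base", suffixes=("_1", "_2")))
        n_sh = len(shared)
        if n_sh < min_anchors:
            n_int = len(sub1) + len(sub2) - n_sh
            length = (sub1["position_cm"].max() + sub2["position_cm"].max()) / 2.0
            fb_rows.append((r.group_p1, int(n_int), float(length), n_sh))
            log.warning("group %s/%s: only %d shared anchors; fallback "
                        "statistics reported", r.group_p1, r.group_p2, n_sh)
            continue
        p1 = shared["position_cm_1"].to_numpy(float)
        p2 = shared["position_cm_2"].to_numpy(float)
        # align orientation of P2 to P1 via anchor order correlation
        if len(p1) >= 2 and np.corrcoef(p1, p2)[0, 1] < 0:
            L2 = sub2["position_cm"].max()
            sub2["position_cm"] = L2 - sub2["position_cm"]
            p2 = L2 - p2
        mean_pos = (p1 + p2) / 2.0
        order = np.argsort(p1, kind="mergesort")
        xa1, xa2, ya = p1[order], p2[order], mean_pos[order]
        # anchor-order conflicts collapse onto the running maximum of means
        ya = np.maximum.accumulate(ya)
        xa2_s = np.sort(xa2)  # P2 interp needs increasing knots

        t1 = _interp(sub1["position_cm"].to_numpy(float), xa1, ya)
        t2 = _interp(sub2["position_cm"].to_numpy(float), xa2_s,
                     np.maximum.accumulate(ya[np.argsort(xa2, kind="mergesort")]))
        sub1 = sub1.assign(position_cm=t1, origin="P1")
        sub2 = sub2.assign(position_cm=t2, origin="P2")
        shared_bases = set(shared["base"])
        is_anchor1 = sub1["base"].isin(shared_bases) & (sub1["seg_class"] == "biparental")
        is_anchor2 = sub2["base"].isin(shared_bases) & (sub2["seg_class"] == "biparental")
        anchors = sub1[is_anchor1].copy()
        anchor_mean = dict(zip(shared["base"], (p1 + p2) / 2.0))
        anchors["position_cm"] = anchors["base"].map(anchor_mean)
        anchors["locus_id"] = anchors["base"]
        anchors["origin"] = "biparental"
        merged = pd.concat([anchors, sub1[~is_anchor1], sub2[~is_anchor2]],
                           ignore_index=True)
        merged["group"] = r.group_p1
        merged["position_cm"] -= merged["position_cm"].min()
        merged = merged.sort_values(["position_cm", "locus_id"],
                                    kind="mergesort").reset_index(drop=True)
        out_rows.append(merged.drop(columns=["base"]))

    for g in sorted(set(map_p1["group"]) - matched1):
        log.warning("group %s (P1) has no corresponding P2 group; passed "
                    "through unchanged", g)
        sub = map_p1[map_p1["group"] == g].copy()
        sub["origin"] = "P1"
        out_rows.append(sub)
    for g in sorted(set(map_p2["group"]) - matched2):
        log.warning("group %s (P2) has no corresponding P1 group; passed "
                    "through unchanged", g)
        sub = map_p2[map_p2["group"] == g].copy()
        sub["origin"] = "P2"
        out_rows.append(sub)

    cols = ["group", "locus_id", "marker_id", "position_cm", "seg_class",
            "distorted", "origin"]
    map_df = (pd.concat(out_rows, ignore_index=True)[cols]
              if out_rows else pd.DataFrame(columns=cols))
    fallback = pd.DataFrame(fb_rows, columns=["group", "n_loci", "length_cm",
                                              "n_shared"])
    return IntegratedMap(map_df=map_df, fallback=fallback, correspondence=corr)


def map_stats(map_df: pd.DataFrame,
              fallback: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-group and total map statistics.

    density = length / n loci (cM per locus, the printed-table convention);
    totals sum lengths and counts, with density and distortion re-derived
    from the totals (count-weighted).  Fallback groups contribute their
    substituted n and length.  The largest gap column reports the flanking
    locus pair.
    """
    rows = []
    for g, sub in map_df.groupby("group", sort=True):
        sub = sub.sort_values("position_cm", kind="mergesort")
        n = len(sub)
        length = float(sub["position_cm"].max() - sub["position_cm"].min())
        if n >= 2:
            gaps = np.diff(sub["position_cm"].to_numpy())
            gi = int(np.argmax(gaps))
            gap = float(gaps[gi])
            gap_pair = (f"{sub['locus_id'].iloc[gi]}|"
                        f"{sub['locus_id'].iloc[gi + 1]}")
        else:
            length, gap, gap_pair = 0.0, 0.0, ""
        n_dist = int(sub["distorted"].sum())
        rows.append(dict(group=g, n_loci=n, length_cm=length,
                         density=length / n if n else float("nan"),
                         distortion_pct=100.0 * n_dist / n if n else float("nan"),
                         n_distorted=n_dist,
                         largest_gap_cm=gap, largest_gap_pair=gap_pair))
    df = pd.DataFrame(rows)
    if fallback is not None and len(fallback):
        for fb in fallback.itertuples():
            df = pd.concat([df, pd.DataFrame([dict(
                group=fb.group, n_loci=int(fb.n_loci),
                length_cm=float(fb.length_cm),
                density=fb.length_cm / fb.n_loci,
                distortion_pct=float("nan"), n_distorted=0,
                largest_gap_cm=float("nan"), largest_gap_pair="(fallback)",
            )])], ignore_index=True)
        df = df.sort_values("group", kind="mergesort").reset_index(drop=True)
    tot_n = int(df["n_loci"].sum())
    tot_len = float(df["length_cm"].sum())
    known = df[df["distortion_pct"].notna()]
    tot_dist = (100.0 * known["n_distorted"].sum() / known["n_loci"].sum()
                if len(known) and known["n_loci"].sum() else float("nan"))
    total = dict(group="Total", n_loci=tot_n, length_cm=tot_len,
                 density=tot_len / tot_n if tot_n else float("nan"),
                 distortion_pct=tot_dist,
                 n_distorted=int(known["n_distorted"].sum()),
                 largest_gap_cm=df["largest_gap_cm"].max(),
                 largest_gap_pair="")
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def infer_homeologs(map_df: pd.DataFrame) -> pd.DataFrame:
    """Infer homeologous group pairs from shared multi-locus marker names.

    Counts, for each unordered group pair, the markers with loci on both
    groups; greedy maximum matching by count (ties lexicographic).  Returns
    columns group_a, group_b, n_shared_markers; empty (with a warning) when
    no marker spans two groups.
    """
    multi = map_df.groupby("marker_id")["group"].agg(set)
    counts: dict[tuple[str, str], int] = {}
    for groups in multi:
        gl = sorted(groups)
        for i in range(len(gl)):
            for j in range(i + 1, len(gl)):
                counts[(gl[i], gl[j])] = counts.get((gl[i], gl[j]), 0) + 1
    if not counts:
        log.warning("no multi-locus markers: empty homeolog pairing")
        return pd.DataFrame(columns=["group_a", "group_b", "n_shared_markers"])
    order = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    used: set[str] = set()
    rows = []
    for (a, b), n in order:
        if a in used or b in used:
            continue
        used.update((a, b))
        rows.append((a, b, n))
    return pd.DataFrame(rows, columns=["group_a", "group_b",
                                       "n_shared_markers"])


def classify_multilocus(map_p1: pd.DataFrame, map_p2: pd.DataFrame,
                        integrated: pd.DataFrame,
                        band_count: Mapping[str, int],
                        pairing: pd.DataFrame,
                        correspondence: pd.DataFrame | None = None
                        ) -> pd.DataFrame:
    """Classify each marker's multi-locus status.

    Type I: the marker shows multiple bands (band_count > 1).  Type II: a
    bi-parental marker whose P1 and P2 placements fall on non-corresponding
    parental groups.  The location class of a multi-locus marker is 'same'
    (all loci on one integrated group), 'homeologous' (spanning an inferred
    homeolog pair) or 'other'.
    """
    pair_lookup: dict[str, str] = {}
    for r in pairing.itertuples():
        pair_lookup[r.group_a] = r.group_b
        pair_lookup[r.group_b] = r.group_a
    corr_lookup: dict[str, str] = {}
    if correspondence is not None:
        for r in correspondence.itertuples():
            corr_lookup[r.group_p2] = r.group_p1

    g1 = map_p1.groupby("marker_id")["group"].agg(set)
    g2 = map_p2.groupby("marker_id")["group"].agg(set)
    gi = integrated.groupby("marker_id")["group"].agg(set)

    rows = []
    for mk in sorted(set(gi.index)):
        groups = gi[mk]
        bc = int(band_count.get(mk, 1))
        type1 = bc > 1
        # Type II: bi-parental placements on non-corresponding groups
        type2 = False
        if mk in g1.index and mk in g2.index:
            p2_as_p1 = {corr_lookup.get(g, g) for g in g2[mk]}
            type2 = len(g1[mk] ^ p2_as_p1) > 0 and not (g1[mk] & p2_as_p1)
        if len(groups) <= 1:
            loc = "same" if (type1 or type2) else "single"
        elif any(pair_lookup.get(a) == b for a in groups for b in groups):
            loc = "homeologous"
        else:
            loc = "other"
        rows.append(dict(marker_id=mk, band_count=bc, type_i=type1,
                         type_ii=type2, n_groups=len(groups),
                         location_class=loc))
    return pd.DataFrame(rows)
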