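"""Grid-sampled linkage-disequilibrium scan over a parental-specific map.

Because each parental channel of a pseudo-testcross is gametic (phase-known
haploid data), LD between two loci is the squared correlation r^2 of their
0/1 allele codes over progeny informative at both.  Loci are thinned to an
approximately regular cM grid before the all-pairs computation, and pairs
on *different* linkage groups with r^2 above a threshold — disequilibrium
that ordinary linkage analysis assumes away — are reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["LDScan", "sample_grid", "r_squared", "scan"]


def sample_grid(map_df: pd.DataFrame, step_cm: float = 5.0) -> list[str]:
    """Pick, per group, the locus nearest each grid point 0, step, 2*step...

    Deterministic: ties go to the smaller position, duplicates are dropped.
    Returns locus ids in (group, position) order.
    """
    chosen: list[str] = []
    for g, sub in map_df.groupby("group", sort=True):
        sub = sub.sort_values(["position_cm", "locus_id"], kind="mergesort")
        pos = sub["position_cm"].to_numpy()
        ids = sub["locus_id"].tolist()
        if not len(pos):
            continue
        picked: set[int] = set()
        gp = 0.0
        while gp <= pos[-1] + step_cm / 2:
            k = int(np.argmin(np.abs(pos - gp)))  # argmin takes first == lower pos
            picked.add(k)
            gp += step_cm
        chosen.extend(ids[k] for k in sorted(picked))
    return chosen


def r_squared(calls_i: np.ndarray, calls_j: np.ndarray, min_n: int = 0
              ) -> tuple[float, int]:
    """Gametic r^2 between two haploid call vectors (0/1, -1 missing).

    r^2 = (f11*f00 - f10*f01)^2 / (p1*p0*q1*q0) over doubly informative
    progeny — the squared Pearson correlation of the 0/1 codes, invariant
    to a/b relabelling.  Returns (r2, n); r2 is NaN when a margin is
    monomorphic or n < min_n.
    """
    a = np.asarray(calls_i)
    b = np.asarray(calls_j)
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    if n < max(min_n, 1):
        return float("nan"), n
    x, y = a[ok], b[ok]
    f11 = int(np.sum((x == 1) & (y == 1)))
    f10 = int(np.sum((x == 1) & (y == 0)))
    f01 = int(np.sum((x == 0) & (y == 1)))
    f00 = int(np.sum((x == 0) & (y == 0)))
    p1, p0 = f11 + f10, f01 + f00
    q1, q0 = f11 + f01, f10 + f00
    den = p1 * p0 * q1 * q0
    if den == 0:
        return float("nan"), n
    return float((f11 * f00 - f10 * f01) ** 2 / den), n


def _pairwise_r2(X: np.ndarray, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs gametic r^2 for an (m, n) call matrix; NaN where undefined."""
    A = (X == 1).astype(np.float64)
    B = (X == 0).astype(np.float64)
    V = A + B
    n = V @ V.T
    f11 = A @ A.T
    f00 = B @ B.T
    f10 = A @ B.T  # i==1, j==0
    p1 = A @ V.T   # margin of locus i over the pair's informative set
    q1 = V @ A.T   # margin of locus j
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (f11 * f00 - f10 * f10.T) ** 2
        den = p1 * (n - p1) * q1 * (n - q1)
        r2 = num / den
    r2[(den == 0) | (n < min_n)] = np.nan
    return r2, n.astype(int)


@dataclass
class LDScan:
    """Result of :func:`scan`: sampled loci, all pairs, and region report."""

    sampled: pd.DataFrame   # locus_id, group, position_cm (scan order)
    pairs: pd.DataFrame     # locus_i, locus_j, group_i, group_j, r2, n, cross_group
    cross_pairs: pd.DataFrame  # the cross-group subset with r2 > threshold
    regions: pd.DataFrame   # group, start_cm, end_cm, n_cross_partners
    matrix: np.ndarray      # square r^2 matrix over sampled loci (NaN diag-less)

    def write(self, outdir, prefix: str = "ld") -> None:
        from pathlib import Path

        outdir = Path(outdir)
        self.pairs.to_csv(outdir / f"{prefix}_pairs.tsv", sep="\t",
                          index=False, float_format="%.6g")
        self.cross_pairs.to_csv(outdir / f"{prefix}_cross_pairs.tsv",
                                sep="\t", index=False, float_format="%.6g")
        self.regions.to_csv(outdir / f"{prefix}_regions.tsv", sep="\t",
                            index=False, float_format="%.6g")
        np.savetxt(outdir / f"{prefix}_matrix.txt", self.matrix, fmt="%.4f")


def scan(map_df: pd.DataFrame, calls: Mapping[str, np.ndarray],
         step_cm: float = 5.0, r2_min: float = 0.5, min_n: int = 30,
         bin_cm: float = 5.0) -> LDScan:
    """Grid-sample a map, compute all pairwise r^2, and report cross-group LD.

    ``calls`` maps locus_id to its haploid call vector.  Regions are merged
    runs of ``bin_cm`` bins holding loci with at least one cross-group
    partner above ``r2_min``, ranked by partner count.
    """
    ids = [l for l in sample_grid(map_df, step_cm) if l in calls]
    sub = (map_df[map_df["locus_id"].isin(ids)]
           .sort_values(["group", "position_cm", "locus_id"], kind="mergesort")
           .reset_index(drop=True))
    ids = sub["locus_id"].tolist()
    groups = sub["group"].to_numpy()
    pos = sub["position_cm"].to_numpy()
    m = len(ids)
    if m == 0:
        empty = pd.DataFrame()
        return LDScan(sub, empty, empty, empty, np.zeros((0, 0)))
    X = np.vstack([np.asarray(calls[l], dtype=np.int8) for l in ids])
    r2, nmat = _pairwise_r2(X, min_n)

    iu, ju = np.triu_indices(m, k=1)
    pairs = pd.DataFrame({
        "locus_i": np.array(ids)[iu], "locus_j": np.array(ids)[ju],
        "group_i": groups[iu], "group_j": groups[ju],
        "pos_i": pos[iu], "pos_j": pos[ju],
        "r2": r2[iu, ju], "n": nmat[iu, ju],
        "cross_group": groups[iu] != groups[ju],
    })
    defined = pairs.dropna(subset=["r2"])
    n_skipped = len(pairs) - len(defined)
    if n_skipped:
        log.info("LD scan: %d of %d pairs skipped (monomorphic or n < %d)",
                 n_skipped, len(pairs), min_n)
    cross = defined[defined["cross_group"] & (defined["r2"] > r2_min)]
    cross = cross.reset_index(drop=True)

    # region report: per group, 5-cM bins counting cross-group partners
    partner_count: dict[tuple[str, int], int] = {}
    for row in cross.itertuples():
        for g, p in ((row.group_i, row.pos_i), (row.group_j, row.pos_j)):
            key = (g, int(p // bin_cm))
            partner_count[key] = partner_count.get(key, 0) + 1
    region_rows = []
    for g in sorted({k[0] for k in partner_count}):
        bins = sorted(b for (gg, b) in partner_count if gg == g)
        run: list[int] = []
        for b in bins:
            if run and b != run[-1] + 1:
                region_rows.append((g, run[0] * bin_cm,
                                    (run[-1] + 1) * bin_cm,
                                    sum(partner_count[(g, x)] for x in run)))
                run = []
            run.append(b)
        if run:
            region_rows.append((g, run[0] * bin_cm, (run[-1] + 1) * bin_cm,
                                sum(partner_count[(g, x)] for x in run)))
    regions = pd.DataFrame(region_rows, columns=["group", "start_cm",
                                                 "end_cm", "n_cross_partners"])
    if len(regions):
        regions = regions.sort_values("n_cross_partners", ascending=False,
                                      kind="mergesort").reset_index(drop=True)
    return LDScan(sampled=sub, pairs=defined.reset_index(drop=True),
                  cross_pairs=cross, regions=regions, matrix=r2)
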