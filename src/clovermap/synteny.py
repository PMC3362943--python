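"""Synteny-block detection between a genetic map and a reference genome.

Markers with a significant homolog hit become anchors (one best hit per
marker).  Within each (linkage group, reference chromosome) cell, anchors
sorted by map position are chained into maximal runs whose consecutive
anchors lie within 10 cM on the map AND 500 kb on the chromosome; runs of
three or more anchors are synteny blocks.  The gap-bound chaining is a
deterministic, order-free reading of the windowed block definition and
reduces to it when anchors are dense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io import best_hits

log = logging.getLogger(__name__)

__all__ = ["Anchor", "SyntenyBlock", "build_anchors", "chain_blocks",
           "colinearity_summary"]


@dataclass(frozen=True)
class Anchor:
    """One marker joined to its best reference hit and its map position."""

    marker_id: str
    group: str
    pos_cm: float
    chromosome: str
    bp: int


@dataclass
class SyntenyBlock:
    """A chained run of anchors with interval bounds on both sides."""

    group: str
    start_cm: float
    end_cm: float
    chromosome: str
    start_bp: int
    end_bp: int
    anchors: list[Anchor]
    orientation: str  # '+', '-' or 'mixed'

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def build_anchors(map_df: pd.DataFrame, hits: pd.DataFrame,
                  evalue_max: float = 1e-10) -> list[Anchor]:
    """Filter hits, keep the best per marker, join to map positions.

    Markers without a passing hit are dropped (count logged).  Uses the
    cli_io tie rule: max bitscore, then min evalue, then lexicographic
    reference id.  Anchor bp is the hit interval midpoint.
    """
    if not len(hits):
        log.warning("empty hit table: zero anchors")
        return []
    passed = hits[hits["evalue"] <= evalue_max]
    best = best_hits(passed)
    by_marker = {r.query_id: r for r in best.itertuples()}
    anchors: list[Anchor] = []
    seen: set[str] = set()
    for row in map_df.itertuples():
        if row.marker_id in seen:
            continue  # one anchor per marker (first mapped locus wins)
        seen.add(row.marker_id)
        hit = by_marker.get(row.marker_id)
        if hit is None:
            continue
        anchors.append(Anchor(marker_id=row.marker_id, group=row.group,
                              pos_cm=float(row.position_cm),
                              chromosome=hit.chromosome,
                              bp=int((hit.start_bp + hit.end_bp) // 2)))
    log.info("anchors: %d of %d mapped markers have a passing hit",
             len(anchors), len(seen))
    return anchors


def _orientation(block: Sequence[Anchor]) -> str:
    cm = [a.pos_cm for a in block]
    bp = [a.bp for a in block]
    if len(set(cm)) < 2 or len(set(bp)) < 2:
        return "mixed"
    rho = sstats.spearmanr(cm, bp).statistic
    if np.isnan(rho) or abs(rho) < 0.5:
        return "mixed"
    return "+" if rho > 0 else "-"


def chain_blocks(anchors: Sequence[Anchor], min_anchors: int = 3,
                 map_win_cm: float = 10.0, ref_win_kb: float = 500.0
                 ) -> list[SyntenyBlock]:
    """Chain anchors into maximal gap-bounded runs per (group, chromosome).

    Within a cell, anchors are sorted by map position (ties by bp); a run
    breaks whenever consecutive anchors differ by more than ``map_win_cm``
    on the map or ``ref_win_kb`` kb on the chromosome.  Runs with at least
    ``min_anchors`` anchors become blocks; orientation is the sign of the
    Spearman correlation between cM and bp (mixed when |rho| < 0.5).
    """
    ref_win_bp = ref_win_kb * 1000.0
    cells: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        cells.setdefault((a.group, a.chromosome), []).append(a)
    blocks: list[SyntenyBlock] = []
    for (g, ch), cell in sorted(cells.items()):
        cell.sort(key=lambda a: (a.pos_cm, a.bp, a.marker_id))
        run: list[Anchor] = []
        for a in cell:
            if run and (a.pos_cm - run[-1].pos_cm > map_win_cm
                        or abs(a.bp - run[-1].bp) > ref_win_bp):
                blocks.extend(_emit(run, min_anchors))
                run = []
            run.append(a)
        blocks.extend(_emit(run, min_anchors))
    return blocks


def _emit(run: list[Anchor], min_anchors: int) -> list[SyntenyBlock]:
    if len(run) < min_anchors:
        return []
    bps = [a.bp for a in run]
    return [SyntenyBlock(group=run[0].group, start_cm=run[0].pos_cm,
                         end_cm=run[-1].pos_cm, chromosome=run[0].chromosome,
                         start_bp=min(bps), end_bp=max(bps),
                         anchors=list(run), orientation=_orientation(run))]


def colinearity_summary(anchors: Sequence[Anchor],
                        blocks: Sequence[SyntenyBlock],
                        loci_per_group: Mapping[str, int] | None = None
                        ) -> pd.DataFrame:
    """Per-group colinearity table: anchors per chromosome, the dominant
    chromosome, the share of mapped loci it explains, and block coverage.

    ``loci_per_group`` gives total mapped loci per group for the percentage
    (defaults to the anchor count).
    """
    rows = []
    groups = sorted({a.group for a in anchors}
                    | ({g for g in loci_per_group} if loci_per_group else set()))
    for g in groups:
        ga = [a for a in anchors if a.group == g]
        counts: dict[str, int] = {}
        for a in ga:
            counts[a.chromosome] = counts.get(a.chromosome, 0) + 1
        total = (loci_per_group or {}).get(g, len(ga))
        if counts:
            dom = max(counts, key=lambda c: (counts[c], c))
            dom_n = counts[dom]
            pct = 100.0 * dom_n / total if total else float("nan")
        else:
            dom, dom_n, pct = "", 0, 0.0
        gb = [b for b in blocks if b.group == g]
        rows.append(dict(
            group=g, n_anchors=len(ga), dominant_chromosome=dom,
            dominant_count=dom_n, dominant_pct_of_loci=pct,
            n_blocks=len(gb),
            block_cm=sum(b.end_cm - b.start_cm for b in gb),
            block_bp=sum(b.end_bp - b.start_bp for b in gb),
            chromosome_counts=";".join(f"{c}:{n}" for c, n
                                       in sorted(counts.items())),
        ))
    return pd.DataFrame(rows)


def blocks_to_frame(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(group=b.group, start_cm=b.start_cm, end_cm=b.end_cm,
             chromosome=b.chromosome, start_bp=b.start_bp, end_bp=b.end_bp,
             n_anchors=b.n_anchors, orientation=b.orientation)
        for b in blocks])
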