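"""Two-point linkage analysis for haploid (pseudo-testcross) segregation data.

In a full-sib F1 family of an outcrossing species, every locus heterozygous
in one parent segregates 1:1 through that parent's meioses, so each parental
channel can be mapped as a haploid population.  This module implements the
classical two-point workflow on such data: pairwise recombination fractions
and LOD scores with phase minimisation, single-linkage grouping at a LOD
threshold, Kosambi map distances, incremental marker ordering under a
least-squares goodness-of-fit criterion with a "jump" control and window-3
ripples, and a reference-guided disassembly procedure for linkage groups that
were over-merged by gametic disequilibrium between chromosomes.

Genotype calls are coded as int8: 0 = allele a, 1 = allele b, -1 = missing.
The a/b labelling is arbitrary per locus; all pairwise statistics minimise
over phase.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx

MISSING = -1

log = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "PairStats",
    "LinkageGroup",
    "DisassemblyEvidence",
    "kosambi",
    "kosambi_inverse",
    "pair_stats",
    "group",
    "order_group",
    "disassemble",
    "mosaicism",
]

# recombination fractions are clamped strictly below 0.5 before the map
# function so distances stay finite
_R_EPS = 1e-12
_R_CLAMP_HIGH = 0.5 - 1e-9


def kosambi(r):
    """Kosambi map distance d = 25*ln((1+2r)/(1-2r)) in cM.

    Accepts scalars or arrays; r is clamped to [0, 0.5).
    """
    r_arr = np.clip(np.asarray(r, dtype=float), 0.0, _R_CLAMP_HIGH)
    d = 25.0 * np.log((1.0 + 2.0 * r_arr) / (1.0 - 2.0 * r_arr))
    return float(d) if np.isscalar(r) or np.ndim(r) == 0 else d


def kosambi_inverse(cm):
    """Inverse Kosambi function r = 0.5*tanh(d/50), clamped to [0, 0.5)."""
    d = np.asarray(cm, dtype=float)
    r = 0.5 * np.tanh(d / 50.0)
    r = np.clip(r, 0.0, _R_CLAMP_HIGH)
    return float(r) if np.isscalar(cm) or np.ndim(cm) == 0 else r


def _lod_from_counts(R: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Testcross LOD: R*log10(2r) + (n-R)*log10(2(1-r)) with r = R/n.

    The r = 0 limit is n*log10(2); r = 0.5 gives 0 exactly.
    """
    n = np.asarray(n, dtype=float)
    R = np.asarray(R, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n > 0, R / np.maximum(n, 1), 0.5)
        t1 = np.where(R > 0, R * np.log10(np.maximum(2.0 * r, _R_EPS)), 0.0)
        t2 = np.where(n - R > 0, (n - R) * np.log10(2.0 * (1.0 - r)), 0.0)
    lod = t1 + t2
    return np.where(n > 0, lod, 0.0)


@dataclass
class PairStats:
    """All pairwise two-point statistics for a set of phased loci.

    Stored as dense symmetric matrices over ``ids``; memory is O(m^2) which
    is fine for the few thousand loci of a mapping experiment.
    """

    ids: list[str]
    n: np.ndarray        # informative (both non-missing) counts
    rec: np.ndarray      # min-phase recombinant count R, R <= n-R
    r_hat: np.ndarray    # R/n in [0, 0.5]; 0.5 where n == 0
    lod: np.ndarray
    flipped: np.ndarray  # True where the minimising phase flips locus j vs i
    usable: np.ndarray   # off-diagonal and n >= min informative bound

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        pos = {lid: k for k, lid in enumerate(self.ids)}
        return np.array([pos[i] for i in ids], dtype=int)

    def subset(self, ids: Sequence[str]) -> "PairStats":
        ix = self.index_of(ids)
        return PairStats(
            ids=list(ids),
            n=self.n[np.ix_(ix, ix)],
            rec=self.rec[np.ix_(ix, ix)],
            r_hat=self.r_hat[np.ix_(ix, ix)],
            lod=self.lod[np.ix_(ix, ix)],
            flipped=self.flipped[np.ix_(ix, ix)],
            usable=self.usable[np.ix_(ix, ix)],
        )


def pair_stats(calls, ids: Sequence[str] | None = None, min_n: int = 20) -> PairStats:
    """Compute all pairwise recombination fractions and LOD scores.

    Parameters
    ----------
    calls
        Either an (m, n_progeny) int array with entries {0, 1, -1} or a
        sequence of objects with ``.calls`` and ``.locus_id`` attributes.
    ids
        Locus identifiers (required when passing a bare matrix).
    min_n
        Pairs with fewer informative progeny are flagged unusable.

    Phase is aligned per pair by minimising mismatches, so the recombinant
    count is R = min(m, n-m) and r_hat = R/n <= 0.5.
    """
    if ids is None:
        ids = [lo.locus_id for lo in calls]
        X = np.vstack([np.asarray(lo.calls, dtype=np.int8) for lo in calls])
    else:
        X = np.asarray(calls, dtype=np.int8)
        ids = list(ids)
    if X.ndim != 2:
        raise ValueError("calls must be a 2-D locus x progeny matrix")

    A = (X == 1).astype(np.float32)
    B = (X == 0).astype(np.float32)
    V = A + B
    n = (V @ V.T).astype(np.int64)
    mism = (A @ B.T + B @ A.T).astype(np.int64)
    same = n - mism
    R = np.minimum(mism, same)
    flipped = mism > same
    with np.errstate(invalid="ignore"):
        r_hat = np.where(n > 0, R / np.maximum(n, 1), 0.5)
    lod = _lod_from_counts(R, n)
    usable = (n >= min_n) & ~np.eye(len(ids), dtype=bool)
    np.fill_diagonal(lod, 0.0)
    np.fill_diagonal(r_hat, 0.0)
    return PairStats(ids=ids, n=n, rec=R, r_hat=r_hat, lod=lod,
                     flipped=flipped, usable=usable)


def group(ps: PairStats, lod_min: float = 10.0, rec_max: float = 0.4) -> list[list[str]]:
    """Partition loci into linkage groups by single linkage.

    Two loci are joined when LOD >= lod_min and r_hat <= rec_max; groups are
    the connected components, returned largest first (ties: by first locus id).
    """
    adj = ps.usable & (ps.lod >= lod_min) & (ps.r_hat <= rec_max)
    g = nx.Graph()
    g.add_nodes_from(range(len(ps.ids)))
    ii, jj = np.nonzero(np.triu(adj, 1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), ps.ids[c[0]]))
    return [[ps.ids[k] for k in c] for c in comps]


@dataclass
class LinkageGroup:
    """An ordered linkage group with cM positions (first locus at 0)."""

    group_id: str
    locus_ids: list[str]
    positions_cm: np.ndarray
    set_aside: list[str] = field(default_factory=list)
    misfit: float = 0.0

    @property
    def length_cm(self) -> float:
        return float(self.positions_cm[-1]) if len(self.locus_ids) else 0.0

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)


def _prepare_pairs(ps: PairStats, lod_order_min: float, rec_max: float):
    """Used-pair arrays (i, j, lod weight, target Kosambi distance, distance
    standard error) for ordering.

    The standard error of a two-point Kosambi distance follows from the
    delta method: se(d) = |dd/dr| * se(r) = 100/(1-4r^2) * sqrt(r(1-r)/n),
    with r floored at 0.5/n so fully coupled pairs keep a finite se.
    """
    use = ps.usable & (ps.lod >= lod_order_min) & (ps.r_hat <= rec_max)
    ii, jj = np.nonzero(np.triu(use, 1))
    w = np.asarray(ps.lod[ii, jj], float)
    r = np.asarray(ps.r_hat[ii, jj], float)
    n = np.maximum(np.asarray(ps.n[ii, jj], float), 1.0)
    dk = np.asarray(kosambi(r), float)
    rf = np.clip(r, 0.5 / n, 0.499)
    se = 100.0 / (1.0 - 4.0 * rf ** 2) * np.sqrt(rf * (1.0 - rf) / n)
    return ii, jj, w, dk, se


def _chain_positions(order: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Positions from cumulative adjacent Kosambi distances along an order."""
    if len(order) == 0:
        return np.zeros(0)
    steps = D[order[:-1], order[1:]]
    return np.concatenate([[0.0], np.cumsum(steps)])


def _misfit(order: np.ndarray, D: np.ndarray, pos_buf: np.ndarray,
            pii: np.ndarray, pjj: np.ndarray, pw: np.ndarray, pdk: np.ndarray,
            pse: np.ndarray, placed_mask: np.ndarray) -> float:
    """LOD-weighted goodness-of-fit misfit of a candidate order.

    Map distances come from the adjacent-chain positions of the order; each
    residual (d_map - d_kosambi) is standardised by the two-point distance
    standard error, so the misfit is a dimensionless chi-square-like mean
    (about 1 for a correct order under sampling noise alone), averaged with
    LOD weights over used pairs among placed loci.
    """
    p = _chain_positions(order, D)
    pos_buf[order] = p
    sel = placed_mask[pii] & placed_mask[pjj]
    if not sel.any():
        return 0.0
    dmap = np.abs(pos_buf[pjj[sel]] - pos_buf[pii[sel]])
    w = pw[sel]
    z = (dmap - pdk[sel]) / pse[sel]
    return float(np.sum(w * z ** 2) / np.sum(w))


_PERM3 = [p for p in itertools.permutations(range(3)) if p != (0, 1, 2)]


def _ripple(order: np.ndarray, D, pos_buf, pii, pjj, pw, pdk, pse,
            placed_mask, best: float) -> tuple[np.ndarray, float]:
    """One left-to-right pass of exhaustive window-3 permutations."""
    for s in range(len(order) - 2):
        for perm in _PERM3:
            cand = order.copy()
            cand[s:s + 3] = order[s + np.array(perm)]
            m = _misfit(cand, D, pos_buf, pii, pjj, pw, pdk, pse, placed_mask)
            if m < best - 1e-12:
                order, best = cand, m
    return order, best


def _wls_positions(order: np.ndarray, pii, pjj, pw, pdk, m: int,
                   max_rank_gap: int = 3) -> np.ndarray:
    """Final positions by nonnegative weighted least squares on intervals.

    Interval lengths g >= 0 between consecutive loci minimise
    sum_pairs lod * (sum_{intervals between} g - d_kosambi)^2; positions are
    the cumulative sums, anchored at 0.  Nonnegativity keeps positions
    monotone by construction.  Only pairs within ``max_rank_gap`` positions
    of each other enter the fit: short-range two-point distances are
    additive to good approximation, whereas long-range Kosambi distances
    systematically undershoot the summed map distance and would shrink the
    map if included.
    """
    from scipy.optimize import nnls

    k = len(order)
    if k < 2:
        return np.zeros(k)
    rank = np.full(m, -1)
    rank[order] = np.arange(k)
    sel = (rank[pii] >= 0) & (rank[pjj] >= 0)
    ri, rj = rank[pii[sel]], rank[pjj[sel]]
    lo, hi = np.minimum(ri, rj), np.maximum(ri, rj)
    near = (hi - lo) <= max_rank_gap
    lo, hi = lo[near], hi[near]
    w = np.sqrt(pw[sel][near])
    d = pdk[sel][near]
    if len(w) == 0:
        return np.zeros(k)
    A = np.zeros((len(w), k - 1))
    for row, (a, b) in enumerate(zip(lo, hi)):
        A[row, a:b] = w[row]
    g, _ = nnls(A, w * d)
    return np.concatenate([[0.0], np.cumsum(g)])


def order_group(ps: PairStats, group_ids: Sequence[str] | None = None,
                jump: float = 5.0, lod_order_min: float = 1.0,
                rec_max: float = 0.4, group_id: str = "LG") -> LinkageGroup:
    """Order one linkage group and assign cM positions.

    Seeds with the highest-LOD pair, adds remaining loci in decreasing
    informativeness (summed LOD to placed loci); each addition is inserted at
    the slot minimising the normalised misfit, followed by a window-3 ripple.
    A locus whose best insertion raises the misfit by more than ``jump`` is
    set aside and retried once after all others; loci failing the retry stay
    in ``set_aside``.  Final positions come from nonnegative weighted least
    squares, with the lexicographically smallest terminal locus at 0.
    """
    sub = ps if group_ids is None else ps.subset(list(group_ids))
    m = len(sub.ids)
    if m == 0:
        return LinkageGroup(group_id, [], np.zeros(0))
    if m == 1:
        return LinkageGroup(group_id, list(sub.ids), np.zeros(1))

    D = kosambi(sub.r_hat)
    pii, pjj, pw, pdk, pse = _prepare_pairs(sub, lod_order_min, rec_max)
    pos_buf = np.zeros(m)
    placed_mask = np.zeros(m, dtype=bool)

    lod = np.where(sub.usable, sub.lod, 0.0)
    i0, j0 = np.unravel_index(np.argmax(lod), lod.shape)
    order = np.array([i0, j0])
    placed_mask[[i0, j0]] = True
    best = _misfit(order, D, pos_buf, pii, pjj, pw, pdk, pse, placed_mask)

    remaining = [k for k in range(m) if k not in (i0, j0)]
    set_aside: list[int] = []

    # per-locus used-pair partners, to detect loci with no positional info
    used_w = np.zeros((m, m))
    used_w[pii, pjj] = pw
    used_w[pjj, pii] = pw

    def try_add(k: int, order, best) -> tuple[np.ndarray, float, bool]:
        if used_w[k, placed_mask].sum() <= 0.0:
            # no usable pair with any placed locus: cannot be positioned
            return order, best, False
        placed_mask[k] = True
        cands = [np.insert(order, s, k) for s in range(len(order) + 1)]
        mis = [_misfit(c, D, pos_buf, pii, pjj, pw, pdk, pse, placed_mask)
               for c in cands]
        s = int(np.argmin(mis))
        if mis[s] - best > jump:
            placed_mask[k] = False
            return order, best, False
        order, best = cands[s], mis[s]
        order, best = _ripple(order, D, pos_buf, pii, pjj, pw, pdk, pse,
                              placed_mask, best)
        return order, best, True

    for passno in (0, 1):  # main pass, then one retry of set-asides
        pool = remaining if passno == 0 else set_aside
        set_aside = [] if passno == 1 else set_aside
        pool = list(pool)
        while pool:
            info = lod[np.ix_(pool, np.nonzero(placed_mask)[0])].sum(axis=1)
            k = pool.pop(int(np.argmax(info)))
            order, best, ok = try_add(k, order, best)
            if not ok:
                set_aside.append(k)

    pos = _wls_positions(order, pii, pjj, pw, pdk, m)
    ids_ordered = [sub.ids[k] for k in order]
    if ids_ordered[-1] < ids_ordered[0]:
        ids_ordered = ids_ordered[::-1]
        pos = pos[-1] - pos[::-1]
    return LinkageGroup(group_id, ids_ordered, pos,
                        set_aside=[sub.ids[k] for k in set_aside],
                        misfit=best)


def mosaicism(calls: np.ndarray, order: Sequence[int] | None = None) -> float:
    """Mean per-progeny fraction of adjacent-locus phase switches.

    On a correctly grouped and ordered chromosome this is small (bounded by
    the adjacent recombination fractions); a group merging several
    chromosomes shows mosaic graphical genotypes and a value near 0.5.
    """
    X = np.asarray(calls, dtype=np.int8)
    if order is not None:
        X = X[np.asarray(order)]
    if X.shape[0] < 2:
        return 0.0
    a, b = X[:-1], X[1:]
    valid = (a >= 0) & (b >= 0)
    switches = (a != b) & valid
    nv = valid.sum()
    return float(switches.sum() / nv) if nv else 0.0


@dataclass
class DisassemblyEvidence:
    """Per-locus evidence used to disassemble an over-merged group."""

    locus_id: str
    partner_group: str | None
    hit_chrom: str | None
    assigned: str | None
    source: str  # 'partner' | 'reference' | 'linkage' | 'unresolved'


def disassemble(suspect_ids: Sequence[str], ps: PairStats,
                marker_of: Mapping[str, str],
                partner_map, hit_chrom: Mapping[str, str] | None = None,
                lod_min: float = 10.0, rec_max: float = 0.4,
                ) -> tuple[list[list[str]], list[DisassemblyEvidence]]:
    """Split a suspect (over-merged) linkage group using external evidence.

    Each locus is labelled by, in order of precedence: (1) the partner-map
    group carrying the same marker, (2) the reference chromosome of its best
    homolog hit (translated to a partner-group label by majority vote of
    loci carrying both kinds of evidence), (3) the labelled subgroup to which
    its mean LOD linkage is maximal.  Every labelled subgroup is re-validated
    by :func:`group` at ``lod_min``; loci failing all three routes are
    returned in a final 'unresolved' evidence state.

    ``partner_map`` is a map DataFrame with columns group/locus_id/marker_id.
    """
    suspect_ids = list(suspect_ids)
    marker_group: dict[str, str] = {}
    if partner_map is not None and len(partner_map):
        for mk, grp in zip(partner_map["marker_id"], partner_map["group"]):
            marker_group.setdefault(mk, grp)

    evidence: dict[str, DisassemblyEvidence] = {}
    labels: dict[str, str] = {}
    chrom_votes: dict[str, dict[str, int]] = {}
    for lid in suspect_ids:
        mk = marker_of.get(lid)
        pg = marker_group.get(mk) if mk is not None else None
        ch = hit_chrom.get(mk) if (hit_chrom and mk is not None) else None
        evidence[lid] = DisassemblyEvidence(lid, pg, ch, None, "unresolved")
        if pg is not None:
            labels[lid] = pg
            evidence[lid].source = "partner"
            if ch is not None:
                chrom_votes.setdefault(ch, {})
                chrom_votes[ch][pg] = chrom_votes[ch].get(pg, 0) + 1

    chrom_label = {ch: max(v, key=lambda g: (v[g], g))
                   for ch, v in chrom_votes.items()}
    for lid in suspect_ids:
        if lid in labels:
            continue
        ch = evidence[lid].hit_chrom
        if ch is not None:
            labels[lid] = chrom_label.get(ch, f"chr:{ch}")
            evidence[lid].source = "reference"

    if not labels:
        raise ValueError("cannot disassemble without reference information")

    # route 3: attach remaining loci to the labelled subgroup with the
    # highest mean LOD linkage
    sub = ps.subset(suspect_ids)
    idx = {lid: k for k, lid in enumerate(sub.ids)}
    lab_names = sorted(set(labels.values()))
    members = {g: [idx[l] for l, lab in labels.items() if lab == g]
               for g in lab_names}
    lodm = np.where(sub.usable & (sub.r_hat <= rec_max), sub.lod, 0.0)
    for lid in suspect_ids:
        if lid in labels:
            continue
        k = idx[lid]
        means = {g: lodm[k, mem].mean() for g, mem in members.items() if mem}
        gbest = max(means, key=lambda g: (means[g], g))
        if means[gbest] > 0:
            labels[lid] = gbest
            evidence[lid].source = "linkage"

    for lid, lab in labels.items():
        evidence[lid].assigned = lab

    subgroups: list[list[str]] = []
    for g in lab_names:
        ids_g = [l for l in suspect_ids if labels.get(l) == g]
        if not ids_g:
            continue
        comps = group(ps.subset(ids_g), lod_min=lod_min, rec_max=rec_max)
        if len(comps) > 1:
            log.warning("disassembled subgroup %s split into %d components "
                        "at LOD %.1f", g, len(comps), lod_min)
        subgroups.extend(comps)
    subgroups.sort(key=lambda c: (-len(c), c[0]))
    return subgroups, [evidence[l] for l in suspect_ids]
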