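"""Truth-scored evaluation scenarios on synthetic data.

The study's raw segregation data are unpublished, so the mapping, LD and
synteny machinery is validated against the synthetic-data generator, whose
:class:`~clovermap.simulate.SimTruth` makes every downstream inference
scorable exactly.  Each function here sets up one scenario at the emulated
study's conditions (188 progeny, 16 linkage groups, LOD-10 grouping) and
returns summary accuracy numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import linkage as lk
from . import simulate as sim
from .ld import scan
from .testcross import split_parental


def _strip(locus_id: str) -> str:
    return locus_id[:-3] if locus_id.endswith(("_P1", "_P2")) else locus_id


def rand_index(labels_a, labels_b) -> float:
    """Rand index between two partitions given as parallel label sequences."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = len(a)
    agree = 0
    for i in range(n):
        sa = a[i + 1:] == a[i]
        sb = b[i + 1:] == b[i]
        agree += int(np.sum(sa == sb))
    total = n * (n - 1) // 2
    return agree / total if total else 1.0


def _true_map_frame(truth: sim.SimTruth, calls: dict) -> pd.DataFrame:
    mdf = truth.loci.rename(columns={"pos_cm": "position_cm"})[
        ["group", "locus_id", "marker_id", "position_cm", "seg_class"]].copy()
    mdf["distorted"] = False
    return mdf[mdf["locus_id"].isin(calls)].reset_index(drop=True)


def grouping_and_ordering(n_seeds: int = 20, n_pairs: int = 8,
                          markers_per_group: int = 10,
                          group_length_cm: float = 100.0,
                          n_progeny: int = 188, lod_min: float = 10.0,
                          seed: int = 0) -> dict:
    """Grouping purity (Rand index) and order recovery on 16-group genomes.

    Per seed, one parental channel is simulated at the study's sample size,
    grouped at the LOD threshold and every group ordered; a group counts as
    recovered when its loci come back in true order or its exact reversal
    with no locus set aside.  Returns mean Rand index and the fraction of
    (seed, group) units recovered.
    """
    rand_vals = []
    rec_ok = rec_tot = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s + 1)
        genome = sim.SimGenome.regular(n_pairs=n_pairs,
                                       length_cm=group_length_cm,
                                       markers_per_group=markers_per_group)
        n_loci = 2 * n_pairs * markers_per_group
        design = sim.SimDesign(n_progeny=n_progeny, n_biparental=0,
                               n_female=n_loci, n_male=0,
                               multi_locus_fraction=0.0,
                               missing_rate=0.05, error_rate=0.01)
        haplos = {"P1": sim.simulate_gametes(genome, design, "P1", rng),
                  "P2": {}}
        loci = sim.assign_loci(genome, design, rng)
        table, truth = sim.render_genotype_table(haplos, loci, design,
                                                 genome, rng)
        p1, _ = split_parental(table)
        ps = lk.pair_stats(p1)
        comps = lk.group(ps, lod_min=lod_min)
        gof = truth.group_of()
        inferred = {}
        for k, comp in enumerate(comps):
            for lid in comp:
                inferred[lid] = k
        ids = [lo.locus_id for lo in p1]
        rand_vals.append(rand_index([gof[_strip(l)] for l in ids],
                                    [inferred[l] for l in ids]))
        tru = truth.loci.set_index("locus_id")
        for comp in comps:
            if len(comp) < 3:
                continue
            rec_tot += 1
            lg = lk.order_group(ps, comp)
            true_sorted = sorted(lg.locus_ids,
                                 key=lambda l: tru.loc[_strip(l), "pos_cm"])
            if not lg.set_aside and (lg.locus_ids == true_sorted
                                     or lg.locus_ids == true_sorted[::-1]):
                rec_ok += 1
    return {"rand_index": float(np.mean(rand_vals)),
            "order_recovery": rec_ok / rec_tot if rec_tot else float("nan"),
            "n_groups_scored": rec_tot}


def rhat_bias(n_reps: int = 1000, r_true=(0.05, 0.2, 0.4),
              n_progeny: int = 188, seed: int = 0) -> dict:
    """Bias and RMSE of the min-phase two-point estimator r_hat = R/n.

    Simulates replicate locus pairs at each true recombination fraction
    through the gamete generator (two loci at the Kosambi distance of r on
    one chromosome) and runs them through :func:`clovermap.linkage.pair_stats`.
    """
    rng = np.random.default_rng(seed + 77)
    out = {}
    for r in r_true:
        d = lk.kosambi(r)
        genome = sim.SimGenome(
            n_homeolog_pairs=1,
            group_lengths_cm={"LG1a": d, "LG1b": d},
            marker_positions={"LG1a": np.array([0.0, d]),
                              "LG1b": np.array([0.0, d])},
            homeolog_pairs=[("LG1a", "LG1b")],
            chrom_of_group={"LG1a": "chr1", "LG1b": "chr1"})
        design = sim.SimDesign(n_progeny=n_progeny, n_biparental=0,
                               n_female=4, n_male=0)
        est = np.empty(n_reps)
        for k in range(n_reps):
            X = sim.simulate_gametes(genome, design, "P1", rng)["LG1a"]
            ps = lk.pair_stats(X, ["a", "b"], min_n=2)
            est[k] = ps.r_hat[0, 1]
        bias = float(est.mean() - r)
        se_binom = np.sqrt(r * (1 - r) / n_progeny)
        rmse = float(np.sqrt(np.mean((est - r) ** 2)))
        out[r] = {"bias": bias, "rmse": rmse, "binomial_se": float(se_binom)}
    return out


def ld_detection(n_seeds: int = 100, dprime: float = 0.9,
                 n_progeny: int = 188, seed: int = 0) -> dict:
    """Power/false-positive study for the cross-group LD scan.

    Plants one cross-chromosome anchor pair at the given coupling D' in the
    male parent, scans the (true) map at the 5-cM grid, and counts seeds
    with at least one cross-group pair at r^2 > 0.5; the matched null run
    (no planted LD) counts false cross-group pairs.
    """
    def one(s: int, dp: float):
        rng = np.random.default_rng(s)
        genome = sim.SimGenome.regular(n_pairs=8, length_cm=100.0,
                                       markers_per_group=14)
        pa = float(genome.marker_positions["LG1a"][7])
        pb = float(genome.marker_positions["LG5a"][7])
        pld = ([sim.PlantedLD("P2", "LG1a", pa, "LG5a", pb, dp)]
               if dp else [])
        n_loci = 16 * 14
        design = sim.SimDesign(n_progeny=n_progeny, n_biparental=0,
                               n_female=0, n_male=n_loci,
                               multi_locus_fraction=0.0, missing_rate=0.05,
                               error_rate=0.01, planted_ld=pld)
        haplos = {"P1": {}, "P2": sim.simulate_gametes(genome, design,
                                                       "P2", rng)}
        loci = sim.assign_loci(genome, design, rng)
        table, truth = sim.render_genotype_table(haplos, loci, design,
                                                 genome, rng)
        _, p2 = split_parental(table)
        calls = {lo.locus_id: lo.calls for lo in p2}
        res = scan(_true_map_frame(truth, calls), calls)
        near_ok = True
        for row in res.cross_pairs.itertuples():
            gs = {row.group_i, row.group_j}
            if gs != {"LG1a", "LG5a"}:
                near_ok = False
        return len(res.cross_pairs), near_ok

    detected = 0
    planted_only = True
    for s in range(n_seeds):
        n_cross, ok = one(seed + 1 + s, dprime)
        detected += int(n_cross > 0)
        planted_only &= ok
    null_pairs = sum(one(seed + 10_000 + s, 0.0)[0] for s in range(n_seeds))
    return {"detection_rate": detected / n_seeds,
            "null_cross_pairs_total": null_pairs,
            "null_cross_pairs_per_genome": null_pairs / n_seeds,
            "all_detections_at_planted_groups": planted_only}


def disassembly_purity(n_seeds: int = 20, n_progeny: int = 188,
                       seed: int = 0) -> dict:
    """Score reference-guided disassembly of a 3-chromosome over-merge.

    Strong planted LD (D' = 0.96, star topology through LG1a) fuses three
    chromosomes of the male map into one LOD-10 group; disassembly uses the
    female partner map plus the synthetic reference hit table.  Returns the
    fraction of seeds where the merged group splits into subgroups that are
    all >= 95% pure, and the mean minimum purity.
    """
    min_purities = []
    n_three = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 1 + s)
        genome = sim.SimGenome.regular(n_pairs=4, length_cm=100.0,
                                       markers_per_group=14)
        hub = float(genome.marker_positions["LG1a"][7])
        pld = [sim.PlantedLD("P2", "LG1a", hub, "LG2a", hub, 0.96),
               sim.PlantedLD("P2", "LG1a", hub, "LG3a", hub, 0.96)]
        design = sim.SimDesign(n_progeny=n_progeny, n_biparental=28,
                               n_female=28, n_male=56,
                               multi_locus_fraction=0.0, missing_rate=0.05,
                               error_rate=0.01, planted_ld=pld)
        haplos = {p: sim.simulate_gametes(genome, design, p, rng)
                  for p in ("P1", "P2")}
        loci = sim.assign_loci(genome, design, rng)
        table, truth = sim.render_genotype_table(haplos, loci, design,
                                                 genome, rng)
        _genes, hits = sim.simulate_reference(genome, loci, rng=rng)
        hit_chrom = dict(zip(hits["query_id"], hits["chromosome"]))
        p1, p2 = split_parental(table)
        gof = truth.group_of()
        p1map = pd.DataFrame({
            "group": [gof[_strip(l.locus_id)] for l in p1],
            "locus_id": [l.locus_id for l in p1],
            "marker_id": [l.marker_id for l in p1]})
        ps = lk.pair_stats(p2)
        comps = lk.group(ps)
        merged = comps[0]
        true_groups = {gof[_strip(l)] for l in merged}
        if len(true_groups) >= 3:
            n_three += 1
        marker_of = {l.locus_id: l.marker_id for l in p2}
        subs, _ev = lk.disassemble(merged, ps, marker_of, p1map, hit_chrom)
        purs = []
        for sg in subs:
            counts: dict[str, int] = {}
            for l in sg:
                g = gof[_strip(l)]
                counts[g] = counts.get(g, 0) + 1
            purs.append(max(counts.values()) / len(sg))
        min_purities.append(min(purs))
    ok = sum(1 for p in min_purities if p >= 0.95)
    return {"frac_seeds_all_subgroups_pure": ok / n_seeds,
            "mean_min_purity": float(np.mean(min_purities)),
            "frac_seeds_overmerged": n_three / n_seeds}


def synteny_coverage(n_seeds: int = 5, seed: int = 0) -> dict:
    """Anchor coverage of synteny blocks on colinear simulations.

    With no rearrangement and decoy-only noise, chaining against the true
    map should place nearly every anchor inside a block, one block per
    linkage group.
    """
    from .io import best_hits
    from .synteny import build_anchors, chain_blocks

    covs, one_block = [], []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 1 + s)
        genome = sim.SimGenome.regular(n_pairs=8, length_cm=100.0,
                                       markers_per_group=14)
        n_loci = 16 * 14
        design = sim.SimDesign(n_progeny=10, n_biparental=0,
                               n_female=n_loci, n_male=0,
                               multi_locus_fraction=0.0)
        loci = sim.assign_loci(genome, design, rng)
        _genes, hits = sim.simulate_reference(genome, loci,
                                              decoy_fraction=0.1, rng=rng)
        mdf = loci.rename(columns={"pos_cm": "position_cm"})[
            ["group", "locus_id", "marker_id", "position_cm"]].copy()
        anchors = build_anchors(mdf, hits, evalue_max=1e-10)
        blocks = chain_blocks(anchors)
        in_blocks = sum(b.n_anchors for b in blocks)
        covs.append(in_blocks / len(anchors))
        per_group = pd.Series([b.group for b in blocks]).value_counts()
        one_block.append(bool((per_group == 1).all()
                              and len(per_group) == 16))
    return {"anchor_coverage": float(np.mean(covs)),
            "one_block_per_group_all_seeds": all(one_block)}
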