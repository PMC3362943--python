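"""End-to-end pipeline: simulate/load inputs, build parental maps with
suspect-group disassembly, integrate, scan LD, and detect synteny.

Every stage writes TSV outputs into the configured output directory and
logs record counts so filter effects stay auditable.  With a fixed seed and
configuration the data outputs are byte-identical across reruns (stage
timings go to the stderr log only, never into output files).
"""

from __future__ import annotations

import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import ld as cld
from . import linkage as lk
from . import simulate as sim
from . import synteny as syn
from .config import PipelineConfig
from .integrate import integrate, map_stats, infer_homeologs, classify_multilocus
from .ssr import find_ssrs_fasta, flag_designable, summarize_motifs
from .testcross import split_parental

log = logging.getLogger("clovermap")


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    for h in list(log.handlers):
        log.removeHandler(h)
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    fh = logging.FileHandler(outdir / "pipeline.log")
    fh.setFormatter(fmt)
    logging.getLogger("clovermap").addHandler(sh)
    logging.getLogger("clovermap").addHandler(fh)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - abort with stage name
                raise StageError(name, e) from e
            log.info("stage %s done in %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("simulate")
def stage_simulate(cfg: PipelineConfig, outdir: Path):
    s = cfg.sim
    rng = np.random.default_rng(cfg.seed)
    design = sim.SimDesign(
        n_progeny=s.n_progeny, n_biparental=s.n_biparental,
        n_female=s.n_female, n_male=s.n_male,
        multi_locus_fraction=s.multi_locus_fraction,
        missing_rate=s.missing_rate, error_rate=s.error_rate,
        planted_ld=[sim.PlantedLD(*pl) for pl in s.planted_ld],
        seed=cfg.seed)
    table, truth = sim.simulate_dataset(design=design, seed=cfg.seed,
                                        bp_per_cm=s.bp_per_cm)
    # distortion loci drawn once the genome exists
    if s.n_distortion_loci:
        groups = truth.genome.groups
        picks = rng.choice(len(groups), size=min(s.n_distortion_loci,
                                                 len(groups)), replace=False)
        design.distortion_loci = [
            ("P1" if k % 2 == 0 else "P2", groups[g],
             float(truth.genome.marker_positions[groups[g]][0]), s.distortion_s)
            for k, g in enumerate(picks)]
        table, truth2 = sim.render_genotype_table(
            truth.gametes, truth.loci, design, truth.genome, rng)
        truth2.reference, truth2.hits = truth.reference, truth.hits
        truth = truth2
    cio.write_genotype_table(table, outdir / "genotypes.tsv")
    truth.loci.to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
    if truth.hits is not None:
        truth.hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
    log.info("simulated %d loci x %d progeny", len(truth.loci),
             table.n_progeny)
    return table, truth


@_stage("mine_ssr")
def stage_mine_ssr(cfg: PipelineConfig, outdir: Path, records=None):
    from Bio import SeqIO

    if records is None:
        if not cfg.fasta:
            return None
        records = list(SeqIO.parse(cfg.fasta, "fasta"))
    hits = find_ssrs_fasta(records, min_len=cfg.ssr_min_len,
                           max_mismatch=cfg.ssr_max_mismatch)
    lengths = {r.id: len(r.seq) for r in records}
    flag_designable(hits, lengths, amplicon=(cfg.amplicon_min,
                                             cfg.amplicon_max),
                    min_flank=cfg.min_flank)
    total_bases = sum(lengths.values())
    report = summarize_motifs(hits, total_bases)
    pd.DataFrame([dict(seq_id=h.seq_id, start=h.start, end=h.end,
                       motif=h.canonical_motif, unit_len=h.unit_len,
                       tract_len=h.tract_len, n_mismatches=h.n_mismatches,
                       designable=h.designable) for h in hits]
                 ).to_csv(outdir / "ssr_hits.tsv", sep="\t", index=False)
    report.to_frame().to_csv(outdir / "ssr_motif_report.tsv", sep="\t",
                             index=False)
    log.info("mined %d SSR tracts in %d bases (density %.0f bp/SSR)",
             report.n_hits, total_bases, report.density_bp or 0)
    return hits, report


def _build_parent_map(loci, cfg: PipelineConfig, parent: str,
                      partner_map=None, hit_chrom=None):
    """Group, optionally disassemble the suspect group, and order."""
    ps = lk.pair_stats(loci, min_n=cfg.pair_min_n)
    comps = lk.group(ps, lod_min=cfg.lod_group, rec_max=cfg.rec_max)
    total = sum(len(c) for c in comps)
    out_groups: list[list[str]] = []
    for c in comps:
        if (len(c) > cfg.suspect_fraction * total and partner_map is not None):
            log.warning("%s: group of %d loci (%.1f%% of %d) flagged as "
                        "over-merged; disassembling", parent, len(c),
                        100 * len(c) / total, total)
            marker_of = {lo.locus_id: lo.marker_id for lo in loci}
            subs, _ev = lk.disassemble(c, ps, marker_of, partner_map,
                                       hit_chrom, lod_min=cfg.lod_group,
                                       rec_max=cfg.rec_max)
            out_groups.extend(subs)
        else:
            out_groups.append(c)
    out_groups.sort(key=lambda c: (-len(c), c[0]))

    by_id = {lo.locus_id: lo for lo in loci}
    frames = []
    for k, ids in enumerate(out_groups, start=1):
        gid = f"{parent}-LG{k:02d}"
        lg = lk.order_group(ps, ids, jump=cfg.jump,
                            lod_order_min=cfg.lod_order_min,
                            rec_max=cfg.rec_max, group_id=gid)
        frames.append(pd.DataFrame({
            "group": gid, "locus_id": lg.locus_ids,
            "marker_id": [by_id[l].marker_id for l in lg.locus_ids],
            "position_cm": lg.positions_cm,
            "seg_class": ["biparental" if by_id[l].locus_id.endswith(("_P1", "_P2"))
                          else ("female" if parent == "P1" else "male")
                          for l in lg.locus_ids],
            "distorted": [by_id[l].distorted for l in lg.locus_ids],
        }))
    return pd.concat(frames, ignore_index=True), ps


@_stage("map")
def stage_map(cfg: PipelineConfig, outdir: Path, table):
    p1, p2 = split_parental(table, alpha=cfg.alpha,
                            min_informative_frac=cfg.min_informative_frac)
    log.info("parental split: %d P1 loci, %d P2 loci", len(p1), len(p2))
    hit_chrom = None
    hits_path = outdir / "hits.tsv"
    if cfg.hit_table:
        hits = cio.read_hit_table(cfg.hit_table, evalue_max=cfg.evalue_prot)
        best = cio.best_hits(hits)
        hit_chrom = dict(zip(best["query_id"], best["chromosome"]))
    elif hits_path.exists():
        best = cio.best_hits(pd.read_csv(hits_path, sep="\t"))
        hit_chrom = dict(zip(best["query_id"], best["chromosome"]))
    map1, ps1 = _build_parent_map(p1, cfg, "P1")
    map2, ps2 = _build_parent_map(p2, cfg, "P2", partner_map=map1,
                                  hit_chrom=hit_chrom)
    cio.write_map(map1, outdir / "map_P1.tsv")
    cio.write_map(map2, outdir / "map_P2.tsv")
    map_stats(map1).to_csv(outdir / "map_P1_stats.tsv", sep="\t", index=False,
                           float_format="%.4g")
    map_stats(map2).to_csv(outdir / "map_P2_stats.tsv", sep="\t", index=False,
                           float_format="%.4g")
    calls = {**{lo.locus_id: lo.calls for lo in p1},
             **{lo.locus_id: lo.calls for lo in p2}}
    return map1, map2, calls


@_stage("integrate")
def stage_integrate(cfg: PipelineConfig, outdir: Path, map1, map2, table):
    result = integrate(map1, map2, min_anchors=cfg.min_anchors)
    cio.write_map(result.map_df.drop(columns=["origin"]),
                  outdir / "map_integrated.tsv")
    stats = map_stats(result.map_df, fallback=result.fallback)
    stats.to_csv(outdir / "map_integrated_stats.tsv", sep="\t", index=False,
                 float_format="%.4g")
    pairing = infer_homeologs(result.map_df)
    pairing.to_csv(outdir / "homeolog_pairs.tsv", sep="\t", index=False)
    bands = {r.marker_id: r.band_count for r in table.rows}
    classes = classify_multilocus(map1, map2, result.map_df, bands, pairing,
                                  result.correspondence)
    classes.to_csv(outdir / "multilocus_classes.tsv", sep="\t", index=False)
    log.info("integrated map: %d loci in %d groups (%d fallback groups)",
             len(result.map_df), result.map_df["group"].nunique(),
             len(result.fallback))
    return result, stats, pairing


@_stage("ld")
def stage_ld(cfg: PipelineConfig, outdir: Path, map1, map2, calls):
    for parent, mdf in (("P1", map1), ("P2", map2)):
        res = cld.scan(mdf, calls, step_cm=cfg.ld_grid_cm,
                       r2_min=cfg.ld_r2_min, min_n=cfg.ld_min_n)
        res.write(outdir, prefix=f"ld_{parent}")
        log.info("LD scan %s: %d sampled loci, %d cross-group pairs with "
                 "r2 > %.2f", parent, len(res.sampled), len(res.cross_pairs),
                 cfg.ld_r2_min)
    return True


@_stage("synteny")
def stage_synteny(cfg: PipelineConfig, outdir: Path, map_df, hits):
    anchors = syn.build_anchors(map_df, hits, evalue_max=cfg.evalue_prot)
    blocks = syn.chain_blocks(anchors, min_anchors=cfg.synteny_min_anchors,
                              map_win_cm=cfg.synteny_map_win_cm,
                              ref_win_kb=cfg.synteny_ref_win_kb)
    loci_per_group = map_df.groupby("group")["locus_id"].nunique().to_dict()
    summary = syn.colinearity_summary(anchors, blocks, loci_per_group)
    syn.blocks_to_frame(blocks).to_csv(outdir / "synteny_blocks.tsv",
                                       sep="\t", index=False,
                                       float_format="%.3f")
    summary.to_csv(outdir / "synteny_summary.tsv", sep="\t", index=False,
                   float_format="%.3f")
    cio.write_links(blocks, outdir / "synteny_links.txt")
    log.info("synteny: %d anchors, %d blocks", len(anchors), len(blocks))
    return blocks, summary


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every configured stage; returns the output directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    cfg.to_yaml(outdir / "config_used.yaml")

    if cfg.genotype_table:
        table = cio.read_genotype_table(cfg.genotype_table)
        truth = None
    elif cfg.simulate:
        table, truth = stage_simulate(cfg, outdir)
    else:
        raise ValueError("configuration error: no genotype_table path given "
                         "and simulation is disabled")

    if cfg.fasta or truth is None:
        stage_mine_ssr(cfg, outdir)

    map1, map2, calls = stage_map(cfg, outdir, table)
    stage_integrate(cfg, outdir, map1, map2, table)
    stage_ld(cfg, outdir, map1, map2, calls)

    hits = None
    if cfg.hit_table:
        hits = cio.read_hit_table(cfg.hit_table, evalue_max=cfg.evalue_prot)
    elif truth is not None and truth.hits is not None:
        hits = truth.hits
    if hits is not None and len(hits):
        stage_synteny(cfg, outdir, map1, hits)
    return outdir
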