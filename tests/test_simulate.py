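"""Synthetic-data generator: determinism, meiosis model, planted features."""

import numpy as np
import pandas as pd
import pytest

from clovermap import simulate as sim
from clovermap.io import write_genotype_table
from clovermap.linkage import kosambi, kosambi_inverse
from clovermap.ld import r_squared
from clovermap.ssr import find_ssrs


def _genome_two_loci(d_cm):
    return sim.SimGenome(
        n_homeolog_pairs=1,
        group_lengths_cm={"LG1a": d_cm, "LG1b": d_cm},
        marker_positions={"LG1a": np.array([0.0, d_cm]),
                          "LG1b": np.array([0.0, d_cm])},
        homeolog_pairs=[("LG1a", "LG1b")],
        chrom_of_group={"LG1a": "chr1", "LG1b": "chr1"})


def test_seed_determinism_identical_tables(tmp_path):
    def build(seed):
        table, truth = sim.simulate_dataset(
            design=sim.SimDesign(n_progeny=40, n_biparental=8, n_female=12,
                                 n_male=12), seed=seed)
        p = tmp_path / f"t{seed}.tsv"
        write_genotype_table(table, p)
        return p.read_text(), truth.loci

    t1, l1 = build(5)
    t2, l2 = build(5)
    t3, _ = build(6)
    assert t1 == t2
    pd.testing.assert_frame_equal(l1, l2)
    assert t1 != t3


def test_zero_distance_loci_always_identical():
    genome = _genome_two_loci(0.0)
    design = sim.SimDesign(n_progeny=500, n_biparental=0, n_female=4,
                           n_male=0)
    h = sim.simulate_gametes(genome, design, "P1",
                             np.random.default_rng(0))["LG1a"]
    np.testing.assert_array_equal(h[0], h[1])


def test_unlinked_groups_are_independent():
    """Monte-Carlo independence: allele correlation 0 +- 3/sqrt(n)."""
    genome = _genome_two_loci(10.0)
    design = sim.SimDesign(n_progeny=100_000, n_biparental=0, n_female=4,
                           n_male=0)
    h = sim.simulate_gametes(genome, design, "P1", np.random.default_rng(1))
    a = h["LG1a"][0].astype(float)
    b = h["LG1b"][0].astype(float)
    corr = np.corrcoef(a, b)[0, 1]
    assert abs(corr) < 3 / np.sqrt(len(a))


def test_adjacent_recombination_matches_kosambi_inverse():
    """Observed recombinant fraction converges to kosambi_inverse(d)."""
    d = 17.0
    genome = _genome_two_loci(d)
    design = sim.SimDesign(n_progeny=100_000, n_biparental=0, n_female=4,
                           n_male=0)
    h = sim.simulate_gametes(genome, design, "P1",
                             np.random.default_rng(2))["LG1a"]
    obs = float(np.mean(h[0] != h[1]))
    r = kosambi_inverse(d)
    se = np.sqrt(r * (1 - r) / 100_000)
    assert abs(obs - r) < 4 * se


def test_planted_full_coupling_gives_r2_one():
    genome = sim.SimGenome.regular(n_pairs=2, length_cm=50,
                                   markers_per_group=6)
    pa = float(genome.marker_positions["LG1a"][3])
    pb = float(genome.marker_positions["LG2a"][3])
    design = sim.SimDesign(
        n_progeny=188, n_biparental=0, n_female=24, n_male=0,
        planted_ld=[sim.PlantedLD("P1", "LG1a", pa, "LG2a", pb, 1.0)])
    for seed in range(3):
        h = sim.simulate_gametes(genome, design, "P1",
                                 np.random.default_rng(seed))
        r2, n = r_squared(h["LG1a"][3], h["LG2a"][3])
        assert r2 == pytest.approx(1.0)


def test_planted_ld_r2_monotone_in_dprime():
    genome = sim.SimGenome.regular(n_pairs=2, length_cm=50,
                                   markers_per_group=6)
    pa = float(genome.marker_positions["LG1a"][3])
    pb = float(genome.marker_positions["LG2a"][3])
    means = []
    for dp in (0.0, 0.5, 0.9):
        vals = []
        for seed in range(10):
            pld = ([sim.PlantedLD("P1", "LG1a", pa, "LG2a", pb, dp)]
                   if dp else [])
            design = sim.SimDesign(n_progeny=188, n_biparental=0,
                                   n_female=24, n_male=0, planted_ld=pld)
            h = sim.simulate_gametes(genome, design, "P1",
                                     np.random.default_rng(100 + seed))
            r2, _ = r_squared(h["LG1a"][3], h["LG2a"][3])
            vals.append(r2)
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]
    assert means[2] == pytest.approx(0.81, abs=0.1)  # r2 ~ D'^2


def test_off_grid_anchor_rejected():
    genome = _genome_two_loci(10.0)
    design = sim.SimDesign(
        n_progeny=10, n_biparental=0, n_female=4, n_male=0,
        planted_ld=[sim.PlantedLD("P1", "LG1a", 3.33, "LG1b", 0.0, 0.9)])
    with pytest.raises(ValueError, match="off any marker"):
        sim.simulate_gametes(genome, design, "P1", np.random.default_rng(0))


# --- rendering -------------------------------------------------------------

def test_no_distortion_gives_balanced_allele_split():
    table, truth = sim.simulate_dataset(
        design=sim.SimDesign(n_progeny=188, n_biparental=0, n_female=320,
                             n_male=0, missing_rate=0.0, error_rate=0.0),
        seed=9)
    fracs = [row.calls["P1"].mean() for row in table.rows]
    # per-locus split is Binomial(188, 1/2); the mean over 320 loci is tight
    assert abs(np.mean(fracs) - 0.5) < 0.02
    assert max(abs(f - 0.5) for f in fracs) < 5 * np.sqrt(0.25 / 188)


def test_multi_locus_fraction_zero_gives_one_locus_per_marker():
    table, truth = sim.simulate_dataset(
        design=sim.SimDesign(n_progeny=20, n_biparental=10, n_female=15,
                             n_male=15, multi_locus_fraction=0.0), seed=1)
    assert truth.loci["marker_id"].is_unique
    assert (truth.loci["band_count"] == 1).all()


def test_multi_locus_markers_duplicate_onto_homeolog_partner():
    table, truth = sim.simulate_dataset(
        design=sim.SimDesign(n_progeny=20, n_biparental=20, n_female=30,
                             n_male=30, multi_locus_fraction=1.0), seed=2)
    dup = truth.loci.groupby("marker_id").filter(lambda g: len(g) == 2)
    assert len(dup) > 0
    pairs = {tuple(p) for p in truth.genome.homeolog_pairs}
    for _, g in dup.groupby("marker_id"):
        ga, gb = sorted(g["group"])
        assert (ga, gb) in pairs or (gb, ga) in pairs
        assert g["pos_cm"].nunique() == 1
        assert set(g["locus_id"].str[-1]) == {"a", "b"}


def test_full_call_error_decouples_locus_from_truth():
    """A locus rendered with 50% call error is independent of its
    neighbours: its pairwise recombination estimate sits near 0.5."""
    from clovermap.linkage import pair_stats

    genome = _genome_two_loci(1.0)
    design = sim.SimDesign(n_progeny=50_000, n_biparental=0, n_female=4,
                           n_male=0, missing_rate=0.0, error_rate=0.5)
    rng = np.random.default_rng(3)
    h = {"P1": sim.simulate_gametes(genome, design, "P1", rng), "P2": {}}
    loci = sim.assign_loci(genome, design, rng)
    table, _ = sim.render_genotype_table(h, loci, design, genome, rng)
    lg1a = [r for r in table.rows
            if loci.set_index("locus_id").loc[r.locus_id, "group"] == "LG1a"]
    ps = pair_stats(np.vstack([r.calls["P1"] for r in lg1a]),
                    [r.locus_id for r in lg1a], min_n=2)
    assert abs(ps.r_hat[0, 1] - 0.5) < 0.02


def test_distortion_shifts_allele_ratio():
    genome = _genome_two_loci(5.0)
    design = sim.SimDesign(n_progeny=2000, n_biparental=0, n_female=4,
                           n_male=0, missing_rate=0.0, error_rate=0.0,
                           distortion_loci=[("P1", "LG1a", 0.0, 0.6)])
    rng = np.random.default_rng(4)
    h = {"P1": sim.simulate_gametes(genome, design, "P1", rng), "P2": {}}
    loci = sim.assign_loci(genome, design, rng)
    table, truth = sim.render_genotype_table(h, loci, design, genome, rng)
    sel = loci.set_index("locus_id")
    target = [r for r in table.rows
              if sel.loc[r.locus_id, "group"] == "LG1a"
              and sel.loc[r.locus_id, "pos_cm"] == 0.0][0]
    frac_b = target.calls["P1"].mean()
    # viability weights 1 : (1-s) -> expected b fraction 0.4/1.4 ~ 0.286
    assert abs(frac_b - 0.4 / 1.4) < 0.04


# --- transcripts -----------------------------------------------------------

def test_planted_tract_recovered_by_miner():
    rng = np.random.default_rng(0)
    recs, truth = sim.simulate_transcripts(
        30, length_range=(400, 600), plant_rate_per_kb=2.0, rng=rng)
    hits = {(h.seq_id): h for r in recs
            for h in find_ssrs(str(r.seq), seq_id=r.id)}
    found = 0
    all_hits = []
    for r in recs:
        all_hits.extend(find_ssrs(str(r.seq), seq_id=r.id))
    for t in truth.itertuples():
        cover = [h for h in all_hits if h.seq_id == t.seq_id
                 and h.start <= t.start and h.end >= t.end]
        found += bool(cover)
    assert found == len(truth)


def test_short_planted_tract_not_reported():
    # a 14-nt di tract is below the 15-nt bound by construction
    seq = "C" * 50 + "AG" * 7 + "C" * 50
    assert find_ssrs(seq) == []


def test_mined_density_tracks_planted_density():
    recs, truth = sim.simulate_transcripts(
        300, length_range=(400, 1000), plant_rate_per_kb=1.0 / 4.7, seed=11)
    n_mined = sum(len(find_ssrs(str(r.seq), seq_id=r.id)) for r in recs)
    assert abs(n_mined - len(truth)) <= 0.1 * len(truth)


# --- synthetic reference ---------------------------------------------------

def _colinear_setup(seed=0, **kw):
    rng = np.random.default_rng(seed)
    genome = sim.SimGenome.regular(n_pairs=2, length_cm=100,
                                   markers_per_group=21)
    design = sim.SimDesign(n_progeny=10, n_biparental=0, n_female=84,
                           n_male=0, multi_locus_fraction=0.0)
    loci = sim.assign_loci(genome, design, rng)
    genes, hits = sim.simulate_reference(genome, loci, rng=rng, **kw)
    mdf = loci.rename(columns={"pos_cm": "position_cm"})[
        ["group", "locus_id", "marker_id", "position_cm"]]
    return genome, loci, mdf, hits


def test_colinear_reference_yields_one_block_per_group():
    from clovermap.synteny import build_anchors, chain_blocks

    genome, loci, mdf, hits = _colinear_setup()
    anchors = build_anchors(mdf, hits, evalue_max=1e-10)
    blocks = chain_blocks(anchors)
    per_group = pd.Series([b.group for b in blocks]).value_counts()
    assert len(per_group) == 4 and (per_group == 1).all()
    assert sum(b.n_anchors for b in blocks) == len(anchors)


def test_translocated_segment_yields_extra_block():
    from clovermap.synteny import build_anchors, chain_blocks

    rearr = [dict(group="LG1a", lo_cm=40.0, hi_cm=60.0, dest_chrom="chr2")]
    genome, loci, mdf, hits = _colinear_setup(rearrangements=rearr)
    anchors = build_anchors(mdf, hits, evalue_max=1e-10)
    blocks = chain_blocks(anchors)
    lg1a = [b for b in blocks if b.group == "LG1a"]
    chroms = {b.chromosome for b in lg1a}
    assert "chr2" in chroms  # recipient chromosome gained a block
    assert sum(b.chromosome == "chr2" for b in lg1a) == 1


def test_lower_bitscore_decoys_do_not_change_blocks():
    from clovermap.synteny import build_anchors, chain_blocks

    g1, l1, m1, clean = _colinear_setup(seed=3)
    g2, l2, m2, noisy = _colinear_setup(seed=3, decoy_fraction=0.5)
    a_clean = build_anchors(m1, clean, evalue_max=1e-10)
    a_noisy = build_anchors(m2, noisy, evalue_max=1e-10)
    assert [(a.marker_id, a.chromosome) for a in a_clean] \
        == [(a.marker_id, a.chromosome) for a in a_noisy]
    b1 = chain_blocks(a_clean)
    b2 = chain_blocks(a_noisy)
    assert len(b1) == len(b2)


def test_design_validation_rejects_bad_rates():
    with pytest.raises(ValueError):
        sim.SimDesign(missing_rate=1.5).validate()
    with pytest.raises(ValueError):
        sim.SimDesign(n_progeny=1).validate()
    with pytest.raises(ValueError):
        sim.SimDesign(planted_ld=[sim.PlantedLD("P1", "a", 0, "b", 0,
                                                1.2)]).validate()
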