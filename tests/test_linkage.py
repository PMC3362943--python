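"""Two-point statistics, grouping, Kosambi, ordering, and disassembly."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clovermap import linkage as lk
from clovermap import simulate as sim
from clovermap.testcross import split_parental
from tests.conftest import strip_suffix


# --- Kosambi map function --------------------------------------------------

def test_kosambi_closed_form_values():
    assert lk.kosambi(0.0) == 0.0
    assert lk.kosambi(0.25) == pytest.approx(25 * np.log(3), abs=1e-9)
    assert lk.kosambi_inverse(0.0) == 0.0


def test_kosambi_roundtrip_to_1e12():
    r = np.arange(0.01, 0.50, 0.01)
    back = lk.kosambi_inverse(lk.kosambi(r))
    assert np.max(np.abs(back - r)) < 1e-12


def test_kosambi_clamps_into_half_open_interval():
    assert lk.kosambi(0.7) < np.inf
    assert lk.kosambi_inverse(1e9) < 0.5


# --- pairwise statistics ---------------------------------------------------

def _pair(ci, cj, min_n=2):
    X = np.vstack([ci, cj]).astype(np.int8)
    return lk.pair_stats(X, ["i", "j"], min_n=min_n)


def test_fully_coupled_pair_lod_is_n_log10_2():
    c = np.tile([0, 1], 94).astype(np.int8)
    ps = _pair(c, c)
    assert ps.r_hat[0, 1] == 0.0
    assert ps.lod[0, 1] == pytest.approx(188 * np.log10(2), abs=1e-9)
    assert ps.lod[0, 1] == pytest.approx(56.59, abs=0.01)


def test_half_recombinant_pair_has_zero_lod():
    ci = np.array([0, 1] * 94, dtype=np.int8)
    cj = np.concatenate([ci[:94], 1 - ci[94:]])
    ps = _pair(ci, cj)
    assert ps.r_hat[0, 1] == 0.5
    assert ps.lod[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_phase_alignment_makes_flipped_vector_fully_linked():
    rng = np.random.default_rng(0)
    ci = rng.integers(0, 2, 188).astype(np.int8)
    ps = _pair(ci, 1 - ci)
    assert ps.r_hat[0, 1] == 0.0
    assert ps.flipped[0, 1]


def test_missing_calls_reduce_informative_count():
    ci = np.array([0, 1, 0, 1, -1, -1], dtype=np.int8)
    cj = np.array([0, 1, -1, 1, 0, 1], dtype=np.int8)
    ps = _pair(ci, cj)
    assert ps.n[0, 1] == 3
    assert ps.rec[0, 1] == 0


def test_rhat_estimator_bias_below_one_percent():
    """Min-phase r_hat over 1000 replicate pairs at the study sample size."""
    from clovermap.evaluation import rhat_bias

    res = rhat_bias(n_reps=1000, seed=3)
    for r, stats in res.items():
        assert abs(stats["bias"]) < 0.01, (r, stats)
        assert stats["rmse"] < 1.2 * stats["binomial_se"], (r, stats)


# --- grouping --------------------------------------------------------------

def test_grouping_splits_unlinked_chromosomes(small_dataset):
    table, truth = small_dataset
    p1, _ = split_parental(table)
    ps = lk.pair_stats(p1)
    comps = lk.group(ps)
    gof = truth.group_of()
    for comp in comps:
        assert len({gof[strip_suffix(l)] for l in comp}) == 1


def test_infinite_lod_threshold_gives_singletons(small_dataset):
    table, _ = small_dataset
    p1, _ = split_parental(table)
    ps = lk.pair_stats(p1)
    comps = lk.group(ps, lod_min=np.inf)
    assert all(len(c) == 1 for c in comps)


# --- ordering --------------------------------------------------------------

def _simulated_channel(seed, n_markers, length_cm, n=188, err=0.01,
                       miss=0.05):
    rng = np.random.default_rng(seed)
    genome = sim.SimGenome.regular(n_pairs=1, length_cm=length_cm,
                                   markers_per_group=n_markers)
    design = sim.SimDesign(n_progeny=n, n_biparental=0,
                           n_female=2 * n_markers, n_male=0,
                           missing_rate=miss, error_rate=err)
    X = sim.simulate_gametes(genome, design, "P1", rng)["LG1a"].copy()
    e = rng.random(X.shape) < err
    X[e] ^= 1
    mk = rng.random(X.shape) < miss
    X[mk] = lk.MISSING
    ids = [f"L{k:02d}" for k in range(n_markers)]
    return lk.pair_stats(X, ids), ids


def test_two_locus_group_length_is_kosambi_distance():
    rng = np.random.default_rng(1)
    n = 10000  # large n so r_hat is essentially exact
    ci = rng.integers(0, 2, n).astype(np.int8)
    rec = np.zeros(n, dtype=bool)
    rec[: n // 10] = True  # exactly 10% recombinants
    cj = ci ^ rec
    ps = lk.pair_stats(np.vstack([ci, cj]), ["a", "b"], min_n=2)
    lg = lk.order_group(ps, ["a", "b"])
    assert lg.length_cm == pytest.approx(lk.kosambi(0.1), rel=1e-6)
    assert lg.length_cm == pytest.approx(10.14, abs=0.01)


def test_order_recovery_on_simulated_groups():
    ok = 0
    for seed in range(20):
        ps, ids = _simulated_channel(seed, 10, 100)
        lg = lk.order_group(ps, ids)
        if not lg.set_aside and (lg.locus_ids == ids
                                 or lg.locus_ids == ids[::-1]):
            ok += 1
    assert ok >= 19  # >= 95% of seeds


def test_estimated_map_length_unbiased():
    lengths = []
    for seed in range(50):
        ps, ids = _simulated_channel(seed, 20, 100)
        lg = lk.order_group(ps, ids)
        lengths.append(lg.length_cm)
    assert abs(np.median(lengths) - 100) <= 15


def test_random_noise_locus_is_set_aside():
    rng = np.random.default_rng(2)
    ps, ids = _simulated_channel(11, 10, 80)
    # replace one locus by pure noise (50% call error equivalent)
    X = np.vstack([rng.integers(0, 2, 188).astype(np.int8)])
    # rebuild with noise locus appended
    genome = sim.SimGenome.regular(n_pairs=1, length_cm=80,
                                   markers_per_group=10)
    design = sim.SimDesign(n_progeny=188, n_biparental=0, n_female=20,
                           n_male=0)
    G = sim.simulate_gametes(genome, design, "P1",
                             np.random.default_rng(11))["LG1a"]
    Xall = np.vstack([G, rng.integers(0, 2, 188, dtype=np.int8)])
    ids = [f"L{k:02d}" for k in range(10)] + ["NOISE"]
    ps = lk.pair_stats(Xall, ids)
    lg = lk.order_group(ps, ids)
    assert "NOISE" in lg.set_aside


def test_single_and_empty_groups():
    X = np.zeros((1, 10), dtype=np.int8)
    ps = lk.pair_stats(X, ["only"], min_n=2)
    lg = lk.order_group(ps, ["only"])
    assert lg.n_loci == 1 and lg.length_cm == 0.0


def test_ordering_matches_exhaustive_optimum_small_groups():
    """order_group misfit within 1% of the exhaustive-permutation optimum."""
    for seed in (0, 1, 2):
        ps, ids = _simulated_channel(seed, 7, 60)
        lg = lk.order_group(ps, ids)
        D = lk.kosambi(ps.r_hat)
        pii, pjj, pw, pdk, pse = lk._prepare_pairs(ps, 1.0, 0.4)
        pos_buf = np.zeros(len(ids))
        placed = np.ones(len(ids), dtype=bool)
        best = min(lk._misfit(np.array(perm), D, pos_buf, pii, pjj, pw, pdk,
                              pse, placed)
                   for perm in itertools.permutations(range(len(ids))))
        assert lg.misfit <= best * 1.01 + 1e-9


def test_orientation_fixed_by_lexicographic_terminal():
    ps, ids = _simulated_channel(4, 8, 60)
    lg = lk.order_group(ps, ids)
    assert lg.locus_ids[0] < lg.locus_ids[-1]
    assert lg.positions_cm[0] == 0.0
    assert np.all(np.diff(lg.positions_cm) >= 0)


# --- disassembly -----------------------------------------------------------

def test_disassembly_splits_overmerge_into_pure_subgroups():
    from clovermap.evaluation import disassembly_purity

    res = disassembly_purity(n_seeds=5, seed=1)
    assert res["frac_seeds_overmerged"] == 1.0
    assert res["frac_seeds_all_subgroups_pure"] == 1.0


def test_disassembly_of_true_single_chromosome_is_idempotent():
    ps, ids = _simulated_channel(3, 10, 60)
    partner = pd.DataFrame({"group": ["LGX"] * len(ids),
                            "locus_id": ids, "marker_id": ids})
    subs, ev = lk.disassemble(ids, ps, {i: i for i in ids}, partner, None)
    assert len(subs) == 1
    assert sorted(subs[0]) == sorted(ids)


def test_disassembly_precedence_partner_beats_reference():
    ps, ids = _simulated_channel(5, 6, 40)
    partner = pd.DataFrame({"group": ["LGA"] * 6, "locus_id": ids,
                            "marker_id": ids})
    # conflicting reference evidence says chr9 for everything
    hit_chrom = {i: "chr9" for i in ids}
    subs, ev = lk.disassemble(ids, ps, {i: i for i in ids}, partner,
                              hit_chrom)
    assert all(e.assigned == "LGA" for e in ev)
    assert all(e.source == "partner" for e in ev)


def test_disassembly_without_any_evidence_raises():
    ps, ids = _simulated_channel(6, 5, 40)
    empty = pd.DataFrame(columns=["group", "locus_id", "marker_id"])
    with pytest.raises(ValueError, match="cannot disassemble"):
        lk.disassemble(ids, ps, {i: i for i in ids}, empty, None)


def test_mosaicism_low_for_true_chromosome_high_for_shuffled():
    genome = sim.SimGenome.regular(n_pairs=1, length_cm=60,
                                   markers_per_group=10)
    design = sim.SimDesign(n_progeny=188, n_biparental=0, n_female=20,
                           n_male=0)
    G = sim.simulate_gametes(genome, design, "P1",
                             np.random.default_rng(0))["LG1a"]
    rng = np.random.default_rng(1)
    noise = rng.integers(0, 2, G.shape, dtype=np.int8)
    assert lk.mosaicism(G) < 0.15
    assert lk.mosaicism(noise) > 0.4
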