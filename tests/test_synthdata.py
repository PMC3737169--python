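"""Generator checks: founder panels, mosaics, HMM emulation, phenotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mpqtl import (
    GeneticMap,
    QTLEffectSpec,
    calibrate_qtl_effects,
    collapse_to_additive,
    emulate_hmm,
    make_crosses,
    simulate_founder_pair,
    simulate_founder_panel,
    simulate_phenotypes,
    simulate_ril_mosaic,
    simulate_ril_set,
)
from mpqtl.synthdata import _STATE_INDEX, GenotypeProbTensor, N_FOUNDERS, STATE_PAIRS

from conftest import MAF, qtl_phenotypes


# ---------------------------------------------------------------------------
# founder panels
# ---------------------------------------------------------------------------


def test_empty_panel_has_eight_founders(gmap):
    panel = simulate_founder_panel(0, gmap, MAF, seed=1)
    assert len(panel.founders) == 8
    assert panel.snps.empty


def test_panel_deterministic_under_seed(gmap):
    a = simulate_founder_panel(200, gmap, MAF, seed=5)
    b = simulate_founder_panel(200, gmap, MAF, seed=5)
    pd.testing.assert_frame_equal(a.snps, b.snps)
    c = simulate_founder_panel(200, gmap, MAF, seed=6)
    assert not a.snps.equals(c.snps)


def test_panel_maf_spectrum_matches_spec(gmap):
    """Carrier counts follow the discretization of the target uniform MAF.

    Oracle: a MAF m ~ U(0.05, 0.5) rounds to k = clip(round(8m), 1, 4)
    carriers out of 8, so the expected histogram over k is computed directly
    from the uniform CDF and compared by chi-square at alpha = 0.01.
    """
    panel = simulate_founder_panel(10_000, gmap, MAF, seed=11)
    counts = panel.snps[panel.founders].sum(axis=1).to_numpy()
    assert set(np.unique(counts)) <= {1, 2, 3, 4}
    lo, hi = 0.05, 0.5
    edges = [(lo, 1.5 / 8), (1.5 / 8, 2.5 / 8), (2.5 / 8, 3.5 / 8), (3.5 / 8, hi)]
    expected = np.array([(min(b, hi) - max(a, lo)) / (hi - lo) for a, b in edges])
    observed = np.array([(counts == k).sum() for k in (1, 2, 3, 4)])
    chi2 = stats.chisquare(observed, expected * len(counts))
    assert chi2.pvalue > 0.01


def test_invalid_maf_spec_rejected(gmap):
    with pytest.raises(ValueError):
        simulate_founder_panel(10, gmap, {"dist": "uniform", "low": 0.0, "high": 0.6}, seed=1)


def test_shared_founder_identical_across_panels(gmap):
    pa, pb = simulate_founder_pair(500, gmap, MAF, {"n_te": 5}, seed=3)
    assert (pa.snps["AB8"] == pb.snps["AB8"]).all()
    assert (pa.snps[["arm", "pos_bp"]] == pb.snps[["arm", "pos_bp"]]).all().all()
    assert (pa.tes["AB8"] == pb.tes["AB8"]).all()


# ---------------------------------------------------------------------------
# mosaics
# ---------------------------------------------------------------------------


def test_no_recombination_gives_single_founder_arms(gmap, pop):
    m = simulate_ril_mosaic(pop["pa"], gmap, breakpoint_rate=0.0, het_fraction=0.0, seed=4)
    for arm, segs in m.segments.items():
        assert len(segs) == 1
        start, end, (f1, f2) = segs[0]
        assert (start, end) == (0, gmap.arm_length_bp(arm))
        assert f1 == f2


def test_segments_tile_each_arm_exactly(gmap, pop):
    """1000 random RILs: segments exactly tile [0, arm_length) with no overlap."""
    rils = simulate_ril_set(pop["pa"], gmap, 1000, breakpoint_rate=50.0,
                            het_fraction=0.05, seed=20)
    for m in rils:
        for arm, segs in m.segments.items():
            assert segs[0][0] == 0
            assert segs[-1][1] == gmap.arm_length_bp(arm)
            for (s0, e0, _), (s1, e1, _) in zip(segs, segs[1:]):
                assert e0 == s1
                assert s0 < e0


def test_junction_count_matches_thinned_poisson():
    """On a 1-Morgan arm at 20 breakpoints/Morgan the mean number of realized
    segment junctions is 20 x (1 - 1/8): a uniform founder draw keeps a
    breakpoint only when the flanking founders differ (probability 7/8)."""
    g = GeneticMap.uniform({"A": 50_000_000}, cm_per_mb=2.0)  # 100 cM = 1 Morgan
    panel = simulate_founder_panel(0, g, MAF, seed=1)
    counts = []
    for i in range(1000):
        m = simulate_ril_mosaic(panel, g, breakpoint_rate=20.0, het_fraction=0.0, seed=1000 + i)
        counts.append(len(m.segments["A"]) - 1)
    counts = np.array(counts)
    expected = 20.0 * (1 - 1 / 8)
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - expected) < 3 * se


def test_het_fraction_bounds(gmap, pop):
    rils = simulate_ril_set(pop["pa"], gmap, 200, breakpoint_rate=50.0,
                            het_fraction=0.05, seed=30)
    het_bp = genome_bp = 0
    for m in rils:
        for arm, segs in m.segments.items():
            for s, e, (f1, f2) in segs:
                genome_bp += e - s
                if f1 != f2:
                    het_bp += e - s
    frac = het_bp / genome_bp
    assert 0.02 < frac < 0.09  # ~5% in expectation


# ---------------------------------------------------------------------------
# HMM emulation and additive collapse
# ---------------------------------------------------------------------------


def _true_states(mosaic, grid_bp=10_000):
    out = []
    for arm, segs in mosaic.segments.items():
        pos = np.arange(0, segs[-1][1], grid_bp)
        bounds = np.array([s[0] for s in segs] + [segs[-1][1]])
        idx = np.searchsorted(bounds, pos, side="right") - 1
        out.extend(_STATE_INDEX[segs[k][2]] for k in idx)
    return np.array(out)


def test_certainty_one_is_one_hot_truth(gmap, pop):
    m = pop["rils_a"][0]
    t = emulate_hmm(m, certainty=1.0, seed=9)
    truth = _true_states(m)
    assert np.array_equal(np.argmax(t.probs, axis=1), truth)
    assert np.all((t.probs == 0) | (t.probs == 1))


def test_soft_emulation_rows_sum_to_one_and_track_truth(gmap, pop):
    accs = []
    for m in pop["rils_a"][:5]:
        t = emulate_hmm(m, certainty=0.95, seed=10)
        assert np.allclose(t.probs.sum(axis=1), 1.0, atol=1e-9)
        assert t.probs.min() >= 0
        accs.append(np.mean(np.argmax(t.probs, axis=1) == _true_states(m)))
    assert np.mean(accs) >= 0.95


def test_emulate_hmm_rejects_bad_args(gmap, pop):
    m = pop["rils_a"][0]
    with pytest.raises(ValueError):
        emulate_hmm(m, certainty=0.0)
    with pytest.raises(ValueError):
        emulate_hmm(m, certainty=0.9, grid_bp=0)


def _tensor_from_row(row):
    grid = pd.DataFrame({"arm": ["A"], "pos_bp": [0]})
    return GenotypeProbTensor("r", grid, np.asarray(row, float)[None, :])


def test_additive_collapse_homozygous_and_heterozygous():
    hom = np.zeros(36)
    hom[_STATE_INDEX[(0, 0)]] = 1.0
    assert np.allclose(collapse_to_additive(_tensor_from_row(hom))[0],
                       [1, 0, 0, 0, 0, 0, 0, 0])
    het = np.zeros(36)
    het[_STATE_INDEX[(0, 1)]] = 1.0
    assert np.allclose(collapse_to_additive(_tensor_from_row(het))[0],
                       [0.5, 0.5, 0, 0, 0, 0, 0, 0])


def test_additive_collapse_preserves_row_sums():
    rng = np.random.default_rng(3)
    rows = rng.dirichlet(np.ones(36), size=50)
    grid = pd.DataFrame({"arm": ["A"] * 50, "pos_bp": np.arange(50)})
    add = collapse_to_additive(GenotypeProbTensor("r", grid, rows))
    assert np.allclose(add.sum(axis=1), 1.0, atol=1e-9)
    assert add.min() >= 0


def test_state_space_is_8_hom_plus_28_het():
    assert len(STATE_PAIRS) == 36
    assert sum(1 for i, j in STATE_PAIRS if i == j) == 8
    assert sum(1 for i, j in STATE_PAIRS if i != j) == 28


# ---------------------------------------------------------------------------
# crosses and phenotypes
# ---------------------------------------------------------------------------


def test_index_pairing_matches_compatible_subpops(gmap, pop):
    a = [m for m in pop["rils_a"][:3]]
    b = [m for m in pop["rils_b"][150:153]]  # pB2 half
    design = make_crosses(a, b)
    assert len(design) == 3
    assert (design["subpop_combo"] == "A1B2").all()


def test_empty_cross_design():
    assert make_crosses([], []).empty


def test_incompatible_pairing_rejected(pop):
    a1 = pop["rils_a"][0]  # pA1
    b1 = pop["rils_b"][0]  # pB1
    with pytest.raises(ValueError, match="incompatible"):
        make_crosses([a1], [b1], pairing=[(a1.ril_id, b1.ril_id)])


def test_deterministic_mean_with_no_variance(pop):
    phen = simulate_phenotypes(
        pop["design"], pop["probsA"], pop["probsB"], [], mu=60.4,
        subpop_effect=0.0, var_poly=0.0, var_env=0.0, seed=1,
    )
    reps = phen.table[["rep1", "rep2", "rep3"]].to_numpy()
    assert (reps == round(60.4)).all()


def test_phenotypes_deterministic_under_seed(pop):
    kw = dict(mu=60, subpop_effect=5, var_poly=50, var_env=160, seed=77)
    a = simulate_phenotypes(pop["design"], pop["probsA"], pop["probsB"], [], **kw)
    b = simulate_phenotypes(pop["design"], pop["probsA"], pop["probsB"], [], **kw)
    pd.testing.assert_frame_equal(a.table, b.table)


def test_qtl_position_off_grid_rejected(pop):
    q = QTLEffectSpec("2L", 99_000_000, np.ones(8), np.ones(8), 0.1)
    with pytest.raises((ValueError, KeyError)):
        simulate_phenotypes(pop["design"], pop["probsA"], pop["probsB"], [q],
                            mu=60, seed=1)


def test_qtl_variance_fraction_realized(pop):
    """The calibrated QTL's recorded genetic component carries the target
    share of total genetic variance (oracle: the simulator's own recorded
    generative components)."""
    rng = np.random.default_rng(8)
    q = QTLEffectSpec("2L", 1_500_000, rng.normal(size=8), rng.normal(size=8),
                      target_fraction=0.2)
    qtls, var_poly = calibrate_qtl_effects([q], pop["design"], pop["probsA"], pop["probsB"],
                                           var_genetic_total=100.0)
    phen = simulate_phenotypes(pop["design"], pop["probsA"], pop["probsB"], qtls,
                               mu=60, var_poly=var_poly, var_env=160, seed=9)
    v_qtl = np.var(phen.components["qtl1"])
    v_gen = np.var(phen.components["genetic"] + phen.components["polygenic"])
    assert v_qtl / v_gen == pytest.approx(0.2, rel=0.10)


def test_effect_vectors_centred():
    q = QTLEffectSpec("2L", 0, np.arange(8.0), np.arange(8.0) + 3, 0.1)
    assert q.paternal_effects.mean() == pytest.approx(0.0, abs=1e-12)
    assert q.maternal_effects.mean() == pytest.approx(0.0, abs=1e-12)


def test_heritability_recovery_through_generator(pop):
    """Round trip: phenotypes at V_g=100, V_e=160, r=3 recover H2 ~ 0.38 / 0.65."""
    y, _ = qtl_phenotypes(pop, [("2L", 1_500_000, 0.2)], seed=55)
    from mpqtl import estimate_heritability
    from mpqtl.synthdata import simulate_phenotypes as sim  # noqa: F401

    # build a full replicate table rather than means
    rng = np.random.default_rng(56)
    qtls, var_poly = calibrate_qtl_effects(
        [QTLEffectSpec("2L", 1_500_000, rng.normal(size=8), rng.normal(size=8), 0.2)],
        pop["design"], pop["probsA"], pop["probsB"], 100.0)
    phen = simulate_phenotypes(pop["design"], pop["probsA"], pop["probsB"], qtls,
                               mu=60, var_poly=var_poly, var_env=160, seed=57)
    h = estimate_heritability(phen.table)
    assert h.h2_individual == pytest.approx(100 / 260, abs=0.08)
    assert h.h2_cross_means == pytest.approx(100 / (100 + 160 / 3), abs=0.08)
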