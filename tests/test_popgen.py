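"""Diversity indices, AMOVA and χ² homogeneity."""

import numpy as np
import pytest

from mtfounder.popgen import (amova, composition_chi2, distance_matrix,
                              diversity, pairwise_phist)
from mtfounder.synthetic import FounderSpec, SimulationConfig, simulate_profiles
from mtfounder.variants import VariantProfile

from conftest import make_profile


def _profile(sid, positions, population="study", region=""):
    return make_profile(sid, [(p, "G") for p in positions],
                        population=population, region=region)


def test_diversity_of_identical_panel_is_zero():
    panel = [_profile(f"s{i}", [10]) for i in range(5)]
    d = diversity(panel)
    assert d.haplotype_diversity == 0.0
    assert d.nucleotide_diversity == 0.0
    assert d.segregating_sites == 0
    assert d.k == 1


def test_diversity_hand_worked_example():
    # haplotypes over 2 sites: AA, AA, AT, TT
    panel = [_profile("a", []), _profile("b", []),
             _profile("c", [2]), _profile("d", [1, 2])]
    d = diversity(panel, callable_sites=2)
    assert d.haplotype_diversity == pytest.approx(
        4 / 3 * (1 - 0.5 ** 2 - 0.25 ** 2 - 0.25 ** 2))
    # all 6 pairs: 0,1,2,1,2,1 -> mean 7/6
    assert d.mean_pairwise_differences == pytest.approx(7 / 6)
    assert d.nucleotide_diversity == pytest.approx(7 / 12)
    assert d.segregating_sites == 2
    assert d.k == 3


def test_diversity_undefined_below_two_samples():
    d = diversity([_profile("only", [])])
    assert "undefined_n_lt_2" in d.flags


def test_bottlenecked_panel_less_diverse_than_host():
    lower = 0
    for seed in range(25):
        cfg = SimulationConfig(seed=seed, study_n=12, reference_n=12,
                               founders=(FounderSpec("U3b1", 10, 500.0, 1),))
        profiles, _ = simulate_profiles(cfg)
        study = [p for p in profiles if p.population == "study"]
        host = [p for p in profiles if p.population == "reference"]
        if (diversity(study).haplotype_diversity
                < diversity(host).haplotype_diversity):
            lower += 1
    assert lower >= 22  # founder-dominated panels are less diverse


def test_amova_hand_worked_two_population_toy():
    # pop A: 4 identical samples; pop B: 4 identical samples at distance 3
    a = [_profile(f"a{i}", [], population="A") for i in range(4)]
    b = [_profile(f"b{i}", [1, 2, 3], population="B") for i in range(4)]
    res = amova({"A": a, "B": b}, n_permutations=99, seed=1)
    # hand-worked: all 16 cross pairs at d=3 -> squared 9
    # SS_total = (4*4*9)/8 = 18, SS_within = 0
    # sigma2_w = 0; n_c = (8 - (16+16)/8)/1 = 4; sigma2_a = 18/4 = 4.5
    assert res.ss_among == pytest.approx(18.0)
    assert res.ss_within == pytest.approx(0.0)
    assert res.sigma2_among == pytest.approx(4.5)
    assert res.phi_st == pytest.approx(1.0)
    assert res.percent_among == pytest.approx(100.0)
    assert res.percent_among + res.percent_within == pytest.approx(100.0)
    # only 8!/(4!4!) = 70 label arrangements; observed is the extreme one
    assert res.p_value < 0.1


def test_amova_hand_worked_with_within_group_variation():
    # pop A: two haplotypes {[], [1]} x2 each; pop B: {[9,10,11]} x4
    a = ([_profile(f"a{i}", [], population="A") for i in range(2)]
         + [_profile(f"a{i+2}", [1], population="A") for i in range(2)])
    b = [_profile(f"b{i}", [9, 10, 11], population="B") for i in range(4)]
    res = amova({"A": a, "B": b}, n_permutations=99, seed=1)
    # within A: pairs (a0,a1)=0 (a2,a3)=0, 4 cross pairs d=1 -> SS_A = 4*1/4 = 1
    # within B: 0. cross A-B: 8 pairs d=3 (d2=9), 8 pairs d=4 (d2=16)
    # SS_total = (2*0 + 4*1 + 2*0 + 8*9 + 8*16)/8 = 204/8 = 25.5
    ss_within = 1.0
    ss_total = (4 * 1 + 8 * 9 + 8 * 16) / 8
    assert res.ss_within == pytest.approx(ss_within)
    assert res.ss_among == pytest.approx(ss_total - ss_within)
    sigma2_w = ss_within / 6
    n_c = (8 - (16 + 16) / 8) / 1
    sigma2_a = ((ss_total - ss_within) / 1 - sigma2_w) / n_c
    assert res.sigma2_among == pytest.approx(sigma2_a)
    assert res.phi_st == pytest.approx(sigma2_a / (sigma2_a + sigma2_w))


def test_amova_identical_groups_near_zero_component():
    panel = [_profile("x1", []), _profile("x2", [5]),
             _profile("x3", [6]), _profile("x4", [5, 6])]
    groups = {"A": panel, "B": [VariantProfile(p.sample_id + "b", p.variants,
                                               population="B")
                                for p in panel]}
    res = amova(groups, n_permutations=199, seed=3)
    # mirrored compositions: the among-group estimate is non-positive and
    # far from significant
    assert res.sigma2_among <= 0
    assert res.p_value > 0.5


def test_amova_permutation_p_reproducible_under_seed():
    rng = np.random.default_rng(0)
    panel = [_profile(f"s{i}", list(rng.integers(1, 100, 3)),
                      population="A" if i < 6 else "B") for i in range(12)]
    groups = {"A": panel[:6], "B": panel[6:]}
    r1 = amova(groups, n_permutations=499, seed=11)
    r2 = amova(groups, n_permutations=499, seed=11)
    r3 = amova(groups, n_permutations=499, seed=12)
    assert r1.p_value == r2.p_value
    assert r1.phi_st == r2.phi_st == r3.phi_st


def test_negative_variance_components_reported_asis():
    # more variation within than between: expect a small negative component
    a = [_profile("a1", [1]), _profile("a2", [2, 3, 4])]
    b = [_profile("b1", [1]), _profile("b2", [2, 3, 4])]
    res = amova({"A": a, "B": b}, n_permutations=49, seed=5)
    assert res.sigma2_among < 0
    assert res.percent_among < 0
    assert res.percent_among + res.percent_within == pytest.approx(100.0)


def test_single_member_group_warns():
    groups = {"A": [_profile("a", [1])],
              "B": [_profile("b1", []), _profile("b2", [2])]}
    with pytest.warns(UserWarning, match="single member"):
        amova(groups, n_permutations=9, seed=0)


def test_pairwise_phist_equals_two_group_amova():
    rng = np.random.default_rng(7)
    groups = {}
    for g in ("A", "B", "C"):
        groups[g] = [_profile(f"{g}{i}", list(rng.integers(1, 60, 2)),
                              population=g) for i in range(5)]
    phi, pvals, names = pairwise_phist(groups, n_permutations=99, seed=2)
    assert names == ["A", "B", "C"]
    assert np.allclose(phi, phi.T) and np.allclose(np.diag(phi), 0)
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        res = amova({names[i]: groups[names[i]], names[j]: groups[names[j]]},
                    n_permutations=99, seed=2)
        assert phi[i, j] == pytest.approx(res.phi_st)
        assert pvals[i, j] == pytest.approx(res.p_value)


def test_phist_null_p_values_roughly_uniform():
    rng = np.random.default_rng(42)
    pvals = []
    for _ in range(150):
        # few segregating sites so pairwise distances actually vary
        panel = [_profile(f"s{i}",
                          [int(p) for p in
                           rng.choice(np.arange(1, 13), 3, replace=False)],
                          population="A" if i < 5 else "B")
                 for i in range(10)]
        res = amova({"A": panel[:5], "B": panel[5:]},
                    n_permutations=49, seed=int(rng.integers(2 ** 31)))
        pvals.append(res.p_value)
    pvals = np.array(pvals)
    assert 0.35 < pvals.mean() < 0.65
    assert (pvals <= 0.1).mean() < 0.25


def test_chi2_proportional_rows_give_zero():
    res = composition_chi2([[10, 20, 30], [1, 2, 3]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_chi2_diagonal_table():
    res = composition_chi2([[10, 0], [0, 10]])
    assert res.statistic == pytest.approx(20.0)
    assert res.df == 1
    assert not res.low_expected_warning   # expected counts are exactly 5
    assert composition_chi2([[4, 0], [0, 4]]).low_expected_warning


def test_chi2_zero_margin_dropped_with_warning():
    with pytest.warns(UserWarning, match="zero-margin"):
        res = composition_chi2([[5, 0, 5], [5, 0, 5]])
    assert res.dropped_cols == (1,)
    assert res.statistic == pytest.approx(0.0)


def test_chi2_null_p_roughly_uniform():
    rng = np.random.default_rng(9)
    pvals = []
    for _ in range(300):
        table = rng.multinomial(40, [0.25] * 4, size=2)  # same row law
        if (table.sum(axis=0) == 0).any():
            continue
        pvals.append(composition_chi2(table).p_value)
    pvals = np.array(pvals)
    assert 0.4 < pvals.mean() < 0.6
    assert abs((pvals <= 0.05).mean() - 0.05) < 0.05
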