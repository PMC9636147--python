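"""Ground-truth fidelity of the synthetic panel generator."""

import numpy as np
import pytest

from mtfounder.errors import ConfigError
from mtfounder.founders import ScanConfig, detect_founder_lineages, \
    exclusive_lineages
from mtfounder.haplogroups import classify_panel
from mtfounder.mito_io import call_variants
from mtfounder.synthetic import (FounderSpec, SimulationConfig,
                                 emulate_study_shape, simulate_panel,
                                 simulate_profiles)
from mtfounder.variants import format_variant


def test_recalling_variants_reproduces_manifest_exactly(reference):
    cfg = SimulationConfig(seed=5, study_n=12, reference_n=10,
                           founders=(FounderSpec("U3b1", 6, 1500.0, 2),),
                           hotspot_noise_rate=0.5)
    panel = simulate_panel(cfg)
    for record in panel.records:
        profile = call_variants(record.sequence, reference,
                                sample_id=record.sample_id)
        got = sorted(format_variant(v) for v in profile.variants)
        truth = panel.manifest["samples"][record.sample_id]
        expected = sorted(truth["planted_variants"]
                          + truth.get("hotspot_noise", []))
        assert got == expected, record.sample_id


def test_same_seed_byte_identical_outputs(tmp_path):
    cfg = SimulationConfig(seed=13, study_n=10, reference_n=8,
                           founders=(FounderSpec("H88a", 5, 900.0, 1),))
    d1 = tmp_path / "a"
    d2 = tmp_path / "b"
    p1 = simulate_panel(cfg).write(d1)
    p2 = simulate_panel(cfg).write(d2)
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key


def test_different_seeds_differ():
    a, _ = simulate_profiles(SimulationConfig(seed=1, study_n=5, reference_n=0))
    b, _ = simulate_profiles(SimulationConfig(seed=2, study_n=5, reference_n=0))
    assert [p.variants for p in a] != [p.variants for p in b]


@pytest.mark.parametrize("fraction,expected", [(0.0, 1.0), (1.0, 0.0)])
def test_admixture_boundary_founder_fractions(fraction, expected):
    cfg = SimulationConfig(seed=3, study_n=12, reference_n=10,
                           founders=(FounderSpec("U3b1", 12, 1000.0, 1),),
                           admixture_fraction=fraction)
    _, manifest = simulate_profiles(cfg)
    assert manifest["expected_founder_fraction"] == pytest.approx(expected)


def test_no_founder_config_never_yields_exclusive_lineages(tree, hotspots):
    for seed in range(50):
        cfg = SimulationConfig(seed=seed, study_n=20, reference_n=30,
                               founders=())
        profiles, _ = simulate_profiles(cfg)
        study = [p for p in profiles if p.population == "study"]
        host = [p for p in profiles if p.population == "reference"]
        calls = classify_panel(profiles, tree, hotspots)
        lineages = detect_founder_lineages(
            study, calls,
            ScanConfig(min_carriers=4, min_relative_frequency=4 / 20,
                       hotspots=hotspots, reference_panel=host))
        assert exclusive_lineages(lineages) == []


def test_planted_recovery_precision_and_recall_one(tree, hotspots):
    """Across seeded noise-free panels, detection is exact."""
    for seed in range(40):
        cfg = SimulationConfig(seed=seed, study_n=24, reference_n=24,
                               founders=(FounderSpec("U3b1", 6, 1500.0, 2),
                                         FounderSpec("M5a1b1a1", 5, 800.0, 1)))
        profiles, manifest = simulate_profiles(cfg)
        study = [p for p in profiles if p.population == "study"]
        host = [p for p in profiles if p.population == "reference"]
        calls = classify_panel(profiles, tree, hotspots)
        found = exclusive_lineages(detect_founder_lineages(
            study, calls,
            ScanConfig(min_carriers=4, min_relative_frequency=4 / 24,
                       hotspots=hotspots, reference_panel=host)))
        got = {(l.haplogroup, frozenset(l.carriers)) for l in found}
        truth = {(l["haplogroup"], frozenset(l["carriers"]))
                 for l in manifest["lineages"].values()}
        assert got == truth, seed


def test_bifurcating_genealogy_shares_branch_variants():
    cfg = SimulationConfig(seed=17, study_n=8, reference_n=0,
                           founders=(FounderSpec("U3b1", 8, 20000.0, 1),),
                           genealogy="bifurcating")
    profiles, manifest = simulate_profiles(cfg)
    label = next(iter(manifest["lineages"]))
    clade = [p for p in profiles
             if manifest["samples"][p.sample_id]["founder_lineage"] == label]
    signature = set(manifest["lineages"][label]["signature"])
    # some non-signature variant should be shared by >1 but not all tips
    shared_counts = {}
    for p in clade:
        for v in p.variants:
            s = format_variant(v)
            if s not in signature:
                shared_counts[s] = shared_counts.get(s, 0) + 1
    partial = [c for c in shared_counts.values() if 1 < c < len(clade)]
    assert partial, "expected shared internal-branch variants"


def test_roma_like_preset_shape():
    cfg = emulate_study_shape("roma-like", seed=1)
    assert cfg.study_n == 144
    assert cfg.reference_n == 1066
    assert len(cfg.founders) == 9
    total = sum(f.carriers for f in cfg.founders)
    assert total == 94
    assert total / cfg.study_n == pytest.approx(0.6528, abs=1e-4)
    sa = sum(f.carriers for f in cfg.founders
             if f.haplogroup.startswith("M"))
    assert sa / cfg.study_n == pytest.approx(0.139, abs=1e-3)
    with pytest.raises(ConfigError):
        emulate_study_shape("unknown")


def test_roma_like_expected_ages_recovered_in_expectation(tree, hotspots):
    """Planted clade ages are recovered by rho dating within Monte-Carlo
    error on the largest clade (averaged over seeds)."""
    from mtfounder.dating import date_clade

    ages = []
    true_age = 2100.0
    for seed in range(30):
        cfg = SimulationConfig(seed=seed, study_n=35, reference_n=0,
                               founders=(FounderSpec("U3b1", 35, true_age, 3),))
        profiles, manifest = simulate_profiles(cfg)
        label = next(iter(manifest["lineages"]))
        clade = [p for p in profiles
                 if manifest["samples"][p.sample_id]["founder_lineage"] == label]
        ages.append(date_clade(clade, hotspots=hotspots, L=cfg.L).age_years)
    se = np.std(ages) / np.sqrt(len(ages))
    assert abs(np.mean(ages) - true_age) < 3 * se + 50


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(study_n=-1)
    with pytest.raises(ConfigError):
        SimulationConfig(hotspot_noise_rate=1.5)
    with pytest.raises(ConfigError):
        SimulationConfig(genealogy="ladder")
    with pytest.raises(ConfigError):
        simulate_profiles(SimulationConfig(
            founders=(FounderSpec("NOPE", 5, 100.0, 1),)))
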