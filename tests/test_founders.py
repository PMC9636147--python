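"""Founder-lineage detection: thresholds, exclusivity, oracle equivalence."""

import numpy as np
import pytest

from mtfounder.errors import MissingCallsError
from mtfounder.founders import (ScanConfig, detect_founder_lineages,
                                exclusive_lineages, founder_fraction_summary,
                                frequency_threshold, scan_reference_population)
from mtfounder.haplogroups import classify_panel
from mtfounder.synthetic import FounderSpec, SimulationConfig, simulate_profiles


def test_frequency_threshold_matches_study_arithmetic():
    assert frequency_threshold(4, 144) == pytest.approx(0.0278, abs=5e-5)


def _run_scan(profiles, manifest, tree, hotspots, min_carriers=4,
              min_freq=None):
    study = [p for p in profiles if p.population == "study"]
    host = [p for p in profiles if p.population == "reference"]
    calls = classify_panel(profiles, tree, hotspots)
    cfg = ScanConfig(
        min_carriers=min_carriers,
        min_relative_frequency=(min_freq if min_freq is not None
                                else max(min_carriers, 1) / max(len(study), 1)),
        hotspots=hotspots, reference_panel=host)
    return detect_founder_lineages(study, calls, cfg), calls, cfg, study, host


def test_no_large_groups_yields_empty_list(tree, hotspots):
    cfg = SimulationConfig(seed=9, study_n=10, reference_n=10, founders=())
    profiles, manifest = simulate_profiles(cfg)
    lineages, *_ = _run_scan(profiles, manifest, tree, hotspots)
    assert exclusive_lineages(lineages) == []


def test_planted_exclusive_lineage_detected(tree, hotspots):
    cfg = SimulationConfig(seed=21, study_n=20, reference_n=30,
                           founders=(FounderSpec("U3b1", 6, 1500.0, 1),))
    profiles, manifest = simulate_profiles(cfg)
    lineages, *_ = _run_scan(profiles, manifest, tree, hotspots)
    found = exclusive_lineages(lineages)
    assert len(found) == 1
    lineage = found[0]
    truth = list(manifest["lineages"].values())[0]
    assert lineage.haplogroup == truth["haplogroup"] == "U3b1"
    assert lineage.carrier_count == 6
    assert sorted(lineage.carriers) == sorted(truth["carriers"])
    sig = {f"{p}{a}" for p, a in lineage.shared_variants}
    # planted signature strings carry the ref allele prefix; compare pos+alt
    assert sig == {s[1:] for s in truth["signature"]}
    assert lineage.exclusivity == "exclusive"


def test_signature_in_reference_panel_marks_violation(tree, hotspots):
    cfg = SimulationConfig(
        seed=22, study_n=20, reference_n=30,
        founders=(FounderSpec("U3b1", 6, 1500.0, 1, planted_in_reference=1),))
    profiles, manifest = simulate_profiles(cfg)
    lineages, *_ = _run_scan(profiles, manifest, tree, hotspots)
    assert len(lineages) == 1
    assert lineages[0].exclusivity == "violated"
    assert exclusive_lineages(lineages) == []
    # the nearest outside match is the planted violator with full overlap
    sid, overlap = lineages[0].nearest_outside_match
    assert overlap == len(lineages[0].shared_variants)


def test_uncalled_profiles_raise_listing_ids(tree, hotspots):
    cfg = SimulationConfig(seed=1, study_n=5, reference_n=0, founders=())
    profiles, _ = simulate_profiles(cfg)
    calls = classify_panel(profiles[:-1], tree, hotspots)
    with pytest.raises(MissingCallsError, match=profiles[-1].sample_id):
        detect_founder_lineages(profiles, calls, ScanConfig(hotspots=hotspots))


def _oracle_scan(study, calls, cfg, n_pop):
    """Exhaustive enumeration oracle: all (haplogroup, variant) carrier
    sets, threshold filter, largest-first disjoint collapse."""
    hs = cfg.hotspots.positions if cfg.hotspots else frozenset()
    out = []
    by_hg = {}
    for p in study:
        by_hg.setdefault(calls[p.sample_id].haplogroup, []).append(p)
    for hg in sorted(by_hg):
        qual = {p.sample_id: {s for s in calls[p.sample_id].private_variants
                              if s[0] not in hs} for p in by_hg[hg]}
        carrier_sets = set()
        for sid, states in qual.items():
            for s in states:
                carrier_sets.add(frozenset(
                    other for other, st in qual.items() if s in st))
        passing = [c for c in carrier_sets
                   if len(c) > cfg.min_carriers
                   and len(c) / n_pop >= cfg.min_relative_frequency]
        accepted = []
        for c in sorted(passing, key=lambda c: (-len(c), tuple(sorted(c)))):
            if all(not (c & a) for a in accepted):
                accepted.append(c)
        for c in accepted:
            sig = frozenset.intersection(*(frozenset(qual[s]) for s in c))
            if sig:
                out.append((hg, frozenset(c), sig))
    return out


def test_equivalence_with_enumeration_oracle_small_panels(tree, hotspots):
    for seed in range(15):
        cfg = SimulationConfig(
            seed=seed, study_n=18, reference_n=12,
            founders=(FounderSpec("M5a1b1a1", 5, 2000.0, 2),
                      FounderSpec("J1c1b", 6, 1000.0, 1)))
        profiles, manifest = simulate_profiles(cfg)
        lineages, calls, scan_cfg, study, host = _run_scan(
            profiles, manifest, tree, hotspots)
        got = {(l.haplogroup, frozenset(l.carriers),
                frozenset(l.shared_variants)) for l in lineages}
        expected = set(_oracle_scan(study, calls, scan_cfg, len(study)))
        assert got == expected


def test_raising_min_carriers_never_adds_lineages(tree, hotspots):
    cfg = SimulationConfig(seed=33, study_n=30, reference_n=20,
                           founders=(FounderSpec("U3b1", 8, 1500.0, 2),
                                     FounderSpec("H88a", 5, 800.0, 1)))
    profiles, manifest = simulate_profiles(cfg)
    counts = []
    for mc in (2, 4, 6, 8):
        lineages, *_ = _run_scan(profiles, manifest, tree, hotspots,
                                 min_carriers=mc, min_freq=1 / 30)
        counts.append(len(lineages))
    assert counts == sorted(counts, reverse=True)


def test_detected_lineages_satisfy_invariants(tree, hotspots):
    cfg = SimulationConfig(seed=4, study_n=25, reference_n=25,
                           founders=(FounderSpec("U3b1", 6, 1500.0, 2),
                                     FounderSpec("M18", 5, 1200.0, 1)))
    profiles, manifest = simulate_profiles(cfg)
    lineages, calls, scan_cfg, study, host = _run_scan(
        profiles, manifest, tree, hotspots)
    seen = set()
    host_states = [set(h.substitution_state(hotspots.positions).items())
                   for h in host]
    for l in lineages:
        assert l.carrier_count > scan_cfg.min_carriers
        assert l.relative_frequency >= scan_cfg.min_relative_frequency
        assert l.shared_variants
        assert not {p for p, _ in l.shared_variants} & set(hotspots.positions)
        assert not seen & set(l.carriers)  # unique membership
        seen |= set(l.carriers)
        if l.exclusivity == "exclusive":
            assert all(not set(l.shared_variants) <= hs for hs in host_states)


def test_fraction_summary_planted_panel(tree, hotspots):
    cfg = SimulationConfig(seed=77, study_n=20, reference_n=15,
                           founders=(FounderSpec("U3b1", 6, 1500.0, 2),))
    profiles, manifest = simulate_profiles(cfg)
    lineages, _, _, study, _ = _run_scan(profiles, manifest, tree, hotspots)
    summary = founder_fraction_summary(lineages, study)
    assert summary["founder_fraction"] == pytest.approx(6 / 20)
    assert sum(summary["fractions"].values()) == pytest.approx(1.0)
    cls_key = [k for k in summary["counts"] if k.startswith("founder")]
    assert cls_key == ["founder (West Eurasian)"]


def test_fraction_summary_no_lineages_all_non_founder(tree, hotspots):
    cfg = SimulationConfig(seed=8, study_n=8, reference_n=0, founders=())
    profiles, _ = simulate_profiles(cfg)
    summary = founder_fraction_summary([], profiles)
    assert summary["fractions"] == {"non-founder": 1.0}


def test_reference_scan_symmetry_and_region_mode(tree, hotspots):
    # same panel scanned as study and as reference gives the same groups
    cfg = SimulationConfig(seed=55, study_n=20, reference_n=0,
                           founders=(FounderSpec("U3b1", 6, 1500.0, 2),))
    profiles, manifest = simulate_profiles(cfg)
    calls = classify_panel(profiles, tree, hotspots)
    scan_cfg = ScanConfig(min_carriers=4, min_relative_frequency=4 / 20,
                          hotspots=hotspots, reference_panel=())
    direct = detect_founder_lineages(profiles, calls, scan_cfg)
    as_reference = scan_reference_population(profiles, calls, scan_cfg)
    assert [(l.haplogroup, l.carriers) for l in direct] == \
           [(l.haplogroup, l.carriers) for l in as_reference]

    # a 3-carrier regional cluster passes only in region mode (n > 2)
    cfg = SimulationConfig(seed=56, study_n=12, reference_n=0,
                           founders=(FounderSpec("H88a", 3, 800.0, 1),),
                           regions=("one",), region_proportions=(1.0,))
    profiles, manifest = simulate_profiles(cfg)
    calls = classify_panel(profiles, tree, hotspots)
    scan_cfg = ScanConfig(min_carriers=4, min_relative_frequency=3 / 12,
                          hotspots=hotspots, reference_panel=())
    whole = scan_reference_population(profiles, calls, scan_cfg)
    regional = scan_reference_population(profiles, calls, scan_cfg,
                                         by_region=True,
                                         region_min_carriers=2)
    assert len(whole) == 0
    assert len(regional) == 1 and regional[0].carrier_count == 3


def test_haplogroup_exclusion_mirrors_known_demography_filter(tree, hotspots):
    # clusters in an excluded haplogroup (e.g. a host-specific H1j1-like
    # clade) are not reported
    cfg = SimulationConfig(seed=57, study_n=15, reference_n=0,
                           founders=(FounderSpec("H1j1", 6, 800.0, 1),))
    profiles, manifest = simulate_profiles(cfg)
    calls = classify_panel(profiles, tree, hotspots)
    scan_cfg = ScanConfig(min_carriers=4, min_relative_frequency=4 / 15,
                          hotspots=hotspots, reference_panel=())
    assert len(scan_reference_population(profiles, calls, scan_cfg)) == 1
    assert scan_reference_population(profiles, calls, scan_cfg,
                                     exclude_haplogroups=("H1j1",)) == []
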