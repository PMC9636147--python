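"""Detect founder lineages: groups of >4 same-haplogroup carriers that
share at least one non-hotspot variant, exceed the relative-frequency
threshold, and are absent from the host reference panel.
"""

from mtfounder import (ScanConfig, classify_panel, default_hotspots,
                       detect_founder_lineages, emulate_study_shape,
                       exclusive_lineages, founder_fraction_summary,
                       frequency_threshold, load_haplotree,
                       simulate_panel)
from mtfounder.synthetic import simulate_profiles

cfg = emulate_study_shape("roma-like", seed=11, reference_n=60)
profiles, manifest = simulate_profiles(cfg)
study = [p for p in profiles if p.population == "study"]
host = [p for p in profiles if p.population == "reference"]

tree = load_haplotree()
hotspots = default_hotspots()
calls = classify_panel(profiles, tree, hotspots)

threshold = frequency_threshold(4, len(study))
print(f"frequency threshold: 4/{len(study)} = {threshold:.4f}\n")

scan = ScanConfig(min_carriers=4, min_relative_frequency=threshold,
                  hotspots=hotspots, reference_panel=host)
lineages = exclusive_lineages(detect_founder_lineages(study, calls, scan))

print(f"{'lineage':28s} {'haplogroup':10s} {'carriers':>8s} "
      f"{'freq':>7s}  signature")
for l in lineages:
    sig = "-".join(f"{pos}{alt}" for pos, alt in l.shared_variants)
    print(f"{l.label:28s} {l.haplogroup:10s} {l.carrier_count:8d} "
          f"{l.relative_frequency:7.4f}  {sig}")

summary = founder_fraction_summary(lineages, study)
print(f"\nfounder fraction: {summary['founder_fraction']:.4f} "
      f"({sum(l.carrier_count for l in lineages)}/{len(study)})")
print(f"planted lineages in manifest: {len(manifest['lineages'])}")
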