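"""Generate a study-shaped synthetic mitogenome panel with ground truth.

The generator plants founder clades of known haplogroup, carrier count
and age in a "study" population, alongside a host "reference" panel;
the manifest records exactly what was planted, so every downstream
result can be checked against truth.
"""

from pathlib import Path

from mtfounder import emulate_study_shape, simulate_panel

cfg = emulate_study_shape("roma-like", seed=11, reference_n=60)
panel = simulate_panel(cfg)

print(f"study samples:     {cfg.study_n}")
print(f"reference samples: {cfg.reference_n}")
print("planted founder lineages:")
for label, lineage in sorted(panel.manifest["lineages"].items()):
    print(f"  {label:28s} {lineage['haplogroup']:10s} "
          f"{lineage['n_carriers']:3d} carriers, "
          f"age {lineage['age_years']:.0f} y")

out = Path(__file__).parent / "output" / "panel"
paths = panel.write(out)
print("\nwritten:")
for name, p in sorted(paths.items()):
    print(f"  {name}: {p}")
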