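"""Call variants against the reference mitogenome and classify
haplogroups on the shipped phylotree-style tree.

Sequences are read from FASTA + metadata TSV, each is expressed as a
variant profile in standard mtDNA nomenclature, and the best-scoring
haplogroup is found by Kulczynski matching of expected vs. observed
variants.
"""

from pathlib import Path

from mtfounder import (FounderSpec, SimulationConfig, call_panel,
                       classify, default_hotspots, load_haplotree,
                       load_reference, read_fasta_panel, simulate_panel)
from mtfounder.variants import format_variant

# write a small panel to disk, then read it back like user data
out = Path(__file__).parent / "output" / "small_panel"
cfg = SimulationConfig(seed=4, study_n=6, reference_n=2,
                       founders=(FounderSpec("U3b1", 5, 1500.0, 2),))
paths = simulate_panel(cfg).write(out)

records = read_fasta_panel(paths["fasta"], paths["metadata"])
reference = load_reference()
tree = load_haplotree()
hotspots = default_hotspots()

profiles = call_panel(records, reference)
for profile in profiles:
    call = classify(profile, tree, hotspots)
    variants = " ".join(format_variant(v) for v in profile.variants)
    print(f"{profile.sample_id:14s} -> {call.haplogroup:10s} "
          f"(score {call.score:.3f})  {variants}")
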