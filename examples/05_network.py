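"""Build a median-joining network for a founder clade, extract the
rooted maximum-parsimony tree and render both to files.

Branch labels carry the variants changing along each branch; back
mutations are flagged with "@".
"""

from pathlib import Path

from mtfounder import (FounderSpec, SimulationConfig, build_mj_network,
                       default_hotspots, extract_parsimony_tree,
                       render_network)
from mtfounder.dating import infer_root_profile
from mtfounder.network import tree_length, tree_to_newick
from mtfounder.synthetic import simulate_profiles

cfg = SimulationConfig(seed=8, study_n=10, reference_n=0,
                       founders=(FounderSpec("U3b1", 10, 9000.0, 2),),
                       genealogy="bifurcating")
profiles, manifest = simulate_profiles(cfg)
hotspots = default_hotspots()

net = build_mj_network(profiles, hotspots=hotspots)
print(f"haplotypes: {len(net.observed_nodes())} observed, "
      f"{len(net.median_nodes())} median vectors")
print(f"network length: {net.length():g}")

root = infer_root_profile(profiles, hotspots=hotspots)
tree = extract_parsimony_tree(net, root, hotspots=hotspots)
print(f"parsimony tree length: {tree_length(tree):g}")
print("newick:", tree_to_newick(tree))

out = Path(__file__).parent / "output"
out.mkdir(parents=True, exist_ok=True)
render_network(net, gml_path=out / "clade.gml",
               figure_path=out / "clade.png")
render_network(tree, newick_path=out / "clade.nwk")
print(f"written: {out}/clade.gml, clade.png, clade.nwk")
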