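"""Haplogroup classification on a phylotree-style tree.

A haplogroup tree maps named nodes to their *defining* variants; a
node's *cumulative* profile is its parent's cumulative profile updated
by its defining variants (back mutations remove the position). Profiles
are assigned to the node maximising the Kulczynski set-overlap score

    score = 1/2 * ( |found ∩ expected| / |expected|
                  + |found ∩ expected| / |found| )

over non-hotspot substitution sites, with deterministic tie-breaking
(deepest node first, then lexicographic name). This mirrors how the
field's standard classifier ranks candidate haplogroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .errors import HaplotreeError
from .reference import HotspotList
from .variants import SUBSTITUTION, Variant, VariantProfile, parse_variant

SiteState = Tuple[int, str]  # (position, derived allele)


@dataclass
class HaplotreeNode:
    name: str
    parent: Optional["HaplotreeNode"] = None
    defining_variants: Tuple[Variant, ...] = ()
    children: List["HaplotreeNode"] = field(default_factory=list)
    depth: int = 0
    # cumulative expected substitution states, position -> derived allele
    cumulative: Dict[int, str] = field(default_factory=dict)

    def __repr__(self) -> str:  # keep recursion out of reprs
        return f"HaplotreeNode({self.name!r}, depth={self.depth})"

    def cumulative_states(self, exclude: Iterable[int] = ()) -> FrozenSet[SiteState]:
        ex = set(exclude)
        return frozenset((p, a) for p, a in self.cumulative.items() if p not in ex)


@dataclass
class Haplotree:
    root: HaplotreeNode
    nodes: Dict[str, HaplotreeNode]

    def __iter__(self):
        return iter(self.nodes.values())

    def __getitem__(self, name: str) -> HaplotreeNode:
        return self.nodes[name]

    def __len__(self) -> int:
        return len(self.nodes)


def load_haplotree(path=None) -> Haplotree:
    """Load a tree from TSV (``node<TAB>parent<TAB>variants``, parent
    ``-`` for the root, variants space-separated, ``@pos`` removing a
    position from the cumulative profile). With no path, the packaged
    synthetic mini-tree fixture is loaded.

    Orphans, duplicate names, cycles and malformed variant strings are
    rejected with :class:`HaplotreeError`.
    """
    if path is None:
        src = resources.files("mtfounder.data").joinpath("mini_haplotree.tsv")
    else:
        src = Path(path)

    rows: List[Tuple[str, str, str]] = []
    with src.open() as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise HaplotreeError(f"{src}:{ln}: need node and parent columns")
            name, parent = parts[0].strip(), parts[1].strip()
            vstr = parts[2].strip() if len(parts) > 2 else ""
            rows.append((name, parent, vstr))

    nodes: Dict[str, HaplotreeNode] = {}
    parents: Dict[str, str] = {}
    for name, parent, vstr in rows:
        if name in nodes:
            raise HaplotreeError(f"duplicate node name {name!r}")
        try:
            variants = tuple(parse_variant(tok) for tok in vstr.split() if tok)
        except Exception as exc:
            raise HaplotreeError(f"node {name!r}: bad variant string: {exc}") from exc
        nodes[name] = HaplotreeNode(name=name, defining_variants=variants)
        parents[name] = parent

    roots = [n for n, p in parents.items() if p in ("-", "", n)]
    if len(roots) != 1:
        raise HaplotreeError(f"expected exactly one root, found {roots}")
    root_name = roots[0]

    for name, parent in parents.items():
        if name == root_name:
            continue
        if parent not in nodes:
            raise HaplotreeError(f"orphan node {name!r}: parent {parent!r} unknown")
        nodes[name].parent = nodes[parent]
        nodes[parent].children.append(nodes[name])

    # cumulative profiles by BFS; any node not reached sits on a cycle
    order: List[HaplotreeNode] = [nodes[root_name]]
    seen = {root_name}
    i = 0
    while i < len(order):
        node = order[i]
        i += 1
        for child in node.children:
            if child.name in seen:
                raise HaplotreeError(f"cycle through node {child.name!r}")
            child.depth = node.depth + 1
            cum = dict(node.cumulative)
            for v in child.defining_variants:
                if v.is_back_mutation:
                    cum.pop(v.position, None)
                elif v.kind == SUBSTITUTION and v.alt_allele:
                    cum[v.position] = v.alt_allele
                # indels in defining sets are carried but not scored
            child.cumulative = cum
            seen.add(child.name)
            order.append(child)
    if len(seen) != len(nodes):
        missing = sorted(set(nodes) - seen)
        raise HaplotreeError(f"nodes unreachable from root (cycle?): {missing}")
    return Haplotree(root=nodes[root_name], nodes=nodes)


@dataclass(frozen=True)
class HaplogroupCall:
    sample_id: str
    haplogroup: str
    score: float
    found_variants: Tuple[SiteState, ...]
    missing_expected_variants: Tuple[SiteState, ...]
    private_variants: Tuple[SiteState, ...]


def _kulczynski(found: FrozenSet[SiteState], expected: FrozenSet[SiteState]) -> float:
    inter = len(found & expected)
    s1 = inter / len(expected) if expected else 1.0
    s2 = inter / len(found) if found else 1.0
    return 0.5 * (s1 + s2)


def classify(profile: VariantProfile, tree: Haplotree,
             hotspots: Optional[HotspotList] = None) -> HaplogroupCall:
    """Assign a profile to its best-matching haplogroup.

    Hotspot positions and the profile's missing positions are excluded
    from both the found and the expected sets. Ties are broken by depth
    (deeper wins), then lexicographic node name. The empty profile maps
    to the tree's reference (root) node with score 1.
    """
    exclude = set(hotspots.positions if hotspots else ()) | set(
        profile.missing_positions)
    found = frozenset(
        (v.position, v.alt_allele) for v in profile.substitutions()
        if v.position not in exclude and v.alt_allele is not None)

    best: Optional[Tuple[float, int, str, HaplotreeNode]] = None
    for node in tree:
        expected = node.cumulative_states(exclude)
        score = _kulczynski(found, expected)
        key = (score, node.depth, node.name)
        if best is None or (key[0], key[1]) > (best[0], best[1]) or (
                key[0] == best[0] and key[1] == best[1] and key[2] < best[2]):
            best = (score, node.depth, node.name, node)
    assert best is not None
    node = best[3]
    expected = node.cumulative_states(exclude)
    return HaplogroupCall(
        sample_id=profile.sample_id,
        haplogroup=node.name,
        score=best[0],
        found_variants=tuple(sorted(found & expected)),
        missing_expected_variants=tuple(sorted(expected - found)),
        private_variants=tuple(sorted(found - expected)),
    )


def classify_panel(profiles: Sequence[VariantProfile], tree: Haplotree,
                   hotspots: Optional[HotspotList] = None
                   ) -> Dict[str, HaplogroupCall]:
    return {p.sample_id: classify(p, tree, hotspots) for p in profiles}


# ---------------------------------------------------------------------------
# Macro-haplogroup ancestry classes

def load_macrogroup_table(path=None) -> Dict[str, str]:
    """Prefix -> ancestry class table; longest-prefix match wins."""
    if path is None:
        src = resources.files("mtfounder.data").joinpath("macrogroups.tsv")
    else:
        src = Path(path)
    table: Dict[str, str] = {}
    with src.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            prefix, cls = line.split("\t")
            table[prefix] = cls
    return table


def _is_clade_prefix(prefix: str, haplogroup: str) -> bool:
    """True when ``haplogroup`` names a subclade of ``prefix``.

    Haplogroup names alternate letter and digit blocks (M → M1 → M1a),
    so a true subclade boundary switches character class: M1a descends
    from M1, but M18 (digit after digit) and HV (letter after letter)
    are siblings, not descendants, of M1 and H.
    """
    if haplogroup == prefix:
        return True
    if not haplogroup.startswith(prefix):
        return False
    last, nxt = prefix[-1], haplogroup[len(prefix)]
    return last.isdigit() != nxt.isdigit()


def macrogroup_of(haplogroup: str, table: Optional[Dict[str, str]] = None) -> str:
    """Ancestry class of a haplogroup name by longest matching clade
    prefix; unmatched names map to ``"other"``."""
    if table is None:
        table = load_macrogroup_table()
    best = ""
    for prefix in table:
        if _is_clade_prefix(prefix, haplogroup) and len(prefix) > len(best):
            best = prefix
    return table[best] if best else "other"


def write_calls_tsv(calls: Dict[str, HaplogroupCall], path) -> None:
    import pandas as pd

    rows = [{"sample_id": c.sample_id, "haplogroup": c.haplogroup,
             "score": round(c.score, 6),
             "private_variants": " ".join(f"{p}{a}" for p, a in c.private_variants)}
            for c in calls.values()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
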