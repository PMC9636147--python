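"""Coding-consequence annotation and deleterious-load comparison.

Substitutions inside annotated protein genes are translated under the
vertebrate mitochondrial genetic code to decide synonymous vs
non-synonymous status (overlapping genes yield one consequence per
reading frame). Predicted pathogenicity scores for amino-acid changes
are consumed as a user-supplied lookup table; founder and non-founder
lineages are compared with a Mann–Whitney U test — exact by full
permutation enumeration for small groups, normal approximation with tie
correction otherwise.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .errors import EmptyGroupError, MtFounderError
from .reference import GeneAnnotation, ReferenceGenome
from .variants import SUBSTITUTION, Variant, VariantProfile

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

EXACT_MAX_N = 8


def translate_codon(codon: str) -> str:
    """One-letter amino acid (or ``*`` for stop) under the vertebrate
    mitochondrial code."""
    codon = codon.upper()
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table[codon]


@dataclass(frozen=True)
class CodingConsequence:
    variant: Variant
    gene: str
    codon_number: int       # 1-based codon index within the gene
    codon_position: int     # 1, 2 or 3
    ref_aa: str
    alt_aa: str

    @property
    def is_synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa


def _consequence_in_gene(v: Variant, gene: GeneAnnotation,
                         reference: ReferenceGenome) -> Optional[CodingConsequence]:
    seq = reference.sequence
    if gene.strand == "+":
        offset = v.position - (gene.start + gene.frame_offset)
        if offset < 0:
            return None
        codon_idx = offset // 3
        codon_start = gene.start + gene.frame_offset + 3 * codon_idx
        if codon_start + 2 > gene.end:
            return None  # incomplete terminal codon
        ref_codon = seq[codon_start - 1:codon_start + 2]
        pos_in_codon = v.position - codon_start  # 0..2
        alt_codon = (ref_codon[:pos_in_codon] + v.alt_allele
                     + ref_codon[pos_in_codon + 1:])
    else:
        offset = (gene.end - gene.frame_offset) - v.position
        if offset < 0:
            return None
        codon_idx = offset // 3
        codon_hi = gene.end - gene.frame_offset - 3 * codon_idx
        if codon_hi - 2 < gene.start:
            return None
        genome_codon = seq[codon_hi - 3:codon_hi]            # 5'->3' genome strand
        ref_codon = "".join(_COMPLEMENT[b] for b in reversed(genome_codon))
        pos_in_codon = codon_hi - v.position                  # 0..2 on coding strand
        alt_base = _COMPLEMENT[v.alt_allele]
        alt_codon = (ref_codon[:pos_in_codon] + alt_base
                     + ref_codon[pos_in_codon + 1:])
    return CodingConsequence(
        variant=v, gene=gene.name, codon_number=codon_idx + 1,
        codon_position=pos_in_codon + 1,
        ref_aa=translate_codon(ref_codon), alt_aa=translate_codon(alt_codon))


def annotate_coding(profile: VariantProfile,
                    reference: ReferenceGenome) -> List[CodingConsequence]:
    """Amino-acid consequences of a profile's coding substitutions.

    A substitution covered by two overlapping protein genes (ATP8/ATP6,
    ND4L/ND4) yields one consequence per frame. RNA-gene and
    control-region variants carry no consequence (use
    :meth:`ReferenceGenome.region_of` to classify them). Deterministic.
    """
    out: List[CodingConsequence] = []
    for v in profile.substitutions():
        if v.alt_allele is None or v.alt_allele not in "ACGT":
            continue
        for gene in reference.genes_at(v.position):
            if gene.kind != "protein":
                continue
            cons = _consequence_in_gene(v, gene, reference)
            if cons is not None:
                out.append(cons)
    return out


# ---------------------------------------------------------------------------
# Pathogenicity score table

class PathogenicityTable:
    """Lookup of predicted pathogenicity scores in [0, 1].

    Rows are keyed by (gene, codon_number, alt_aa) — or, when the table
    carries a nucleotide ``position`` column instead, by (position,
    alt_aa). Duplicate keys are rejected.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        cols = set(frame.columns)
        if {"gene", "codon"}.issubset(cols):
            keys = list(zip(frame["gene"], frame["codon"].astype(int),
                            frame["alt_aa"]))
        elif "position" in cols:
            keys = list(zip(frame["position"].astype(int), frame["alt_aa"]))
        else:
            raise MtFounderError(
                "score table needs columns (gene, codon, alt_aa, score) "
                "or (position, alt_aa, score)")
        scores = frame["score"].astype(float)
        if ((scores < 0) | (scores > 1)).any():
            raise MtFounderError("pathogenicity scores must lie in [0, 1]")
        if len(set(keys)) != len(keys):
            raise MtFounderError("duplicate keys in pathogenicity table")
        self._scores: Dict[tuple, float] = dict(zip(keys, scores))

    def __len__(self) -> int:
        return len(self._scores)

    @classmethod
    def from_tsv(cls, path) -> "PathogenicityTable":
        return cls(pd.read_csv(path, sep="\t"))

    def lookup(self, cons: CodingConsequence) -> Optional[float]:
        key = (cons.gene, cons.codon_number, cons.alt_aa)
        if key in self._scores:
            return self._scores[key]
        return self._scores.get((cons.variant.position, cons.alt_aa))


# ---------------------------------------------------------------------------
# Mann–Whitney U

def mann_whitney(x: Sequence[float], y: Sequence[float]
                 ) -> Tuple[float, float, str]:
    """Two-sided Mann–Whitney U.

    For groups of at most 8 each, the exact two-sided p-value is found
    by enumerating all label arrangements of the pooled sample (midranks
    handle ties): p = P(|U − nm/2| ≥ |U_obs − nm/2|). Larger groups use
    the tie-corrected normal approximation.

    Returns (U of the first group, p, method).
    """
    x, y = list(map(float, x)), list(map(float, y))
    if not x or not y:
        raise EmptyGroupError("both groups must be non-empty")
    n, m = len(x), len(y)
    pooled = np.array(x + y)
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2)

    if n <= EXACT_MAX_N and m <= EXACT_MAX_N:
        mid = n * m / 2.0
        dev_obs = abs(u_obs - mid)
        hits = 0
        total = 0
        for idx in itertools.combinations(range(n + m), n):
            u = float(ranks[list(idx)].sum() - n * (n + 1) / 2)
            if abs(u - mid) >= dev_obs - 1e-12:
                hits += 1
            total += 1
        return u_obs, hits / total, "exact"

    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "asymptotic"


# ---------------------------------------------------------------------------
# Founder vs non-founder load comparison

@dataclass(frozen=True)
class LoadComparison:
    group_a: str
    group_b: str
    scores_a: Tuple[float, ...]
    scores_b: Tuple[float, ...]
    u_statistic: float
    p_value: float
    method: str
    direction: str  # which group has the higher mean score

    @property
    def mean_a(self) -> float:
        return float(np.mean(self.scores_a))

    @property
    def mean_b(self) -> float:
        return float(np.mean(self.scores_b))


def _group_scores(profiles: Sequence[VariantProfile],
                  reference: ReferenceGenome,
                  table: PathogenicityTable,
                  pooling: str,
                  restrict_positions: Optional[set] = None) -> List[float]:
    per_variant: Dict[tuple, float] = {}
    per_individual: List[float] = []
    for p in profiles:
        indiv: List[float] = []
        for cons in annotate_coding(p, reference):
            if cons.is_synonymous:
                continue
            if (restrict_positions is not None
                    and cons.variant.position not in restrict_positions):
                continue
            score = table.lookup(cons)
            if score is None:
                continue
            per_variant[(cons.gene, cons.codon_number, cons.alt_aa)] = score
            indiv.append(score)
        if indiv:
            per_individual.append(float(np.mean(indiv)))
    if pooling == "per_variant":
        return sorted(per_variant.values())
    if pooling == "per_individual":
        return per_individual
    raise MtFounderError(f"unknown pooling mode {pooling!r}")


def lineage_load_comparison(profiles: Sequence[VariantProfile],
                            membership: Mapping[str, str],
                            table: PathogenicityTable,
                            reference: ReferenceGenome,
                            pooling: str = "per_variant",
                            lineage_classes: Optional[Mapping[str, str]] = None,
                            scope: str = "all",
                            lineage_signatures: Optional[Mapping[str, set]] = None
                            ) -> List[LoadComparison]:
    """Compare predicted pathogenicity between founder and non-founder
    lineages.

    ``membership`` maps sample_id -> founder lineage label (absent =
    non-founder). With ``lineage_classes`` (label -> ancestry class) the
    founder side is additionally broken down per class against the
    non-founder group, raw p-values reported (apply multiple-testing
    control downstream if desired). ``scope="defining"`` restricts
    founder scores to the lineages' shared signature positions
    (requires ``lineage_signatures``: label -> set of positions).
    """
    founders = [p for p in profiles if p.sample_id in membership]
    non_founders = [p for p in profiles if p.sample_id not in membership]
    if not founders:
        raise EmptyGroupError("founder group is empty")
    if not non_founders:
        raise EmptyGroupError("non-founder group is empty")

    def restrict_for(samples: Sequence[VariantProfile]) -> Optional[set]:
        if scope != "defining":
            return None
        if lineage_signatures is None:
            raise MtFounderError("scope='defining' needs lineage_signatures")
        positions: set = set()
        for p in samples:
            label = membership.get(p.sample_id)
            if label and label in lineage_signatures:
                positions |= set(lineage_signatures[label])
        return positions

    comparisons: List[LoadComparison] = []

    def compare(name_a, group_a, name_b, group_b, restrict_a=None):
        sa = _group_scores(group_a, reference, table, pooling, restrict_a)
        sb = _group_scores(group_b, reference, table, pooling)
        if not sa or not sb:
            warnings.warn(f"no scored non-synonymous variants for "
                          f"{name_a if not sa else name_b}; comparison skipped")
            return
        u, p, method = mann_whitney(sa, sb)
        direction = name_a if np.mean(sa) > np.mean(sb) else name_b
        comparisons.append(LoadComparison(
            group_a=name_a, group_b=name_b,
            scores_a=tuple(sa), scores_b=tuple(sb),
            u_statistic=u, p_value=p, method=method, direction=direction))

    compare("founder", founders, "non-founder", non_founders,
            restrict_for(founders))

    if lineage_classes:
        by_class: Dict[str, List[VariantProfile]] = {}
        for p in founders:
            cls = lineage_classes.get(membership[p.sample_id], "other")
            by_class.setdefault(cls, []).append(p)
        for cls in sorted(by_class):
            compare(f"founder ({cls})", by_class[cls],
                    "non-founder", non_founders,
                    restrict_for(by_class[cls]))
    return comparisons


def write_load_tsv(comparisons: Sequence[LoadComparison], path) -> None:
    rows = [{"group_a": c.group_a, "group_b": c.group_b,
             "n_a": len(c.scores_a), "n_b": len(c.scores_b),
             "mean_a": round(c.mean_a, 4), "mean_b": round(c.mean_b, 4),
             "U": c.u_statistic, "p_value": c.p_value,
             "method": c.method, "higher_mean": c.direction}
            for c in comparisons]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
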