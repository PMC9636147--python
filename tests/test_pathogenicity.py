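"""Mitochondrial coding consequences and deleterious-load comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtfounder.errors import EmptyGroupError
from mtfounder.pathogenicity import (PathogenicityTable, annotate_coding,
                                     lineage_load_comparison, mann_whitney,
                                     translate_codon)
from mtfounder.synthetic import FounderSpec, SimulationConfig, simulate_panel
from mtfounder.variants import Variant, VariantProfile

from conftest import make_profile

# The vertebrate mitochondrial genetic code, frozen independently: the
# standard code with AGA/AGG -> stop, ATA -> Met, TGA -> Trp.
_STANDARD = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_MITO_OVERRIDES = {"AGA": "*", "AGG": "*", "ATA": "M", "TGA": "W"}
MITO_CODE = {**_STANDARD, **_MITO_OVERRIDES}


def test_translation_table_matches_vertebrate_mito_code_all_64_codons():
    for codon in map("".join, itertools.product("ACGT", repeat=3)):
        assert translate_codon(codon) == MITO_CODE[codon], codon


def _nd1_codon(reference, codon_number):
    gene = next(g for g in reference.genes if g.name == "ND1")
    start = gene.start + 3 * (codon_number - 1)
    return start, reference.sequence[start - 1:start + 2]


def test_all_nine_changes_of_one_codon_enumerate_correctly(reference):
    start, ref_codon = _nd1_codon(reference, 5)
    for offset in range(3):
        pos = start + offset
        ref_base = reference.base_at(pos)
        for alt in "ACGT":
            if alt == ref_base:
                continue
            profile = make_profile("x", [(pos, alt)], reference=reference)
            (cons,) = annotate_coding(profile, reference)
            alt_codon = ref_codon[:offset] + alt + ref_codon[offset + 1:]
            assert cons.gene == "ND1"
            assert cons.codon_number == 5
            assert cons.codon_position == offset + 1
            assert cons.ref_aa == MITO_CODE[ref_codon]
            assert cons.alt_aa == MITO_CODE[alt_codon]
            assert cons.is_synonymous == (cons.ref_aa == cons.alt_aa)


def test_minus_strand_gene_uses_reverse_complement(reference):
    gene = next(g for g in reference.genes if g.name == "ND6")
    # first codon of ND6 sits at the gene's high end on the genome strand
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    genome_codon = reference.sequence[gene.end - 3:gene.end]
    coding_codon = "".join(comp[b] for b in reversed(genome_codon))
    pos = gene.end  # first base of the coding codon
    ref_base = reference.base_at(pos)
    alt = next(b for b in "ACGT" if b != ref_base)
    (cons,) = annotate_coding(make_profile("x", [(pos, alt)],
                                           reference=reference), reference)
    assert cons.gene == "ND6"
    assert cons.codon_number == 1
    assert cons.ref_aa == MITO_CODE[coding_codon]
    assert cons.alt_aa == MITO_CODE[comp[alt] + coding_codon[1:]]


def test_overlapping_genes_yield_one_consequence_per_frame(reference):
    # ATP8 (8366-8572) and ATP6 (8527-9207) overlap
    pos = 8530
    ref_base = reference.base_at(pos)
    alt = next(b for b in "ACGT" if b != ref_base)
    cons = annotate_coding(make_profile("x", [(pos, alt)],
                                        reference=reference), reference)
    assert sorted(c.gene for c in cons) == ["ATP6", "ATP8"]


def test_noncoding_variants_have_no_consequence(reference):
    profile = make_profile("x", [(16400, "A" if reference.base_at(16400) != "A"
                                  else "C")], reference=reference)
    assert annotate_coding(profile, reference) == []
    assert reference.region_of(16400) == "control"
    assert reference.region_of(700) == "rRNA"


# ---------------------------------------------------------------------------
# Mann–Whitney U

def test_exact_p_for_separated_triples():
    u, p, method = mann_whitney([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
    assert (u, method) == (0.0, "exact")
    assert p == pytest.approx(0.1)  # 2 extreme of 20 arrangements


def test_identical_multisets_give_p_one():
    _, p, method = mann_whitney([0.4, 0.5, 0.6], [0.4, 0.5, 0.6])
    assert method == "exact"
    assert p == pytest.approx(1.0)


def test_exact_path_matches_scipy_enumeration_when_tie_free():
    rng = np.random.default_rng(1)
    for _ in range(25):
        n, m = int(rng.integers(2, 8)), int(rng.integers(2, 8))
        pooled = rng.choice(np.arange(100), size=n + m, replace=False) / 100
        x, y = pooled[:n], pooled[n:]
        u, p, method = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert method == "exact"
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


def test_u_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    x = rng.uniform(0, 1, 6)
    y = rng.uniform(0, 1, 5)
    u1, p1, _ = mann_whitney(x, y)
    u2, p2, _ = mann_whitney(np.exp(3 * x), np.exp(3 * y))
    assert u1 == u2 and p1 == p2


def test_large_samples_use_asymptotic_method():
    rng = np.random.default_rng(3)
    _, p, method = mann_whitney(rng.uniform(0, 1, 30), rng.uniform(0, 1, 25))
    assert method == "asymptotic"
    assert 0 < p <= 1


def test_empty_group_rejected():
    with pytest.raises(EmptyGroupError):
        mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# Load comparison on a planted panel

@pytest.fixture(scope="module")
def planted_panel():
    cfg = SimulationConfig(seed=19, study_n=30, reference_n=30,
                           founders=(FounderSpec("U3b1", 8, 2500.0, 3),
                                     FounderSpec("M5a1b1a1", 6, 2500.0, 3)))
    return simulate_panel(cfg)


def test_planted_consequences_match_generator_bookkeeping(planted_panel,
                                                          reference):
    from mtfounder.variants import parse_variant

    truth = {(c["gene"], c["codon"], c["alt_aa"]): c
             for c in planted_panel.manifest["variant_consequences"]}
    assert truth, "panel should contain non-synonymous variation"
    sample = next(s for s, d in planted_panel.manifest["samples"].items()
                  if d["founder_lineage"])
    planted = planted_panel.manifest["samples"][sample]["planted_variants"]
    profile = VariantProfile(
        sample, tuple(parse_variant(v) for v in planted))
    for cons in annotate_coding(profile, reference):
        if cons.is_synonymous:
            continue
        key = (cons.gene, cons.codon_number, cons.alt_aa)
        assert key in truth
        assert truth[key]["ref_aa"] == cons.ref_aa


def test_founder_group_has_lower_predicted_load(planted_panel, reference):
    from mtfounder.variants import parse_variant

    table = PathogenicityTable(planted_panel.score_table)
    manifest = planted_panel.manifest
    profiles = []
    for sid, d in manifest["samples"].items():
        if d["population"] != "study":
            continue
        profiles.append(VariantProfile(
            sid, tuple(parse_variant(v) for v in d["planted_variants"])))
    membership = {sid: d["founder_lineage"]
                  for sid, d in manifest["samples"].items()
                  if d["founder_lineage"] and d["population"] == "study"}
    comparisons = lineage_load_comparison(profiles, membership, table,
                                          reference)
    overall = comparisons[0]
    assert overall.direction == "non-founder"
    assert overall.mean_a < overall.mean_b
    assert overall.p_value < 0.05


def test_score_table_validation():
    with pytest.raises(Exception, match="\\[0, 1\\]"):
        PathogenicityTable(pd.DataFrame(
            {"gene": ["ND1"], "codon": [1], "ref_aa": ["M"],
             "alt_aa": ["T"], "score": [1.5]}))
    with pytest.raises(Exception, match="duplicate"):
        PathogenicityTable(pd.DataFrame(
            {"gene": ["ND1", "ND1"], "codon": [1, 1],
             "ref_aa": ["M", "M"], "alt_aa": ["T", "T"],
             "score": [0.5, 0.6]}))
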