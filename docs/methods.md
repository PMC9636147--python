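# Methods

This note documents the statistical models, the parameters and their
defaults, the scope of the synthetic generator, and the numerical and
design choices made in `mtfounder`. It states what the package computes;
it makes no empirical claims beyond what the test suite verifies.

## Coordinate system and variant profiles

All sequences are expressed against a 16,569-bp circular mitochondrial
reference in 1-based coordinates. A sample is represented as a
`VariantProfile`: a sorted tuple of differences from the reference in
standard mtDNA nomenclature — substitutions (`A2833G`, or the bare
`2833G` form), deletions (`8281d`), insertions (`8280.1C`) and back
mutations (`@16261`). Sequences of full reference length are compared
column-wise; other lengths are globally aligned first (match +1,
mismatch −1, gap open −4, extend −1). IUPAC ambiguity codes become
missing positions; a sample with more than 5% missing positions is
flagged `high_missing` but not rejected.

## Haplogroup classification

Classification scores every node of a phylotree-style tree against the
sample. With `E` the node's cumulative expected variant set (root to
node, back mutations removing earlier expectations) and `F` the sample's
observed substitution states, the score is the Kulczynski coefficient

    score = 1/2 ( |F ∩ E| / |E| + |F ∩ E| / |F| ),

with either term defined as 1 when its denominator set is empty.
Hotspot positions and the sample's missing positions are excluded from
both sets. Ties are broken by preferring the deeper node, then
lexicographically. The shipped tree is a small utility tree whose node
set covers the haplogroups used by the synthetic presets; any
tab-separated `node / parent / variants` file in the same format can be
substituted, so a full phylotree export drops in without code changes.
Macrohaplogroup assignment uses longest clade-prefix matching with
letter/digit boundaries (so `M18` is not treated as a descendant of
`M1`).

## Founder-lineage detection

A founder lineage is a group of **more than** `min_carriers` (default 4)
study samples that

1. carry the same haplogroup call,
2. share at least one non-hotspot substitution beyond the haplogroup's
   cumulative profile (the candidate-defining state),
3. reach relative frequency `min_relative_frequency` (default 4/144 =
   0.0278) in the study panel, and
4. are *exclusive*: the group's full shared signature (the intersection
   of members' qualifying states) is carried by no sample of the host
   reference panel. Non-exclusive candidates are retained in reports
   with `exclusivity = "violated"` and the nearest outside match.

Candidate carrier sets are enumerated per (haplogroup, variant) pair;
overlapping candidates are collapsed largest-first so each sample
belongs to at most one lineage. The scan is deterministic and is tested
against an independent exhaustive enumeration.

## Clade dating (ρ statistic)

For a clade with inferred root haplotype (strict consensus of members'
states, or a supplied outgroup/root), ρ is the mean number of
substitutions separating each member from the root. The error follows
Saillard's estimator: for star-like data σ = √(ρ/n); when a genealogy is
supplied, σ = √(Σ nᵢ² ℓᵢ)/n over branches with ℓᵢ mutations and nᵢ
descendant tips.

Conversion to years uses a whole-molecule clock μ = 2.355 × 10⁻⁸
substitutions per site per year over L callable sites (16,569 minus
excluded hotspots), giving t = ρ/(μL) when no correction is applied.

The optional purifying-selection correction models the transient excess
of slightly deleterious variants on young branches:

    ρ(t) = μ L ( t + a τ (1 − e^(−t/τ)) ),   a = 0.41, τ = 2000 y.

The observed ρ is inverted for t by bracketed root finding (`brentq`),
and σ is converted through the local slope dρ/dt. The coefficients are
shipped as a JSON data file and are a stand-in for any published
time-dependent calibration the user prefers; corrected ages are always
younger than uncorrected ones and the inversion is tested to be
monotone and self-consistent.

## Median-joining networks and parsimony trees

Haplotypes are binary-encoded over their segregating substitution
sites, hotspot sites dropped. Inputs with more than 200 segregating
sites are refused (combinatorial blowup) unless forced.

*Small inputs* (≤ 8 segregating sites, ≤ 10 observed haplotypes, unit
weights, ε = 0) use an exact construction: the full median closure of
the observed haplotypes is computed (for binary characters the closure
— the median network — contains every maximum-parsimony tree), then
pruned to the node set of one canonical minimum Steiner tree found by
the Dreyfus–Wagner dynamic program. The resulting network therefore
provably contains a maximum-parsimony tree; tests verify this against
an independent Dreyfus–Wagner search over the full hypercube.

*Larger inputs* use the classic median-joining heuristic: Kruskal-style
ε-relaxed minimum spanning network, iterative insertion of median
(majority) vectors of connected triples, and removal of latent vectors
whose deletion does not lengthen the network. The heuristic carries no
optimality guarantee, matching the behaviour of standard MJ software.

`extract_parsimony_tree` takes a deterministic minimum spanning tree of
the network (edges sorted by weight, then endpoints), inserts the root
haplotype if absent, orients away from the root, and labels each branch
with its changing variants; a change restoring the root's state is
rendered `@position`. Networks export to GML, trees to Newick, figures
to PNG with node size scaled by carrier multiplicity and colour by
population.

## Population structure

Haplotype diversity H = n/(n−1) (1 − Σ pᵢ²); nucleotide diversity π =
mean pairwise substitution differences per callable site; S = number of
segregating sites.

AMOVA is the one-level Excoffier partition on squared substitution-count
distances: SS_total = (1/N) Σᵢ<ⱼ dᵢⱼ², within/among sums from group
blocks, n_c = (N − Σ nᵢ²/N)/(k − 1), Φ_ST = σ²_among/σ²_total. Negative
variance components are reported as computed. Significance is a label
permutation test with p = (#{Φ_perm ≥ Φ_obs} + 1)/(n_perm + 1); the
default of 999 permutations keeps whole-panel runs fast (the CLI's
`--permutations` raises it). The nested "regions within populations"
question is answered by stratified one-level runs, not a two-level
decomposition. Haplogroup-composition homogeneity uses the χ² test
without continuity correction, with zero-margin categories dropped
(warned) and a flag when any expected count is below 5.

## Coding consequences and deleterious load

Protein-coding consequences are computed per overlapping reading frame
(ATP8/ATP6 and ND4L/ND4 overlaps give one consequence per gene), on the
correct strand (ND6 is annotated on the minus strand), under the
vertebrate mitochondrial code (AGA/AGG → stop, ATA → Met, TGA → Trp).
Incomplete terminal codons are skipped.

Load comparison pools pathogenicity scores of non-synonymous variants
(per variant, or per individual sums) for founder vs non-founder
samples and applies a two-sided Mann–Whitney test: full permutation
enumeration with midranks when both groups have ≤ 8 observations
(deviation statistic |U − nm/2|), otherwise the tie-corrected normal
approximation. Scores must lie in [0, 1] and key duplicates are
rejected.

## Synthetic panels

The generator emulates a two-population study design:

- a host/reference panel of backbone haplotypes (configurable haplogroup
  pool) with Poisson(3) private variants per sample;
- founder clades planted in the study panel with known haplogroup,
  carrier count, signature length and age; tip variation is
  Poisson(μLt) per tip (star genealogy) or placed on the branches of a
  random bifurcating genealogy of depth t, sharing stem mutations among
  descendant tips;
- admixed study samples that are copies of host donors (fraction
  configurable), modelling shared haplotypes between the populations;
- optional exclusivity violations (copies of a founder signature planted
  into the host panel);
- hotspot noise at excluded positions and missing-data masking;
- a pathogenicity score table covering the panel's non-synonymous
  variants, drawn Beta(2,6) for founder-signature changes and Beta(6,2)
  otherwise, so the planted truth has milder founder load.

All variant positions are globally unique (drawn from a pool that
excludes tree-defining and hotspot positions), so every planted variant
is recallable and the manifest records the exact ground truth per
sample and per lineage. The same seed yields byte-identical panels. The
`"roma-like"` preset reproduces the shape of the motivating study: 144
study mitogenomes vs 1,066 host samples, nine founder lineages totalling
94 carriers (65.3% founder fraction, 13.9% of the study panel in South
Asian M lineages).

The generator does **not** model site-specific mutation-rate spectra,
heteroplasmy, sequencing error beyond ambiguity masking, indel
processes in planted variation, or within-host population structure.
Planted ages are exact tree depths, not coalescent draws.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng(seed)`; every
  public entry point that uses randomness takes a seed, and the pipeline
  derives stage seeds from its run seed, so whole runs are reproducible
  byte-for-byte.
- Exact-path size limits: Mann–Whitney enumeration at ≤ 8 per group;
  exact network construction at ≤ 8 sites / ≤ 10 haplotypes; networks
  refused above 200 segregating sites. These are the package's own
  tractability choices.
- Ages are reported in years and kya (rounded to 0.1 kya for display);
  internal computation is unrounded.
- The pipeline writes `report.json` (validated against a shipped JSON
  schema), `report.md`, TSV artifacts per stage, and SHA-256 digests of
  its inputs.

## Limitations

- The shipped haplogroup tree is a small utility tree; classification
  quality on real data depends on supplying a full phylotree export.
- The purifying-selection coefficients are a generic transient-excess
  parameterisation, not a fitted published calibration.
- The MJ heuristic above the exact-path limits can miss
  maximum-parsimony optima, as all MJ implementations can.
- One-level AMOVA only; no nested variance decomposition.
- ρ-based dating inherits the known biases of the method (root
  misspecification, non-star genealogies inflate σ); the genealogy-aware
  σ is available when a genealogy is supplied.
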