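# Methods

## Scope and model

`plastcub` implements the standard comparative analysis of synonymous codon
usage bias (CUB) in plastid protein-coding genes. The underlying model of
the field is that synonymous codon frequencies are shaped jointly by
mutation pressure (directional base composition drift, strongest at the
weakly constrained third codon position) and translational/natural
selection (preference for specific codons independent of composition). The
package computes the descriptive indices (RSCU, SCUO, ENC, CAI) and the
three classical diagnostics that separate the two forces (ENC-plot,
PR2-bias plot, neutrality plot), plus optimal-codon identification and
RSCU-based clustering of taxa.

## Genetic code and counting conventions

- Default translation table: NCBI table 11 (plant plastid), configurable by
  NCBI id. Under it, 59 codons are "analyzable": the 64 minus AUG and UGG
  (single-codon families) and the three stops. The degeneracy census is
  nine 2-fold, one 3-fold (Ile), five 4-fold and three 6-fold families.
- Sequences are read as DNA; codons are reported in the RNA alphabet.
- Triplets containing IUPAC ambiguity letters are excluded from every count
  and tallied per gene (`n_skipped`).
- Terminal stop codons are excluded from composition and all CUB statistics
  by default (they encode no amino acid); a flag retains them for
  diagnostics. Whether published pipelines include stops in GC3 varies by
  tool; exclusion is this package's documented choice.
- QC filter chain, in fixed order: frame (length divisible by 3), length
  ≥ 300 bp, duplicate, ATG start, terminal stop present, no internal stop.
  Each rejection is charged to the first failing rule. Deduplication is by
  exact nucleotide string (first occurrence kept); name-based deduplication
  is available because plastome inverted repeats carry identical gene
  copies under one name. Filtering is idempotent by construction.

## Index definitions and numerical choices

**RSCU.** RSCU_ij = X_ij / ((1/n_i) Σ_j X_ij). Zero counts are replaced by
0.5 *inside the RSCU computation only* (raw counts are used everywhere
else), so all values are strictly positive and each family still sums to
its degeneracy n_i — a property tested on random inputs.

**SCUO.** Per family, H_i = −Σ_j p_ij log2 p_ij with 0·log 0 = 0, and
SCUO_i = 1 − H_i / log2 n_i. The gene value is the unweighted mean of
SCUO_i over degeneracy-≥2 families observed at least once. The
amino-acid-frequency-weighted variant found in parts of the SCUO
literature is deliberately not used; the unweighted mean is the simpler
reading and the one this analysis standardises on. A gene with no observed
multi-codon family gets NaN, not an exception.

**Observed ENC.** Wright's estimator: per-family homozygosity
F = (n Σ p_j² − 1)/(n − 1), usable when the family total n ≥ 2 and F > 0;
class means F̄_k over usable families of degeneracy k; then
ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆. A missing 3-fold class (Ile unused)
is imputed as F̄₃ = (F̄₂ + F̄₄)/2, the CodonW convention; any other missing
class leaves ENC undefined (NaN) for that gene, and such genes are listed
in the ENC-plot result rather than silently dropped. The estimate is
capped into [20, 61] — equal-usage finite samples exceed 61 before capping
— and the raw value is also exposed.

**Expected ENC.** The null curve 2 + GC3 + 29/(GC3² + (1−GC3)²), evaluated
at all-third-position GC3 (not synonymous-only GC3s) because that is the
variable the rest of the pipeline uses; pipelines built on CodonW's GC3s
will differ slightly. The curve is not symmetric about 0.5: the linear
term offsets the branches by exactly 2d, hence 31 at GC3 = 0 vs 32 at 1.

**ENC-ratio.** (expected − observed)/expected; |ratio| ≤ 0.05 classifies a
gene as mutation-dominated, outside as selection-dominated. The window and
the ENC > 45 census threshold are parameters.

**CAI and the expression proxy.** Sharp & Li relative adaptiveness
w_ij = RSCU_ij / max_j RSCU_ij from a reference set; CAI is the
count-weighted geometric mean of w over a gene's analyzable codons. The
default reference is the taxon's own pooled filtered CDS — the only
self-contained, reproducible choice when no curated high-expression set is
supplied; a user reference is accepted. The reference's zero-substitution
keeps w > 0, so the geometric mean is always defined. The expression proxy
reported alongside is MILC = 1 − CAI. This is an idiosyncratic usage kept
for continuity with the analysis it supports: it is **not** the
Supek–Vlahoviček MILC statistic, and the docstrings say so.

**Correlations.** Pearson r across genes with the exact t-transform
two-tailed p (n − 2 df), stars at 0.05/0.01, no multiple-testing
correction (matching how such tables are conventionally reported).
Zero-variance variables yield NaN, flagged not raised.

**Neutrality.** OLS of GC12 on GC3 (scipy linregress). Genes exactly on
the y = x diagonal count as "above" (tie-break documented here). All-equal
GC3 gives NaN slope.

**Optimal codons.** Genes ranked by the expression proxy (MILC by
default; metric and tail fraction configurable), tails of
max(min_genes, round(fraction·n)) genes with ties broken by gene id;
counts pooled per library (per-gene-mean RSCU averaging is a documented
alternative the pipeline does not default to); entry criterion
ΔRSCU ≥ 0.08 with RSCU_high ≥ 1, star tiers at 0.08/0.3/0.5. Note the
criterion is applied to the high library's RSCU — the natural reading for
codons "optimal" in highly expressed genes. Raising either threshold can
only shrink the set (tested). **Caveat:** with tails of 5–9 genes the
per-codon sampling noise of ΔRSCU is of order 0.05–0.15, comparable to the
0.08 threshold, so entry counts at this scale are partly noise-driven and
should be read as candidate sets, not sharp inventories; the ranking
metric being itself a codon-usage statistic further correlates the tails
with specific codons.

**Clustering.** Pooled per-taxon counts → RSCU matrix (fixed row order:
amino acids alphabetically, codons alphabetically within family) →
Euclidean distances between taxon columns → average linkage (UPGMA).
Likelihood-based tree methods are undefined on RSCU vectors, so
agglomerative clustering is the principled choice; complete/Ward linkage
and correlation distance are options. Taxon columns are sorted by name
before linkage so ties resolve deterministically; merge heights become
branch lengths; trees serialize to Newick via scikit-bio and round-trip
stably.

## Synthetic data generator

Each gene is ATG + i.i.d. body codons + UAA, length drawn log-uniformly in
[300, 4500] nt (multiples of 3), 55 genes by default — the shape of a
filtered plastome CDS set. All randomness flows through one
`numpy.random.default_rng(seed)`; the same seed yields byte-identical
FASTA. Regimes:

- `uniform`: equal within-family codon probabilities, uniform amino-acid
  composition. Pooled RSCU → 1 by the law of large numbers.
- `at_biased`: A/U-ending codons up-weighted (default weight 3) in every
  family.
- `mutation_gradient`: per-gene GC pressure g ~ Uniform(0.2, 0.8); codon
  probability ∝ product of per-base weights (G/C: g/2, A/U: (1−g)/2) over
  all three positions, restricted to sense codons. GC1, GC2 and GC3 all
  track g, so GC12 regresses on GC3 with slope near 1 and within-family
  usage is exactly what third-position composition predicts (genes hug the
  expected-ENC curve).
- `selection_regime`: one fixed A/U-ending preferred codon per family
  (alphabetically first, recorded in the metadata) up-weighted identically
  in all genes, amino-acid composition fixed — so GC12 is decoupled from
  GC3 (slope near 0) and observed ENC falls below the expected curve.

`regime_truth` returns the recovery bands used by the tests: slope in
[0.7, 1.1] for `mutation_gradient`, [−0.1, 0.25] for `selection_regime`
(verified by simulation at 100 genes across seeds before freezing).

What the generator does *not* emulate: real amino-acid composition,
between-gene functional heterogeneity, inverted-repeat duplication,
annotation errors, and correlated (non-i.i.d.) codon order. Passing the
recovery tests therefore shows the estimators and diagnostics are correct
on data satisfying their assumptions, not that any particular biological
dataset will show a given signal.

## Problem sizes

The test suite and analysis scripts use 40–100-gene sets (roughly 20k–60k
codons per set) and 5-replicate seeds for the stochastic recovery checks —
sizes at which every slope band and construction guarantee is stable while
a full run stays interactive. The reference-quantity script
(`scripts/acceptance.py`) uses closed-form count tables whose scale is
drawn from the seed, since the identities it checks are scale-invariant.

## Known limitations

- CAI depends on the reference set; with the self-referenced default,
  absolute CAI/MILC levels are comparable within a taxon but only loosely
  across taxa or against published values computed with other references.
- ENC is undefined for genes missing a whole degeneracy class (short or
  compositionally extreme genes); they are reported, not imputed, except
  for the 3-fold class.
- PR2 coordinates are undefined when a third-position denominator is zero;
  such genes are flagged.
- GenBank CDS extraction trusts the annotation; differing annotation
  versions of the same accession yield differing gene sets.
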