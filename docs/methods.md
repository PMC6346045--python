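# Methods

## Problem setting

A germplasm panel of *n* cultivars (default 42) is profiled for (i)
transcript-level expression of a large gene family (TPM; 440 transcripts
from 414 genes by default, alternative transcripts named `Gene-1`,
`Gene-2`, …), (ii) the contents of nine mono-ginsenosides plus their total
(TS = Σ monos, enforced at relative tolerance 1e-9), and (iii) genic
SNP/InDel genotypes called from RNA-seq in transcript coordinates.
`cypscreen` ranks family members as biosynthesis candidates by requiring
three independent lines of evidence: expression–trait correlation,
variant–trait association, and co-expression with the trait-anchored
network.

## Stage 1 — correlation screen

Pearson correlation on raw TPM, two-tailed significance through
*t* = *r*·√((*n*−2)/(1−*r*²)) on *n*−2 df. Spearman is available as an
option but is never the default; the screen mirrors the default behaviour
of mainstream bivariate-correlation routines. Tiers are inclusive
(*p* ≤ α), and no multiple-testing correction is applied at this stage —
the screen is deliberately permissive and the correction enters at the
association stage. Zero-variance transcripts are skipped with a warning
rather than an error: they cannot carry signal, and aborting a 440-
transcript screen for one flat row helps nobody. Missing values are
rejected at validation; the intended input is a complete panel.

A gene passes a tier if ≥ 1 of its transcripts passes for ≥ 1 trait.
Reports count transcripts and genes separately, since isoforms of one gene
often co-pass.

## Stage 2 — variant filtering and association

Variants use anchored `pos_REF_ALT` notation (1-based transcript
coordinates, VCF-style shared leading base for indels). Genotypes are
binary carrier/non-carrier: pooled RNA-seq calls do not resolve diploid
dosage. The presence filter keeps variants carried by ≥ 4 cultivars; the
chance probability (1/L)^k quantifies why — four independent recurrences
of a sequencing/assembly artifact at one position of an average 1306-bp
transcript have probability ≈ 3.4e-13.

The association test defaults to the **pooled-variance Student t-test**,
which for a binary marker is algebraically the single-marker regression
(trait ~ genotype) of QTL mapping. We validated this choice by Monte
Carlo before fixing it: at the reference conditions (2-SD carrier effect,
12 of 42 carriers, strict threshold 1e-4, 20 000 replicates) the pooled
test has power ≈ 0.95 and a null *p* ≤ 0.05 rate of 0.0495, whereas the
Welch variant — attractive in principle because carrier groups are small —
pays for its larger critical values with power ≈ 0.87 under the same
conditions. Welch remains available via `test="welch"` for panels with
genuinely heteroskedastic groups. Variants with fewer than two carriers or
two non-carriers after filtering are skipped with a logged reason.

Effect % is 100·|mean_carrier − mean_non-carrier| / mean_non-carrier, with
the sign recoverable from the reported group means; when the non-carrier
mean is zero the effect is flagged undefined while the p-value is still
reported. Variance explained (point-biserial r²·100) is available as an
alternative via `effect_mode="variance_explained"`; the two definitions
are not interchangeable and reports state which was used. The Bonferroni
divisor m defaults to the number of genes entering the association stage
(not the number of variants or of variant × trait tests), matching the
candidate-gene convention in which the gene is the unit of hypothesis.

## Stage 2b — ORF consequence classification

The ORF finder scans the three forward frames (inputs are oriented
mRNA-like assemblies; a flag enables the reverse strand), returns the
longest ATG→stop ORF, ties to the smallest start. Classification rules:
outside the ORF → `not_in_orf`; SNP in the ORF → translate the affected
codon before/after (`synonymous` / `non_synonymous`, standard nuclear
code); indel in the ORF → `orf_shift` if the length change is not a
multiple of 3, else `in_frame_indel`. The five-way scheme collapses to the
conventional four labels (S / NS / ORF shift / Not in ORF) for reporting;
`in_frame_indel` is kept internally because a 3k-length indel is
biologically distinct from a frameshift. An insertion anchored at the
ORF's final base inserts after the stop codon and is `not_in_orf`; a
deletion overlaps the ORF if any deleted base (positions pos+1 …
pos+|REF|−1) falls inside it. The test suite proves the rules equivalent
to a mutate–re-find-ORF–re-translate oracle (hand-rolled codon table) on
1000+ random sequence/variant pairs.

## Stage 3 — co-expression network and tendency test

Nodes are the selected transcripts plus every trait column; an edge joins
two nodes when the two-tailed *p* of their Pearson correlation is ≤ α
(default 0.05). Clusters are connected components over nodes of degree
≥ 1 — the minimal assumption, with an optional stricter |r| cutoff.
Gene–gene, gene–trait and trait–trait edges are counted separately so
either inclusion convention can be read off. Trait–trait edges are
expected by construction (TS is the sum of the monos) and are identical
across candidate and control networks, so they cancel in the tendency
comparison.

The tendency test builds the candidate network once, then R (default 20)
control networks from random same-size subsets of a disjoint background
pool, each including the same trait nodes. "Number of nodes" counts nodes
of degree ≥ 1 — a node with no edges has not joined the network.
Significance uses the predictive form of the one-sample comparison,
*t* = (obs − mean)/(s·√(1+1/R)) on R−1 df, two-sided. The naive one-sample
*t* (SE = s/√R) treats the observed count as a fixed population constant;
under the null the candidate count is itself one draw from the control
distribution, the naive statistic has standard deviation ≈ √(R+1), and it
would reject the majority of null candidate sets. The predictive form is
calibrated (measured false-positive rate ≈ 2% at the 1% level over 200
replicate panels, the residual discreteness coming from small integer edge
counts) while losing essentially no power: a planted module at loading 0.9
yields p ≪ 0.01 in every replicate. A one-sided add-one empirical
percentile, floor 1/(R+1) ≈ 0.048 at R = 20, is reported alongside.

## Synthetic panels

The generator emulates the study conditions: 42 cultivars, 440 transcripts
from 414 genes (the first 26 genes carry two isoforms), nine lognormal
mono contents (log-mean 0.8, log-sd 0.35 — positive, right-skewed,
comparable magnitudes, as HPLC contents are) with TS their exact sum, and
TPM = max(0, 50 + 10·z) so that Pearson correlations planted on the
z-scores survive the affine map to the TPM scale.

Planted signal:

* a correlated transcript is built as ρ·z + √(1−ρ²)·ε against the
  *realized standardized trait* z, so the sample correlation targets ρ
  without attenuation;
* a variant effect adds effect·SD(trait) to the carriers of one mono trait
  (carriers drawn without replacement); TS inherits the effect through the
  sum. Effects are planted one per trait — stacking several shifted
  carrier groups on one trait inflates its within-group variance and masks
  all of them, which is a property of the design, not of the test;
* a module shares one latent factor at a stated loading.

Transcript sequences are generated only for variant-bearing transcripts
(REF alleles always match the sequence); the requested ORF geometry is
realized by rejection sampling until the planted ORF is the unique longest
one. A `generate_sequences=False` mode skips sequence realization for
large statistics-only replicate studies.

What the generator does **not** emulate: library-size and mean–variance
structure of real RNA-seq counts, linkage between variants, population
structure among cultivars, dosage (heterozygote) effects, and measurement
error correlations among HPLC traits. Passing tests therefore demonstrate
the statistical machinery is correct and calibrated under the stated
model, not that real panels are free of confounding — population
structure in particular would require mixed-model extensions that are out
of scope here.

## Replicate studies and study sizes

The evaluation module fixes these study sizes (chosen to estimate each
rate to within roughly a percentage point): screen null calibration, 100–
200 panels × 400 transcripts × 10 traits; association null calibration,
60–100 panels × ~40 filtered variants × 10 traits; screen sensitivity,
60–100 panels × 10 transcripts planted at ρ = 0.6; variant detection,
100–200 panels × 9 planted 2-SD effects; tendency, 30–50 planted and 100–
200 null panels at R = 20. Per-replicate seeds derive deterministically
from one base seed. Measured values: screen null rate ≈ 0.050 at the 0.05
tier (0.0098 at 0.01), association null rate ≈ 0.050–0.061, screen
sensitivity ≈ 0.98 (Fisher-z prediction 0.96), variant detection ≈ 0.95,
planted-module tendency significant in 100% of replicates, null tendency
rejection ≈ 0–2% at the 1% level.

## Numerical conventions

Sample Pearson r is clipped to [−1, 1]; |r| = 1 maps to the smallest
positive float rather than p = 0. Tables are UTF-8 TSV with `.` decimal
point; p-values serialize in scientific notation with 3 significant
digits; expression/trait round-trips are bit-exact for decimal text of
≤ 12 significant digits. All coordinates in variant and ORF space are
1-based inclusive. Heatmap export z-scores each row (constant rows become
zeros with a warning) and orders rows by average-linkage clustering on
1 − r.

## Known limitations

Effect % against a near-zero non-carrier mean is numerically unstable and
flagged rather than reported. The ORF finder implements the longest-ORF
convention; genes whose functional CDS is not the longest ORF would be
misclassified, as would any annotation-free method. The pipeline assumes
one shared sample universe; batch effects across cultivars are the
caller's responsibility.
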