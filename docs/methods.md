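# Methods

This note documents the models, procedures and design choices behind
`methcoupler`: what each stage assumes, which tunable parameters matter,
what the synthetic-data generator does and does not emulate, and the
numerical conventions used throughout.

## Data model and conventions

All genomic coordinates are 1-based inclusive internally; BED input is
converted at the boundary (`start_internal = start_bed + 1`,
`end_internal = end_bed`).  Methylation travels as beta values (per-CpG
methylated fraction, in [0, 1]); expression as FPKM (≥ 0).  Matrices,
sample sheets, manifests and gene models are TSV with `#` comment headers
recording tool version and parameters, chosen over binary formats so every
fixture and output is human-readable and diffable.  Boolean covariates are
coded 1/0 on load; unparseable covariate cells become missing (never
silently 0) and are excluded pairwise downstream.

## Differential methylation

Per probe, the default test is the two-sided Welch (unequal-variance)
*t*-test on beta values.  Welch is the safer default for small, possibly
heteroscedastic clinical groups (here 5 vs 6); a pooled-variance flag
exists for exact replication of classical *t*-tests, and an ordinary
least-squares route (beta ~ group + covariates, group-coefficient *t*)
provides covariate adjustment.  Adjustment is off by default: the
covariate screen (pairwise-complete Pearson with *t*-based *P*, entries
masked above α) is the intended instrument for deciding whether
confounding is plausible in the first place.

Testing is done on the beta scale, not M-values, so that the
biological-relevance threshold (|Δβ| ≥ `delta_min`, default 0.05, i.e. a
5-percentage-point methylation change) applies directly to the tested
quantity.  Significance (*P* < α) and relevance (|Δβ| ≥ δ) are separate
flags because downstream consumers differ: annotation summaries and
pairing use *P* < 0.05 alone, while headline DMC counts conventionally
require both.  BH FDR is computed across all tested probes.  Degenerate
probes (zero variance in both groups) get *P* = 1 when means are equal
rather than NaN.

PCA centres features (no scaling) and fixes each component's sign by
forcing its largest-magnitude loading positive, making scores
reproducible across BLAS backends.  Hierarchical clustering is Ward
minimum-variance on Euclidean distances via `scipy`; exact merge ties are
resolved by scipy's nearest-neighbor-chain order, which is deterministic
for a given input ordering (ties have measure zero on continuous data).

## Annotation

Each probe gets exactly one (region, context).  The annotation promoter is
the 1.5 kb strictly upstream of the TSS, strand-aware.  Gene models are
BED-like and carry no transcript structure, so 5′/3′ UTRs are approximated
by fixed-length spans at the strand-aware gene ends (optional
`utr5_len`/`utr3_len` columns, default 200 bp) — a documented convention,
adequate for region-level summaries but not isoform-resolved annotation.
Region priority when a probe hits several features is promoter > 5′UTR >
3′UTR > body, ties broken by TSS distance; one gene per probe, because the
integration stage needs a unique gene assignment (multi-mapping is
logged).  CGI context uses the standard 450K-style distances: island =
inside a CGI, shore ≤ 2 kb from an edge, shelf ≤ 4 kb, open sea beyond.

Two distinct promoter windows coexist deliberately: the annotation
promoter (−1500, 0) above, and the motif-scan promoter (−1500, +500) used
when scanning DEG promoters for response elements.  They are named and
parameterised separately (`promoter_span` vs `upstream`/`downstream`) to
avoid silently conflating the two conventions.

The promoter-island enrichment test is a 2×2 χ² without continuity
correction (promoter-island vs not × DMC vs non-DMC background); when any
expected cell drops below 1 a Fisher exact *P* is reported alongside.

## Differential expression

The built-in test — Welch *t* on log₂(FPKM + 1) — is a deliberately simple
surrogate suited to the synthetic cohorts; externally computed DE tables
can be imported instead (a missing q column is recomputed by BH, a present
one is preserved).  The +1 offset handles zeros and is configurable.  The
three-part filter (*P* < 0.05, |fold-change| > 1.5, FPKM > 2) uses strict
inequalities; fold-change is defined on (mean FPKM + 1) ratios so the
threshold is well-defined at zero expression, and the FPKM clause is
interpreted as max of the two group means (either-group and overall-mean
interpretations are selectable).

## Integration

Pairing requires: probe significant (optionally also |Δβ| ≥ δ via a flag),
probe annotated promoter + island to the gene, the gene's DEG record
qualifying (default: the full filter; a flag relaxes to *P* < 0.05 only),
and opposite signs of Δβ and log₂FC.  Inverseness is defined on group-mean
signs, not per-sample.  A gene may carry several probes (many-to-one).

The group-wise statistic pools one point per (pair, sample):
x = beta of the probe in that sample, y = log₂(FPKM + 1) of the gene.
Pearson *r* and the two-sided *t*-transform *P* are computed per group
independently; a per-pair alternative (Δβ vs log₂FC across pairs) is also
available for comparison.  A caveat documented here because it shaped the
generator design: pooled points are not fully independent — a gene's
expression value is shared by its probes within a sample, and a probe's
baseline methylation is shared across samples — so between-unit mean
dispersion inflates the statistic's null variance beyond 1/n.  The
synthetic generator therefore keeps between-probe baseline dispersion
small for planted promoter CpGs (below); with strong clustered structure
in real data the pooled *P* should be read as descriptive rather than
exactly calibrated.

Regulator covariation ranks every gene by Pearson correlation of
log₂(FPKM + 1) with a seed gene across all samples, splitting *P* < α
genes into positive/negative classes.  Cross-study concordance counts
genes significant in two DEG tables and reports the sign-agreement
fraction as a percentage of the overlap.

## Enrichment

ORA is the one-sided Fisher exact (hypergeometric upper-tail) test of a
query list against each set of a GMT collection, restricted to a stated
universe, BH-corrected across the collection.  The default universe is
all genes with measured expression — the conventional background.  The
enrichment ratio reported is hits/set-size.  A ChIP target gene counts as
hypermethylated when ≥ 1 significant promoter-island probe with Δβ > 0
maps to it (genes are tallied, not probes; an all-probes mode exists).
Histone-mark set enrichment is the same operation on a different GMT — no
separate code path.

## Motif analysis

Windows are ±`flank` (default 10) bases around the DMC cytosine on the
forward strand; windows that cannot be centred are dropped with a
warning.  PWMs score by log₂ odds against a uniform 0.25 background with a
pseudocount (default 0.5); a window is a hit when its best placement on
either strand reaches `score_frac` (default 0.8) of the maximum attainable
score — for sharp consensus-built PWMs this admits essentially exact
matches only, which keeps hit calls oracle-testable.  The CpG bias of
DMC-centred windows is handled by background *selection*, not by the
scoring background: background windows are sampled without replacement to
match the target's joint (CpG-dinucleotide count, GC rounded to 0.05)
histogram, deterministically given a seed.  One consequence worth knowing:
because a planted GC-rich motif raises a window's GC bin, matched
backgrounds are slightly enriched for motif-bearing windows relative to
naive sampling — the matching is conservative by construction.

Enrichment is the one-sided hypergeometric tail on target hits against
the combined hit total, with the log₁₀ odds detection ratio (Haldane 0.5
correction) as the ranking effect size, the percentage of target windows
with the motif, and the positional offsets of best hits relative to the
central CpG (a CpG-centred planted consensus peaks at offset ≈ 0).

De novo discovery is reduced to exhaustive k-mer window-presence
enrichment (k configurable, default 7; both strands, one count per
window, palindromes not double-counted).  This is a deliberate design
choice: it is reproducible, enumerable and sufficient to recover a planted
consensus, where seed-refinement heuristics are neither deterministic nor
oracle-testable.

## The synthetic-cohort generator

The generator emulates the statistical structure the analysis assumes, on
one synthetic chromosome with genes tiled every 10 kb (alternating
strands, TSS at each slot centre, 3.5 kb gene span):

* **Cohort**: 6 cases vs 6 controls generated, one case dropped (default),
  leaving 5 vs 6 — the group-imbalance code paths are always exercised.
  Covariates (age, ejection fraction, diabetes, smoking) are independent
  of group.
* **Geometry**: planted genes (and 30% of null genes) carry a promoter CGI
  (TSS ± 300 bp).  The per-gene CpG template places 3 probes in the
  promoter island, one in the promoter shore, one in the body shelf and
  one in intergenic open sea, so all annotation cells are populated.
* **Methylation**: beta values are drawn on the logit scale — normal noise
  with sd = 4 × `beta_noise_sd` (the sigmoid slope at β = 0.5 is 1/4, so
  this calibrates the beta-scale sd near 0.5) — and mapped back through
  the inverse logit, guaranteeing (0, 1) support without truncation.
  Planted promoter-island CpGs are shifted by ±`delta_beta` (default
  0.15) in cases.  Their control baselines are drawn from a narrow
  intermediate band (U[0.48, 0.52]): CGI promoters sit near intermediate
  methylation in tissue arrays, and — per the integration caveat above —
  small between-probe baseline dispersion keeps the pooled correlation
  statistic calibrated under the null.  Null probes draw baselines from
  U[0.2, 0.8].
* **Expression**: log₂(FPKM + 1) = baseline + noise.  Null-gene baselines
  are N(3, 1.5), which puts ~80% of genes past the FPKM > 2 filter so the
  filter is exercised meaningfully.  Planted modules share one
  well-expressed baseline (4.5): metabolic modules are coherently
  expressed in heart tissue, the planted effects stay clear of the FPKM
  filter, and the control group is exactly exchangeable — making the
  control-group pooled correlation null by construction.  In cases only,
  planted genes add `coupling_slope` (default −6) × (realized promoter
  island mean β − planted control mean): a mechanistic coupling whose
  expected expression shift (±0.9 log₂ units at Δβ = 0.15) clears the
  fold-change filter with margin.
* **Regulator**: one null gene shares a latent N(0, 1) factor with
  `regulator_targets` (default 10) other null genes, half with positive
  and half with negative sign (expected |r| ≈ 0.9).
* **Sequence**: the genome is uniform random ACGT with CG forced at every
  probe position; the consensus motif (default CCCGCCC) is written with
  its CG aligned to the probe CpG in planted promoter-island windows at
  `motif_target_rate` (0.40) and in all other probe windows at
  `motif_background_rate` (0.05).  Planted fractions
  (`frac_hyper_genes` = `frac_hypo_genes` = 0.2 of 120 genes) were set by
  a power analysis at design time: ~144 planted promoter-island CpGs give
  the hypergeometric motif test and the pair-recovery statistics
  comfortable margins at the 5-vs-6 cohort size.
* **Truth table**: per-gene planted direction (hyper+down / hypo+up /
  null), regulator roles and signs; per-CpG planted Δβ and motif-planting
  flags — the surface against which recovery is scored.

What the generator does **not** emulate: probe-chemistry artifacts
(type I/II bias), batch effects, cell-type composition, linkage between
neighbouring CpGs beyond shared gene membership, realistic expression
covariance structure, or sequence composition beyond uniform base usage.
Passing recovery tests therefore demonstrates that the pipeline's
statistics detect the structures they target at realistic effect and
noise levels — not that real tissue data meet the tests' assumptions.

## Numerical choices

Degenerate inputs are made definite: zero-variance *t*-tests give *P* = 1
(equal means) or 0; constant covariates are masked with a warning;
singleton contexts report SEM 0; empty pair tables warn rather than fail.
Haldane's 0.5 keeps the ODT finite at zero counts.  BH is used for all
multiplicity correction.  All randomness flows from explicit
`numpy.random.default_rng` seeds; the pipeline seed derives per-stage
seeds by fixed offsets (background sampling = seed + 101) so stages are
independently reproducible, and identical seeds give byte-identical
outputs end to end.

## Problem sizes

Default study conditions are 120 genes × 6 CpGs (720 probes) at 5 vs 6
samples.  Calibration runs use 420-gene null cohorts (zero planted delta,
zero coupling; ~84,000 probe tests over 25 seeds); recovery properties are
evaluated over 100 seeded replicates in the test suite and 30 in the
acceptance script.  These sizes give stable Monte-Carlo estimates
(binomial SE below one percentage point on all reported fractions) while
keeping a full pipeline run on one cohort in the low seconds.

## Known limitations

The DE surrogate ignores count overdispersion and library-size effects —
import externally computed tables for real RNA-seq.  The pooled
correlation *P* assumes independent points (see above).  UTR annotation
is a fixed-width convention.  The k-mer surrogate cannot discover
degenerate motifs whose instances differ from the consensus.  Chi-squared
enrichment is asymptotic; the Fisher fallback triggers only below
expected counts of 1.
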