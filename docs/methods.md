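# Methods

This note documents the models, parameter choices and numerical conventions
behind `ahrcross`, and what the synthetic-data generators do and do not
emulate.

## Two-color normalization

Each array hybridizes a treated and a control sample labeled with opposite
dyes.  We work on M = log2(treated/control) and A = (log2 Cy5 + log2 Cy3)/2
per spot.  Dye chemistry induces a smooth intensity-dependent bias in M,
which we remove by subtracting a LOWESS fit of M on A per array
(`lowess_frac` = 0.4, two robustifying iterations).  Because M is always
formed treated-over-control — the treated channel is identified from the
sample sheet, not from the dye — dye-swap replicates need no extra sign
handling, and any bias component that does not flip with the swap is further
cancelled when replicates are averaged.  The trend also absorbs constant
offsets, so normalized M is centered per array.  Arrays with fewer than 20
usable spots are rejected (the trend is unfittable); callers are advised to
supply log ratios directly in that regime.

Probes at exactly equal A receive the same trend offset, so within-A rank
order of M is preserved — a useful sanity property of any monotone-in-A
correction.

## Empirical-Bayes differential expression and P1(t)

Per condition (species × time × contrast) with n replicate arrays and
per-gene sample variance s²_g on d_g = n_g − 1 degrees of freedom, variances
are shrunk toward a scaled inverse-chi-square prior whose hyperparameters
(d₀, s₀²) are moment-matched on the log-variance scale (digamma/trigamma
method; the trigamma equation is inverted by Newton iteration).  When the
observed variances are no more dispersed than chi-square sampling alone
explains, d₀ → ∞ and every gene receives the pooled variance.  The moderated
statistic is t_g = m̄_g / √(s²_post,g/n_g).

The posterior probability of activity is a two-component mixture computed on
the moderated-statistic scale with Gaussian components: null N(0, 1) versus
active N(0, 1 + c), mixed with prior active fraction π₁:

* `prior_active` (π₁), default 0.01 — the expected fraction of genes with a
  real response; configurable.
* `signal_variance_ratio` (c), default 64 — the variance of true effects
  relative to the sampling variance of the mean.  At the defaults, P1 >
  0.999 corresponds to |t| ≳ 5.3, which keeps the all-null false-positive
  fraction far below the 0.5 % budget while real 2-log2 effects at noise
  SD 0.2 sit at |t| ≳ 20.

Gaussian components (rather than scaled-t) keep the log posterior odds
unbounded in |t|, so arbitrarily strong evidence is expressible at any
moderated degrees of freedom, and P1 is strictly increasing in |t| by
construction.  The moderation step, not the mixture, carries the
small-sample variance uncertainty.  The exact hyperparameters of the
historical P1(t) implementation this emulates are not recoverable; what is
reproduced is the contract — a monotone posterior probability thresholded at
0.999 together with a strict 1.4-fold-change requirement.

Fold change is signed with magnitude ≥ 1: fc = sign(m̄)·2^|m̄|.  Both call
thresholds are strict inequalities; values exactly at 0.999 or 1.4 are not
called.

Probe-to-gene collapse takes the probe with the highest P1 (and, among
significant conditions, the time point of maximal |fc| fixes the reported
direction).  Both probe-level and gene-collapsed counts are reported, since
the two counting conventions legitimately differ.

## Hierarchical clustering of response profiles

Any-time-responsive genes are clustered on their per-time mean-M profiles
with average linkage on Euclidean distances.  Missing cells use
pairwise-complete distances rescaled by √(total/observed dimensions), an
unbiased-in-expectation completion that requires no imputation.  Rows are
sorted by gene id before linkage, making the tree invariant to input order;
trees are serialized as Newick with branch lengths equal to the difference
of merge heights (leaves sit at height 0).

## Cross-species classification

Ortholog groups map each species to at most one gene.  A species' status is
the direction of its strongest significant fold change (ns if none; absent
if its platform lacks the gene).  Categories, mutually exclusive and total:
divergent (≥ 2 significant species with opposite signs) takes precedence;
conserved requires every represented species significant in one direction;
partial covers same-direction agreement with at least one represented
species non-significant — reported separately so that conserved stays
strict; specific is exactly one significant among ≥ 2 represented species.
Groups represented on fewer than two platforms support no comparison and
fall in "none".  Denominators of overlap fractions count only groups
represented on both platforms of the pair.

## CHX primary/secondary classification

Two contrasts are fit with the same machinery: r0 = TCDD vs vehicle and
r1 = TCDD+CHX vs CHX; contrasting against CHX alone absorbs cycloheximide's
own transcriptional effects.  A gene responsive in r0 is primary when r1 is
significant, same-signed, and retains ≥ `retention_alpha` of |r0|
(default 0.5 — "attenuated" needs a quantitative cut and half-retention is
the documented, configurable choice); superinduction (|r1| > |r0|) is always
primary.  It is secondary when r1 fails the thresholds or retains less than
that fraction, and unclassified when r1 is significant with the opposite
sign.  The 4 h and 12 h classes merge conservatively: equal classes stand, a
classified time point beats a nonresponsive one, and a primary/secondary
conflict yields unclassified.  Classification uses contrast magnitudes and
posteriors only; no interaction term is tested.

## DRE scanning and conservation

Promoter windows default to 10 000 bp upstream through 1 000 bp downstream
of the TSS.  Both strands are scanned for GCGTG (CACGC on the forward text
corresponds to a minus-strand core); DRE function is not strand-dependent,
and a plus-strand-only mode remains available for strict single-strand
runs.  Positions are signed TSS-relative offsets of the core's center base
(0-based core start + 2, the only reading of a 5-mer's center), TSS = 0,
upstream negative.  BED output, available when genomic coordinates are
attached, is 0-based half-open with score = round(1000·MS).

Each core is extended by 7 bp per side; minus-strand hits are
reverse-complemented into DRE orientation, so reported 19-mers always carry
GCGTG at positions 7–11.  Cores with less than 7 bp of flank are dropped
with a warning — padding would fabricate sequence.

The PWM is trained from aligned functional 19-mers with pseudocount 0.25
per base (column probabilities (count + 0.25)/(n + 1)).  Column information
weights are c_i = 2 + Σ_b p log2 p, zero for uninformative columns, and the
matrix similarity of a sequence is the information-weighted score linearly
rescaled between the per-position-worst (MS = 0) and consensus (MS = 1)
sequences.  Whether a minimum MS should gate core counts is left to the
caller: raw-core and MS-filtered counts are both available (`ms_min`).

Cross-species DRE comparison one-hot encodes 19-mers over {A,C,G,T}, giving
Euclidean distance √(2·h) for h mismatches.  The metric was named in the
original procedure but not its encoding; one-hot is the natural choice and
makes the clustering threshold interpretable: θ = 3.0 admits ≤ 4 mismatches
(√8 ≈ 2.83) and rejects 5 (√10 ≈ 3.16).  Complete-linkage clustering cut at
θ guarantees every within-cluster pair is within θ; clusters spanning ≥ 2
species are orthologous DREs.  Hits are sorted by (species, position,
strand) before linkage for order invariance.  Positional conservation is
reported descriptively (member positions and their spread); no positional
threshold is applied.

## Synthetic-data generators

`generate_experiment` emulates the study design: 7-point time courses
(1–48 h), 3 replicates × dye-swap labelings (6 arrays per condition),
per-probe baseline intensities uniform on log2 ∈ [7, 13], multiplicative
lognormal channel noise (M noise SD 0.2 by default), and a cubic
intensity-dependent dye bias (amplitude ≈ 0.4 log2) added to the raw log
ratio with its sign fixed to the dye orientation — so it flips relative to
the biological effect under dye swap, giving the normalization stage a real
artifact to remove.  Planted log2 effects default to magnitude 2, constant
across the time course (per-time truth is recorded, so time-varying
profiles are a straightforward extension).  Ortholog structure is built
from a three-way-group fraction and a two-way fraction cycling over species
pairs; categories (conserved up/down, specific, divergent) are assigned at
the three-way-group level at configurable proportions, with divergent
groups flipping exactly one species' sign.

`generate_chx_experiment` produces the 2×2 factorial at 4 and 12 h with
primary genes holding modifiers {1, 1.5, 2} (maintained to superinduced)
and secondary genes {0, 0.2} (blocked to strongly attenuated).

`generate_promoters` plants DRE 19-mers at exact TSS-relative positions on
an i.i.d.-uniform background from which every GCGTG/CACGC window is
rejection-sampled away (junctions re-drawn after insertion), so scanner
recovery is exact rather than statistical.  `generate_dre_training_set`
perturbs a consensus 19-mer with per-position substitution rates.

What the generators do **not** emulate: probe-level spatial artifacts,
print-tip or batch effects, cross-hybridization, probe-specific affinity
differences, missing-spot patterns correlated with intensity, non-uniform
genomic background composition (CpG islands, repeats), or many-to-many
paralogy.  Passing tests therefore demonstrate the correctness of the
statistical machinery and classification logic under the stated noise
model, not performance on raw scanner output from real arrays or real
genome sequence, where normalization and background assumptions are
stressed in ways these fixtures cannot produce.

## Problem sizes and determinism

Tests and the acceptance script use 60–5000 genes per species, 1–7 time
points, and promoter windows of 1–2.5 kb — sizes at which the all-null
calibration (5000 genes) and the recovery suites are statistically
informative while the complete run stays interactive.  Every generator is a
pure function of (config, seed); the pipeline derives per-stage seeds from
the single config seed, and a rerun with identical config reproduces
byte-identical outputs (verified by manifest SHA-256 digests).

## Known limitations

* The empirical-Bayes posterior is a calibrated re-specification, not a
  reproduction of the historical implementation; absolute P1 values differ
  from that tool's even where calls agree.
* The normalization is per-array trend removal only; between-array scale
  normalization is not applied (replicate averaging and the strict
  thresholds make calls insensitive to it at the simulated noise levels).
* Platform-scale headline counts (hundreds of responsive genes per species,
  genome-wide DRE censuses) depend on the original arrays and genome
  assemblies and are out of scope; the recovery and calibration suites on
  planted truth stand in for them.
* Ortholog groups are taken as given; paralog resolution is upstream.
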