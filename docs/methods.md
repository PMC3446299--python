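# Methods

## Translation-profile statistics

A translation profile is defined only for genes with data in all four
polysome pools; raw abundances are normalized to percentages summing to
100, and genes with a missing, negative, or all-zero pool in any
required sample are excluded from calling rather than imputed.

The sum of differences D is the L1 distance between stress and control
percentage profiles (range 0–200). The weighted score
S = 0.1·p₁ + 0.2·p₂ + 0.3·p₃ + 0.4·p₄ rises when mass moves into
heavier fractions; moving ε percentage points from fraction j to k
changes S by exactly ε·(wₖ − wⱼ). The translation ratio R = Sˢ/Sᶜ.
Both statistics are computed per replicate pair and averaged
arithmetically; each stress replicate is compared against the control
of the same acquisition round when the replicate labels align, and
against all controls otherwise.

Calling: a gene is a candidate if averaged D ≥ 30 **or** averaged R
passes 1.15 on either side. The down-side cutoff is the reciprocal
R ≤ 1/1.15 by default (the symmetric choice on the ratio scale); an
additive variant (R ≤ 2 − cutoff) is available. Cutoff comparisons are
inclusive, avoiding knife-edge drop-outs. Direction is assigned by the
curation rule — down requires the pooled fractions 1–2 to rise while
fractions 3–4 fall (stress − control), up the inverse — evaluated on
replicate-mean profiles; strict mode additionally requires every
replicate pair to show the same sign pattern. The rule's minimum
co-directional shift defaults to 0 percentage points and is
configurable. Human visual curation is not reproducible exactly; the
deterministic rule plus the strict-consistency flag is this package's
codification, and strict calls are provably a subset of lenient calls.

## Proteome time course

Proteins need ≥ 2 unique peptides in at least one sample, and (for
quantitative comparison) a nonzero count in all 12 samples.

Calibration fits a single gain per sample, no intercept, against the
protein-wise mean across samples: aₛ = Σᵢ xᵢₛcᵢ / Σᵢ xᵢₛ². The gain is
exactly scale-equivariant (multiplying a sample by c divides its gain
by c) and gains are identified up to one global factor.
**Known limitation:** the calibration assumes a mostly-stable proteome.
When ~10% of simulated proteins carry genuine trends, the fitted gains
drift ~3% across the time course and imprint small inverse trends on
stable proteins, raising their miscall rate from the nominal 5% to
~6.5%. This is a property of average-control normalization itself and
is measured, not hidden: the null false-positive calibration of the
F-test is therefore assessed on a stable proteome, where it is nominal.

Log2 ratios are taken per replicate against that replicate's own 0-min
sample (replicate-matched reference, keeping replicate-specific
baselines), with a pseudocount of 0.5 (counts are positive after the
detected-in-all filter, so the pseudocount only matters under lenient
filtering); duplicates are then averaged per time point, so the 0-min
trajectory value is 0 by construction.

Temporal regression fits y(t) = β₀ + β₁t + β₂t² by least squares with
time in minutes, centered and scaled to unit variance for conditioning
(an ordinal time encoding is available); coefficients are reported on
the native scale. Significance is the overall F-test of
(β₁, β₂) = (0, 0) against the intercept-only model at α = 0.05.
Significant profiles with a two-sided β₂ t-test below the same α are
quadratic (convex if β₂ > 0, else concave); otherwise linear by the
sign of β₁. This overall-F + β₂-split construction is one reasonable
reading of quadratic-linear time-course classification; sequential-test
variants would differ only for marginal profiles. Degenerate inputs:
constant trajectories give F = 0 and `unchanged`; zero residual
variance with a nonzero trend (noiseless input) is reported as
significant with p = 0 and a warning so that exact trajectories remain
classifiable; fewer than 4 time points is an error.

## Integration

mRNA directions use a strict > log2(1.5) threshold at ≥ 4 of the
pooled stress time points across all supplied experiments (time-0
columns are ignored; missing values never pass). The discordance rule
table is evaluated in fixed order (antagonistic mRNA/translation
classes first, then protein-vs-mRNA classes, then concordant,
unclassified last), making the classes mutually exclusive and
collectively exhaustive. Protein temporal categories collapse to
directions as: linear_up and quadratic_concave (a transient
within-window rise) → up; linear_down and quadratic_convex (a transient
dip) → down. The signed maximum change keeps the sign of the
largest-magnitude log2 value. Enrichment reports the upper tail
P(X ≥ k) of the hypergeometric distribution with all sets intersected
with the universe; Benjamini–Hochberg adjustment is available but off
by default (raw tail probabilities are the primary output). Clustering
is average linkage on 1 − Spearman correlation between gene rows,
hence invariant to monotone transforms of individual rows; constant
rows are dropped with a warning, and the reported leaf order is scipy's
deterministic dendrogram order.

## Synthetic-data generator

The generator emulates the *structure* of the study's three layers, not
its content. Planted-effect labels occupy deterministic contiguous gene
blocks (randomness enters only through noise draws), so ground-truth
comparisons are exact. With `concordant=True` (default) the translation
and mRNA blocks coincide co-directionally, reflecting the observed
coupling of transcription and translation.

- **Fraction pools**: per-gene baseline profiles draw the pooled light
  mass uniformly from [shift + 5, 95 − shift] so planted shifts are
  always feasible (shifts above ~45 points are rejected); translational
  regulation moves `effect_size_shift` (default 30) percentage points
  between the pooled light and heavy fractions, distributed
  proportionally within each pool; raw pools are the profile times a
  log-normal per-gene abundance with multiplicative log-normal
  measurement noise (`noise_sd_log`, default 0.1 — a realistic
  two-channel array ratio error). Default replicates: 3 control, 3
  stress, at 15 and 60 min.
- **mRNA layer**: log2 ratios follow a transient trajectory — linear
  rise to the full effect by 0.75× the peak time (default peak 60 min),
  plateau to 2× the peak time, then linear decay to half amplitude at
  the last of the 7 stress time points {15, 30, 45, 60, 90, 120, 180}
  min (the 7-point grid is a design choice; only its size is given by
  the study design). Planted effects default to ±1 log2 unit; optional
  per-gene effect heterogeneity (`mrna_effect_spread`) supports
  correlation analyses that need variance in true effect sizes.
- **Proteome layer**: Poisson counts around per-protein log-normal
  baselines (median `count_depth`, default 200) following planted
  linear or quadratic mean log2 trajectories of amplitude
  `protein_log2_effect` (default 1.0 — the study reports protein
  dynamics compressed relative to mRNA, so the protein amplitude does
  not exceed the mRNA amplitude), times per-sample true gains (default
  none; configurable log-normal spread for calibration-recovery tests).
  Unique-peptide counts are ≥ 2 unless a drop-out fraction removes
  proteins from 1–3 random samples.
- **Coupled proteome** (for mRNA–protein relationship analyses):
  protein levels follow first-order synthesis/degradation
  dP/dt = k(m(t) − P) with m(t) = 2^x(t) the relative synthesis implied
  by the mRNA trajectory and k = ln 2 / half-life. The default
  half-life is 300 min; genes with planted mRNA repression carry a
  1200-min half-life — the planted decoupling in which long-lived
  proteins buffer transcript repression within a 3-h window, the
  pattern the integration statistics are expected to detect.

What the generator does **not** emulate: spot-level microarray
artifacts and dye effects, peptide-level identification noise and
shared-peptide inference, burst-like transcription kinetics, and
biological replicate covariance beyond independent draws. Passing
recovery tests therefore demonstrates the statistics behave correctly
under the assumed noise models, not performance on real arrays or MS
runs.

## Problem sizes and determinism

All simulations run in seconds: recovery suites use 1,000–4,000 genes
(the study scale: ~2,000 quantified proteins), 10,000 Monte-Carlo
trajectories for the F-test type-I check, and the planted proteome
fraction mirrors the study's ~11% significantly changed proteins. All
randomness flows through `numpy.random.default_rng` seeded from the
configuration; identical configurations reproduce outputs bit for bit,
and the pipeline manifest records config, seed, and input checksums.
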