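# Methods

This note documents the models, default parameters, numerical choices and
known limitations of the `uvg2` analysis chain. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Moderated differential polysome loading

Expression is analyzed on the log2 scale: microarray intensities as given,
RNA-seq counts as log2 counts-per-million with a 0.5 pseudocount (library
size plus 1). Keeping one inference engine for both platforms — rather than
a count GLM for the RNA-seq arm — is a deliberate simplification: the two
platforms are used symmetrically and only set membership is carried
forward.

For a contrast (condition A − condition B within one gradient fraction),
each gene g with groups of size n₁, n₂ gives a mean difference (log2FC), a
pooled residual variance s²_g on d = n₁+n₂−2 degrees of freedom, and a
moderated t

    t̃_g = log2FC_g / sqrt(s̃²_g · (1/n₁ + 1/n₂)),
    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),

with the prior (d₀, s₀²) estimated by moment matching of z = log s²: under
the scaled-F sampling model E[z] and Var[z] are digamma/trigamma
expressions in d and d₀, solved with a Newton trigamma inverse. When the
observed variance of z is no larger than its pure-sampling component, d₀ is
infinite and all posterior variances equal s₀².

The B statistic is the log posterior odds of differential expression under
a two-component model: a proportion p of genes (default 0.01, configurable)
have true effects with coefficient-scale prior variance v₀. With
ν = d₀ + d,

    B = log(p/(1−p)) + ½·log r + (ν+1)/2 · log((t̃² + ν)/(t̃²·r + ν)),
    r = v_g / (v_g + v₀),  v_g = 1/n₁ + 1/n₂,

reducing to B = log-odds + ½·log r + t̃²(1−r)/2 in the infinite-ν limit.
v₀ is estimated by the method of moments: the mean squared moderated t
exceeds its null value ν/(ν−2) by p·v₀/v̄_g, which is solved for v₀ and
clipped at zero. This is simpler than quantile-matching estimators used
elsewhere; since B is monotone in |t̃| at fixed v_g, candidate selection is
insensitive to the difference, and the formulas are verified gene-by-gene
against an independent scalar implementation in the tests.

Candidate selection applies |log2FC| ≥ log2(2) and B > 0 (both printed
constants of the original pipeline, exposed in `RunConfig`). "Similar fold
change" for the G2 subtraction is not defined numerically in the source
material; the default removes genes present in both lists whose log2FCs
agree in sign and differ by < 1.0 (configurable). The microarray and
RNA-seq candidate lists are intersected (the containment of the RNA-seq
list in the microarray list is reported alongside). No multiple-testing
correction is applied at this stage — selection is on fold change and B
only. The linear model treats replicates as unpaired.

## Screen scoring

**DNA content.** Integrated nuclear-stain intensity is modeled on the log2
scale as a two-component normal mixture with the 4n mode constrained to the
2n mode plus exactly 1 and a shared sd. EM is run from several
deterministic, shift-equivariant starts — the circular-mean phase of
exp(2πi·x) (which exploits the fixed unit spacing of the modes) at each
integer offset inside the data range, plus two quantile starts — and the
best log-likelihood wins; this prevents collapse onto a single wide
component when one ploidy class dominates a well. Likelihood ties (a
single-mode well cannot distinguish "all 2n" from "all 4n") are broken
toward the 2n-dominant labeling, matching an unperturbed interphase
population. Cells within ±0.15 log2 units (configurable) of a fitted mode
take that mode's phase; cells between the modes outside both margins are S
phase. Wells under the cell floor (default 200 cells) are unevaluable.

**Foci.** The analysis unit is the per-well mean foci count, avoiding
pseudo-replication across cells. Within each (cell line, timepoint) stratum
a one-way layout over perturbations supplies the pooled error variance, and
each perturbation is compared with the non-targeting (NT) control by the
Tukey–Kramer statistic referred to the studentized range with k groups and
the pooled error df. At least 3 NT wells are required; single-well groups
report an undefined p. The two-group case reduces exactly to the pooled
t-test (q = t√2), one of the tested closed forms.

**Scores and tiers.** The per-axis point values of the original scoring
table are not published in the main text; the rubric here is therefore
config-driven and its defaults are this package's choice — 0/2/4 points
(weak/strong) per axis over five axes: viability drop vs NT, delayed 4n
accumulation at 24 h, retained 4n at 40 h, significant foci increase,
significant foci decrease — so that a full phenotype clears the published
tier boundary. Only the tier rules are anchored to the source: siRNA total
≥ 10 in both cell lines = high confidence, in exactly one = low;
overexpression score > 2 in both lines = high, > 3 in one = low, with the
viability axis triggered by a > 25% drop in transduced fraction after UV
(ratio < 0.75). Default rubric outputs must not be read as reproductions of
the original screen tables. Toxic-control (PLK1) wells serve only as assay
controls and are never scored.

## Pathway deregulation score

Genes are z-scored across samples (dropping constant genes), samples are
projected onto principal components up to cumulative explained variance
0.9 with a floor of two components (preventing trivially linear curves),
and a principal curve is fitted by Hastie–Stuetzle alternation: initialize
on the first principal-component segment, then repeat (a) project all
points onto the current polyline, (b) smooth each coordinate against
arc-length position, until the mean squared projection distance changes by
less than a relative 1e-4 (max 50 iterations; non-convergence returns the
best curve flagged).

The smoother is a **local linear regression** over a rank window covering a
span of 0.3 of the samples (asymmetric at the boundaries). Local averaging
would shrink the curve ends inward; local linear fits reproduce affine
coordinate functions exactly, which gives the package a sharp closed form —
for exactly collinear data the fitted curve is the first-PC segment and the
PDS equals the min–max-normalized first-PC projection to machine precision
— used as an oracle in the tests. The curve is discretized at the projected
sample positions; ties in arc length are broken by stable input order; a
degenerate (zero-length) curve scores every sample 0.

PDS_i = λ_i / L ∈ [0,1], after orienting the curve so the reference
samples' median position is at the low end. The cohort analyzed here has no
normal-tissue samples; by default the zero-mutation subgroup serves as the
reference, overridable by an explicit sample list. The one-gene special
case is the reference-oriented min–max-normalized expression.

## Cohort association

USM load per Mb partitions samples into zero (exactly 0), low (0 < load <
3.6), mid (3.6 ≤ load ≤ 54.6, closed interval) and high (> 54.6). The
published low-group definition contains an apparent typo (">3.6" would
overlap mid); the open interval below 3.6 is the only reading consistent
with the other groups. PDS–load association uses Spearman rank correlation
(mid-ranks, t-approximation p). Subgroup comparisons use two-sided
Mann–Whitney rank-sum tests (Welch t optional) with Benjamini–Hochberg
adjustment across the requested pairs; groups under 3 samples are skipped
with a warning. Gene-level ranking applies the same rank-sum test per gene
(low vs high by default), BH-adjusted across genes, ordered by adjusted p
then |median difference|. Confounder screening is out of the statistical
core; callers can rerun on stratified sample lists.

## Synthetic data generators

All generators are pure functions of their spec (the seed is a spec field).

**Polysome designs** (`gen_polysome`): 3 conditions (asynchronous, G2,
UV-G2) × 2 fractions (total, polysome) × 3 replicates over 1000 genes.
Gene-wise baselines are N(8, 1.5²) log2 units; microarray noise is Gaussian
(sd 0.3, a typical array residual); RNA-seq counts are negative binomial
around 2^(baseline+effect) with dispersion 0.05. Planted classes (1%
transcriptional-only, 5% translational-only, 1% G2-generic, all at +2 log2
units) mirror the published structure: a small DE fraction of the
transcriptome dominated by translational-only regulation (~86% of the
polysome list after G2 subtraction). Keeping the planted fraction small
also keeps the composition bias of relative (CPM) RNA-seq measurements
second-order; large planted fractions would attenuate RNA-seq fold changes
toward the cutoff, which is a property of relative abundance, not of the
selection rules.

**Screen** (`gen_screen`): per-well cell counts are Poisson around the
planted viability; DNA content is the 2n/4n lognormal pair (4n mode exactly
twice the 2n mode, log2 sd 0.08 emulating high-quality integrated-intensity
measurement) with a uniform S-phase bridge of weight 0.1; foci are negative
binomial (size 3) around timepoint baselines (1 / 8 / 4 for noUV / UV24 /
UV40) times the archetype's multipliers. Control 4n baselines (0.25 / 0.55
/ 0.30) encode the arrest-and-recovery kinetics. Archetypes may be
line-specific (a dict keyed by cell line) to plant one-line "low
confidence" genes. Overexpression mode adds a Bernoulli transduced flag
whose post-UV rate carries the archetype's transduced-viability
multipliers.

**Cohort** (`gen_cohort`): n = 352 samples (the published cohort size) over
a 43-gene panel whose identifiers are the known checkpoint / DNA-damage
repair / MASTL-pathway members assembled from the screen's hit lists; the
exact membership of the original supplementary panel is approximated and
the identifiers are treated as opaque. Each sample has latent dysregulation
t ~ U(0,1); gene g follows baseline + a_g·t + c_g·(t²−t) + N(0, 0.25) with
loadings a_g ~ N(1, 0.3²) and curvature c_g ~ N(0, 0.6²) (linear mode
available for closed-form checks; inter-gene noise is independent by
default, with an optional shared factor). Mutation load is negative
binomial with log-mean log(12) + 0.95·t per Mb (size 0.6, 30 Mb exome); the
slope was calibrated once so the true Spearman(t, load) is ≈ 0.25 at
n = 352, the magnitude of the weak association the method is meant to
detect. A zero-fraction 12/352 of samples — those with the smallest
expected load, i.e. the lowest-t samples when the slope is positive —
are set to exactly zero load, giving a genuinely reference-like zero-USM
subgroup while leaving the zero-slope case a true null.

What the generators do **not** emulate: probe-level microarray artifacts,
batch and library-size biases beyond composition, spike-in normalization,
image segmentation noise and focus mis-threshold, cell-cycle substructure
beyond three phases, inter-gene correlation structure of real tumors, and
confounders (site, age, subtype) of real cohorts. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery on
data matching its assumptions, not robustness to every artifact of the real
assays.

## Problem sizes

The repeated studies run at: 1000-gene polysome designs, 300-cell wells
(90 wells per screen), and 352-sample cohorts; the test suite uses 200
repetitions for recovery/tiering studies and 400 for null calibration, and
`scripts/acceptance.py` uses 40/40/100/800 repetitions for its respective
sections. These sizes keep each study's Monte-Carlo error well below the
margins being asserted.

## Known limitations

- The B statistic's v₀ moment estimator is coarse when the realized DE
  fraction differs greatly from the prior p; only the selection rule
  (which is threshold-monotone in |t̃|) is consumed downstream.
- The DNA-content model ignores sub-G1 debris and >4n polyploidy.
- The principal curve is fitted in the PCA space retaining 90% variance;
  with very noisy cohorts this keeps many components and the curve fit
  slows accordingly.
- Single-gene PDS uses min–max normalization and is therefore sensitive to
  single outlier samples in a way the curve-based score is not.
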