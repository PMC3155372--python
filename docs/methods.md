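# Methods

## Study design and data model

The pipeline assumes the paired-drug safety design: seven groups —
vehicle, plus low/medium/high doses of a toxic drug T and of a
non-toxic comparator E — with 12 male rats per group (84 samples).
Expression is a normalized genes × samples matrix on the log2 scale;
clinical chemistry is an animals × analytes table; gene sets arrive as
Broad-dialect GMT.  Samples are joined to metadata on exact string ids
and any mismatch is an error: silent misjoins, not statistics, are the
dominant failure mode of this pipeline shape.

Dose enters the models as the ordinal code 0/1/2/3 shared by both
drugs.  The two drugs' mg/kg scales differ (30/110/400 vs 15/55/200)
but both ladders place the middle dose near the geometric mean of the
extremes, so the ordinal scale is close to log-linear within each drug
and — more importantly — makes the two slopes directly comparable in
the between-drug test.  Log10(mg/kg) coding is available
(`dose_coding="log"`), with an additive offset (default: the smallest
positive dose) so the vehicle is defined; it changes the relative
weighting of dose steps but not the permutation logic.

## Per-gene dose-response testing

For each drug, expression is regressed on dose over that drug's 36
animals plus the 12 shared vehicle animals (48 points; sharing the
vehicle is the default and can be disabled).  The T−V and E−V test
statistic is the slope t-ratio; its null distribution is generated by
permuting the expression values among exactly those 48 animals, which
is implemented as permuting their dose labels.  The T−E statistic is
(β_T − β_E)/√(se_T² + se_E²), with the null generated by permuting
drug identity within each dose stratum (each permutation reassigns
which 12 of the 24 animals at a dose level count as drug T), so the
dose structure of the design is never broken.  All tests are two-sided;
p = (exceedances + 1)/(B + 1) over B random permutations (default
10,000) guarantees p ≥ 1/(B+1).  For enumerable toy designs
`method="exact"` replaces sampling with exhaustive enumeration of the
distinct dose assignments / stratified swaps.  Permutations come from a
single seeded generator consumed in a fixed order, so results are
reproducible and independent of threading.

Degenerate genes are handled explicitly: a constant gene has slope 0
with zero SE and is assigned statistic 0 (hence p = 1); a perfect
noiseless fit yields an infinite t-ratio that only ties with other
perfect fits.  Slope differences at floating-point rounding scale
(≤ 1e-8 of the slope magnitudes) with zero pooled SE count as zero
evidence rather than infinity.

Benjamini–Hochberg step-up FDR is applied separately within each of
the three comparisons across genes (BH rather than BY: the default
choice under independence-like behaviour of gene-level tests;
configurable).  Significance downstream always means q ≤ α with
α = 0.05.

## Categorization

Direction is resolved first: if the two observed slope signs disagree,
only the divergent branch is reachable (d = sig(T−E);
D adds sig(T−V) ∧ sig(E−V)).  With agreeing signs:
t = sig(T−V) ∧ ¬sig(E−V) (T adds sig(T−E)); e/E mirrored;
c = sig(T−V) ∧ sig(E−V) (C adds ¬sig(T−E)).  Anything else is `none`:
the scheme is built to capture the ideal-marker patterns, not to
partition all outcomes.  The comparator drug's observed slope sign is
used even when that slope is not significant — the category definitions
require both drugs to share the directional effect.  A flag
(`strict_divergent`) additionally requires nominal p < α in both
drug-vs-vehicle comparisons before a gene may be called divergent,
for the stricter reading of "both drugs differ from the vehicle";
it is off by default because weak-effect divergent genes would
otherwise vanish.  Genes with an exactly zero slope but a significant
call are reported `none` with a warning.

## SOM validation

Candidate (categorized) genes are embedded as 8-vectors of group means
(V, E-low, E-mid, E-high, V, T-low, T-mid, T-high), z-standardized per
gene so that profile shape, not magnitude, drives clustering; constant
genes are excluded with a warning.  A 5×5 rectangular SOM is trained
online: codebooks initialized from random data rows, Gaussian
neighborhood with radius annealed linearly from max(k1,k2)/2 to 1 and
learning rate from 0.5 to 0.01 over 50 epochs; training is
deterministic given the seed.  Each unit is labeled with the primary
category whose within-unit count is most improbable under a binomial
null, scored by the upper tail P[X ≥ n_k | m, π_k] with π_k the
category's prevalence among candidates (ties: larger count, then fixed
category order); empty units stay unlabeled.  The exact labeling rule
is a design choice of this package — a binomial-likelihood criterion
with the tail probability as the concrete enrichment score.

Concordance is the fraction of candidate genes whose unit's label
matches their own primary letter, reported overall and restricted to
ideal-category genes (an ideal gene counts as matching a unit labeled
with its primary letter, since units carry primary labels).  Printed
percentages round half away from zero.

Keeping the final neighborhood radius at 1 (rather than annealing
toward 0) is deliberate: the residual coupling keeps each response
archetype on one or few adjacent units; fully decoupled units fragment
archetypes across the map and destroy unit-level interpretability.

## Pathway analysis

Sets with at least one categorized gene are candidates; a candidate
whose categorized members are all tolcapone-specific (T/t) is flagged
tol-specific.  The set-level test compares the vehicle and the two
high-dose groups over the set's genes with Wilks' Λ =
det(W)/det(W+H); when the set has at least as many genes as
within-group degrees of freedom (33 at n = 3×12), W is first
regularized by shrinking the pooled within-group correlations toward
zero with the analytic (Schäfer–Strimmer) intensity, leaving variances
untouched.  p-values come from permuting group labels (so no
multivariate-normal assumption is invoked); for a single-gene set the
procedure reduces exactly to a permutation one-way ANOVA.  Pillai's
trace is available by config.  Fisher over-representation is included
only as a comparison baseline for simulations — it discards
near-threshold genes and ignores gene–gene correlation, which is what
the MANOVA route exists to fix — and is not a pipeline output.

## Discrimination

Each marker is scored as a single-covariate logistic classifier on the
class pair its category is defined by: drug-specific markers, that
drug's high dose vs vehicle; common, pooled high doses vs vehicle;
divergent, high dose vs high dose (high-dose-only is the default;
`pool_doses` uses all dose groups).  The fit is IRLS with a small ridge
(1e-2) on the standardized covariate's slope, leaving the intercept
unpenalized, so complete separation still yields a defined fit.
Prediction is leave-one-out at the 0.5 probability threshold;
sensitivity and specificity therefore lie on a 1/n grid (n = class
size, 12 by default).

A property worth knowing: for an uninformative gene, LOOCV recall sits
near 1/3, not 1/2 — removing one sample from balanced classes tips the
training majority against the held-out label and the near-zero slope
lets the intercept decide.  This pessimistic anti-bias is inherent to
leave-one-out at this class size and explains why per-marker recall
ranges bottom out around 0.33; informative genes are unaffected.

## Clinical chemistry and susceptible animals

The 7-group one-way ANOVA and Tukey HSD are computed either from raw
per-animal values or from published-style group summaries (mean, SE,
n): with exact summaries the two routes are identical, since
MSW = Σ(nᵢ−1)nᵢseᵢ²/Σ(nᵢ−1) recovers the pooled variance.  Tukey uses
q = |Δmean|/√(MSW/n) against the studentized-range distribution, with
the harmonic mean of the pair's sizes (Tukey–Kramer, flagged) when they
differ.  A bundled example summary table of 13 analytes across the
seven groups exercises this route; p-values reconstructed from
2-decimal summaries are reliable to roughly ±0.005 except for analytes
whose summaries are at the rounding scale (total bilirubin, with means
of 0.13–0.25 printed to 2 decimals, reconstructs to 0.057 vs a printed
0.048 and is excluded from tolerance checks).

Outliers are flagged per analyte within treatment group by Tukey
fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR; type-7 linear-interpolation
quartiles, the common default — the criterion is tolerance-tested so
the estimator choice is not load-bearing).  For a constant group the
fences collapse and any non-tied value flags.  Note a single spike on
a flat background usually cannot make the 7-group ANOVA significant by
itself (it inflates MSW as much as MSB); significance flips on outlier
removal arise when a mild trend and an extreme animal combine, which is
the scenario the tests construct.

Animals flagged high on a monitored analyte enter the gene-level
analysis (elevation is a high-side notion; low-side flags are still
reported).  A gene counts as elevated in an animal if its expression
exceeds the leave-that-animal-out upper fence of its group mates
(z-score > 2.5 available as an alternative rule).  The cross-animal
intersection of elevated genes is reported for the toxic drug's
high-dose group, where a sensitive subpopulation would surface; gene
vs analyte Pearson correlations are computed across that animal's full
treatment group (12 animals).

## Synthetic data

The generator emulates the design above exactly (7 × 12 samples; doses
30/110/400 and 15/55/200 mg/kg) with gene-wise independent normal
noise on log2 scale around group means linear in the dose code — the
structure the slope test assumes — so planted slopes are recoverable
parameters.  Defaults: residual SD 0.25 log2 units (a typical
within-group array SD; the real studies' variance is not published, so
this is chosen for testability, not fidelity), baselines uniform on
[6, 12], `slope_effect` 2.0 residual-SDs per dose step for a
full-strength planted gene, 25 genes per category plus 1,800 nulls, 20
pathways of 5–20 genes, and 2 susceptible animals.

Per-category slope multipliers (T-drug, E-drug) are listed in the
module docstring.  Two are worth explaining.  Drug-specific genes
(T/E) carry a trace same-direction response of the comparator drug
(multiplier 0.1): the categories are defined with both drugs sharing
the directional effect, and with a literally zero comparator slope the
observed comparator sign is a coin flip that would send half of the
drug-specific genes into the divergent branch.  The multiplier is
sized so the comparator slope's z-statistic sits midway between losing
its sign (z = 0) and clearing the FDR threshold (z ≈ 2.9) — the window
the drug-specific pattern occupies; even so, roughly 10–15% of planted
drug-specific genes land in a neighboring category at the default
effect size, which is the honest ceiling of the scheme, and planted
common/divergent genes recover essentially fully.  Second, the
weak-category genes (t/e/c/d) are deliberately placed in underpowered
windows (e.g. t has both drugs responding weakly so T−V fires but T−E
cannot), so their recovery is intentionally partial — they model the
primary-but-not-ideal fringe.

Susceptible animals are drawn from the toxic drug's high-dose group;
the monitored analytes are split across them (each animal extreme on
its own analytes — two same-group animals extreme on the same analyte
would mask each other under within-group IQR fences) and a common set
of T-category genes is shifted in all of them, by 4 within-group SDs
on both sides, producing IQR-flaggable outliers with positively
correlated gene/analyte elevations.

What passing on synthetic data does not show: robustness to
gene–gene correlation (noise is independent across genes; the
permutation tests are per-gene exact regardless, but FDR behaviour
under strong dependence is untested), to non-linear dose-response
shapes, to batch structure, or to heavy-tailed noise.

## Problem sizes and numerics

Default test-suite and acceptance runs use 2,000 genes with 1,000
permutations, 50 planted genes per primary category, and reduced
permutation counts (99–500) for calibration sweeps — sizes chosen so a
full desk-scale validation completes in minutes on one core while
keeping every p-value grid fine enough for α = 0.05 decisions.
Permutation statistics are evaluated in vectorized chunks (default 512
columns) to bound memory at a few hundred MB; exceedance counting uses
a relative tolerance of 1e-12 so enumerated ties (including the
identity permutation) count as exceedances.  Seeds: every stochastic
stage consumes its own stream derived from the master seed by hashing
the stage name, recorded in the run manifest; re-running with the same
seed reproduces reports byte for byte.
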