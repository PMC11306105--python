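# Methods

## Plate-reader conventions (`lagshift.io`)

Raw microtitre absorbance differs from cuvette OD600 by the well geometry
(150 µl under a hexadecane overlay vs. a 1 cm light path); a multiplicative
calibration factor converts between the two. The default, 3.8603, is an
instrument-specific constant and is configurable.

Background is estimated **per well** as the mean absorbance over the stable
non-growth window, by default 2–8 h after inoculation, and subtracted from
every reading of that well. Using a per-well rather than plate-wide
background absorbs well-to-well optical offsets. Negative corrected values
are retained: clipping at zero would bias the fitted initial size upward.
The window is configurable because the stable phase depends on inoculum
size and strain; the default assumes no measurable growth before 8 h.

Before fitting, each curve is trimmed to the contiguous span between its
global minimum and global maximum OD (ties resolved to the first
occurrence). A curve whose maximum precedes its minimum never grew; it is
flagged non-growing and excluded from lag statistics rather than fitted.

## Logistic model and closed-form statistics (`lagshift.logistic`)

The model is the three-parameter logistic N(t) = K / [1 + ((K−N0)/N0)e^(−rt)].
Fitting minimizes the residual sum of squares with Levenberg–Marquardt on
(log K, log N0, log r), so positivity holds by construction and the
optimizer never sits on a boundary. Initialization uses quantile crossings:
K starts at the observed maximum; r from the 0.2 K → 0.8 K rise time (that
interval spans ln 16 / r for a logistic); N0 from the half-maximum crossing
via N0 = K/(1+e^{r t50}). Tolerances are 1e−12 (ftol/xtol/gtol) with at most
10,000 function evaluations. The logistic itself is evaluated as
K·expit(rt − ln((K−N0)/N0)), which is overflow-free for extreme parameters.

A well is declared non-growing when its observed dynamic range (or fitted
K − N0) is below a floor of 0.02 OD600, when the optimizer fails, or when
the estimates violate 0 < N0 < K; such wells carry `converged=False` and NaN
statistics.

Lag time is defined as the time the *fitted* curve crosses a detection
threshold, default 0.01 OD600 on the background-subtracted scale, computed
by the exact closed-form inversion (so predict(lag) returns the threshold to
machine precision; tests require 1e−9 and agreement with bisection
root-finding to 1e−8). A fit with N0 above the threshold yields a negative
lag, which is reported rather than clamped so condition differences remain
well defined. Doubling time is the same inversion at N_t = 2 N0 and is
undefined when 2 N0 ≥ K.

## Delta-lag statistics (`lagshift.stats`)

Condition summaries use the sample mean and sample sd (n−1). The effect of
a supplement is Δlag = mean(control) − mean(treatment), positive for a
shortening, with sd sqrt(s₁²/n₁ + s₂²/n₂) — the standard deviation of the
estimated difference between two means with independent replicate noise.

Significance comes from a one-way ANOVA view of all conditions in a call:
Dunnett's many-to-one procedure compares each treatment against the shared
control using the pooled error variance, two-sided (supplements can shorten
or prolong the lag — methionine-like prolongations are real effects). The
adjusted p-values are computed by `scipy.stats.dunnett`, which integrates
the equicorrelated multivariate-t probability by quasi-Monte Carlo; the QMC
stream is seeded for reproducibility. When the pooled within-group variance
is exactly zero the t statistic is undefined; the implementation returns
p = 1 for equal means and p = 0 otherwise. Categories: *** ≤ 0.001,
** ≤ 0.01, * ≤ 0.05, NS otherwise. The 0.01–0.05 band is treated as
significant (`*`) since NS is defined as p > 0.05. Variance is pooled
across whichever condition set is passed in one call.

## One-carbon budget (`lagshift.budget`)

The assimilatory demand counts the C1 groups consumed in building one
cell's complement of seven C1-sink metabolites: the nucleoside
triphosphates ATP, GTP, dATP, dGTP and dTTP, plus histidine and methionine.
Serine (a C1 *donor* when made from glucose), spermidine (methyl recycling
uncertain), phosphatidylcholine, macromolecule methylations and
low-abundance sinks are excluded. The packaged table derives the per-cell
amounts from the standard biochemical composition of an exponentially
growing *E. coli* cell (µmol per g dry weight × 280 fg dry weight; 1
mmol/gDW × 1 fg = 1 amol exactly), with a net one C1 group per molecule,
giving a total of ≈190.1 amol C1 per duplication. The table is an editable
CSV; a fallback mode accepts the 190.1 amol total directly.

The dissimilatory demand is the growth-associated ATP maintenance (GAM) of
the organism's metabolic model, default 85 mmol ATP/gDW → 23,800 amol
ATP/cell at 280 fg. One ATP per dissimilated methyl group (formate–THF
ligase route) is the default yield, configurable.

Supply per cell divides the external methyl pool (concentration × methyl
groups per molecule) by the cell density (CFU equated with cells, CFU/ml →
CFU/L). Coverage percentages are kept at full precision internally; display
formatting rounds to integer percent (assimilatory) and one decimal
(dissimilatory). All five operations are exactly linear in their numeric
inputs, and coverage is invariant under joint scaling of concentration and
density — both property-tested.

## Expression-table rules (`lagshift.expression`)

The module curates an already-quantified table; DE statistics (log2 fold
change, adjusted p) are *inputs*, not computed here. Operations: rRNA
removal (depletion efficiency varies by sample, so rRNA features would skew
abundance comparisons); TPM conversion (per-sample columns summing to 1e6);
top-k ranking of a tagged gene set by mean TPM with deterministic
lexicographic tie-breaks; a DE filter keeping padj ≤ 0.05 and |log2FC| ≥
0.585 (= log2 1.5, both inclusive; genes with missing statistics are
excluded); and an abundance floor keeping genes with ≥ 50 mean TPM in at
least one sample group (groups are typically time points). The DE and
abundance filters commute and are idempotent. Fractional counts from
multi-mapping assignment are accepted.

## Synthetic data (`lagshift.simulate`)

The plate generator reproduces the study conditions of a supplementation
experiment: four replicate wells per condition, readings every 20 min for
30 h, additive Gaussian noise of sd 0.003 on the raw absorbance scale, a
flat background level, and the 3.8603 calibration factor, i.e.
raw(t) = [N(t−shift) + background + ε]/factor. Ground truth (lag, doubling,
Δlag) is computed from the noiseless closed forms and is exact by
construction.

Lag effects are injected through N0: `lag_effect_via_n0` solves the
closed form for the initial size that shifts the lag by a requested amount,
which keeps the generative model inside the fitted family (so estimator
bias is attributable to noise, not misspecification) and leaves the
doubling time essentially unchanged — matching the empirical signature of
methyl supplementation (earlier growth, identical slope). A per-condition
`time_shift` provides an out-of-model stressor.

The control's default *effective* N0 is 1e-7 OD600 (control lag ≈ 14.4 h at
K = 0.5, r = 0.8/h). This is deliberately below a typical nominal inoculum
OD: a real stationary-phase inoculum shows a genuine delay before growth,
so its OD stays flat through the 2–8 h background window, whereas a pure
logistic with N0 = 1e-5 would already grow measurably inside that window
(and a condition shortened by 2.5 h even more so), contaminating the
background estimate in a way the emulated protocol excludes by
construction. 1e-7 keeps the window growth-free for injected shortenings up
to ~2.5 h while still saturating well before 30 h. What passing recovery
tests therefore show is that the estimator chain is accurate *when the
background window is genuinely growth-free*, as the protocol assumes; they
do not probe miscalibrated windows, plate edge effects, non-logistic
kinetics (except via the time-shift stressor), or replicate correlations.

The feature-table generator draws lognormal gene means, negative-binomial
counts (dispersion 10) with mild per-sample depth variation, rRNA genes at
200× elevated abundance, and DE statistics constructed to respect the
filter thresholds with margin (significant genes: |log2FC| in [0.7, 2.5],
padj ≤ 0.04; others fail at least one threshold). Truth labels for the
combined DE + abundance filter are computed at generation time with
independent arithmetic on the rRNA-removed table, so exact set recovery is
a meaningful pipeline-consistency check, not a tautology.

Randomness: one integer seed per simulation, split into per-well (or
per-table) streams via `numpy.random.SeedSequence.spawn`.

## Problem sizes and numerical choices in the verification suite

The test suite and the acceptance script use: 1,000 random parameter sets
for the closed-form vs. bisection comparison (tolerance 1e−8); 200
simulated experiments (each: control + 1.0 h and 2.5 h injected effects,
n = 4, noise sd 0.003) for Δlag recovery within 3·sd and for the power of
detecting a 2.5 h shortening at adjusted p ≤ 0.001; 1,000 global-null
trials (4 groups × 4 replicates) for Dunnett family-wise error calibration
at α = 0.05; and a 1,000-gene, 6-sample table for filter exactness. These
sizes keep the full verification run within a few tens of seconds on one
core while leaving Monte-Carlo error well below the margins being asserted.

## Known limitations

- Single-plate analysis: no mixed-effects structure, batch correction or
  plate-to-plate normalization.
- The logistic family cannot represent a true zero-growth delay; lag is an
  effective quantity defined through the threshold crossing of the fitted
  curve, and very early-growing wells can contaminate a fixed background
  window (choose the window per experiment).
- Alternative growth models (Gompertz, Baranyi) and single-cell lag
  heterogeneity are out of scope.
- The C1 sink table transfers *E. coli* composition to other copiotrophic
  bacteria of similar size; organism-specific tables can be supplied as CSV.
- DE inference (count modelling, shrinkage) is not performed here.
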