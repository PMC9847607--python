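# Methods

This note documents the models, numerical choices and known limitations of
`sjtbw`. It is written for users who want to judge what the package's
computations — and the tests that validate them — do and do not establish.

## Simultaneity-curve model

The per-window simultaneous-response rate over actual SOA *t* (seconds) is
modelled as `y(t) = a·exp(−(t−b)²/(2c²))`, an unnormalised Gaussian. *a* is
the peak rate (a probability, though sampling noise can push window rates
above fitted *a*), *b* the point of subjective simultaneity, *c* the scale.
The model is descriptive, not mechanistic: it assumes a unimodal, symmetric
simultaneity profile. Real SJ curves are often mildly asymmetric; the
Gaussian fit then averages the asymmetry into *b* and *c*.

### Trial selection and binning

Trials are dropped when no response was given or when the actual SOA lies
outside (−1000, +1000] ms. The boundary is asymmetric on purpose (−1000
excluded, +1000 retained), reproducing the exclusion rule this analysis
follows, and the binning convention is matched to it: 21 contiguous 100-ms
windows spanning (−1050, +1050], lower-open/upper-closed, centers −1000,
−900, …, +1000 ms. The window set is configurable; the default is the
symmetric 21-window partition consistent with the exclusion bound, since
the exact window edges used historically are not recorded. Empty windows
carry a 0/0 rate; they are treated as undefined and excluded from the fit
rather than imputed as zero, which would bias the tails downward.

Rates are computed per participant and condition with all sessions pooled
(the analysis is defined "by condition and by participant"); a per-session
option exists in the pipeline configuration for sensitivity checks.

### Fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`) on the
occupied windows, unweighted — equal weighting is the literal least-squares
reading, and no weighting scheme is part of the original analysis. Bounds:
a ∈ (0, 1.2], |b| ≤ 1 s, c ∈ [0.01, 5] s; the upper bound 1.2 on *a*
tolerates sampling noise above 1 while keeping the peak interpretable.
Multi-start over c₀ ∈ {0.2, 0.4, 0.8} s with a₀ = max rate and b₀ = the
highest-rate window center (ties broken toward 0 ms); the best of the three
runs is returned and its SSE is checked against a dense grid-search oracle
in the tests. Fitting needs ≥ 4 occupied windows (3 parameters + 1) and a
nonzero peak; failures raise `FitError`, which the pipeline records per
participant without aborting the study.

Fits are performed with t in seconds. Indices therefore come out in
seconds; I/O is in milliseconds with explicit conversion at the module
boundary.

### Width indices

HWHH = c·√(2 ln 2); FWHH = 2·HWHH; σ = c. The absolute-threshold indices
exist only when the curve actually crosses the threshold: width75 =
2c·√(2 ln(a/0.75)) and JND75 = width75/2 require a > 0.75, δ50 =
c·√(2 ln(a/0.5)) requires a > 0.5; otherwise they are reported as undefined
with the reason attached. Goodness-of-fit is the Pearson correlation
between observed and fitted rates at occupied windows; it is undefined
(NaN) when either side has zero variance. The pipeline warns, but does not
fail, below 0.4 — historically observed fits in this paradigm range from
0.67 upward.

## Inferential layer

* **Wilcoxon signed-rank**: zero differences dropped, average ranks for
  tied |differences|, z from the tie-corrected normal approximation with no
  continuity correction (the convention that reproduces the published z
  values at n = 10 pairs). For ≤ 25 nonzero differences the exact two-sided
  p (2·min-tail over the full sign-flip distribution, computed by dynamic
  programming) is attached. Exhaustive enumeration shows the approximate
  and exact p agree within 0.03 wherever the exact p ≤ 0.1 for 5 ≤ n ≤ 15;
  near the center of the coarse discrete null they can differ by up to
  ~0.13 at n = 5, which is immaterial for decisions but worth knowing when
  reading large p-values.
* **Effect sizes** are reported as absolute values. r = |z|/√n uses the
  convention that n counts participants × conditions (20 for 10 paired
  participants), matching how these analyses are conventionally entered
  into power software, even though pairs-based n is more common elsewhere.
  d_z uses the standard paired denominator √(σ₁² + σ₂² − 2ρσ₁σ₂) with ρ the
  Spearman correlation between conditions. The two-group pooled d weights
  variances by n (not n − 1), exactly as this literature defines it.
* **Correlations**: Spearman ρ as the Pearson correlation of average ranks;
  the no-correlation test uses t = ρ√((n−2)/(1−ρ²)) on n−2 df; strength
  labels at |ρ| = 0 / 0.4 / 0.7 / 1.

## Power analysis

All three computations share a noncentral-t kernel (`scipy.stats.nct`, with
a reflection fallback for far-tail underflow at large noncentrality).

* **Matched-pairs Wilcoxon, post hoc** — A.R.E. method: effective sample
  size n′ = n·ARE(parent) with ARE(normal) = 3/π ≈ 0.955; power =
  noncentral-t power at ncp = d_z·√n′, df = n′ − 1, with n′ kept as a real
  number (an integer-df switch exists for sensitivity checks only). Here n
  is the total sample size as entered — 20 for a 10-participant
  within-subject comparison, following the participants × conditions
  convention noted above. A 10⁵-replicate simulation of the actual exact
  Wilcoxon test on normal paired data agrees with the A.R.E. power within
  0.02 in the tests.
* **Exact correlation test, post hoc** — the critical sample correlation is
  derived from the null t distribution (r = t/√(n−2+t²)); power integrates
  Hotelling's exact density of the sample correlation under the alternative
  ρ by adaptive quadrature, with the hypergeometric factor evaluated via
  `scipy.special.hyp2f1` in log space. A Fisher-z approximation is provided
  as an explicitly labelled fallback and never silently substituted.
* **Wilcoxon–Mann–Whitney, a priori** — smallest group sizes (respecting
  the allocation ratio; equal groups walk even totals) whose A.R.E.-adjusted
  two-sample noncentral-t power reaches the target; power is monotone in n,
  so the first hit is minimal, and minimality is verified programmatically
  in the tests.

## Synthetic observers

The generator replaces unavailable raw data and defines the conditions the
validation suite runs under. It reproduces the paradigm's design exactly:
23 nominal SOA steps (0, ±50…±400, ±500, ±600, ±800 ms), 92-trial sessions
with every step four times and no step on consecutive trials (rejection
resampling of permutations), a fixed 5-trial training order, and three
sessions per condition.

Observer responses follow the same Gaussian law the analysis fits, so the
end-to-end recovery tests are internally consistent by construction. Per
trial: actual SOA = nominal + Normal(0, 30 ms) jitter (the apparatus
produces nominal-vs-actual discrepancies of unstated distribution; Gaussian
with 30 ms SD is this package's modelling choice, and occasional jittered
SOAs beyond ±1000 ms exercise the exclusion rule), a 1% lapse probability
producing a missing response (not a random guess), matching ~99% trial
adoption, otherwise a Bernoulli draw at the observer's curve.

Cohorts draw per-participant parameters from hyperpriors: lognormal widths
(moment-matched mean/SD; positivity), truncated-normal amplitudes on
[0, 1], normal centers. Default condition shapes follow the group-level
curves of the emulated design — congruent a = 0.73, b = −0.16 s, width
mean 0.44 s (SD 0.195); incongruent a = 0.76, b = −0.11 s, width mean
0.32 s (SD 0.10) — with widths correlated across conditions at Spearman
ρ = 0.71 through a Gaussian copula (latent correlation 2·sin(πρ/6), so the
rank correlation is controlled directly, since it is what enters d_z).
Randomness is split from one master seed via `SeedSequence.spawn`, one
stream per participant, so any sub-unit reproduces independently.

What the generator does **not** emulate: respiration/sniff phase, stimulus
intensity and duration physics, inter-trial timing, asymmetric or
non-Gaussian simultaneity profiles, session-order (learning) effects, and
response biases. Passing recovery tests therefore show the pipeline is
correct and well-calibrated *under the model it assumes*, not that real
olfactory–gustatory data satisfy those assumptions.

Synthetic perceptual-dimension ratings (a monotone noisy map from the
participant's generative width onto the 0–6 scale) exist purely so the
correlation branch of the pipeline can be exercised end to end; they carry
no empirical content.

## Validation sizes and numerical tolerances

The test suite checks: noiseless curve recovery to 10⁻⁶; optimiser SSE
against dense grid search (tolerance 10⁻⁸); Wilcoxon exact enumeration
against an independent 2ⁿ brute force; both power functions against 10⁵
Monte-Carlo replicates (within 0.02 and 0.01 respectively) and the
noncentral-t kernel against 10⁶ draws (within 0.002); type-I error of the
full pipeline on 400 null cohorts (10 participants, one session per
condition; rejection rate must fall in 5% ± 2%); and recovery of the width
parameter with < 10% median relative error over 200 simulated observers at
the study's 276-trial budget. These problem sizes were chosen to make
sampling error comfortably smaller than the tolerance being checked while
keeping the default suite runnable in a couple of minutes.

## Known limitations

* The Gaussian jitter SD (30 ms) and the lapse rate (1%) are modelling
  choices; only their downstream consequences (adoption rate, exclusion
  behaviour) are constrained by the emulated design.
* `power_correlation_exact` supports only a zero null correlation.
* The A.R.E. method is an approximation to the true power of rank tests;
  it is accurate near the normal parent but can misstate power for
  heavy-tailed parents, where the Wilcoxon is actually more efficient.
* Report JSON rounds floats to 10 significant digits so repeated runs are
  byte-identical; downstream consumers needing full precision should use
  the library API.
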