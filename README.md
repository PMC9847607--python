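# sjtbw — temporal-binding-window analysis for simultaneity judgments

`sjtbw` is a Python toolkit for analysing **simultaneity-judgment (SJ)
experiments** on olfactory–gustatory temporal integration: a participant
receives an odor and a taste stimulus separated by a signed stimulus onset
asynchrony (SOA; negative = odor first) and reports whether the two felt
simultaneous or successive. The package takes per-trial response tables and
produces fitted simultaneity curves, temporal-binding-window (TBW) indices,
and the nonparametric inferential and power-analysis battery used in this
literature. Because raw trial data are rarely shared, it also ships a
synthetic-observer generator that reproduces the statistical structure of
the paradigm for validation and design work.

## The model

The probability of a "simultaneous" response as a function of the actual
SOA *t* (in seconds) is modelled as an unnormalised Gaussian

```
y(t) = a · exp(−(t − b)² / (2c²))
```

where *a* is the peak simultaneous-response rate, *b* the point of
subjective simultaneity (PSS), and *c* the curve's scale. Per participant
and condition, trials surviving the exclusion rules (a response was given;
actual SOA in (−1000, +1000] ms) are binned into 21 contiguous 100-ms
windows of actual SOA, and (*a*, *b*, *c*) are estimated by unweighted
least squares on the per-window rates. The headline TBW width index is the
**half width at half height**,

```
HWHH = c · √(2 ln 2) ≈ 1.18 c,
```

with FWHH, σ, the 75%-interval, JND and δ indices derived from the same
fit. Goodness-of-fit is the Pearson correlation between observed and
fitted window rates.

On top of the per-participant indices the package implements:

* Wilcoxon signed-rank comparison between conditions, with effect sizes
  r = z/√n and Cohen's d_z = |m₁−m₂| / √(σ₁² + σ₂² − 2ρσ₁σ₂);
* Spearman correlations between perceptual-dimension ratings and HWHH,
  with the t-based test of no correlation;
* post-hoc power for the matched-pairs Wilcoxon test via the asymptotic
  relative efficiency (A.R.E.) method on the noncentral-t distribution,
  post-hoc power for the exact bivariate-normal correlation test
  (Hotelling's exact density of the sample correlation), and a-priori
  sample size for the two-group Wilcoxon–Mann–Whitney test.

## Worked example

Simulate a 10-participant, two-condition cohort (three 92-trial sessions
per condition, the design's 23 SOA steps) and run the full analysis:

```sh
sjtbw report --participants 10 --sessions 3 --seed 42 --out-dir demo
```

which prints

```
HWHH congruent 0.467 s vs incongruent 0.390 s; z = 1.07, p = 0.285, ES r = 0.24, d_z = 0.44, post-hoc power = 0.45
report written to demo/report.json
```

Reading: for this simulated cohort the congruent condition's mean binding
window (0.467 s) is wider than the incongruent one's (0.390 s) — the
direction built into the generator — but with 10 participants the paired
Wilcoxon test does not reach significance (z = 1.07, p = 0.285) and the
post-hoc power at the observed d_z = 0.44 is only 0.45, illustrating why
small cohorts often fail to resolve real TBW differences.
`demo/report.json` additionally contains per-participant fits
(e.g. adoption rates near 99%, goodness-of-fit values, all six width
indices), the correlation block (here the synthetic congruency rating
correlates with HWHH at ρ = 0.81, t(18) = 5.81, exact power 1.00), and an
a-priori Wilcoxon–Mann–Whitney sample size for the observed pooled effect.
Companion TSV tables (`participant_indices.tsv`, `binned_rates.tsv`) hold
the same numbers for spreadsheet use.

The same pipeline runs on real data: `sjtbw analyze --trials trials.csv
--ratings ratings.csv --out-dir out` with the CSV layout
`participant_id,condition,session,trial_index,nominal_soa_ms,actual_soa_ms,response`
(response coded 1 = simultaneous, 2 = successive, NA = no report).

Library use mirrors the CLI:

```python
from sjtbw import StudyConfig, run_study, power_wilcoxon_matched

report = run_study(StudyConfig(mode="simulate", n_participants=10, seed=42))
print(power_wilcoxon_matched(d_z=0.81, n=20).power)   # 0.9172...
```

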