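# Methods

## The stimulus model

Stimuli in the serial reaction time (SRT) task are generated by a
probabilistic context tree (a variable-length Markov chain) over the
alphabet {1, 2, 3}.  A context tree is a suffix-free set of finite
histories, each with a distribution over the next symbol; the emitting
context of a position is the unique context that is a suffix of the past
sequence.  The packaged task tree is

| context | next symbol |
|---|---|
| (1)    | 2 with probability 1 |
| (1, 2) | 2 with p = 0.26, 3 with p = 0.74 |
| (2, 2) | 1 with probability 1 |
| (3)    | 1 with probability 1 |

Each emitted symbol is labelled **F** (fixed) when its context is
deterministic and **V** (variable) otherwise, joined with the symbol: F1,
F2, V2, V3.  Every session therefore decomposes into triplets (1, 2, 3) or
(1, 2, 2): a 750-trial session contains exactly 250 F1, 250 F2 and 250
variable events regardless of the random draw, while the V2/V3 split is
binomial with expectation 65/185.  The stationary law is obtained
analytically from the induced Markov chain on contexts (left unit
eigenvector of its transition matrix), and the per-label frequency sums the
emission law over contexts.

Design choices where the tree's description is open:

* **Transition from 3.**  Fixed as 3 → 1 with probability 1; any other
  choice breaks the triplet structure and the exact per-block F1/F2 counts.
* **Leading symbol.**  Sessions start at symbol 1 with no history; it is
  labelled F1 (the triplet-initial fixed event), which keeps structural
  counts exact.  Any other unmatched position is labelled UNKNOWN.
* **Randomness contract.**  One integer seed fully determines a sequence;
  exactly one uniform variate is consumed per variable-context emission and
  none for deterministic contexts, so a fully deterministic tree is
  seed-independent.  A burn-in option discards leading symbols but is off by
  default so blocks stay triplet-aligned.
* **Shared vs per-subject sequences.**  Whether all subjects hear one fixed
  realisation or each gets their own is supported both ways
  (`shared_sequence` flag); per-subject sequences are the default.

## The synthetic cohort

`ctsrt.synthetic` emulates the study design — two groups (motor execution
ME, motor imagery MI) of 10 subjects, 750 trials in 5 blocks of 150, a
2000 ms response window, and a near-zero (0.001) per-trial error rate.
Reaction times are built additively (all units ms):

```
rt = baseline(group) + subject_intercept + block_effect(group, block)
     + slope(group, block) * (sub_block - 1) + event_offset(group, event)
     + interaction(group, event, last_var) + noise
```

* **Baselines** 450 (ME) and 900 (MI): imagined responses end with a
  confirmation key press and are substantially slower than executed ones.
* **Planted effects** (defaults, all overridable): MI has a monotone
  negative block effect (0, −40, −80, −110, −130) and ME none; both groups
  have negative within-block sub-block slopes in early blocks; MI has larger
  event differentiation (V2, the rare variable event, slowest in both); the
  event × last-variable interaction is crossed in MI (repeating a variable
  event speeds its repeat) and loads on the fixed events in ME.  These
  mirror the qualitative pattern of the study's findings for demonstration
  and power analysis; they are not estimates of the participant data, whose
  trial-level variances are unpublished.
* **Noise.**  Trial residuals are mean-zero, SD 150 ms, lognormal-shaped by
  default (fixed shape 0.6, skewness ≈ 2.2) because real RT distributions
  are right-skewed; a Gaussian option exists for analytic checks.
  Between-subject intercepts are Gaussian with SD 50 ms.
* **Censoring.**  Draws outside (0, 2000) ms are redrawn up to 100 times,
  then marked incorrect — this avoids a point mass at the window edge.
  Incorrect trials keep an RT (the task waited for the correct key) and are
  excluded by the filter, not deleted.
* The task's display timing constants (500 ms anticipatory window, 220 ms
  stimulus duration) are stored for documentation only: RT is defined from
  stimulus end, so they never enter generation.

What the generator does **not** emulate: sequential RT autocorrelation,
post-error slowing, fatigue/attention drift within a session beyond the
planted linear trends, and any coupling between accuracy and speed.  Tests
that pass on this generator certify the pipeline's arithmetic and
calibration, not conclusions about real participants.

## Preprocessing

Only correct responses strictly faster than 2000 ms enter any analysis.
Cell means are per subject × factor combination; sub-block means average 50
consecutive trials (three per 150-trial block), ignoring stimulus type.
When the Block factor is collapsed for the mixed design, trials are pooled
per subject × event (each trial weighted equally) rather than averaging
block means, because variable-event counts are unbalanced across blocks; a
`block_collapse="block_mean"` mode implements the alternative.  Cells left
empty after filtering propagate as missing, and the affected subject is
dropped from that specific ANOVA (complete-case) with a logged warning.

## Statistics

* **Two-way repeated-measures ANOVA** from the classical balanced
  subject-crossed decomposition: each within effect is tested against its
  interaction-with-subject stratum.  The rank variant applies the
  decomposition to pooled average ranks of all subject × cell means entering
  the design (ties averaged) — the standard rank-transform robustification.
  Rank output is invariant under strictly monotone transforms of the data.
* **Mixed (split-plot) ANOVA**: the between effect is tested against
  subjects-within-groups; the within effect and interaction against the
  within-subjects error.  Balanced groups are required.  Following the
  convention that the rank transform was described for the within-group
  design only, the mixed ANOVA runs on untransformed means.
* **Sphericity.**  Per within effect with more than 1 numerator df,
  Greenhouse–Geisser epsilon is computed from the covariance of orthonormal
  (Helmert) contrast scores — Kronecker products of the factor contrasts
  for interactions — and Mauchly's test uses the chi-square approximation
  with the second-order term (as in R's ezANOVA).  The correction is applied
  to the reported p (`p_report`) exactly when Mauchly rejects at 0.05; both
  raw and corrected p are always emitted.  When the contrast dimension
  reaches the subject count the covariance is singular, Mauchly is reported
  untestable (NaN) and the raw p stands.
* **Follow-ups**: paired (default) or two-sample t-tests over all level
  pairs, Bonferroni-adjusted as min(1, m·p) with the family size m recorded;
  significance tiers 0.05/0.01.  Zero-variance differences are flagged, not
  silently tested.
* **Sub-block slopes**: per subject × block OLS slope of the three sub-block
  means against index 1..3, then a two-sided one-sample t-test of the
  subjects' slopes against zero (df = n − 1) per group × block.
* **Calibration harness**: `error_rate_harness` simulates cohorts, runs a
  named design, and reports per-effect rejection fractions with exact
  Clopper–Pearson intervals.  Under the null configuration this measures
  type-I error; with planted effects, power.  Rejection uses `p_report`.

Numerical details: sums of squares below 1e-12 of the total are zeroed
(constant tables give F = 0, p = 1 rather than 0/0 residue); epsilon is
clipped to [1/df, 1].

## Problem sizes and verification

The test suite verifies both ANOVA paths against a brute-force
least-squares projection oracle (nested model comparison on dummy design
matrices) to 1e-8 relative error on 60 random small designs, and against an
independently published implementation on spot checks.  Monte-Carlo checks
use 500 replicates for type-I calibration (full-size null cohorts, one
group) and power (5 subjects/group with the default planted effects), and
3×10⁵ symbols (10⁵ variable events) for transition-probability recovery;
these sizes put the binomial standard error well below the margins tested.

Planted-effect *recovery* checks isolate one effect family at a time (e.g.
slopes planted with event offsets zeroed).  The reason is a property of the
design, not an estimator defect: 50-trial sub-blocks are not multiples of
the 3-trial period, so event composition differs slightly across sub-blocks
and a planted event offset leaks ≈0.4 ms/sub-block into the slope estimand.
Detection (power) checks use the full default effect sizes.

## Known limitations

* The ANOVA implementation requires balanced complete-case designs; heavily
  missing data should go to a mixed-effects model instead, which is out of
  scope here.
* The per-block V2/V3 counts of any single published realisation are one
  stochastic draw; the generator reproduces their expectation (65/185 per
  session), not the particular draw.
* The participant-level F statistics of the original study cannot be
  reproduced without the raw RTs; the pipeline reproduces the designs, df,
  and calibrated behaviour instead.
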