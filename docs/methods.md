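# Methods

## The feedback engine

The fed-back quantity is the partial correlation `r_p` between the PFC
and amygdala ROI signals controlling for a corticospinal-tract (CST)
control signal, computed over a moving window of the `L = 20` most
recent volumes and updated at every volume. Volume indexing is
1-based and the window at volume `t` covers `t−L+1 .. t` **inclusive
of the current volume**; this is the only convention under which the
first volume of a 20-volume feedback mini-block contributes a 1:19
feedback:other ratio and the last volume 20:0. Windows that would
reach before the first volume of a run are undefined — every run
opens with a fixation block at least as long as the window, so the
first displayed value already has a full window, and no data is
carried across runs.

Two mathematically equivalent routes to `r_p` exist in the code base:
the scalar reference (`partial_correlation`) residualizes both signals
on the control signal with an intercept and correlates the residuals;
the streaming path (`windowed_partial_correlation`) applies the closed
form `(r_xy − r_xc·r_yc)/√((1−r_xc²)(1−r_yc²))` to every window via a
vectorized sliding view. Every window is recomputed from scratch — no
incremental covariance updates — and the test suite asserts agreement
between the two routes to 1e−10 everywhere and 1e−12 on random
instances. Degenerate windows (a constant channel, or a channel
collinear with the control, detected at `1 − r² ≤ 1e−12`) yield an
explicit undefined value; the display falls back to the frozen segment
because a real-time display must render something.

### Thermometer quantization

`segment = clamp(floor(n_segments·(r_p − lower)/(upper − lower)), 0,
n_segments)` with `lower = 0` always and `upper ∈ {−1, −0.3, +1}` for
the negative, weighted-negative, and positive implementations. Floor
with a `1e−9` boundary guard (absorbing float round-off such as
`0.15/0.3·10 = 4.999…`) gives a deterministic, tie-free rule; the
upper bound maps exactly to the full thermometer. Segment spacing is
therefore `|upper|/10` — 0.1, 0.03, 0.1 correlation units per segment
for the three implementations. Integer segments are assumed; whether
the original display interpolated within a segment is unknowable from
the outside and irrelevant to the analyses.

### Extended-design boundary counting

In the extended design (40-volume feedback blocks), the
inclusive-of-current convention yields window compositions of 20:0 at
positions 20 through 40 of a feedback block — 21 positions, where a
description that counts only strictly-interior volumes would say
twenty. The schedule module reports the actual per-position
compositions and takes no side; nothing downstream depends on the
distinction.

## The synthetic generator

The generator reproduces, at the ROI-signal level, exactly the
statistical structure the analysis consumes; it does not model images,
motion, physiology, or hemodynamics.

Per subject, PFC and amygdala innovations are bivariate Gaussian with
instantaneous correlation

    ρ(t) = rho_base + delta_response·1[t in feedback block] + run_drift·(run − 1)

produced by the mixing construction `y = ρx + √(1−ρ²)e`, which
controls the innovation correlation exactly and piecewise-constantly
per block. Each channel passes through an AR(1) filter (`ar_coef`,
default 0.3) for BOLD-like smoothness; applying the same filter to
both channels preserves their correlation in stationarity. `|ρ(t)| ≥ 1`
at any volume is rejected as an invalid coupling.

The nuisance structure deserves a note. The control channel is an
independent AR(1) process that leaks into PFC and amygdala with
loading `gamma` (default 0.5); the task channels' nuisance share is
thus an exact multiple of the control signal, and regressing the
control channel out removes it completely — which is the design
premise of using a control ROI in the first place. The alternative
construction (an additive confound plus *extra* independent
control-channel noise) was considered and rejected: it provably leaves
residual confounding after partialling (the residual cross-covariance
`γ²(1−β)²σ_g² + β²σ_w²` is strictly positive), so no analysis built on
it could demonstrate confound removal. Block transitions change the
coupling instantaneously; the moving window itself supplies the
transition smearing that a hemodynamic model would otherwise add.

At the cohort level, covariates are Gaussian (questionnaire totals and
GABA/creatine-scale concentrations; ranges are not enforced because
every downstream statistic is scale-free) and subject parameters are
deterministic link functions of the *population*-standardized
covariates plus Gaussian noise:

| link | default | emulated relationship |
|------|--------:|-----------------------|
| STAI-T → rho_base | +0.08/SD | trait anxiety ↑ baseline coupling |
| TCAQ → rho_base | −0.08/SD | thought control ↓ baseline coupling |
| STAI-S → delta_response | +0.04/SD | state anxiety attenuates the feedback response |
| STAI-S×PFC-GABA → delta | −0.035/SD² | two-way moderation |
| STAI-S×PFC-GABA×ACC-GABA → delta | +0.04/SD³ | three-way moderation |
| run_drift → TCAQ change | −2.5 pts/SD | practice-related fc drift ↔ thought-control gain |

Mean feedback response `delta_mean = −0.15`, subject noise 0.04 on the
correlation scale; magnitudes are generator conventions chosen once
for adequate statistical power at cohort sizes of tens to hundreds —
the field reports observational correlations, not generative effect
sizes, so any choice here is a convention and is documented as such.
Because the links use population standardization while the moderation
fit centers by sample means, the realized lower-order coefficients
shift by Op(1/√n) per replicate; the three-way product coefficient is
the replicate-invariant estimand and is the one checked in parameter
recovery.

Counterbalancing: half of each cohort (seeded, exactly balanced)
receives the schedule with mini-block conditions exchanged. In the
asymmetric extended design the swap exchanges block *order* while each
condition keeps its own length, so feedback blocks stay 40 volumes in
both arms.

What passing tests do **not** show about real data: the generator has
no hemodynamic lag, no motion or physiological artefacts, no
non-Gaussian questionnaire distributions, and its brain–behaviour
links are noiseless functions plus Gaussian error. Results on it
validate the *machinery* — bookkeeping, estimators, calibration — not
the empirical claims of any particular study.

## Subject-level metrics

- **Initial fc**: mean defined `r_p` over the first two post-fixation
  mini-blocks of run 1, irrespective of condition — under the
  alternating design this mixes one feedback and one no-feedback block
  in both counterbalancing arms. A block with no defined values is
  skipped with a warning; only defined-window volumes enter.
- **Practice slope**: OLS slope of per-run mean `r_p` on run index.
  "Per-run mean" defaults to all mini-block volumes of both conditions
  (`slope_scope: all`); `fcnf_only`/`nonf_only` restrict it. Fixation
  volumes never enter. Negative slope = drift toward negative
  connectivity, the trained direction.
- **fc-NF-effect**: mean no-feedback `r_p` minus mean feedback `r_p`
  pooled over runs; positive = connectivity more negative under
  feedback. Because each volume is attributed to the condition of its
  own mini-block while its window mixes both conditions, the measured
  effect is structurally attenuated relative to the generating
  coupling shift (roughly by the mean within-window condition
  fraction); sign and ordering are preserved, which is what the group
  analyses use.
- **Profiles**: `r_p` averaged per within-block position across
  mini-blocks and runs, with counts of negative values and of
  contributing (defined) windows, plus the mean number of feedback
  volumes in the window at that position — the abscissa of the
  profile-versus-count analysis.

## Group statistics

Group profiles average subject profiles with equal subject weight
(not equal volume weight). The profile-versus-count analysis
correlates the group mean fc (or the negative-`r_p` frequency) with
the window feedback-volume count over all positions of both conditions
(40 points in the standard design).

Two independent correlations are compared by Fisher's z: statistic
`(atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))` against the standard
normal. A Student-t variant (same statistic, `n₁+n₂−4` df) sits behind
`variant="t"`; at the sample sizes involved the two agree to the
decision level, and the exact historical t formulation is not
recoverable, so the z form is the default.

Multivariate outliers are flagged by bootstrapping the Mahalanobis
distance: for each of B = 1,000 resamples (with replacement) of the
point cloud, every original point's squared distance to the resample's
mean/covariance is computed; points whose distance averaged over
resamples exceeds the chi-square(2) 0.975 quantile (≈ 7.378) are
flagged. The threshold and B are configurable; flags are deterministic
given the seed; singular full-sample covariances are an error and
degenerate resamples are redrawn. Correlations are reported both raw
and after removal; missing data are handled by pairwise deletion. No
multiple-testing correction is applied by default (a Benjamini–
Hochberg option exists but is off), mirroring standard practice in
small-cohort neurofeedback studies.

## Moderation

OLS of Y on mean-centered X, W, Z and the four products formed *after*
centering (products not re-centered — the standard moderation
convention). SEs from the coefficient covariance, two-tailed t with
`n − 8` residual df, 95% t-based CIs. Simple slopes
`θ(w, z) = b1 + b3w + b5z + b7wz` at the nine combinations of
±1 sample SD and 0, with SEs from the linear-combination variance
`aᵀΣa` and the full model's residual df — at (0, 0) the slope and its
SE equal `b1`'s exactly, a structural identity the tests assert. The
moderator spread uses the sample SD; a percentile-bootstrap CI option
was considered and left out as out of scope for the decisions this
model supports. A batch specificity mode refits the model for
alternative moderator column pairs and reports each model's overall F
and p.

## Numerical and reproducibility conventions

- All tables are UTF-8 TSV, one header row, floats at 12 significant
  digits; every writer round-trips through its reader bit-stably.
- One global seed fans out as
  `stage_seed = SeedSequence([seed, stage_index]) mod 2³¹` with stage
  indices simulate=1, feedback=2, metrics=3, groupstats=4,
  moderation=5, so stages re-run in isolation reproduce their part of
  a pipeline run. The pipeline report is byte-identical across
  repeated runs.
- Problem sizes used by the test suite and examples — cohorts of 6 to
  20 subjects for end-to-end runs, 200–500 subjects for link-recovery
  checks, 200 replicates for coverage experiments, 10,000-volume runs
  for convergence checks — were chosen as the smallest sizes at which
  the corresponding statistical property is decisively visible.

## Known limitations

- No hemodynamic convolution or lag; coupling changes are
  instantaneous at block boundaries.
- The incremental (rolling-update) covariance path is not implemented;
  every window is recomputed, which is exact and fast at these scales.
- The measured fc-NF-effect is attenuated by window mixing (see
  above); analyses that need the generating coupling shift should use
  the generator parameters directly.
- Questionnaire covariates are unbounded Gaussians; analyses that
  depend on floor/ceiling effects are out of scope.
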