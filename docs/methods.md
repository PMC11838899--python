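# Methods

## Data representation

The unit of analysis is one 2Dmito plot: per-fibre (log mass, log OXPHOS)
pairs for k−1 control subjects and one patient, patient last. Input tables
are long-format CSV (`fibre_id, subject_id, subject_type, channel, value`);
pairing is by exact `(subject_id, fibre_id)` match and fibres missing either
channel are dropped and counted, never imputed. The log transform is the
natural log (any base only rescales slopes and intercepts); fibres with a
non-positive intensity in either channel are excluded and reported rather
than offset, since pseudo-counts would distort the low-intensity tail that
matters most for deficiency calls.

## The hierarchical mixture model

Control fibres follow per-subject lines with a shared within-subject
precision τ; patient fibres follow a two-component mixture sharing the
patient's line: component one with precision τ (like-control), component two
with fixed precision γ (not-like-control). Assumptions worth stating
explicitly:

- **Shared τ.** Within-subject residual spread is assumed equal across
  subjects in a plot. This is what lets the controls inform the patient's
  like-control component.
- **Fixed γ.** The deficient population is heterogeneous across patients
  and proteins; modelling it with a single broad zero-information component
  (γ ≪ τ, default 1e−4) avoids over-fitting and removes label switching.
  The component's mean is the patient's own line purely for convenience:
  with so small a precision the density is nearly flat over the data range.
- **Truncated slope prior.** m_i ≥ 0.1: OXPHOS abundance is assumed to rise
  with mitochondrial mass. The bound is configurable (`PriorSpec.slope_lower`).
- **π ∈ [0, 0.5].** The method is explicitly unreliable for patients with a
  deficient majority (the regression would fit the deficient population);
  the uniform prior encodes that restriction.

## Prior elicitation

Per-control-subject OLS fits give slopes, intercepts and residual
precisions. Their means set a_m, a_c and the τ prior; b_m = b_c = 0.25²
(high certainty: these means come from the same experiment). Gamma
distributions are parameterised by shape and **rate** throughout — a classic
silent-bug source, so it is stated here and in the code. The τ prior
matches its **mode** to the mean control precision with variance 10. The
population precisions τ_m, τ_c get mode 50, variance 50, i.e. shape 51.981
and rate 1.020 to three decimals, obtained by solving (g−1)/h = mode,
g/h² = variance (h the positive root of var·h² − mode·h − 1 = 0). Mode
matching is used because it reproduces those printed constants exactly;
mean matching would give (50, 1). For sensitivity analysis,
`scale_prior_variances(spec, f)` multiplies every prior variance by f while
holding the normal means and gamma modes fixed (f = 5 and 1/5 in the
shipped checks).

## Inference

A Z-augmented Gibbs sampler:

1. (m_i, c_i) per subject as a **block**: the joint conditional is bivariate
   normal truncated in m; m is drawn from its truncated marginal, c from
   c | m. Blocking matters — one-at-a-time updates mix slowly because slope
   and intercept are strongly correlated when X is far from zero.
2. τ from its gamma conditional over all control residuals plus the
   patient's currently-like-control residuals.
3. μ_m and τ_m by Metropolis-within-Gibbs: the conjugate conditional that
   ignores the slope-truncation constant is the proposal, and the acceptance
   ratio is exactly the ratio of truncation constants Φ̄((0.1−μ_m)√τ_m)^k.
   Whenever the bound is far in the prior's lower tail the ratio is ≈ 1 and
   the step behaves as a conjugate update, but the scheme stays exact in
   general. μ_c, τ_c are fully conjugate.
4. Z_j ~ Bernoulli of the membership probability (computed in log space),
   then π from Beta(1 + ΣZ, 1 + n_p − ΣZ) truncated to [0, 0.5] by inverse
   CDF.

Defaults: 3 chains, 22,000 iterations with a 20,000 burn-in. The test suite
and shipped checks use a reduced preset (3,000 iterations, 1,000 burn-in =
2,000 retained draws, usually one chain); at that preset the blocked sampler
achieves ESS ≈ 0.9× the draw count, so the reduced runs carry nearly the
same information per draw as long ones.

**Initialization.** Per-subject lines start at their OLS fits (patient
included), hyperparameters at their prior centres, π at 0.1 — and τ at its
prior mode, which the elicitation pipeline makes equal to the mean
per-control-subject OLS precision. Starting τ from a *pooled* OLS fit is
dangerous: pooling is precisely the flaw the hierarchy corrects, and when
subjects' lines differ (or the patient has many deficient fibres) the
pooled precision is several-fold too small, so component one starts wide
enough to absorb the entire patient mixture and the chain can remain in
that degenerate π ≈ 0 mode indefinitely.

**Diagnostics.** Per chain and parameter: bulk ESS, and the split R-hat of
the chain's two halves (a quantitative stand-in for trace-plot inspection;
threshold 1.05). Chains flagged by the drift check are excluded; inference
uses the remaining chain with the highest minimum per-parameter ESS. If
every chain is flagged, fitting raises rather than returning unreliable
draws.

**Correctness evidence.** The marginalised log posterior matches an
independent exhaustive-sum-over-Z evaluation to 1e−10; membership
probabilities match direct density-ratio evaluation to 1e−12; and
simulation-based calibration (truth drawn from the prior, data simulated
from the model, rank of truth among thinned posterior draws) yields ranks
for π and τ that pass a χ² uniformity test at the 1% level over 100
replicates.

## Posterior outputs

- Per-fibre probability p_j = posterior mean membership; label 1 iff
  p_j ≥ 0.5 (a fibre exactly at 50% is called not-like-control, matching
  the convention that like-control means *below* 50%).
- HDIs are sample-based shortest windows (the HDInterval algorithm). For
  parameters with known bounded support (π), when the chosen window abuts an
  extreme order statistic the endpoint is reported as the support bound:
  the sample extreme is a biased-inward estimate of an HDI endpoint that
  lies on the boundary (e.g. a posterior piling up at π = 0), and snapping
  is conservative (it widens the interval by at most the gap between the
  sample extreme and the bound, ~1e−6 in practice).
- The posterior predictive band is for component one only (a new
  *like-control* fibre): at each grid point the predictive CDF is the
  draw-mixture of normal CDFs and the equal-tailed quantiles are found by
  root-finding, so a point-mass posterior reproduces the closed-form normal
  interval exactly.
- Comparisons of π against a reference proportion (frequentist or manual)
  report the posterior median, 95%/99% HDIs of the difference, and a
  one-sided tail probability in the direction of the reference relative to
  the posterior median; when no draw is as extreme the resolution floor
  1/n_draws is reported as an upper bound rather than a fake zero.

## The frequentist baseline

All control fibres pooled, one OLS line, and the classical t-based
out-of-sample prediction interval
ŷ(x₀) ± t_{n−2,(1+level)/2}·s·√(1 + 1/n + (x₀−x̄)²/S_xx). The original
pipeline never states its interval formula; this is the standard choice and
at pooled sizes ~1,000 the t vs normal distinction is negligible. Z_j = 1
iff the fibre falls outside the interval at its x. An above/below side
column is provided for inspection but does not alter the binary rule.

## Synthetic data generator

Emulates the observed IMC regime: k = 5 by default (4 controls + patient),
per-subject fibre counts drawn from the observed ranges (controls 154–363,
patient 151–1,199) unless given, log mass X ~ N(2.0, 0.5²) per subject
(i.e. log-normal mass), population slope 1.0 and intercept 0.0 with
precisions 50 (inter-subject sd ≈ 0.14), like-control residual precision
τ = 25 (sd 0.2). Deficient patient fibres are drawn from a line shifted by
δ = −2.0 log units with precision τ_def = 4.0 (sd 0.5): a *separate*,
noisier population below the like-control band, which is how deficient
populations present in observed 2Dmito plots. A closer, broader deficient
component (say δ = −1, sd 1) would overlap the like-control band enough
that a sizeable fraction of deficient fibres is genuinely unidentifiable
from a single channel and any method's π must be biased low; the defaults
deliberately describe the identifiable regime the method is designed for.
The D02-style variant linearly transforms the mass scale (IF-like larger
abundances) and widens inter-subject spread by a configurable factor.

What passing tests on these data do **not** show: robustness to
heteroscedastic or non-normal residuals, intensity artefacts, segmentation
errors, or deficiency patterns that overlap the like-control band — real
data contain all of these to some degree, and the manual-classification
comparison in the original workflow exists precisely because no synthetic
benchmark covers them.

## Evaluation protocol

Confusion matrices are indexed (model label, reference label); the
misclassification rate is 100·(n01+n10)/total. Reference labels come from
ground truth (synthetic) or an annotation CSV; an expert-consensus helper
ANDs multiple annotation columns (unanimous agreement required for a
not-like-control reference label). The γ sweep refits the model per γ value
with a common seed and scores |posterior median of π − reference|. The
80/20 split check refits on controls plus 80% of patient fibres (controls
are never split — they anchor the hierarchy) and compares per-fibre
membership probabilities for *all* patient fibres against the full-data
fit; no over-fitting is declared when 0 lies in the 99% HDI of the
differences.

## Numerical choices and degenerate inputs

- Truncated-normal and truncated-beta draws use inverse-CDF sampling via
  `scipy.special` (ndtr/ndtri, betainc/betaincinv), stable in both tails;
  uniforms are clipped to [1e−15, 1−1e−15] to avoid infinite quantiles.
- OLS requires n ≥ 3 and non-degenerate x; an exact-fit (zero residual)
  pool is rejected rather than returning infinite precision.
- A patient with fewer than 5 fibres fits with a warning (the hierarchy is
  still identified by the controls); an empty subject or a subject losing
  all fibres to the positivity filter is an error.
- Reported CSVs round-trip bitwise: values are written via shortest-repr
  and parsed with `float_precision="round_trip"`.

## Known limitations

- Single-channel classification only; no joint modelling across OXPHOS
  proteins or patients.
- The method assumes a deficient minority (π ≤ 0.5) and a positive
  mass–abundance correlation; both are prior constraints, not findings.
- The Gibbs sampler is exact but single-site in the hyperparameters; for
  pathological datasets far outside the elicited prior's support, multiple
  chains plus the selection rule are the safety net, not a guarantee.
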