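# Methods

## Dose-volume histograms

A DVH is stored in differential form on a uniform dose grid (default bin
width 0.1 Gy, the usual treatment-planning increment of 10 cGy), with
fractional volumes normalised to sum to one. The dose attributed to a bin
is its **midpoint**; whether reported DVHs index bins by lower edge or
midpoint is generally ambiguous, so the choice is configurable at the
reader level (midpoint is the default because it is unbiased for the mean
under within-bin uniformity). The interchange CSV is long-format
(`structure, dose_gy, volume_fraction`) with the cumulative/differential
dialect declared in a `# dialect:` header comment, which makes round-trips
unambiguous. Cumulative inputs are converted by adjacent differencing and
must be non-increasing. All volumes are fractions of structure volume;
absolute volumes are normalised on construction. DICOM-RT ingestion is out
of scope: the CSV contract is the ingestion surface.

Scalar metrics: mean dose is Σ vᵢ·Dᵢ over bin midpoints; V_x counts the
volume of bins whose midpoint dose is at least the threshold (a
non-increasing step function with V(0) = 1); gEUD is the power mean
(Σ vᵢ·Dᵢ^(1/n))ⁿ with zero-dose bins excluded from the power sum (their
contribution is exactly 0 for 1/n > 0, and excluding them keeps very small
n numerically safe — the max dose is also factored out of the sum to avoid
overflow). gEUD(n = 1) equals the mean dose identically, and gEUD is
non-increasing in n for heterogeneous dose.

## Forward models and TD_x inversion

The probit (LKB) response is Φ((d − TD50)/(m·TD50)) with Φ evaluated
through the error function (`scipy.special.ndtr`) to machine precision; no
approximation tables. The logistic response is the inverse logit of the
linear predictor. Tolerance doses use the closed forms
TDₓ = TD50·(1 + m·Φ⁻¹(x)) and D = (logit(x) − β₀ − offset)/β_dose. A
solution at or below 0 Gy is reported as the distinguished *not-achieved*
value (`None`; rendered as a dash in tables) — for a gentle, thresholdless
dose–response the low-risk levels genuinely lie outside the physical dose
range. Multivariable logistic models require an explicit covariate profile
for the non-dose features; no default profile is assumed, because the
reported S-PCE table cannot be reproduced under any obvious hypertension
coding and guessing one would silently change the answer. Reporting
conventions: probabilities to 2 decimals, tolerance doses to 1.

## Maximum-likelihood fitting

**LKB.** The binomial log-likelihood (probabilities clipped at 1e-12 so the
objective stays finite under extreme parameters) is maximised over
θ = log(n, m, TD50), the log transform enforcing positivity. A coarse grid
(21 × 21 × 24 log-spaced points over the default box n ∈ [0.05, 2],
m ∈ [0.05, 2], TD50 ∈ [5, 120] Gy — chosen to bracket published pericardium
estimates with margin) ranks starting points; projected gradient descent
(central-difference gradients, Barzilai–Borwein step lengths safeguarded by
Armijo backtracking, box projection) runs from the top three. Convergence
is declared at gradient max-norm < 1e-6; non-convergence returns the best
iterate, flagged. Because descent starts at the best grid point, the
returned optimum can never be worse than the grid. With `fix_n` set only
(m, TD50) move; `fix_n = 1` uses each record's MHD directly and needs no
DVHs. Under uniform-dose cohorts the likelihood is flat in n; the fit
succeeds and the near-zero n-gradient is reported rather than hidden.
Per-n gEUD vectors are cached, and cohort DVHs are stacked onto a common
grid for vectorised evaluation.

**Logistic.** Delegated to statsmodels `Logit` (Newton, tol 1e-8); the
wrapper returns intercept, per-feature log-odds coefficients and the
covariance matrix for Wald odds-ratio CIs. Perfect or quasi-separation
(statsmodels warning, singular Hessian, or |coefficient| > 50) raises a
dedicated error instead of returning diverged estimates.

**Stepwise.** Forward selection adds, per round, the candidate with the
largest likelihood-ratio gain whose LRT p (chi-square, df = 1 per added
parameter) is below α = 0.05; candidates are scanned in lexicographic
order so ties are deterministic. Candidates are expected to come from the
univariate p < 0.10 screen.

## Validation

AUC is the midrank Mann–Whitney U statistic divided by n₁·n₀ (ties count
½), with a 95% stratified bootstrap percentile CI (2000 replicates;
stratified because the point estimate conditions on the class totals; the
analytic alternative was not used to stay consistent with the
bootstrap-centric design). Bootstrap optimism correction follows TRIPOD:
B = 1000 naive (unstratified) resamples at cohort size, refit per
resample, optimism_b = AUC on the resample minus AUC of the
resample-fitted model on the original cohort, adjusted = apparent − mean
optimism; single-class or separation-failing resamples are redrawn and
logged. Hosmer–Lemeshow ranks patients into g = 10 near-equal groups with
tied predictions kept together, merges groups with zero expected count
into their neighbour, and sums (obs − exp)²/exp over both outcome states.
The default df is g − 2 (appropriate after model fitting) but is
configurable — df = g is the correct null when the supplied probabilities
are external truths rather than fitted values, and that is what the
calibration-null simulations use. Model-vs-model agreement is ordinary
least squares of one prediction vector on the other with R² = 1 −
SS_res/SS_tot.

## Synthetic cohorts

The generator encodes the study conditions: 229 patients, MHD marginal a
truncated log-normal on [0.46, 56.9] Gy whose log-scale location is solved
(Brent) at configuration time so the truncated median is exactly 32.2 Gy;
the log-scale spread defaults to σ = 1.3, the family member whose implied
any-grade incidence under the published logistic truth (≈ 46.5%) comes
closest to the reported 43.7% — no member of a median/range-matched
truncated log-normal family reaches 43.7% exactly (the real dose marginal
is evidently more left-skewed), which is a known fidelity limit of this
family. Hypertension is Bernoulli(0.301), independent of MHD by default
(the true joint distribution is unknown; a log-OR-per-Gy dependence knob
exists for sensitivity runs, and the independence assumption is flagged in
the cohort metadata). Outcomes are independent Bernoulli draws from a
truth model per endpoint — any-grade from the published logistic model,
symptomatic from the published MHD-based probit (the printed S-PCE
logistic coefficients imply ≈ 19% incidence on any median-matched
marginal, far from the reported 7.9%, so they are not a usable truth; the
probit gives ≈ 12%). An optional subset mode nests S-PCE inside A-PCE by
conditional thinning.

DVHs come from a normalised logistic cumulative fall-off whose location is
jittered per patient and whose scale (default 7 Gy) sets heterogeneity;
multiplicative gamma noise (drawn once per DVH so the rescaling loop
converges) adds realistic wiggle, and the dose axis is rescaled until the
realised mean dose matches the sampled MHD within 0.02 Gy (hard failure
beyond 0.05 Gy or past the 80 Gy cap). Zero heterogeneity produces a
single bin centred exactly on the target, for which gEUD is independent
of n. These shapes emulate partially irradiated hearts well enough that
gEUD at n < 1 separates clearly from the mean dose, but they are not
anatomically derived dose distributions: passing tests demonstrate
estimator correctness under the assumed data-generating process, not
clinical transportability.

## Problem sizes and numerical choices

Simulation-backed checks use sizes that make the statistics decisive while
keeping the default suite quick: 50 replicate cohorts of n = 1000 for
TD50/m recovery (observed bias ≲ 0.5%), 500-patient DVH cohorts at 0.5 Gy
bins for free three-parameter recovery (n is weakly identified — a known
property of the volume-effect exponent — so recovery is asserted on the
median of replicates for m and TD50), B = 100–200 for optimism
demonstrations, and 200 replicates for null-distribution checks. Seeds are
explicit everywhere; the package-level default fitting seed is an
arbitrary fixed constant.

## Known limitations

- The MHD marginal family cannot reproduce the reported incidence exactly
  (above); simulated any-grade incidence runs ≈ 3 pp high.
- The volume-effect exponent n is poorly identified at realistic cohort
  sizes and DVH heterogeneity; TD50 and m are the reliable outputs of the
  free LKB fit.
- No fractionation corrections (EQD2/BED): the emulated cohort is
  conventionally fractionated and none were applied in the source
  analysis.
- Bootstrap AUC CIs and the Hosmer–Lemeshow df convention vary across
  software; both are configurable rather than canonical.
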