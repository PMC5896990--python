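# Methods

## Setting and model

The package analyses the causal effect of a plasma lipid fraction
(LDL cholesterol, HDL cholesterol, triglycerides, or total cholesterol) on
incident abdominal aortic aneurysm (AAA), a binary clinical event, using
genetic variants as instrumental variables. Effects are expressed per one
standard deviation (SD) of the lipid; the consortium SDs used for scaling
are LDL 38.7, HDL 15.5, TG 90.7, TC 41.8 mg/dL. The outcome stage is a
logistic model, so the causal parameter θ is a log odds ratio per SD; no
follow-up time is modelled (incident status, not survival).

An instrument j must be associated with the lipid (relevance), free of
confounder associations (exchangeability), and affect AAA only through the
lipid (exclusion restriction). The estimators relax the third assumption to
different degrees, which is why all three are run together.

## Estimators

Given harmonized per-instrument estimates (β̂_Xj, σ_Xj) and (β̂_Yj, σ_Yj):

* **Wald ratio**: θ̂_j = β̂_Yj/β̂_Xj, SE σ_Yj/|β̂_Xj| (first-order delta
  method only; second-order terms are negligible at F ≫ 10 and would add
  noise at F ≈ 10).
* **IVW (fixed effect)**: inverse-variance pooling of the ratios. A
  multiplicative random-effects variant (SE scaled by √(Q/(k−1)), truncated
  below at 1) is available by flag but is not the default.
* **MR-Egger**: instruments oriented so β̂_X ≥ 0, weighted regression
  (weights σ_Yj⁻²) of β̂_Y on β̂_X with intercept. Coefficient SEs are
  multiplied by max(1, residual SD) and p-values use t with k−2 df; a
  normal-inference flag exists. A test hook constrains the intercept to 0
  with unit dispersion and normal inference, in which case the fit reduces
  exactly to fixed-effect IVW (the truncated dispersion and t df are
  deliberately disabled there, otherwise the equivalence cannot be exact).
* **Weighted median**: ratios sorted ascending, normalized weights w′_j,
  cumulative midpoints s_j = Σ_{i≤j} w′_i − w′_j/2, linear interpolation of
  ratio against s at s = 0.5, clamped to the extreme ratios when 0.5 falls
  outside [s_1, s_k]. SE from a parametric bootstrap (default 1000
  replicates) redrawing both β̂_X and β̂_Y from normals at their SEs; the
  seed is mandatory, and weights are recomputed from the redrawn β̂_X.

All 95% intervals use 1.96·SE exactly (matching two-decimal reporting
conventions), including the Egger coefficients, whose p-values are
nonetheless t-based; the slight mismatch is intentional and documented.

## Heterogeneity and pleiotropy diagnostics

Cochran's Q is computed about the IVW pooled estimate (its minimizer on the
inverse-variance metric), with a χ²(k−1) p-value and I² = max(0, (Q−df)/Q).
The I² interval is the test-based interval on ln H (H² = Q/df): se(ln H) =
½(ln Q − ln df)/(√(2Q) − √(2df−1)) for Q > k, with the usual small-Q
approximation otherwise; H is truncated at 1 before the interval is built
and the interval is truncated to keep the point estimate inside [0, 100].
The Egger intercept with its t-based p is surfaced as the directional
pleiotropy check, flagged at p < 0.05.

## Instrument strength and sample overlap

The joint F statistic is (n−k−1)/k · r²/(1−r²) with r² = Σ 2p_j(1−p_j)β_j²
for a unit-variance exposure. When a proportion ω of the outcome sample
overlaps the exposure sample, the IV estimate under the null drifts toward
the confounded observational association β_obs: expected bias ω·β_obs/F.
The implied type-I error of the nominal two-sided α test uses the
approximate null SE of the IV log-OR for a binary outcome,
s = (r²·n·v(1−v))^(−1/2) with case fraction v:
Φ(−z_{1−α/2} − b/s) + 1 − Φ(z_{1−α/2} − b/s). The case fraction default is
388/8,793 (the cohort case count; an alternative count of 338 appears in
some summaries of the same study and changes the result by <0.001).
These closed forms reproduce every reproducible cell of the published
diagnostic table; the two cells whose printed r² inputs are rounded to
three decimals reproduce only to ±0.1 in F, which is the propagated
rounding, not an implementation difference.

## Harmonization rules

Inner join on variant ID; outcome estimates coded on the opposite allele are
sign-flipped; alleles matching only after strand complement are complemented
first; anything else is dropped with a logged reason. Palindromic variants
(A/T, C/G) are dropped when either side's effect-allele frequency is missing
or lies in [0.42, 0.58] (configurable), because a strand flip is then
indistinguishable from an allele swap; retained palindromes are aligned by
frequency side alone, since their allele labels carry no strand information.
Instrument selection is greedy p-value-ordered clumping against a supplied
r² matrix (defaults p < 5×10⁻⁸, r² ≤ 0.001), ties broken lexicographically
by variant ID for determinism; no distance windows and no LD computation
from panels.

## Cohort stages

Friedewald LDL is TC − HDL − TG/5, undetermined above 400 mg/dL TG.
Eligibility filters run in a fixed order (non-white, missing genotype,
lipid-lowering medication, fasting <8 h, any missing lipid) with
first-filter attribution of removals, mirroring the usual exclusion-table
bookkeeping; the retained set is order-invariant. Event adjudication is an
exact-match boolean rule over coded records — one hospital-discharge
diagnosis 441.3/441.4, two outpatient diagnoses with those codes ≥7 days
apart (boundary inclusive), procedure 38.44/39.71, or underlying cause of
death 441.3/441.4/I71.3/I71.4 — with an optional date-range filter and a
review list for near-miss codes, which are never auto-qualified.

The per-SNP logistic regression is written as iteratively reweighted least
squares with step-halving (so the log-likelihood is monotone), convergence
at max|Δβ| < 1e-8 within 50 iterations, and SEs from the observed
information at the MLE (observed and expected coincide under the logit
link); non-convergence or a diverging linear predictor raises a separation
error rather than returning a silent estimate. This in-package IRLS exists
because the Monte-Carlo validation runs ~15,000 such fits; statsmodels
serves as an independent cross-check in the tests. The observational
(confounded) lipid model adjusts for age, sex, center, smoking, height,
white blood count, fibrinogen, hypertension, diabetes and peripheral
arterial disease, plus the other two of {LDL, HDL, TG} for those three
exposures; the TC model excludes the lipid covariates because TC is their
exact linear combination here.

## Synthetic data

The generator emulates the two-sample lipid–AAA design: k = 78 independent
instruments (post-clumping, so LD-free; a block-LD helper exists only to
exercise clumping), minor allele frequencies uniform on [0.05, 0.5],
per-allele effects scaled so Σ 2p(1−p)β² equals the target r² exactly
(defaults 0.071 two-sample, 0.087 in the one-sample validation), exposure
GWAS n = 188,577, cohort n = 8,793 with 4.4% incidence, and θ = ln 1.55.
Confounding defaults are γ_X = 0.4 (per SD) and γ_Y = 0.6 (log-odds),
chosen once so the implied observational log-OR θ + γ_Xγ_Y ≈ 0.24 per SD
sits in the regime of the published confounded estimates (~0.24).

Summary-statistic mode adds sampling noise at the analytic SEs
((n·2p(1−p))^(−1/2) for the unit-variance exposure;
(n·2p(1−p)·v(1−v))^(−1/2) for the binary outcome log-OR). Overlap is
modelled by correlating the two sampling errors per SNP with
corr = ω·β_obs·√(v(1−v))/√(1−r²) — the correlation induced by shared
participants whose non-genetic exposure residual also drives the outcome
through the confounder (derived from the covariance of the two regression
errors over the same individuals). With this mechanism the empirical IVW
bias at ω = 1 matches the analytic ω·β_obs/F prediction, which is exactly
what the cross-validation test demands.

Directional pleiotropy draws half-normal direct effects on a random subset
of instruments with a common sign **relative to the exposure-increasing
allele** (α_j carries sign(β_j)): in an arbitrary allele coding a literal
common sign cancels across instruments and produces no systematic ratio
shift, which would make "directional" indistinguishable from balanced.
Magnitudes are independent of instrument strength, so InSIDE holds and the
Egger slope remains consistent. Balanced pleiotropy is mean-zero normal.

Cohort mode draws Hardy–Weinberg genotypes, builds the unit-variance latent
exposure from genetics + confounder + residual, calibrates the event-model
intercept by root-finding so realized incidence hits the target, emits
lipids in mg/dL with the Friedewald identity built in (TC constructed as
LDL + HDL + TG/5, or LDL backed out when TC is the exposure), plants weak
age/sex/center/PC effects on the event, and writes coded records whose
rule-based adjudication recovers the planted status exactly. Exclusion
flags are planted only at caller-specified rates (default none).

What the generator does **not** emulate: real allele-frequency spectra and
LD structure, population stratification (the PCs are planted noise
covariates, not ancestry), selection of instruments within the same sample
(winner's curse), time-to-event structure, and measurement error in lipids.
Passing tests therefore demonstrate the statistical machinery under the
stated design, not robustness to those real-data features.

## Validation design and problem sizes

The analytic diagnostics are checked cell-by-cell from printed inputs
(<1 s). Estimator implementations are checked against independent
weighted-least-squares oracles to 1e-10 on 50 simulated instruments.
Monte-Carlo properties use 500 replicates at the study's own scale
(k = 78, the SE regimes above): mean IVW OR within 5% of the true 1.55 and
≥90% CI coverage; Egger intercept rejection 5% ± 2% under no pleiotropy;
and with 40% of instruments carrying large directional pleiotropy
(half-normal scale 1.0), the weighted median's absolute bias under a third
of IVW's. The one-sample overlap validation runs 200 full pipeline
replicates (simulate → exclusions → 78 linear + 78 logistic fits → MR) at
n = 8,793, θ = 0, full overlap, and compares the empirical IVW rejection
rate to the analytic prediction within two binomial Monte-Carlo SEs; β_obs
for the prediction is measured by the observational model on a separate
simulated cohort, not assumed. Replicate counts were chosen to keep the
full suite under ten minutes on one CPU while leaving the Monte-Carlo SEs
well inside the asserted margins.

## Known limitations

Two-sample estimators only (plus the single-ratio helper); no mode-based
estimators, MR-PRESSO, multivariable MR, or leave-one-out scans. No strand
inference from reference genomes or proxy-variant lookup. The published
odds-ratio table itself is not reproducible without the real consortium and
cohort data; the package validates that layer by the property battery
above instead. P-values are reported unadjusted across lipids and methods,
matching the analysis design the package reproduces.
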