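# Methods

## Scope and data model

The package analyses person × item matrices of dichotomous (rated / not
rated) checklist responses with three per-person categorical covariates:
gender (male/female), school-age group (infant, kindergarten, primary,
junior high, high) and CARS-classified symptom severity (non-autism,
mild-to-moderate, severe). Missing cells are treated as not administered
and excluded pairwise from every sum (likelihood, residuals, counts,
correlations); nothing is imputed. Weighted ABC scoring (items worth 1–4
points, positive screen at ≥ 68 of the weighted total) is supported for
scoring sheets, but all model fitting happens on the dichotomous form.

The packaged instrument definition carries the published item texts where
available; the remaining texts are empty strings flagged `text_source:
"absent"`, subscale membership beyond what published tables imply is flagged
`"unverified"`, and the per-item weights are placeholders flagged
`"placeholder"` because the full frequency-derived weight catalogue is not
reproduced here. None of these fields enter any model; they are scoring and
display metadata only.

## Rasch calibration

Estimation is joint maximum likelihood (JML), the approach of WINSTEPS-style
software: the raw score is sufficient for each parameter, so the algorithm
alternates damped Newton solves of the per-person and per-item score
equations until the largest parameter change over a cycle falls below `tol`
(default 1e-6 logits, `max_iter` 100). Starting values are
`logit((score+0.5)/(count+1))` for persons and the centered failure-logit
for items. The gauge is fixed by re-centering item difficulties to mean
zero each cycle, shifting person measures by the same constant so the
likelihood is untouched. Persons or items with perfect or zero observed
margins have no finite estimate; they are removed beforehand by iterative
extreme screening and reported as dropped rather than extrapolated (the
extrapolation constants of commercial software are not reproduced).

JML difficulty estimates carry the classic multiplicative bias of order
L/(L−1) at small item counts; an optional `(L−1)/L` correction is available
(`bias_correction=True`, default off, matching the reported-software
convention). Standard errors are the binomial-information closed form
`1/sqrt(Σ W_pi)` with `W = P(1−P)`.

## Fit diagnostics

Standardized residuals are `z = (x − P)/sqrt(P(1−P))`. Outfit MNSQ is the
plain mean of `z²` over observed cells; infit weights by `W`. Zstd uses the
Wilson–Hilferty cube-root transformation `(MNSQ^{1/3} − 1)·3/q + q/3`, with
the statistic's model variance `q²` from the Bernoulli fourth-moment
formulas (`C = W(1 − 3W)`): `Var(outfit) = ΣC/W²/N² − 1/N`,
`Var(infit) = Σ(C − W²)/(ΣW)²`. Displayed Zstd is clamped at ±9.9, the
print convention of the classic software tables. Flagging windows default
to MNSQ ∈ [0.75, 1.33] and Zstd ∈ [−2, 2] on the infit columns, both
configurable (e.g. 0.5–1.5 conventions are one argument away).

Separation uses model error only: error variance = mean(se²), true variance
= max(var(measures) − error, 0), `G = sqrt(true/error)`,
`R = G²/(1+G²)`. The misfit-inflated "real" variants some software also
prints are not computed; outputs are labelled model-based.

## Dimensionality

PCA is computed on the item × item Pearson correlation matrix of the
standardized residuals (pairwise-complete; item pairs with fewer than 30
overlapping persons are reported as low-overlap). Loadings are
eigenvector × sqrt(eigenvalue); each contrast's sign is fixed so its
largest-|loading| item is positive. The unidimensionality flag is the
conjunction: variance explained by measures ≥ 40% and first contrast
eigenvalue < 2.0 item-units.

"Variance explained by the measures" follows the eigenvalue-unit convention
of the software whose 40% rule is being applied: the explained raw variance
`Σ W(β−δ)²` is rescaled by the raw residual variance `Σ W`, which
corresponds to the L units of the residual-correlation trace, giving
`V = L·ΣW(β−δ)²/ΣW` and a percentage `100·V/(V+L)`. Under this convention
model-true data shaped like the ABC calibration sample show ~59% explained;
a per-person averaging convention would report ~19% on the same data and
make the 40% rule inoperable, which is why it was rejected. The published
measure-to-contrast variance ratios are reported (`measure_contrast_ratios`)
but deliberately excluded from the unidimensionality flag.

## DIF model and optimizer

Uniform DIF is modelled in the marginal two-parameter logistic
`logit P = α_i(θ − δ_i − xᵀγ_i)` with a standard-normal latent trait
integrated by Gauss–Hermite quadrature (default 21 nodes; persons are
compressed to distinct covariate patterns before evaluation). Dummy coding
uses reference groups female / high school / severe, so a reference person
is an all-zero row and `γ_ik < 0` makes item i easier for group k. With all
discriminations forced to 1 (`rasch_constrained=True`) the model is the
Rasch variant; the default leaves α free, which is what the generalized
partial-credit formulation reduces to on dichotomous items.

The penalized marginal likelihood `ℓ − λΣ|γ|` is maximized by L-BFGS-B
after splitting `γ = γ⁺ − γ⁻` with both halves bounded at zero: the penalty
becomes a smooth linear term and active bounds deliver exact zeros, which a
smooth |·| approximation would not. Discriminations are optimized on the
log scale (hence always positive). `λ_max` is the largest absolute gamma-
gradient of the unpenalized likelihood at the no-DIF fit — the smallest
penalty at which the all-zero solution is stationary — and the path runs
log-spaced from `λ_max` down to `λ_max/1000` (default 50 points), each fit
warm-started from the previous one. Coefficients with `|γ| < 1e-4` are
reported as zero and excluded from df. BIC is `−2·loglik + log(n_persons)·df`
with df the count of surviving parameters; ties select the larger λ
(sparser model). Non-converged path points are flagged and skipped during
selection.

On a coarse λ grid the step below `λ_max` can admit several coefficients at
once, so very small `n_lambda` (≲ 5) can miss a sparse solution that a finer
grid finds; the default 50-point path does not have this problem.

## Synthetic data

`simulate` draws, in a fixed order from one seeded PCG64 generator:
covariates from the configured categorical margins (factors independent by
default — the joint demographic table was never published — with an
optional joint table), latent traits from N(mean, sd²) plus optional
per-group mean shifts, and responses Bernoulli(logistic(α(θ − δ − xγ)))
item-major. Optional MCAR missingness (default 0). Equal seeds give
byte-identical output.

The default configuration mirrors the published calibration sample: 3,319
persons; male 79.69%; age margins 42.60 / 45.28 / 11.45 / 0.6 / 0.07%;
severity 34.20 / 43.57 / 22.23%; 57 unit-discrimination items with 54
difficulties equally spaced on [−2, 2] plus outliers at −4.22, −4.27
(the two near-universal behaviors) and +1.1 (the rarest), and no DIF.
The per-group trait shift exists so *impact* (real group differences in the
trait) can be generated separately from DIF; a detector that confuses the
two fails the impact suite. Multi-trait generation (`n_traits`,
`item_trait`) plants genuinely multidimensional data for the residual-PCA
alternative.

What the generator does not emulate: real item weights/weighted scoring at
the generative level (simulation is dichotomous, as the analysis consumes),
local item dependence, rater effects, non-uniform DIF, informative
missingness, and the unknown joint distribution of age × severity × gender.
Passing the simulation suites therefore shows the estimators recover the
stated generating processes — not that real ABC data satisfy those
processes.

## Problem sizes used in the checks

Simulation-based checks run at: difficulty recovery n = 500 × 20 items;
model-true fit statistics n = 2,000 × 20; residual-PCA null and two-trait
alternative n = 1,000 × 20, ten seeded replicates each with an 8-of-10
pass rule; DIF null / planted-effect (γ = 1.0 on one item's gender column)
/ impact-only (trait shift 0.5, γ ≡ 0) at n = 800 × 15, ten replicates
each, with an 8-point λ path and 15 quadrature nodes. These sizes keep each
suite in the tens of seconds while leaving the binomial/selection noise
well inside the asserted margins.

## Known limitations

- JML estimates are inconsistent in the fixed-items asymptotics; at 15–57
  items the bias is visible in absolute difficulty values (correlation-based
  recovery checks are unaffected).
- The DIF marginal likelihood is non-convex in (α, δ, γ); warm starts make
  the path stable in practice but global optimality is not guaranteed.
- "Real" (misfit-inflated) separation, non-uniform DIF, anchor purification
  and polytomous models are out of scope.
- The published tables shipped as reference data are inputs for screening
  and tabulation checks; the study's own fitted measures are not
  reproducible without its raw data.
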