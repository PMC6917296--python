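# Methods

## Model and assumptions

The score treats a family's lifetime *pure* breast-cancer risk p — the
probability a member develops the disease over a lifetime in the absence of
competing mortality — as a shared frailty with a Beta(α, β) prior.  Onset
times of first-degree female relatives follow the cause-specific hazard
λ_p(t) = f(p) λ₀(t), with λ₀ the population one-year baseline.  The
multiplier

    f(p) = log(1−p) / log(1−p₀)

is the unique multiplicative form under which a member's own lifetime pure
risk equals p; it satisfies f(p₀) = 1 and f → 0 as p → 0.  This functional
form is a reconstruction: it is forced by requiring the documented
posterior density to follow from the censored-survival likelihood, but its
original derivation is not part of this package.

With relatives observed to ages Xᵢ (diagnosis if dᵢ = 1, else current or
death age), the likelihood ∏ [f(p)λ₀(Xᵢ)]^{dᵢ} exp(−f(p)Λ₀(Xᵢ)) reduces,
as a function of p, to f(p)^m (1−p)^{−c} with m = Σdᵢ and
c = ΣΛ₀(Xᵢ)/log(1−p₀) ≤ 0.  The posterior is therefore

    π(p | data) ∝ p^{α−1} (1−p)^{β−c−1} (−log(1−p))^m,

and the score is its mean.  Assumptions that matter: mothers and sisters
are exchangeable (identical weight); half-sisters are excluded as
second-degree; censoring (current age, death) is independent of p; the
index woman's own follow-up is *not* part of the family likelihood — the
score summarises her relatives, and her own age enters downstream models as
a covariate (flag `include_index` is deliberately absent rather than
defaulted: scoring code only ever sees the relatives it is given).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| p₀ | 0.197 | probability | population lifetime pure risk; prior mean anchor |
| α, β | 1.184, 4.828 | — | Beta prior shapes (published calibration at p₀ = 0.197) |
| familial RR | 2 | ratio | doubling constraint used by the solving calibration variants |
| lifetime horizon | 90 | years | upper age of lifetime-risk integrals (conventional bound) |
| LOESS span | 0.5 | fraction | degree-1 tricube local regression, no robustness iterations |

β = 4.828 is kept verbatim even though α(1−0.197)/0.197 = 4.826; the
1-in-2000 discrepancy is attributable to rounding of p₀ at the third
decimal, and the printed pair is treated as authoritative.  The three
solving variants in `prior.calibrate_prior` (`conjugate_event_ratio`,
`posterior_mean_ratio`, `joint_event_ratio`) are distinct, documented
operationalisations of "risk doubles given an affected relative"; none
reproduces α = 1.184 exactly (they give α ≈ 0.8–1.0), which is why
`printed_constants` is the default and the variants exist for sensitivity
analysis only.

## Numerical choices

* **Hazard arithmetic.**  Rates are piecewise-constant on [a, a+1); Λ is
  exact under that convention, including fractional ages.  Evaluation
  outside the table raises rather than extrapolating, because lifetime
  risks are dominated by the hazard tail.
* **Posterior mean, closed form.**  The moments
  ∫ p^{a−1}(1−p)^{b−1}(−log(1−p))^m dp equal (−1)^m ∂^m B(a,b)/∂b^m,
  computed by the product-rule recursion B^{(k)} = Σ C(k−1,j) B^{(j)} g_{k−j}
  with g_k = ψ^{(k−1)}(b) − ψ^{(k−1)}(a+b); the (−1)^m and B(a,b) scalings
  cancel in the numerator/denominator ratio.  Used for m ≤ 12; the
  alternating recursion loses accuracy beyond that and defers to quadrature
  with a logged notice.
* **Posterior mean, quadrature.**  After u = −log(1−p) the integrands are
  (1−e^{−u})^{a−1} e^{−ub} u^m on (0, ∞), removing the log singularity at
  p = 1; adaptive quadrature at 1e−11 relative tolerance.  The untransformed
  (0, 1) integral survives only as a test oracle.  The two routes agree to
  well under 1e−6 across α ∈ (0.5, 5), b ∈ (1, 30), m ≤ 5.
* **Absolute risk.**  Cause-specific cumulative incidence with exact
  within-year competing-risk algebra, S(t)·h₁/(h₁+h₂)·(1−e^{−(h₁+h₂)}) per
  year (fractional final years handled the same way), not the cruder h₁·S
  approximation.  It equals the pure risk when mortality vanishes and never
  exceeds it.
* **Calibration bins.**  Bin k covers ((k−1)%, k%] with open ends at 1 and
  10; expected counts use k% even in the open-ended bins — a deliberate,
  slight approximation.  Degrees of freedom stay fixed at 9 even when bins
  are empty (empty bins contribute 0, with a notice).  Clopper–Pearson
  intervals use the rounded weighted denominator, since exact binomial
  intervals need integer trials.
* **Loss to follow-up.**  Women censored event-free before 5 years weight
  the denominator by (absolute risk experienced) / (5-year absolute risk).
  They are excluded from ROC computation — the weighting is defined for the
  goodness-of-fit denominator only — which is a documented limitation.
* **ROC.**  Empirical curve with midpoint tie handling, so identical scores
  give AUC 0.5 and AUC equals the normalised Mann–Whitney U.  pAUC is the
  unnormalised area over specificity 0.90–1.00 (maximum 0.1); sensitivity
  at 90% specificity is the best TPR among achievable thresholds with
  FPR ≤ 0.1, without interpolation.
* **Cox fitting.**  Partial-likelihood fitting, baselines and log-likelihood
  values are delegated to standard survival routines; this package consumes
  per-woman hazards and log-likelihoods (`likelihood_ratio_test`,
  `MODEL_GRID`) rather than re-implementing them.

## Synthetic cohorts

`bfhs.simulate` inverts the score's own generative model: p ~ Beta(α, β),
relatives' onset ages by inverse-transform sampling of f(p)Λ₀, independent
death from a Gompertz-like mortality table, censoring at an attained age.
Index women enrol cancer-free at U(35, 74) and are followed for 5-year
outcomes with administrative follow-up U(5, 10) years and a 2.3%
loss-to-follow-up fraction censored uniformly inside the window.  Family
sizes are Poisson(3.9) truncated to 0–16 (mean ≈ 3.9, matching the target
cohort shape); relatives' attained ages are uniform on 30–85, with the
mother, when present, attaining the index age + 25.

These structural distributions are stand-ins — the joint distribution of
real family structure is unknown, the bundled hazard tables are synthetic
(SEER-like in shape, calibrated so the lifetime pure risk is exactly 0.197,
zero before age 20 and increasing thereafter), and no selection on family
history is simulated.  What the simulator does guarantee is *internal model
consistency*: the data-generating process is exactly the process the score
assumes, so E[p | data] = BFHS holds by construction and is verified
empirically (decile-binned latent risk vs score agrees within 0.01 on
20,000 families).  Passing these tests demonstrates the inferential
machinery is correct; it does not validate the model against real
pedigrees, reporting error, or cohort selection.

Problem sizes used by the checks — 20,000 families for calibration
recovery, 100 replicates of 2,000 families for goodness-of-fit calibration
— were chosen as the smallest sizes at which Monte-Carlo error is
comfortably below the tolerances being asserted.

## Known limitations

* Only first-degree female relatives enter the likelihood; second-degree
  relatives and full pedigrees (BOADICEA/BRCAPRO territory) are out of
  scope, as are genotype-informed scores.
* The worked misreporting example reproduces the published *ordering and
  magnitude* (≈ 0.28, shifts < 0.002) on the bundled synthetic table; exact
  published values would require the original registry-derived hazard
  table.
* The goodness-of-fit expected counts inherit the k%-per-bin approximation,
  so even a perfectly specified predictor carries a small upward χ² bias
  from within-bin risk spread.
* Whether fractional or integer-year ages were used for Λ₀ in the original
  analyses is unknowable from the available description; this package
  supports both and the simulator exercises fractional ages.
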