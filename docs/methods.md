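# Methods

## Outcome model and rule construction

All estimators assume a continuous outcome Y (higher better) from a two-arm
trial with treatment effect-coded A ∈ {−1/2, +1/2} and randomisation
probability π (default 1/2):

    Y = α₀ + α·X + A (β₀ + β·Z) + e

X are prognostic variables, Z candidate moderators. The target rule is
PTR(Z) = I{β₀ + β·Z > 0}, treating exactly when the conditional effect is
positive. Ties at exactly zero recommend control (strict inequality), and a
rule's recommendations are invariant to positive rescaling of its
coefficients.

**Regression method.** OLS of Y on [1, main effects, A, A×Z]. Main effects
include every prognostic and moderator variable once; the rule is read off
the A and A×Z coefficients. Rank-deficient designs raise an error naming
the collinear columns (no silent pseudo-inverse), and n must exceed the
parameter count.

**Kraemer's composite moderator.** For all n_T·n_C treated×control pairs the
outcome difference decomposes as Δ(Y) = α·Δ(X) + β₀ + β·μ(Z) + Δ(e), where
Δ is the within-pair difference and μ the within-pair mean. The weight
regression fits Δ(Y) on [1, μ(Z₁)…μ(Z_K)] jointly by OLS; the slopes are the
weights w_k. The fit includes an intercept even though the compact weighted
sum formulation omits it: the pair decomposition contains β₀, so omitting
the intercept would force the average treatment effect into the weights of
any moderator with non-zero mean (the Z3 level indicators have mean 1/3).
An optional `adjust_dX` flag adds the Δ(X) columns as covariates; their
coefficients are reported as prognostic effect sizes and never enter the
composite. The composite Z*ᵢ = Σ w_k Z_ik feeds a second OLS,
Y ~ [1, Z*, A, A·Z*], whose A-part (β₀*, β*) defines the rule; the rule
also expands to the equivalent raw-moderator rule β₀* + Σ (β*w_k) Z_k.

**Prognostic-score matching (modified Kraemer).** The treatment-free outcome
is modelled on control-arm rows only — μ(Y | A=−1/2) = α₀ + α·Xᵀ — and every
subject in both arms is scored. Each treated subject is matched to its
single nearest control by absolute score distance, with replacement, subject
to a caliper of `caliper_sd` (default 0.1) times the sample SD (n−1
denominator) of the score over **all** subjects; treated subjects without an
admissible control are dropped and counted. Equidistant controls are broken
deterministically by the lowest control row index. Weights, composite and
rule are then computed exactly as above but on the matched pairs. The point
of matching is that pairs with similar treatment-free prognosis have a small
α·Δ(X) nuisance term in Δ(Y), so the weight regression sees a cleaner
moderator signal — at the price of far fewer pairs and possible exclusions.
Degenerate outcomes (constant score, zero admissible matches, a composite
that is constant because all weights vanish) raise typed errors carrying the
matching diagnostics; the study runner records them as method failures.

**Moderator screening** (for applications): stage 1 tests each candidate in
its own model Y ~ 1 + X + Z_k + A + A·Z_k and keeps it if the Wald p-value
of the interaction is below 0.10 (OLS t-distribution); stage 2 refits one
joint model with all retained moderators and drops those with interaction
p > 0.3. An empty survivor set is a legitimate result.

## Policy value, contrasts and inference

The value of a rule is estimated by inverse probability weighting:

    μ{PTR} = (1/n) Σ [ (A+½)(PTR+½)/π · Y + (½−A)(½−PTR)/(1−π) · Y ]

The products of shifted ±1/2 codes are literal 0/1 indicators of receiving
the recommended arm, so μ{PTR} is the mean outcome of rule-followers
weighted by 1/π or 1/(1−π). Contrasts: θ_T = μ{PTR} − μ{A=+1/2} and
θ_C = μ{PTR} − μ{A=−1/2}; the identity θ_T − θ_C = μ{A=−1/2} − μ{A=+1/2}
holds exactly in every sample, and θ_T (θ_C) is exactly zero for the
treat-all (control-all) rule. π is the known design probability, not the
empirical arm fraction (the schema supplies it for real data; 1/2 in all
simulations).

Inference bootstraps the evaluation sample only, with the rule held fixed —
the rule must come from an independent training split, otherwise the value
estimate is optimistic. Resamples missing an entire arm are redrawn (cap
1000 per draw). SE is the bootstrap SD over B = 1000 resamples (default);
the 95% CI is estimate ± 1.96·SE and the p-value is two-sided from the
normal approximation (one-sided by flag). A degenerate contrast (e.g. θ_C
of the control-all rule) correctly yields SE = 0 and p = 1.

In simulations the misclassification rate is the fraction of subjects whose
recommendation conflicts with the known optimal arm I{Y(+1/2) > Y(−1/2)}.

## Synthetic-trial generator

Seven scenarios share one mechanism: draw biomarkers, assign A by a fair
coin, compute both potential outcomes Y(a) = prognostic + a·effect + e with
a single error draw, and observe the A-selected one. The individual effect
τ = effect is then noise-free, and the optimal arm is exact. Scenario
coefficient rosters are in the registry (`ptrkit scenarios` prints it):
1a simple linear; 1b adds exchangeable correlation ρ = 0.5; 2 weak
moderators; 3 adds 12·U1 with U1 hidden; 4 adds 10·U2 to the effect with U2
hidden; 5 adds squares/products to the prognostic part (U1 hidden, M1
observed); 6 adds interactions to the effect part (U2 hidden); 7 divides
the effect by a linear form (subjects with an exactly zero denominator are
redrawn; the resulting heavy tails are deliberately not truncated).

Distributional choices the generator makes (fixed defaults, overridable):

- X1, Z1, Z2, U1, U2, M1 iid standard normal; error e ~ N(0, 1);
- Z3: three equally likely levels, obtained by cutting a standard-normal
  latent at its tertiles and reference-coded as Z3.lv2/Z3.lv3. Using the
  latent-cut construction in every scenario makes 1b with ρ = 0 reproduce 1a
  draw-for-draw;
- scenario 1b correlates the (X1, Z1, Z2, Z3-latent) block with an
  exchangeable correlation matrix via its Cholesky factor; U1, U2, M1 stay
  independent.

Every observed variable is declared with role **both** (prognostic and
candidate moderator): an analyst without knowledge of the generating process
lets all observed variables enter both parts of every prediction model, so
the regression method also estimates null interactions (e.g. A×X1), the
weight regression includes all observed pair-means, and the prognostic score
is fitted on all observed variables. This single "variables in the
prediction model" set is also what gives the matched method its value: a
prognostic score restricted to variables with no moderating role captures
too little treatment-free variation for matching to remove much nuisance.

Train/test draws come from disjoint sub-streams SeedSequence([seed, 0]) and
SeedSequence([seed, 1]) of one master seed. The study runner derives the
per-replicate seed as SeedSequence([master_seed, cell_index, rep]) reduced
below 2³¹, so no stream is shared between replicates or cells, and repeated
runs of the same config are byte-identical.

What the generator does **not** emulate: missing data, measurement error in
biomarkers, non-normal or heteroscedastic outcome errors, informative
censoring, or covariate-adaptive randomisation. Passing simulation tests
therefore demonstrates correctness of the estimators under the stated
parametric conditions, not robustness on messy real trials — the
misspecification scenarios (5, 6, 7) probe the latter only within the
declared forms.

## Study sizes and numerical choices

- The Monte Carlo headline comparison is run at 500 replicates per
  (scenario, n=300) cell with all three methods, enough to order mean θ_T
  with Monte Carlo SEs near 0.015 under the linear scenarios; the runner
  accepts the full 5000-replicate configuration unchanged.
- Aggregates are means/SDs over non-failed replicates with the failure rate
  reported alongside; the SD column is the across-replicate SD of θ_T and is
  NA with fewer than two usable replicates.
- OLS uses `numpy.linalg.lstsq`; rank deficiency is detected from the lstsq
  rank and attributed to columns via QR with pivoting. Wald p-values (for
  screening) come from statsmodels' OLS t-tests.
- CSV round trips are exact: floats are written in shortest round-tripping
  form and parsed with pandas' `round_trip` parser.
- Sample-size grids: the runner takes any list; {50, 200, 300} and
  {75, 200, 300} are both in common use for this comparison and neither is
  privileged.

## Known limitations

- All three estimators are linear-model based; under strong non-linearity
  (scenario 7) none reliably beats treat-everybody, and the package
  deliberately offers no variable selection, basis expansion or
  regularisation.
- The bootstrap treats the rule as fixed; uncertainty from rule estimation
  itself (training-split variability) is not propagated.
- Binary/survival outcomes, >2 arms and cluster randomisation are out of
  scope; missing values are rejected rather than imputed.
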