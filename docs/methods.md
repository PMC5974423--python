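# Methods

## The problem

Case-control neuroimaging studies are rarely balanced. A cohort of 671
minimally drinking adolescents and 34 regular drinkers differs not only
in drinking status but in age and socioeconomic status (SES), both of
which strongly influence regional brain metrics. The conventional
remedy is sequential: fit a confound model on the controls, subtract
its prediction from every subject's metrics ("residualization"), and
run group analysis or classification on the residuals. The premise of
this package is the observation that the confound fit is under-determined
— many regression surfaces explain the control data about equally well
— and the sequential pipeline picks one without regard to the
downstream classification task, potentially discarding group-relevant
signal. The joint model instead estimates the confound coefficients and
a sparse logistic classifier against a single objective.

## Models

**Confound model.** For each metric `i`, a per-metric linear model on
the design `d = [1, age, age², ses]` fitted on controls only, either by
least squares or by robust bisquare regression (Tukey biweight,
`c = 4.685`, scale MAD/0.6745 re-estimated each IRLS iteration, at most
50 iterations — the long-standing defaults of the robust-regression
literature; the statsmodels `RLM` implementation is used). Residuals
`r_s = i_s − Φ·d_sᵀ` are computed for every subject, cases included,
from the control-derived `Φ`.

**Sparse classifier.** Logistic regression with scores `ωᵀr + ν` under
the hard constraint `‖ω‖₀ ≤ N_K`. The metrics with nonzero weight form
the *pattern*. The constraint is handled by penalty decomposition: a
dense companion `ψ` coupled to `ω` by `ρ‖ω − ψ‖²`, with `ρ` grown
geometrically (factor √10, cap 1e8). At each `ρ` the smooth convex
subproblem in `(ν, ψ)` is solved by L-BFGS with analytic gradients; `ω`
is the closed-form projection keeping the `N_K` largest-|ψ| entries
(ties to the lowest index, for reproducible patterns).

**Joint model.** The penalized objective

    (1 − γ)·L(Φ, ν, ψ) + γ·G(Φ) + ρ‖ω − ψ‖²

where `L` is the logistic cost over all subjects on residuals
parameterized by `Φ`, and `G` is the squared confound-model residual
over controls only. `γ = 1/(2σ² + 1)` encodes the assumed noise scale
`σ`; `γ = 0` is the classification-only variant (`JOI_OPT`), and
`γ → 1` recovers the control-only least-squares fit. Optimization is
block coordinate descent (`Φ`, then `(ν, ψ)`, then `ω`), inner sweeps
stopping when every block's relative max-norm change is below
`ε_B = 1e-4`, the outer loop when `‖ω − ψ‖_max < ε_P = 1e-3`. `Φ` is
initialized from the control-only least-squares solution; `ω = ψ = 0`,
`ν = 0`.

## Numerical choices

- **Whitened design.** `[1, age, age², ses]` is severely
  ill-conditioned (age² spans hundreds). All smooth `Φ` solves run in a
  basis whitened by the Cholesky factor of the control-design Gram
  matrix, which makes the `G` Hessian the identity per metric; the
  reparameterization is exact and changes no minimizer.
- **Noise-referenced standardization.** Metrics are centred at the
  control mean and scaled by the SD of the control residuals about the
  least-squares confound fit, not by the raw SD. A group effect of one
  noise-SD then has unit size for every metric regardless of how much
  confound variance it carries. With raw-SD scaling, the ridge-like
  early iterations of penalty decomposition are biased against
  strongly age-driven metrics, measurably degrading support recovery.
  The scaler is stored inside every fitted object and applied
  identically to new tables.
- **Size-scaled initial coupling.** The first `(ν, ψ)` subproblem at
  `ρ₀` is a ridge-regularized logistic fit. Because the loss is a sum
  over `N` subjects, a fixed `ρ₀` becomes vanishingly weak on large
  cohorts; on separable data the dense weights then approach the
  max-margin direction, whose ranking has little to do with per-metric
  signal. `ρ₀ = max(1, N/64)` keeps the per-subject regularization
  constant across scales (and equals 1 at desk scale).
- **Support splicing.** After the outer loop converges, the selected
  support is debiased and refined: the weakest selected metrics are
  tentatively exchanged against the excluded metrics with the largest
  loss gradient, each trial re-polished (for the joint model the
  confound map is re-optimized inside every trial), and a swap is kept
  only when the penalty-free objective strictly decreases. Without
  this step the penalty-decomposition path occasionally settles on a
  support whose fully optimized objective is strictly worse than the
  best one; with it, desk-scale fits match exhaustive-support
  enumeration.
- **Solver tolerances.** Smooth blocks stop at gradient max-norm
  1e-8 (`ftol` effectively disabled); the debiasing alternation stops
  at a relative objective change of 1e-11. All fits are deterministic
  functions of their inputs; seeds enter only through data generation
  and fold splitting.
- **Decision rule.** A subject is labelled a case iff its score is
  strictly positive; zero scores go to the control class, so a
  degenerate constant-zero classifier predicts the majority class.

## Evaluation protocol

Two-fold cross-validation with fold assignment chosen among 200 seeded
candidate stratified splits to minimize the worst standardized mean
difference of the nuisance demographics (sex, ethnicity, scanner,
supratentorial volume — everything except the modelled confounds age
and SES). Test-fold predictions are pooled before metrics are computed
once: sensitivity, specificity, their mean (normalized accuracy —
chance is 50% under any imbalance), rank-based AUC (ties 0.5), and a
two-tailed Fisher exact p for the predicted-versus-true table.
Matched accuracy re-computes normalized accuracy on a 1:1 greedy
nearest-neighbour subset (exact on sex and scanner, then closest in
standardized age/SES, controls used at most once, ties by subject id).
The age-test applies the trained classifier to the held-out controls of
each fold, pools, splits at the median age (ties to the younger group),
and passes iff the Fisher p exceeds 0.01; the SES-test is the same on
SES. Correlated AUCs are compared with the DeLong placement-value
test. Cohort comparability uses pooled-variance t-tests for continuous
demographics and Pearson chi-square without continuity correction for
categorical ones — the combination that reproduces the published
example tables exactly.

Pattern stability is assessed by recording the selected pattern over a
(fold × N_K × σ) grid, collapsing order-insensitively, and normalizing
each pattern's count by the *suitable* runs — those whose budget could
have produced it (a k-metric pattern cannot appear when `N_K < k`).
Patterns above 50% of suitable runs are *dominant*; nested patterns of
different sizes can therefore be dominant simultaneously. Dominant
patterns are re-scored by an unconstrained logistic fit on
least-squares residuals restricted to the pattern, and per-metric
group differences by pooled-variance t-tests on residuals.

## Synthetic cohorts

`make_ncanda_like` emulates the study design: 671 controls (ages
uniform 12–21; SES normal 16.7 ± 2.5) and 34 cases (ages truncated
normal 19.5 ± 1.7 on [14, 21]; SES 18.0 ± 2.3), so age and SES are
genuinely confounded while sex, ethnicity, scanner and supratentorial
volume are drawn from common distributions. Each of 32 structural and
112 diffusion metrics follows the confound model with coefficients
drawn once per metric — intercept U(−1, 1), linear age U(−1, 1) per
year, quadratic age U(−0.02, 0.02), SES U(−0.1, 0.1), i.i.d. Gaussian
noise of SD 1 — and stored as ground truth. The age slopes make age
the dominant variance source, as in adolescent developmental data,
where age effects outweigh the group effects being sought. A
`true_pattern` of (by default) four metrics carries an additional group
effect of `δ` noise-SD units whose sign is aligned with the metric's
age trend: apparent raw-score group differences are thereby inflated by
age, which is exactly the adversarial geometry a confounded
case-control design produces and the reason the raw-score comparator
inherits an age-dependent decision rule. An optional contamination
switch replaces a fraction of observations with 5×-SD outliers to
exercise the robust branch.

What the generator does *not* emulate: spatial correlation between
regional metrics, site/scanner effects on the metrics themselves,
longitudinal structure, and non-Gaussian measurement noise. Passing
tests therefore demonstrate correctness of the estimators and the
claimed qualitative contrasts between pipelines under the model's own
assumptions — not performance on real imaging data.

`make_fig1_cohort` is the didactic single-metric setting: two groups of
30 with ages uniform on the same interval (17–21), a linear age trend
(slope 2 noise-SD per year), and a 5 noise-SD group offset. The age
trend spreads each group by ~8 noise-SD, so the raw-score classifier
cannot separate the groups while the joint fit, free to choose the
confound line that best serves classification, separates them exactly.

## Problem sizes used in the test suite

The acceptance suite runs the full-size cohort (705 × 144) over 20
seeds for recovery/indifference rates, 50 seeds of the didactic
experiment, and 20 desk-scale instances (n = 60, up to 8 metrics)
against exhaustive-support oracles; unit tests use reduced cohorts
(~150–200 subjects, ≤ 20 metrics). The acceptance script reports
recovery rates over 12 seeds derived from its `--seed`.

## Known limitations

- The joint objective is non-convex; block coordinate descent plus
  splicing finds the global support reliably at desk scale, but no
  global guarantee exists, and with very few cases the globally
  loss-optimal support can genuinely differ from the generating one
  (overfitting is a property of the objective, not the solver).
- Per-subject robust weights (`1/σ_s²`) apply to the sequential
  bisquare branch only; the joint model uses a single fixed `σ`
  through `γ`.
- The robust branch accepts the statsmodels IRLS result after its
  iteration cap rather than raising on non-convergence.
- `N_K` and `σ` are exploration parameters; nothing in the package
  selects them automatically beyond the recorded grids.
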