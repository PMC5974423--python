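"""Joint estimation of the confound model and the sparse classifier.

Instead of residualizing first and classifying second, the joint model
minimizes a single penalized objective over the confound coefficients
``Phi``, the classifier offset ``nu``, the dense weights ``psi``, and
their sparse companion ``omega``::

    (1 - gamma) * L(Phi, nu, psi)  +  gamma * G(Phi)  +  rho * ||omega - psi||^2

where ``L`` is the logistic cost over *all* subjects evaluated on
residuals ``i_s - Phi d_s^T``, ``G`` is the squared confound-model
residual summed over *controls only*, and ``gamma = 1 / (2 sigma^2 + 1)``
trades classification accuracy against confound-model fidelity
(``sigma`` is the assumed metric noise scale, fixed a priori). Setting
``gamma = 0`` gives the classification-only variant (``JOI_OPT``); the
``gamma -> 1`` limit recovers the control-only least-squares confound
fit.

Optimization is block coordinate descent with a growing coupling
penalty: at each ``rho``, cycle

    Phi-update  ->  (nu, psi)-update  ->  omega = project_l0(psi)

until every block's relative change falls below ``eps_b``, then grow
``rho`` until ``||omega - psi||_max < eps_p``. ``Phi`` is initialized
from the control-only least-squares fit; ``omega = psi = 0`` and
``nu = 0``. Each smooth block is solved by a quasi-Newton method in a
whitened design basis (the control design Gram factorized by Cholesky),
which removes the severe ill-conditioning of ``[1, age, age^2, ses]``
columns without changing any minimizer.

Every fit is deterministic given its inputs; random seeds enter only
through data generation and fold splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import minimize

from .cohort import CohortTable, select_modality
from .errors import ConvergenceError
from .gam import GamFit, Scaler, fit_gam, noise_scaler, ols_phi, residualize
from .sparse import (
    GRAD_TOL,
    SOLVER_MAX_ITER,
    RhoSchedule,
    SparseClassifier,
    _delta,
    _loss_and_grad,
    fit_sparse_logistic,
    logistic_loss,
    project_l0,
    theta,
)

PIPELINES = ("NO_GAM", "SEQ_OLS", "SEQ_ROBUST", "JOI", "JOI_OPT", "JOI_STR", "JOI_DTI")
JOINT_VARIANTS = ("JOI", "JOI_OPT", "JOI_STR", "JOI_DTI")

#: Default noise-scale grid for parameter exploration; gamma = 1/(2 sigma^2 + 1)
#: spans ~0.03 .. 0.89.
SIGMA_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)
NK_GRID = tuple(range(1, 11))


def gamma_from_sigma(sigma: float) -> float:
    """Mixing weight ``gamma = 1 / (2 sigma^2 + 1)``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return 1.0 / (2.0 * sigma ** 2 + 1.0)


@dataclass
class JointFit:
    """Result of the joint block-coordinate fit.

    ``psi`` is the dense companion of the sparse ``omega``; after
    convergence and support-restricted debiasing they coincide on the
    selected support. ``objective_trace`` records the penalized
    objective after every block update as ``(rho, value)`` pairs;
    within a fixed ``rho`` the sequence is non-increasing.
    """

    Phi: np.ndarray
    nu: float
    omega: np.ndarray
    psi: np.ndarray
    gamma: float
    sigma: Optional[float]
    N_K: int
    variant: str
    scaler: Scaler
    metric_names: list[str]
    use_ses: bool
    rho_trace: list = field(default_factory=list)
    objective_trace: list = field(default_factory=list)
    converged: bool = True

    @property
    def pattern(self) -> tuple[str, ...]:
        return tuple(self.metric_names[j] for j in np.flatnonzero(self.omega))

    def as_gam_fit(self) -> GamFit:
        """View the jointly learned confound coefficients as a GamFit."""
        n_controls = 1  # weights are not defined for the joint fit
        return GamFit(
            Phi=self.Phi.copy(),
            method="joint",
            control_weights=np.ones((n_controls, len(self.metric_names))),
            scaler=self.scaler,
            metric_names=list(self.metric_names),
            use_ses=self.use_ses,
        )

    def classifier(self) -> SparseClassifier:
        return SparseClassifier(
            omega=self.omega.copy(),
            nu=self.nu,
            N_K=self.N_K,
            pattern=self.pattern,
            training_loss=float("nan"),
            metric_names=list(self.metric_names),
        )


# ---------------------------------------------------------------------------
# objective pieces (standardized metric matrix I, design D, labels z)
# ---------------------------------------------------------------------------


def _residuals(I: np.ndarray, D: np.ndarray, Phi: np.ndarray) -> np.ndarray:
    return I - D @ Phi.T


def gam_cost(Phi: np.ndarray, I: np.ndarray, D: np.ndarray, cmask: np.ndarray) -> float:
    """Control-only squared residual cost ``G(Phi)``."""
    Rc = _residuals(I[cmask], D[cmask], Phi)
    return float(np.sum(Rc ** 2))


def joint_objective(
    Phi: np.ndarray,
    nu: float,
    psi: np.ndarray,
    omega: np.ndarray,
    gamma: float,
    rho: float,
    I: np.ndarray,
    D: np.ndarray,
    z: np.ndarray,
    cmask: np.ndarray,
) -> float:
    """Penalized joint objective.

    ``(1-gamma) L(Phi, nu, psi) + gamma G(Phi) + rho ||omega - psi||^2``
    with ``L`` over all subjects and ``G`` over controls only.
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must lie in [0, 1)")
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    R = _residuals(I, D, Phi)
    L = logistic_loss(psi, nu, R, z)
    return (
        (1.0 - gamma) * L
        + gamma * gam_cost(Phi, I, D, cmask)
        + rho * float(np.sum((omega - psi) ** 2))
    )


class _JointProblem:
    """Shared precomputation for one training table (standardized units).

    Whitens the design with the Cholesky factor ``L_c`` of the control
    Gram matrix: ``D = Dw L_c^T``, so ``Phi_raw = Phi_w @ inv(L_c)`` and
    the control-only quadratic ``G`` has identity curvature per metric.
    """

    def __init__(self, I: np.ndarray, D: np.ndarray, z: np.ndarray, cmask: np.ndarray):
        self.I, self.D, self.z, self.cmask = I, D, z.astype(float), cmask
        gram = D[cmask].T @ D[cmask]
        try:
            self.L_c = np.linalg.cholesky(gram)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "control design Gram matrix is not positive definite "
                "(rank-deficient confound design)"
            ) from exc
        # D = Dw @ L_c.T  =>  Dw = D @ inv(L_c).T
        self.Dw = solve_triangular(self.L_c, D.T, lower=True).T
        self.n, self.n_features = I.shape
        self.p = D.shape[1]

    def phi_to_white(self, Phi: np.ndarray) -> np.ndarray:
        return Phi @ self.L_c

    def phi_from_white(self, Phi_w: np.ndarray) -> np.ndarray:
        # Phi_raw = Phi_w @ inv(L_c): solve L_c^T x = Phi_w^T column-wise
        return solve_triangular(self.L_c, Phi_w.T, lower=True, trans="T").T

    def ols_phi(self) -> np.ndarray:
        """Control-only least-squares Phi (raw design units)."""
        return ols_phi(self.D[self.cmask], self.I[self.cmask])


def update_confound_map(
    problem: _JointProblem,
    Phi: np.ndarray,
    nu: float,
    psi: np.ndarray,
    gamma: float,
) -> np.ndarray:
    """Minimize ``(1-gamma) L(Phi, nu', psi') + gamma G(Phi)`` over ``Phi``.

    The logistic term regularizes the confound fit toward whatever
    tilting of the regression surface helps classification; at
    ``gamma -> 1`` (or ``psi' = 0``, which makes ``L`` constant in
    ``Phi``) the minimizer is the control-only least-squares solution.
    """
    I, Dw, z, cmask = problem.I, problem.Dw, problem.z, problem.cmask
    Iw_c, Dw_c = I[cmask], Dw[cmask]
    if gamma > 0.0 and not np.any(psi):
        return problem.ols_phi()  # L constant in Phi; G alone decides
    if gamma == 0.0 and not np.any(psi):
        return Phi  # objective independent of Phi
    shape = (problem.n_features, problem.p)
    x0 = problem.phi_to_white(Phi).ravel()

    def fun(x):
        Phi_w = x.reshape(shape)
        R = I - Dw @ Phi_w.T
        margins = z * (R @ psi + nu)
        L = float(theta(margins).sum())
        s = 1.0 / (1.0 + np.exp(np.clip(margins, -500, 500)))
        # dL/dPhi_w = sum_s sigmoid(-a_s) z_s psi d_w,s^T
        coef = s * z
        gL = np.outer(psi, coef @ Dw)
        Rc = Iw_c - Dw_c @ Phi_w.T
        G = float(np.sum(Rc ** 2))
        gG = -2.0 * Rc.T @ Dw_c
        val = (1.0 - gamma) * L + gamma * G
        grad = (1.0 - gamma) * gL + gamma * gG
        return val, grad.ravel()

    res = minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": SOLVER_MAX_ITER, "gtol": GRAD_TOL, "ftol": 1e-14},
    )
    return problem.phi_from_white(res.x.reshape(shape))


def update_classifier_continuous(
    problem: _JointProblem,
    Phi: np.ndarray,
    nu: float,
    psi: np.ndarray,
    omega: np.ndarray,
    gamma: float,
    rho: float,
    support: Optional[np.ndarray] = None,
) -> tuple[float, np.ndarray]:
    """Minimize ``(1-gamma) L(Phi', nu, psi) + rho ||omega' - psi||^2`` over ``(nu, psi)``.

    Smooth and convex (strictly so for ``rho > 0``). When ``support`` is
    given, the minimization is restricted to those components of
    ``psi`` (used by the debiasing pass); all others stay zero.
    """
    R = _residuals(problem.I, problem.D, Phi)
    z = problem.z
    cols = np.arange(problem.n_features) if support is None else support
    Rs = R[:, cols]
    x0 = np.append(psi[cols], nu)
    scale = max(1.0 - gamma, 1e-12)

    def fun(x):
        w, b = x[:-1], x[-1]
        loss, gw, gnu = _loss_and_grad(w, b, Rs, z)
        pen = rho * np.sum((omega[cols] - w) ** 2)
        gpen = -2.0 * rho * (omega[cols] - w)
        return scale * loss + pen, np.append(scale * gw + gpen, scale * gnu)

    res = minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": SOLVER_MAX_ITER, "gtol": GRAD_TOL, "ftol": 1e-14},
    )
    psi_new = np.zeros(problem.n_features)
    psi_new[cols] = res.x[:-1]
    return float(res.x[-1]), psi_new


def _polish(
    problem: _JointProblem,
    support: np.ndarray,
    gamma: float,
    Phi: np.ndarray,
    nu: float = 0.0,
    psi: Optional[np.ndarray] = None,
    max_rounds: int = 300,
    rtol: float = 1e-11,
) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Alternate the Phi- and support-restricted (nu, psi)-updates to
    convergence of the penalty-free objective; returns (Phi, nu, psi, objective)."""
    if psi is None:
        psi = np.zeros(problem.n_features)
    I, D, z, cmask = problem.I, problem.D, problem.z, problem.cmask
    prev = np.inf
    cur = prev
    for _ in range(max_rounds):
        nu, psi = update_classifier_continuous(
            problem, Phi, nu, psi, psi, gamma, rho=0.0, support=support
        )
        Phi = update_confound_map(problem, Phi, nu, psi, gamma)
        cur = joint_objective(Phi, nu, psi, psi, gamma, 0.0, I, D, z, cmask)
        if prev - cur < rtol * max(1.0, abs(cur)):
            break
        prev = cur
    return Phi, nu, psi, cur


def _refine_support_joint(
    problem: _JointProblem,
    support: np.ndarray,
    gamma: float,
    Phi: np.ndarray,
    nu: float,
    psi: np.ndarray,
    n_candidates: int = 6,
    n_drops: int = 3,
    max_rounds: int = 6,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Greedy support splicing for the joint objective.

    Candidate exchanges pair the weakest-|psi| selected metrics with
    the excluded metrics of largest logistic-gradient magnitude at the
    current solution; each trial support is scored by a short
    alternating polish (warm-started at the current ``Phi``) and a swap
    is kept only when the penalty-free joint objective strictly
    decreases. The confound map is re-optimized inside every trial, so
    a metric whose regression line could be tilted to mimic a group
    effect competes on equal footing with genuinely informative ones.
    """
    support = np.sort(np.asarray(support, dtype=int))
    Phi, nu, psi, best = _polish(problem, support, gamma, Phi, nu, psi)
    for _ in range(max_rounds):
        R = _residuals(problem.I, problem.D, Phi)
        margins = problem.z * (R @ psi + nu)
        s = 1.0 / (1.0 + np.exp(np.clip(margins, -500, 500)))
        grad = R.T @ (-s * problem.z)
        off = np.setdiff1d(np.arange(problem.n_features), support)
        if off.size == 0:
            break
        cand = off[np.argsort(-np.abs(grad[off]), kind="stable")[:n_candidates]]
        weak = support[np.argsort(np.abs(psi[support]), kind="stable")[:n_drops]]
        best_trial = None
        for i in weak:
            for c in cand:
                trial = np.sort(np.append(support[support != i], c))
                _, _, _, obj = _polish(
                    problem, trial, gamma, Phi, nu=0.0, psi=None,
                    max_rounds=40, rtol=1e-9,
                )
                if obj < best - 1e-9 * (1.0 + abs(best)) and (
                    best_trial is None or obj < best_trial[1]
                ):
                    best_trial = (trial, obj)
        if best_trial is None:
            break
        support = best_trial[0]
        Phi, nu, psi, best = _polish(problem, support, gamma, Phi, nu=0.0, psi=None)
    return support, Phi, nu, psi


def fit_joint(
    table: CohortTable,
    N_K: int,
    sigma: Optional[float] = 1.0,
    variant: str = "JOI",
    schedule: RhoSchedule = RhoSchedule(),
    gamma: Optional[float] = None,
    standardize: bool = True,
    debias: bool = True,
    refine: bool = True,
) -> JointFit:
    """Fit the joint confound + sparse-classifier model.

    Parameters
    ----------
    table
        Training cohort (cases and controls).
    N_K
        Sparsity budget: at most ``N_K`` metrics receive nonzero weight.
    sigma
        Assumed metric noise scale; sets ``gamma = 1/(2 sigma^2 + 1)``.
        Ignored for ``variant="JOI_OPT"``, which forces ``gamma = 0``.
    variant
        ``JOI`` (all metrics), ``JOI_STR`` / ``JOI_DTI`` (single
        modality), or ``JOI_OPT`` (classification-only objective).
    gamma
        Overrides the sigma-derived mixing weight when given.
    debias
        After support identification, re-optimize ``Phi`` and the
        support-restricted ``(nu, psi)`` alternately without the
        coupling penalty, then set ``omega = psi``.
    """
    if variant not in JOINT_VARIANTS:
        raise ValueError(f"unknown joint variant {variant!r}")
    if variant == "JOI_STR":
        table = select_modality(table, "STR")
    elif variant == "JOI_DTI":
        table = select_modality(table, "DTI")
    if variant == "JOI_OPT":
        gamma = 0.0
    elif gamma is None:
        gamma = gamma_from_sigma(sigma)
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must lie in [0, 1)")
    if len(np.unique(table.labels)) < 2:
        raise ValueError("training data must contain both classes")

    scaler = (
        noise_scaler(table.controls())
        if standardize
        else Scaler.identity(table.n_features)
    )
    I = scaler.transform(table.metrics)
    D = table.design_matrix()
    problem = _JointProblem(I, D, table.labels, table.controls_mask)

    Phi = problem.ols_phi()
    psi = np.zeros(table.n_features)
    omega = np.zeros(table.n_features)
    nu = 0.0
    rho = schedule.initial_rho(table.n)
    rho_trace, objective_trace = [], []

    def obj(Phi_, nu_, psi_, omega_, rho_):
        return joint_objective(
            Phi_, nu_, psi_, omega_, gamma, rho_, I, D, table.labels, table.controls_mask
        )

    while True:
        rho_trace.append(rho)
        for _ in range(schedule.max_inner):
            Phi_new = update_confound_map(problem, Phi, nu, psi, gamma)
            objective_trace.append((rho, obj(Phi_new, nu, psi, omega, rho)))
            nu_new, psi_new = update_classifier_continuous(
                problem, Phi_new, nu, psi, omega, gamma, rho
            )
            objective_trace.append((rho, obj(Phi_new, nu_new, psi_new, omega, rho)))
            omega_new = project_l0(psi_new, N_K)
            objective_trace.append((rho, obj(Phi_new, nu_new, psi_new, omega_new, rho)))
            changes = max(
                _delta(Phi_new, Phi),
                _delta(nu_new, nu),
                _delta(omega_new, omega),
                _delta(psi_new, psi),
            )
            Phi, nu, psi, omega = Phi_new, nu_new, psi_new, omega_new
            if changes < schedule.eps_b:
                break
        if np.max(np.abs(omega - psi)) < schedule.eps_p:
            break
        if rho >= schedule.cap:
            raise ConvergenceError(
                "penalty cap reached before omega/psi agreement "
                f"(||omega-psi||_max={np.max(np.abs(omega - psi)):.3g})",
                last_state={
                    "Phi": Phi, "nu": nu, "psi": psi, "omega": omega,
                    "rho_trace": rho_trace, "objective_trace": objective_trace,
                },
            )
        rho = min(rho * schedule.factor, schedule.cap)

    if debias:
        support = np.flatnonzero(omega)
        if support.size:
            if refine:
                support, Phi, nu, psi = _refine_support_joint(
                    problem, support, gamma, Phi, nu, psi
                )
            else:
                Phi, nu, psi, _ = _polish(problem, support, gamma, Phi, nu, psi)
            omega = psi.copy()

    return JointFit(
        Phi=Phi, nu=nu, omega=omega, psi=psi, gamma=gamma,
        sigma=None if variant == "JOI_OPT" else sigma,
        N_K=N_K, variant=variant, scaler=scaler,
        metric_names=list(table.metric_names), use_ses=table.use_ses,
        rho_trace=rho_trace, objective_trace=objective_trace, converged=True,
    )


# ---------------------------------------------------------------------------
# uniform pipeline front end
# ---------------------------------------------------------------------------


@dataclass
class FittedPipeline:
    """A trained pipeline with a uniform prediction surface.

    Wraps whichever of the seven implementations was requested and
    exposes ``decision_scores`` / ``predict`` on new cohort tables
    (applying the stored modality selection, standardization, and
    confound removal exactly as during training).
    """

    pipeline: str
    classifier: SparseClassifier
    gamfit: Optional[GamFit] = None
    jointfit: Optional[JointFit] = None
    modality: str = "ALL"
    classifier_scaler: Optional[Scaler] = None

    @property
    def pattern(self) -> tuple[str, ...]:
        return self.classifier.pattern

    def _residual_matrix(self, table: CohortTable) -> np.ndarray:
        table = select_modality(table, self.modality)
        if self.gamfit is not None:
            return residualize(self.gamfit, table).values
        # NO_GAM: standardized raw metrics
        return self.classifier_scaler.transform(table.metrics)

    def decision_scores(self, table: CohortTable) -> np.ndarray:
        return self.classifier.decision_scores(self._residual_matrix(table))

    def predict(self, table: CohortTable) -> np.ndarray:
        scores = self.decision_scores(table)
        return np.where(scores > 0, 1, -1)


def run_pipeline(
    table: CohortTable,
    pipeline: str,
    N_K: int,
    sigma: float = 1.0,
    schedule: RhoSchedule = RhoSchedule(),
) -> FittedPipeline:
    """Train one of the seven implementations on a training table.

    ``NO_GAM`` fits the sparse classifier on standardized raw metrics;
    ``SEQ_OLS`` / ``SEQ_ROBUST`` first fit the confound model on the
    training controls (least squares / bisquare) and classify
    residuals; the ``JOI*`` variants are the joint model.
    """
    if pipeline not in PIPELINES:
        raise ValueError(f"unknown pipeline {pipeline!r}")
    if pipeline in JOINT_VARIANTS:
        jf = fit_joint(table, N_K=N_K, sigma=sigma, variant=pipeline, schedule=schedule)
        modality = {"JOI_STR": "STR", "JOI_DTI": "DTI"}.get(pipeline, "ALL")
        fp = FittedPipeline(
            pipeline=pipeline,
            classifier=jf.classifier(),
            gamfit=jf.as_gam_fit(),
            jointfit=jf,
            modality=modality,
        )
        return fp
    if pipeline == "NO_GAM":
        scaler = noise_scaler(table.controls())
        X = scaler.transform(table.metrics)
        clf = fit_sparse_logistic(
            X, table.labels, N_K=N_K, schedule=schedule, metric_names=table.metric_names
        )
        return FittedPipeline(pipeline=pipeline, classifier=clf, classifier_scaler=scaler)
    method = "ols" if pipeline == "SEQ_OLS" else "bisquare"
    gamfit = fit_gam(table.controls(), method=method)
    R = residualize(gamfit, table)
    clf = fit_sparse_logistic(
        R.values, table.labels, N_K=N_K, schedule=schedule, metric_names=table.metric_names
    )
    return FittedPipeline(pipeline=pipeline, classifier=clf, gamfit=gamfit)
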