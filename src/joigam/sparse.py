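"""l0-constrained sparse logistic regression via penalty decomposition.

The classifier scores a subject's residual metric vector ``r`` as
``omega^T r + nu`` and models the label probability with a logistic
link. The weight vector is constrained to at most ``N_K`` nonzero
entries; the metrics carrying nonzero weight form the selected
*pattern*.

The nonconvex l0 constraint is handled by penalty decomposition: a
dense companion ``psi`` of the sparse ``omega`` is introduced, coupled
by a quadratic penalty ``rho * ||omega - psi||^2`` whose weight grows
geometrically. At each ``rho`` the smooth, convex subproblem in
``(nu, psi)`` is solved by a quasi-Newton method, then ``omega`` is the
closed-form Euclidean projection of ``psi`` onto the sparsity set
(keep the ``N_K`` largest-magnitude entries). The outer loop stops once
``omega`` and ``psi`` agree to within ``eps_p`` in max-norm.

After support identification the classifier is debiased: an
unconstrained logistic fit restricted to the selected support supplies
the reported weights and training loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import ConvergenceError

#: Stopping tolerance (gradient max-norm) for smooth subproblems.
GRAD_TOL = 1e-8
SOLVER_MAX_ITER = 500


@dataclass(frozen=True)
class RhoSchedule:
    """Geometric schedule for the coupling penalty ``rho``.

    The penalty starts at ``rho0``, multiplies by sqrt(10) per outer
    iteration, and is capped at 1e8; the outer loop stops at
    ``||omega - psi||_max < eps_p`` and each inner block sweep at
    relative change ``eps_b`` (both on standardized features).

    ``rho0=None`` (the default) resolves to ``max(1, N/64)`` for an
    ``N``-subject training set: the logistic cost is a sum over
    subjects, so the coupling must grow with ``N`` to keep the first,
    ridge-like subproblem at a constant per-subject regularization
    strength (the reference point is rho0 = 1 on a 64-subject cohort).
    With a size-independent rho0 the early dense iterates of a large
    cohort approach the max-margin solution of a separable problem,
    whose weight ranking is unrelated to per-metric signal strength,
    and support identification degrades.
    """

    rho0: Optional[float] = None
    factor: float = np.sqrt(10.0)
    cap: float = 1e8
    eps_p: float = 1e-3
    eps_b: float = 1e-4
    max_inner: int = 200

    def initial_rho(self, n_subjects: int) -> float:
        if self.rho0 is not None:
            return self.rho0
        return max(1.0, n_subjects / 64.0)


def theta(a: np.ndarray) -> np.ndarray:
    """Logistic loss kernel ``log(1 + exp(-a))``, overflow-safe."""
    return np.logaddexp(0.0, -a)


def logistic_loss(omega: np.ndarray, nu: float, R: np.ndarray, z: np.ndarray) -> float:
    """Total logistic cost ``sum_s theta(z_s (omega^T r_s + nu))``."""
    R = np.asarray(R, dtype=float)
    z = np.asarray(z, dtype=float)
    if R.shape[0] != z.shape[0] or R.shape[1] != np.size(omega):
        raise ValueError("dimension mismatch between weights, residuals, and labels")
    margins = z * (R @ np.asarray(omega, dtype=float) + nu)
    return float(theta(margins).sum())


def _loss_and_grad(w: np.ndarray, nu: float, R: np.ndarray, z: np.ndarray):
    """Loss plus analytic gradient in (w, nu).

    d theta(a)/da = -sigmoid(-a); the chain rule gives the gradient
    below with ``s = sigmoid(-z*(Rw+nu))``.
    """
    margins = z * (R @ w + nu)
    loss = float(theta(margins).sum())
    s = 1.0 / (1.0 + np.exp(np.clip(margins, -500, 500)))  # sigmoid(-margins)
    coef = -s * z
    return loss, R.T @ coef, float(coef.sum())


def project_l0(psi: np.ndarray, N_K: int) -> np.ndarray:
    """Euclidean projection onto ``{w : ||w||_0 <= N_K}``.

    Keeps the ``N_K`` largest-|psi| entries and zeroes the rest, which
    is the closed-form minimizer of ``||w - psi||^2`` over the sparsity
    set. Magnitude ties are broken toward the lowest index
    (deterministic patterns).
    """
    psi = np.asarray(psi, dtype=float)
    if not 1 <= N_K <= psi.size:
        raise ValueError(f"N_K={N_K} out of range for {psi.size} features")
    order = np.argsort(-np.abs(psi), kind="stable")
    out = np.zeros_like(psi)
    keep = order[:N_K]
    out[keep] = psi[keep]
    return out


def fit_logistic(
    R: np.ndarray,
    z: np.ndarray,
    support: Optional[Sequence[int]] = None,
    w0: Optional[np.ndarray] = None,
    nu0: float = 0.0,
    max_iter: int = SOLVER_MAX_ITER,
):
    """Unconstrained maximum-likelihood logistic fit (optionally on a support).

    Returns ``(omega_full, nu, loss)`` with ``omega_full`` dense over all
    columns of ``R`` (zeros off-support). Used for the final debiasing
    refit and by the unconstrained comparison pipelines.
    """
    R = np.asarray(R, dtype=float)
    z = np.asarray(z, dtype=float)
    cols = np.arange(R.shape[1]) if support is None else np.asarray(list(support), dtype=int)
    Rs = R[:, cols]
    x0 = np.zeros(len(cols) + 1)
    if w0 is not None:
        x0[:-1] = np.asarray(w0, dtype=float)[cols]
        x0[-1] = nu0

    def fun(x):
        loss, gw, gnu = _loss_and_grad(x[:-1], x[-1], Rs, z)
        return loss, np.append(gw, gnu)

    res = minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": GRAD_TOL, "ftol": 1e-14},
    )
    omega = np.zeros(R.shape[1])
    omega[cols] = res.x[:-1]
    return omega, float(res.x[-1]), float(res.fun)


@dataclass
class SparseClassifier:
    """A fitted sparse logistic classifier.

    ``omega`` has at most ``N_K`` nonzeros; ``pattern`` lists the metric
    names of the nonzero entries in column order.
    """

    omega: np.ndarray
    nu: float
    N_K: int
    pattern: tuple[str, ...]
    training_loss: float
    metric_names: list[str] = field(default_factory=list)

    def decision_scores(self, R: np.ndarray) -> np.ndarray:
        return np.asarray(R, dtype=float) @ self.omega + self.nu

    def predict(self, R: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(R)
        return np.where(scores > 0, 1, -1)

    def to_dict(self) -> dict:
        nz = np.flatnonzero(self.omega)
        return {
            "nu": self.nu,
            "N_K": self.N_K,
            "n_features": int(self.omega.size),
            "weights": {int(j): float(self.omega[j]) for j in nz},
            "pattern": list(self.pattern),
            "training_loss": self.training_loss,
            "metric_names": list(self.metric_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SparseClassifier":
        omega = np.zeros(int(d["n_features"]))
        for j, v in d["weights"].items():
            omega[int(j)] = v
        return cls(
            omega=omega,
            nu=float(d["nu"]),
            N_K=int(d["N_K"]),
            pattern=tuple(d["pattern"]),
            training_loss=float(d["training_loss"]),
            metric_names=list(d.get("metric_names", [])),
        )


def predict(classifier: SparseClassifier, R) -> tuple[np.ndarray, np.ndarray]:
    """Scores ``omega^T r + nu`` and hard labels (+1 iff score > 0; ties -> -1)."""
    values = R.values if hasattr(R, "values") else np.asarray(R, dtype=float)
    scores = classifier.decision_scores(values)
    return scores, np.where(scores > 0, 1, -1)


def _delta(new, old) -> float:
    """Relative max-norm change ``||a'-a''||_max / max(||a'||_max, 1)``."""
    new = np.atleast_1d(np.asarray(new, dtype=float))
    old = np.atleast_1d(np.asarray(old, dtype=float))
    return float(np.max(np.abs(new - old)) / max(np.max(np.abs(new)), 1.0))


def _refine_support_logistic(
    R: np.ndarray,
    z: np.ndarray,
    support: np.ndarray,
    n_candidates: int = 8,
    n_drops: int = 3,
    max_rounds: int = 10,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Greedy support splicing for the l0 logistic problem.

    Starting from a candidate support, repeatedly try exchanging one of
    the weakest selected features for one of the largest-|gradient|
    excluded features, keeping a swap only when the refit loss strictly
    decreases. This local search corrects the occasional suboptimal
    support that the penalty-decomposition path locks onto.
    """
    support = np.sort(np.asarray(support, dtype=int))
    omega, nu, best = fit_logistic(R, z, support=support)
    for _ in range(max_rounds):
        margins = z * (R @ omega + nu)
        s = 1.0 / (1.0 + np.exp(np.clip(margins, -500, 500)))
        grad = R.T @ (-s * z)
        off = np.setdiff1d(np.arange(R.shape[1]), support)
        if off.size == 0:
            break
        cand = off[np.argsort(-np.abs(grad[off]), kind="stable")[:n_candidates]]
        weak = support[np.argsort(np.abs(omega[support]), kind="stable")[:n_drops]]
        improved = False
        best_trial = None
        for i in weak:
            for c in cand:
                trial = np.sort(np.append(support[support != i], c))
                _, _, loss = fit_logistic(R, z, support=trial, max_iter=200)
                if loss < best - 1e-9 * (1.0 + abs(best)) and (
                    best_trial is None or loss < best_trial[1]
                ):
                    best_trial = (trial, loss)
        if best_trial is not None:
            support = best_trial[0]
            omega, nu, best = fit_logistic(R, z, support=support)
            improved = True
        if not improved:
            break
    return support, omega, nu, best


def fit_sparse_logistic(
    R: np.ndarray,
    z: np.ndarray,
    N_K: int,
    schedule: RhoSchedule = RhoSchedule(),
    metric_names: Optional[Sequence[str]] = None,
    debias: bool = True,
    refine: bool = True,
) -> SparseClassifier:
    """Fit the l0-constrained logistic classifier by penalty decomposition.

    Starting from ``omega = psi = 0, nu = 0``, alternates at each
    ``rho``:

    1. ``(nu, psi) <- argmin  loss(psi, nu) + rho ||omega - psi||^2``
       (smooth, convex; quasi-Newton),
    2. ``omega <- project_l0(psi, N_K)`` (closed form),

    until the relative change of every block falls below ``eps_b``;
    ``rho`` then grows geometrically until ``||omega - psi||_max <
    eps_p``. Raises ``ConvergenceError`` (carrying the trace) if the
    ``rho`` cap is reached first.
    """
    R = np.asarray(R, dtype=float)
    z = np.asarray(z, dtype=float)
    if len(np.unique(z)) < 2:
        raise ValueError("training data must contain both classes")
    n_features = R.shape[1]
    if metric_names is None:
        metric_names = [f"m{j}" for j in range(n_features)]
    metric_names = list(metric_names)

    psi = np.zeros(n_features)
    omega = np.zeros(n_features)
    nu = 0.0
    rho = schedule.initial_rho(R.shape[0])
    rho_trace, objective_trace = [], []

    def penalized(psi_, nu_, omega_, rho_):
        margins = z * (R @ psi_ + nu_)
        return float(theta(margins).sum() + rho_ * np.sum((omega_ - psi_) ** 2))

    while True:
        rho_trace.append(rho)
        for _ in range(schedule.max_inner):
            x0 = np.append(psi, nu)

            def fun(x, _omega=omega, _rho=rho):
                loss, gw, gnu = _loss_and_grad(x[:-1], x[-1], R, z)
                pen = _rho * np.sum((_omega - x[:-1]) ** 2)
                gpen = -2.0 * _rho * (_omega - x[:-1])
                return loss + pen, np.append(gw + gpen, gnu)

            res = minimize(
                fun, x0, jac=True, method="L-BFGS-B",
                options={"maxiter": SOLVER_MAX_ITER, "gtol": GRAD_TOL, "ftol": 1e-14},
            )
            psi_new, nu_new = res.x[:-1], float(res.x[-1])
            objective_trace.append((rho, penalized(psi_new, nu_new, omega, rho)))
            omega_new = project_l0(psi_new, N_K)
            objective_trace.append((rho, penalized(psi_new, nu_new, omega_new, rho)))
            changes = max(
                _delta(psi_new, psi), _delta(nu_new, nu), _delta(omega_new, omega)
            )
            psi, nu, omega = psi_new, nu_new, omega_new
            if changes < schedule.eps_b:
                break
        if np.max(np.abs(omega - psi)) < schedule.eps_p:
            break
        if rho >= schedule.cap:
            raise ConvergenceError(
                f"penalty cap rho={rho:g} reached with ||omega-psi||_max="
                f"{np.max(np.abs(omega - psi)):.3g} >= eps_p={schedule.eps_p:g}",
                last_state={
                    "omega": omega, "psi": psi, "nu": nu,
                    "rho_trace": rho_trace, "objective_trace": objective_trace,
                },
            )
        rho = min(rho * schedule.factor, schedule.cap)

    support = np.flatnonzero(omega)
    if debias and support.size:
        if refine:
            support, omega, nu, loss = _refine_support_logistic(R, z, support)
        else:
            omega, nu, loss = fit_logistic(R, z, support=support, w0=omega, nu0=nu)
    else:
        loss = logistic_loss(omega, nu, R, z)
    pattern = tuple(metric_names[j] for j in np.flatnonzero(omega))
    clf = SparseClassifier(
        omega=omega, nu=nu, N_K=N_K, pattern=pattern,
        training_loss=loss, metric_names=metric_names,
    )
    clf.rho_trace = rho_trace
    clf.objective_trace = objective_trace
    return clf
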