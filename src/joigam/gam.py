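"""Confound regression on controls and residualization of all subjects.

Each imaging metric ``i`` is regressed on the confound design
``d = [1, age, age^2, ses]`` using only the control cohort, giving one
coefficient row ``alpha_i`` of the matrix ``Phi``. The fit is either
ordinary least squares (uniform noise variance across subjects) or a
robust bisquare fit (Tukey biweight, iteratively reweighted least
squares), which interprets the inverse per-subject noise variance as a
sample weight and downweights outliers. Residual ("desensitized")
scores ``r_s = i_s - Phi d_s^T`` are then computed for *every* subject,
cases included, using the control-derived ``Phi``.

Metrics are z-scored against the fitting controls before regression
(scale-free residuals and thresholds); the scaler is stored in the fit
so new tables are transformed identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm

from .cohort import CohortTable
from .errors import CohortValidationError

#: Tukey biweight tuning constant (95% Gaussian efficiency) used by the
#: bisquare branch, with scale re-estimated each IRLS iteration as
#: MAD/0.6745.
BISQUARE_C = 4.685
IRLS_MAX_ITER = 50
IRLS_TOL = 1e-8


@dataclass(frozen=True)
class Scaler:
    """Per-metric mean/SD transform fitted on training-fold controls."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Scaler":
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)  # constant metrics pass through centered
        return cls(mean=mean, sd=sd)

    @classmethod
    def identity(cls, n_features: int) -> "Scaler":
        return cls(mean=np.zeros(n_features), sd=np.ones(n_features))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


@dataclass
class GamFit:
    """Control-fitted confound model for a metric panel.

    ``Phi`` has one row per metric and one column per design term
    ``[1, age, age^2(, ses)]``. ``control_weights`` holds the final IRLS
    weight of each fitting control for each metric (all ones for OLS);
    weighting is per metric-subject pair because the regression is
    separable per metric and bisquare weights are defined per response.
    """

    Phi: np.ndarray
    method: str
    control_weights: np.ndarray
    scaler: Scaler
    metric_names: list[str]
    use_ses: bool

    def predict_confound(self, table: CohortTable) -> np.ndarray:
        """Predicted confound contribution ``Phi d_s^T`` per subject (standardized units)."""
        if table.use_ses != self.use_ses:
            raise CohortValidationError("table SES availability differs from the fit")
        if list(table.metric_names) != list(self.metric_names):
            raise CohortValidationError("table metric panel differs from the fit")
        return table.design_matrix() @ self.Phi.T

    def to_json(self, path) -> None:
        payload = {
            "method": self.method,
            "use_ses": self.use_ses,
            "metric_names": list(self.metric_names),
            "Phi": self.Phi.tolist(),
            "scaler_mean": self.scaler.mean.tolist(),
            "scaler_sd": self.scaler.sd.tolist(),
            "control_weights": self.control_weights.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GamFit":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            Phi=np.asarray(payload["Phi"], dtype=float),
            method=payload["method"],
            control_weights=np.asarray(payload["control_weights"], dtype=float),
            scaler=Scaler(
                mean=np.asarray(payload["scaler_mean"], dtype=float),
                sd=np.asarray(payload["scaler_sd"], dtype=float),
            ),
            metric_names=list(payload["metric_names"]),
            use_ses=bool(payload["use_ses"]),
        )


@dataclass
class ResidualTable:
    """Residual scores aligned with a source table (subjects x metrics)."""

    values: np.ndarray
    labels: np.ndarray
    metric_names: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]


def noise_scaler(controls: CohortTable) -> Scaler:
    """Noise-referenced standardizer fitted on controls.

    Centers each metric at its control mean and scales by the standard
    deviation of the control residuals about the least-squares confound
    fit — i.e. by the noise scale, not the total variance. On this
    scale a group effect of one noise-SD has unit size for every metric
    regardless of how much confound-driven variance the metric carries,
    which keeps coefficient penalties and convergence thresholds
    comparable across metrics.
    """
    D = controls.design_matrix()
    Phi_raw = ols_phi(D, controls.metrics)
    resid = controls.metrics - D @ Phi_raw.T
    sd = resid.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return Scaler(mean=controls.metrics.mean(axis=0), sd=sd)


def ols_phi(D: np.ndarray, I: np.ndarray) -> np.ndarray:
    """Closed-form least-squares coefficients, one row of Phi per metric.

    Solves the normal equations ``(D^T D) Phi^T = D^T I`` for all metrics
    at once. Raises on a rank-deficient design.
    """
    gram = D.T @ D
    if np.linalg.matrix_rank(gram) < D.shape[1]:
        raise CohortValidationError("confound design matrix is rank deficient")
    return np.linalg.solve(gram, D.T @ I).T


def fit_gam(
    controls: CohortTable,
    method: str = "ols",
    scaler: Optional[Scaler] = None,
    standardize: bool = True,
) -> GamFit:
    """Fit the confound model on a control cohort.

    Parameters
    ----------
    controls
        The fitting subjects; must be controls only. (A table containing
        cases is rejected so the "parameterized on the control group"
        contract cannot be violated silently.)
    method
        ``"ols"`` for the least-squares solution (uniform weights) or
        ``"bisquare"`` for the robust IRLS fit.
    scaler
        Optional pre-fitted standardizer; by default one is fitted on
        ``controls``. Pass ``standardize=False`` to work in raw units.
    """
    if np.any(controls.cases_mask):
        raise CohortValidationError("fit_gam expects a controls-only table")
    D = controls.design_matrix()
    if controls.n <= D.shape[1]:
        raise CohortValidationError(
            f"need more than {D.shape[1]} controls to fit the confound model"
        )
    if scaler is None:
        scaler = noise_scaler(controls) if standardize else Scaler.identity(
            controls.n_features
        )
    I = scaler.transform(controls.metrics)

    if method == "ols":
        Phi = ols_phi(D, I)
        weights = np.ones((controls.n, controls.n_features))
    elif method == "bisquare":
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise CohortValidationError("confound design matrix is rank deficient")
        Phi = np.empty((controls.n_features, D.shape[1]))
        weights = np.empty((controls.n, controls.n_features))
        norm = sm.robust.norms.TukeyBiweight(c=BISQUARE_C)
        for j in range(controls.n_features):
            res = sm.RLM(I[:, j], D, M=norm).fit(
                maxiter=IRLS_MAX_ITER, tol=IRLS_TOL, scale_est="mad", conv="coefs"
            )
            Phi[j] = res.params
            weights[:, j] = res.weights
    else:
        raise ValueError(f"unknown method {method!r}; expected 'ols' or 'bisquare'")

    return GamFit(
        Phi=Phi,
        method=method,
        control_weights=weights,
        scaler=scaler,
        metric_names=list(controls.metric_names),
        use_ses=controls.use_ses,
    )


def residualize(fit: GamFit, table: CohortTable) -> ResidualTable:
    """Residual scores ``r_s = i_s - Phi d_s^T`` for every subject.

    The control-derived ``Phi`` (and control-derived scaler) is applied
    to cases and controls alike, so case deviations from the control
    norm survive in the residuals.
    """
    pred = fit.predict_confound(table)  # validates dimensions first
    R = fit.scaler.transform(table.metrics) - pred
    return ResidualTable(values=R, labels=table.labels.copy(), metric_names=list(table.metric_names))
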