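"""Synthetic cohorts with the statistical structure the models assume.

Two generators are provided, both returning standard ``CohortTable``
objects plus an exact ground-truth record so downstream tests can score
recovery:

* ``make_fig1_cohort`` — the minimal didactic setting: one metric that
  is a linear function of age plus noise, with a constant offset added
  to the case group. Both groups share the same age range, so age is a
  nuisance spreading each group without separating them.
* ``make_ncanda_like`` — a 671-control / 34-case cohort with 32
  structural and 112 diffusion metrics. Every metric follows the
  confound model (intercept, linear + quadratic age, linear SES) with
  coefficients drawn once per metric and stored; a small *true
  pattern* of metrics additionally carries a group effect of
  ``delta`` noise-SD units. Case ages and SES are shifted upward
  relative to controls, reproducing the confounded case-control
  design (cohorts matched on sex/ethnicity/scanner/supratentorial
  volume but not on age or SES).

Noise is i.i.d. Gaussian per metric; an optional contamination switch
replaces a fraction of control observations with 5x-SD outliers to
exercise the robust regression branch. All draws go through a single
``numpy`` generator seeded explicitly, so identical (spec, seed) pairs
give bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .cohort import MODALITY_DTI, MODALITY_STR, CohortTable
from .errors import JoigamError

# Categorical mixes shared by both cohorts (matched factors).
SEX_LEVELS = ("M", "F")
SEX_PROBS = (0.5, 0.5)
SCANNER_LEVELS = ("GE", "Siemens")
SCANNER_PROBS = (0.667, 0.333)
ETHNICITY_LEVELS = ("Caucasian", "African-American", "Asian", "Pacific-Islander",
                    "Native-American", "Mixed")
ETHNICITY_PROBS = (0.733, 0.130, 0.081, 0.006, 0.004, 0.046)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the confounded case-control generator.

    Defaults emulate the study cohort: 671 controls aged 12-21
    (uniform) and 34 cases aged about 19.5 +/- 1.7 (truncated normal,
    clipped to 14-21); SES in years of parental education around
    16.7 (controls) versus 18.0 (cases). Confound coefficients are
    drawn per metric from the stated ranges; the group effect ``delta``
    is expressed in noise-SD units and confined to ``pattern_size``
    metrics.
    """

    n_controls: int = 671
    n_cases: int = 34
    n_str: int = 32
    n_dti: int = 112
    control_age: tuple[float, float] = (12.0, 21.0)
    case_age_mean: float = 19.5
    case_age_sd: float = 1.7
    case_age_range: tuple[float, float] = (14.0, 21.0)
    control_ses_mean: float = 16.7
    control_ses_sd: float = 2.5
    case_ses_mean: float = 18.0
    case_ses_sd: float = 2.3
    stv_mean: float = 1248.0
    stv_sd: float = 127.0
    intercept_range: tuple[float, float] = (-1.0, 1.0)
    age_lin_range: tuple[float, float] = (-1.0, 1.0)
    age_quad_range: tuple[float, float] = (-0.02, 0.02)
    ses_lin_range: tuple[float, float] = (-0.1, 0.1)
    pattern_size: int = 4
    true_pattern: Optional[tuple[str, ...]] = None
    delta: float = 1.0
    noise_sd: float = 1.0
    outlier_frac: float = 0.0
    outlier_scale: float = 5.0


@dataclass(frozen=True)
class GeneratorTruth:
    """Resolved ground truth of one generated cohort."""

    spec: GeneratorSpec
    seed: int
    metric_names: tuple[str, ...]
    coefficients: np.ndarray          # (N_F, 4): intercept, age, age^2, ses
    true_pattern: tuple[str, ...]
    effect: dict                      # metric -> signed group effect (raw units)


def _draw_categoricals(rng: np.random.Generator, n: int) -> dict:
    return {
        "sex": rng.choice(SEX_LEVELS, size=n, p=SEX_PROBS).astype(object),
        "ethnicity": rng.choice(ETHNICITY_LEVELS, size=n, p=ETHNICITY_PROBS).astype(object),
        "scanner": rng.choice(SCANNER_LEVELS, size=n, p=SCANNER_PROBS).astype(object),
    }


def make_ncanda_like(
    spec: GeneratorSpec = GeneratorSpec(), seed: int = 0
) -> tuple[CohortTable, GeneratorTruth]:
    """Generate a confounded case-control cohort plus its ground truth."""
    if spec.noise_sd <= 0:
        raise JoigamError("noise SD must be positive")
    n_f = spec.n_str + spec.n_dti
    if spec.pattern_size > n_f:
        raise JoigamError("true pattern larger than the metric panel")
    rng = np.random.default_rng(seed)
    names = tuple(
        [f"str_{j:03d}" for j in range(spec.n_str)]
        + [f"dti_{j:03d}" for j in range(spec.n_dti)]
    )
    tags = [MODALITY_STR] * spec.n_str + [MODALITY_DTI] * spec.n_dti

    n = spec.n_controls + spec.n_cases
    labels = np.array([-1] * spec.n_controls + [1] * spec.n_cases)
    age = np.empty(n)
    age[: spec.n_controls] = rng.uniform(*spec.control_age, size=spec.n_controls)
    lo = (spec.case_age_range[0] - spec.case_age_mean) / spec.case_age_sd
    hi = (spec.case_age_range[1] - spec.case_age_mean) / spec.case_age_sd
    age[spec.n_controls:] = stats.truncnorm.rvs(
        lo, hi, loc=spec.case_age_mean, scale=spec.case_age_sd,
        size=spec.n_cases, random_state=rng,
    )
    ses = np.empty(n)
    ses[: spec.n_controls] = rng.normal(spec.control_ses_mean, spec.control_ses_sd,
                                        spec.n_controls)
    ses[spec.n_controls:] = rng.normal(spec.case_ses_mean, spec.case_ses_sd, spec.n_cases)
    stv = rng.normal(spec.stv_mean, spec.stv_sd, n)
    categoricals = _draw_categoricals(rng, n)

    coefs = np.column_stack([
        rng.uniform(*spec.intercept_range, n_f),
        rng.uniform(*spec.age_lin_range, n_f),
        rng.uniform(*spec.age_quad_range, n_f),
        rng.uniform(*spec.ses_lin_range, n_f),
    ])
    if spec.true_pattern is None:
        # split the pattern across modalities where possible
        n_str_pick = min(spec.pattern_size // 2, spec.n_str)
        n_dti_pick = min(spec.pattern_size - n_str_pick, spec.n_dti)
        n_str_pick = spec.pattern_size - n_dti_pick
        picks = np.concatenate([
            rng.choice(spec.n_str, size=n_str_pick, replace=False),
            spec.n_str + rng.choice(spec.n_dti, size=n_dti_pick, replace=False),
        ])
        true_pattern = tuple(names[j] for j in np.sort(picks))
    else:
        unknown = set(spec.true_pattern) - set(names)
        if unknown:
            raise JoigamError(f"true_pattern names not in panel: {sorted(unknown)}")
        true_pattern = tuple(spec.true_pattern)
    # Group effects point along each metric's age trend: with the case
    # cohort older, apparent raw-score group differences are inflated by
    # age, the adversarial geometry a confounded case-control design
    # produces (and the reason age must be modelled rather than ignored).
    signs = np.where(coefs[[names.index(m) for m in true_pattern], 1] >= 0, 1.0, -1.0)
    effect = {m: float(s * spec.delta * spec.noise_sd) for m, s in zip(true_pattern, signs)}

    D = np.column_stack([np.ones(n), age, age ** 2, ses])
    metrics = D @ coefs.T + rng.normal(0.0, spec.noise_sd, size=(n, n_f))
    for m, e in effect.items():
        metrics[labels == 1, names.index(m)] += e
    if spec.outlier_frac > 0:
        mask = rng.random(size=(n, n_f)) < spec.outlier_frac
        metrics[mask] += (
            rng.choice([-1.0, 1.0], size=int(mask.sum()))
            * spec.outlier_scale * spec.noise_sd
        )

    table = CohortTable(
        subject_ids=np.array([f"S{i:05d}" for i in range(n)], dtype=object),
        labels=labels,
        age=age,
        metrics=metrics,
        metric_names=list(names),
        modality_tags=tags,
        ses=ses,
        supratentorial_volume=stv,
        categoricals=categoricals,
    )
    truth = GeneratorTruth(
        spec=spec, seed=seed, metric_names=names, coefficients=coefs,
        true_pattern=true_pattern, effect=effect,
    )
    return table, truth


def make_fig1_cohort(
    seed: int = 0,
    n_per_group: int = 30,
    age_low: float = 17.0,
    age_high: float = 21.0,
    slope: float = 2.0,
    intercept: float = 1.0,
    group_offset: float = 5.0,
    noise_sd: float = 1.0,
) -> CohortTable:
    """Single-metric didactic cohort: linear age trend plus a group offset.

    Both groups draw ages uniformly from the same interval; the metric
    is ``intercept + slope*age + offset*[case] + N(0, noise_sd)``. With
    the default slope the age-driven spread (8 units over the age
    range) dwarfs the group offset, so a classifier on the raw metric
    cannot separate the groups while one on properly de-aged residuals
    can.
    """
    if n_per_group < 2:
        raise JoigamError("need at least 2 subjects per group")
    if noise_sd < 0:
        raise JoigamError("noise SD must be nonnegative")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    labels = np.array([-1] * n_per_group + [1] * n_per_group)
    age = rng.uniform(age_low, age_high, size=n)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    metric = intercept + slope * age + group_offset * (labels == 1) + noise
    return CohortTable(
        subject_ids=np.array([f"S{i:03d}" for i in range(n)], dtype=object),
        labels=labels,
        age=age,
        metrics=metric[:, None],
        metric_names=["metric"],
        modality_tags=[MODALITY_STR],
        ses=None,
        supratentorial_volume=None,
        categoricals={},
    )


@dataclass(frozen=True)
class RecoveryReport:
    jaccard: float
    hits: int
    false_picks: int
    missed: int


def recovery_report(fit_pattern, truth: GeneratorTruth) -> RecoveryReport:
    """Jaccard overlap between a selected pattern and the generating truth."""
    sel = set(fit_pattern)
    true = set(truth.true_pattern)
    inter = len(sel & true)
    union = len(sel | true)
    return RecoveryReport(
        jaccard=inter / union if union else 1.0,
        hits=inter,
        false_picks=len(sel - true),
        missed=len(true - sel),
    )
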