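"""Two-fold cross-validation and the accuracy / indifference metrics.

The study design is heavily unbalanced (few cases, many controls), so
plain accuracy is uninformative. The harness therefore reports:

* sensitivity / specificity and their mean, the *normalized accuracy*
  (balanced accuracy), which compensates for cohort-size imbalance;
* rank-based AUC;
* a two-tailed Fisher exact p-value for the predicted-vs-true 2x2
  table (the chance a random cohort assignment reproduces the output);
* *matched accuracy*: normalized accuracy recomputed on a 1:1
  demographically matched equal-size subset of the test data;
* confound-indifference tests: a Fisher exact test of the trained
  classifier's outputs on controls against an older/younger median-age
  split (and the same for SES); an implementation passes at p > 0.01.

Cross-validation pools the test-fold predictions of both folds and
computes each metric once on the pooled set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohort import CASE, CONTROL, CohortTable
from .errors import CohortValidationError
from .joint import FittedPipeline, RhoSchedule, run_pipeline

N_SPLIT_CANDIDATES = 200
AGE_TEST_ALPHA = 0.01
SIGNIFICANCE_ALPHA = 0.002


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------


def _smd(values, fold_a: np.ndarray, fold_b: np.ndarray) -> float:
    """Absolute standardized mean difference of one variable between folds."""
    va, vb = values[fold_a], values[fold_b]
    if va.dtype == object or not np.issubdtype(va.dtype, np.number):
        worst = 0.0
        for level in np.unique(values):
            pa, pb = np.mean(va == level), np.mean(vb == level)
            p = np.mean(values == level)
            denom = np.sqrt(p * (1.0 - p)) if 0.0 < p < 1.0 else 1.0
            worst = max(worst, abs(pa - pb) / denom)
        return worst
    sd = values.std(ddof=0)
    return abs(va.mean() - vb.mean()) / sd if sd > 0 else 0.0


def two_fold_split(
    table: CohortTable,
    seed: int,
    balance_vars: Optional[Sequence[str]] = None,
) -> tuple[CohortTable, CohortTable]:
    """Stratified halving that balances nuisance demographics.

    Cases and controls are each split ~50/50. Among
    ``N_SPLIT_CANDIDATES`` seeded random candidate splits, the one
    minimizing the worst absolute standardized mean difference of the
    balance variables between the folds is returned (deterministic for
    a given seed). By default the balance variables are every
    categorical factor plus supratentorial volume — the demographics
    *other than* the modelled confounds age and SES.
    """
    cases = np.flatnonzero(table.cases_mask)
    controls = np.flatnonzero(table.controls_mask)
    if len(cases) < 2 or len(controls) < 2:
        raise CohortValidationError("need at least two cases and two controls to split")

    if balance_vars is None:
        balance_vars = list(table.categoricals.keys())
        if table.supratentorial_volume is not None:
            balance_vars = balance_vars + ["stv"]

    def var_values(name):
        if name == "age":
            return table.age
        if name == "ses":
            return table.ses
        if name == "stv":
            return table.supratentorial_volume
        return table.categoricals[name]

    rng = np.random.default_rng(seed)
    best, best_score = None, np.inf
    for _ in range(N_SPLIT_CANDIDATES):
        perm_cases = rng.permutation(cases)
        perm_controls = rng.permutation(controls)
        a = np.sort(np.concatenate([perm_cases[: len(cases) // 2],
                                    perm_controls[: len(controls) // 2]]))
        b = np.sort(np.setdiff1d(np.arange(table.n), a))
        score = 0.0
        for name in balance_vars:
            vals = var_values(name)
            if vals is None:
                continue
            score = max(score, _smd(np.asarray(vals), a, b))
        if score < best_score:
            best, best_score = (a, b), score
    a, b = best
    return table.subset(a), table.subset(b)


# ---------------------------------------------------------------------------
# accuracy metrics
# ---------------------------------------------------------------------------


def confusion_counts(pred: np.ndarray, true: np.ndarray) -> dict:
    pred, true = np.asarray(pred), np.asarray(true)
    return {
        "TP": int(np.sum((pred == CASE) & (true == CASE))),
        "FN": int(np.sum((pred == CONTROL) & (true == CASE))),
        "TN": int(np.sum((pred == CONTROL) & (true == CONTROL))),
        "FP": int(np.sum((pred == CASE) & (true == CONTROL))),
    }


def confusion_metrics(pred: np.ndarray, true: np.ndarray) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, normalized accuracy %).

    Normalized accuracy is the mean of sensitivity over cases and
    specificity over controls, so chance is 50% regardless of the
    cohort-size imbalance.
    """
    c = confusion_counts(pred, true)
    if c["TP"] + c["FN"] == 0 or c["TN"] + c["FP"] == 0:
        raise ValueError("both classes must be present in the true labels")
    sens = 100.0 * c["TP"] / (c["TP"] + c["FN"])
    spec = 100.0 * c["TN"] / (c["TN"] + c["FP"])
    return sens, spec, (sens + spec) / 2.0


def auc(scores: np.ndarray, true: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC in [0, 1]; ties count 0.5."""
    scores, true = np.asarray(scores, dtype=float), np.asarray(true)
    if len(np.unique(true)) < 2:
        raise ValueError("both classes must be present")
    if np.all(scores == scores[0]):
        return 0.5
    return float(roc_auc_score(true == CASE, scores))


def fisher_exact_two_tailed(table2x2) -> float:
    """Two-tailed Fisher exact p (sum of hypergeometric tables at most as probable)."""
    t = np.asarray(table2x2, dtype=int)
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def accuracy_significance(pred: np.ndarray, true: np.ndarray) -> float:
    """Fisher p for the predicted-label x true-label 2x2 table."""
    c = confusion_counts(pred, true)
    return fisher_exact_two_tailed([[c["TP"], c["FP"]], [c["FN"], c["TN"]]])


# ---------------------------------------------------------------------------
# DeLong test for two correlated AUCs
# ---------------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_test(scores_a, scores_b, true) -> float:
    """Two-sided DeLong test of equal AUC for two score vectors on the
    same subjects.

    Uses the placement-value (structural component) variance estimator;
    returns p = 1 when the variance of the AUC difference is zero
    (e.g. identical scores).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    true = np.asarray(true)
    if scores_a.shape != scores_b.shape or scores_a.shape != true.shape:
        raise ValueError("score vectors and labels must be aligned")
    pos, neg = true == CASE, true == CONTROL
    m, n = int(pos.sum()), int(neg.sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")

    aucs, v01s, v10s = [], [], []
    for s in (scores_a, scores_b):
        rank_all = _midrank(s)
        rank_pos = _midrank(s[pos])
        rank_neg = _midrank(s[neg])
        a = (rank_all[pos].sum() - m * (m + 1) / 2.0) / (m * n)
        v01 = (rank_all[pos] - rank_pos) / n          # per-case placements
        v10 = 1.0 - (rank_all[neg] - rank_neg) / m    # per-control placements
        aucs.append(a)
        v01s.append(v01)
        v10s.append(v10)

    s01 = np.cov(np.vstack(v01s)) if m > 1 else np.zeros((2, 2))
    s10 = np.cov(np.vstack(v10s)) if n > 1 else np.zeros((2, 2))
    cov = s01 / m + s10 / n
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 0:
        return 1.0
    zstat = (aucs[0] - aucs[1]) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(zstat)))


# ---------------------------------------------------------------------------
# matched subset and confound-indifference tests
# ---------------------------------------------------------------------------


def build_matched_subset(test_table: CohortTable, seed: int = 0) -> CohortTable:
    """1:1 greedy nearest-neighbour control match for every case.

    Exact match on sex and scanner where those factors exist, then
    minimum standardized Euclidean distance on (age, SES); each control
    is used at most once; distance ties break on subject id. When no
    exact-tier candidate remains for a case the categorical constraints
    are relaxed one at a time (with a warning).
    """
    cases = np.flatnonzero(test_table.cases_mask)
    controls = np.flatnonzero(test_table.controls_mask)
    if len(controls) < len(cases):
        raise CohortValidationError("fewer controls than cases; cannot 1:1 match")

    cont_vars = [test_table.age]
    if test_table.ses is not None:
        cont_vars.append(test_table.ses)
    X = np.column_stack(cont_vars)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = X / sd

    exact_keys = [k for k in ("sex", "scanner") if k in test_table.categoricals]
    used = set()
    chosen = []
    for ci in cases:
        for relax in range(len(exact_keys) + 1):
            keys = exact_keys[: len(exact_keys) - relax]
            pool = [
                j for j in controls
                if j not in used
                and all(test_table.categoricals[k][j] == test_table.categoricals[k][ci]
                        for k in keys)
            ]
            if pool:
                if relax:
                    warnings.warn(
                        f"no exact demographic match for case "
                        f"{test_table.subject_ids[ci]!r}; relaxed {exact_keys[len(exact_keys)-relax:]}"
                    )
                break
        if not pool:
            raise CohortValidationError("no eligible control remains for a case")
        d = np.linalg.norm(Xs[pool] - Xs[ci], axis=1)
        best = min(zip(d, [str(test_table.subject_ids[j]) for j in pool], pool))
        chosen.append(best[2])
        used.add(best[2])

    keep = np.sort(np.concatenate([cases, np.asarray(chosen, dtype=int)]))
    return test_table.subset(keep)


def matched_accuracy(fitted: FittedPipeline, test_table: CohortTable, seed: int = 0) -> float:
    """Normalized accuracy (%) on the matched equal-size test subset."""
    subset = build_matched_subset(test_table, seed)
    pred = fitted.predict(subset)
    return confusion_metrics(pred, subset.labels)[2]


def _indifference_test(pred: np.ndarray, values: np.ndarray) -> tuple[float, bool]:
    """Fisher test of predictions against an older/younger median split."""
    if len(np.unique(pred)) < 2:
        return 1.0, True
    median = np.median(values)
    upper = values > median  # ties at the median go to the lower group
    t = [
        [int(np.sum((pred == CASE) & upper)), int(np.sum((pred == CASE) & ~upper))],
        [int(np.sum((pred == CONTROL) & upper)), int(np.sum((pred == CONTROL) & ~upper))],
    ]
    p = fisher_exact_two_tailed(t)
    return p, p > AGE_TEST_ALPHA


def age_test(fitted: FittedPipeline, controls_table: CohortTable) -> tuple[float, bool]:
    """Indifference of the trained classifier's control outputs to age.

    Controls are split at their median age; a Fisher exact test on
    predicted label x age group must give p > 0.01 for the
    implementation to pass (the age effect is then absent or far weaker
    than the group effect).
    """
    if controls_table.n < 4:
        raise CohortValidationError("need at least 4 controls for the age-test")
    pred = fitted.predict(controls_table)
    return _indifference_test(pred, controls_table.age)


def ses_test(fitted: FittedPipeline, controls_table: CohortTable) -> tuple[float, bool]:
    """The age-test procedure applied to socioeconomic status."""
    if controls_table.ses is None:
        return 1.0, True
    pred = fitted.predict(controls_table)
    return _indifference_test(pred, controls_table.ses)


def matching_diagnostics(table: CohortTable) -> dict:
    """Per-variable cohort-comparability p-values.

    Continuous demographics (age, SES, supratentorial volume): pooled
    -variance two-sided t-tests. Categorical factors: Pearson
    chi-square without continuity correction. Single-level categoricals
    are skipped with a warning.
    """
    cases, controls = table.cases_mask, table.controls_mask
    out = {}
    cont = {"age": table.age}
    if table.ses is not None:
        cont["ses"] = table.ses
    if table.supratentorial_volume is not None:
        cont["stv"] = table.supratentorial_volume
    for name, vals in cont.items():
        out[name] = float(stats.ttest_ind(vals[cases], vals[controls], equal_var=True)[1])
    for name, vals in table.categoricals.items():
        levels = np.unique(vals)
        if len(levels) < 2:
            warnings.warn(f"categorical {name!r} has a single level; skipped")
            continue
        counts = np.array(
            [[np.sum(vals[controls] == lv), np.sum(vals[cases] == lv)] for lv in levels]
        )
        out[name] = float(stats.chi2_contingency(counts, correction=False)[1])
    return out


# ---------------------------------------------------------------------------
# report and CV harness
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Pooled two-fold evaluation of one implementation."""

    pipeline: str
    sensitivity: float
    specificity: float
    auc: float
    normalized_accuracy: float
    matched_accuracy: float
    fisher_p: float
    matched_fisher_p: float
    age_test_p: float
    age_test_pass: bool
    ses_test_p: float
    ses_test_pass: bool
    fold_confusions: list = field(default_factory=list)
    patterns: list = field(default_factory=list)
    delong_p: Optional[float] = None
    scores: Optional[np.ndarray] = None
    true_labels: Optional[np.ndarray] = None
    error: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "pipeline": self.pipeline,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "normalized_accuracy": self.normalized_accuracy,
            "matched_accuracy": self.matched_accuracy,
            "fisher_p": self.fisher_p,
            "matched_fisher_p": self.matched_fisher_p,
            "age_test_p": self.age_test_p,
            "age_test_pass": self.age_test_pass,
            "ses_test_p": self.ses_test_p,
            "ses_test_pass": self.ses_test_pass,
            "fold_confusions": self.fold_confusions,
            "patterns": [list(p) for p in self.patterns],
            "delong_p": self.delong_p,
            "error": self.error,
        }

    def to_text(self) -> str:
        rows = [
            f"pipeline             {self.pipeline}",
            f"sensitivity          {self.sensitivity:6.1f} %",
            f"specificity          {self.specificity:6.1f} %",
            f"AUC                  {self.auc:6.1f} %",
            f"normalized accuracy  {self.normalized_accuracy:6.1f} %  (Fisher p={self.fisher_p:.4g})",
            f"matched accuracy     {self.matched_accuracy:6.1f} %  (Fisher p={self.matched_fisher_p:.4g})",
            f"age-test             p={self.age_test_p:.4g}  ->  {'pass' if self.age_test_pass else 'FAIL'}",
            f"ses-test             p={self.ses_test_p:.4g}  ->  {'pass' if self.ses_test_pass else 'FAIL'}",
        ]
        return "\n".join(rows)


def evaluate_pipeline(
    table: CohortTable,
    pipeline: str,
    N_K: int,
    sigma: float = 1.0,
    seed: int = 0,
    schedule: RhoSchedule = RhoSchedule(),
    match_seed: int = 0,
) -> EvalReport:
    """Full two-fold cross-validated evaluation of one implementation.

    Each fold is used once for training and once for testing; test-set
    scores and predictions are pooled across folds before the metrics,
    Fisher test, matched-subset accuracy, and age/SES indifference
    tests are computed.
    """
    fold1, fold2 = two_fold_split(table, seed)
    scores, preds, truths = [], [], []
    matched_preds, matched_truths = [], []
    ages_c, ses_c, preds_c = [], [], []
    fold_confusions, patterns = [], []
    for train, test in ((fold1, fold2), (fold2, fold1)):
        fitted = run_pipeline(train, pipeline, N_K=N_K, sigma=sigma, schedule=schedule)
        s = fitted.decision_scores(test)
        p = np.where(s > 0, 1, -1)
        scores.append(s)
        preds.append(p)
        truths.append(test.labels)
        fold_confusions.append(confusion_counts(p, test.labels))
        patterns.append(fitted.pattern)
        msub = build_matched_subset(test, match_seed)
        matched_preds.append(fitted.predict(msub))
        matched_truths.append(msub.labels)
        ctrl = test.controls()
        preds_c.append(fitted.predict(ctrl))
        ages_c.append(ctrl.age)
        ses_c.append(ctrl.ses if ctrl.ses is not None else np.full(ctrl.n, np.nan))

    scores = np.concatenate(scores)
    preds = np.concatenate(preds)
    truths = np.concatenate(truths)
    sens, spec, nacc = confusion_metrics(preds, truths)
    matched_preds = np.concatenate(matched_preds)
    matched_truths = np.concatenate(matched_truths)
    _, _, macc = confusion_metrics(matched_preds, matched_truths)
    preds_c = np.concatenate(preds_c)
    ages_c = np.concatenate(ages_c)
    ses_c = np.concatenate(ses_c)
    age_p, age_pass = _indifference_test(preds_c, ages_c)
    if np.any(np.isnan(ses_c)):
        ses_p, ses_pass = 1.0, True
    else:
        ses_p, ses_pass = _indifference_test(preds_c, ses_c)
    return EvalReport(
        pipeline=pipeline,
        sensitivity=sens,
        specificity=spec,
        auc=100.0 * auc(scores, truths),
        normalized_accuracy=nacc,
        matched_accuracy=macc,
        fisher_p=accuracy_significance(preds, truths),
        matched_fisher_p=accuracy_significance(matched_preds, matched_truths),
        age_test_p=age_p,
        age_test_pass=age_pass,
        ses_test_p=ses_p,
        ses_test_pass=ses_pass,
        fold_confusions=fold_confusions,
        patterns=patterns,
        scores=scores,
        true_labels=truths,
    )
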