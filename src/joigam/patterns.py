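"""Pattern-frequency analysis across parameter-exploration runs.

Training an implementation involves a grid of hyperparameters (the
sparsity budget ``N_K`` and noise scale ``sigma``) crossed with the
training folds. Each run yields a *pattern* — the metric set with
nonzero classifier weight. Tabulating how often each unique pattern
recurs across runs measures selection stability; patterns selected in
more than half of the *suitable* runs (those whose ``N_K`` is at least
the pattern's size, since a k-metric pattern cannot appear when
``N_K < k``) are called *dominant*.

Dominant patterns are then re-evaluated with a plain unconstrained
logistic classifier on least-squares confound residuals restricted to
the pattern, and per-metric group-difference t-tests localize which
members differ between cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import CohortTable
from .errors import JoigamError
from .evaluation import (
    EvalReport,
    _indifference_test,
    accuracy_significance,
    auc,
    build_matched_subset,
    confusion_counts,
    confusion_metrics,
    two_fold_split,
)
from .gam import fit_gam, residualize
from .joint import NK_GRID, SIGMA_GRID, RhoSchedule, run_pipeline
from .sparse import fit_logistic


@dataclass(frozen=True)
class PatternRun:
    """One training run: hyperparameters, selected pattern, training accuracy."""

    pattern: Optional[tuple[str, ...]]
    N_K: int
    sigma: float
    pipeline: str
    fold: int
    training_normalized_accuracy: float = float("nan")
    error: Optional[str] = None


@dataclass
class PatternFrequencyRow:
    pattern: tuple[str, ...]
    count: int
    frequency: float
    suitable_frequency: float
    dominant: bool = False


@dataclass
class PatternFrequencyTable:
    """Unique patterns with frequencies, sorted descending."""

    rows: list[PatternFrequencyRow]
    n_runs: int

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)


def run_parameter_exploration(
    table: CohortTable,
    pipeline: str,
    nk_grid: Sequence[int] = NK_GRID,
    sigma_grid: Sequence[float] = SIGMA_GRID,
    seed: int = 0,
    schedule: RhoSchedule = RhoSchedule(),
) -> list[PatternRun]:
    """One training run per (fold x N_K x sigma) grid cell.

    Individual run failures are recorded in the run list (with the
    error message) rather than aborting the exploration. Deterministic
    given the seed, which fixes the fold split.
    """
    if not nk_grid or not sigma_grid:
        raise JoigamError("hyperparameter grids must be non-empty")
    folds = two_fold_split(table, seed)
    runs = []
    for fold_idx, train in enumerate(folds):
        for N_K in nk_grid:
            for sigma in sigma_grid:
                try:
                    fitted = run_pipeline(
                        train, pipeline, N_K=N_K, sigma=sigma, schedule=schedule
                    )
                    pred = fitted.predict(train)
                    nacc = confusion_metrics(pred, train.labels)[2]
                    runs.append(
                        PatternRun(
                            pattern=fitted.pattern,
                            N_K=N_K,
                            sigma=sigma,
                            pipeline=pipeline,
                            fold=fold_idx,
                            training_normalized_accuracy=nacc,
                        )
                    )
                except Exception as exc:  # recorded, not fatal
                    runs.append(
                        PatternRun(
                            pattern=None, N_K=N_K, sigma=sigma,
                            pipeline=pipeline, fold=fold_idx, error=str(exc),
                        )
                    )
    return runs


def pattern_frequencies(runs: Sequence[PatternRun]) -> PatternFrequencyTable:
    """Collapse runs to unique patterns with normalized frequencies.

    Metric sets are compared order-insensitively. ``frequency`` is
    count over all successful runs; ``suitable_frequency`` divides by
    the runs whose ``N_K`` admits the pattern's size. Sorted by
    descending frequency, ties by first appearance.
    """
    ok = [r for r in runs if r.pattern is not None]
    if not ok:
        raise JoigamError("no successful runs to tabulate")
    order, counts, first_seen = {}, {}, {}
    for i, r in enumerate(ok):
        key = frozenset(r.pattern)
        counts[key] = counts.get(key, 0) + 1
        if key not in first_seen:
            first_seen[key] = i
            order[key] = tuple(sorted(r.pattern))
    n_runs = len(ok)
    rows = []
    for key, cnt in counts.items():
        size = len(key)
        suitable = sum(1 for r in ok if r.N_K >= size)
        rows.append(
            PatternFrequencyRow(
                pattern=order[key],
                count=cnt,
                frequency=cnt / n_runs,
                suitable_frequency=cnt / suitable if suitable else 0.0,
            )
        )
    rows.sort(key=lambda row: (-row.frequency, first_seen[frozenset(row.pattern)]))
    return PatternFrequencyTable(rows=rows, n_runs=n_runs)


def dominant_patterns(
    freq_table: PatternFrequencyTable, threshold: float = 0.5
) -> list[PatternFrequencyRow]:
    """Patterns whose suitable-run frequency strictly exceeds ``threshold``.

    Because frequencies are measured against the runs that could have
    selected the pattern, nested patterns of different sizes can be
    dominant simultaneously.
    """
    out = []
    for row in freq_table.rows:
        row.dominant = row.suitable_frequency > threshold
        if row.dominant:
            out.append(row)
    return out


def evaluate_pattern(
    pattern: Sequence[str],
    table: CohortTable,
    seed: int = 0,
    match_seed: int = 0,
) -> EvalReport:
    """Two-fold evaluation of a fixed pattern.

    Per fold: fit the least-squares confound model on training
    controls, residualize, fit an *unconstrained* logistic classifier
    on the residual scores of the pattern's metrics, and predict the
    test fold. Test predictions are pooled before computing metrics.
    """
    pattern = list(pattern)
    if not pattern:
        raise JoigamError("pattern is empty")
    sub = table.select_metrics(pattern)
    fold1, fold2 = two_fold_split(sub, seed)
    scores, preds, truths = [], [], []
    matched_preds, matched_truths = [], []
    preds_c, ages_c = [], []
    fold_confusions = []
    for train, test in ((fold1, fold2), (fold2, fold1)):
        gamfit = fit_gam(train.controls(), method="ols")
        Rtr = residualize(gamfit, train)
        omega, nu, _ = fit_logistic(Rtr.values, train.labels)
        Rte = residualize(gamfit, test)
        s = Rte.values @ omega + nu
        p = np.where(s > 0, 1, -1)
        scores.append(s)
        preds.append(p)
        truths.append(test.labels)
        fold_confusions.append(confusion_counts(p, test.labels))
        msub = build_matched_subset(test, match_seed)
        sm_ = residualize(gamfit, msub).values @ omega + nu
        matched_preds.append(np.where(sm_ > 0, 1, -1))
        matched_truths.append(msub.labels)
        ctrl = test.controls()
        sc = residualize(gamfit, ctrl).values @ omega + nu
        preds_c.append(np.where(sc > 0, 1, -1))
        ages_c.append(ctrl.age)
    scores, preds, truths = map(np.concatenate, (scores, preds, truths))
    sens, spec, nacc = confusion_metrics(preds, truths)
    matched_preds = np.concatenate(matched_preds)
    matched_truths = np.concatenate(matched_truths)
    _, _, macc = confusion_metrics(matched_preds, matched_truths)
    age_p, age_pass = _indifference_test(np.concatenate(preds_c), np.concatenate(ages_c))
    return EvalReport(
        pipeline=f"pattern:{','.join(pattern)}",
        sensitivity=sens,
        specificity=spec,
        auc=100.0 * auc(scores, truths),
        normalized_accuracy=nacc,
        matched_accuracy=macc,
        fisher_p=accuracy_significance(preds, truths),
        matched_fisher_p=accuracy_significance(matched_preds, matched_truths),
        age_test_p=age_p,
        age_test_pass=age_pass,
        ses_test_p=1.0,
        ses_test_pass=True,
        fold_confusions=fold_confusions,
        patterns=[tuple(pattern)] * 2,
        scores=scores,
        true_labels=truths,
    )


def group_difference_tests(
    residuals: np.ndarray,
    labels: np.ndarray,
    metric_names: Sequence[str],
    metric_subset: Optional[Sequence[str]] = None,
) -> dict:
    """Per-metric two-sided pooled-variance t-tests on residual scores.

    Returns ``{metric: (p, direction)}`` where direction is +1 when the
    case mean exceeds the control mean, -1 when lower, 0 when equal.
    """
    residuals = np.asarray(residuals, dtype=float)
    labels = np.asarray(labels)
    names = list(metric_names)
    wanted = names if metric_subset is None else list(metric_subset)
    pos = {m: j for j, m in enumerate(names)}
    out = {}
    cases, controls = labels == 1, labels == -1
    for m in wanted:
        col = residuals[:, pos[m]]
        diff = col[cases].mean() - col[controls].mean()
        p = float(stats.ttest_ind(col[cases], col[controls], equal_var=True)[1])
        out[m] = (p, int(np.sign(diff)))
    return out


def mass_univariate_baseline(
    table: CohortTable,
    seed: int = 0,
    p_threshold: float = 0.01,
    match_seed: int = 0,
) -> tuple[EvalReport, list[list[str]]]:
    """Mass-univariate screen + unconstrained logistic comparison.

    Per fold: on training residuals, keep metrics whose case/control
    t-test gives p <= threshold; fit an unconstrained logistic
    classifier on the retained metrics; evaluate on the test fold.
    Returns the pooled report and the retained metric lists per fold.
    If a fold retains nothing, its predictions fall back to the
    majority class (chance performance) with a warning.
    """
    import warnings as _warnings

    fold1, fold2 = two_fold_split(table, seed)
    scores, preds, truths = [], [], []
    matched_preds, matched_truths = [], []
    retained_per_fold = []
    for train, test in ((fold1, fold2), (fold2, fold1)):
        gamfit = fit_gam(train.controls(), method="ols")
        Rtr = residualize(gamfit, train)
        tests = group_difference_tests(Rtr.values, train.labels, train.metric_names)
        retained = [m for m in train.metric_names if tests[m][0] <= p_threshold]
        retained_per_fold.append(retained)
        Rte = residualize(gamfit, test)
        if not retained:
            _warnings.warn("no metrics retained by the univariate screen; chance fallback")
            s = np.zeros(test.n)
        else:
            cols = [train.metric_names.index(m) for m in retained]
            omega, nu, _ = fit_logistic(Rtr.values[:, cols], train.labels)
            s = Rte.values[:, cols] @ omega + nu
        p = np.where(s > 0, 1, -1)
        scores.append(s)
        preds.append(p)
        truths.append(test.labels)
        msub = build_matched_subset(test, match_seed)
        Rm = residualize(gamfit, msub)
        if not retained:
            sm_ = np.zeros(msub.n)
        else:
            sm_ = Rm.values[:, cols] @ omega + nu
        matched_preds.append(np.where(sm_ > 0, 1, -1))
        matched_truths.append(msub.labels)
    scores, preds, truths = map(np.concatenate, (scores, preds, truths))
    sens, spec, nacc = confusion_metrics(preds, truths)
    matched_preds = np.concatenate(matched_preds)
    matched_truths = np.concatenate(matched_truths)
    _, _, macc = confusion_metrics(matched_preds, matched_truths)
    report = EvalReport(
        pipeline="mass_univariate",
        sensitivity=sens,
        specificity=spec,
        auc=100.0 * auc(scores, truths) if np.any(scores != scores[0]) else 50.0,
        normalized_accuracy=nacc,
        matched_accuracy=macc,
        fisher_p=accuracy_significance(preds, truths),
        matched_fisher_p=accuracy_significance(matched_preds, matched_truths),
        age_test_p=1.0,
        age_test_pass=True,
        ses_test_p=1.0,
        ses_test_pass=True,
        scores=scores,
        true_labels=truths,
    )
    return report, retained_per_fold


def plot_pattern_frequencies(freq_table: PatternFrequencyTable, path, threshold: float = 0.5):
    """Frequency-versus-rank diagnostic plot (dominance threshold dashed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ys = [row.suitable_frequency for row in freq_table.rows]
    ax.plot(range(1, len(ys) + 1), ys, marker="o", ms=3, lw=1)
    ax.axhline(threshold, color="red", ls="--", lw=1)
    ax.set_xlabel("pattern rank")
    ax.set_ylabel("normalized frequency (suitable runs)")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
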