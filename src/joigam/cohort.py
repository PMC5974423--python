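"""Subject tables for confounded case-control studies of imaging metrics.

A cohort is a table of subjects, each carrying a two-class label
(+1 = case, -1 = control), demographic covariates (age, socioeconomic
status, categorical factors such as sex and scanner, and optionally a
supratentorial volume), and a fixed-length vector of numeric imaging
metrics tagged by modality (``STR`` for macro-structural volume scores,
``DTI`` for micro-structural diffusion scores).

The confound design vector of a subject is ``[1, age, age^2, ses]``
(``[1, age, age^2]`` when SES is absent table-wide): an intercept, a
quadratic age model, and a linear SES model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CohortValidationError, SchemaError

MODALITY_STR = "STR"
MODALITY_DTI = "DTI"
MODALITIES = (MODALITY_STR, MODALITY_DTI)

CASE = 1
CONTROL = -1


@dataclass(frozen=True)
class CohortSchema:
    """Column-role mapping for reading/writing cohort CSV files.

    Column roles are explicit; no name heuristics are applied.
    """

    label_col: str
    age_col: str
    str_metric_cols: tuple[str, ...] = ()
    dti_metric_cols: tuple[str, ...] = ()
    subject_col: Optional[str] = None
    ses_col: Optional[str] = None
    stv_col: Optional[str] = None
    categorical_cols: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.str_metric_cols and not self.dti_metric_cols:
            raise SchemaError("schema defines no metric columns")
        metric_cols = tuple(self.str_metric_cols) + tuple(self.dti_metric_cols)
        if len(set(metric_cols)) != len(metric_cols):
            raise SchemaError("metric column names are not unique")
        object.__setattr__(self, "str_metric_cols", tuple(self.str_metric_cols))
        object.__setattr__(self, "dti_metric_cols", tuple(self.dti_metric_cols))
        object.__setattr__(self, "categorical_cols", tuple(self.categorical_cols))

    @classmethod
    def from_yaml(cls, path) -> "CohortSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise SchemaError(f"schema file {path} does not contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        try:
            return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        except TypeError as exc:
            raise SchemaError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        data = {
            "label_col": self.label_col,
            "age_col": self.age_col,
            "str_metric_cols": list(self.str_metric_cols),
            "dti_metric_cols": list(self.dti_metric_cols),
        }
        if self.subject_col:
            data["subject_col"] = self.subject_col
        if self.ses_col:
            data["ses_col"] = self.ses_col
        if self.stv_col:
            data["stv_col"] = self.stv_col
        if self.categorical_cols:
            data["categorical_cols"] = list(self.categorical_cols)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class SubjectRecord:
    """A single subject: label, demographics, and metric vector."""

    subject_id: str
    label: int
    age: float
    ses: Optional[float]
    categoricals: dict
    supratentorial_volume: Optional[float]
    metrics: np.ndarray


@dataclass
class CohortTable:
    """An ordered table of subjects sharing one metric panel.

    Metric values are stored as an ``(N, N_F)`` float array aligned with
    ``metric_names`` / ``modality_tags``. Labels are +1 (case) / -1
    (control). ``ses`` and ``supratentorial_volume`` are either present
    for every subject or ``None`` table-wide.
    """

    subject_ids: np.ndarray
    labels: np.ndarray
    age: np.ndarray
    metrics: np.ndarray
    metric_names: list[str]
    modality_tags: list[str]
    ses: Optional[np.ndarray] = None
    supratentorial_volume: Optional[np.ndarray] = None
    categoricals: dict = field(default_factory=dict)

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=int)
        self.age = np.asarray(self.age, dtype=float)
        self.metrics = np.asarray(self.metrics, dtype=float)
        self.metric_names = list(self.metric_names)
        self.modality_tags = list(self.modality_tags)
        if self.ses is not None:
            self.ses = np.asarray(self.ses, dtype=float)
        if self.supratentorial_volume is not None:
            self.supratentorial_volume = np.asarray(self.supratentorial_volume, dtype=float)
        self.categoricals = {k: np.asarray(v, dtype=object) for k, v in self.categoricals.items()}
        self._validate()

    def _validate(self):
        n = len(self.subject_ids)
        if self.metrics.ndim != 2 or self.metrics.shape[0] != n:
            raise CohortValidationError(
                f"metrics shape {self.metrics.shape} does not match {n} subjects"
            )
        if self.metrics.shape[1] != len(self.metric_names):
            raise CohortValidationError("metric_names length does not match metric columns")
        if len(self.modality_tags) != len(self.metric_names):
            raise CohortValidationError("modality_tags length does not match metric columns")
        if len(set(self.metric_names)) != len(self.metric_names):
            raise CohortValidationError("metric names are not unique")
        bad_tags = set(self.modality_tags) - set(MODALITIES)
        if bad_tags:
            raise CohortValidationError(f"unknown modality tags: {sorted(bad_tags)}")
        bad = set(np.unique(self.labels)) - {CASE, CONTROL}
        if bad:
            raise CohortValidationError(
                f"labels must be in {{-1, +1}}; found {sorted(bad)}"
            )
        if not np.any(self.labels == CONTROL):
            raise CohortValidationError("cohort contains no controls")
        if np.any(~np.isfinite(self.age)) or np.any(self.age <= 0):
            raise CohortValidationError("age must be positive and finite for every subject")
        if np.any(~np.isfinite(self.metrics)):
            i, j = np.argwhere(~np.isfinite(self.metrics))[0]
            raise CohortValidationError(
                f"non-finite metric value at subject {self.subject_ids[i]!r}, "
                f"column {self.metric_names[j]!r}"
            )
        if self.ses is not None and np.any(~np.isfinite(self.ses)):
            raise CohortValidationError("ses contains missing values; drop the column instead")
        for key, vals in self.categoricals.items():
            if len(vals) != n:
                raise CohortValidationError(f"categorical {key!r} length mismatch")

    # ---- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return self.metrics.shape[1]

    @property
    def use_ses(self) -> bool:
        return self.ses is not None

    @property
    def controls_mask(self) -> np.ndarray:
        return self.labels == CONTROL

    @property
    def cases_mask(self) -> np.ndarray:
        return self.labels == CASE

    def record(self, i: int) -> SubjectRecord:
        return SubjectRecord(
            subject_id=str(self.subject_ids[i]),
            label=int(self.labels[i]),
            age=float(self.age[i]),
            ses=float(self.ses[i]) if self.ses is not None else None,
            categoricals={k: v[i] for k, v in self.categoricals.items()},
            supratentorial_volume=(
                float(self.supratentorial_volume[i])
                if self.supratentorial_volume is not None
                else None
            ),
            metrics=self.metrics[i].copy(),
        )

    def design_matrix(self) -> np.ndarray:
        """Confound design, one row ``[1, age, age^2(, ses)]`` per subject."""
        cols = [np.ones(self.n), self.age, self.age ** 2]
        if self.ses is not None:
            cols.append(self.ses)
        return np.column_stack(cols)

    # ---- subsetting ------------------------------------------------------

    def subset(self, index) -> "CohortTable":
        """Row subset (boolean mask or integer index array), order preserved."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CohortTable(
            subject_ids=self.subject_ids[idx],
            labels=self.labels[idx],
            age=self.age[idx],
            metrics=self.metrics[idx],
            metric_names=list(self.metric_names),
            modality_tags=list(self.modality_tags),
            ses=self.ses[idx] if self.ses is not None else None,
            supratentorial_volume=(
                self.supratentorial_volume[idx]
                if self.supratentorial_volume is not None
                else None
            ),
            categoricals={k: v[idx] for k, v in self.categoricals.items()},
        )

    def controls(self) -> "CohortTable":
        return self.subset(self.controls_mask)

    def select_metrics(self, names: Sequence[str]) -> "CohortTable":
        """Column subset by metric name, in the order given."""
        pos = {m: j for j, m in enumerate(self.metric_names)}
        missing = [m for m in names if m not in pos]
        if missing:
            raise CohortValidationError(f"unknown metrics: {missing}")
        cols = [pos[m] for m in names]
        if not cols:
            raise CohortValidationError("metric selection is empty")
        return CohortTable(
            subject_ids=self.subject_ids,
            labels=self.labels,
            age=self.age,
            metrics=self.metrics[:, cols],
            metric_names=[self.metric_names[c] for c in cols],
            modality_tags=[self.modality_tags[c] for c in cols],
            ses=self.ses,
            supratentorial_volume=self.supratentorial_volume,
            categoricals=self.categoricals,
        )

    # ---- dataframe bridge ------------------------------------------------

    def to_dataframe(self, schema: CohortSchema) -> pd.DataFrame:
        data = {}
        if schema.subject_col:
            data[schema.subject_col] = self.subject_ids
        data[schema.label_col] = self.labels
        data[schema.age_col] = self.age
        if schema.ses_col and self.ses is not None:
            data[schema.ses_col] = self.ses
        if schema.stv_col and self.supratentorial_volume is not None:
            data[schema.stv_col] = self.supratentorial_volume
        for c in schema.categorical_cols:
            data[c] = self.categoricals[c]
        for j, name in enumerate(self.metric_names):
            data[name] = self.metrics[:, j]
        return pd.DataFrame(data)


def build_confound_vector(record: SubjectRecord, use_ses: bool) -> np.ndarray:
    """Design vector ``[1, age, age^2, ses]`` (or length 3 without SES)."""
    if use_ses:
        if record.ses is None:
            raise CohortValidationError(
                f"subject {record.subject_id!r} has no SES but use_ses was requested"
            )
        return np.array([1.0, record.age, record.age ** 2, record.ses])
    return np.array([1.0, record.age, record.age ** 2])


def select_modality(table: CohortTable, which: str) -> CohortTable:
    """Restrict metric columns to one modality (``STR``/``DTI``); ``ALL`` is identity."""
    if which == "ALL":
        return table
    if which not in MODALITIES:
        raise CohortValidationError(f"unknown modality {which!r}")
    names = [m for m, t in zip(table.metric_names, table.modality_tags) if t == which]
    if not names:
        raise CohortValidationError(f"no metrics tagged {which!r}")
    return table.select_metrics(names)


def load_cohort_table(path, schema: CohortSchema) -> CohortTable:
    """Read a cohort CSV under an explicit column-role schema.

    Raises ``SchemaError`` when a mapped column is absent, and
    ``CohortValidationError`` for bad labels, non-numeric metric cells,
    missing ages, or a cohort without controls. Row order is preserved.
    """
    df = pd.read_csv(path)
    required = [schema.label_col, schema.age_col]
    required += list(schema.str_metric_cols) + list(schema.dti_metric_cols)
    if schema.subject_col:
        required.append(schema.subject_col)
    if schema.ses_col:
        required.append(schema.ses_col)
    if schema.stv_col:
        required.append(schema.stv_col)
    required += list(schema.categorical_cols)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    labels_raw = df[schema.label_col]
    labels = pd.to_numeric(labels_raw, errors="coerce")
    bad = labels.isna() | ~labels.isin([CASE, CONTROL])
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise CohortValidationError(
            f"{path}: invalid label {labels_raw.iloc[i]!r} in row {i} "
            f"(expected -1 or +1)"
        )

    age = pd.to_numeric(df[schema.age_col], errors="coerce")
    if age.isna().any():
        i = int(np.flatnonzero(age.isna().to_numpy())[0])
        raise CohortValidationError(f"{path}: missing or non-numeric age in row {i}")

    metric_names = list(schema.str_metric_cols) + list(schema.dti_metric_cols)
    tags = [MODALITY_STR] * len(schema.str_metric_cols) + [MODALITY_DTI] * len(
        schema.dti_metric_cols
    )
    metric_block = np.empty((len(df), len(metric_names)))
    for j, col in enumerate(metric_names):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            i = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise CohortValidationError(
                f"{path}: non-numeric metric cell at row {i}, column {col!r}"
            )
        metric_block[:, j] = vals.to_numpy(dtype=float)

    ses = None
    if schema.ses_col:
        ses_vals = pd.to_numeric(df[schema.ses_col], errors="coerce")
        # Missing SES anywhere drops the column table-wide (length-3 design)
        # rather than imputing.
        if not ses_vals.isna().any():
            ses = ses_vals.to_numpy(dtype=float)

    stv = None
    if schema.stv_col:
        stv_vals = pd.to_numeric(df[schema.stv_col], errors="coerce")
        if not stv_vals.isna().any():
            stv = stv_vals.to_numpy(dtype=float)

    if schema.subject_col:
        subject_ids = df[schema.subject_col].astype(str).to_numpy(dtype=object)
    else:
        subject_ids = np.array([f"S{i:05d}" for i in range(len(df))], dtype=object)

    categoricals = {c: df[c].astype(str).to_numpy(dtype=object) for c in schema.categorical_cols}

    return CohortTable(
        subject_ids=subject_ids,
        labels=labels.to_numpy(dtype=int),
        age=age.to_numpy(dtype=float),
        metrics=metric_block,
        metric_names=metric_names,
        modality_tags=tags,
        ses=ses,
        supratentorial_volume=stv,
        categoricals=categoricals,
    )


def write_cohort_table(table: CohortTable, path, schema: CohortSchema) -> None:
    """Write the table as CSV in the column order implied by the schema."""
    table.to_dataframe(schema).to_csv(Path(path), index=False)


def default_schema(table: CohortTable) -> CohortSchema:
    """A canonical schema for tables produced by the synthetic generators."""
    return CohortSchema(
        subject_col="subject",
        label_col="label",
        age_col="age",
        ses_col="ses" if table.ses is not None else None,
        stv_col="stv" if table.supratentorial_volume is not None else None,
        categorical_cols=tuple(table.categoricals.keys()),
        str_metric_cols=tuple(
            m for m, t in zip(table.metric_names, table.modality_tags) if t == MODALITY_STR
        ),
        dti_metric_cols=tuple(
            m for m, t in zip(table.metric_names, table.modality_tags) if t == MODALITY_DTI
        ),
    )
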