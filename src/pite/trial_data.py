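"""Two-arm randomized trial tables.

A :class:`TrialDataset` holds one row per patient: an identifier, a treatment
arm label (``"E"`` experimental / ``"C"`` control), a continuous outcome, and
a matrix of baseline covariates tagged ``continuous`` or ``binary``. Loading
applies a complete-case filter (rows with any missing analysis value are
dropped and counted — silent data loss is impossible); arbitrary two-level
treatment codings in the file are mapped to E/C through a schema.

CSV dialect is fixed: comma-separated, header row, UTF-8, ``.`` decimal.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

EXPERIMENTAL = "E"
CONTROL = "C"
ARMS = (EXPERIMENTAL, CONTROL)

CONTINUOUS = "continuous"
BINARY = "binary"
COVARIATE_KINDS = (CONTINUOUS, BINARY)

HIGHER_IS_BETTER = "higher_is_better"
LOWER_IS_BETTER = "lower_is_better"
OUTCOME_DIRECTIONS = (HIGHER_IS_BETTER, LOWER_IS_BETTER)


class SchemaError(ValueError):
    """A required column or schema field is missing or malformed."""


class ValidationError(ValueError):
    """Data violate the trial-table contract (e.g. >2 treatment levels)."""


class EmptyDataError(ValueError):
    """No complete-case rows remain after filtering."""


class SplitError(ValueError):
    """A requested split would leave an arm empty in one part."""


@dataclass(frozen=True)
class TrialSchema:
    """Column-role mapping for a trial CSV.

    Parameters
    ----------
    id_col, treatment_col, outcome_col
        Column names in the file.
    covariates
        Mapping from covariate column name to its kind
        (``"continuous"`` or ``"binary"``).
    experimental_label, control_label
        The two values the treatment column may take; they are mapped to
        ``"E"`` and ``"C"`` internally.
    outcome_direction
        Which direction of the outcome is clinically beneficial.
    """

    id_col: str
    treatment_col: str
    outcome_col: str
    covariates: Mapping[str, str]
    experimental_label: str = EXPERIMENTAL
    control_label: str = CONTROL
    outcome_direction: str = HIGHER_IS_BETTER

    def __post_init__(self) -> None:
        if not self.covariates:
            raise SchemaError("schema must name at least one covariate column")
        for name, kind in self.covariates.items():
            if kind not in COVARIATE_KINDS:
                raise SchemaError(
                    f"covariate {name!r} has unknown kind {kind!r}; "
                    f"expected one of {COVARIATE_KINDS}"
                )
        if self.outcome_direction not in OUTCOME_DIRECTIONS:
            raise SchemaError(
                f"outcome_direction must be one of {OUTCOME_DIRECTIONS}, "
                f"got {self.outcome_direction!r}"
            )
        if str(self.experimental_label) == str(self.control_label):
            raise SchemaError("experimental and control labels must differ")

    @property
    def used_columns(self) -> list[str]:
        return [self.id_col, self.treatment_col, self.outcome_col,
                *self.covariates]

    def to_dict(self) -> dict:
        return {
            "id": self.id_col,
            "treatment": {
                "column": self.treatment_col,
                "experimental": self.experimental_label,
                "control": self.control_label,
            },
            "outcome": self.outcome_col,
            "outcome_direction": self.outcome_direction,
            "covariates": dict(self.covariates),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrialSchema":
        try:
            trt = d["treatment"]
            if isinstance(trt, str):  # bare column name, default E/C labels
                trt = {"column": trt, "experimental": EXPERIMENTAL,
                       "control": CONTROL}
            return cls(
                id_col=d["id"],
                treatment_col=trt["column"],
                outcome_col=d["outcome"],
                covariates=dict(d["covariates"]),
                experimental_label=trt.get("experimental", EXPERIMENTAL),
                control_label=trt.get("control", CONTROL),
                outcome_direction=d.get("outcome_direction", HIGHER_IS_BETTER),
            )
        except KeyError as exc:
            raise SchemaError(f"schema is missing required field {exc}") from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "TrialSchema":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise SchemaError(f"schema file {path} does not hold a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2) + "\n", encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")


@dataclass(frozen=True)
class LoadReport:
    """Bookkeeping from :func:`load_trial`: how many rows survived."""

    n_read: int
    n_kept: int
    n_dropped: int


@dataclass
class TrialDataset:
    """In-memory two-arm randomized trial table.

    ``covariates`` is an ``n x p`` :class:`pandas.DataFrame` with unique
    column names; ``covariate_kinds`` tags every column as continuous or
    binary. All arrays are aligned positionally.
    """

    patient_ids: np.ndarray
    treatment: np.ndarray
    outcome: np.ndarray
    covariates: pd.DataFrame
    covariate_kinds: dict[str, str] = field(default_factory=dict)
    outcome_direction: str = HIGHER_IS_BETTER

    def __post_init__(self) -> None:
        self.patient_ids = np.asarray(self.patient_ids)
        self.treatment = np.asarray(self.treatment, dtype=object)
        self.outcome = np.asarray(self.outcome, dtype=float)
        if not isinstance(self.covariates, pd.DataFrame):
            self.covariates = pd.DataFrame(np.asarray(self.covariates, float))
            self.covariates.columns = [f"x{j + 1}" for j in range(self.p)]
        self.covariates = self.covariates.reset_index(drop=True).astype(float)
        n = len(self.patient_ids)
        if n < 1:
            raise EmptyDataError("a trial dataset needs at least one patient")
        if len(self.treatment) != n or len(self.outcome) != n \
                or len(self.covariates) != n:
            raise ValidationError("patient_ids, treatment, outcome and "
                                  "covariates must have equal length")
        if len(np.unique(self.patient_ids)) != n:
            raise ValidationError("patient identifiers must be unique")
        levels = set(self.treatment.tolist())
        if not levels <= set(ARMS):
            raise ValidationError(
                f"treatment labels must be within {set(ARMS)}, got {levels}")
        if self.covariates.columns.duplicated().any():
            raise ValidationError("covariate column names must be unique")
        if not self.covariate_kinds:
            self.covariate_kinds = {
                c: BINARY if set(np.unique(self.covariates[c])) <= {0.0, 1.0}
                else CONTINUOUS
                for c in self.covariates.columns
            }
        if set(self.covariate_kinds) != set(self.covariates.columns):
            raise ValidationError("covariate_kinds must cover exactly the "
                                  "covariate columns")
        for c, kind in self.covariate_kinds.items():
            if kind not in COVARIATE_KINDS:
                raise ValidationError(f"unknown covariate kind {kind!r}")
            if kind == BINARY:
                vals = set(np.unique(self.covariates[c].to_numpy()))
                if not vals <= {0.0, 1.0}:
                    raise ValidationError(
                        f"binary covariate {c!r} contains values other "
                        f"than 0/1: {sorted(vals)[:5]}")
        if np.isnan(self.outcome).any() or \
                self.covariates.isna().to_numpy().any():
            raise ValidationError("missing values present; apply the "
                                  "complete-case filter before constructing")
        if self.outcome_direction not in OUTCOME_DIRECTIONS:
            raise ValidationError(
                f"outcome_direction must be one of {OUTCOME_DIRECTIONS}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.patient_ids)

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def columns(self) -> list[str]:
        return list(self.covariates.columns)

    def arm_mask(self, arm: str) -> np.ndarray:
        if arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")
        return self.treatment == arm

    def arm(self, arm: str) -> "TrialDataset":
        """Restrict to one treatment arm."""
        return self.take(np.flatnonzero(self.arm_mask(arm)))

    def take(self, indices: np.ndarray) -> "TrialDataset":
        indices = np.asarray(indices)
        return TrialDataset(
            patient_ids=self.patient_ids[indices],
            treatment=self.treatment[indices],
            outcome=self.outcome[indices],
            covariates=self.covariates.iloc[indices],
            covariate_kinds=dict(self.covariate_kinds),
            outcome_direction=self.outcome_direction,
        )

    def require_both_arms(self) -> None:
        for arm in ARMS:
            if not self.arm_mask(arm).any():
                raise ValidationError(
                    f"arm {arm!r} is empty; model fitting needs both arms")

    def default_schema(self) -> TrialSchema:
        return TrialSchema(
            id_col="patient_id", treatment_col="treatment",
            outcome_col="outcome", covariates=dict(self.covariate_kinds),
            outcome_direction=self.outcome_direction,
        )

    def to_frame(self, schema: TrialSchema | None = None) -> pd.DataFrame:
        schema = schema or self.default_schema()
        label = {EXPERIMENTAL: schema.experimental_label,
                 CONTROL: schema.control_label}
        df = pd.DataFrame({
            schema.id_col: self.patient_ids,
            schema.treatment_col: [label[t] for t in self.treatment],
            schema.outcome_col: self.outcome,
        })
        for c in schema.covariates:
            df[c] = self.covariates[c].to_numpy()
        return df


def load_trial(
    path: str | Path,
    schema: TrialSchema,
    outcome_direction: str | None = None,
) -> tuple[TrialDataset, LoadReport]:
    """Read a trial CSV, map column roles, and apply the complete-case filter.

    Returns the dataset together with a :class:`LoadReport` counting the rows
    dropped for missingness. Raises :class:`SchemaError` when a named column
    is absent, :class:`ValidationError` when the treatment column holds values
    outside the schema's two levels, and :class:`EmptyDataError` when no
    complete row remains.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in schema.used_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"file {path} is missing required columns {missing}")
    df = df[schema.used_columns]
    n_read = len(df)
    df = df.dropna()
    n_kept = len(df)
    if n_kept == 0:
        raise EmptyDataError(f"no complete-case rows in {path}")
    report = LoadReport(n_read=n_read, n_kept=n_kept,
                        n_dropped=n_read - n_kept)
    if report.n_dropped:
        logger.info("complete-case filter dropped %d of %d rows from %s",
                    report.n_dropped, n_read, path)

    raw = df[schema.treatment_col].astype(str)
    mapping = {str(schema.experimental_label): EXPERIMENTAL,
               str(schema.control_label): CONTROL}
    unknown = sorted(set(raw) - set(mapping))
    if unknown:
        raise ValidationError(
            f"treatment column {schema.treatment_col!r} has values outside "
            f"the schema's two levels: {unknown}")

    direction = outcome_direction or schema.outcome_direction
    if outcome_direction is None and "outcome_direction" not in \
            schema.to_dict():  # pragma: no cover - schema always carries it
        direction = HIGHER_IS_BETTER

    data = TrialDataset(
        patient_ids=df[schema.id_col].to_numpy(),
        treatment=np.array([mapping[t] for t in raw], dtype=object),
        outcome=df[schema.outcome_col].to_numpy(dtype=float),
        covariates=df[list(schema.covariates)],
        covariate_kinds=dict(schema.covariates),
        outcome_direction=direction,
    )
    return data, report


def write_trial(
    data: TrialDataset,
    path: str | Path,
    schema: TrialSchema | None = None,
    float_format: str = "%.12g",
) -> TrialSchema:
    """Write a trial CSV (and return the schema describing it).

    ``load_trial(path, schema)`` round-trips the dataset up to the float
    precision of ``float_format`` (12 significant digits by default).
    """
    schema = schema or data.default_schema()
    data.to_frame(schema).to_csv(path, index=False, float_format=float_format,
                                 encoding="utf-8")
    return schema


def split_trial(
    data: TrialDataset, fraction: float, seed: int
) -> tuple[TrialDataset, TrialDataset]:
    """Stratified (by arm) random split into two disjoint, exhaustive parts.

    The first part receives ``round(fraction * n_arm)`` patients of each arm.
    Raises :class:`SplitError` if either part would lose an arm entirely.
    Deterministic given ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise SplitError(f"fraction must be in (0, 1), got {fraction}")
    data.require_both_arms()
    rng = np.random.default_rng(seed)
    first: list[np.ndarray] = []
    second: list[np.ndarray] = []
    for arm in ARMS:
        idx = np.flatnonzero(data.arm_mask(arm))
        k = int(round(fraction * len(idx)))
        if k == 0 or k == len(idx):
            raise SplitError(
                f"fraction {fraction} leaves arm {arm!r} empty in one part "
                f"(arm size {len(idx)})")
        perm = rng.permutation(len(idx))
        first.append(idx[perm[:k]])
        second.append(idx[perm[k:]])
    a = np.sort(np.concatenate(first))
    b = np.sort(np.concatenate(second))
    return data.take(a), data.take(b)
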