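"""Cohort data model, schema handling and result I/O.

A cohort is a rectangular table of ``n`` observations with a schema that
assigns every column a measurement kind (continuous / binary / ordinal) and
an analytic role (exposure, adjustment, baseline adjustment, time, event, or
one of the survey-design roles weight / stratum / cluster).  The schema also
records which variables are considered free of measurement error (typically
age, sex and race/ethnicity in mortality cohorts), which the measurement
vibration engine leaves untouched.

Missing data are handled once, at load time, by complete-case deletion over
the union of all schema variables, so that every downstream engine sees the
identical set of rows.  If the exposure is continuous it is standardised at
load time so hazard ratios are per standard deviation of the exposure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    CohortValidationError,
    DegenerateVariableError,
    SchemaError,
    VoeError,
)

logger = logging.getLogger(__name__)

KINDS = ("continuous", "binary", "ordinal")
ROLES = (
    "exposure",
    "adjustment",
    "baseline_adjustment",
    "time",
    "event",
    "weight",
    "stratum",
    "cluster",
)
#: roles that may occur at most / exactly once in a schema
_UNIQUE_ROLES = ("exposure", "time", "event", "weight", "stratum", "cluster")
_REQUIRED_ROLES = ("exposure", "time", "event")


@dataclass(frozen=True)
class VariableSpec:
    """Schema entry for one cohort column.

    Parameters
    ----------
    name : str
        Column name in the cohort table.
    kind : {"continuous", "binary", "ordinal"}
        Measurement scale.  Binary variables are coded 0/1; ordinal
        variables are integer scores ``1..L`` entered into models as a
        single linear term.
    role : str
        Analytic role, one of :data:`ROLES`.
    error_free : bool
        If True, the measurement vibration engine never corrupts this
        variable.
    levels : tuple, optional
        Ordered category labels, required for ordinal variables (L >= 3).
    """

    name: str
    kind: str
    role: str
    error_free: bool = False
    levels: tuple | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")
        if self.kind == "ordinal":
            if self.levels is None or len(self.levels) < 3:
                raise SchemaError(
                    f"ordinal variable {self.name!r} needs >= 3 ordered levels"
                )
            object.__setattr__(self, "levels", tuple(self.levels))
        elif self.levels is not None:
            raise SchemaError(f"levels only apply to ordinal variables ({self.name!r})")


@dataclass(frozen=True)
class EffectEstimate:
    """One fitted exposure effect (log hazard ratio) and its provenance.

    ``provenance`` is a ``(type, id)`` pair, e.g. ``("model", 37)``,
    ``("subsample", 12)`` or ``("error_draw", 980)``.  For non-converged
    fits ``se`` and ``p_value`` are ``None`` and ``log_hr``/``hr`` are NaN.
    """

    log_hr: float
    hr: float
    se: float | None
    p_value: float | None
    converged: bool
    provenance: tuple[str, int]

    def __post_init__(self):
        if self.converged:
            if not np.isclose(self.hr, np.exp(self.log_hr), rtol=1e-10, atol=0):
                raise VoeError("hr must equal exp(log_hr)")
            if self.se is None or self.se < 0:
                raise VoeError("converged estimate needs se >= 0")
            if self.p_value is None or not (0 < self.p_value <= 1):
                raise VoeError("converged estimate needs p in (0, 1]")


def _validate_schema(schema: Sequence[VariableSpec]) -> tuple[VariableSpec, ...]:
    schema = tuple(schema)
    names = [v.name for v in schema]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate variable names in schema")
    for role in _UNIQUE_ROLES:
        count = sum(v.role == role for v in schema)
        if count > 1:
            raise SchemaError(f"role {role!r} appears {count} times (max 1)")
        if role in _REQUIRED_ROLES and count == 0:
            raise SchemaError(f"schema must contain exactly one {role!r} variable")
    return schema


@dataclass(frozen=True)
class Cohort:
    """A validated survival cohort: data table plus variable schema."""

    data: pd.DataFrame
    schema: tuple[VariableSpec, ...]

    def __post_init__(self):
        schema = _validate_schema(self.schema)
        object.__setattr__(self, "schema", schema)
        df = self.data
        missing = [v.name for v in schema if v.name not in df.columns]
        if missing:
            raise SchemaError(f"cohort table lacks schema columns: {missing}")
        df = df.loc[:, [v.name for v in schema]].reset_index(drop=True)
        object.__setattr__(self, "data", df)
        self._validate_values()

    def _validate_values(self) -> None:
        df = self.data
        if df.isna().any().any():
            raise CohortValidationError("cohort contains missing values after load")
        t = df[self.time_var].to_numpy(float)
        if (t < 0).any():
            raise CohortValidationError("event/censoring times must be >= 0")
        ev = df[self.event_var].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise CohortValidationError("event indicator must be 0/1")
        for v in self.schema:
            if v.kind == "binary" and v.role not in ("time", "event"):
                vals = df[v.name].to_numpy()
                if not np.isin(vals, (0, 1)).all():
                    raise CohortValidationError(f"binary variable {v.name!r} not 0/1")
        w = self.design_var("weight")
        if w is not None and (df[w].to_numpy(float) <= 0).any():
            raise CohortValidationError("weights must be > 0")

    # -- schema accessors ------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    def _one(self, role: str) -> str:
        return next(v.name for v in self.schema if v.role == role)

    @property
    def exposure(self) -> str:
        return self._one("exposure")

    @property
    def time_var(self) -> str:
        return self._one("time")

    @property
    def event_var(self) -> str:
        return self._one("event")

    @property
    def baseline_vars(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.schema if v.role == "baseline_adjustment")

    @property
    def optional_vars(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.schema if v.role == "adjustment")

    @property
    def adjustment_vars(self) -> tuple[str, ...]:
        return self.baseline_vars + self.optional_vars

    def design_var(self, role: str) -> str | None:
        return next((v.name for v in self.schema if v.role == role), None)

    def spec_of(self, name: str) -> VariableSpec:
        try:
            return next(v for v in self.schema if v.name == name)
        except StopIteration:
            raise SchemaError(f"no variable {name!r} in schema") from None

    def with_data(self, data: pd.DataFrame) -> "Cohort":
        """Return a new cohort with the same schema and replaced values."""
        return Cohort(data=data, schema=self.schema)


# ---------------------------------------------------------------------------
# schema / cohort loading


def _schema_from_mapping(mapping: Mapping[str, Mapping]) -> list[VariableSpec]:
    specs = []
    for name, entry in mapping.items():
        if not isinstance(entry, Mapping) or "kind" not in entry or "role" not in entry:
            raise SchemaError(f"schema entry for {name!r} needs 'kind' and 'role'")
        levels = entry.get("levels")
        specs.append(
            VariableSpec(
                name=name,
                kind=entry["kind"],
                role=entry["role"],
                error_free=bool(entry.get("error_free", False)),
                levels=tuple(levels) if levels is not None else None,
            )
        )
    return specs


def read_schema(schema_path: str | Path) -> list[VariableSpec]:
    """Read a variable schema from a YAML or JSON mapping file."""
    text = Path(schema_path).read_text()
    mapping = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(mapping, Mapping):
        raise SchemaError("schema file must contain a mapping column -> attributes")
    return _schema_from_mapping(mapping)


def write_schema(schema: Sequence[VariableSpec], schema_path: str | Path) -> None:
    mapping = {}
    for v in schema:
        entry: dict = {"kind": v.kind, "role": v.role, "error_free": v.error_free}
        if v.levels is not None:
            entry["levels"] = list(v.levels)
        mapping[v.name] = entry
    Path(schema_path).write_text(yaml.safe_dump(mapping, sort_keys=False))


def load_cohort(
    table_path: str | Path,
    schema_path: str | Path,
    standardize_exposure: bool = True,
) -> Cohort:
    """Load a cohort CSV and its schema, applying complete-case deletion.

    Rows with a missing value in any schema variable are dropped (the count
    is logged).  If ``standardize_exposure`` and the exposure is continuous,
    it is standardised to mean 0 / SD 1 so effects are per SD.
    """
    schema = _validate_schema(read_schema(schema_path))
    df = pd.read_csv(table_path)
    missing_cols = [v.name for v in schema if v.name not in df.columns]
    if missing_cols:
        raise SchemaError(f"CSV lacks schema columns: {missing_cols}")
    df = df.loc[:, [v.name for v in schema]]
    complete = df.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d incomplete rows (complete-case)", n_dropped)
    cohort = Cohort(data=df.loc[complete].reset_index(drop=True), schema=tuple(schema))
    exp_spec = cohort.spec_of(cohort.exposure)
    if standardize_exposure and exp_spec.kind == "continuous":
        cohort = standardize_continuous(cohort, [cohort.exposure])
    return cohort


def standardize_continuous(cohort: Cohort, names: Iterable[str]) -> Cohort:
    """Standardise the named continuous columns to mean 0, sample SD 1.

    Idempotent; all other columns and the row order are unchanged.
    """
    df = cohort.data.copy()
    for name in names:
        spec = cohort.spec_of(name)
        if spec.kind != "continuous":
            raise SchemaError(f"{name!r} is {spec.kind}, not continuous")
        x = df[name].to_numpy(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateVariableError(f"{name!r} has zero variance")
        df[name] = (x - x.mean()) / sd
    return cohort.with_data(df)


# ---------------------------------------------------------------------------
# result I/O

_CSV_COLUMNS = [
    "provenance_type",
    "provenance_id",
    "log_hr",
    "hr",
    "se",
    "p_value",
    "converged",
]


def estimates_to_frame(estimates: Sequence[EffectEstimate]) -> pd.DataFrame:
    """Long-format table with one row per effect estimate."""
    rows = [
        {
            "provenance_type": e.provenance[0],
            "provenance_id": e.provenance[1],
            "log_hr": e.log_hr,
            "hr": e.hr,
            "se": e.se if e.se is not None else np.nan,
            "p_value": e.p_value if e.p_value is not None else np.nan,
            "converged": e.converged,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_results(result, out_dir: str | Path) -> dict[str, Path]:
    """Write a vibration result as ``estimates.csv`` + ``summary.json``.

    The CSV holds one row per estimate with its provenance; the JSON holds
    the vibration summary (RHR, RP, Janus flag, significance counts), the
    run settings and the master seed, so a run is reconstructible from the
    summary alone.  Returns the written paths.
    """
    if not result.estimates:
        raise VoeError("refusing to write an empty result")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "estimates.csv"
    estimates_to_frame(result.estimates).to_csv(csv_path, index=False)
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(result.summary_dict(), indent=2, sort_keys=True))
    return {"estimates": csv_path, "summary": summary_path}


def read_results(out_dir: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read back what :func:`write_results` wrote."""
    out_dir = Path(out_dir)
    frame = pd.read_csv(out_dir / "estimates.csv")
    summary = json.loads((out_dir / "summary.json").read_text())
    return frame, summary
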