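"""Procedure tables, variable metadata, and readers/writers.

The central container is :class:`ProcedureTable`: an N x R matrix of
procedure characteristics (limits of detection, solvent volumes, greenness
scores, ...) together with per-variable metadata (:class:`VariableSpec`).
Missing values are explicit (``NaN``), never encoded as 0 — a procedure that
uses 0 mL of solvent is real data, a procedure whose solvent use was not
reported is not.

A transcription of the published benzo[a]pyrene survey table (41 procedures
with NEMI and Eco-Scale scores) ships as package data; see
:func:`load_fixture_table1`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    NoCompleteProceduresError,
    SchemaError,
    TableParseError,
    ValidationError,
)

ROLES = ("environmental", "metrological")
ORIENTATIONS = ("low_is_good", "high_is_good", "target_100")


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one variable of a procedure table.

    Parameters
    ----------
    name : str
        Column name; unique within a schema.
    units : str
        Physical units ("ng/g", "mL", "%", ...) or "" for unitless scores.
    role : {"environmental", "metrological"}
        Whether the variable describes greenness or analytical performance.
    orientation : {"low_is_good", "high_is_good", "target_100"}
        How raw values map onto "good": small values good (LOD, waste),
        large values good (bounded greenness scores), or closeness to 100%
        good (recovery).
    required : bool
        Whether completeness filtering treats the variable as mandatory.
    scale_max : float, optional
        Fixed upper anchor used when reflecting a ``high_is_good`` variable
        (4 for the NEMI green-field count, 100 for the Eco-Scale); when
        absent the observed column maximum is used.
    """

    name: str
    units: str = ""
    role: str = "environmental"
    orientation: str = "low_is_good"
    required: bool = True
    scale_max: float | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(f"unknown orientation {self.orientation!r}")


#: The eleven survey variables, in publication order.  The number of other
#: analytes determined per run defaults to high_is_good (a multianalyte run
#: amortises its footprint); flip the orientation in a custom schema to
#: treat it as a cost instead.
DEFAULT_SCHEMA: tuple[VariableSpec, ...] = (
    VariableSpec("lod", "ng/g", "metrological", "low_is_good"),
    VariableSpec("precision", "%", "metrological", "low_is_good"),
    VariableSpec("recovery", "%", "metrological", "target_100"),
    VariableSpec("sample_mass", "g", "environmental", "low_is_good"),
    VariableSpec("other_analytes", "", "environmental", "high_is_good"),
    VariableSpec("solvent_volume", "mL", "environmental", "low_is_good"),
    VariableSpec("hazard_weighted_solvent", "mL", "environmental", "low_is_good"),
    VariableSpec("solid_waste", "g", "environmental", "low_is_good"),
    VariableSpec("time_h", "h", "environmental", "low_is_good"),
    VariableSpec("nemi", "", "environmental", "high_is_good", scale_max=4.0),
    VariableSpec("eco_scale", "", "environmental", "high_is_good", scale_max=100.0),
)

#: Default information bases.  NEMI/Eco-Scale are deliberately left out of
#: the environmental set (they are composite assessments of the same
#: physical quantities); toggle them in via ``include_scores``.
ENVIRONMENTAL_VARIABLES = (
    "sample_mass",
    "other_analytes",
    "solvent_volume",
    "hazard_weighted_solvent",
    "solid_waste",
    "time_h",
)
METROLOGICAL_VARIABLES = ("lod", "precision", "recovery")


def schema_by_name(schema: Sequence[VariableSpec]) -> dict[str, VariableSpec]:
    out: dict[str, VariableSpec] = {}
    for spec in schema:
        if spec.name in out:
            raise SchemaError(f"duplicate variable name {spec.name!r}")
        out[spec.name] = spec
    return out


@dataclass
class ProcedureTable:
    """Procedures x variables data matrix with variable metadata.

    ``values`` is a DataFrame indexed by procedure id with one numeric
    column per variable (NaN = missing).  ``meta`` optionally carries
    non-numeric columns (technique label, literature reference) aligned on
    the same index.
    """

    values: pd.DataFrame
    variables: tuple[VariableSpec, ...]
    meta: pd.DataFrame | None = None
    dropped_ids: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.variables = tuple(self.variables)
        by_name = schema_by_name(self.variables)
        extra = set(self.values.columns) - set(by_name)
        if extra:
            raise SchemaError(f"columns without a VariableSpec: {sorted(extra)}")
        if len(self.values) < 1 or len(self.values.columns) < 1:
            raise ValidationError("table must have at least one row and one column")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate procedure ids: {dupes}")
        self.values = self.values.astype(float)
        self._check_score_columns()

    def _check_score_columns(self):
        if "nemi" in self.values.columns:
            col = self.values["nemi"].dropna()
            bad = col[(col < 0) | (col > 4) | (col != col.round())]
            if len(bad):
                raise ValidationError(
                    f"NEMI scores must be integers in [0, 4]; offending ids: "
                    f"{bad.index.tolist()}"
                )
        if "eco_scale" in self.values.columns:
            col = self.values["eco_scale"].dropna()
            bad = col[col > 100]
            if len(bad):
                raise ValidationError(
                    f"Eco-Scale scores must be <= 100; offending ids: "
                    f"{bad.index.tolist()}"
                )

    @property
    def procedure_ids(self) -> tuple:
        return tuple(self.values.index)

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.variables)

    @property
    def n_procedures(self) -> int:
        return len(self.values)

    def spec(self, name: str) -> VariableSpec:
        return schema_by_name(self.variables)[name]

    def variables_for_role(self, role: str) -> tuple[str, ...]:
        if role not in ROLES:
            raise ValidationError(f"unknown role {role!r}")
        return tuple(
            s.name for s in self.variables
            if s.role == role and s.name in self.values.columns
        )

    # ------------------------------------------------------------------ IO
    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="procedure_id")

    def to_json(self, path=None):
        """JSON export: schema + values; missing cells serialised as null."""
        payload = {
            "variables": [
                {
                    "name": s.name,
                    "units": s.units,
                    "role": s.role,
                    "orientation": s.orientation,
                    "required": s.required,
                    "scale_max": s.scale_max,
                }
                for s in self.variables
            ],
            "procedure_ids": [_plain(i) for i in self.values.index],
            "values": [
                [None if math.isnan(v) else v for v in row]
                for row in self.values.to_numpy()
            ],
        }
        if path is None:
            return json.dumps(payload, indent=2)
        Path(path).write_text(json.dumps(payload, indent=2))
        return None

    @classmethod
    def from_json(cls, source) -> "ProcedureTable":
        text = source if isinstance(source, str) and source.lstrip().startswith("{") \
            else Path(source).read_text()
        payload = json.loads(text)
        variables = tuple(
            VariableSpec(
                v["name"], v.get("units", ""), v.get("role", "environmental"),
                v.get("orientation", "low_is_good"), v.get("required", True),
                v.get("scale_max"),
            )
            for v in payload["variables"]
        )
        values = pd.DataFrame(
            [[np.nan if v is None else v for v in row] for row in payload["values"]],
            index=pd.Index(payload["procedure_ids"], name="procedure_id"),
            columns=[s.name for s in variables],
            dtype=float,
        )
        return cls(values, variables)


def _plain(x):
    return x.item() if hasattr(x, "item") else x


def read_procedure_table(
    path,
    schema: Sequence[VariableSpec] = DEFAULT_SCHEMA,
    sep: str = ",",
) -> ProcedureTable:
    """Read a CSV/TSV of procedures into a :class:`ProcedureTable`.

    The file must have a header row; one column must be ``procedure_id``
    (otherwise the first column is taken as the id).  Every other column
    must appear in ``schema``; blank and NA cells become missing values.

    Raises
    ------
    SchemaError
        If a column is not covered by the schema.
    TableParseError
        Naming the row and column of the first non-numeric cell.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.columns.size == 0:
        raise SchemaError(f"{path}: empty header")
    id_col = "procedure_id" if "procedure_id" in raw.columns else raw.columns[0]
    by_name = schema_by_name(schema)
    unknown = [c for c in raw.columns if c != id_col and c not in by_name]
    if unknown:
        raise SchemaError(f"{path}: columns not in schema: {unknown}")

    ids = [_coerce_id(v) for v in raw[id_col]]
    data = {}
    na_tokens = {"", "na", "nan", "n/a", "none", "null", "-"}
    for col in raw.columns:
        if col == id_col:
            continue
        parsed = []
        for row_id, cell in zip(ids, raw[col]):
            cell = cell.strip()
            if cell.lower() in na_tokens:
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(cell))
            except ValueError:
                raise TableParseError(row_id, col, cell) from None
        data[col] = parsed
    values = pd.DataFrame(data, index=pd.Index(ids, name="procedure_id"))
    variables = tuple(by_name[c] for c in values.columns)
    return ProcedureTable(values, variables)


def _coerce_id(value: str):
    value = value.strip()
    try:
        return int(value)
    except ValueError:
        return value


def validate_completeness(
    table: ProcedureTable, required: Iterable[str]
) -> ProcedureTable:
    """Keep only procedures with no missing value among ``required``.

    The returned table records the dropped procedure ids in
    ``dropped_ids``.  Idempotent; never increases N.

    Raises
    ------
    SchemaError
        If a required variable is not in the table.
    NoCompleteProceduresError
        If no procedure is complete.
    """
    required = list(required)
    missing_cols = [c for c in required if c not in table.values.columns]
    if missing_cols:
        raise SchemaError(f"required variables not in table: {missing_cols}")
    ok = table.values[required].notna().all(axis=1)
    dropped = tuple(table.values.index[~ok])
    if not ok.any():
        raise NoCompleteProceduresError(
            f"no procedure has complete data for {required}"
        )
    meta = table.meta.loc[ok] if table.meta is not None else None
    return ProcedureTable(
        table.values.loc[ok], table.variables, meta=meta, dropped_ids=dropped
    )


TABLE1_SCHEMA: tuple[VariableSpec, ...] = (
    schema_by_name(DEFAULT_SCHEMA)["nemi"],
    schema_by_name(DEFAULT_SCHEMA)["eco_scale"],
)


def load_fixture_table1() -> ProcedureTable:
    """Load the bundled 41-procedure benzo[a]pyrene survey table.

    Columns: NEMI green-field count (0-4) and Eco-Scale score, plus the
    technique label and literature reference number as metadata.
    """
    with resources.files("greenrank._fixtures").joinpath("table1.csv").open() as fh:
        raw = pd.read_csv(fh, dtype={"reference": "Int64"})
    raw = raw.set_index("procedure_id")
    values = raw[["nemi", "eco_scale"]].astype(float)
    meta = raw[["technique", "reference"]]
    return ProcedureTable(values, TABLE1_SCHEMA, meta=meta)
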