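"""Patient tables: CSV I/O and numeric encoding of mixed-type variables.

The in-memory container is :class:`PatientTable`: an ``n x p`` raw-value
frame conforming to a variable schema, a label vector ``y`` over
``{-1, 0, +1}`` (0 = unlabeled), and unique row identifiers.  The similarity
graph operates on an encoded view (:class:`EncodedMatrix`) in which discrete
variables are one-hot expanded and continuous variables are z-scored, so that
the Gaussian edge weights act on a plain Euclidean vector space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractError, SchemaError, ValidationError
from .schema import VariableSchema, validate_schema

logger = logging.getLogger(__name__)

__all__ = ["PatientTable", "EncodedMatrix", "read_patient_table", "write_patient_table", "encode"]

#: CSV sentinels that mark an unlabeled row.
UNLABELED_SENTINELS = {"", "NA", "na", "NaN", "nan", "0"}


@dataclass
class PatientTable:
    """An ``n x p`` cohort with partial binary labels.

    ``y[i] = +1`` (survived), ``-1`` (dead) or ``0`` (unlabeled); ``nl`` and
    ``nu`` count labeled and unlabeled rows, so ``n = nl + nu``.
    """

    X: pd.DataFrame
    y: np.ndarray
    ids: np.ndarray
    schema: list[VariableSchema] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        self.ids = np.asarray(self.ids)
        if len(self.X) != len(self.y) or len(self.y) != len(self.ids):
            raise ContractError("X, y and ids must have equal length")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValidationError("row identifiers must be unique")
        bad = set(np.unique(self.y)) - {-1, 0, 1}
        if bad:
            raise ValidationError(f"labels must be in {{-1, 0, +1}}, found {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def nl(self) -> int:
        return int(np.count_nonzero(self.y))

    @property
    def nu(self) -> int:
        return self.n - self.nl

    @property
    def labeled_mask(self) -> np.ndarray:
        return self.y != 0

    def validate(self) -> None:
        """Check every value against the schema; raise on the first violation."""
        validate_schema(self.schema)
        missing = [v.name for v in self.schema if v.name not in self.X.columns]
        if missing:
            raise SchemaError(f"columns missing from table: {missing}")
        extra = [c for c in self.X.columns if c not in {v.name for v in self.schema}]
        if extra:
            raise SchemaError(f"unexpected columns not in schema: {extra}")
        for v in self.schema:
            col = self.X[v.name]
            if col.isna().any():
                rows = self.ids[col.isna().to_numpy()][:5]
                raise ValidationError(f"{v.name}: missing values at rows {list(rows)} (missing data is not supported)")
            if v.kind == "discrete":
                vals = col.to_numpy()
                if not np.all(vals == np.floor(vals)):
                    raise ValidationError(f"{v.name}: discrete values must be integer codes")
                out = (vals < 1) | (vals > v.cardinality)
                if out.any():
                    rows = self.ids[out][:5]
                    raise ValidationError(
                        f"{v.name}: codes outside 1..{v.cardinality} at rows {list(rows)}"
                    )

    def subset(self, idx: np.ndarray) -> "PatientTable":
        """Row subset (positional indices); preserves order of ``idx``."""
        return PatientTable(
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y[idx].copy(),
            ids=self.ids[idx].copy(),
            schema=self.schema,
        )


@dataclass
class EncodedMatrix:
    """Numeric view of a :class:`PatientTable`.

    ``Z`` is ``n x q`` with one-hot blocks for discrete variables and z-scored
    columns for continuous ones.  ``column_map`` maps each schema variable to
    the list of its column indices in ``Z`` so importances and feature subsets
    can be mapped back to original variables.
    """

    Z: np.ndarray
    column_map: Dict[str, list[int]]
    columns: list[str]
    centers: np.ndarray
    scales: np.ndarray

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def select_variables(self, names: Sequence[str]) -> np.ndarray:
        """Columns of ``Z`` belonging to the given schema variables."""
        cols: list[int] = []
        for name in names:
            if name not in self.column_map:
                raise SchemaError(f"unknown variable {name!r}")
            cols.extend(self.column_map[name])
        return self.Z[:, cols]


def read_patient_table(
    path: str | Path,
    schema: Sequence[VariableSchema],
    label_column: str = "survivability",
    id_column: Optional[str] = None,
) -> PatientTable:
    """Read a cohort CSV into a validated :class:`PatientTable`.

    The header must contain exactly the schema variables plus the label
    column (and the id column, if given).  Label values ``+1``/``-1`` are
    kept; empty, ``NA`` or ``0`` entries mark unlabeled rows.
    """
    schema = list(schema)
    validate_schema(schema)
    df = pd.read_csv(path, dtype={label_column: str}, keep_default_na=False)
    if label_column not in df.columns:
        raise SchemaError(f"label column {label_column!r} not found in {path}")

    expected = {v.name for v in schema} | {label_column}
    if id_column is not None:
        if id_column not in df.columns:
            raise SchemaError(f"id column {id_column!r} not found in {path}")
        expected.add(id_column)
    unexpected = [c for c in df.columns if c not in expected]
    if unexpected:
        raise SchemaError(f"unexpected columns in {path}: {unexpected}")
    missing = [v.name for v in schema if v.name not in df.columns]
    if missing:
        raise SchemaError(f"columns missing from {path}: {missing}")

    raw_labels = df[label_column].str.strip()
    y = np.zeros(len(df), dtype=np.int64)
    for i, s in enumerate(raw_labels):
        if s in UNLABELED_SENTINELS:
            continue
        try:
            val = int(float(s))
        except ValueError as exc:
            raise ValidationError(f"row {i}: cannot parse label {s!r}") from exc
        if val not in (-1, 1):
            raise ValidationError(f"row {i}: label must be -1, +1 or an unlabeled sentinel, got {s!r}")
        y[i] = val

    ids = df[id_column].to_numpy() if id_column is not None else np.arange(len(df))
    X = df[[v.name for v in schema]].copy()
    for v in schema:
        X[v.name] = pd.to_numeric(X[v.name], errors="coerce")
    table = PatientTable(X=X, y=y, ids=ids, schema=schema)
    table.validate()
    return table


def write_patient_table(table: PatientTable, path: str | Path, label_column: str = "survivability") -> None:
    """Write a :class:`PatientTable` back to CSV (unlabeled rows get ``NA``)."""
    df = table.X.copy()
    df.insert(0, "id", table.ids)
    labels = np.where(table.y == 0, "NA", table.y.astype(str))
    df[label_column] = labels
    df.to_csv(path, index=False)


def encode(table: PatientTable, schema: Optional[Sequence[VariableSchema]] = None) -> EncodedMatrix:
    """One-hot discrete variables and z-score continuous ones.

    A constant continuous column is encoded as all zeros (with a warning)
    rather than raising; z-scoring uses the sample standard deviation
    (``ddof=1``) when ``n >= 2``.
    """
    schema = list(schema) if schema is not None else table.schema
    table_schema_names = set(table.X.columns)
    for v in schema:
        if v.name not in table_schema_names:
            raise SchemaError(f"variable {v.name!r} not present in table")

    n = table.n
    blocks: list[np.ndarray] = []
    column_map: Dict[str, list[int]] = {}
    columns: list[str] = []
    centers: list[float] = []
    scales: list[float] = []
    col_cursor = 0
    for v in schema:
        raw = table.X[v.name].to_numpy()
        if v.kind == "discrete":
            codes = raw.astype(np.int64)
            block = np.zeros((n, v.cardinality))
            block[np.arange(n), codes - 1] = 1.0
            names = [f"{v.name}={c}" for c in v.codes]
            centers.extend([0.0] * v.cardinality)
            scales.extend([1.0] * v.cardinality)
        else:
            x = raw.astype(np.float64)
            mu = float(np.mean(x)) if n else 0.0
            sd = float(np.std(x, ddof=1)) if n >= 2 else 1.0
            if sd == 0.0 or not np.isfinite(sd):
                logger.warning("constant continuous column %r encoded as all-zero", v.name)
                block = np.zeros((n, 1))
                sd = 1.0
            else:
                block = ((x - mu) / sd)[:, None]
            names = [v.name]
            centers.append(mu)
            scales.append(sd)
        blocks.append(block)
        column_map[v.name] = list(range(col_cursor, col_cursor + block.shape[1]))
        columns.extend(names)
        col_cursor += block.shape[1]

    Z = np.hstack(blocks) if blocks else np.zeros((n, 0))
    return EncodedMatrix(
        Z=Z,
        column_map=column_map,
        columns=columns,
        centers=np.asarray(centers),
        scales=np.asarray(scales),
    )


def decode_discrete(enc: EncodedMatrix, schema: Sequence[VariableSchema], name: str) -> np.ndarray:
    """Recover the original integer codes of a discrete variable from ``Z``."""
    var = next((v for v in schema if v.name == name), None)
    if var is None or var.kind != "discrete":
        raise SchemaError(f"{name!r} is not a discrete schema variable")
    block = enc.Z[:, enc.column_map[name]]
    return np.argmax(block, axis=1) + 1
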