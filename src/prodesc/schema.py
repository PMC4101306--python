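"""Variable schemas for mixed-type patient tables.

A schema declares, per prognostic variable, whether it is discrete (integer
codes ``1..cardinality``) or continuous (optionally with cohort moments and
an admissible range).  The packaged default is the 16-variable breast-cancer
survivability schema (11 discrete, 5 continuous).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Tuple

import yaml

from .exceptions import SchemaError

__all__ = [
    "VariableSchema",
    "default_schema",
    "load_schema",
    "save_schema",
    "validate_schema",
]


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of a single prognostic variable.

    Parameters
    ----------
    name:
        Unique variable name.
    kind:
        ``"discrete"`` or ``"continuous"``.
    cardinality:
        Number of codes of a discrete variable; its code set is
        ``{1, ..., cardinality}``.  Must be ``None`` for continuous variables.
    mean, sd:
        Cohort moments of a continuous variable (used by the synthetic
        generator); optional.
    declared_range:
        Optional ``(low, high)`` pair for a continuous variable; either end
        may be ``None`` (unbounded).
    """

    name: str
    kind: str
    cardinality: Optional[int] = None
    mean: Optional[float] = None
    sd: Optional[float] = None
    declared_range: Optional[Tuple[Optional[float], Optional[float]]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "continuous"):
            raise SchemaError(f"{self.name}: kind must be 'discrete' or 'continuous', got {self.kind!r}")
        if self.kind == "discrete":
            if self.cardinality is None or self.cardinality < 2:
                raise SchemaError(f"{self.name}: discrete variable needs cardinality >= 2")
            if self.mean is not None or self.sd is not None:
                raise SchemaError(f"{self.name}: moments are only meaningful for continuous variables")
        else:
            if self.cardinality is not None:
                raise SchemaError(f"{self.name}: continuous variable must not declare a cardinality")
            if self.sd is not None and self.sd <= 0:
                raise SchemaError(f"{self.name}: sd must be positive")

    @property
    def codes(self) -> range:
        """Code set of a discrete variable (1-based)."""
        if self.kind != "discrete":
            raise SchemaError(f"{self.name} is continuous and has no code set")
        return range(1, self.cardinality + 1)


def validate_schema(schema: Sequence[VariableSchema]) -> None:
    """Raise :class:`SchemaError` if names are not unique or the list is empty."""
    if not schema:
        raise SchemaError("schema must declare at least one variable")
    names = [v.name for v in schema]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SchemaError(f"duplicate variable names in schema: {dupes}")


def _from_mapping(entry: dict) -> VariableSchema:
    rng = entry.get("range")
    if rng is not None:
        rng = (rng[0], rng[1])
    return VariableSchema(
        name=entry["name"],
        kind=entry["kind"],
        cardinality=entry.get("cardinality"),
        mean=entry.get("mean"),
        sd=entry.get("sd"),
        declared_range=rng,
    )


def load_schema(path: str | Path) -> list[VariableSchema]:
    """Load a schema from a YAML file with a top-level ``variables`` list."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "variables" not in doc:
        raise SchemaError(f"{path}: expected a mapping with a 'variables' list")
    schema = [_from_mapping(e) for e in doc["variables"]]
    validate_schema(schema)
    return schema


def save_schema(schema: Sequence[VariableSchema], path: str | Path) -> None:
    """Write a schema to YAML in the same layout :func:`load_schema` reads."""
    entries = []
    for v in schema:
        e: dict = {"name": v.name, "kind": v.kind}
        if v.cardinality is not None:
            e["cardinality"] = v.cardinality
        if v.mean is not None:
            e["mean"] = v.mean
        if v.sd is not None:
            e["sd"] = v.sd
        if v.declared_range is not None:
            e["range"] = list(v.declared_range)
        entries.append(e)
    with open(path, "w") as fh:
        yaml.safe_dump({"variables": entries}, fh, sort_keys=False)


def default_schema() -> list[VariableSchema]:
    """The packaged 16-variable breast-cancer survivability schema."""
    ref = resources.files("prodesc.data").joinpath("seer_schema.yaml")
    with resources.as_file(ref) as path:
        return load_schema(path)
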