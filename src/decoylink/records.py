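"""Tabular record containers for record linkage.

A :class:`RecordTable` wraps a :class:`pandas.DataFrame` holding one row per
record, a declared list of categorical linkage variables, and a few reserved
columns: ``record_id`` (unique within the table), ``source`` (``"A"``,
``"B"`` or ``"SYNTH"``), and optionally ``entity_id`` (ground-truth identity,
evaluation only) and ``block`` (error-free partitioning variable).

Tables are read and written as delimited text with a YAML sidecar schema that
names the linkage variables and the optional identifier / blocking columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SOURCE_A = "A"
SOURCE_B = "B"
SOURCE_SYNTH = "SYNTH"

_RESERVED = ("record_id", "source", "entity_id", "block")


@dataclass
class RecordTable:
    """A file of records with categorical linkage variables.

    Parameters
    ----------
    data:
        One row per record.  Must contain ``record_id`` and ``source``
        columns plus one column per declared linkage variable.  ``entity_id``
        and ``block`` columns are optional.
    variables:
        Ordered names of the linkage variables.
    """

    data: pd.DataFrame
    variables: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.variables = list(self.variables)
        df = self.data
        if "record_id" not in df.columns:
            df = df.copy()
            df["record_id"] = np.arange(len(df))
        if "source" not in df.columns:
            df = df.copy()
            df["source"] = SOURCE_B
        for v in self.variables:
            if v in _RESERVED:
                raise ValueError(f"variable name {v!r} clashes with a reserved column")
            if v not in df.columns:
                raise ValueError(f"declared variable {v!r} missing from data")
        if df["record_id"].duplicated().any():
            raise ValueError("record_id values must be unique within a table")
        synth = df["source"] == SOURCE_SYNTH
        if "entity_id" in df.columns and synth.any():
            if df.loc[synth, "entity_id"].notna().any():
                raise ValueError("synthetic records cannot carry an entity_id")
        self.data = df.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def values(self) -> pd.DataFrame:
        """Just the linkage-variable columns, in declared order."""
        return self.data[self.variables]

    @property
    def record_ids(self) -> pd.Series:
        return self.data["record_id"]

    @property
    def is_synthetic(self) -> np.ndarray:
        return (self.data["source"] == SOURCE_SYNTH).to_numpy()

    @property
    def has_block(self) -> bool:
        return "block" in self.data.columns

    def subset(self, mask) -> "RecordTable":
        return RecordTable(self.data.loc[mask].reset_index(drop=True), self.variables)

    def concat(self, other: "RecordTable") -> "RecordTable":
        if list(other.variables) != list(self.variables):
            raise ValueError("cannot concatenate tables with different variables")
        df = pd.concat([self.data, other.data], ignore_index=True)
        return RecordTable(df, self.variables)

    # -- I/O -------------------------------------------------------------
    def write(self, csv_path: str | Path, schema_path: str | Path | None = None) -> None:
        csv_path = Path(csv_path)
        self.data.to_csv(csv_path, index=False)
        if schema_path is None:
            schema_path = csv_path.with_suffix(".schema.yaml")
        schema = {"variables": list(self.variables)}
        if "entity_id" in self.data.columns:
            schema["entity_id"] = "entity_id"
        if self.has_block:
            schema["block"] = "block"
        Path(schema_path).write_text(yaml.safe_dump(schema))

    @classmethod
    def read(
        cls,
        csv_path: str | Path,
        schema: str | Path | dict | None = None,
        source: str = SOURCE_B,
    ) -> "RecordTable":
        """Read a delimited file plus its schema (YAML path or dict).

        Without a schema every non-reserved column is taken as a linkage
        variable.  ``source`` fills in the provenance column when the file
        does not carry one.
        """
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        if schema is None:
            side = csv_path.with_suffix(".schema.yaml")
            schema = side if side.exists() else {}
        if isinstance(schema, (str, Path)):
            schema = yaml.safe_load(Path(schema).read_text()) or {}
        variables = schema.get("variables") or [c for c in df.columns if c not in _RESERVED]
        for key in ("entity_id", "block", "record_id"):
            col = schema.get(key)
            if col and col != key:
                if col not in df.columns:
                    raise ValueError(f"schema column {col!r} missing from {csv_path}")
                df = df.rename(columns={col: key})
        if "source" not in df.columns:
            df["source"] = source
        return cls(df, variables)
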