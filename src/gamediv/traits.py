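"""Species-by-trait tables mixing numeric and categorical columns.

Each column carries a declared type (``numeric`` or ``categorical``),
supplied as a schema alongside the data; missing values are allowed and
handled downstream by Gower's pairwise-deletion weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import normalize_name

NUMERIC = "numeric"
CATEGORICAL = "categorical"


class ZeroVarianceError(ValueError):
    """A numeric trait with no variation cannot be standardized."""


@dataclass
class TraitTable:
    """Trait matrix (rows: species, index normalized) plus column schema."""

    data: pd.DataFrame
    schema: dict[str, str]

    def __post_init__(self):
        self.data = self.data.copy()
        self.data.index = [normalize_name(s) for s in self.data.index]
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate species: {', '.join(dups)}")
        if len(self.data) < 2:
            raise ValueError("need at least 2 species")
        if self.data.shape[1] < 1:
            raise ValueError("need at least 1 trait")
        unknown = set(self.data.columns) - set(self.schema)
        if unknown:
            raise ValueError(f"columns missing from schema: {sorted(unknown)}")
        for col in self.data.columns:
            kind = self.schema[col]
            if kind == NUMERIC:
                self.data[col] = pd.to_numeric(self.data[col], errors="raise")
            elif kind == CATEGORICAL:
                vals = self.data[col]
                self.data[col] = vals.where(vals.notna(), np.nan).astype(object)
            else:
                raise ValueError(f"column {col!r}: unknown type {kind!r}")
        all_missing = self.data.isna().all(axis=1)
        if all_missing.any():
            bad = list(self.data.index[all_missing])
            raise ValueError(f"species with all traits missing: {', '.join(bad)}")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def numeric_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.schema[c] == NUMERIC]

    def categorical_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.schema[c] == CATEGORICAL]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="species")


def standardize_traits(table: TraitTable) -> TraitTable:
    """Centre and scale numeric traits to mean 0 and sample SD 1.

    Categorical columns and the missingness pattern are untouched.  A
    numeric column with zero variance (or fewer than two observed values)
    raises :class:`ZeroVarianceError` naming the column.
    """
    data = table.data.copy()
    for col in table.numeric_columns():
        vals = data[col].astype(float)
        obs = vals.dropna()
        if len(obs) < 2:
            raise ZeroVarianceError(
                f"numeric trait {col!r} has fewer than 2 observed values"
            )
        sd = obs.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ZeroVarianceError(f"numeric trait {col!r} has zero variance")
        data[col] = (vals - obs.mean()) / sd
    return TraitTable(data, dict(table.schema))


def read_trait_csv(path, schema: dict[str, str] | str) -> TraitTable:
    """Read a trait CSV (first column species) with a column-type schema.

    ``schema`` is either a mapping or the path of a JSON sidecar
    ``{"column": "numeric" | "categorical", ...}``.
    """
    if not isinstance(schema, dict):
        with open(schema) as fh:
            schema = json.load(fh)
    data = pd.read_csv(path, index_col=0)
    return TraitTable(data, schema)
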