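"""Gower's distance for mixed numeric/categorical trait tables.

For species *i*, *j* and traits *k*:

    d(i, j) = sum_k delta_ijk * s_ijk / sum_k delta_ijk

where ``delta_ijk`` is 1 iff trait *k* is observed for both species
(pairwise deletion), ``s_ijk = |x_ik - x_jk| / range_k`` for a numeric
trait (range over the non-missing values of that column) and a simple
mismatch indicator for a categorical trait.  Distances therefore lie in
[0, 1] and are invariant to affine rescaling of any numeric column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traits import TraitTable


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")

    def __len__(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries in row-major (i > j) order."""
        idx = np.tril_indices(len(self.labels), k=-1)
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="species")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DistanceMatrix":
        return cls(list(frame.index), frame.values)


def gower_distance(table: TraitTable) -> DistanceMatrix:
    """Pairwise Gower distances between the species of a trait table."""
    species = table.species
    n = len(species)
    num = np.zeros((n, n))
    den = np.zeros((n, n))

    for col in table.data.columns:
        vals = table.data[col]
        if table.schema[col] == "numeric":
            x = vals.to_numpy(dtype=float)
            obs = np.isfinite(x)
            if obs.sum() == 0:
                continue
            rng = np.nanmax(x) - np.nanmin(x)
            if obs.sum() >= 2 and rng == 0:
                raise ValueError(f"numeric trait {col!r} has zero range")
            both = np.outer(obs, obs)
            with np.errstate(invalid="ignore"):
                diff = np.abs(x[:, None] - x[None, :]) / rng if rng > 0 else None
            if diff is None:
                continue
            num[both] += diff[both]
            den += both
        else:
            x = vals.to_numpy(dtype=object)
            obs = np.array([not pd.isna(v) for v in x])
            both = np.outer(obs, obs)
            mism = np.ones((n, n))
            eq = np.array(
                [[obs[i] and obs[j] and x[i] == x[j] for j in range(n)] for i in range(n)]
            )
            mism[eq] = 0.0
            num[both] += mism[both]
            den += both

    np.fill_diagonal(num, 0.0)
    uncovered = (den == 0) & ~np.eye(n, dtype=bool)
    if uncovered.any():
        pairs = [
            f"({species[i]}, {species[j]})"
            for i, j in zip(*np.where(np.tril(uncovered, k=-1)))
        ]
        raise ValueError(
            "species pairs share no jointly observed trait: " + ", ".join(pairs)
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # symmetrize away rounding noise
    return DistanceMatrix(species, d)
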