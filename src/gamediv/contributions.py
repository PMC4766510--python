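"""Per-species contributions to the total diversity of a tree.

Two metrics, applied both to phylogenies (ED, PC) and to functional
dendrograms (FD, FC):

* **distinctiveness** (ED / FD): the fair-proportion score -- the sum,
  over every branch on a species' root-to-tip path, of branch length
  divided by the number of tip species sharing that branch.  Summed over
  all species it recovers the total branch length exactly (fair-proportion
  conservation).
* **terminal contribution** (PC / FC): the species' own terminal branch
  length -- the diversity lost if exactly that one species is removed.

Raw scores are scaled by the total branch length ``T`` of the tree and
expressed as deviations from the equal-contribution share ``1/S``, which
makes assemblages of different richness directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .trees import Phylogeny

METRICS = ("ED", "PC", "FD", "FC")
#: metrics whose raw values sum to the total branch length
_CONSERVED = ("ED", "FD")


def total_branch_length(tree: Phylogeny) -> float:
    """Sum of all branch lengths, excluding any root edge."""
    return float(sum(tree.lengths[i] for i in range(tree.n_nodes) if i != 0))


def evolutionary_distinctiveness(tree: Phylogeny) -> pd.Series:
    """Raw fair-proportion score per species, in branch-length units."""
    counts = tree.tips_below()
    acc = np.zeros(tree.n_nodes)
    order = list(tree.preorder())
    for i in order:
        if i == 0:
            continue
        p = tree.parents[i]
        acc[i] = acc[p] + tree.lengths[i] / counts[i]
    values = {tree.tip_label[i]: acc[i] for i in tree.tip_label}
    return pd.Series(values, name="raw").sort_index()


def terminal_contribution(tree: Phylogeny) -> pd.Series:
    """Raw terminal branch length per species."""
    values = {tree.tip_label[i]: float(tree.lengths[i]) for i in tree.tip_label}
    return pd.Series(values, name="raw").sort_index()


@dataclass
class ContributionTable:
    """Raw, scaled and deviation-from-equal contributions for one metric."""

    metric: str
    raw: pd.Series
    scaled: pd.Series
    deviation: pd.Series
    total_length: float

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        s = float(self.scaled.sum())
        if self.metric in _CONSERVED:
            if abs(s - 1.0) > 1e-6:
                raise ValueError(f"{self.metric} scaled values sum to {s}, not 1")
        elif not -1e-9 <= s <= 1.0 + 1e-9:
            raise ValueError(f"{self.metric} scaled values sum to {s}, outside [0, 1]")
        if (self.raw < 0).any():
            raise ValueError("negative raw contribution")

    @property
    def n_species(self) -> int:
        return len(self.raw)

    @property
    def species(self) -> list[str]:
        return list(self.raw.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.raw.index,
                "metric": self.metric,
                "raw": self.raw.values,
                "scaled": self.scaled.values,
                "deviation": self.deviation.values,
            }
        )


def scale_contributions(
    raw: Mapping[str, float] | pd.Series, tree: Phylogeny, metric: str
) -> ContributionTable:
    """Scale raw contributions by total tree length and centre on 1/S."""
    raw = pd.Series(dict(raw)).sort_index().astype(float)
    labels = set(tree.tip_labels)
    if set(raw.index) != labels:
        raise ValueError("raw contribution keys do not match tree tip labels")
    total = total_branch_length(tree)
    if total <= 0:
        raise ValueError("total branch length is zero; scaling undefined")
    scaled = raw / total
    deviation = scaled - 1.0 / len(raw)
    return ContributionTable(metric, raw, scaled, deviation, total)


def phylo_contributions(tree: Phylogeny) -> dict[str, ContributionTable]:
    """ED and PC tables for one phylogeny."""
    return {
        "ED": scale_contributions(evolutionary_distinctiveness(tree), tree, "ED"),
        "PC": scale_contributions(terminal_contribution(tree), tree, "PC"),
    }


def write_contribution_tsv(tables: list[ContributionTable], path) -> None:
    """Long-format TSV: species, metric, raw, scaled, deviation."""
    frame = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    frame = frame.sort_values(["metric", "species"], kind="mergesort")
    frame.to_csv(path, sep="\t", index=False)
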