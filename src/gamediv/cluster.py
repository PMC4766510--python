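"""Agglomerative clustering of trait distances into functional dendrograms.

The dendrogram is the object the functional-diversity metrics are read
from: its node heights are half the merge distance, so the cophenetic
distance between two tips (twice the height of their lowest common
ancestor) reproduces the merge distance, and branch lengths are height
differences.  UPGMA, WPGMA, single and complete linkage are available;
the method is normally chosen by cophenetic correlation against the
original distances (:func:`select_linkage`).

Tie-break: when two candidate merges are at equal minimal distance (to
1e-12), the pair whose combined sorted leaf indices are lexicographically
smallest is merged first, making the merge order deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contributions import (
    ContributionTable,
    evolutionary_distinctiveness,
    scale_contributions,
    terminal_contribution,
)
from .gower import DistanceMatrix
from .trees import Phylogeny, read_newick

LINKAGE_METHODS = ("single", "complete", "upgma", "wpgma")
_TIE_TOL = 1e-12


@dataclass
class Dendrogram:
    """Ultrametric rooted tree produced by agglomerative clustering."""

    labels: list[str]
    method: str
    #: (leaf indices of cluster A, of cluster B, merge height) per merge
    merges: list[tuple[tuple[int, ...], tuple[int, ...], float]]
    #: full matrix of tree distances (2 x LCA height) between tips
    cophenetic: np.ndarray
    newick: str = field(repr=False, default="")

    @property
    def root_height(self) -> float:
        return self.merges[-1][2] if self.merges else 0.0

    def as_phylogeny(self) -> Phylogeny:
        return read_newick(self.newick)

    def total_branch_length(self) -> float:
        from .contributions import total_branch_length

        return total_branch_length(self.as_phylogeny())

    def to_newick(self) -> str:
        return self.newick


def _update_distance(method, d_ik, d_jk, n_i, n_j):
    if method == "single":
        return min(d_ik, d_jk)
    if method == "complete":
        return max(d_ik, d_jk)
    if method == "upgma":
        return (n_i * d_ik + n_j * d_jk) / (n_i + n_j)
    if method == "wpgma":
        return (d_ik + d_jk) / 2.0
    raise ValueError(f"unknown linkage method {method!r}")


def linkage_cluster(d: DistanceMatrix, method: str = "upgma") -> Dendrogram:
    """Cluster a distance matrix into an ultrametric dendrogram."""
    method = method.lower()
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage method {method!r}")
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 labels to cluster")

    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(d.values[i, j])

    members = {i: (i,) for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    frags = {i: d.labels[i].replace(" ", "_") for i in range(n)}
    active = set(range(n))
    coph = np.zeros((n, n))
    merges = []
    next_id = n

    def pair_key(a, b):
        return (a, b) if a < b else (b, a)

    while len(active) > 1:
        dmin = min(dist[pair_key(a, b)] for a in active for b in active if a < b)
        candidates = [
            (a, b)
            for a in sorted(active)
            for b in sorted(active)
            if a < b and dist[pair_key(a, b)] <= dmin + _TIE_TOL
        ]
        a, b = min(candidates, key=lambda p: tuple(sorted(members[p[0]] + members[p[1]])))
        h = dist[pair_key(a, b)] / 2.0
        mem_a, mem_b = members[a], members[b]
        for i in mem_a:
            for j in mem_b:
                coph[i, j] = coph[j, i] = 2.0 * h
        merges.append((tuple(sorted(mem_a)), tuple(sorted(mem_b)), h))
        frag = (
            f"({frags[a]}:{h - heights[a]:.17g},{frags[b]}:{h - heights[b]:.17g})"
        )
        new = next_id
        next_id += 1
        members[new] = tuple(sorted(mem_a + mem_b))
        heights[new] = h
        frags[new] = frag
        n_a, n_b = len(mem_a), len(mem_b)
        active.discard(a)
        active.discard(b)
        for k in active:
            d_ak = dist.pop(pair_key(a, k))
            d_bk = dist.pop(pair_key(b, k))
            dist[pair_key(new, k)] = _update_distance(method, d_ak, d_bk, n_a, n_b)
        dist.pop(pair_key(a, b))
        active.add(new)

    root = active.pop()
    return Dendrogram(
        labels=list(d.labels),
        method=method,
        merges=merges,
        cophenetic=coph,
        newick=frags[root] + ";",
    )


def cophenetic_distances(dend: Dendrogram) -> DistanceMatrix:
    return DistanceMatrix(list(dend.labels), dend.cophenetic.copy())


def cophenetic_correlation(d: DistanceMatrix, dend: Dendrogram) -> float:
    """Pearson correlation between observed and dendrogram distances."""
    if set(d.labels) != set(dend.labels):
        raise ValueError("distance matrix and dendrogram label sets differ")
    if len(d) < 3:
        raise ValueError("cophenetic correlation needs at least 3 labels")
    order = [dend.labels.index(lab) for lab in d.labels]
    coph = dend.cophenetic[np.ix_(order, order)]
    idx = np.tril_indices(len(d), k=-1)
    x, y = d.values[idx], coph[idx]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (constant) distance vector")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class LinkageSelection:
    method: str
    dendrogram: Dendrogram
    scores: dict[str, float]


def select_linkage(
    d: DistanceMatrix, candidates: tuple[str, ...] = LINKAGE_METHODS
) -> LinkageSelection:
    """Pick the linkage whose dendrogram best preserves the distances.

    All candidates are clustered and scored by cophenetic correlation;
    ties (and the degenerate all-equal case) go to the earliest candidate.
    """
    if not candidates:
        raise ValueError("no candidate linkage methods")
    scores: dict[str, float] = {}
    dendrograms: dict[str, Dendrogram] = {}
    for method in candidates:
        dend = linkage_cluster(d, method)
        dendrograms[method] = dend
        scores[method] = cophenetic_correlation(d, dend)
    best = max(candidates, key=lambda m: scores[m])
    # ties go to candidate-list order: max() already keeps the first argmax
    return LinkageSelection(best, dendrograms[best], scores)


def functional_contributions(
    dend: Dendrogram,
) -> tuple[ContributionTable, ContributionTable]:
    """FD and FC tables from a functional dendrogram.

    The algorithm is identical to ED / PC on a phylogeny, applied to the
    dendrogram's branches; FD raw values sum to the dendrogram's total
    branch length.
    """
    tree = dend.as_phylogeny()
    fd = scale_contributions(evolutionary_distinctiveness(tree), tree, "FD")
    fc = scale_contributions(terminal_contribution(tree), tree, "FC")
    return fd, fc
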