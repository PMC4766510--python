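"""Independent brute-force implementations used only as test oracles.

These deliberately avoid the traversal/update tricks of the package code:
fair proportion is computed by exhaustively enumerating ancestor edges
and subtree tips per species, and agglomerative linkage by recomputing
every cluster-pair distance from the raw matrix at every step.
"""

from __future__ import annotations

import numpy as np

from gamediv.trees import Phylogeny


def brute_force_fair_proportion(tree: Phylogeny) -> dict[str, float]:
    """ED by explicit ancestor-edge enumeration per tip."""
    out = {}
    for tip, label in tree.tip_label.items():
        total = 0.0
        node = tip
        while node != 0:
            # count tips under `node` exhaustively
            stack, n_desc = [node], 0
            while stack:
                j = stack.pop()
                if tree.is_tip(j):
                    n_desc += 1
                stack.extend(tree.children[j])
            total += tree.lengths[node] / n_desc
            node = tree.parents[node]
        out[label] = total
    return out


def brute_force_linkage(d: np.ndarray, method: str):
    """Merge heights and cophenetic matrix by direct recomputation.

    At every step the distance between two clusters is recomputed from
    the original matrix (mean over all cross pairs for UPGMA, min/max for
    single/complete); ties break on the lexicographically smallest sorted
    member union, matching the documented convention.
    """
    n = d.shape[0]
    clusters: list[tuple[int, ...]] = [(i,) for i in range(n)]
    coph = np.zeros((n, n))
    heights = []

    def cluster_dist(a, b):
        vals = [d[i, j] for i in a for j in b]
        if method == "single":
            return min(vals)
        if method == "complete":
            return max(vals)
        if method == "upgma":
            return float(np.mean(vals))
        raise ValueError(method)

    while len(clusters) > 1:
        pairs = [
            (cluster_dist(clusters[ai], clusters[bi]), ai, bi)
            for ai in range(len(clusters))
            for bi in range(ai + 1, len(clusters))
        ]
        dmin = min(p[0] for p in pairs)
        candidates = [p for p in pairs if p[0] <= dmin + 1e-12]
        dist, ai, bi = min(
            candidates, key=lambda p: tuple(sorted(clusters[p[1]] + clusters[p[2]]))
        )
        h = dist / 2.0
        heights.append(h)
        a, b = clusters[ai], clusters[bi]
        for i in a:
            for j in b:
                coph[i, j] = coph[j, i] = 2.0 * h
        clusters = [c for k, c in enumerate(clusters) if k not in (ai, bi)]
        clusters.append(tuple(sorted(a + b)))
    return heights, coph


def random_distance_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    m = rng.uniform(0.05, 1.0, size=(n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m
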