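"""Rooted phylogenies with branch lengths.

Trees are read from Newick text (via dendropy) and validated: every
non-root node must carry a non-negative branch length, tip labels must be
unique and non-empty after name normalization.  A branch length attached
to the root itself is recorded but plays no part in any downstream metric
-- no species "shares" an edge above the root.
"""

from __future__ import annotations

import re
from typing import Iterator

import dendropy


class NewickError(ValueError):
    """Malformed Newick text."""


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates the tree contract."""


def normalize_name(name: str) -> str:
    """Canonical species-name form used for matching across input files.

    Underscores become spaces, surrounding whitespace is stripped and
    internal whitespace collapsed.  Matching stays case-sensitive.
    """
    return re.sub(r"\s+", " ", str(name).replace("_", " ")).strip()


class Phylogeny:
    """A rooted tree held as flat parent/child arrays.

    Node 0 is the root.  ``lengths[i]`` is the length of the edge above
    node ``i`` (``None`` for the root; a root edge length from the input,
    if any, is kept in :attr:`root_edge_length`).
    """

    def __init__(
        self,
        children: list[list[int]],
        parents: list[int | None],
        lengths: list[float | None],
        tip_label: dict[int, str],
        root_edge_length: float | None = None,
    ):
        self.children = children
        self.parents = parents
        self.lengths = lengths
        self.tip_label = tip_label
        self.root_edge_length = root_edge_length
        self._validate()

    # -- construction ------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        children: list[list[int]] = [[] for _ in nodes]
        parents: list[int | None] = [None] * len(nodes)
        lengths: list[float | None] = [None] * len(nodes)
        tip_label: dict[int, str] = {}
        root_edge = nodes[0].edge.length if nodes else None
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parents[i] = p
                children[p].append(i)
                lengths[i] = nd.edge.length
            if nd.is_leaf():
                raw = None
                if nd.taxon is not None and nd.taxon.label is not None:
                    raw = nd.taxon.label
                elif nd.label:
                    raw = nd.label
                tip_label[i] = normalize_name(raw) if raw is not None else ""
        return cls(children, parents, lengths, tip_label, root_edge)

    # -- validation --------------------------------------------------

    def _node_description(self, i: int) -> str:
        if i in self.tip_label:
            return f"tip '{self.tip_label[i]}'"
        tips = sorted(self.tip_label[t] for t in self._subtree_tips(i))
        shown = ", ".join(tips[:3]) + ("..." if len(tips) > 3 else "")
        return f"internal node above [{shown}]"

    def _validate(self) -> None:
        if not self.children:
            raise TreeValidationError("empty tree")
        missing = [
            self._node_description(i)
            for i in range(self.n_nodes)
            if i != 0 and self.lengths[i] is None
        ]
        if missing:
            raise TreeValidationError(
                "nodes missing branch lengths: " + "; ".join(missing)
            )
        negative = [
            self._node_description(i)
            for i in range(self.n_nodes)
            if i != 0 and self.lengths[i] is not None and self.lengths[i] < 0
        ]
        if negative:
            raise TreeValidationError(
                "negative branch lengths on: " + "; ".join(negative)
            )
        labels = list(self.tip_label.values())
        if any(lab == "" for lab in labels):
            raise TreeValidationError("empty tip label")
        seen: set[str] = set()
        dups = set()
        for lab in labels:
            if lab in seen:
                dups.add(lab)
            seen.add(lab)
        if dups:
            raise TreeValidationError(
                "duplicate tip labels after normalization: " + ", ".join(sorted(dups))
            )

    # -- basic accessors ---------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def n_tips(self) -> int:
        return len(self.tip_label)

    @property
    def tip_labels(self) -> list[str]:
        return sorted(self.tip_label.values())

    def is_tip(self, i: int) -> bool:
        return i in self.tip_label

    def preorder(self) -> Iterator[int]:
        stack = [0]
        while stack:
            i = stack.pop()
            yield i
            stack.extend(reversed(self.children[i]))

    def postorder(self) -> Iterator[int]:
        yield from reversed(list(self.preorder()))

    def _subtree_tips(self, i: int) -> list[int]:
        out, stack = [], [i]
        while stack:
            j = stack.pop()
            if self.is_tip(j):
                out.append(j)
            stack.extend(self.children[j])
        return out

    def tips_below(self) -> list[int]:
        """Number of tip species descending from (or equal to) each node."""
        counts = [0] * self.n_nodes
        for i in self.postorder():
            if self.is_tip(i):
                counts[i] = 1
            else:
                counts[i] = sum(counts[c] for c in self.children[i])
        return counts

    # -- output ------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            if self.is_tip(i):
                body = self.tip_label[i].replace(" ", "_")
            else:
                body = "(" + ",".join(fmt(c) for c in self.children[i]) + ")"
            if i == 0:
                if self.root_edge_length is not None:
                    return f"{body}:{self.root_edge_length:.17g}"
                return body
            return f"{body}:{self.lengths[i]:.17g}"

        return fmt(0) + ";"


def read_newick(text: str) -> Phylogeny:
    """Parse one rooted Newick tree with mandatory branch lengths.

    Raises :class:`NewickError` on malformed input (the message carries the
    parser's position report) and :class:`TreeValidationError` for missing
    or negative branch lengths, duplicate or empty tip labels.
    """
    if not text or not text.strip():
        raise NewickError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise NewickError(f"malformed Newick: {exc}") from exc
    if dtree.seed_node is None:
        raise NewickError("no tree found in input")
    return Phylogeny.from_dendropy(dtree)


def read_newick_file(path) -> Phylogeny:
    with open(path) as fh:
        return read_newick(fh.read())
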