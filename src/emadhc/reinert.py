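"""Reinert-style descending hierarchical classification (DHC).

The algorithm recursively bipartitions the binary unit x form matrix.  Each
split maximizes phi2 = chi2/n of the 2 x V contingency table obtained by
summing the rows of the two sides (n is that table's grand total).  The
initial cut comes from a correspondence analysis of the sub-table: units
are ordered by their first-axis row coordinate and all contiguous cuts are
scanned.  The cut is then refined by a deterministic hill climb that moves
one unit at a time whenever the move strictly increases phi2.

Splitting proceeds top-down: the root is split, then each of its two
children, and thereafter the largest remaining leaf, until the requested
number of terminal leaves exists or nothing is splittable.  Finally, leaves
smaller than ceil(n_texts / n_requested) are pruned and their units
declared unclassified.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from emadhc.lexicon import LexicalTable


class ParameterError(ValueError):
    """Invalid algorithm parameter."""


class DegenerateSplitError(ValueError):
    """A contingency side has an all-zero margin."""


# --- phi2 ------------------------------------------------------------------


def phi2(top_margin: Sequence[float], bottom_margin: Sequence[float]) -> float:
    """chi2/n of the 2 x V table with rows ``top_margin``, ``bottom_margin``.

    Columns with zero total contribute 0.  For a two-row table the value is
    bounded by 1.  Raises :class:`DegenerateSplitError` if either side sums
    to zero.
    """
    a = np.asarray(top_margin, dtype=float)
    b = np.asarray(bottom_margin, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("margins must be one-dimensional vectors of equal length")
    if a.sum() <= 0 or b.sum() <= 0:
        raise DegenerateSplitError("one side of the split has an all-zero margin")
    return _phi2(a, b)


def _phi2(a: np.ndarray, b: np.ndarray) -> float:
    """phi2 without validation; zero-total columns are skipped."""
    ra = a.sum()
    rb = b.sum()
    n = ra + rb
    c = a + b
    mask = c > 0
    cm = c[mask]
    ea = ra * cm / n
    eb = rb * cm / n
    chi2 = float(((a[mask] - ea) ** 2 / ea).sum() + ((b[mask] - eb) ** 2 / eb).sum())
    return chi2 / n


def _phi2_prefixes(cum: np.ndarray, total: np.ndarray) -> np.ndarray:
    """phi2 of every contiguous prefix/suffix cut, vectorized.

    ``cum`` holds cumulative row sums of the ordered sub-table; row k of the
    result is the phi2 of cutting after ordered position k (k = 0..n-2).
    """
    A = cum[:-1, :].astype(float)
    B = total[None, :] - A
    n = float(total.sum())
    ra = A.sum(axis=1, keepdims=True)
    rb = n - ra
    c = total[None, :].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ea = ra * c / n
        eb = rb * c / n
        terms = np.where(ea > 0, (A - ea) ** 2 / np.where(ea > 0, ea, 1.0), 0.0)
        terms += np.where(eb > 0, (B - eb) ** 2 / np.where(eb > 0, eb, 1.0), 0.0)
    return terms.sum(axis=1) / n


# --- correspondence-analysis ordering --------------------------------------


def ca_first_axis_coordinates(X: np.ndarray) -> np.ndarray | None:
    """First-axis row standard coordinates of a binary table.

    SVD of the standardized residual matrix of the row/column profiles.
    Returns ``None`` when the table has no non-trivial axis (e.g. all rows
    identical).  The sign is canonicalized so that the first row with a
    nonzero coordinate is negative.
    """
    X = X.astype(float)
    n = X.sum()
    r = X.sum(axis=1) / n
    c = X.sum(axis=0) / n
    keep = c > 0
    Xk = X[:, keep]
    ck = c[keep]
    P = Xk / n
    expected = np.outer(r, ck)
    S = (P - expected) / np.sqrt(expected)
    try:
        U, s, _ = np.linalg.svd(S, full_matrices=False)
    except np.linalg.LinAlgError:  # pragma: no cover - numerical safety net
        return None
    if s.size == 0 or s[0] < 1e-10:
        return None
    coords = U[:, 0] / np.sqrt(r)
    for value in coords:
        if abs(value) > 1e-10:
            if value > 0:
                coords = -coords
            break
    return coords


# --- split containers ------------------------------------------------------


@dataclass
class SplitResult:
    """One optimized bipartition of a set of text units."""

    left_units: tuple[str, ...]
    right_units: tuple[str, ...]
    phi2: float
    n_reassignment_passes: int = 0
    converged: bool = True
    degenerate: bool = False
    initial_phi2: float = 0.0
    phi2_trace: list[float] = field(default_factory=list)

    @classmethod
    def degenerate_split(cls) -> "SplitResult":
        return cls(left_units=(), right_units=(), phi2=0.0, degenerate=True)


def initial_bipartition(table: LexicalTable) -> SplitResult:
    """Correspondence-analysis seeded cut of one cluster's sub-table.

    Units are ordered by their first-axis row coordinate (ties broken by
    row position for determinism); every contiguous cut is evaluated and
    the phi2-maximal one is returned.  A rank-deficient sub-table (no
    lexical variation) yields a result with ``degenerate=True``.
    """
    X = np.asarray(table.cells, dtype=float)
    if X.shape[0] < 2:
        return SplitResult.degenerate_split()
    coords = ca_first_axis_coordinates(X)
    if coords is None:
        return SplitResult.degenerate_split()
    order = np.lexsort((np.arange(len(coords)), coords))
    cum = np.cumsum(X[order], axis=0)
    total = cum[-1]
    values = _phi2_prefixes(cum, total)
    # maximal phi2; exact ties (common on block-separable tables) resolved
    # toward the most balanced cut, then the lowest cut index
    ties = np.flatnonzero(values >= values.max() - 1e-12)
    k = int(ties[np.argmin(np.abs((ties + 1) - X.shape[0] / 2))])
    left_idx = order[: k + 1]
    right_idx = order[k + 1 :]
    ids = np.asarray(table.unit_ids, dtype=object)
    value = float(values[k])
    return SplitResult(
        left_units=tuple(ids[left_idx]),
        right_units=tuple(ids[right_idx]),
        phi2=value,
        initial_phi2=value,
    )


def refine_bipartition(
    table: LexicalTable, split: SplitResult, max_passes: int = 200
) -> SplitResult:
    """Hill-climb the bipartition by single-unit moves.

    Sweeps units in ascending unit-id order; a move to the other side is
    kept only if it strictly increases phi2 and does not empty a side.
    Terminates when a full sweep accepts no move.  Accepted phi2 values are
    recorded in ``phi2_trace`` (strictly increasing).
    """
    if split.degenerate:
        return split
    X = np.asarray(table.cells, dtype=float)
    index = {uid: i for i, uid in enumerate(table.unit_ids)}
    in_left = np.zeros(X.shape[0], dtype=bool)
    for uid in split.left_units:
        in_left[index[uid]] = True
    for uid in split.right_units:
        if uid not in index:
            raise ParameterError(f"unit {uid!r} not in table")

    a = X[in_left].sum(axis=0)
    b = X[~in_left].sum(axis=0)
    n_left = int(in_left.sum())
    n_right = X.shape[0] - n_left
    current = _phi2(a, b)
    trace: list[float] = []
    sweep_order = sorted(range(X.shape[0]), key=lambda i: table.unit_ids[i])

    passes = 0
    converged = False
    while passes < max_passes:
        passes += 1
        accepted_any = False
        for i in sweep_order:
            x = X[i]
            if in_left[i]:
                if n_left == 1:
                    continue
                candidate = _phi2(a - x, b + x)
                if candidate > current + 1e-12:
                    a -= x
                    b += x
                    in_left[i] = False
                    n_left -= 1
                    n_right += 1
                    current = candidate
                    trace.append(candidate)
                    accepted_any = True
            else:
                if n_right == 1:
                    continue
                candidate = _phi2(a + x, b - x)
                if candidate > current + 1e-12:
                    a += x
                    b -= x
                    in_left[i] = True
                    n_left += 1
                    n_right -= 1
                    current = candidate
                    trace.append(candidate)
                    accepted_any = True
        if not accepted_any:
            converged = True
            break

    ids = np.asarray(table.unit_ids, dtype=object)
    return SplitResult(
        left_units=tuple(ids[in_left]),
        right_units=tuple(ids[~in_left]),
        phi2=current,
        n_reassignment_passes=passes,
        converged=converged,
        initial_phi2=split.initial_phi2,
        phi2_trace=trace,
    )


# --- tree ------------------------------------------------------------------


@dataclass
class DHCNode:
    node_id: int
    unit_ids: tuple[str, ...]
    depth: int
    parent: int | None = None
    children: tuple[int, int] | None = None
    phi2: float | None = None
    frozen: bool = False
    pruned: bool = False

    @property
    def size(self) -> int:
        return len(self.unit_ids)

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class DHCTree:
    """Binary cluster tree produced by :func:`run_dhc`.

    Leaves are terminal clusters; ``pruned`` leaves (marked by
    :func:`prune_small_clusters`) contribute their units to
    ``unclassified_units`` instead of the classification.
    """

    nodes: dict[int, DHCNode]
    root_id: int
    requested_terminal_clusters: int
    unclassifiable_units: list[str] = field(default_factory=list)
    min_cluster_size: int = 1
    n_corpus_texts: int = 0

    def leaves(self) -> list[DHCNode]:
        return [node for node in self.nodes.values() if node.is_leaf]

    def kept_leaves(self) -> list[DHCNode]:
        return [node for node in self.leaves() if not node.pruned]

    @property
    def unclassified_units(self) -> list[str]:
        out: list[str] = []
        for node in self.leaves():
            if node.pruned:
                out.extend(node.unit_ids)
        return out

    @property
    def classification_rate(self) -> float:
        total = self.n_corpus_texts
        if total == 0:
            return 0.0
        kept = sum(node.size for node in self.kept_leaves())
        return kept / total

    def assignment(self) -> dict[str, int]:
        """unit id -> kept-leaf node id (pruned/unclassifiable units absent)."""
        out: dict[str, int] = {}
        for node in self.kept_leaves():
            for uid in node.unit_ids:
                out[uid] = node.node_id
        return out

    def to_json(self) -> str:
        payload = {
            "root_id": self.root_id,
            "requested_terminal_clusters": self.requested_terminal_clusters,
            "min_cluster_size": self.min_cluster_size,
            "n_corpus_texts": self.n_corpus_texts,
            "classification_rate": self.classification_rate,
            "unclassifiable_units": list(self.unclassifiable_units),
            "nodes": [
                {
                    "node_id": node.node_id,
                    "parent": node.parent,
                    "children": list(node.children) if node.children else None,
                    "depth": node.depth,
                    "size": node.size,
                    "phi2": node.phi2,
                    "is_leaf": node.is_leaf,
                    "frozen": node.frozen,
                    "pruned": node.pruned,
                    "unit_ids": list(node.unit_ids) if node.is_leaf else None,
                }
                for node in sorted(self.nodes.values(), key=lambda n: n.node_id)
            ],
        }
        return json.dumps(payload, indent=2)

    def to_newick(self) -> str:
        """Newick string; leaves labelled ``c<id>_n<size>``, internal nodes
        ``n<size>``, branch length = the parent split's phi2."""

        def render(node_id: int) -> str:
            node = self.nodes[node_id]
            length = 0.0
            if node.parent is not None:
                parent_phi2 = self.nodes[node.parent].phi2 or 0.0
                length = parent_phi2
            if node.is_leaf:
                flag = "pruned_" if node.pruned else ""
                return f"{flag}c{node.node_id}_n{node.size}:{length:.6f}"
            left, right = node.children
            return f"({render(left)},{render(right)})n{node.size}:{length:.6f}"

        return render(self.root_id) + ";"


def min_cluster_size(n_corpus_texts: int, n_requested: int) -> int:
    """Minimum size for a terminal cluster to be kept:
    ``ceil(n_corpus_texts / n_requested)``."""
    if n_requested < 1:
        raise ParameterError("n_requested must be >= 1")
    return math.ceil(n_corpus_texts / n_requested)


def _split_leaf(table: LexicalTable, node: DHCNode) -> SplitResult:
    sub = table.subset(node.unit_ids)
    split = initial_bipartition(sub)
    if split.degenerate:
        return split
    return refine_bipartition(sub, split)


def run_dhc(
    table: LexicalTable,
    n_terminal: int = 20,
    min_split_size: int = 2,
    n_corpus_texts: int | None = None,
) -> DHCTree:
    """Build the descending hierarchical classification tree.

    The root is split first, and thereafter the largest splittable leaf
    (ties broken by node creation order) until ``n_terminal`` leaves exist
    or no leaf is splittable.  Each split is an
    initial correspondence-analysis cut followed by the phi2 hill climb.
    Leaves below ``min_split_size`` units or without lexical variation are
    frozen.

    ``n_corpus_texts`` defaults to the number of table units plus the
    table's unclassifiable units, and is the denominator of the
    classification rate.
    """
    if n_terminal < 2:
        raise ParameterError("n_terminal must be >= 2")
    if table.n_units == 0:
        raise ParameterError("table is empty")
    if n_corpus_texts is None:
        n_corpus_texts = table.n_units + len(table.unclassifiable_units)

    nodes: dict[int, DHCNode] = {}
    next_id = 0

    def new_node(unit_ids: tuple[str, ...], depth: int, parent: int | None) -> DHCNode:
        nonlocal next_id
        node = DHCNode(node_id=next_id, unit_ids=tuple(unit_ids), depth=depth, parent=parent)
        nodes[next_id] = node
        next_id += 1
        return node

    root = new_node(tuple(table.unit_ids), 0, None)

    def try_split(node: DHCNode) -> tuple[DHCNode, DHCNode] | None:
        if node.size < max(2, min_split_size):
            node.frozen = True
            return None
        split = _split_leaf(table, node)
        if split.degenerate:
            node.frozen = True
            return None
        node.phi2 = split.phi2
        left = new_node(split.left_units, node.depth + 1, node.node_id)
        right = new_node(split.right_units, node.depth + 1, node.node_id)
        node.children = (left.node_id, right.node_id)
        return left, right

    # Root split, then always the largest splittable leaf (ties broken by
    # creation order).  Right after the root split its two children are the
    # only leaves, so both are split before any grandchild of comparable
    # size.
    try_split(root)
    while _leaf_count(nodes) < n_terminal:
        candidates = [
            node
            for node in nodes.values()
            if node.is_leaf and not node.frozen and node.size >= max(2, min_split_size)
        ]
        if not candidates:
            break
        target = max(candidates, key=lambda node: (node.size, -node.node_id))
        if try_split(target) is None:
            continue

    return DHCTree(
        nodes=nodes,
        root_id=root.node_id,
        requested_terminal_clusters=n_terminal,
        unclassifiable_units=list(table.unclassifiable_units),
        n_corpus_texts=n_corpus_texts,
    )


def _leaf_count(nodes: dict[int, DHCNode]) -> int:
    return sum(1 for node in nodes.values() if node.is_leaf)


def prune_small_clusters(
    tree: DHCTree, n_corpus_texts: int | None = None, n_requested: int | None = None
) -> DHCTree:
    """Mark leaves smaller than ``ceil(n_corpus_texts / n_requested)`` as
    pruned; their units become unclassified.  Returns the tree (mutated in
    place) with ``min_cluster_size`` and the classification rate updated."""
    if n_corpus_texts is None:
        n_corpus_texts = tree.n_corpus_texts
    if n_requested is None:
        n_requested = tree.requested_terminal_clusters
    threshold = min_cluster_size(n_corpus_texts, n_requested)
    tree.min_cluster_size = threshold
    tree.n_corpus_texts = n_corpus_texts
    for node in tree.leaves():
        node.pruned = node.size < threshold
    return tree
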