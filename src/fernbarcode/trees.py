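"""Unrooted trees, bipartitions, Newick I/O, consensus and monophyly.

A tree is stored as an adjacency map over integer node ids; leaves are
``0..n-1`` in the order of ``leaf_names``. Internal edges are exposed as
*splits*: integer bitmasks over leaf indices, normalised so that leaf 0
is never in the masked side. A :class:`SupportTree` additionally carries
bootstrap percentages per split (and, for bootstrap consensus trees, the
frequencies of every split observed across replicates).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .errors import ValidationError

__all__ = [
    "Tree",
    "SupportTree",
    "NOT_A_CLADE",
    "group_support",
    "majority_consensus",
    "splits_from_adj",
]


class _NotAClade:
    """Sentinel: the queried group is not a bipartition of the tree."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NOT_A_CLADE"

    def __bool__(self) -> bool:
        return False


NOT_A_CLADE = _NotAClade()

_NEEDS_QUOTE = set(" ()[]':;,")


def _quote(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


class Tree:
    """Unrooted tree with uniquely labelled leaves (polytomies allowed)."""

    def __init__(self, leaf_names: Sequence[str], adjacency: Mapping[int, Iterable[int]]):
        self.leaf_names = tuple(leaf_names)
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ValidationError("leaf labels must be unique")
        self.adjacency: dict[int, tuple[int, ...]] = {
            int(u): tuple(int(v) for v in vs) for u, vs in adjacency.items()
        }
        n = len(self.leaf_names)
        for i in range(n):
            if len(self.adjacency.get(i, ())) != 1 and n > 1:
                raise ValidationError(f"leaf {i} must have exactly one neighbour")
        self._splits: frozenset[int] | None = None

    # -- constructors --------------------------------------------------
    @classmethod
    def from_engine_adj(cls, adj: np.ndarray, leaf_names: Sequence[str]) -> "Tree":
        adjacency = {
            u: tuple(int(v) for v in row if v >= 0)
            for u, row in enumerate(np.asarray(adj))
            if any(v >= 0 for v in row)
        }
        return cls(leaf_names, adjacency)

    @classmethod
    def from_newick(cls, newick: str, leaf_order: Sequence[str] | None = None) -> "Tree":
        tree, _ = _parse_newick(newick, leaf_order, cls)
        return tree

    # -- basic structure ----------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def degree(self, u: int) -> int:
        return len(self.adjacency.get(u, ()))

    @property
    def is_binary(self) -> bool:
        return all(
            self.degree(u) == 3 for u in self.adjacency if u >= self.n_leaves
        )

    def _side_mask(self, u: int, away_from: int) -> int:
        """Bitmask of leaves reachable from ``u`` without crossing ``away_from``."""
        mask = 0
        stack = [(u, away_from)]
        while stack:
            node, parent = stack.pop()
            if node < self.n_leaves:
                mask |= 1 << node
                continue
            for v in self.adjacency[node]:
                if v != parent:
                    stack.append((v, node))
        return mask

    def splits(self) -> frozenset[int]:
        """Normalised bitmasks of all internal edges (leaf 0 excluded side)."""
        if self._splits is None:
            n = self.n_leaves
            full = (1 << n) - 1
            out = set()
            for u, vs in self.adjacency.items():
                if u < n:
                    continue
                for v in vs:
                    if v < n or v < u:
                        continue
                    mask = self._side_mask(v, u)
                    if mask & 1:
                        mask = full ^ mask
                    out.add(mask)
            self._splits = frozenset(out)
        return self._splits

    def mask_of(self, group: Iterable[str]) -> int:
        idx = {nm: i for i, nm in enumerate(self.leaf_names)}
        mask = 0
        for g in group:
            if g not in idx:
                raise ValidationError(f"unknown leaf {g!r}")
            mask |= 1 << idx[g]
        return mask

    def topology_key(self) -> tuple:
        """Hashable identity of the unrooted topology (label based)."""
        order = tuple(sorted(self.leaf_names))
        remap = {self.leaf_names.index(nm): i for i, nm in enumerate(order)}
        n = self.n_leaves
        full = (1 << n) - 1

        def renorm(mask: int) -> int:
            out = 0
            for i in range(n):
                if mask >> i & 1:
                    out |= 1 << remap[i]
            if out & 1:
                out = full ^ out
            return out

        return (order, frozenset(renorm(m) for m in self.splits()))

    # -- Newick --------------------------------------------------------
    def to_newick(self, support: Mapping[int, float] | None = None) -> str:
        n = self.n_leaves
        if n == 1:
            return f"{_quote(self.leaf_names[0])};"
        if n == 2:
            return f"({_quote(self.leaf_names[0])},{_quote(self.leaf_names[1])});"
        full = (1 << n) - 1

        def rec(u: int, parent: int) -> tuple[str, int]:
            if u < n:
                return _quote(self.leaf_names[u]), 1 << u
            parts = []
            mask = 0
            for v in self.adjacency[u]:
                if v == parent:
                    continue
                s, m = rec(v, u)
                parts.append(s)
                mask |= m
            label = ""
            if support is not None:
                key = full ^ mask if mask & 1 else mask
                if key in support:
                    label = format(round(support[key], 2), "g")
            return "(" + ",".join(parts) + ")" + label, mask

        root = self.adjacency[0][0]
        parts = [_quote(self.leaf_names[0])]
        for v in self.adjacency[root]:
            if v != 0:
                parts.append(rec(v, root)[0])
        return "(" + ",".join(parts) + ");"


class SupportTree(Tree):
    """Tree whose internal edges carry bootstrap percentages in [0, 100].

    ``split_frequencies`` (when present) records the percentage of
    bootstrap replicates containing *every* observed split, including
    those below the consensus threshold; identification queries use it
    to read support for groups that did not make the consensus.
    """

    def __init__(
        self,
        leaf_names: Sequence[str],
        adjacency: Mapping[int, Iterable[int]],
        support: Mapping[int, float],
        split_frequencies: Mapping[int, float] | None = None,
    ):
        super().__init__(leaf_names, adjacency)
        self.support = dict(support)
        for mask, pct in self.support.items():
            if not 0.0 <= pct <= 100.0:
                raise ValidationError(f"support {pct} outside [0, 100]")
        self.split_frequencies = dict(split_frequencies or {})

    @classmethod
    def from_newick(
        cls, newick: str, leaf_order: Sequence[str] | None = None
    ) -> "SupportTree":
        tree, support = _parse_newick(newick, leaf_order, Tree)
        return cls(tree.leaf_names, tree.adjacency, support)

    def frequency(self, group: Iterable[str]) -> float:
        """Bootstrap % of the bipartition separating ``group`` (0 if unseen)."""
        group = list(group)
        n = self.n_leaves
        if len(group) in (1, n - 1):
            return 100.0
        mask = self.mask_of(group)
        if mask & 1:
            mask = ((1 << n) - 1) ^ mask
        if self.split_frequencies:
            return self.split_frequencies.get(mask, 0.0)
        return self.support.get(mask, 0.0)

    def to_newick(self, support: Mapping[int, float] | None = None) -> str:
        return super().to_newick(self.support if support is None else support)


def group_support(st: SupportTree, group: Iterable[str]):
    """Support of ``group`` as a clade of the (consensus) tree.

    Singleton groups (and complements of singletons) are trivially
    monophyletic and return 100. If no internal edge of the tree splits
    off exactly ``group``, returns :data:`NOT_A_CLADE`.
    """
    group = set(group)
    leaves = set(st.leaf_names)
    if not group or not group <= leaves:
        raise ValidationError("group must be a non-empty subset of the leaves")
    if group == leaves:
        raise ValidationError("group must be a proper subset of the leaves")
    if len(group) == 1 or len(group) == len(leaves) - 1:
        return 100.0
    mask = st.mask_of(group)
    n = st.n_leaves
    if mask & 1:
        mask = ((1 << n) - 1) ^ mask
    if mask in st.splits():
        return st.support.get(mask, 100.0)
    return NOT_A_CLADE


# ---------------------------------------------------------------------------
# Newick parsing (via dendropy)


def _parse_newick(newick: str, leaf_order, tree_cls):
    dt = dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    leaf_labels = [lf.taxon.label for lf in dt.leaf_node_iter()]
    names = list(leaf_order) if leaf_order is not None else sorted(leaf_labels)
    if set(names) != set(leaf_labels):
        raise ValidationError("leaf_order does not match the newick leaf set")
    index = {nm: i for i, nm in enumerate(names)}
    n = len(names)
    full = (1 << n) - 1

    node_id: dict = {}
    next_id = n
    for nd in dt.preorder_node_iter():
        if nd.is_leaf():
            node_id[nd] = index[nd.taxon.label]
        else:
            node_id[nd] = next_id
            next_id += 1
    adjacency: dict[int, list[int]] = defaultdict(list)
    support: dict[int, float] = {}
    for nd in dt.preorder_node_iter():
        for ch in nd.child_nodes():
            adjacency[node_id[nd]].append(node_id[ch])
            adjacency[node_id[ch]].append(node_id[nd])
        if not nd.is_leaf() and nd.parent_node is not None and nd.label:
            try:
                pct = float(nd.label)
            except ValueError:
                pct = None
            if pct is not None:
                mask = 0
                for lf in nd.leaf_iter():
                    mask |= 1 << index[lf.taxon.label]
                if mask & 1:
                    mask = full ^ mask
                support[mask] = pct
    # suppress degree-2 nodes (a rooted newick's root)
    for u in [u for u in list(adjacency) if u >= n and len(adjacency[u]) == 2]:
        a, b = adjacency.pop(u)
        adjacency[a] = [b if v == u else v for v in adjacency[a]]
        adjacency[b] = [a if v == u else v for v in adjacency[b]]
    return tree_cls(names, adjacency), support


# ---------------------------------------------------------------------------
# Consensus


def majority_consensus(
    split_frequencies: Mapping[int, float],
    leaf_names: Sequence[str],
    threshold: float = 0.5,
) -> SupportTree:
    """Majority-rule consensus from split frequencies (percentages).

    Keeps exactly the splits occurring in strictly more than
    ``threshold`` (a fraction, default 0.5) of replicates; such splits
    are always pairwise compatible, so the tree exists and is unique.
    """
    if not 0.5 <= threshold <= 1.0:
        raise ValidationError("consensus threshold must be in [0.5, 1]")
    n = len(leaf_names)
    chosen = sorted(
        (m for m, f in split_frequencies.items() if f > 100.0 * threshold),
        key=lambda m: -bin(m).count("1"),
    )
    root = n
    node_of = {m: n + 1 + i for i, m in enumerate(chosen)}
    adjacency: dict[int, list[int]] = defaultdict(list)

    def parent_of(mask: int, start: int) -> int:
        # smallest chosen superset strictly containing mask; chosen is
        # sorted by size descending, so scan from the end
        for j in range(start - 1, -1, -1):
            sup = chosen[j]
            if sup != mask and (mask | sup) == sup:
                return node_of[sup]
        return root

    for i, m in enumerate(chosen):
        par = parent_of(m, i)
        adjacency[par].append(node_of[m])
        adjacency[node_of[m]].append(par)
    for leaf in range(n):
        if leaf == 0:
            par = root
        else:
            par = root
            for m in reversed(chosen):  # smallest first
                if m >> leaf & 1:
                    par = node_of[m]
                    break
        adjacency[par].append(leaf)
        adjacency[leaf].append(par)
    # suppress a degree-2 root (happens when one split covers all but leaf 0)
    if len(adjacency[root]) == 2:
        a, b = adjacency.pop(root)
        adjacency[a] = [b if v == root else v for v in adjacency[a]]
        adjacency[b] = [a if v == root else v for v in adjacency[b]]
    support = {m: split_frequencies[m] for m in chosen}
    return SupportTree(
        leaf_names, adjacency, support, split_frequencies=dict(split_frequencies)
    )


def splits_from_adj(adj: np.ndarray, n_leaves: int) -> frozenset[int]:
    """Normalised splits of an engine adjacency array."""
    full = (1 << n_leaves) - 1
    out = set()
    adj = np.asarray(adj)
    for u in range(n_leaves, adj.shape[0]):
        for v in adj[u]:
            if v < n_leaves or v < u:
                continue
            mask = 0
            stack = [(int(v), u)]
            while stack:
                node, parent = stack.pop()
                if node < n_leaves:
                    mask |= 1 << node
                    continue
                for w in adj[node]:
                    if w >= 0 and w != parent:
                        stack.append((int(w), node))
            if mask & 1:
                mask = full ^ mask
            out.add(mask)
    return frozenset(out)
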