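"""Equal-weights maximum parsimony: Fitch length, search, bootstrap.

The matrix is encoded as 4-bit state-set masks so ambiguity codes keep
their full base set and gaps/missing data are the complete set (they can
never force a change). Constant-compatible site patterns — those whose
state sets share a common base across all taxa — cost zero on every
topology and are removed up front, with the original site count retained
for bootstrap resampling; duplicate patterns collapse into one weighted
column. Fitch lengths are therefore exact, not approximations.

``heuristic_search`` follows the classic PAUP*-style recipe: repeated
random-addition-order stepwise building, each followed by hill-climbing
branch swapping (SPR by default, NNI available). ``exhaustive_search``
enumerates every unrooted binary topology (up to 9 taxa) and serves as
the correctness oracle for the heuristic. ``bootstrap_consensus``
resamples sites with replacement, reruns the heuristic per replicate,
and summarises bipartition frequencies as a majority-rule consensus;
replicates with several co-optimal trees split their unit vote evenly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import _engine
from .alignment import CharacterKind, CombinedMatrix
from .errors import ValidationError
from .markers import STATE_MASKS
from .trees import SupportTree, Tree, majority_consensus, splits_from_adj

__all__ = [
    "SearchConfig",
    "FULL_DATABASE_SEARCH",
    "QUERY_SEARCH",
    "ParsimonyMatrix",
    "fitch_length",
    "SearchResult",
    "exhaustive_search",
    "heuristic_search",
    "bootstrap_consensus",
    "n_unrooted_topologies",
]

_INDEL_MASK = {"0": 1, "1": 2, "?": 3, "-": 3}


@dataclass(frozen=True)
class SearchConfig:
    """Settings for heuristic search and bootstrapping.

    The conventional full-scale settings are 1000 bootstrap replicates
    with 100 addition cycles each for database assessment and 20
    replicates for per-query identification (:data:`FULL_DATABASE_SEARCH`,
    :data:`QUERY_SEARCH`); the plain defaults are desk-scale.
    """

    n_addition_cycles: int = 10
    swap: str = "spr"  # "spr" | "nni"
    n_bootstrap: int = 100
    consensus_threshold: float = 0.5
    seed: int = 0
    max_trees: int = 100
    max_swap_rounds: int = 50

    def __post_init__(self) -> None:
        if self.n_addition_cycles < 1:
            raise ValidationError("n_addition_cycles must be >= 1")
        if not 0.5 <= self.consensus_threshold <= 1.0:
            raise ValidationError("consensus_threshold must be in [0.5, 1]")
        if self.swap not in {"spr", "nni"}:
            raise ValidationError(
                f"swap {self.swap!r} unsupported (available: 'spr', 'nni')"
            )


FULL_DATABASE_SEARCH = SearchConfig(n_addition_cycles=100, n_bootstrap=1000)
QUERY_SEARCH = SearchConfig(n_addition_cycles=100, n_bootstrap=20)


class ParsimonyMatrix:
    """Encoded taxa x site-pattern matrix with integer pattern weights."""

    def __init__(self, taxa: Sequence[str], masks: np.ndarray, n_sites: int | None = None):
        self.taxa = list(taxa)
        masks = np.asarray(masks, dtype=np.uint8)
        if masks.ndim != 2 or masks.shape[0] != len(self.taxa):
            raise ValidationError("mask matrix must be (n_taxa, n_chars)")
        self.n_sites = int(n_sites if n_sites is not None else masks.shape[1])
        # drop zero-cost patterns (common base shared by all taxa)
        if masks.shape[1]:
            common = masks[0].copy()
            for row in masks[1:]:
                common &= row
            keep = common == 0
            masks = masks[:, keep]
        if masks.shape[1]:
            pats, counts = np.unique(masks.T, axis=0, return_counts=True)
            self.patterns = np.ascontiguousarray(pats.T)
            self.weights = counts.astype(np.int64)
        else:
            self.patterns = np.zeros((len(self.taxa), 0), dtype=np.uint8)
            self.weights = np.zeros(0, dtype=np.int64)

    # -- constructors --------------------------------------------------
    @classmethod
    def from_combined(cls, m: CombinedMatrix) -> "ParsimonyMatrix":
        masks = np.zeros(m.cells.shape, dtype=np.uint8)
        for p in m.partitions:
            table = STATE_MASKS if p.kind is CharacterKind.NUCLEOTIDE else _INDEL_MASK
            block = m.cells[:, p.start : p.end]
            enc = np.zeros(block.shape, dtype=np.uint8)
            for ch, mask in table.items():
                enc[block == ch] = mask
            if (enc == 0).any():
                raise ValidationError("unencodable character state in matrix")
            masks[:, p.start : p.end] = enc
        return cls(m.taxa, masks, n_sites=m.width)

    @classmethod
    def from_strings(cls, rows: Mapping[str, str]) -> "ParsimonyMatrix":
        taxa = list(rows)
        width = len(next(iter(rows.values())))
        masks = np.zeros((len(taxa), width), dtype=np.uint8)
        for i, t in enumerate(taxa):
            if len(rows[t]) != width:
                raise ValidationError("rows differ in length")
            masks[i] = [STATE_MASKS[ch] for ch in rows[t].upper()]
        return cls(taxa, masks, n_sites=width)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def states_for(self, leaf_order: Sequence[str]) -> np.ndarray:
        idx = [self.taxa.index(t) for t in leaf_order]
        return np.ascontiguousarray(self.patterns[idx])


def _state_buffer(n_leaves: int, leaf_states: np.ndarray) -> np.ndarray:
    S = np.empty((2 * n_leaves - 2, leaf_states.shape[1]), dtype=np.uint8)
    S[:n_leaves] = leaf_states
    return S


def _buffers(n_leaves: int):
    k = max(n_leaves - 2, 1)
    return (
        np.empty(k, np.int32),
        np.empty(k, np.int32),
        np.empty(k, np.int32),
    )


def fitch_length(tree: Tree, m: ParsimonyMatrix, weights: np.ndarray | None = None) -> int:
    """Minimum number of state changes of ``m`` on ``tree`` (Fitch)."""
    if set(tree.leaf_names) != set(m.taxa):
        diff = sorted(set(tree.leaf_names) ^ set(m.taxa))
        raise ValidationError(f"tree/matrix taxa mismatch: {diff}")
    if not tree.is_binary:
        raise ValidationError("Fitch scoring requires a fully resolved (binary) tree")
    w = m.weights if weights is None else np.asarray(weights, dtype=np.int64)
    states = m.states_for(tree.leaf_names)
    n = tree.n_leaves
    if n < 2 or m.n_patterns == 0:
        return 0
    if n == 2:
        clash = (states[0] & states[1]) == 0
        return int(w[clash].sum())
    adj = _tree_to_engine_adj(tree)
    S = _state_buffer(n, states)
    c1, c2, nid = _buffers(n)
    return int(_engine.tree_length(adj, 0, n, S, w, c1, c2, nid))


def _tree_to_engine_adj(tree: Tree) -> np.ndarray:
    n = tree.n_leaves
    internal_ids = sorted(u for u in tree.adjacency if u >= n)
    remap = {u: n + i for i, u in enumerate(internal_ids)}
    for i in range(n):
        remap[i] = i
    adj = np.full((2 * n - 2, 3), -1, dtype=np.int32)
    for u, vs in tree.adjacency.items():
        for j, v in enumerate(vs):
            adj[remap[u], j] = remap[v]
    return adj


# ---------------------------------------------------------------------------
# Search


@dataclass
class SearchResult:
    score: int
    trees: list[Tree]
    n_topologies: int | None = None  # exhaustive only


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! unrooted binary topologies on n labelled leaves."""
    out = 1
    for k in range(3, n + 1):
        out *= 2 * k - 5
    return out


def _trivial_result(m: ParsimonyMatrix) -> SearchResult:
    n = m.n_taxa
    if n == 2:
        t = Tree(m.taxa, {0: (1,), 1: (0,)})
        clash = (m.patterns[0] & m.patterns[1]) == 0
        return SearchResult(int(m.weights[clash].sum()), [t], 1)
    if n == 3:
        t = Tree(m.taxa, {0: (3,), 1: (3,), 2: (3,), 3: (0, 1, 2)})
        return SearchResult(fitch_length(t, m), [t], 1)
    raise ValidationError("need >= 2 taxa")


def exhaustive_search(m: ParsimonyMatrix) -> SearchResult:
    """Enumerate all unrooted binary topologies; exact optimum (<= 9 taxa)."""
    n = m.n_taxa
    if n > 9:
        raise ValidationError(
            f"exhaustive search refused for {n} taxa (limit 9; "
            f"{n_unrooted_topologies(n)} topologies)"
        )
    if n < 4:
        return _trivial_result(m)
    states = m.states_for(m.taxa)
    S = _state_buffer(n, states)
    w = m.weights
    c1, c2, nid = _buffers(n)
    adj = np.full((2 * n - 2, 3), -1, dtype=np.int32)
    adj[0, 0] = adj[1, 0] = adj[2, 0] = n
    adj[n] = (0, 1, 2)
    best: list[int] = [np.iinfo(np.int64).max]
    best_adjs: list[np.ndarray] = []
    visited = [0]

    def edges_now() -> list[tuple[int, int]]:
        out = []
        for u in range(2 * n - 2):
            if adj[u, 0] < 0 and u >= n:
                continue
            for v in adj[u]:
                if v > u:
                    out.append((u, int(v)))
        return out

    def attach(leaf: int, w_node: int, u: int, v: int) -> None:
        adj[u][adj[u] == v] = w_node
        adj[v][adj[v] == u] = w_node
        adj[w_node] = (u, v, leaf)
        adj[leaf, 0] = w_node

    def detach(leaf: int, w_node: int, u: int, v: int) -> None:
        adj[u][adj[u] == w_node] = v
        adj[v][adj[v] == w_node] = u
        adj[w_node] = -1
        adj[leaf, 0] = -1

    def rec(i: int) -> None:
        if i == n:
            visited[0] += 1
            sc = int(_engine.tree_length(adj, 0, n, S, w, c1, c2, nid))
            if sc < best[0]:
                best[0] = sc
                best_adjs.clear()
            if sc == best[0]:
                best_adjs.append(adj.copy())
            return
        w_node = n + i - 2
        for u, v in edges_now():
            attach(i, w_node, u, v)
            rec(i + 1)
            detach(i, w_node, u, v)

    rec(3)
    trees = [Tree.from_engine_adj(a, m.taxa) for a in best_adjs]
    return SearchResult(best[0], trees, visited[0])


def _run_cycles(
    m: ParsimonyMatrix,
    weights: np.ndarray,
    cfg: SearchConfig,
    rng: np.random.Generator,
) -> tuple[int, list[np.ndarray]]:
    """Random-addition + swapping cycles; returns best score and adjs."""
    n = m.n_taxa
    states = m.states_for(m.taxa)
    S = _state_buffer(n, states)
    nni_only = cfg.swap == "nni"
    best_score: int | None = None
    best_adjs: list[np.ndarray] = []
    seen: set[frozenset[int]] = set()
    for _ in range(cfg.n_addition_cycles):
        order = rng.permutation(n).astype(np.int32)
        adj = _engine.stepwise_build(order, n, S, weights)
        sc = int(_engine.spr_hillclimb(adj, n, S, weights, nni_only, cfg.max_swap_rounds))
        if best_score is None or sc < best_score:
            best_score = sc
            best_adjs = []
            seen = set()
        if sc == best_score and len(best_adjs) < cfg.max_trees:
            key = splits_from_adj(adj, n)
            if key not in seen:
                seen.add(key)
                best_adjs.append(adj)
    assert best_score is not None
    return best_score, best_adjs


def heuristic_search(m: ParsimonyMatrix, cfg: SearchConfig | None = None) -> SearchResult:
    """Random-addition stepwise building plus branch swapping.

    Deterministic for a given ``cfg.seed``; distinct co-optimal final
    trees (up to ``cfg.max_trees``) are returned.
    """
    cfg = cfg or SearchConfig()
    n = m.n_taxa
    if n < 4:
        return _trivial_result(m)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    score, adjs = _run_cycles(m, m.weights, cfg, rng)
    return SearchResult(score, [Tree.from_engine_adj(a, m.taxa) for a in adjs])


def bootstrap_consensus(m: ParsimonyMatrix, cfg: SearchConfig | None = None) -> SupportTree:
    """Nonparametric bootstrap over sites plus majority-rule consensus.

    Each replicate resamples ``m.n_sites`` columns with replacement
    (constant sites included, so variable-pattern weights follow the
    correct binomial law), reruns the heuristic search, and contributes
    one vote split evenly over its co-optimal trees. Supports are
    percentages of replicates; the returned tree keeps every observed
    split's frequency in ``split_frequencies``.
    """
    cfg = cfg or SearchConfig()
    n = m.n_taxa
    if n < 4:
        t = _trivial_result(m).trees[0]
        return SupportTree(t.leaf_names, t.adjacency, {}, {})
    P = m.n_patterns
    n_var = int(m.weights.sum())
    n_const = m.n_sites - n_var
    probs = np.concatenate([m.weights, [n_const]]) / m.n_sites
    counts_acc: dict[int, float] = defaultdict(float)
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_bootstrap)
    for child in children:
        rng = np.random.default_rng(child)
        if P:
            w_rep = rng.multinomial(m.n_sites, probs)[:P].astype(np.int64)
        else:
            w_rep = m.weights
        if w_rep.sum() == 0:
            continue  # no variable sites drawn: the replicate is a star
        _, adjs = _run_cycles(m, w_rep, cfg, rng)
        split_sets = {splits_from_adj(a, n) for a in adjs}
        vote = 1.0 / len(split_sets)
        for sset in split_sets:
            for mask in sset:
                counts_acc[mask] += vote
    freqs = {
        mask: min(100.0, 100.0 * c / cfg.n_bootstrap) for mask, c in counts_acc.items()
    }
    return majority_consensus(freqs, m.taxa, cfg.consensus_threshold)
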