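"""Constraint-based causal structure learning over markers and the trait.

Implements the PC-stable variant: Fisher's Z conditional-independence tests
on the marker/trait correlation matrix, level-wise skeleton discovery with
frozen adjacencies (order-independent), collider orientation from the
recorded separation sets, Meek's orientation-propagation rules, and two
trait-specific post-processing steps — a taboo on trait-to-marker edges
(a germline genotype cannot be caused by the phenotype) and extraction of
the trait's ancestral subgraph (nodes with a directed path into the trait).

All tie-breaking is deterministic: nodes are processed in sorted ID order
and conditioning subsets in lexicographic order, so repeated runs on the
same input produce identical graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CIContext",
    "Skeleton",
    "CPDAG",
    "partial_correlation",
    "fisher_z_test",
    "gaussian_ci_test",
    "dsep_ci_test",
    "learn_skeleton",
    "orient_v_structures",
    "apply_meek_rules",
    "enforce_trait_constraints",
    "ancestral_subgraph",
    "learn_graph",
    "cpdag_from_dag",
    "d_separated",
]

_CLAMP = 1.0 - 1e-12

CITest = Callable[[int, int, tuple[int, ...]], bool]  # True => independent


@dataclass
class CIContext:
    """Sufficient statistics for Gaussian conditional-independence testing."""

    corr: np.ndarray
    n: int
    alpha: float = 0.05
    max_cond: int = 3

    def __post_init__(self) -> None:
        c = np.asarray(self.corr, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("correlation matrix must be square")
        if self.n <= self.max_cond + 3:
            raise ValueError("sample size too small for the conditioning depth")
        self.corr = c

    @classmethod
    def from_data(cls, data: np.ndarray, alpha: float = 0.05,
                  max_cond: int = 3) -> "CIContext":
        vals = np.asarray(data, dtype=float)
        vals = vals - vals.mean(axis=0)
        sd = vals.std(axis=0)
        sd[sd == 0] = 1.0
        corr = np.corrcoef((vals / sd), rowvar=False)
        corr = np.atleast_2d(corr)
        np.fill_diagonal(corr, 1.0)
        return cls(corr=np.nan_to_num(corr), n=vals.shape[0],
                   alpha=alpha, max_cond=max_cond)


@dataclass
class Skeleton:
    nodes: list[str]
    adj: dict[str, set[str]]
    sepsets: dict[frozenset, tuple[str, ...]]

    def edges(self) -> list[tuple[str, str]]:
        return sorted({tuple(sorted((u, v))) for u in self.adj for v in self.adj[u]})


class CPDAG:
    """Partially directed graph: a set of directed and undirected edges.

    The class enforces that no pair of nodes carries both a directed and an
    undirected edge, and offers the small amount of graph algebra the PC
    pipeline needs (orientation, reachability, consistent DAG extension).
    """

    def __init__(self, nodes: Iterable[str]):
        self.nodes: list[str] = sorted(nodes)
        self._node_set = set(self.nodes)
        self.directed_edges: set[tuple[str, str]] = set()
        self.undirected_edges: set[frozenset] = set()
        self.edge_weights: dict[tuple[str, str], float] = {}

    # -- construction -------------------------------------------------
    def add_undirected(self, u: str, v: str) -> None:
        self._check(u, v)
        if (u, v) in self.directed_edges or (v, u) in self.directed_edges:
            raise ValueError(f"{u},{v} already directed")
        self.undirected_edges.add(frozenset((u, v)))

    def add_directed(self, u: str, v: str) -> None:
        self._check(u, v)
        self.undirected_edges.discard(frozenset((u, v)))
        if (v, u) in self.directed_edges:
            raise ValueError(f"adding {u}->{v} would create a 2-cycle")
        self.directed_edges.add((u, v))

    def orient(self, u: str, v: str) -> None:
        """Turn the undirected edge u-v into u->v."""
        if frozenset((u, v)) not in self.undirected_edges:
            raise ValueError(f"no undirected edge {u}-{v}")
        self.undirected_edges.discard(frozenset((u, v)))
        self.directed_edges.add((u, v))

    def remove_edge(self, u: str, v: str) -> None:
        self.directed_edges.discard((u, v))
        self.directed_edges.discard((v, u))
        self.undirected_edges.discard(frozenset((u, v)))
        self.edge_weights.pop((u, v), None)
        self.edge_weights.pop((v, u), None)

    def _check(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError("self loops not allowed")
        if u not in self._node_set or v not in self._node_set:
            raise KeyError(f"unknown node in edge {u},{v}")

    # -- queries ------------------------------------------------------
    def has_directed(self, u: str, v: str) -> bool:
        return (u, v) in self.directed_edges

    def has_undirected(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self.undirected_edges

    def adjacent(self, u: str, v: str) -> bool:
        return (self.has_undirected(u, v) or (u, v) in self.directed_edges
                or (v, u) in self.directed_edges)

    def parents(self, v: str) -> list[str]:
        return sorted(u for u, w in self.directed_edges if w == v)

    def children(self, u: str) -> list[str]:
        return sorted(w for s, w in self.directed_edges if s == u)

    def undirected_neighbors(self, v: str) -> list[str]:
        return sorted((set(e) - {v}).pop() for e in self.undirected_edges if v in e)

    def neighbors(self, v: str) -> list[str]:
        out = {u for u, w in self.directed_edges if w == v}
        out |= {w for u, w in self.directed_edges if u == v}
        out |= set(self.undirected_neighbors(v))
        return sorted(out)

    def out_degree(self, v: str) -> int:
        return sum(1 for u, _ in self.directed_edges if u == v)

    def copy(self) -> "CPDAG":
        g = CPDAG(self.nodes)
        g.directed_edges = set(self.directed_edges)
        g.undirected_edges = set(self.undirected_edges)
        g.edge_weights = dict(self.edge_weights)
        return g

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, CPDAG) and self.nodes == other.nodes
                and self.directed_edges == other.directed_edges
                and self.undirected_edges == other.undirected_edges)

    __hash__ = None  # mutable container

    def has_directed_cycle(self) -> bool:
        indeg = {v: 0 for v in self.nodes}
        for _, v in self.directed_edges:
            indeg[v] += 1
        stack = [v for v, d in indeg.items() if d == 0]
        seen = 0
        children = {v: [] for v in self.nodes}
        for u, v in self.directed_edges:
            children[u].append(v)
        while stack:
            u = stack.pop()
            seen += 1
            for v in children[u]:
                indeg[v] -= 1
                if indeg[v] == 0:
                    stack.append(v)
        return seen < len(self.nodes)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v in sorted(self.directed_edges):
            g.add_edge(u, v, directed=True,
                       **({"weight": self.edge_weights[(u, v)]}
                          if (u, v) in self.edge_weights else {}))
        for e in sorted(tuple(sorted(e)) for e in self.undirected_edges):
            g.add_edge(e[0], e[1], directed=False)
        return g

    def consistent_extension(self) -> "CPDAG":
        """Orient all undirected edges into one DAG of the equivalence class
        (Dor-Tarsi procedure, deterministic by sorted node order).

        Falls back to orienting remaining edges in sorted order (skipping
        orientations that would close a cycle) if no proper extension
        exists, which can happen after the trait-constraint surgery; the
        fallback is logged.
        """
        g = self.copy()
        work = self.copy()
        remaining = set(work.nodes)
        while any(work.undirected_neighbors(v) for v in remaining):
            progress = False
            for x in sorted(remaining):
                if work.children(x):
                    continue
                und = work.undirected_neighbors(x)
                if not und:
                    continue
                nbrs = set(work.neighbors(x))
                if all(all(work.adjacent(y, z) for z in nbrs - {y}) for y in und):
                    for y in und:
                        g.orient(y, x)
                        work.remove_edge(y, x)
                    remaining.discard(x)
                    progress = True
                    break
            if not progress:
                logger.warning("no consistent extension; orienting leftover "
                               "undirected edges in node order")
                for e in sorted(tuple(sorted(e)) for e in work.undirected_edges):
                    u, v = e
                    trial = g.copy()
                    trial.orient(u, v)
                    if trial.has_directed_cycle():
                        g.orient(v, u)
                    else:
                        g.orient(u, v)
                    work.remove_edge(u, v)
                break
            # drop isolated finished nodes from consideration
            remaining = {v for v in remaining if work.neighbors(v)}
        return g


# ---------------------------------------------------------------------------
# conditional-independence primitives


def partial_correlation(corr: np.ndarray, i: int, j: int,
                        S: tuple[int, ...] = ()) -> float:
    """Partial correlation of variables i and j given the set S, from the
    inverse of the (i, j, S) correlation submatrix; clamped away from +-1.
    A numerically singular submatrix is treated as degenerate and reported
    as zero correlation (independence)."""
    if i in S or j in S:
        raise ValueError("conditioning set must exclude i and j")
    if not S:
        rho = corr[i, j]
    else:
        idx = [i, j, *S]
        sub = corr[np.ix_(idx, idx)]
        try:
            omega = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            logger.warning("singular correlation submatrix for (%d,%d|%s); "
                           "treating as independent", i, j, S)
            return 0.0
        denom = np.sqrt(omega[0, 0] * omega[1, 1])
        if not np.isfinite(denom) or denom <= 0:
            return 0.0
        rho = -omega[0, 1] / denom
    return float(np.clip(rho, -_CLAMP, _CLAMP))


def fisher_z_test(ctx: CIContext, i: int, j: int,
                  S: tuple[int, ...] = ()) -> tuple[float, float, bool]:
    """Fisher's Z conditional-independence test.

    z = atanh(rho), statistic = sqrt(n - |S| - 3) * |z|, two-sided normal
    p-value; independence is declared when p > alpha.
    """
    if ctx.n - len(S) - 3 <= 0:
        raise ValueError("sample size too small for this conditioning set")
    rho = partial_correlation(ctx.corr, i, j, tuple(S))
    z = 0.5 * np.log((1 + rho) / (1 - rho))
    statistic = np.sqrt(ctx.n - len(S) - 3) * abs(z)
    p = 2.0 * stats.norm.sf(statistic)
    return float(statistic), float(p), bool(p > ctx.alpha)


def gaussian_ci_test(ctx: CIContext) -> CITest:
    """CI-test closure over a fitted ``CIContext`` for the skeleton search."""

    def test(i: int, j: int, S: tuple[int, ...]) -> bool:
        return fisher_z_test(ctx, i, j, S)[2]

    return test


# -- d-separation oracle (for simulation truth and exhaustive testing) ------


def d_separated(dag_parents: dict[str, set[str]], x: str, y: str,
                S: Iterable[str]) -> bool:
    """d-separation via the moralised ancestral graph criterion.

    ``dag_parents`` maps each node to its parent set.  Suitable for the
    small graphs used in oracle-based recovery tests.
    """
    S = set(S)
    relevant = {x, y} | S
    anc = set()
    stack = list(relevant)
    while stack:
        v = stack.pop()
        if v in anc:
            continue
        anc.add(v)
        stack.extend(dag_parents.get(v, ()))
    # moralise: connect co-parents, drop directions
    adj: dict[str, set[str]] = {v: set() for v in anc}
    for v in anc:
        ps = [p for p in dag_parents.get(v, ()) if p in anc]
        for p in ps:
            adj[v].add(p)
            adj[p].add(v)
        for a, b in combinations(ps, 2):
            adj[a].add(b)
            adj[b].add(a)
    # separation in the moral graph with S removed
    if x == y:
        return False
    seen = {x}
    stack = [x]
    while stack:
        v = stack.pop()
        for w in adj.get(v, ()):
            if w in S or w in seen:
                continue
            if w == y:
                return False
            seen.add(w)
            stack.append(w)
    return True


def dsep_ci_test(dag_edges: Iterable[tuple[str, str]], nodes: list[str]) -> CITest:
    """Perfect CI oracle for a known DAG, indexed like the data columns."""
    parents: dict[str, set[str]] = {v: set() for v in nodes}
    for u, v in dag_edges:
        parents[v].add(u)

    def test(i: int, j: int, S: tuple[int, ...]) -> bool:
        return d_separated(parents, nodes[i], nodes[j], tuple(nodes[k] for k in S))

    return test


# ---------------------------------------------------------------------------
# PC-stable pipeline


def learn_skeleton(
    data: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
    max_cond: int = 3,
    ci_test: CITest | None = None,
    nodes: list[str] | None = None,
) -> Skeleton:
    """PC-stable skeleton discovery.

    For conditioning size l = 0..max_cond, every adjacent pair (i, j) is
    tested against all size-l subsets of the level-frozen adjacency of i and
    then of j; the edge is removed (and the separating set recorded) at the
    first independence.  Freezing adjacencies per level makes the result
    independent of processing order.
    """
    if ci_test is None:
        if isinstance(data, pd.DataFrame):
            nodes = [str(c) for c in data.columns]
            vals = data.to_numpy(dtype=float)
        else:
            vals = np.asarray(data, dtype=float)
            nodes = nodes or [f"V{k}" for k in range(vals.shape[1])]
        ctx = CIContext.from_data(vals, alpha=alpha, max_cond=max_cond)
        ci_test = gaussian_ci_test(ctx)
    elif nodes is None:
        raise ValueError("nodes must be given with a custom CI test")
    if len(nodes) < 2:
        raise ValueError("need at least two nodes")

    index = {v: k for k, v in enumerate(nodes)}
    adj: dict[str, set[str]] = {v: set(nodes) - {v} for v in nodes}
    sepsets: dict[frozenset, tuple[str, ...]] = {}

    for level in range(max_cond + 1):
        frozen = {v: sorted(adj[v]) for v in nodes}
        any_candidate = False
        for u in nodes:
            for v in frozen[u]:
                if v not in adj[u] or u > v:
                    continue
                removed = False
                for base in (u, v):
                    other = v if base == u else u
                    pool = [w for w in frozen[base] if w != other]
                    if len(pool) < level:
                        continue
                    any_candidate = True
                    for S in combinations(pool, level):
                        if ci_test(index[u], index[v], tuple(index[w] for w in S)):
                            adj[u].discard(v)
                            adj[v].discard(u)
                            sepsets[frozenset((u, v))] = S
                            removed = True
                            break
                    if removed:
                        break
        if not any_candidate and level > 0:
            break
    return Skeleton(nodes=list(nodes), adj=adj, sepsets=sepsets)


def _separating_sets(skel: Skeleton, i: str, j: str, ci_test: CITest,
                     index: dict[str, int], max_cond: int):
    """All subsets of the skeleton adjacencies of i and of j (up to
    max_cond) that the CI test declares separating for the pair."""
    seen = set()
    for base in (i, j):
        other = j if base == i else i
        pool = sorted(set(skel.adj[base]) - {other})
        for size in range(min(len(pool), max_cond) + 1):
            for S in combinations(pool, size):
                if S in seen:
                    continue
                seen.add(S)
                if ci_test(index[i], index[j], tuple(index[w] for w in S)):
                    yield set(S)


def orient_v_structures(
    skel: Skeleton,
    ci_test: CITest | None = None,
    max_cond: int = 3,
) -> CPDAG:
    """Collider orientation on unshielded triples i-k-j.

    Without a CI test, the classic rule applies: orient i->k<-j iff k is
    absent from the recorded sepset(i, j).  When a CI test is supplied the
    conservative rule is used instead: every separating subset of the
    skeleton adjacencies of i and j is enumerated and the collider is
    declared only if k appears in none of them — finite-sample sepsets
    recorded at a low conditioning level otherwise produce spurious
    colliders (triples with conflicting evidence are left unoriented and
    logged).  With a perfect CI oracle the two rules agree.  Orientation
    conflicts between overlapping v-structures are resolved
    first-writer-wins in deterministic node order and logged.
    """
    g = CPDAG(skel.nodes)
    for u, v in skel.edges():
        g.add_undirected(u, v)
    index = {v: k for k, v in enumerate(skel.nodes)}
    for k in skel.nodes:
        nbrs = sorted(skel.adj[k])
        for i, j in combinations(nbrs, 2):
            if j in skel.adj[i]:
                continue  # shielded
            if ci_test is not None:
                membership = {k in S for S in
                              _separating_sets(skel, i, j, ci_test, index, max_cond)}
                if not membership:
                    membership = {k in skel.sepsets.get(frozenset((i, j)), ())}
                if membership == {True}:
                    continue  # consistently a non-collider
                if membership == {True, False}:
                    logger.info("ambiguous triple %s-%s-%s left unoriented",
                                i, k, j)
                    continue
            elif k in skel.sepsets.get(frozenset((i, j)), ()):
                continue
            for tail in (i, j):
                if g.has_undirected(tail, k):
                    g.orient(tail, k)
                elif g.has_directed(k, tail):
                    logger.info("v-structure conflict at %s->%s kept earlier "
                                "orientation", k, tail)
    return g


def _meek_pass(g: CPDAG) -> bool:
    changed = False
    for e in sorted(tuple(sorted(e)) for e in list(g.undirected_edges)):
        for b, c in (e, e[::-1]):
            if not g.has_undirected(b, c):
                break
            # R1: a -> b - c, a and c non-adjacent  =>  b -> c
            if any(not g.adjacent(a, c) for a in g.parents(b)):
                g.orient(b, c)
                changed = True
                continue
            # R2: b -> k -> c with b - c  =>  b -> c
            if any(g.has_directed(k, c) for k in g.children(b)):
                g.orient(b, c)
                changed = True
                continue
            # R3: b - c, b - k1, b - k2, k1 -> c, k2 -> c, k1,k2 non-adjacent
            und = [k for k in g.undirected_neighbors(b)
                   if k != c and g.has_directed(k, c)]
            if any(not g.adjacent(k1, k2) for k1, k2 in combinations(und, 2)):
                g.orient(b, c)
                changed = True
                continue
            # R4: b - c, exists d adjacent to b with d -> k -> c? (chain
            # d -> k, k -> c, d and c non-adjacent, b adjacent to d)
            hit = False
            for k in g.parents(c):
                for d in g.parents(k):
                    if d != b and not g.adjacent(d, c) and g.adjacent(b, d):
                        g.orient(b, c)
                        changed = True
                        hit = True
                        break
                if hit:
                    break
    return changed


def apply_meek_rules(g: CPDAG) -> CPDAG:
    """Meek rules R1-R4 applied to a fixpoint (returns a new graph)."""
    out = g.copy()
    while _meek_pass(out):
        pass
    return out


def enforce_trait_constraints(g: CPDAG, trait: str) -> CPDAG:
    """Reverse-edge taboo: trait->marker edges are statistical artifacts and
    are deleted; undirected trait edges are oriented marker->trait; Meek
    rules are re-applied.  The trait ends with out-degree 0."""
    if trait not in g._node_set:
        raise KeyError(f"trait node {trait!r} not in graph")
    out = g.copy()
    for child in out.children(trait):
        logger.info("removing reverse edge %s -> %s", trait, child)
        out.remove_edge(trait, child)
    for nbr in out.undirected_neighbors(trait):
        out.orient(nbr, trait)
    out = apply_meek_rules(out)
    # Meek propagation cannot re-orient out of the trait: its undirected
    # edges are gone; assert the contract anyway.
    for child in out.children(trait):  # pragma: no cover - defensive
        out.remove_edge(trait, child)
    return out


def ancestral_subgraph(g: CPDAG, trait: str,
                       include_undirected: bool = False) -> CPDAG:
    """Induced subgraph on the trait plus all nodes with a directed path to
    it.  Undirected edges are not traversed unless ``include_undirected``
    (the permissive variant treats them as traversable both ways)."""
    if trait not in g._node_set:
        raise KeyError(f"trait node {trait!r} not in graph")
    keep = {trait}
    stack = [trait]
    while stack:
        v = stack.pop()
        preds = set(g.parents(v))
        if include_undirected:
            preds |= set(g.undirected_neighbors(v))
        for u in preds:
            if u not in keep:
                keep.add(u)
                stack.append(u)
    if keep == {trait}:
        logger.warning("trait is isolated; ancestral subgraph is {trait}")
    sub = CPDAG(keep)
    for u, v in g.directed_edges:
        if u in keep and v in keep:
            sub.add_directed(u, v)
    for e in g.undirected_edges:
        u, v = tuple(e)
        if u in keep and v in keep:
            sub.add_undirected(u, v)
    return sub


def learn_graph(
    data: pd.DataFrame,
    trait: str,
    alpha: float = 0.05,
    max_cond: int = 3,
    ci_test: CITest | None = None,
    nodes: list[str] | None = None,
    include_undirected: bool = False,
    residualize: pd.DataFrame | None = None,
) -> CPDAG:
    """End-to-end structure learning: skeleton -> colliders -> Meek ->
    trait constraints -> ancestral subgraph.

    ``data`` holds the selected marker columns plus the trait column.  Pass
    ``residualize`` (PC scores) to learn on de-confounded marker residuals
    instead of raw dosages.
    """
    if ci_test is None and residualize is not None:
        vals = data.copy()
        pcs = residualize.to_numpy(dtype=float)
        pcs = np.column_stack([np.ones(len(pcs)), pcs])
        for col in vals.columns:
            if col == trait:
                continue
            v = vals[col].to_numpy(dtype=float)
            coef, *_ = np.linalg.lstsq(pcs, v, rcond=None)
            vals[col] = v - pcs @ coef
        data = vals
    if ci_test is None:
        nodes = [str(c) for c in data.columns]
        ctx = CIContext.from_data(data.to_numpy(dtype=float), alpha=alpha,
                                  max_cond=max_cond)
        ci_test = gaussian_ci_test(ctx)
    skel = learn_skeleton(data, alpha=alpha, max_cond=max_cond,
                          ci_test=ci_test, nodes=nodes)
    if trait not in skel.nodes:
        raise KeyError(f"trait node {trait!r} not among columns")
    g = orient_v_structures(skel, ci_test=ci_test, max_cond=max_cond)
    g = apply_meek_rules(g)
    g = enforce_trait_constraints(g, trait)
    return ancestral_subgraph(g, trait, include_undirected=include_undirected)


def cpdag_from_dag(edges: Iterable[tuple[str, str]],
                   nodes: Iterable[str]) -> CPDAG:
    """CPDAG (Markov-equivalence class representative) of a known DAG:
    skeleton + colliders of the DAG, closed under Meek's rules.  Used to
    score inferred graphs against simulation truth."""
    nodes = sorted(nodes)
    edges = list(edges)
    parents: dict[str, set[str]] = {v: set() for v in nodes}
    for u, v in edges:
        parents[v].add(u)
    g = CPDAG(nodes)
    adjacent = {frozenset(e) for e in edges}
    for u, v in edges:
        g.add_undirected(u, v)
    for k in nodes:
        for i, j in combinations(sorted(parents[k]), 2):
            if frozenset((i, j)) in adjacent:
                continue
            for tail in (i, j):
                if g.has_undirected(tail, k):
                    g.orient(tail, k)
    return apply_meek_rules(g)
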