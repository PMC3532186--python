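"""Markov clustering (MCL) of the line graph.

MCL simulates a random walk on the graph and alternates two operations
on the column-stochastic transition matrix: *expansion* (matrix
powering, which lets the walk flow along longer paths) and *inflation*
(entrywise powering followed by column renormalisation, which sharpens
strong transitions and starves weak ones).  The iteration converges to
a doubly idempotent matrix whose attractor structure defines a disjoint
clustering.  The inflation parameter controls granularity: higher
inflation fragments the walk faster and yields more, smaller clusters.

The implementation is deterministic; given the same graph and
parameters it always returns the same clustering, and the result is
invariant under relabelling of the input nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .line_graph import LineGraph, build_line_graph
from .network_io import Edge, InteractionNetwork

logger = logging.getLogger(__name__)

#: below this many line-graph nodes dense arithmetic is faster
DENSE_THRESHOLD = 2000


@dataclass(frozen=True)
class MclParams:
    """Parameters of the Markov clustering iteration.

    Defaults mirror the documented defaults of the canonical ``mcl``
    tool: expansion power 2, unit self-loops, pruning of transition
    probabilities below 1e-5.
    """

    inflation: float = 2.0
    expansion: int = 2
    max_iterations: int = 200
    convergence_tol: float = 1e-6
    prune_threshold: float = 1e-5
    self_loop_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.inflation > 1.0:
            raise ValueError(
                f"inflation must exceed 1.0, got {self.inflation}"
            )
        if self.expansion < 2:
            raise ValueError("expansion power must be >= 2")
        if self.self_loop_weight <= 0:
            raise ValueError("self_loop_weight must be positive")


@dataclass
class InteractionClustering:
    """Disjoint partition of the interactions into clusters.

    ``clusters`` is ordered by size (largest first), ties broken by the
    lexicographically smallest member, so cluster indices are stable
    under relabelling of the input.
    """

    clusters: list[set[Edge]]
    assignment: dict[Edge, int] = field(init=False)

    def __post_init__(self) -> None:
        self.clusters = sorted(
            (set(c) for c in self.clusters),
            key=lambda c: (-len(c), min(c)),
        )
        self.assignment = {
            e: i for i, c in enumerate(self.clusters) for e in c
        }

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def _column_normalize(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return m / colsum


def _iterate_dense(
    m: np.ndarray, params: MclParams
) -> tuple[np.ndarray, bool]:
    m = _column_normalize(m)
    for _ in range(params.max_iterations):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = _column_normalize(m**params.inflation)
        if params.prune_threshold > 0:
            # keep each column's maximum so no column is zeroed out
            keep = m >= params.prune_threshold
            keep[m.argmax(axis=0), np.arange(m.shape[1])] = True
            m = np.where(keep, m, 0.0)
            m = _column_normalize(m)
        if np.abs(m - prev).max() <= params.convergence_tol:
            return m, True
    return m, False


def _iterate_sparse(
    m: sp.csc_matrix, params: MclParams
) -> tuple[sp.csc_matrix, bool]:
    def normalize(x: sp.csc_matrix) -> sp.csc_matrix:
        colsum = np.asarray(x.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        return x @ sp.diags(1.0 / colsum)

    def prune(x: sp.csc_matrix) -> sp.csc_matrix:
        x = x.tocsc()
        argmax = np.asarray(x.argmax(axis=0)).ravel()
        x.data[x.data < params.prune_threshold] = 0.0
        x.eliminate_zeros()
        x = x.tolil()
        for j, i in enumerate(argmax):
            if x[i, j] == 0:
                x[i, j] = params.prune_threshold
        return normalize(x.tocsc())

    m = normalize(m.tocsc())
    for _ in range(params.max_iterations):
        prev = m
        mp = m
        for _ in range(params.expansion - 1):
            mp = mp @ m
        m = mp.power(params.inflation)
        m = normalize(m)
        if params.prune_threshold > 0:
            m = prune(m)
        if abs(m - prev).max() <= params.convergence_tol:
            return m, True
    return m, False


def _extract_clusters(m: np.ndarray, tol: float) -> list[list[int]]:
    """Interpret the limit matrix as attractor systems.

    Attractors are nodes with positive return probability (nonzero
    diagonal); attractors connected through nonzero entries form one
    system; every other node joins the system holding its largest
    transition mass.  Overlaps (a rare MCL degeneracy) resolve to the
    largest matrix entry, ties to the cluster that sorts first by size
    then smallest member.
    """
    n = m.shape[0]
    eps = max(tol, 1e-12)
    diag = np.diag(m)
    attractors = np.where(diag > eps)[0]
    if attractors.size == 0:
        # non-converged degenerate state: every node its own attractor
        attractors = np.arange(n)

    # union attractors sharing mass into systems
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    attr_set = set(attractors.tolist())
    for i in attractors:
        row_nz = np.where(m[i, :] > eps)[0]
        col_nz = np.where(m[:, i] > eps)[0]
        for j in np.concatenate([row_nz, col_nz]):
            if j in attr_set:
                union(int(i), int(j))

    # non-attractor columns join the system of their heaviest attractor row
    assigned: dict[int, int] = {int(i): find(int(i)) for i in attractors}
    pending = [j for j in range(n) if j not in assigned]
    for j in pending:
        col = m[:, j]
        best_root, best_mass = None, -1.0
        for i in attractors:
            mass = col[i]
            if mass > best_mass and mass > eps:
                best_mass = mass
                best_root = find(int(i))
        if best_root is None:
            # no attractor mass: fall back to the heaviest row overall
            i = int(np.argmax(col))
            best_root = assigned.get(i, find(i))
        assigned[j] = best_root

    groups: dict[int, list[int]] = {}
    for j, root in assigned.items():
        groups.setdefault(root, []).append(j)
    return list(groups.values())


def mcl_cluster(
    graph: LineGraph, params: MclParams | None = None
) -> InteractionClustering:
    """Cluster the line graph with Markov clustering.

    Builds the column-stochastic transition matrix from the link weights
    (plus ``self_loop_weight`` on the diagonal), iterates
    expansion/inflation with pruning until the maximum entry change
    drops below ``convergence_tol``, and reads the clusters off the
    attractor structure of the limit matrix.  Non-convergence within
    ``max_iterations`` returns the current clustering with a warning.
    """
    params = params or MclParams()
    n = graph.n_nodes
    if n == 0:
        raise ValueError("cannot cluster an empty line graph")

    if n < DENSE_THRESHOLD:
        m = np.zeros((n, n))
        for (i, j), _protein in graph.links.items():
            w = graph.link_weight.get((i, j), 1.0)
            m[i, j] = w
            m[j, i] = w
        np.fill_diagonal(m, params.self_loop_weight)
        limit, converged = _iterate_dense(m, params)
        limit_dense = limit
    else:
        rows, cols, vals = [], [], []
        for (i, j), _protein in graph.links.items():
            w = graph.link_weight.get((i, j), 1.0)
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        rows += list(range(n))
        cols += list(range(n))
        vals += [params.self_loop_weight] * n
        m = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
        limit, converged = _iterate_sparse(m, params)
        limit_dense = np.asarray(limit.todense())

    if not converged:
        logger.warning(
            "MCL did not converge within %d iterations (inflation %.3f); "
            "returning the current clustering",
            params.max_iterations,
            params.inflation,
        )

    groups = _extract_clusters(limit_dense, params.convergence_tol)
    clusters = [{graph.nodes[i] for i in grp} for grp in groups]
    return InteractionClustering(clusters=clusters)


def cluster_interactions(
    network: InteractionNetwork,
    inflation: float,
    use_weights: bool = False,
    params: MclParams | None = None,
) -> InteractionClustering:
    """Cluster the interactions of ``network`` via its line graph."""
    if params is None:
        params = MclParams(inflation=inflation)
    else:
        params = MclParams(
            inflation=inflation,
            expansion=params.expansion,
            max_iterations=params.max_iterations,
            convergence_tol=params.convergence_tol,
            prune_threshold=params.prune_threshold,
            self_loop_weight=params.self_loop_weight,
        )
    lg = build_line_graph(network, use_weights=use_weights)
    return mcl_cluster(lg, params)
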