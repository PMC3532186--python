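"""Degree-preserving random rewiring of interaction networks.

Rewiring swaps endpoints between pairs of edges: (a,b), (c,d) becomes
(a,d), (c,b) (or (a,c), (b,d)).  Each accepted swap destroys two real
interactions and creates two false ones while preserving every
protein's degree, so a partially rewired network carries a labelled set
of plausible-looking false interactions.  These serve two purposes:
tuning the clustering granularity (the inflation that best separates
original from rewired link scores) and providing negatives for ROC
benchmarking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network_io import Edge, InteractionNetwork, canonical_edge

logger = logging.getLogger(__name__)


class RewiringError(RuntimeError):
    """Raised when the requested number of swaps cannot be completed."""


@dataclass
class RewiredInstance:
    """A partially rewired network with per-edge provenance labels."""

    network: InteractionNetwork
    rewired_edges: set[Edge]
    removed_edges: set[Edge]
    seed: int

    def surviving_original_edges(self) -> set[Edge]:
        """Original edges still present after rewiring."""
        return self.network.edges - self.rewired_edges


def _swap_target(fraction: float, n_edges: int) -> int:
    """Number of swaps realising ~fraction of the edges rewired.

    The rewired-edge count is round(fraction * |E|) rounded to an even
    number (two false interactions per swap), so e.g. 3% of 100 edges
    targets 3 edges and performs 2 swaps = 4 rewired edges.
    """
    target_edges = round(fraction * n_edges)
    return max(1, round(target_edges / 2))


def rewire_fraction(
    network: InteractionNetwork,
    fraction: float,
    seed: int,
    retry_factor: int = 100,
) -> RewiredInstance:
    """Rewire ``fraction`` of the edges by valid degree-preserving swaps.

    A candidate swap is rejected if it would create a self-loop, a
    duplicate edge, reconstitute an edge of the original network, touch
    an edge already rewired (labels must stay unambiguous), or change
    the number of connected components.  Deterministic given ``seed``.

    Raises :class:`RewiringError` when the retry budget
    (``retry_factor`` draws per requested swap) is exhausted, which
    signals a pathologically constrained network.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_edges = network.n_edges
    if n_edges < 4:
        raise ValueError("rewiring needs at least 4 edges")
    if fraction * n_edges < 2:
        raise ValueError(
            f"fraction {fraction} of {n_edges} edges leaves fewer than "
            "2 edges to rewire"
        )
    n_swaps = _swap_target(fraction, n_edges)
    rng = np.random.default_rng(seed)
    original = network.edges
    work = network.copy()
    g = work._g  # mutate in place; re-wrapped below
    n_components = network.n_components()

    edge_list = network.sorted_edges()
    rewired: set[Edge] = set()
    removed: set[Edge] = set()
    touched: set[Edge] = set()
    budget = retry_factor * n_swaps
    done = 0
    while done < n_swaps:
        if budget <= 0:
            raise RewiringError(
                f"retry budget exhausted after {done}/{n_swaps} swaps; "
                "the network is too constrained for this fraction"
            )
        budget -= 1
        i, j = rng.choice(len(edge_list), size=2, replace=False)
        e1, e2 = edge_list[i], edge_list[j]
        if e1 in touched or e2 in touched:
            continue
        (a, b), (c, d) = e1, e2
        if rng.integers(2):  # choose one of the two swap orientations
            new1, new2 = (a, d), (c, b)
        else:
            new1, new2 = (a, c), (b, d)
        if new1[0] == new1[1] or new2[0] == new2[1]:
            continue
        n1, n2 = canonical_edge(*new1), canonical_edge(*new2)
        if n1 == n2:
            continue
        if n1 in original or n2 in original:
            continue
        if g.has_edge(*n1) or g.has_edge(*n2):
            continue
        g.remove_edge(*e1)
        g.remove_edge(*e2)
        g.add_edge(*n1)
        g.add_edge(*n2)
        if nx.number_connected_components(g) != n_components:
            g.remove_edge(*n1)
            g.remove_edge(*n2)
            g.add_edge(*e1)
            g.add_edge(*e2)
            continue
        rewired.update((n1, n2))
        removed.update((e1, e2))
        touched.update((e1, e2, n1, n2))
        done += 1

    result = InteractionNetwork()
    result._g = g
    return RewiredInstance(
        network=result, rewired_edges=rewired, removed_edges=removed, seed=seed
    )


def rewire_full(
    network: InteractionNetwork,
    seed: int,
    swap_rounds: int = 10,
) -> RewiredInstance:
    """Fully randomise a network by repeated degree-preserving swaps.

    Performs ``swap_rounds * |E|`` swap attempts.  Per-swap validity
    (no self-loops, no duplicates, component count unchanged) is
    enforced, and each swap avoids recreating an edge of the original
    network, but an original edge may return through a later swap:
    exact avoidance is impossible under full randomisation, so this is
    the standard double-edge-swap null model.  If no valid swap exists
    (e.g. a star network) the identical network is returned with a
    warning.
    """
    n_edges = network.n_edges
    if n_edges < 4:
        raise ValueError("rewiring needs at least 4 edges")
    rng = np.random.default_rng(seed)
    original = network.edges
    work = network.copy()
    g = work._g
    n_components = network.n_components()
    accepted = 0
    for _ in range(swap_rounds * n_edges):
        edges = list(g.edges)
        i, j = rng.choice(len(edges), size=2, replace=False)
        (a, b), (c, d) = edges[i], edges[j]
        if rng.integers(2):
            new1, new2 = (a, d), (c, b)
        else:
            new1, new2 = (a, c), (b, d)
        if new1[0] == new1[1] or new2[0] == new2[1]:
            continue
        n1, n2 = canonical_edge(*new1), canonical_edge(*new2)
        if n1 == n2 or g.has_edge(*n1) or g.has_edge(*n2):
            continue
        if n1 in original or n2 in original:
            continue
        e1, e2 = canonical_edge(a, b), canonical_edge(c, d)
        g.remove_edge(*e1)
        g.remove_edge(*e2)
        g.add_edge(*n1)
        g.add_edge(*n2)
        if nx.number_connected_components(g) != n_components:
            g.remove_edge(*n1)
            g.remove_edge(*n2)
            g.add_edge(*e1)
            g.add_edge(*e2)
            continue
        accepted += 1
    if accepted == 0:
        logger.warning(
            "no valid degree-preserving swap exists; returning the "
            "network unchanged"
        )
    result = InteractionNetwork()
    result._g = g
    final_edges = result.edges
    return RewiredInstance(
        network=result,
        rewired_edges=final_edges - original,
        removed_edges=original - final_edges,
        seed=seed,
    )
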