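"""Fidelity and confidence scoring of interactions.

Given a disjoint clustering of a network's interactions, the *fidelity*
F(p, c) of protein p to cluster c is the lower-tail cumulative
hypergeometric probability

    F(p, c) = P(X <= L_pc)
            = sum_{k=0}^{L_pc} C(L_p, k) C(L - L_p, L_c - k) / C(L, L_c)

where L_pc is the number of interactions of p inside c, L_p the degree
of p, L_c the number of interactions in c, and L the total number of
interactions in the network.  F is near 1 when c is enriched in the
interactions of p, i.e. when p is specific to c.  The confidence of an
interaction between p1 and p2 assigned to cluster c is the product
F(p1, c) * F(p2, c): high only if both partners are specific to the
cluster that contains the interaction.

The CDF is evaluated through scipy's hypergeometric distribution, which
works on log scale internally and stays accurate for interactome-scale
networks (L ~ 75,000) where direct factorials overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from .mcl import InteractionClustering
from .network_io import Edge, InteractionNetwork


@dataclass(frozen=True)
class FidelityContext:
    """The four link counts entering one fidelity evaluation.

    L_pc: links of protein p inside cluster c (>= 0)
    L_p:  degree of p (>= 1)
    L_c:  links in cluster c (>= 1)
    L_total: links in the network (>= 1)
    """

    L_pc: int
    L_p: int
    L_c: int
    L_total: int

    def __post_init__(self) -> None:
        if self.L_p < 1 or self.L_c < 1 or self.L_total < 1:
            raise ValueError(f"counts must be positive: {self}")
        if self.L_pc < 0:
            raise ValueError(f"L_pc must be non-negative: {self}")
        if self.L_pc > min(self.L_p, self.L_c):
            raise ValueError(f"L_pc exceeds min(L_p, L_c): {self}")
        if self.L_p > self.L_total or self.L_c > self.L_total:
            raise ValueError(f"L_p and L_c cannot exceed L_total: {self}")


def fidelity(ctx: FidelityContext) -> float:
    """Lower-tail hypergeometric CDF P(X <= L_pc); the fidelity of a
    protein to a cluster.  Returns 1.0 exactly at the upper support
    bound (all of the protein's links, or the whole cluster, inside)."""
    hi = min(ctx.L_p, ctx.L_c)
    if ctx.L_pc >= hi:
        return 1.0
    # population L_total, L_p successes, L_c draws, X = in-cluster links
    value = float(hypergeom.cdf(ctx.L_pc, ctx.L_total, ctx.L_p, ctx.L_c))
    return min(1.0, max(0.0, value))


@dataclass
class ConfidenceResult:
    """Per-interaction confidence scores plus the fidelity table behind
    them and the clustering/inflation they came from."""

    scores: dict[Edge, float]
    fidelity: dict[tuple[str, int], float]
    clustering: InteractionClustering
    inflation: float | None = None


def score_network(
    network: InteractionNetwork,
    clustering: InteractionClustering,
    inflation: float | None = None,
) -> ConfidenceResult:
    """Score every interaction as the product of its endpoints'
    fidelities to the cluster containing it.

    The clustering must partition exactly the network's interaction
    set.  Fidelities are computed once per (protein, cluster) pair.
    """
    edges = network.edges
    clustered = set(clustering.assignment)
    if clustered != edges:
        missing = sorted(edges - clustered)[:5]
        extra = sorted(clustered - edges)[:5]
        raise ValueError(
            "clustering does not partition the network's interactions: "
            f"{len(edges - clustered)} unclustered (e.g. {missing}), "
            f"{len(clustered - edges)} unknown (e.g. {extra})"
        )
    L_total = network.n_edges
    cluster_sizes = clustering.sizes()

    # links of protein p inside cluster c, for clusters touching p
    L_pc: dict[tuple[str, int], int] = {}
    for edge, c in clustering.assignment.items():
        for p in edge:
            L_pc[(p, c)] = L_pc.get((p, c), 0) + 1

    fid_cache: dict[tuple[str, int], float] = {}

    def fid(p: str, c: int) -> float:
        key = (p, c)
        if key not in fid_cache:
            ctx = FidelityContext(
                L_pc=L_pc[key],
                L_p=network.degree(p),
                L_c=cluster_sizes[c],
                L_total=L_total,
            )
            fid_cache[key] = fidelity(ctx)
        return fid_cache[key]

    scores: dict[Edge, float] = {}
    for edge, c in clustering.assignment.items():
        p1, p2 = edge
        scores[edge] = fid(p1, c) * fid(p2, c)
    return ConfidenceResult(
        scores=scores,
        fidelity=fid_cache,
        clustering=clustering,
        inflation=inflation,
    )
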