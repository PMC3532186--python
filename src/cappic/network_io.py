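"""Reading, writing and in-memory representation of interaction networks.

An interaction network is an undirected simple graph whose nodes are
opaque protein/gene identifiers.  Edges may carry an experimental
evidence weight (positive real) and/or a publication count (non-negative
integer).  Two plain-text formats are supported: tab/whitespace separated
edge lists (``tsv``) and the Cytoscape SIF dialect
``node1<TAB>relation<TAB>node2`` (the relation token is ignored).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


class NetworkIOError(ValueError):
    """Malformed input file or inconsistent write request."""


def canonical_edge(u: str, v: str) -> Edge:
    """Return the unordered pair (u, v) in canonical (sorted) order."""
    return (u, v) if u <= v else (v, u)


class InteractionNetwork:
    """Undirected simple graph of proteins with optional edge annotations.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is
    a node.  Edges are identified by their canonical (lexicographically
    sorted) endpoint pair throughout the package.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        weights: Mapping[Edge, float] | None = None,
        evidence: Mapping[Edge, int] | None = None,
    ) -> "InteractionNetwork":
        net = cls()
        for u, v in edges:
            net.add_edge(u, v)
        if weights:
            for e, w in weights.items():
                net.set_weight(*e, float(w))
        if evidence:
            for e, c in evidence.items():
                net.set_evidence(*e, int(c))
        return net

    def add_edge(
        self,
        u: str,
        v: str,
        weight: float | None = None,
        evidence: int | None = None,
    ) -> None:
        """Add edge u-v; duplicates merge by keeping the maximum weight
        and maximum evidence count (order-independent, conservative)."""
        if u == v:
            raise NetworkIOError(f"self-loop {u!r}-{v!r} is not allowed")
        a, b = canonical_edge(u, v)
        if self._g.has_edge(a, b):
            data = self._g[a][b]
            if weight is not None:
                data["weight"] = max(weight, data.get("weight", weight))
            if evidence is not None:
                data["evidence"] = max(evidence, data.get("evidence", evidence))
            return
        attrs: dict = {}
        if weight is not None:
            attrs["weight"] = float(weight)
        if evidence is not None:
            attrs["evidence"] = int(evidence)
        self._g.add_edge(a, b, **attrs)

    def set_weight(self, u: str, v: str, weight: float) -> None:
        a, b = canonical_edge(u, v)
        self._g[a][b]["weight"] = float(weight)

    def set_evidence(self, u: str, v: str, count: int) -> None:
        a, b = canonical_edge(u, v)
        self._g[a][b]["evidence"] = int(count)

    # -- queries -------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[Edge]:
        return {canonical_edge(u, v) for u, v in self._g.edges}

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def degree(self, node: str) -> int:
        return self._g.degree(node)

    def degree_map(self) -> dict[str, int]:
        return dict(self._g.degree())

    def neighbors(self, node: str) -> set[str]:
        return set(self._g.neighbors(node))

    def incident_edges(self, node: str) -> list[Edge]:
        return [canonical_edge(node, nbr) for nbr in self._g.neighbors(node)]

    def weight(self, u: str, v: str, default: float = 1.0) -> float:
        a, b = canonical_edge(u, v)
        return float(self._g[a][b].get("weight", default))

    def evidence(self, u: str, v: str, default: int = 0) -> int:
        a, b = canonical_edge(u, v)
        return int(self._g[a][b].get("evidence", default))

    def has_weights(self) -> bool:
        return any("weight" in d for _, _, d in self._g.edges(data=True))

    def evidence_map(self) -> dict[Edge, int]:
        return {
            canonical_edge(u, v): int(d["evidence"])
            for u, v, d in self._g.edges(data=True)
            if "evidence" in d
        }

    def weight_map(self) -> dict[Edge, float]:
        return {
            canonical_edge(u, v): float(d["weight"])
            for u, v, d in self._g.edges(data=True)
            if "weight" in d
        }

    def n_components(self) -> int:
        return nx.number_connected_components(self._g)

    def copy(self) -> "InteractionNetwork":
        net = InteractionNetwork()
        net._g = self._g.copy()
        return net

    def to_networkx(self) -> nx.Graph:
        """A copy of the underlying networkx graph."""
        return self._g.copy()

    def __iter__(self) -> Iterator[Edge]:
        return iter(self.sorted_edges())

    def __len__(self) -> int:
        return self.n_edges

    def __repr__(self) -> str:
        return (
            f"InteractionNetwork({self.n_nodes} nodes, {self.n_edges} edges)"
        )


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_network(
    path: str | Path,
    format: str = "tsv",
    weight_col: int | None = None,
    evidence_col: int | None = None,
) -> InteractionNetwork:
    """Read an interaction network from a plain-text edge list.

    Parameters
    ----------
    path:
        Input file.  Lines starting with ``#`` are comments; a header
        line is detected when the third field of the first data row is
        non-numeric.
    format:
        ``"tsv"`` (whitespace/tab separated ``node1 node2 [weight]
        [evidence]``) or ``"sif"`` (``node1 relation node2``).
    weight_col, evidence_col:
        Zero-based column indices overriding the default role assignment
        (TSV: column 2 = weight, column 3 = evidence count).

    Duplicate rows (including reversed duplicates) collapse to a single
    edge keeping the maximum weight/evidence.  Self-loop rows are
    dropped with a warning.  Node identifiers are case-sensitive and
    whitespace-trimmed.
    """
    if format not in ("tsv", "sif"):
        raise NetworkIOError(f"unknown format {format!r}")
    path = Path(path)
    net = InteractionNetwork()
    n_rows = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) == 1:
                fields = line.split()
            if format == "sif":
                if len(fields) != 3:
                    raise NetworkIOError(
                        f"{path}:{lineno}: SIF row needs 3 columns, "
                        f"got {len(fields)}"
                    )
                u, _, v = fields
                weight = evidence = None
            else:
                if len(fields) < 2:
                    raise NetworkIOError(
                        f"{path}:{lineno}: expected at least 2 columns, "
                        f"got {len(fields)}"
                    )
                u, v = fields[0], fields[1]
                if n_rows == 0 and (u.lower(), v.lower()) == ("node1", "node2"):
                    continue
                wc = weight_col if weight_col is not None else 2
                ec = evidence_col if evidence_col is not None else 3
                weight = evidence = None
                if len(fields) > wc:
                    tok = fields[wc]
                    if n_rows == 0 and not _is_number(tok):
                        # header row: skip entirely
                        continue
                    if not _is_number(tok):
                        raise NetworkIOError(
                            f"{path}:{lineno}: non-numeric weight {tok!r}"
                        )
                    weight = float(tok)
                if len(fields) > ec and ec != wc:
                    tok = fields[ec]
                    if not _is_number(tok):
                        raise NetworkIOError(
                            f"{path}:{lineno}: non-numeric evidence "
                            f"count {tok!r}"
                        )
                    evidence = int(float(tok))
            n_rows += 1
            if u == v:
                logger.warning(
                    "%s:%d: dropping self-loop %r", path, lineno, u
                )
                continue
            net.add_edge(u, v, weight=weight, evidence=evidence)
    if n_rows == 0:
        raise NetworkIOError(f"{path}: no data rows")
    return net


def write_scored_network(
    network: InteractionNetwork,
    scores: Mapping[Edge, float],
    path: str | Path,
    decimals: int = 6,
) -> None:
    """Write a TSV with columns node1, node2, confidence.

    Rows are ordered lexicographically by canonical endpoint pair so the
    output is deterministic.  Every edge of the network must have a
    score.
    """
    missing = [e for e in network.edges if e not in scores]
    if missing:
        raise NetworkIOError(
            f"missing scores for {len(missing)} edge(s), e.g. "
            f"{sorted(missing)[:5]}"
        )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tconfidence\n")
        for u, v in network.sorted_edges():
            fh.write(f"{u}\t{v}\t{scores[(u, v)]:.{decimals}f}\n")


def write_network(
    network: InteractionNetwork, path: str | Path, decimals: int = 6
) -> None:
    """Write a plain edge-list TSV (node1, node2[, weight][, evidence])."""
    path = Path(path)
    has_w = network.has_weights()
    has_e = bool(network.evidence_map())
    with open(path, "w") as fh:
        header = ["node1", "node2"]
        if has_w:
            header.append("weight")
        if has_e:
            header.append("evidence")
        fh.write("\t".join(header) + "\n")
        for u, v in network.sorted_edges():
            row = [u, v]
            if has_w:
                row.append(f"{network.weight(u, v):.{decimals}f}")
            if has_e:
                row.append(str(network.evidence(u, v)))
            fh.write("\t".join(row) + "\n")
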