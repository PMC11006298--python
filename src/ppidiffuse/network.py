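"""Protein-protein interaction network IO and graph utilities.

Networks are undirected simple graphs over string identifiers with a
confidence weight in [0, 1] per edge. Two on-disk dialects are supported:
the STRING ``protein.links`` format (space separated, integer combined
score on a 0-1000 scale, every edge listed in both orientations) and a
generic tab-separated edge list. Gene symbols are translated to network
identifiers through a simple two-column alias table.
"""

from __future__ import annotations

import gzip
import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "AliasMap",
    "NetworkParseError",
    "read_string_links",
    "read_edge_list",
    "write_edge_list",
    "read_alias_map",
    "map_seed_symbols",
    "induced_subgraph",
]


class NetworkParseError(ValueError):
    """Raised when a network or alias file is malformed."""


@dataclass
class Network:
    """An undirected simple graph with per-edge confidence weights.

    Invariants (enforced by the readers): no self loops, each unordered
    pair stored once, every edge weight >= the cutoff recorded in
    ``meta['cutoff']``.
    """

    graph: nx.Graph
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        """Node identifiers in sorted order (the canonical ordering)."""
        return sorted(self.graph.nodes)

    def density(self) -> float:
        n = self.n_nodes
        if n < 2:
            raise ValueError("density undefined for networks with < 2 nodes")
        return 2.0 * self.n_edges / (n * (n - 1))

    def has_node(self, node: str) -> bool:
        return node in self.graph

    def adjacency(self, weighted: bool = False) -> sp.csr_array:
        """Sparse adjacency in sorted-node order (binary unless weighted)."""
        order = self.nodes
        a = nx.to_scipy_sparse_array(
            self.graph, nodelist=order, weight="weight" if weighted else None
        )
        return sp.csr_array(a, dtype=float)

    def degrees(self) -> np.ndarray:
        """Unweighted degrees in sorted-node order."""
        return np.array([self.graph.degree(v) for v in self.nodes], dtype=int)

    def edge_tuples(self) -> list[tuple[str, str, float]]:
        """Edges as sorted ``(u, v, weight)`` with u < v, for diffing."""
        out = []
        for u, v, w in self.graph.edges(data="weight", default=1.0):
            a, b = (u, v) if u <= v else (v, u)
            out.append((a, b, float(w)))
        return sorted(out)


@dataclass
class AliasMap:
    """Gene symbol -> network identifier translation (many-to-one allowed).

    ``unmapped`` records symbols seen during resolution that had no target;
    it is filled by :func:`map_seed_symbols`, not by the reader.
    """

    entries: dict[str, str] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)

    def get(self, symbol: str) -> str | None:
        return self.entries.get(symbol)

    @classmethod
    def identity(cls, symbols: Iterable[str]) -> "AliasMap":
        return cls(entries={s: s for s in symbols})


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _build_network(
    edges: Mapping[tuple[str, str], float], meta: dict
) -> Network:
    g = nx.Graph()
    for (u, v), w in edges.items():
        g.add_edge(u, v, weight=w)
    meta = dict(meta)
    meta["n_nodes"] = g.number_of_nodes()
    meta["n_edges"] = g.number_of_edges()
    return Network(graph=g, meta=meta)


def read_string_links(path: str | Path, cutoff: float = 0.7) -> Network:
    """Read a STRING ``protein.links`` file, keeping edges at or above *cutoff*.

    The file is space separated with header ``protein1 protein2
    combined_score``; scores are integers on a 0-1000 scale and every edge
    appears in both orientations. An edge is kept when ``combined_score /
    1000 >= cutoff`` (a 0.7 cutoff therefore means combined_score >= 700).
    Self loops are dropped; the duplicate orientation is collapsed, with
    mismatching duplicate scores treated as a parse error. Gzip-compressed
    files (``.gz``) are handled transparently.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    edges: dict[tuple[str, str], float] = {}
    with _open_text(path) as fh:
        header = fh.readline()
        cols = header.split()
        if cols[:3] != ["protein1", "protein2", "combined_score"]:
            raise NetworkParseError(
                f"{path}: line 1: expected header "
                f"'protein1 protein2 combined_score', got {header.strip()!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 3:
                raise NetworkParseError(
                    f"{path}: line {lineno}: expected 3 fields, got {len(parts)}"
                )
            u, v, raw = parts[0], parts[1], parts[2]
            try:
                score = int(raw)
            except ValueError as exc:
                raise NetworkParseError(
                    f"{path}: line {lineno}: combined_score {raw!r} is not an integer"
                ) from exc
            if not 0 <= score <= 1000:
                raise NetworkParseError(
                    f"{path}: line {lineno}: combined_score {score} outside 0-1000"
                )
            w = score / 1000.0
            if u == v:
                continue
            if w < cutoff:
                continue
            key = (u, v) if u <= v else (v, u)
            if key in edges and edges[key] != w:
                raise NetworkParseError(
                    f"{path}: line {lineno}: edge {key} listed with conflicting "
                    f"scores ({edges[key] * 1000:.0f} vs {score})"
                )
            edges[key] = w
    return _build_network(
        edges, {"source": str(path), "format": "string_links", "cutoff": cutoff}
    )


def read_edge_list(path: str | Path) -> Network:
    """Read a generic TSV edge list (``node_a  node_b  [weight]``).

    Weight defaults to 1.0. A pair listed twice with different weights is an
    error (the intended weight would be ambiguous); an exact duplicate is
    collapsed silently. The recorded cutoff is 0.
    """
    edges: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    with _open_text(path) as fh:
        header = fh.readline()
        cols = header.rstrip("\n").split("\t")
        if len(cols) < 2 or cols[0] != "node_a" or cols[1] != "node_b":
            raise NetworkParseError(
                f"{path}: line 1: expected header 'node_a\\tnode_b[\\tweight]', "
                f"got {header.strip()!r}"
            )
        has_weight = len(cols) >= 3 and cols[2] == "weight"
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise NetworkParseError(
                    f"{path}: line {lineno}: expected >= 2 fields"
                )
            u, v = parts[0], parts[1]
            w = 1.0
            if has_weight and len(parts) >= 3 and parts[2] != "":
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise NetworkParseError(
                        f"{path}: line {lineno}: weight {parts[2]!r} not a number"
                    ) from exc
            if u == v:
                continue
            nodes.update((u, v))
            key = (u, v) if u <= v else (v, u)
            if key in edges and edges[key] != w:
                raise NetworkParseError(
                    f"{path}: line {lineno}: duplicate edge {key} with "
                    f"conflicting weights ({edges[key]} vs {w})"
                )
            edges[key] = w
    net = _build_network(
        edges, {"source": str(path), "format": "edge_list", "cutoff": 0.0}
    )
    return net


def write_edge_list(network: Network, path: str | Path) -> None:
    """Serialise as a sorted TSV edge list (stable byte-for-byte output)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for u, v, w in network.edge_tuples():
            fh.write(f"{u}\t{v}\t{w:g}\n")


def read_alias_map(path: str | Path) -> AliasMap:
    """Read a two-column TSV ``symbol  identifier`` alias table.

    A symbol appearing on multiple rows with conflicting targets resolves to
    its first occurrence; the conflict is logged as a warning so the choice
    is auditable.
    """
    entries: dict[str, str] = {}
    with _open_text(path) as fh:
        first = fh.readline()
        lines = []
        cols = first.rstrip("\n").split("\t")
        # header row is optional; accept both with and without
        if cols[:2] != ["symbol", "identifier"]:
            lines.append((1, first))
        for lineno, line in enumerate(fh, start=2):
            lines.append((lineno, line))
        for lineno, line in lines:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise NetworkParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields"
                )
            symbol, ident = parts[0], parts[1]
            if symbol in entries:
                if entries[symbol] != ident:
                    logger.warning(
                        "alias conflict for %s: keeping %s, ignoring %s (line %d)",
                        symbol, entries[symbol], ident, lineno,
                    )
                continue
            entries[symbol] = ident
    return AliasMap(entries=entries)


def map_seed_symbols(
    symbols: Iterable[str],
    aliases: AliasMap | None,
    network: Network,
) -> tuple[list[str], list[str]]:
    """Translate gene symbols to network nodes.

    Symbols without an alias entry, or whose alias target is absent from the
    network, are returned as unmapped. Two symbols aliasing to one node map
    to a single node (set semantics). ``aliases=None`` means symbols already
    are network identifiers. Both outputs are sorted for determinism.
    """
    mapped: set[str] = set()
    unmapped: list[str] = []
    for symbol in symbols:
        target = symbol if aliases is None else aliases.get(symbol)
        if target is not None and network.has_node(target):
            mapped.add(target)
        else:
            unmapped.append(symbol)
    if aliases is not None:
        aliases.unmapped = sorted(set(unmapped))
    return sorted(mapped), sorted(set(unmapped))


def induced_subgraph(network: Network, nodeset: Iterable[str]) -> Network:
    """Subgraph on *nodeset* with exactly the edges internal to it.

    Nodes not present in the network are ignored with a warning.
    """
    nodeset = set(nodeset)
    missing = nodeset - set(network.graph.nodes)
    if missing:
        warnings.warn(
            f"{len(missing)} requested nodes absent from network; ignored",
            stacklevel=2,
        )
    keep = nodeset - missing
    sub = nx.Graph(network.graph.subgraph(keep))
    meta = dict(network.meta)
    meta.update(induced_from=meta.get("source", "?"), n_nodes=sub.number_of_nodes(),
                n_edges=sub.number_of_edges())
    return Network(graph=sub, meta=meta)
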