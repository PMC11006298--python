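"""Network diffusion on the regularised Laplacian kernel.

The signed seed vector s is smoothed over the graph by f = K s with
K = (I + sigma * L)^-1 and L = D - A the (combinatorial) graph Laplacian.
K is symmetric positive definite and row-stochastic in the sense K 1 = 1,
so diffusion conserves total seed mass: sum(f) = sum(s). sigma controls
the smoothing range: sigma -> 0 returns the seeds unchanged, sigma -> inf
averages the seeds over each connected component.

The extreme tails of the diffusion scores — the nodes with the most
positive and the most negative smoothed evidence — are selected separately
for downstream pathway enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import Network
from .seeds import SeedVector

__all__ = [
    "DiffusionResult",
    "LaplacianKernel",
    "laplacian",
    "regularized_laplacian_kernel",
    "diffuse",
    "select_extremes",
    "run_diffusion",
    "write_diffusion_table",
]

#: Below this node count the kernel is built densely; above, only the
#: factorised linear solve is kept (the explicit inverse is never formed).
DENSE_LIMIT = 2000


def laplacian(network: Network, weighted: bool = False) -> sp.csr_array:
    """Graph Laplacian L = D - A in sorted-node order.

    A is binary by default; with ``weighted`` the edge confidences are
    used. Row sums of L are exactly zero.
    """
    order = network.nodes
    lap = nx.laplacian_matrix(
        network.graph, nodelist=order, weight="weight" if weighted else None
    )
    return sp.csr_array(lap, dtype=float)


def regularized_laplacian_kernel(L, sigma: float = 1.0) -> np.ndarray:
    """Dense regularised Laplacian kernel K = (I + sigma L)^-1.

    Computed by solving (I + sigma L) K = I rather than via an explicit
    matrix inverse. Intended for small to medium graphs; large graphs
    should use :class:`LaplacianKernel`, which only ever factorises.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if sp.issparse(L):
        L = L.toarray()
    L = np.asarray(L, dtype=float)
    n = L.shape[0]
    K = np.linalg.solve(np.eye(n) + sigma * L, np.eye(n))
    if not np.all(np.isfinite(K)):
        raise FloatingPointError("kernel solve produced non-finite entries")
    return K


class LaplacianKernel:
    """Factorised regularised-Laplacian smoother for one network.

    Stores a sparse LU factorisation of (I + sigma L); applying it to a
    seed vector is a single triangular solve, so many seed vectors can be
    diffused cheaply on the same network.
    """

    def __init__(self, network: Network, sigma: float = 1.0,
                 weighted: bool = False):
        if sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {sigma}")
        self.network = network
        self.sigma = sigma
        self.weighted = weighted
        self.node_order = network.nodes
        L = laplacian(network, weighted=weighted)
        n = len(self.node_order)
        A = (sp.identity(n, format="csc") + sigma * L).tocsc()
        self._solve = spla.factorized(A)

    def apply(self, s: np.ndarray) -> np.ndarray:
        """f = (I + sigma L)^-1 s for a dense vector in node order."""
        s = np.asarray(s, dtype=float)
        if s.shape != (len(self.node_order),):
            raise ValueError(
                f"seed vector length {s.shape} does not match "
                f"{len(self.node_order)} network nodes"
            )
        f = self._solve(s)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError("diffusion solve produced non-finite scores")
        return f


def diffuse(K: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Matrix-form diffusion f = K s (for an explicitly built kernel)."""
    K = np.asarray(K, dtype=float)
    s = np.asarray(s, dtype=float)
    if K.shape[1] != s.shape[0]:
        raise ValueError(f"dimension mismatch: K {K.shape} vs s {s.shape}")
    return K @ s


def select_extremes(
    scores: Mapping[str, float],
    q: float = 0.01,
    tie_policy: str = "lexicographic",
) -> tuple[list[str], list[str]]:
    """The m = round(q * |V|) most positive and most negative scored nodes.

    Boundary ties are broken lexicographically by identifier so the
    selection is deterministic; with all-equal scores the selection
    degenerates to the lexicographically first m identifiers.
    """
    if not 0.0 < q < 0.5:
        raise ValueError(f"quantile q must be in (0, 0.5), got {q}")
    if tie_policy != "lexicographic":
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    nodes = list(scores)
    m = round(q * len(nodes))
    if m == 0:
        raise ValueError(
            f"q={q} selects 0 of {len(nodes)} nodes; increase q or network size"
        )
    pos = sorted(nodes, key=lambda v: (-scores[v], v))[:m]
    neg = sorted(nodes, key=lambda v: (scores[v], v))[:m]
    return sorted(pos), sorted(neg)


@dataclass
class DiffusionResult:
    scores: dict[str, float]
    top_positive: list[str]
    top_negative: list[str]
    quantile: float
    sigma: float
    weighted: bool
    seed_nodes: list[str] = field(default_factory=list)


def run_diffusion(
    network: Network,
    seed: SeedVector,
    sigma: float = 1.0,
    q: float = 0.01,
    weighted: bool = False,
) -> DiffusionResult:
    """Diffuse a seed vector and select the extreme-score tails."""
    kernel = LaplacianKernel(network, sigma=sigma, weighted=weighted)
    s = seed.dense(kernel.node_order)
    f = kernel.apply(s)
    scores = {v: float(x) for v, x in zip(kernel.node_order, f)}
    pos, neg = select_extremes(scores, q=q)
    return DiffusionResult(
        scores=scores,
        top_positive=pos,
        top_negative=neg,
        quantile=q,
        sigma=sigma,
        weighted=weighted,
        seed_nodes=sorted(seed.scores),
    )


def write_diffusion_table(
    result: DiffusionResult, seed: SeedVector, path: str | Path
) -> None:
    """TSV ``node  seed_score  diffusion_score  selected`` (+/-/.)."""
    pos = set(result.top_positive)
    neg = set(result.top_negative)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("node\tseed_score\tdiffusion_score\tselected\n")
        for node in sorted(result.scores):
            mark = "+" if node in pos else "-" if node in neg else "."
            fh.write(
                f"{node}\t{seed.scores.get(node, 0.0):.10g}\t"
                f"{result.scores[node]:.10g}\t{mark}\n"
            )
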