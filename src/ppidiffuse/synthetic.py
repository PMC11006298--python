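"""Synthetic benchmark generator with planted ground truth.

Emulates the three inputs of the analysis at desk scale so every stage is
exercisable without external downloads:

* a sparse undirected interaction network (Erdős–Rényi or preferential
  attachment) with a planted densified module — the "functionally related"
  seed neighbourhood the connectivity test should detect;
* a DEG evidence table in the star-tier dialect, where module genes carry
  small p-values (Beta(a, 1)) with a coherent direction and background
  genes carry uniform p-values; only rows significant at p < 0.05 are
  emitted, as in curated literature tables;
* a GMT pathway collection in which "true" pathways overlap the planted
  module and decoys are drawn from the background.

Every generator is reproducible bit-for-bit given its rng seed, and the
ground truth needed for recovery scoring is returned (and serialised)
explicitly.

Defaults are the benchmark's study conditions: a 2,000-node preferential
attachment graph, a 45-node planted module (the size of the mapped seed
set the pipeline was designed around), 5 true and 45 decoy pathways of
20-80 members with 50% module overlap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .network import Network, write_edge_list
from .enrichment import GeneSetCollection, write_gmt

__all__ = [
    "SyntheticTruth",
    "generate_network",
    "plant_module",
    "generate_deg_table",
    "generate_pathways",
    "generate_bundle",
]

TIER_EDGES = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class SyntheticTruth:
    """Ground truth of one generated benchmark instance."""

    module_nodes: list[str] = field(default_factory=list)
    true_pathways: list[str] = field(default_factory=list)
    decoy_pathways: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    rng_seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def _node_name(i: int) -> str:
    return f"g{i:04d}"


def generate_network(
    n: int, model: str = "PA", param: float = 3, rng_seed: int = 0
) -> Network:
    """Random undirected simple graph on nodes g0000..g{n-1}.

    ``ER``: Erdős–Rényi G(n, p) with *param* the edge probability.
    ``PA``: preferential attachment with *param* edges per new node
    (heavy-tailed degrees, closer to PPI network topology).
    """
    if n < 10:
        raise ValueError("need n >= 10")
    if model == "ER":
        if not 0.0 <= param <= 1.0:
            raise ValueError(f"ER edge probability must be in [0, 1], got {param}")
        g = nx.gnp_random_graph(n, param, seed=rng_seed)
    elif model == "PA":
        m = int(param)
        if not 1 <= m < n:
            raise ValueError(f"PA attachment parameter must be in [1, n), got {param}")
        g = nx.barabasi_albert_graph(n, m, seed=rng_seed)
    else:
        raise ValueError(f"unknown model {model!r}")
    relabel = {i: _node_name(i) for i in range(n)}
    g = nx.relabel_nodes(g, relabel)
    g.add_nodes_from(relabel.values())  # keep isolated nodes (ER, small p)
    nx.set_edge_attributes(g, 1.0, "weight")
    return Network(
        graph=g,
        meta={"source": f"synthetic:{model}", "cutoff": 0.0,
              "model": model, "param": param, "rng_seed": rng_seed,
              "n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges()},
    )


def plant_module(
    network: Network, m: int = 45, p_in: float = 0.25, rng_seed: int = 0
) -> tuple[Network, list[str]]:
    """Densify a random m-node subset: add each absent internal edge w.p. p_in.

    Returns the augmented network and the sorted module membership. With
    p_in = 1 the module becomes a clique; with p_in = 0 the network is
    returned unchanged (same member list is still drawn).
    """
    nodes = network.nodes
    if m > len(nodes):
        raise ValueError(f"module size {m} exceeds network size {len(nodes)}")
    if not 0.0 <= p_in <= 1.0:
        raise ValueError(f"p_in must be in [0, 1], got {p_in}")
    rng = np.random.default_rng(rng_seed)
    module = sorted(rng.choice(len(nodes), size=m, replace=False).tolist())
    module_nodes = [nodes[i] for i in module]
    g = network.graph.copy()
    for i in range(m):
        for j in range(i + 1, m):
            u, v = module_nodes[i], module_nodes[j]
            if not g.has_edge(u, v) and rng.random() < p_in:
                g.add_edge(u, v, weight=1.0)
    meta = dict(network.meta)
    meta.update(planted_module_size=m, planted_p_in=p_in,
                n_nodes=g.number_of_nodes(), n_edges=g.number_of_edges())
    return Network(graph=g, meta=meta), module_nodes


def generate_deg_table(
    module_nodes: list[str],
    background_nodes: list[str],
    n_signal: int = 45,
    n_background: int = 100,
    beta_a: float = 0.05,
    coherence: float = 0.9,
    rng_seed: int = 0,
    tiers: bool = True,
    path: str | Path | None = None,
) -> tuple[list[dict], dict]:
    """Evidence table with module signal and uniform background noise.

    Signal genes (a sample of the module) get p ~ Beta(beta_a, 1) — heavily
    right-skewed toward 0 — and direction UP with probability *coherence*.
    Background genes get p ~ Uniform(0, 1) and a fair-coin direction. Rows
    with p >= 0.05 are dropped: like a curated literature table, only
    nominally significant findings appear. With ``tiers`` the p-values are
    binned into the star dialect, else left numeric.

    Returns (rows, truth_info); each row is a dict with keys
    gene/direction/significance/source.
    """
    if n_signal > len(module_nodes):
        raise ValueError("n_signal exceeds module size")
    if not 0.0 < beta_a < 1.0:
        raise ValueError("beta_a must be in (0, 1)")
    if not 0.5 <= coherence <= 1.0:
        raise ValueError("coherence must be in [0.5, 1]")
    rng = np.random.default_rng(rng_seed)
    signal = [module_nodes[i] for i in
              sorted(rng.choice(len(module_nodes), size=n_signal, replace=False))]
    if n_background > len(background_nodes):
        raise ValueError("n_background exceeds background pool")
    bg = [background_nodes[i] for i in
          sorted(rng.choice(len(background_nodes), size=n_background,
                            replace=False))]
    rows: list[dict] = []
    emitted_signal: list[str] = []
    for gene in signal:
        p = float(rng.beta(beta_a, 1.0))
        p = max(p, 1e-300)
        direction = "UP" if rng.random() < coherence else "DOWN"
        if p >= 0.05:
            continue
        rows.append(_deg_row(gene, direction, p, "synthetic signal", tiers))
        emitted_signal.append(gene)
    emitted_bg: list[str] = []
    for gene in bg:
        p = float(rng.uniform(0.0, 1.0))
        p = max(p, 1e-300)
        direction = "UP" if rng.random() < 0.5 else "DOWN"
        if p >= 0.05:
            continue
        rows.append(_deg_row(gene, direction, p, "synthetic background", tiers))
        emitted_bg.append(gene)
    truth = {
        "signal_genes": signal,
        "emitted_signal_genes": emitted_signal,
        "emitted_background_genes": emitted_bg,
        "params": {"n_signal": n_signal, "n_background": n_background,
                   "beta_a": beta_a, "coherence": coherence,
                   "tiers": tiers, "rng_seed": rng_seed},
    }
    if path is not None:
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("gene\tdirection\tsignificance\tsource\n")
            for row in rows:
                fh.write(
                    f"{row['gene']}\t{row['direction']}\t"
                    f"{row['significance']}\t{row['source']}\n"
                )
    return rows, truth


def _deg_row(gene: str, direction: str, p: float, source: str,
             tiers: bool) -> dict:
    if tiers:
        sig = next(t for edge, t in TIER_EDGES if p < edge)
    else:
        sig = f"{p:.6g}"
    return {"gene": gene, "direction": direction, "significance": sig,
            "source": source}


def generate_pathways(
    module_nodes: list[str],
    all_nodes: list[str],
    n_true: int = 5,
    n_decoy: int = 45,
    size_range: tuple[int, int] = (20, 80),
    overlap_frac: float = 0.5,
    rng_seed: int = 0,
) -> tuple[GeneSetCollection, SyntheticTruth]:
    """True pathways overlap the module; decoys are background-only.

    Each true pathway of size s contains ceil(overlap_frac * s) module
    members, the rest background; decoys draw every member from the
    background. Returns the collection and a truth record with the
    true/decoy id lists.
    """
    if not 0.0 < overlap_frac <= 1.0:
        raise ValueError("overlap_frac must be in (0, 1]")
    lo, hi = size_range
    if not 1 <= lo <= hi:
        raise ValueError(f"bad size_range {size_range}")
    needed = math.ceil(overlap_frac * hi)
    if needed > len(module_nodes):
        raise ValueError(
            f"module of {len(module_nodes)} cannot supply up to {needed} "
            f"overlap members"
        )
    module_set = set(module_nodes)
    background = sorted(set(all_nodes) - module_set)
    rng = np.random.default_rng(rng_seed)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    true_ids, decoy_ids = [], []
    for i in range(n_true):
        size = int(rng.integers(lo, hi + 1))
        n_mod = math.ceil(overlap_frac * size)
        mod_part = rng.choice(len(module_nodes), size=n_mod, replace=False)
        bg_part = rng.choice(len(background), size=size - n_mod, replace=False)
        members = tuple(sorted(
            [module_nodes[j] for j in mod_part]
            + [background[j] for j in bg_part]
        ))
        set_id = f"TRUE_{i:02d}"
        sets[set_id] = (f"planted pathway {i}", members)
        true_ids.append(set_id)
    for i in range(n_decoy):
        size = int(rng.integers(lo, hi + 1))
        bg_part = rng.choice(len(background), size=size, replace=False)
        members = tuple(sorted(background[j] for j in bg_part))
        set_id = f"DECOY_{i:02d}"
        sets[set_id] = (f"decoy pathway {i}", members)
        decoy_ids.append(set_id)
    collection = GeneSetCollection(sets=sets, source="synthetic")
    truth = SyntheticTruth(
        module_nodes=sorted(module_nodes),
        true_pathways=true_ids,
        decoy_pathways=decoy_ids,
        params={"n_true": n_true, "n_decoy": n_decoy,
                "size_range": list(size_range), "overlap_frac": overlap_frac},
        rng_seed=rng_seed,
    )
    return collection, truth


def generate_bundle(
    outdir: str | Path,
    n: int = 2000,
    model: str = "PA",
    param: float = 3,
    module_size: int = 45,
    p_in: float = 0.25,
    n_signal: int | None = None,
    n_background: int = 100,
    beta_a: float = 0.05,
    coherence: float = 0.9,
    n_true: int = 5,
    n_decoy: int = 45,
    size_range: tuple[int, int] = (20, 80),
    overlap_frac: float = 0.5,
    tiers: bool = True,
    rng_seed: int = 0,
) -> SyntheticTruth:
    """Write a complete input bundle (edges, DEG table, aliases, GMT, truth).

    Sub-generators get distinct child seeds derived deterministically from
    *rng_seed*, so the bundle is reproducible byte-for-byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if n_signal is None:
        n_signal = module_size
    ss = np.random.SeedSequence(rng_seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    base = generate_network(n, model=model, param=param, rng_seed=seeds[0])
    net, module_nodes = plant_module(base, m=module_size, p_in=p_in,
                                     rng_seed=seeds[1])
    background = sorted(set(net.nodes) - set(module_nodes))
    generate_deg_table(
        module_nodes, background, n_signal=n_signal,
        n_background=n_background, beta_a=beta_a, coherence=coherence,
        rng_seed=seeds[2], tiers=tiers, path=outdir / "deg_table.tsv",
    )
    collection, truth = generate_pathways(
        module_nodes, net.nodes, n_true=n_true, n_decoy=n_decoy,
        size_range=size_range, overlap_frac=overlap_frac, rng_seed=seeds[3],
    )
    write_edge_list(net, outdir / "network.tsv")
    write_gmt(collection, outdir / "pathways.gmt")
    with open(outdir / "aliases.tsv", "wt", encoding="utf-8") as fh:
        fh.write("symbol\tidentifier\n")
        for v in net.nodes:
            fh.write(f"{v}\t{v}\n")
    truth.params.update(
        network={"n": n, "model": model, "param": param,
                 "module_size": module_size, "p_in": p_in},
        deg={"n_signal": n_signal, "n_background": n_background,
             "beta_a": beta_a, "coherence": coherence, "tiers": tiers},
    )
    truth.rng_seed = rng_seed
    truth.to_json(outdir / "truth.json")
    return truth
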