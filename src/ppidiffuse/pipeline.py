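"""End-to-end analysis: seeds -> connectivity -> diffusion -> enrichment.

``run_pipeline`` composes the four analysis stages on in-memory objects;
``run_pipeline_files`` is the same composition starting from the on-disk
formats (edge list / STRING links, DEG TSV, alias TSV, GMT). When an
output directory is given, every stage's result is serialised in a stable,
byte-reproducible form (sorted rows, fixed float formatting), so two runs
with the same inputs and seed produce identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .network import AliasMap, Network, read_alias_map, read_edge_list, \
    read_string_links
from .seeds import DEGRecord, SeedVector, build_seed_vector, parse_deg_table, \
    write_seed_vector
from .connectivity import ConnectivityResult, run_connectivity_test
from .diffusion import DiffusionResult, run_diffusion, write_diffusion_table
from .enrichment import EnrichmentRecord, GeneSetCollection, enrich, \
    enrichment_report, read_gmt

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_files",
           "recovery_metrics"]


@dataclass
class PipelineResult:
    seed_vector: SeedVector
    connectivity: ConnectivityResult
    diffusion: DiffusionResult
    positive_enrichment: list[EnrichmentRecord]
    negative_enrichment: list[EnrichmentRecord]
    params: dict = field(default_factory=dict)

    def passing_pathways(self) -> set[str]:
        """Pathways passing the filters in either selection tail."""
        return {
            r.pathway
            for r in (*self.positive_enrichment, *self.negative_enrichment)
            if r.passes_filters
        }


def run_pipeline(
    network: Network,
    records: Iterable[DEGRecord],
    collection: GeneSetCollection,
    aliases: AliasMap | None = None,
    combine: str = "sum",
    n_samples: int = 10_000,
    null_model: str = "uniform",
    sigma: float = 1.0,
    q: float = 0.01,
    weighted: bool = False,
    min_overlap: int = 3,
    alpha: float = 0.05,
    rng_seed: int = 0,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full network analysis of a DEG evidence table."""
    seed = build_seed_vector(records, aliases, network, combine=combine)
    conn = run_connectivity_test(
        network, sorted(seed.scores), n_samples=n_samples,
        null_model=null_model, rng_seed=rng_seed,
    )
    diff = run_diffusion(network, seed, sigma=sigma, q=q, weighted=weighted)
    universe = network.nodes
    pos = enrich(diff.top_positive, "POSITIVE", collection, universe,
                 min_overlap=min_overlap, alpha=alpha)
    neg = enrich(diff.top_negative, "NEGATIVE", collection, universe,
                 min_overlap=min_overlap, alpha=alpha)
    result = PipelineResult(
        seed_vector=seed,
        connectivity=conn,
        diffusion=diff,
        positive_enrichment=pos,
        negative_enrichment=neg,
        params={"combine": combine, "n_samples": n_samples,
                "null_model": null_model, "sigma": sigma, "q": q,
                "weighted": weighted, "min_overlap": min_overlap,
                "alpha": alpha, "rng_seed": rng_seed},
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_seed_vector(result.seed_vector, outdir / "seeds.tsv")
    result.connectivity.to_json(outdir / "connectivity.json")
    write_diffusion_table(result.diffusion, result.seed_vector,
                          outdir / "diffusion.tsv")
    enrichment_report(result.positive_enrichment, result.negative_enrichment,
                      outdir / "enrichment.tsv")
    summary = {
        "params": result.params,
        "n_seed_nodes": len(result.seed_vector.scores),
        "unmapped_symbols": result.seed_vector.unmapped,
        "connectivity": json.loads(result.connectivity.to_json()),
        "selection_size": len(result.diffusion.top_positive),
        "passing_pathways": sorted(result.passing_pathways()),
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def run_pipeline_files(
    network_path: str | Path,
    deg_path: str | Path,
    gmt_path: str | Path,
    alias_path: str | Path | None = None,
    network_format: str = "edge_list",
    cutoff: float = 0.7,
    **kwargs,
) -> PipelineResult:
    """File-based front end to :func:`run_pipeline`."""
    if network_format == "edge_list":
        network = read_edge_list(network_path)
    elif network_format == "string":
        network = read_string_links(network_path, cutoff=cutoff)
    else:
        raise ValueError(f"unknown network format {network_format!r}")
    records = parse_deg_table(deg_path)
    collection = read_gmt(gmt_path)
    aliases = read_alias_map(alias_path) if alias_path is not None else None
    return run_pipeline(network, records, collection, aliases=aliases, **kwargs)


def recovery_metrics(
    result: PipelineResult,
    true_pathways: Iterable[str],
    decoy_pathways: Iterable[str],
) -> dict:
    """Planted-truth recovery: true pathways found, decoys passing."""
    passing = result.passing_pathways()
    true_set = set(true_pathways)
    decoy_set = set(decoy_pathways)
    tp = sorted(passing & true_set)
    fp = sorted(passing & decoy_set)
    return {
        "n_true": len(true_set),
        "n_decoy": len(decoy_set),
        "true_recovered": len(tp),
        "decoys_passing": len(fp),
        "recovered_ids": tp,
        "false_positive_ids": fp,
    }
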