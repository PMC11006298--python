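"""Signed seed scores from differential-expression evidence.

Each row of a DEG evidence table carries a gene symbol, a regulation
direction (UP/DOWN), and a significance given either as a numeric p-value
or as a star tier (``*`` p < 0.05, ``**`` p < 0.01, ``***`` p < 0.001).
A row's seed score is sign(direction) * -log10(p): upregulation positive,
downregulation negative, stronger significance -> larger magnitude. Scores
are aggregated per network node to form the diffusion input vector.

A transcription-factor perturbation evidence table (THAP1 dystonia models,
51 rows over 49 genes) ships with the package as
``data/thap1_deg_table.tsv`` and is exposed via :func:`packaged_deg_table`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

from .network import AliasMap, Network, NetworkParseError, map_seed_symbols

logger = logging.getLogger(__name__)

__all__ = [
    "DEGRecord",
    "SeedVector",
    "TIER_P",
    "parse_deg_table",
    "packaged_deg_table",
    "tier_to_p",
    "record_score",
    "build_seed_vector",
    "write_seed_vector",
]

#: Star tier -> representative p-value (the tier's boundary; see docs).
TIER_P: dict[str, float] = {"*": 0.05, "**": 0.01, "***": 0.001}

_SIGN = {"UP": 1.0, "DOWN": -1.0}


@dataclass(frozen=True)
class DEGRecord:
    """One row of differential-expression evidence for one gene."""

    gene: str
    direction: Literal["UP", "DOWN"]
    p_value: float
    source: str = ""
    significance_raw: str = ""

    def __post_init__(self):
        if self.direction not in _SIGN:
            raise ValueError(f"direction must be UP or DOWN, got {self.direction!r}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value must be in (0, 1], got {self.p_value}")


@dataclass
class SeedVector:
    """Signed per-node seed scores with per-node provenance."""

    scores: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, list[DEGRecord]] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)
    combine: str = "sum"

    def __len__(self) -> int:
        return len(self.scores)

    def dense(self, node_order: list[str]) -> "np.ndarray":  # noqa: F821
        import numpy as np

        return np.array([self.scores.get(v, 0.0) for v in node_order])


def tier_to_p(tier: str) -> float:
    """Map a star tier to its boundary p-value (* 0.05, ** 0.01, *** 0.001)."""
    try:
        return TIER_P[tier]
    except KeyError:
        raise ValueError(f"unknown significance tier {tier!r}") from None


def _parse_significance(raw: str, gene: str, na_policy: str) -> float | None:
    """Resolve a significance cell to a p-value.

    Accepts a star tier, a comma-separated list of tiers (multi-study rows;
    the weakest tier, i.e. the largest boundary p, is used), a numeric
    p-value, or N/A. N/A resolves per *na_policy*: ``weakest_tier`` assigns
    tier * with a warning, ``drop`` returns None.
    """
    cell = raw.strip()
    if cell.upper() in {"N/A", "NA", ""}:
        if na_policy == "drop":
            logger.warning("dropping %s: significance N/A", gene)
            return None
        logger.warning("significance N/A for %s: assigned weakest tier (*)", gene)
        return TIER_P["*"]
    tokens = [t.strip() for t in cell.split(",") if t.strip()]
    if all(t in TIER_P for t in tokens):
        return max(tier_to_p(t) for t in tokens)
    try:
        p = float(cell)
    except ValueError:
        raise NetworkParseError(
            f"significance {raw!r} for {gene} is neither a tier nor a number"
        ) from None
    if not (0.0 < p <= 1.0):
        raise NetworkParseError(f"p-value {p} for {gene} outside (0, 1]")
    return p


def parse_deg_table(
    path: str | Path, na_policy: str = "weakest_tier"
) -> list[DEGRecord]:
    """Parse a TSV evidence table with columns gene/direction/significance/source.

    Direction tokens are matched case-insensitively. A gene may appear on
    several rows (conflicting evidence across studies is kept as-is and
    resolved later by the aggregation policy).
    """
    if na_policy not in {"weakest_tier", "drop"}:
        raise ValueError(f"unknown na_policy {na_policy!r}")
    records: list[DEGRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["gene", "direction", "significance"]
        if header[: len(required)] != required:
            raise NetworkParseError(
                f"{path}: expected columns gene/direction/significance[/source], "
                f"got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise NetworkParseError(
                    f"{path}: line {lineno}: expected >= 3 fields"
                )
            gene, direction_raw, sig = parts[0], parts[1], parts[2]
            source = parts[3] if len(parts) > 3 else ""
            direction = direction_raw.strip().upper()
            if direction not in _SIGN:
                raise NetworkParseError(
                    f"{path}: line {lineno}: unknown direction {direction_raw!r}"
                )
            p = _parse_significance(sig, gene, na_policy)
            if p is None:
                continue
            records.append(
                DEGRecord(
                    gene=gene.strip(),
                    direction=direction,  # type: ignore[arg-type]
                    p_value=p,
                    source=source,
                    significance_raw=sig.strip(),
                )
            )
    return records


def packaged_deg_table(na_policy: str = "weakest_tier") -> list[DEGRecord]:
    """The packaged THAP1-model DEG evidence table (51 rows, 49 genes)."""
    ref = resources.files("ppidiffuse").joinpath("data/thap1_deg_table.tsv")
    with resources.as_file(ref) as path:
        return parse_deg_table(path, na_policy=na_policy)


def record_score(record: DEGRecord) -> float:
    """Signed evidence score: sign(direction) * -log10(p)."""
    if record.p_value <= 0.0:
        raise ValueError("p-value 0 gives an infinite score")
    return _SIGN[record.direction] * (-math.log10(record.p_value))


def build_seed_vector(
    records: Iterable[DEGRecord],
    aliases: AliasMap | None,
    network: Network,
    combine: str = "sum",
    exclude: Iterable[str] = (),
) -> SeedVector:
    """Aggregate evidence rows into one signed score per network node.

    Symbols are mapped through the alias table; unmappable symbols are
    reported on the result, never scored. Multiple rows per node combine
    per *combine*: ``sum`` adds signed scores (contradictions attenuate);
    ``max_abs`` keeps the single largest-magnitude score, falling back to
    the sum on an exact magnitude tie. Genes in *exclude* (e.g. the
    perturbed transcription factor itself) are skipped.
    """
    if combine not in {"sum", "max_abs"}:
        raise ValueError(f"combine must be 'sum' or 'max_abs', got {combine!r}")
    exclude = set(exclude)
    records = [r for r in records if r.gene not in exclude]
    symbols = sorted({r.gene for r in records})
    mapped, unmapped = map_seed_symbols(symbols, aliases, network)
    mapped_set = set(mapped)
    sym_to_node = {
        s: (s if aliases is None else aliases.get(s)) for s in symbols
    }
    per_node: dict[str, list[DEGRecord]] = {}
    for rec in records:
        node = sym_to_node.get(rec.gene)
        if node in mapped_set:
            per_node.setdefault(node, []).append(rec)
    scores: dict[str, float] = {}
    for node in sorted(per_node):
        vals = [record_score(r) for r in per_node[node]]
        if combine == "sum" or len(vals) == 1:
            s = sum(vals)
        else:
            mags = [abs(v) for v in vals]
            top = max(mags)
            winners = [v for v, m in zip(vals, mags) if m == top]
            s = winners[0] if len(set(winners)) == 1 else sum(vals)
        scores[node] = s
    return SeedVector(
        scores=scores,
        provenance=per_node,
        unmapped=unmapped,
        combine=combine,
    )


def write_seed_vector(seed: SeedVector, path: str | Path) -> None:
    """Serialise as TSV ``node  score  n_records`` (sorted, reproducible)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("node\tscore\tn_records\n")
        for node in sorted(seed.scores):
            fh.write(
                f"{node}\t{seed.scores[node]:.10g}\t{len(seed.provenance[node])}\n"
            )
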