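"""Hypergeometric pathway over-representation of diffusion-score tails.

Each pathway in a GMT collection is tested for over-representation in a
selection of n nodes drawn from a universe of N nodes: with K pathway
members in the universe and k of them in the selection, the p-value is
the hypergeometric upper tail P(X >= k). A pathway "passes" under the
dot-plot filters: at least ``min_overlap`` selected members and p below
``alpha``. Benjamini-Hochberg q-values are reported alongside but do not
enter the pass/fail flag, which deliberately mirrors the raw-p filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import NetworkParseError

__all__ = [
    "GeneSetCollection",
    "EnrichmentRecord",
    "read_gmt",
    "write_gmt",
    "hypergeom_upper_tail",
    "enrich",
    "enrichment_report",
]


@dataclass
class GeneSetCollection:
    """Pathway id -> (description, members); members deduplicated."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id][1]

    def ids(self) -> list[str]:
        return sorted(self.sets)


@dataclass
class EnrichmentRecord:
    pathway: str
    direction: str  # POSITIVE or NEGATIVE selection tail
    k: int  # overlap: selection ∩ pathway (within universe)
    K: int  # pathway size within universe
    n: int  # selection size
    N: int  # universe size
    p: float
    q: float = float("nan")  # BH-adjusted, reported but not filtered on
    passes_filters: bool = False


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``set_id<TAB>description<TAB>member...`` per line.

    Duplicate members within a set are collapsed; duplicate set ids are an
    error.
    """
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise NetworkParseError(
                    f"{path}: line {lineno}: GMT line needs >= 3 fields "
                    f"(id, description, members)"
                )
            set_id, desc = parts[0], parts[1]
            if set_id in sets:
                raise NetworkParseError(
                    f"{path}: line {lineno}: duplicate set id {set_id!r}"
                )
            seen: dict[str, None] = {}
            for m in parts[2:]:
                if m:
                    seen.setdefault(m)
            members = tuple(seen)
            if not members:
                raise NetworkParseError(
                    f"{path}: line {lineno}: set {set_id!r} has no members"
                )
            sets[set_id] = (desc, members)
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for set_id in sorted(collection.sets):
            desc, members = collection.sets[set_id]
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    The probability that a uniform n-subset of an N-universe containing K
    marked elements hits at least k of them. Evaluated through the
    log-space survival function, so tiny tails keep full relative accuracy.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    selection: Iterable[str],
    direction_label: str,
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_overlap: int = 3,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Over-representation of *selection* in each pathway of *collection*.

    Pathway membership is intersected with the universe before sizing (K is
    the in-universe size). One record per pathway with k >= 1, sorted by p
    then pathway id. ``passes_filters`` is k >= min_overlap and p < alpha.
    BH q-values are computed across all pathways with K >= 1 (pathways with
    zero overlap contribute p = 1 to the correction).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    selection = set(selection)
    if not selection <= universe:
        raise ValueError("selection must be a subset of the universe")
    n = len(selection)
    N = len(universe)
    tested: list[tuple[str, int, int, float]] = []  # (id, k, K, p)
    for set_id in collection.ids():
        members = set(collection.members(set_id)) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & selection)
        p = hypergeom_upper_tail(k, K, n, N)
        tested.append((set_id, k, K, p))
    records: list[EnrichmentRecord] = []
    if tested:
        _, qvals, _, _ = multipletests([t[3] for t in tested], method="fdr_bh")
        for (set_id, k, K, p), q in zip(tested, qvals):
            if k < 1:
                continue
            records.append(
                EnrichmentRecord(
                    pathway=set_id, direction=direction_label,
                    k=k, K=K, n=n, N=N, p=p, q=float(q),
                    passes_filters=(k >= min_overlap and p < alpha),
                )
            )
    records.sort(key=lambda r: (r.p, r.pathway))
    return records


def enrichment_report(
    positive_records: Sequence[EnrichmentRecord],
    negative_records: Sequence[EnrichmentRecord],
    path: str | Path,
) -> int:
    """Write the combined dot-plot table as TSV; returns rows written.

    Columns: pathway, direction, k, K, n, N, p, q, passes_filters — the
    data behind a direction-coloured, set-size-scaled enrichment dot plot.
    """
    rows = list(positive_records) + list(negative_records)
    if not any(r.passes_filters for r in rows):
        warnings.warn("no enrichment record passes the filters", stacklevel=2)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("pathway\tdirection\tk\tK\tn\tN\tp\tq\tpasses_filters\n")
        for r in rows:
            fh.write(
                f"{r.pathway}\t{r.direction}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.p:.6g}\t{r.q:.6g}\t{str(r.passes_filters).lower()}\n"
            )
    return len(rows)
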