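"""Comprehensive ranking: geometric mean of per-algorithm ranks.

Each stability algorithm contributes a competition ranking (exact metric
ties share the minimum rank; the next rank is skipped accordingly).  The
comprehensive score of a gene is the geometric mean of its ranks across
algorithms — the RefFinder-style weighting — and the final order sorts this
score ascending.  Ties in the geometric mean are broken by the arithmetic
mean rank, then by input gene order, so the output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

from .errors import RgstabError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .stability import StabilityTable


def rank_genes(metric: Mapping[str, float] | pd.Series) -> pd.Series:
    """Competition ranking of a stability metric, ascending (lower = better).

    Exact ties share the minimum rank and the following rank is skipped:
    metrics {A: 0.074, B: 0.074, C: 0.122} rank as {A: 1, B: 1, C: 3}.
    Ranking happens on the unrounded values; rounding for display never
    feeds back into ranks.
    """
    s = pd.Series(metric, dtype=float)
    if s.empty:
        raise RgstabError("cannot rank an empty metric map", code="EMPTY")
    if not np.isfinite(s.to_numpy()).all():
        raise RgstabError("metrics must be finite", code="BAD_METRIC")
    return s.rank(method="min", ascending=True).astype(int)


@dataclass
class AggregateRanking:
    """Per-gene rank vectors, geometric-mean score and comprehensive order."""

    ranks: pd.DataFrame  # genes x algorithms, integer ranks
    geomean: pd.Series  # full-precision geometric mean of each gene's ranks
    final_rank: pd.Series  # 1-based comprehensive position
    algorithm_order: list[str]

    @property
    def order(self) -> list[str]:
        """Gene ids sorted by comprehensive rank."""
        return list(self.final_rank.sort_values().index)

    def to_frame(self) -> pd.DataFrame:
        """Rendered table: Ranking Order | Gene Name | Geomean | per-algorithm rank."""
        genes = self.order
        out = pd.DataFrame(
            {
                "ranking_order": self.final_rank[genes].values,
                "gene": genes,
                "geomean": self.geomean[genes].round(2).values,
            }
        )
        for alg in self.algorithm_order:
            out[f"{alg}_rank"] = self.ranks.loc[genes, alg].values
        return out


def aggregate_rankings(tables: "list[StabilityTable]") -> AggregateRanking:
    """Combine per-algorithm stability tables into the comprehensive ranking.

    All tables must cover the same gene set; a mismatch raises with the
    symmetric difference.  The geometric mean is kept at full precision
    internally and only rounded (2 decimals) in rendered output.
    """
    if not tables:
        raise RgstabError("need at least one stability table", code="EMPTY")
    genes = list(tables[0].metric.index)
    gene_set = set(genes)
    for t in tables[1:]:
        other = set(t.metric.index)
        if other != gene_set:
            diff = sorted(gene_set.symmetric_difference(other))
            raise RgstabError(
                f"gene sets differ between stability tables: {diff}",
                code="GENE_MISMATCH",
            )
    algorithm_order = [t.algorithm for t in tables]
    ranks = pd.DataFrame(
        {t.algorithm: t.rank.reindex(genes) for t in tables}, index=genes
    ).astype(int)
    geomean = pd.Series(
        np.exp(np.log(ranks.to_numpy(dtype=float)).mean(axis=1)), index=genes
    )
    mean_rank = ranks.mean(axis=1)
    order = sorted(
        genes, key=lambda g: (geomean[g], mean_rank[g], genes.index(g))
    )
    final_rank = pd.Series({g: i + 1 for i, g in enumerate(order)}).reindex(genes)
    return AggregateRanking(
        ranks=ranks, geomean=geomean, final_rank=final_rank,
        algorithm_order=algorithm_order,
    )


def render_full_table(ranking: AggregateRanking, tables: "list[StabilityTable]") -> pd.DataFrame:
    """Comprehensive table with each algorithm's metric next to its rank."""
    out = ranking.to_frame()
    by_name = {t.algorithm: t for t in tables}
    for alg in ranking.algorithm_order:
        out[f"{alg}_metric"] = by_name[alg].metric.reindex(out["gene"]).round(3).values
    return out
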