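"""The four candidate reference-gene stability algorithms.

All four operate on a preprocessed Ct matrix (complete, candidate genes
only — the spike-in row, if still attached, is ignored) and return a
:class:`StabilityTable` whose metric is in cycles, lower = more stable:

* **geNorm** — mean pairwise variation M with stepwise exclusion of the
  least stable gene; the two genes surviving to the final round share one
  M value by construction.
* **comparative-Ct (delta-Ct) method** — mean, over all partner genes, of
  the SD of pairwise Ct differences; identical to the pre-exclusion geNorm
  M for every gene.
* **NormFinder** — model-based decomposition of each gene's variance into
  intragroup variance (and, with two groups, an intergroup bias term
  shrunk by an empirical-Bayes factor); metric is the stability value SV.
* **BestKeeper** — descriptive dispersion of the raw Ct values
  (SD(+/-Ct), a mean absolute deviation by default), plus the per-sample
  geometric-mean index and each gene's correlation against it.

Amplification efficiency is fixed at 2 (one cycle = one log2 unit), so all
ratio-based definitions reduce to arithmetic on Ct differences.  Sample
standard deviations use the n-1 denominator throughout; with 3-donor
designs the estimator choice is material, so it is fixed once here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .aggregation import rank_genes
from .errors import DegenerateDataError, RgstabError
from .io import CtMatrix


@dataclass
class StabilityTable:
    """Per-gene stability metric and competition rank for one algorithm."""

    algorithm: str
    metric: pd.Series  # gene -> stability value (cycles, lower = more stable)
    rank: pd.Series  # gene -> integer >= 1, competition ranking of metric
    extras: Any = None

    def __post_init__(self) -> None:
        self.metric = self.metric.astype(float)
        self.rank = self.rank.astype(int)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.metric.index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.metric.index, "metric": self.metric.values, "rank": self.rank.values}
        )


@dataclass
class GenormExtras:
    exclusion_order: list[str]  # first removed -> last removed
    final_pair: tuple[str, str]
    pairwise_variation: pd.DataFrame  # symmetric V matrix on the full panel


@dataclass
class NormFinderExtras:
    groups_used: list[str]  # condition labels, or ["single"]
    intragroup_variance: pd.DataFrame  # genes x groups, cycles^2
    intergroup_difference: pd.DataFrame | None = None  # genes x groups (2-group mode)


@dataclass
class BestKeeperExtras:
    descriptives: pd.DataFrame  # per gene: geo_mean, ar_mean, min, max, sd, cv_pct
    index: pd.Series  # per-sample geometric mean of candidate Ct
    index_correlation: pd.Series  # gene -> Pearson r vs index (NaN if undefined)


def _candidate_frame(matrix: CtMatrix, min_genes: int, min_samples: int, who: str) -> pd.DataFrame:
    vals = matrix.candidate_values()
    if vals.shape[0] < min_genes:
        raise RgstabError(
            f"{who} needs at least {min_genes} candidate genes, got {vals.shape[0]}",
            code="TOO_FEW_GENES",
        )
    if vals.shape[1] < min_samples:
        raise RgstabError(
            f"{who} needs at least {min_samples} samples, got {vals.shape[1]}",
            code="TOO_FEW_SAMPLES",
        )
    if vals.isna().any().any():
        raise RgstabError(
            f"{who} requires a complete matrix; floor missing values first",
            code="MISSING_VALUES",
        )
    return vals


def pairwise_variation(matrix: CtMatrix, gene_a: str, gene_b: str) -> float:
    """SD (n-1) over samples of the Ct difference between two genes.

    This is the geNorm pairwise variation V_jk; it is symmetric, zero for a
    gene against itself or against a constant-offset copy of itself.
    """
    vals = _candidate_frame(matrix, 1, 2, "pairwise_variation")
    diff = vals.loc[gene_a] - vals.loc[gene_b]
    return float(diff.std(ddof=1))


def _pairwise_sd_matrix(vals: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of SDs of pairwise Ct differences (V_jk)."""
    arr = vals.to_numpy()
    k = arr.shape[0]
    v = np.zeros((k, k))
    for i in range(k):
        d = arr[i] - arr  # (k, n) differences against every gene
        v[i] = d.std(axis=1, ddof=1)
    v = (v + v.T) / 2  # enforce exact symmetry against fp noise
    np.fill_diagonal(v, 0.0)
    return pd.DataFrame(v, index=vals.index, columns=vals.index)


def _mean_pairwise(v: pd.DataFrame) -> pd.Series:
    k = v.shape[0]
    return v.sum(axis=1) / (k - 1)


def delta_ct_stability(matrix: CtMatrix) -> StabilityTable:
    """Comparative-Ct stability: mean SD of a gene's pairwise Ct differences.

    Equals the pre-exclusion geNorm M for every gene (same formula, no
    stepwise removal).
    """
    vals = _candidate_frame(matrix, 2, 2, "delta_ct_stability")
    metric = _mean_pairwise(_pairwise_sd_matrix(vals))
    return StabilityTable("delta_ct", metric, rank_genes(metric))


def genorm(matrix: CtMatrix) -> StabilityTable:
    """geNorm expression-stability measure M with stepwise exclusion.

    Each gene's M is the mean pairwise variation against all remaining
    partners.  The gene with the highest M is removed and M recomputed until
    two genes remain; each gene's reported metric is its M at the iteration
    of its removal, and the final two genes both carry the final-round M
    (equal by construction, since each has only the other as partner).  Ties
    at the exclusion step remove the gene occurring later in input order.
    """
    vals = _candidate_frame(matrix, 3, 2, "genorm")
    v_full = _pairwise_sd_matrix(vals)
    remaining = list(vals.index)
    metric = pd.Series(np.nan, index=vals.index)
    exclusion: list[str] = []
    while len(remaining) > 2:
        m = _mean_pairwise(v_full.loc[remaining, remaining])
        worst_val = m.max()
        # later-in-input-order tie-break: scan from the end
        worst = next(g for g in reversed(remaining) if m[g] == worst_val)
        metric[worst] = m[worst]
        exclusion.append(worst)
        remaining.remove(worst)
    final_m = float(v_full.loc[remaining[0], remaining[1]])
    metric[remaining] = final_m
    extras = GenormExtras(
        exclusion_order=exclusion,
        final_pair=(remaining[0], remaining[1]),
        pairwise_variation=v_full,
    )
    return StabilityTable("genorm", metric, rank_genes(metric), extras)


# -- NormFinder -------------------------------------------------------------


def _normfinder_sigma2(vals: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Bias-corrected intragroup variances for one group of samples.

    Starting from the two-way additive model y_ij = a_i + b_j + e_ij, the
    raw per-gene residual variance s2_i (residuals r_ij = y_ij - rowmean -
    colmean + grandmean, n-1 denominator) underestimates sigma2_i because
    every residual absorbs a share of all genes' errors:

        E[s2_i] = sigma2_i (1 - 2/k) + (sum_l sigma2_l) / k^2

    Summing over genes gives sum_i E[s2_i] = (sum sigma2) (1 - 1/k), so the
    total is estimated first and then each sigma2_i solved for and clamped
    at zero.  Requires k >= 3 (the 1 - 2/k factor degenerates at k = 2).
    """
    k, n = vals.shape
    if k < 3:
        raise RgstabError(
            f"NormFinder variance correction needs >= 3 genes, got {k}",
            code="TOO_FEW_GENES",
        )
    arr = vals.to_numpy()
    resid = arr - arr.mean(axis=1, keepdims=True) - arr.mean(axis=0, keepdims=True) + arr.mean()
    s2 = pd.Series((resid**2).sum(axis=1) / (n - 1), index=vals.index)
    total = s2.sum() / (1 - 1 / k)
    sigma2 = (s2 - total / k**2) / (1 - 2 / k)
    clamped = sigma2.index[sigma2 < 0].tolist()
    if clamped:
        logger.debug("negative variance estimates clamped to 0 for %s", clamped)
    return sigma2.clip(lower=0.0), s2


def normfinder(matrix: CtMatrix, mode: str = "single") -> StabilityTable:
    """NormFinder stability value from a model-based variance decomposition.

    ``mode="single"`` pools all samples as one group: the metric is the
    square root of the bias-corrected intragroup variance.  This matches
    pasting one table into the applet and is the default for per-condition
    and merged analyses alike.

    ``mode="by_condition"`` (exactly two condition groups) additionally
    estimates each gene's intergroup expression difference d, shrinks it by
    the empirical-Bayes factor gamma^2 / (gamma^2 + sigma2_ig / n_g), and
    scores each gene as the mean over groups of |d~_ig| + sigma_ig/sqrt(n_g).
    """
    if mode not in ("single", "by_condition"):
        raise ValueError(f"unknown NormFinder mode {mode!r}")
    min_samples = 3 if mode == "single" else 2
    vals = _candidate_frame(matrix, 3, min_samples, "normfinder")

    if mode == "single":
        sigma2, _ = _normfinder_sigma2(vals)
        metric = np.sqrt(sigma2)
        extras = NormFinderExtras(
            groups_used=["single"],
            intragroup_variance=sigma2.to_frame("single"),
        )
        return StabilityTable("normfinder", metric, rank_genes(metric), extras)

    groups = [c for c in matrix.conditions]
    if len(groups) != 2:
        raise RgstabError(
            f"by_condition mode supports exactly 2 groups, got {groups}",
            code="BAD_GROUPS",
        )
    # sample-centered values: removes per-sample (RNA input) offsets; the
    # intergroup difference is each gene's group-mean deviation relative to
    # its overall mean across both groups
    z_all = vals - vals.mean(axis=0)
    overall = z_all.mean(axis=1)
    sigma2_by_group = {}
    d_by_group = {}
    for g in groups:
        samples = [s for s in vals.columns if matrix.condition[s] == g]
        if len(samples) < 2:
            raise RgstabError(f"group {g!r} has fewer than 2 samples", code="TOO_FEW_SAMPLES")
        block = vals[samples]
        n_g = len(samples)
        d_hat = z_all[samples].mean(axis=1) - overall
        sigma2, _ = _normfinder_sigma2(block)
        gamma2 = max(0.0, float(d_hat.var(ddof=1)) - float(sigma2.mean()) / n_g)
        shrink = gamma2 / (gamma2 + sigma2 / n_g) if gamma2 > 0 else sigma2 * 0.0
        d_by_group[g] = d_hat * shrink
        sigma2_by_group[g] = sigma2

    sigma2_df = pd.DataFrame(sigma2_by_group)
    d_df = pd.DataFrame(d_by_group)
    n_sizes = {g: len([s for s in vals.columns if matrix.condition[s] == g]) for g in groups}
    per_group = pd.DataFrame(
        {g: d_df[g].abs() + np.sqrt(sigma2_df[g] / n_sizes[g]) for g in groups}
    )
    metric = per_group.mean(axis=1)
    extras = NormFinderExtras(
        groups_used=groups, intragroup_variance=sigma2_df, intergroup_difference=d_df
    )
    return StabilityTable("normfinder", metric, rank_genes(metric), extras)


def bestkeeper(matrix: CtMatrix, dispersion: str = "mad") -> StabilityTable:
    """BestKeeper descriptive statistics and index correlation.

    Per gene: geometric mean, arithmetic mean, min, max, SD(+/-Ct) and CV%.
    SD(+/-Ct) is the mean absolute deviation from the arithmetic mean
    (``dispersion="mad"``, the classical definition); ``dispersion="sd"``
    substitutes the n-1 standard deviation.  The BestKeeper index is the
    per-sample geometric mean across candidate genes; each gene's Pearson r
    against it is reported (NaN when the index has zero variance).  Ranking
    uses SD(+/-Ct), lower = more stable.
    """
    if dispersion not in ("mad", "sd"):
        raise ValueError(f"unknown dispersion {dispersion!r}")
    vals = _candidate_frame(matrix, 1, 2, "bestkeeper")
    arr = vals.to_numpy()
    if (arr <= 0).any():
        raise DegenerateDataError("BestKeeper requires positive Ct values (geometric mean)")

    am = arr.mean(axis=1)
    gm = np.exp(np.log(arr).mean(axis=1))
    if dispersion == "mad":
        sd = np.abs(arr - am[:, None]).mean(axis=1)
    else:
        sd = arr.std(axis=1, ddof=1)
    desc = pd.DataFrame(
        {
            "geo_mean": gm,
            "ar_mean": am,
            "min": arr.min(axis=1),
            "max": arr.max(axis=1),
            "sd": sd,
            "cv_pct": 100.0 * sd / am,
        },
        index=vals.index,
    )
    index = pd.Series(np.exp(np.log(arr).mean(axis=0)), index=vals.columns, name="index")
    if float(index.std(ddof=1)) == 0.0:
        corr = pd.Series(np.nan, index=vals.index)
    else:
        idx_centered = index.to_numpy() - index.mean()
        corr_vals = []
        for row in arr:
            rc = row - row.mean()
            denom = np.sqrt((rc**2).sum() * (idx_centered**2).sum())
            corr_vals.append(float((rc * idx_centered).sum() / denom) if denom > 0 else np.nan)
        corr = pd.Series(corr_vals, index=vals.index)
    metric = desc["sd"].copy()
    extras = BestKeeperExtras(descriptives=desc, index=index, index_correlation=corr)
    return StabilityTable("bestkeeper", metric, rank_genes(metric), extras)


ALGORITHMS = {
    "genorm": genorm,
    "normfinder": normfinder,
    "bestkeeper": bestkeeper,
    "delta_ct": delta_ct_stability,
}


def run_all(
    matrix: CtMatrix,
    algorithms: list[str] | None = None,
    normfinder_mode: str = "single",
) -> list[StabilityTable]:
    """Run the requested algorithms (default: all four, in canonical order)."""
    names = algorithms or ["genorm", "normfinder", "bestkeeper", "delta_ct"]
    tables = []
    for name in names:
        if name not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {name!r}")
        if name == "normfinder":
            tables.append(normfinder(matrix, mode=normfinder_mode))
        else:
            tables.append(ALGORITHMS[name](matrix))
    return tables
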