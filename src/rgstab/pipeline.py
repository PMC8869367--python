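"""End-to-end orchestration: preprocess -> stability -> aggregate -> quantify.

The driver reproduces the three-panel analysis layout of a two-condition
reference-gene study: one comprehensive ranking per single condition plus
one for the merged sample set, each produced by the fixed preprocessing
order (presence calling on raw detections, detection-limit flooring,
candidate filtering, spike-in equalization, global-mean equalization)
followed by the four stability algorithms and geometric-mean aggregation.
Also houses the exploratory utilities: centered-SVD PCA of samples and the
cross-dataset mean-Ct regression.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess
from .aggregation import AggregateRanking, aggregate_rankings, render_full_table
from .errors import RgstabError
from .io import CtMatrix, read_ct_matrix, write_result_table
from .stability import StabilityTable, run_all

logger = logging.getLogger("rgstab")


@dataclass
class ScopeResult:
    """Everything computed for one analysis scope (a condition set)."""

    scope: tuple[str, ...]
    matrix: CtMatrix  # preprocessed, candidates only (+ spike row)
    tables: list[StabilityTable]
    ranking: AggregateRanking


def preprocess_matrix(
    matrix: CtMatrix, scope: set[str] | list[str] | None = None
) -> CtMatrix:
    """Run the fixed cleaning chain for one scope.

    Spike-in equalization is skipped when the matrix carries no spike gene.
    """
    report = preprocess.call_presence(matrix)
    floored = preprocess.floor_to_detection_limit(matrix)
    filtered = preprocess.filter_candidates(floored, report, scope=scope)
    if filtered.spike_gene is not None and filtered.spike_gene in filtered.gene_ids:
        filtered = preprocess.spike_in_equalize(filtered)
    return preprocess.global_mean_equalize(filtered)


def analyze_scope(
    matrix: CtMatrix,
    scope: set[str] | list[str] | None = None,
    algorithms: list[str] | None = None,
    normfinder_mode: str = "single",
) -> ScopeResult:
    """Preprocess one scope and run the stability + aggregation stack."""
    conds = tuple(sorted(set(scope))) if scope is not None else tuple(matrix.conditions)
    clean = preprocess_matrix(matrix, scope=scope)
    tables = run_all(clean, algorithms=algorithms, normfinder_mode=normfinder_mode)
    ranking = aggregate_rankings(tables)
    return ScopeResult(scope=conds, matrix=clean, tables=tables, ranking=ranking)


def analyze_all_scopes(
    matrix: CtMatrix,
    algorithms: list[str] | None = None,
    normfinder_mode: str = "single",
) -> dict[str, ScopeResult]:
    """Each condition alone plus the merged set (key ``"ALL"``)."""
    out: dict[str, ScopeResult] = {}
    for cond in matrix.conditions:
        out[cond] = analyze_scope(matrix, scope={cond}, algorithms=algorithms,
                                  normfinder_mode=normfinder_mode)
    if len(matrix.conditions) > 1:
        out["ALL"] = analyze_scope(matrix, scope=None, algorithms=algorithms,
                                   normfinder_mode=normfinder_mode)
    return out


@dataclass
class PipelineConfig:
    """Plain-text configuration for a full pipeline run."""

    input_path: str
    output_dir: str
    spike_gene: str | None = None
    detection_threshold: float = 27.0
    detection_limit: float = 28.0
    algorithms: list[str] = field(
        default_factory=lambda: ["genorm", "normfinder", "bestkeeper", "delta_ct"]
    )
    normfinder_mode: str = "single"
    target: str | None = None
    reference: str | None = None
    milestone: str | None = None
    log_level: str = "INFO"

    _LIST_KEYS = ("algorithms",)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key=value`` config file (lists comma-separated)."""
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in cls._LIST_KEYS:
                kwargs[key] = [v.strip() for v in value.split(",") if v.strip()]
            elif key in ("detection_threshold", "detection_limit"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value if value.lower() != "none" else None
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for key, value in self.__dict__.items():
            if isinstance(value, list):
                value = ",".join(value)
            lines.append(f"{key}={value}")
        Path(path).write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full pipeline and write one CSV bundle to the output dir.

    Produces ``ranking_<scope>.csv`` per scope and, when a quantification
    target is configured, ``quantification.csv``.  Deterministic given
    inputs; stage names are attached to propagated errors.
    """
    logging.basicConfig(stream=sys.stderr, level=config.log_level.upper())
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _stage(name: str):
        logger.info("stage: %s", name)
        return name

    stage = _stage("read")
    try:
        matrix = read_ct_matrix(
            config.input_path,
            spike_gene=config.spike_gene,
            detection_limit=config.detection_limit,
            detection_threshold=config.detection_threshold,
        )
        stage = _stage("stability")
        results = analyze_all_scopes(
            matrix, algorithms=config.algorithms, normfinder_mode=config.normfinder_mode
        )
        for scope_name, res in results.items():
            path = outdir / f"ranking_{scope_name}.csv"
            table = render_full_table(res.ranking, res.tables)
            write_result_table(table, path, f"run scope={scope_name}")
            written[f"ranking_{scope_name}"] = path
        if config.target is not None:
            stage = _stage("quantify")
            from .quantification import relative_expression

            if config.reference is None or config.milestone is None:
                raise RgstabError(
                    "quantification requires reference and milestone", code="BAD_CONFIG"
                )
            clean = preprocess_matrix(matrix)
            rq = relative_expression(clean, config.target, config.reference, config.milestone)
            frame = pd.DataFrame(
                {"sample": list(rq.rq), "rq": list(rq.rq.values())}
            )
            path = outdir / "quantification.csv"
            write_result_table(frame, path, "quantify")
            written["quantification"] = path
    except RgstabError as exc:
        raise RgstabError(f"[stage {stage}] {exc}", code=exc.code) from exc
    return written


# -- exploratory utilities --------------------------------------------------


def pca_samples(matrix: CtMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples from gene-centered Ct values (no scaling).

    Rows (genes) are centered across samples; no unit-variance scaling or
    other transformation is applied.  Returns per-sample coordinates
    (samples x axes) and the per-axis variance fractions (summing to 1).
    Axis signs are arbitrary.
    """
    vals = matrix.candidate_values()
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise RgstabError("PCA needs at least 2 genes and 2 samples", code="TOO_SMALL")
    if vals.isna().any().any():
        raise RgstabError("PCA requires a complete matrix", code="MISSING_VALUES")
    arr = vals.to_numpy()
    centered = arr - arr.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0.0):
        raise RgstabError("constant matrix: no variance to decompose", code="DEGENERATE")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    coords = (vt.T * s[None, :])  # samples x axes
    fractions = s**2 / (s**2).sum()
    n_axes = coords.shape[1]
    frame = pd.DataFrame(
        coords, index=vals.columns, columns=[f"PC{i + 1}" for i in range(n_axes)]
    )
    return frame, fractions


def cross_dataset_correlation(
    matrix_a: CtMatrix, matrix_b: CtMatrix
) -> tuple[float, pd.DataFrame]:
    """R^2 between per-gene mean Ct of two datasets, plus presence classes.

    Genes are classified ``both`` / ``only_a`` / ``only_b`` by each
    dataset's presence calls (present in every condition of that dataset).
    The regression uses genes with values in both matrices; at least 3 are
    required.
    """
    shared = [g for g in matrix_a.candidate_genes if g in matrix_b.candidate_genes]
    means_a = matrix_a.values.mean(axis=1, skipna=True)
    means_b = matrix_b.values.mean(axis=1, skipna=True)
    usable = [g for g in shared if np.isfinite(means_a[g]) and np.isfinite(means_b[g])]
    if len(usable) < 3:
        raise RgstabError(
            f"need >= 3 shared genes with values in both datasets, got {len(usable)}",
            code="TOO_FEW_GENES",
        )
    x = means_a[usable].to_numpy()
    y = means_b[usable].to_numpy()
    r = np.corrcoef(x, y)[0, 1]
    r2 = float(r**2)

    rep_a = preprocess.call_presence(matrix_a)
    rep_b = preprocess.call_presence(matrix_b)
    in_a = set(rep_a.retained_genes())
    in_b = set(rep_b.retained_genes())
    rows = []
    for g in sorted(set(matrix_a.candidate_genes) | set(matrix_b.candidate_genes)):
        if g in in_a and g in in_b:
            cls = "both"
        elif g in in_a:
            cls = "only_a"
        elif g in in_b:
            cls = "only_b"
        else:
            cls = "neither"
        rows.append({"gene": g, "presence_class": cls})
    return r2, pd.DataFrame(rows)
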