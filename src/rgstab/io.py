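"""Reading, validating and writing Ct matrices and result tables.

The in-memory container is :class:`CtMatrix`: a genes x samples grid of
quantification-cycle (Ct) values held in a float DataFrame (``NaN`` marks a
missing / undetermined reaction), plus per-sample condition labels, an
optional exogenous spike-in row, and the instrument's detection threshold and
limit (27 and 28 cycles for OpenArray-style panels; a Ct above the threshold
is treated as below the reliable detection range).

Canonical file dialect
----------------------
Genes as rows, samples as columns, comma-delimited::

    gene,C1,C2,C3,S1,S2,S3
    condition,CTRL,CTRL,CTRL,SF,SF,SF
    miR-16-5p,20.1,20.4,19.9,20.2,20.6,20.0
    miR-34a-5p,24.0,NA,22.1,25.3,23.9,ND

The ``condition`` annotation line is optional; without it, labels are
inferred from the alphabetic prefix of each sample id (``C`` -> ``CTRL``,
``S`` -> ``SF``, anything else kept verbatim).  Empty cells and the tokens
``NA``, ``ND`` and ``Undetermined`` (case-insensitive) denote missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import MatrixFormatError

MISSING_TOKENS = frozenset({"", "na", "nd", "undetermined"})

#: Condition labels inferred from sample-id prefixes when no annotation
#: line is present.
_PREFIX_LABELS = {"C": "CTRL", "S": "SF"}


def _is_missing_token(cell: str) -> bool:
    return cell.strip().lower() in MISSING_TOKENS


@dataclass
class CtMatrix:
    """A genes x samples grid of Ct values with sample annotations.

    Parameters
    ----------
    values
        Float DataFrame indexed by gene id with sample ids as columns;
        ``NaN`` encodes a missing (undetermined) reaction.
    condition
        Mapping of sample id to condition label, e.g. ``"CTRL"`` / ``"SF"``.
    spike_gene
        Gene id of the exogenous spike-in channel (e.g. ``ath-miR-159a``),
        if the panel carries one.  The spike row is excluded from candidate
        lists but travels with the matrix for equalization.
    detection_limit, detection_threshold
        Cycles.  Values above the threshold are unreliable and are floored
        to the limit by preprocessing; defaults 28 and 27.
    """

    values: pd.DataFrame
    condition: dict[str, str] = field(default_factory=dict)
    spike_gene: str | None = None
    detection_limit: float = 28.0
    detection_threshold: float = 27.0

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not self.condition:
            self.condition = {s: infer_condition(s) for s in self.sample_ids}

    # -- basic accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def candidate_genes(self) -> list[str]:
        """Gene ids excluding the spike-in channel."""
        return [g for g in self.gene_ids if g != self.spike_gene]

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels in sample order."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.condition.get(s, ""), None)
        return list(seen)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition.get(s) == condition]

    def candidate_values(self) -> pd.DataFrame:
        """The value grid restricted to candidate (non-spike) genes."""
        return self.values.loc[self.candidate_genes]

    def copy(self) -> "CtMatrix":
        return replace(self, values=self.values.copy(), condition=dict(self.condition))

    def drop_spike(self) -> "CtMatrix":
        """A copy without the spike-in row (no-op if no spike is set)."""
        if self.spike_gene is None or self.spike_gene not in self.gene_ids:
            return self.copy()
        return replace(
            self,
            values=self.values.drop(index=self.spike_gene),
            condition=dict(self.condition),
            spike_gene=None,
        )

    def subset(
        self, genes: Iterable[str] | None = None, samples: Iterable[str] | None = None
    ) -> "CtMatrix":
        genes = list(genes) if genes is not None else self.gene_ids
        samples = list(samples) if samples is not None else self.sample_ids
        spike = self.spike_gene if self.spike_gene in genes else None
        return replace(
            self,
            values=self.values.loc[genes, samples].copy(),
            condition={s: self.condition[s] for s in samples},
            spike_gene=spike,
        )

    def equals(self, other: "CtMatrix", rtol: float = 1e-6) -> bool:
        if self.gene_ids != other.gene_ids or self.sample_ids != other.sample_ids:
            return False
        if self.condition != other.condition or self.spike_gene != other.spike_gene:
            return False
        a, b = self.values.to_numpy(), other.values.to_numpy()
        return bool(np.allclose(a, b, rtol=rtol, equal_nan=True))


def infer_condition(sample_id: str) -> str:
    """Condition label from a sample id's leading alphabetic prefix."""
    prefix = ""
    for ch in sample_id:
        if ch.isalpha():
            prefix += ch
        else:
            break
    return _PREFIX_LABELS.get(prefix, prefix or sample_id)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_matrix`; errors empty iff the matrix is valid."""

    errors: list[tuple[str, str]]
    warnings: list[tuple[str, str]]
    n_genes: int
    n_samples: int
    n_missing: int

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_matrix(matrix: CtMatrix) -> ValidationReport:
    """Check every CtMatrix invariant and report violations as data.

    Codes: ``EMPTY`` (no genes or samples), ``DUPLICATE_GENE`` /
    ``DUPLICATE_SAMPLE``, ``NEGATIVE_CT`` (non-positive or non-finite value),
    ``BAD_LIMITS`` (threshold >= limit), ``SPIKE_UNKNOWN``,
    ``CONDITION_MISSING`` (sample without a label).
    """
    errors: list[tuple[str, str]] = []
    warnings: list[tuple[str, str]] = []
    vals = matrix.values

    if vals.shape[0] == 0 or vals.shape[1] == 0:
        errors.append(("EMPTY", f"matrix has shape {vals.shape}"))
    for axis, code in ((vals.index, "DUPLICATE_GENE"), (vals.columns, "DUPLICATE_SAMPLE")):
        dupes = axis[axis.duplicated()].unique().tolist()
        if dupes:
            errors.append((code, f"duplicated identifiers: {dupes}"))

    arr = vals.to_numpy(dtype=float)
    bad = ~np.isnan(arr) & (~np.isfinite(arr) | (arr <= 0))
    for i, j in zip(*np.nonzero(bad)):
        errors.append(
            ("NEGATIVE_CT",
             f"value {arr[i, j]!r} at gene {vals.index[i]!r}, sample {vals.columns[j]!r} "
             "is not a positive finite cycle count")
        )
    if not matrix.detection_threshold < matrix.detection_limit:
        errors.append(
            ("BAD_LIMITS",
             f"detection_threshold {matrix.detection_threshold} must be below "
             f"detection_limit {matrix.detection_limit}")
        )
    if matrix.spike_gene is not None and matrix.spike_gene not in matrix.gene_ids:
        errors.append(("SPIKE_UNKNOWN", f"spike gene {matrix.spike_gene!r} not in matrix"))
    unlabeled = [s for s in matrix.sample_ids if s not in matrix.condition]
    if unlabeled:
        errors.append(("CONDITION_MISSING", f"samples without condition label: {unlabeled}"))

    return ValidationReport(
        errors=errors,
        warnings=warnings,
        n_genes=vals.shape[0],
        n_samples=vals.shape[1],
        n_missing=int(np.isnan(arr).sum()),
    )


def read_ct_matrix(
    path: str | Path,
    delimiter: str = ",",
    orientation: str = "genes-as-rows",
    conditions: Mapping[str, str] | None = None,
    spike_gene: str | None = None,
    detection_limit: float = 28.0,
    detection_threshold: float = 27.0,
) -> CtMatrix:
    """Parse a delimited Ct matrix file into a :class:`CtMatrix`.

    The first row holds sample ids (or gene ids for
    ``orientation="samples-as-rows"``), the first column identifiers.  An
    optional annotation line/column named ``condition`` supplies labels;
    ``conditions`` overrides both it and prefix inference.  Missing-value
    tokens are preserved as ``NaN`` — flooring to the detection limit is a
    separate, explicit preprocessing step.
    """
    if orientation not in ("genes-as-rows", "samples-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    raw = pd.read_csv(
        path, sep=delimiter, index_col=0, dtype=str, comment="#",
        keep_default_na=False, skip_blank_lines=True,
    )
    if orientation == "samples-as-rows":
        raw = raw.T

    cond_from_file: dict[str, str] = {}
    if "condition" in (str(i).lower() for i in raw.index):
        mask = raw.index.str.lower() == "condition"
        cond_row = raw.loc[mask].iloc[0]
        cond_from_file = {str(s): str(v).strip() for s, v in cond_row.items()}
        raw = raw.loc[~mask]

    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise MatrixFormatError(f"{path}: matrix is empty", code="EMPTY")
    for axis, what in ((raw.index, "gene"), (raw.columns, "sample")):
        dupes = axis[axis.duplicated()].unique().tolist()
        if dupes:
            raise MatrixFormatError(
                f"{path}: duplicated {what} identifiers: {dupes}", code="DUPLICATE_ID"
            )

    values = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns, dtype=float)
    for gene in raw.index:
        for sample in raw.columns:
            cell = str(raw.at[gene, sample])
            if _is_missing_token(cell):
                continue
            try:
                values.at[gene, sample] = float(cell)
            except ValueError:
                raise MatrixFormatError(
                    f"{path}: non-numeric cell {cell!r} at gene {gene!r}, "
                    f"sample {sample!r}",
                    code="BAD_CELL",
                ) from None

    if conditions is not None:
        cond = {s: conditions[s] for s in values.columns}
    elif cond_from_file:
        cond = {s: cond_from_file.get(s, infer_condition(s)) for s in values.columns}
    else:
        cond = {s: infer_condition(s) for s in values.columns}

    return CtMatrix(
        values=values,
        condition=cond,
        spike_gene=spike_gene,
        detection_limit=detection_limit,
        detection_threshold=detection_threshold,
    )


def _format_value(v: float) -> str:
    if math.isnan(v):
        return "NA"
    return format(v, ".10g")


def write_ct_matrix(matrix: CtMatrix, path: str | Path, delimiter: str = ",") -> None:
    """Write a matrix in the canonical dialect (condition line included).

    Round-trips through :func:`read_ct_matrix` to at least 10 significant
    digits; missing values become ``NA`` cells.
    """
    report = validate_matrix(matrix)
    if not report.ok:
        raise MatrixFormatError(
            "refusing to write invalid matrix: "
            + "; ".join(f"{c}: {m}" for c, m in report.errors)
        )
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene" + delimiter + delimiter.join(matrix.sample_ids) + "\n")
        fh.write(
            "condition" + delimiter
            + delimiter.join(matrix.condition[s] for s in matrix.sample_ids) + "\n"
        )
        for gene in matrix.gene_ids:
            row = (_format_value(matrix.values.at[gene, s]) for s in matrix.sample_ids)
            fh.write(gene + delimiter + delimiter.join(row) + "\n")


def write_result_table(
    frame: pd.DataFrame, path: str | Path, command: str, index: bool = False
) -> None:
    """Write a result table as CSV with a one-line provenance comment header."""
    from . import __version__

    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# rgstab {__version__} {command}\n")
        frame.to_csv(fh, index=index)
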