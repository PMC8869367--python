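"""Detection-limit handling, presence calling and per-sample equalization.

The cleaning chain for an OpenArray-style miRNA panel is::

    call_presence -> floor_to_detection_limit -> filter_candidates
                  -> spike_in_equalize -> global_mean_equalize

Presence is judged on the raw above-threshold pattern (a missing reaction
counts as above threshold), so calling it before or after flooring gives the
same answer; the pipeline fixes the order above so the presence report stays
interpretable in raw cycles.  Both equalizations act additively on the Ct
scale — multiplicatively on the linear abundance scale — and therefore leave
every within-sample Ct difference unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyPanelError, RgstabError, SpikeMissingError
from .io import CtMatrix


@dataclass
class PresenceReport:
    """Per-(gene, condition) detection calls.

    A gene is *absent* in a condition when more than ``floor(n/2)`` of that
    condition's n samples are above the detection threshold or missing —
    for the usual 3-donor design this is the two-out-of-three rule.  A gene
    is retained for an analysis scope only when present in every condition
    of the scope.
    """

    table: pd.DataFrame  # columns: gene, condition, n_samples, n_above_threshold, present
    spike_gene: str | None = None

    def present(self, gene: str, condition: str) -> bool:
        sel = self.table[(self.table.gene == gene) & (self.table.condition == condition)]
        if sel.empty:
            raise KeyError(f"no presence call for ({gene!r}, {condition!r})")
        return bool(sel.present.iloc[0])

    def retained_genes(self, scope: set[str] | list[str] | None = None) -> list[str]:
        """Candidate genes present in every condition of ``scope``.

        ``scope=None`` means all conditions.  The spike-in channel is never a
        candidate and is excluded regardless of its calls.
        """
        tab = self.table
        if scope is not None:
            scope = set(scope)
            missing = scope - set(tab.condition)
            if missing:
                raise KeyError(f"unknown conditions in scope: {sorted(missing)}")
            tab = tab[tab.condition.isin(scope)]
        ok = tab.groupby("gene", sort=False).present.all()
        return [g for g in ok.index[ok] if g != self.spike_gene]


def floor_to_detection_limit(matrix: CtMatrix) -> CtMatrix:
    """Replace missing values and values above the detection threshold by the limit.

    With the default threshold/limit of 27/28 cycles, a Ct of 27.5 and an
    undetermined reaction both become 28; everything at or below 27 is left
    untouched.  Idempotent; the input is not mutated.
    """
    out = matrix.copy()
    arr = out.values.to_numpy()
    mask = np.isnan(arr) | (arr > matrix.detection_threshold)
    arr[mask] = matrix.detection_limit
    out.values.iloc[:, :] = arr
    return out


def call_presence(matrix: CtMatrix) -> PresenceReport:
    """Call per-gene, per-condition presence from the above-threshold pattern."""
    rows = []
    for cond in matrix.conditions:
        samples = matrix.samples_for(cond)
        if not samples:
            raise RgstabError(f"condition {cond!r} has no samples", code="EMPTY_CONDITION")
        block = matrix.values[samples]
        above = (block.isna() | (block > matrix.detection_threshold)).sum(axis=1)
        n = len(samples)
        for gene in matrix.gene_ids:
            k = int(above[gene])
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "n_samples": n,
                    "n_above_threshold": k,
                    "present": k <= math.floor(n / 2),
                }
            )
    return PresenceReport(table=pd.DataFrame(rows), spike_gene=matrix.spike_gene)


def filter_candidates(
    matrix: CtMatrix,
    report: PresenceReport,
    scope: set[str] | list[str] | None = None,
) -> CtMatrix:
    """Restrict to genes present in every condition of the scope.

    The returned matrix keeps only the samples of the scope's conditions and
    the surviving candidate genes; the spike-in row is carried along (it is
    not subject to the presence requirement) so downstream spike equalization
    still works, but it is never a candidate.
    """
    retained = report.retained_genes(scope)
    if not retained:
        raise EmptyPanelError("no candidate gene passed the presence filter")
    genes = list(retained)
    if matrix.spike_gene is not None and matrix.spike_gene in matrix.gene_ids:
        genes.append(matrix.spike_gene)
    conds = set(scope) if scope is not None else set(matrix.conditions)
    samples = [s for s in matrix.sample_ids if matrix.condition[s] in conds]
    return matrix.subset(genes=genes, samples=samples)


def spike_in_equalize(matrix: CtMatrix) -> CtMatrix:
    """Equalize technical handling differences using the spike-in channel.

    Each sample j receives the additive correction
    ``mean(spike Ct) - spike Ct_j``, which sets the spike row constant at its
    mean and shifts every gene of sample j with it.  Values previously
    floored at the detection limit are shifted like any other value — the
    floor is an imputation, not a measurement, so equalized floored values no
    longer sit exactly at the limit.
    """
    if matrix.spike_gene is None or matrix.spike_gene not in matrix.gene_ids:
        raise RgstabError("matrix has no spike-in gene", code="NO_SPIKE")
    spike = matrix.values.loc[matrix.spike_gene]
    for s in matrix.sample_ids:
        if np.isnan(spike[s]):
            raise SpikeMissingError(s)
    correction = spike.mean() - spike
    out = matrix.copy()
    out.values.iloc[:, :] = out.values.to_numpy() + correction.to_numpy()[None, :]
    return out


def global_mean_equalize(matrix: CtMatrix) -> CtMatrix:
    """Center each sample's mean candidate Ct on the grand mean.

    Absorbs residual differences in the amount of starting RNA: sample j
    receives ``grand mean - mean(candidate Ct in j)`` additively, computed
    over the retained candidate genes (the spike-in is excluded from the
    means but shifted along with its sample).  Afterwards every sample's
    candidate mean equals the grand mean.
    """
    cand = matrix.candidate_values()
    if cand.shape[0] == 0:
        raise EmptyPanelError("no candidate genes to equalize")
    if cand.shape[0] == 1:
        warnings.warn(
            "global-mean equalization with a single candidate gene forces that "
            "gene constant and destroys all signal",
            stacklevel=2,
        )
    sample_means = cand.mean(axis=0, skipna=True)
    correction = float(cand.to_numpy().flatten()[~np.isnan(cand.to_numpy().flatten())].mean()) - sample_means
    out = matrix.copy()
    out.values.iloc[:, :] = out.values.to_numpy() + correction.to_numpy()[None, :]
    return out
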