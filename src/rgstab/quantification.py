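"""Comparative-Ct (ddCt) relative quantification and its statistics.

Relative quantity of a target miRNA in sample s against reference gene r
and milestone sample m, with amplification efficiency fixed at 2::

    RQ_s = 2 ** -[(Ct_target,s - Ct_ref,s) - (Ct_target,m - Ct_ref,m)]

so the milestone sample is exactly 1.  Treated-vs-control fold changes are
taken per paired donor as RQ_treated / RQ_control, which is algebraically
the within-donor 2^-ddCt and hence independent of the milestone choice.

The significance machinery mirrors small-n qPCR practice: Grubbs' test to
screen a triplet for a single outlier, then a one-sample t-test of the fold
values against a hypothetical mean of 1, combined with a fold-change cutoff
(default: fold >= 2 AND p <= 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, RgstabError
from .io import CtMatrix


@dataclass
class RelativeExpressionTable:
    """Per-sample relative quantities of one target against one reference."""

    target: str
    reference: str
    milestone: str
    rq: dict[str, float]  # sample -> fold vs milestone (> 0; milestone = 1)
    mean: float
    sd: float  # n-1 SD over samples


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: int
    significant: bool
    criterion: str


@dataclass
class OutlierResult:
    index: int | None  # position of the flagged value, None if no outlier
    value: float | None
    g_statistic: float
    g_critical: float

    @property
    def is_outlier(self) -> bool:
        return self.index is not None


def relative_expression(
    matrix: CtMatrix, target: str, reference: str, milestone: str
) -> RelativeExpressionTable:
    """ddCt relative quantities for every sample, milestone fixed at 1."""
    if target == reference:
        raise RgstabError("target and reference gene must differ", code="SAME_GENE")
    for g in (target, reference):
        if g not in matrix.gene_ids:
            raise RgstabError(f"gene {g!r} not in matrix", code="UNKNOWN_GENE")
    if milestone not in matrix.sample_ids:
        raise RgstabError(f"milestone sample {milestone!r} not in matrix", code="UNKNOWN_SAMPLE")
    dct = matrix.values.loc[target] - matrix.values.loc[reference]
    ddct = dct - dct[milestone]
    rq = {s: float(2.0 ** -ddct[s]) for s in matrix.sample_ids}
    vals = np.array(list(rq.values()))
    return RelativeExpressionTable(
        target=target, reference=reference, milestone=milestone, rq=rq,
        mean=float(vals.mean()), sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
    )


def condition_ratio(
    table_treated: RelativeExpressionTable,
    table_control: RelativeExpressionTable,
    pairing: dict[str, tuple[str, str]],
) -> dict[str, float]:
    """Per-donor treated/control fold change from two RQ tables.

    ``pairing`` maps donor id -> (treated sample, control sample).  Both
    tables must share target and reference; swapping the tables' roles
    inverts every ratio.
    """
    if (table_treated.target, table_treated.reference) != (
        table_control.target, table_control.reference
    ):
        raise RgstabError(
            "treated and control tables must share target and reference gene",
            code="TABLE_MISMATCH",
        )
    ratios = {}
    for donor, (treated_s, control_s) in pairing.items():
        if treated_s not in table_treated.rq or control_s not in table_control.rq:
            raise RgstabError(
                f"donor {donor!r}: samples ({treated_s!r}, {control_s!r}) not covered "
                "by the RQ tables",
                code="UNPAIRED_DONOR",
            )
        ratios[donor] = table_treated.rq[treated_s] / table_control.rq[control_s]
    return ratios


def one_sample_t_test(
    values: list[float] | np.ndarray,
    mu: float = 1.0,
    alpha: float = 0.05,
    fold_criterion: float | None = 2.0,
) -> TestResult:
    """Two-sided one-sample t-test against ``mu``, with optional fold cutoff.

    With ``fold_criterion`` set (the default, 2), significance is the
    compound rule: mean >= fold_criterion AND p <= alpha.  Pass
    ``fold_criterion=None`` for the plain test (p <= alpha only).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise RgstabError("t-test needs at least 2 values", code="TOO_FEW_VALUES")
    if float(x.std(ddof=1)) == 0.0:
        raise DegenerateDataError("sample SD is zero; t statistic undefined")
    res = stats.ttest_1samp(x, popmean=mu, alternative="two-sided")
    mean = float(x.mean())
    p = float(res.pvalue)
    if fold_criterion is None:
        significant = p <= alpha
        criterion = f"p <= {alpha}"
    else:
        significant = (mean >= fold_criterion) and (p <= alpha)
        criterion = f"mean >= {fold_criterion} and p <= {alpha}"
    return TestResult(
        statistic=float(res.statistic), p_value=p, df=x.size - 1,
        significant=significant, criterion=criterion,
    )


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided single-outlier Grubbs critical value.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise RgstabError("Grubbs' test needs at least 3 values", code="TOO_FEW_VALUES")
    t = stats.t.ppf(1.0 - alpha / (2 * n), df=n - 2)
    return float((n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2)))


def grubbs_test(values: list[float] | np.ndarray, alpha: float = 0.05) -> OutlierResult:
    """Two-sided single-outlier Grubbs' test.

    Flags at most the one value farthest from the mean (in units of the n-1
    SD) when its G statistic exceeds the critical value.  A zero-SD sample
    cannot contain an outlier and returns G = 0.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    g_crit = grubbs_critical_value(n, alpha)  # validates n >= 3
    s = float(x.std(ddof=1))
    if s == 0.0:
        return OutlierResult(index=None, value=None, g_statistic=0.0, g_critical=g_crit)
    dev = np.abs(x - x.mean())
    i = int(dev.argmax())
    g = float(dev[i] / s)
    if g > g_crit:
        return OutlierResult(index=i, value=float(x[i]), g_statistic=g, g_critical=g_crit)
    return OutlierResult(index=None, value=None, g_statistic=g, g_critical=g_crit)


def fold_change_report(
    ratios: dict[str, float],
    alpha: float = 0.05,
    fold_criterion: float | None = 2.0,
    screen_outliers: bool = False,
) -> TestResult:
    """t-test of per-donor fold changes against 1, optionally Grubbs-screened.

    With ``screen_outliers`` the flagged donor (at most one) is dropped
    before testing, reducing n.
    """
    vals = list(ratios.values())
    if screen_outliers and len(vals) >= 3:
        res = grubbs_test(vals, alpha=alpha)
        if res.is_outlier:
            vals = [v for i, v in enumerate(vals) if i != res.index]
    return one_sample_t_test(vals, mu=1.0, alpha=alpha, fold_criterion=fold_criterion)
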