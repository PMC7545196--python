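"""Reliability statistics for repeated morphometric measurements.

Implements the three indices used to validate the method on phantom
scans and repeated operator sessions: the intraclass correlation
coefficient (ICC) from ANOVA variance components, the coefficient of
variation (CV), and the mean ± SD of case-wise differences from the
consensus (mean-of-all-repeats) value, in absolute units and as a
percentage of the consensus.

Conventions: consensus differences are absolute values and their
spread is the population SD over all measurements; the CV uses the
sample SD within each case. The default ICC form is ICC(2,1) —
two-way random effects, absolute agreement, single measurement — the
usual choice for inter-operator designs; a one-way form is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "RatingsTable",
    "ReliabilityReport",
    "ConsensusDifferences",
    "consensus_differences",
    "icc",
    "cv",
    "build_report",
]

log = logging.getLogger(__name__)

_ICC_FORMS = ("two-way-absolute-single", "one-way")


@dataclass(frozen=True)
class RatingsTable:
    """Complete (case × rater-or-repeat) measurement matrix.

    Rows are cases (e.g. MRI data sets or phantom geometries), columns
    are repeats or raters. The design must be complete: at least two
    cases, at least two repeats, no missing cells.
    """

    values: np.ndarray
    parameter: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValidationError("ratings must form a 2D (case x repeat) matrix")
        n, k = vals.shape
        if n < 2 or k < 2:
            raise ValidationError(
                f"need >= 2 cases and >= 2 repeats, got {n} x {k}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValidationError("missing or non-finite cells are not allowed")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]

    @property
    def n_repeats(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_csv(cls, path, parameter: str = "", units: str = "") -> "RatingsTable":
        """Read a ratings CSV: header row, one case per row, repeats as columns.

        A non-numeric first column is treated as case labels.
        """
        df = pd.read_csv(Path(path))
        first = df.columns[0]
        if not pd.api.types.is_numeric_dtype(df[first]):
            df = df.drop(columns=[first])
        return cls(df.to_numpy(dtype=float), parameter=parameter, units=units)


@dataclass(frozen=True)
class ConsensusDifferences:
    """Mean ± SD of absolute differences from the per-case consensus."""

    mean_abs_diff: float
    sd: float
    percent: float
    percent_sd: float


def consensus_differences(table: RatingsTable) -> ConsensusDifferences:
    """Case-wise differences from the consensus value.

    The per-case consensus is the mean over repeats (taken as the true
    value in the absence of a gold standard). Differences are absolute;
    the report gives their mean and population SD over all
    measurements, and the same figures as percentages of the case
    consensus.
    """
    vals = table.values
    consensus = vals.mean(axis=1, keepdims=True)
    if np.any(consensus == 0):
        raise ValidationError("a case consensus of zero leaves percentages undefined")
    diffs = np.abs(vals - consensus)
    pct = 100.0 * diffs / np.abs(consensus)
    return ConsensusDifferences(
        mean_abs_diff=float(diffs.mean()),
        sd=float(diffs.std(ddof=0)),
        percent=float(pct.mean()),
        percent_sd=float(pct.std(ddof=0)),
    )


def icc(table: RatingsTable, form: str = "two-way-absolute-single") -> float:
    """Intraclass correlation coefficient from ANOVA mean squares.

    ``two-way-absolute-single`` is ICC(2,1):
    (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n); ``one-way`` is
    ICC(1,1): (MSB − MSW) / (MSB + (k−1)·MSW). The estimate is ≤ 1 and
    may be slightly negative. A table with zero total variance is
    defined as perfectly reliable (1.0, logged).
    """
    if form not in _ICC_FORMS:
        raise ValidationError(f"unknown ICC form {form!r}; choose from {_ICC_FORMS}")
    vals = table.values
    n, k = vals.shape
    grand = vals.mean()
    if np.allclose(vals, grand):
        log.info("degenerate ratings table (zero total variance): ICC defined as 1")
        return 1.0
    row_means = vals.mean(axis=1)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    if form == "one-way":
        ssw = np.sum((vals - row_means[:, None]) ** 2)
        msw = ssw / (n * (k - 1))
        return float((msr - msw) / (msr + (k - 1) * msw))
    col_means = vals.mean(axis=0)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sst = np.sum((vals - grand) ** 2)
    sse = sst - k * np.sum((row_means - grand) ** 2) - n * np.sum(
        (col_means - grand) ** 2
    )
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def cv(table: RatingsTable) -> float:
    """Coefficient of variation: per-case sample SD over mean, averaged.

    Returned as a dimensionless fraction (0.1 means 10%).
    """
    vals = table.values
    means = vals.mean(axis=1)
    if np.any(means == 0):
        raise ValidationError("a case mean of zero leaves the CV undefined")
    sds = vals.std(axis=1, ddof=1)
    return float(np.mean(sds / np.abs(means)))


@dataclass(frozen=True)
class ReliabilityReport:
    """ICC, CV and consensus-difference statistics for one parameter."""

    icc: float
    icc_form: str
    cv: float
    mean_abs_diff: float
    sd: float
    percent: float
    percent_sd: float
    parameter: str = ""
    units: str = ""
    n_cases: int = 0
    n_repeats: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def format_table(self) -> str:
        """One-line human-readable summary in the reliability-table layout."""
        unit = f" {self.units}" if self.units else ""
        return (
            f"{self.parameter or 'parameter'}: "
            f"{self.mean_abs_diff:.2f} ± {self.sd:.2f}{unit}  "
            f"{self.percent:.1f} ± {self.percent_sd:.1f} %  "
            f"ICC {self.icc:.2f}  CV {self.cv:.2f}"
        )


def build_report(
    table: RatingsTable, icc_form: str = "two-way-absolute-single"
) -> ReliabilityReport:
    """All reliability statistics for one ratings table."""
    diffs = consensus_differences(table)
    return ReliabilityReport(
        icc=icc(table, icc_form),
        icc_form=icc_form,
        cv=cv(table),
        mean_abs_diff=diffs.mean_abs_diff,
        sd=diffs.sd,
        percent=diffs.percent,
        percent_sd=diffs.percent_sd,
        parameter=table.parameter,
        units=table.units,
        n_cases=table.n_cases,
        n_repeats=table.n_repeats,
    )
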