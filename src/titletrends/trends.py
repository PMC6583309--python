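"""Mass-univariate linear trend screening of term frequencies over time.

For every term that survives the low-frequency floor, an ordinary
least-squares line is fitted to its yearly frequency (per 100,000 words)
against calendar year:

    f_{t,y} = alpha_t + beta_t * y + eps

The slope ``beta_t`` is the mean annual change in frequency; its two-tailed
t-test p-value (df = n_years - 2) is corrected across terms with the
Benjamini-Hochberg step-up procedure, and terms with adjusted q below the
FDR threshold (default 0.01) are called significantly increased/decreased.

The object-oriented surface is :class:`TrendScreenModel` (built from a
:class:`~titletrends.ngrams.FrequencyTable`) whose :meth:`~TrendScreenModel.fit`
returns a :class:`TrendScreenResults` carrying the per-term estimates, the
ranked top lists and a ``summary()`` table; the underlying operations are
also exposed as plain functions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ngrams import FrequencyTable, TermSeries, get_series, low_frequency_filter

__all__ = [
    "TrendResult",
    "ScreenReport",
    "TrendScreenModel",
    "TrendScreenResults",
    "fit_term_trend",
    "bh_adjust",
    "screen",
    "cloud_weights",
]


@dataclass(frozen=True)
class TrendResult:
    """OLS trend estimate for one term.

    Units: slope, se, CI bounds and total_change are per 100,000 words
    (slope and se per year); ``total_change = slope * (year_max - year_min)``.
    """

    term: str
    slope: float
    intercept: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    n_years: int
    total_change: float
    q: float = math.nan

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError(f"{self.term}: CI does not bracket the slope")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"{self.term}: p outside [0, 1]")


def fit_term_trend(series: TermSeries) -> TrendResult:
    """Fit the continuous linear model of frequency on calendar year.

    Closed-form OLS with intercept: ``beta = S_xy / S_xx``,
    ``se = sqrt(SSE / (n - 2) / S_xx)``, two-tailed p from Student's t with
    n - 2 degrees of freedom, and a 95% CI ``beta +/- t_{0.975, n-2} * se``.

    Degenerate contract for an exact fit (SSE == 0): p = 1 when the slope is
    zero (a constant series carries no evidence of trend) and p = 0 when it
    is not (the trend is exact).
    """
    x = np.asarray(series.years, dtype=float)
    y = np.asarray(series.freq, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"{series.term}: need >= 3 years, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError(f"{series.term}: constant year vector")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    beta = sxy / sxx
    alpha = float(y.mean() - beta * x.mean())
    resid = y - (alpha + beta * x)
    sse = float(resid @ resid)
    df = n - 2
    span = float(x.max() - x.min())
    # float noise floor: an exact fit can leave SSE ~ 1e-28 and a constant
    # series a ~1e-17 slope from rounding; both must read as exact fits
    scale = max(1.0, float(np.abs(y).max()))
    if sse <= 1e-12 * scale * scale * n:
        if abs(beta) * span <= 1e-9 * scale:
            beta, p, t_stat = 0.0, 1.0, 0.0
        else:
            p, t_stat = 0.0, math.inf * np.sign(beta)
        return TrendResult(
            term=series.term, slope=beta, intercept=alpha, se=0.0,
            ci_low=beta, ci_high=beta, t=float(t_stat), p=p,
            n_years=n, total_change=beta * span,
        )
    se = math.sqrt(sse / df / sxx)
    t_stat = beta / se
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    half = float(stats.t.ppf(0.975, df)) * se
    return TrendResult(
        term=series.term, slope=beta, intercept=alpha, se=se,
        ci_low=beta - half, ci_high=beta + half, t=t_stat, p=p,
        n_years=n, total_change=beta * span,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in the input order.

    With p sorted ascending, ``q_i = min_{j >= i} min(1, p_j * m / j)``.
    The adjusted values are componentwise >= the raw ones and <= 1;
    thresholding them at the FDR level marks significance.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    # p*m/j can round one ulp below p at j = m; the true q is never below p
    return np.maximum(q, p)


@dataclass
class ScreenReport:
    """Outcome of a trend screen: per-term results and ranked top lists."""

    results: list[TrendResult]
    fdr_threshold: float
    top_increased: list[TrendResult] = field(default_factory=list)
    top_decreased: list[TrendResult] = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        return sum(1 for r in self.results if r.q < self.fdr_threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": r.term, "slope": r.slope, "se": r.se,
                    "ci_low": r.ci_low, "ci_high": r.ci_high, "t": r.t,
                    "p": r.p, "q": r.q, "total_change": r.total_change,
                    "n_years": r.n_years,
                }
                for r in self.results
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def top_lists_json(self) -> str:
        def rows(lst: list[TrendResult]) -> list[dict]:
            return [
                {"term": r.term, "slope": r.slope, "ci_low": r.ci_low,
                 "ci_high": r.ci_high, "q": r.q}
                for r in lst
            ]

        return json.dumps(
            {"increased": rows(self.top_increased), "decreased": rows(self.top_decreased)},
            indent=2,
        )


def screen(
    table: FrequencyTable,
    fdr_threshold: float = 0.01,
    k: int = 20,
    low_freq_threshold: float = 1e-4,
) -> ScreenReport:
    """Fit every retained term, BH-correct within the table, rank top-k.

    The low-frequency floor is applied first; the BH family is this table
    alone (monograms and bigrams are corrected separately when screened from
    separate tables). Top lists hold only q < threshold terms — increased
    sorted by slope descending, decreased ascending — with slope ties broken
    lexicographically by term.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    retained, _ = low_frequency_filter(table, low_freq_threshold)
    if not retained:
        raise ValueError("no terms retained after the low-frequency filter")
    fits = [fit_term_trend(get_series(table, t)) for t in sorted(retained)]
    q = bh_adjust([f.p for f in fits])
    results = [
        TrendResult(
            term=f.term, slope=f.slope, intercept=f.intercept, se=f.se,
            ci_low=f.ci_low, ci_high=f.ci_high, t=f.t, p=f.p,
            n_years=f.n_years, total_change=f.total_change, q=float(qi),
        )
        for f, qi in zip(fits, q)
    ]
    sig = [r for r in results if r.q < fdr_threshold]
    inc = sorted((r for r in sig if r.slope > 0), key=lambda r: (-r.slope, r.term))[:k]
    dec = sorted((r for r in sig if r.slope < 0), key=lambda r: (r.slope, r.term))[:k]
    return ScreenReport(
        results=results, fdr_threshold=fdr_threshold, top_increased=inc, top_decreased=dec
    )


def cloud_weights(report: ScreenReport, year_span: int) -> dict[str, float]:
    """Word-cloud weights: |slope| * year_span for each significant term.

    The weight is the magnitude of the absolute frequency change over the
    study period, sign-invariant; non-significant terms are absent.
    """
    if year_span < 1:
        raise ValueError("year_span must be >= 1")
    return {
        r.term: abs(r.slope) * year_span
        for r in report.results
        if r.q < report.fdr_threshold
    }


class TrendScreenModel:
    """Mass-univariate trend model over a term-frequency table.

    Parameters
    ----------
    table : FrequencyTable
        Per-year counts for one n-gram order.
    fdr_threshold : float
        Benjamini-Hochberg significance level (default 0.01).
    low_freq_threshold : float
        Aggregate-frequency floor below which terms are excluded
        (default 1e-4, i.e. 0.01% of all period tokens).
    """

    def __init__(
        self,
        table: FrequencyTable,
        fdr_threshold: float = 0.01,
        low_freq_threshold: float = 1e-4,
    ) -> None:
        self.table = table
        self.fdr_threshold = fdr_threshold
        self.low_freq_threshold = low_freq_threshold

    @classmethod
    def from_records(cls, records, order: int = 1, cfg=None, **kwargs) -> "TrendScreenModel":
        """Build the model straight from parsed article records."""
        from .ngrams import build_frequency_table

        return cls(build_frequency_table(records, order=order, cfg=cfg), **kwargs)

    def fit(self, k: int = 20) -> "TrendScreenResults":
        report = screen(
            self.table,
            fdr_threshold=self.fdr_threshold,
            k=k,
            low_freq_threshold=self.low_freq_threshold,
        )
        return TrendScreenResults(self, report)


class TrendScreenResults:
    """Fitted trend screen: estimates, top lists, summary and plots."""

    def __init__(self, model: TrendScreenModel, report: ScreenReport) -> None:
        self.model = model
        self.report = report

    @property
    def results_frame(self) -> pd.DataFrame:
        return self.report.to_frame()

    @property
    def top_increased(self) -> list[TrendResult]:
        return self.report.top_increased

    @property
    def top_decreased(self) -> list[TrendResult]:
        return self.report.top_decreased

    def cloud_weights(self, year_span: int | None = None) -> dict[str, float]:
        if year_span is None:
            year_span = max(self.model.table.years) - min(self.model.table.years)
        return cloud_weights(self.report, year_span)

    def summary(self, top: int = 10) -> str:
        """Human-readable summary of the screen (top terms with 95% CIs)."""
        t = self.model.table
        lines = [
            "Term-frequency trend screen",
            "=" * 60,
            f"order: {'monogram' if t.order == 1 else 'bigram'}   "
            f"years: {min(t.years)}-{max(t.years)}   terms tested: {len(self.report.results)}",
            f"FDR threshold: {self.report.fdr_threshold}   "
            f"significant: {self.report.n_significant}",
            "",
            f"{'term':<28}{'slope/yr':>10}{'95% CI':>22}{'q':>12}",
            "-" * 72,
        ]
        for label, lst in (("top increased", self.top_increased[:top]),
                           ("top decreased", self.top_decreased[:top])):
            lines.append(f"-- {label} --")
            for r in lst:
                lines.append(
                    f"{r.term:<28}{r.slope:>10.3f}"
                    f"{'[' + format(r.ci_low, '.3f') + ', ' + format(r.ci_high, '.3f') + ']':>22}"
                    f"{r.q:>12.3g}"
                )
        return "\n".join(lines)

    def plot_top_terms(self, k: int = 20, ax=None):
        """Horizontal bar plot of top increased/decreased slopes with CIs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.3 * 2 * k + 1.5))
        rows = list(reversed(self.top_decreased[:k])) + list(self.top_increased[:k])[::-1]
        ypos = np.arange(len(rows))
        slopes = [r.slope for r in rows]
        err = np.array([[r.slope - r.ci_low for r in rows], [r.ci_high - r.slope for r in rows]])
        ax.barh(ypos, slopes, xerr=err, color=["tab:red" if s < 0 else "tab:blue" for s in slopes])
        ax.set_yticks(ypos)
        ax.set_yticklabels([r.term for r in rows])
        ax.set_xlabel("mean annual frequency change per 100,000 words")
        ax.axvline(0, color="k", lw=0.8)
        return ax
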