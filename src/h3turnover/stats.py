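"""Correlation and enrichment statistics for turnover analyses.

Thin, typed wrappers over the standard tests: product-moment correlation
with a t-distribution p-value (df = n-2) and the Pearson chi-squared
test on 2x2 contingency tables without continuity correction. Headline
correlations are reported unadjusted; multiple-testing control lives in
the enrichment caller only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .signal import SignalTrack, resample_track


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float

    @property
    def df(self) -> int:
        return self.n - 2

    def __str__(self) -> str:
        p = f"{self.p:.3g}" if self.p >= 1e-300 else "<1e-300"
        return f"PCC = {self.r:.4f}, df = {self.df}, P = {p}"


@dataclass
class ContingencyResult:
    table: np.ndarray
    chi2: float
    df: int
    p: float

    def __str__(self) -> str:
        p = f"{self.p:.3g}" if self.p >= 1e-300 else "<1e-300"
        return f"Chi-squared = {self.chi2:.1f}, df = {self.df}, P = {p}"


def pearson(
    track_a: SignalTrack | np.ndarray,
    track_b: SignalTrack | np.ndarray,
    mask: np.ndarray | None = None,
) -> CorrelationResult:
    """Pearson correlation over paired finite values under an optional mask."""
    a = track_a.values if isinstance(track_a, SignalTrack) else np.asarray(track_a, float)
    b = track_b.values if isinstance(track_b, SignalTrack) else np.asarray(track_b, float)
    if a.shape != b.shape:
        raise ValueError("inputs must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need at least 3 paired finite values")
    if a.max() == a.min() or b.max() == b.min():
        raise ValueError("zero variance input")
    res = sps.pearsonr(a, b)
    return CorrelationResult(r=float(res.statistic), n=len(a), p=float(res.pvalue))


def chisq_2x2(table) -> ContingencyResult:
    """Pearson chi-squared test on a 2x2 table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return ContingencyResult(table=t, chi2=float(chi2), df=int(df), p=float(p))


def spearman(a, b) -> float:
    """Spearman rank correlation on finite pairs (parameter-recovery checks)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    keep = np.isfinite(a) & np.isfinite(b)
    return float(sps.spearmanr(a[keep], b[keep]).statistic)


def replicate_concordance(
    rate_a: SignalTrack,
    rate_b: SignalTrack,
    resolution: int = 10,
    bins: int = 50,
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Correlation of two rate tracks at fine resolution, plus a density grid.

    Both tracks are resampled to ``resolution``-bp windows and correlated
    over windows finite in both (the intersection of the replicates'
    enriched universes, since un-enriched windows carry NaN). The 2-D
    histogram table supports density scatter plotting.
    """
    if rate_a.grid != rate_b.grid:
        raise ValueError("rate tracks must share a grid")
    if rate_a.grid.width != resolution:
        rate_a = resample_track(rate_a, resolution)
        rate_b = resample_track(rate_b, resolution)
    cor = pearson(rate_a, rate_b)
    keep = np.isfinite(rate_a.values) & np.isfinite(rate_b.values)
    h, xe, ye = np.histogram2d(rate_a.values[keep], rate_b.values[keep], bins=bins)
    rows = []
    nz = np.nonzero(h)
    for i, j in zip(*nz):
        rows.append({
            "x_low": xe[i], "x_high": xe[i + 1],
            "y_low": ye[j], "y_high": ye[j + 1],
            "count": int(h[i, j]),
        })
    return cor, pd.DataFrame(rows)
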