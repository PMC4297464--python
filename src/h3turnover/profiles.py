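"""Strand-aware metaprofiles and region summaries of signal tracks.

A profile matrix holds one row per anchor (TSS, peak summit, site
midpoint) and one column per offset bin; oriented aggregation reverses
rows of minus-strand anchors so positive offsets always point downstream
of transcription. Bins with no underlying finite windows are missing and
excluded from means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import FeatureSet
from .signal import SignalTrack

logger = logging.getLogger(__name__)


def standardize(track: SignalTrack) -> SignalTrack:
    """Scale a track to mean 0, variance 1 over its finite values.

    Population convention for the standard deviation; missing values
    propagate unchanged.
    """
    finite = np.isfinite(track.values)
    v = track.values[finite]
    if len(np.unique(v)) < 2:
        raise ValueError("cannot standardize a track with < 2 distinct finite values")
    mean, sd = v.mean(), v.std()
    out = np.full_like(track.values, np.nan)
    out[finite] = (v - mean) / sd
    return track.copy_with(out)


@dataclass
class ProfileMatrix:
    """anchors x offset-bins matrix of mean signal."""

    anchors: pd.DataFrame        # chrom, pos, strand per row
    offsets: np.ndarray          # bp bin centers relative to the anchor
    values: np.ndarray           # anchors x offsets, NaN where missing
    bin_width: int

    def __post_init__(self):
        if self.values.shape != (len(self.anchors), len(self.offsets)):
            raise ValueError("values shape must be anchors x offsets")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            columns=[f"{int(o):+d}" for o in self.offsets],
        )


def _point_anchors(anchors: FeatureSet | pd.DataFrame) -> pd.DataFrame:
    if isinstance(anchors, FeatureSet):
        return anchors.midpoints()
    df = anchors.copy()
    if "pos" not in df.columns:
        raise ValueError("anchor frame needs a 'pos' column")
    if "strand" not in df.columns:
        df["strand"] = "."
    return df.reset_index(drop=True)


def profile_matrix(
    track: SignalTrack,
    anchors: FeatureSet | pd.DataFrame,
    flank: int,
    bin: int = 100,
    step: int | None = None,
    oriented: bool = False,
) -> ProfileMatrix:
    """Mean track signal in sliding bins around each anchor.

    Bins of width ``bin`` are placed every ``step`` bp (default: ``bin``,
    i.e. non-overlapping) covering [-flank, +flank); each cell averages
    the finite track windows whose midpoints fall in the bin. With
    ``oriented``, rows of minus-strand anchors are reversed so offsets
    follow the direction of transcription.
    """
    step = bin if step is None else step
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of the bin width")
    if step <= 0 or bin <= 0 or step > bin:
        raise ValueError("need 0 < step <= bin")
    pts = _point_anchors(anchors)
    bin_starts = np.arange(-flank, flank - bin + 1, step)
    offsets = bin_starts + bin // 2
    grid = track.grid
    values = np.full((len(pts), len(offsets)), np.nan)

    win_mid = {}
    for chrom in grid.chroms.names:
        starts, ends = grid.window_bounds(chrom)
        win_mid[chrom] = starts + (ends - starts) // 2

    for r, (chrom, pos, strand) in enumerate(
        zip(pts["chrom"], pts["pos"], pts["strand"])
    ):
        if chrom not in grid.chroms:
            continue
        mids = win_mid[chrom]
        v = track.chrom_values(chrom)
        lo = np.searchsorted(mids, pos - flank, side="left")
        hi = np.searchsorted(mids, pos + flank, side="left")
        rel = mids[lo:hi] - pos
        vv = v[lo:hi]
        for c, bs in enumerate(bin_starts):
            sel = (rel >= bs) & (rel < bs + bin)
            if sel.any():
                chunk = vv[sel]
                fin = np.isfinite(chunk)
                if fin.any():
                    values[r, c] = chunk[fin].mean()
        if oriented and strand == "-":
            values[r] = values[r, ::-1]
    return ProfileMatrix(pts, offsets, values, bin)


def mean_profile(
    matrix: ProfileMatrix, groups: pd.Series | np.ndarray | None = None
) -> pd.DataFrame:
    """Column-wise mean curve per anchor group.

    Returns a long table (group, offset, mean, n); ``n`` counts finite
    contributing rows per bin. Empty groups are dropped with a warning.
    """
    if groups is None:
        groups = pd.Series("all", index=range(len(matrix.anchors)))
    groups = pd.Series(np.asarray(groups), index=range(len(matrix.anchors)))
    if len(groups) != len(matrix.anchors):
        raise ValueError("one group label per anchor required")
    rows = []
    for g, idx in groups.groupby(groups).groups.items():
        sub = matrix.values[np.asarray(idx)]
        if sub.size == 0:
            logger.warning("empty anchor group %r dropped", g)
            continue
        fin = np.isfinite(sub)
        n = fin.sum(axis=0)
        total = np.where(fin, sub, 0.0).sum(axis=0)
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
        for off, m, k in zip(matrix.offsets, mean, n):
            rows.append({"group": g, "offset": int(off), "mean": m, "n": int(k)})
    return pd.DataFrame(rows)


def profile_peak(
    curves: pd.DataFrame,
    group=None,
    min_support: float = 0.2,
) -> tuple[int, float]:
    """Offset (bin center, bp) of the maximum of a mean-profile curve.

    Bins supported by fewer than ``min_support`` of the curve's maximum
    per-bin n are excluded: with sparse enriched universes, bins fed by a
    single anchor are dominated by sampling extremes and do not reflect
    the aggregate profile.
    """
    sub = curves if group is None else curves[curves["group"] == group]
    sub = sub[np.isfinite(sub["mean"])]
    if not len(sub):
        raise ValueError("profile curve has no finite bins")
    n_req = max(3, int(np.ceil(min_support * sub["n"].max())))
    supported = sub[sub["n"] >= n_req]
    if not len(supported):
        supported = sub
    row = supported.loc[supported["mean"].idxmax()]
    return int(row["offset"]), float(row["mean"])


def region_summary(
    tracks: dict[str, SignalTrack],
    feature_sets: list[FeatureSet],
    flank: int = 5000,
) -> pd.DataFrame:
    """feature-set x track matrix of mean signal around site midpoints.

    Each entry is the mean of finite track values over all windows whose
    midpoints lie within +-flank of any site midpoint in the set, pooled
    across sites (heatmap-ready).
    """
    if not feature_sets:
        raise ValueError("at least one feature set required")
    out = pd.DataFrame(index=[fs.name for fs in feature_sets],
                       columns=list(tracks), dtype=float)
    for name, track in tracks.items():
        grid = track.grid
        mids_by_chrom = {}
        for chrom in grid.chroms.names:
            starts, ends = grid.window_bounds(chrom)
            mids_by_chrom[chrom] = starts + (ends - starts) // 2
        for fs in feature_sets:
            pooled = []
            for chrom, pos, _ in fs.midpoints().itertuples(index=False):
                if chrom not in grid.chroms:
                    continue
                mids = mids_by_chrom[chrom]
                lo = np.searchsorted(mids, pos - flank, side="left")
                hi = np.searchsorted(mids, pos + flank, side="right")
                pooled.append(track.chrom_values(chrom)[lo:hi])
            if pooled:
                allv = np.concatenate(pooled)
                allv = allv[np.isfinite(allv)]
                out.loc[fs.name, name] = allv.mean() if len(allv) else np.nan
    return out


def plot_profiles(curves: pd.DataFrame, ax=None):
    """Line plot of mean_profile output, one line per group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for g, sub in curves.groupby("group"):
        ax.plot(sub["offset"], sub["mean"], label=str(g))
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("offset from anchor (bp)")
    ax.set_ylabel("mean signal")
    ax.legend(fontsize="small")
    return ax
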