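"""Genomic feature classification: proximity, expression bins, TF overlap.

Distance between half-open intervals is the gap in bp (0 for overlapping
or book-ended intervals); proximity cutoffs are inclusive ("within 5 kbp"
reads as <= 5000). Strand is ignored for all proximity and overlap
classification.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import FeatureSet

logger = logging.getLogger(__name__)

# FPKM bin edges, upper-inclusive: (30,inf) top10, (10,30] top20,
# (3,10] medium, (1,3] low, [0,1] silent
EXPRESSION_BINS = (
    ("top10", 30.0),
    ("top20", 10.0),
    ("medium", 3.0),
    ("low", 1.0),
)


def bin_expression(fpkm: float) -> str:
    """Assign a transcript expression category from its FPKM.

    >30 FPKM: top10; (10, 30]: top20; (3, 10]: medium; (1, 3]: low;
    [0, 1]: silent. Boundaries are upper-inclusive so the verbal ranges
    tile [0, inf) without gaps.
    """
    if fpkm < 0 or not np.isfinite(fpkm):
        raise ValueError(f"FPKM must be a finite non-negative number, got {fpkm}")
    for category, lower in EXPRESSION_BINS:
        if fpkm > lower:
            return category
    return "silent"


def bin_expression_table(expression: pd.DataFrame) -> pd.DataFrame:
    """Add a 'category' column to a (transcript_id, fpkm) table."""
    out = expression.copy()
    out["category"] = [bin_expression(f) for f in out["fpkm"]]
    return out


def interval_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Gap in bp between two half-open intervals; 0 when they touch or overlap."""
    return max(0, start_b - end_a, start_a - end_b)


def _min_distances(sites: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Minimum gap distance from each site to any target interval.

    Per chromosome, sorted target starts/ends let searchsorted find the
    flanking neighbours; overlap detection uses the running maximum of
    target ends. Sites on chromosomes without targets get distance inf.
    """
    dist = np.full(len(sites), np.inf)
    by_chrom = {c: t for c, t in targets.groupby("chrom", sort=False)}
    for chrom, sub in sites.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            logger.warning("no target intervals on %s; sites treated as distal", chrom)
            continue
        t = by_chrom[chrom].sort_values("start")
        tstart = t["start"].to_numpy(np.int64)
        tend = t["end"].to_numpy(np.int64)
        cummax_end = np.maximum.accumulate(tend)
        s = sub["start"].to_numpy(np.int64)
        e = sub["end"].to_numpy(np.int64)
        # nearest target starting at/after the site end -> gap on the right
        right = np.searchsorted(tstart, e, side="left")
        d_right = np.where(right < len(tstart), tstart[np.minimum(right, len(tstart) - 1)] - e, np.inf)
        # targets starting before the site end: overlap if any extends past site start
        left = np.searchsorted(tstart, e, side="left") - 1
        has_left = left >= 0
        left_end = np.where(has_left, cummax_end[np.maximum(left, 0)], -1)
        overlap = has_left & (left_end > s)
        d_left = np.where(has_left, s - left_end, np.inf)
        d_left = np.maximum(d_left, 0)
        d = np.minimum(d_right, d_left)
        d[overlap] = 0
        dist[sub.index.to_numpy()] = d
    return dist


def min_distance_brute(sites: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Brute-force pairwise minimum gap; reference for small instances."""
    dist = np.full(len(sites), np.inf)
    for i, srow in enumerate(sites.itertuples(index=False)):
        for trow in targets.itertuples(index=False):
            if srow.chrom != trow.chrom:
                continue
            g = interval_gap(srow.start, srow.end, trow.start, trow.end)
            dist[i] = min(dist[i], g)
    return dist


def classify_proximity(
    sites: FeatureSet, transcripts: FeatureSet, cutoff: int = 5000
) -> pd.Series:
    """Label each site proximal (gap to any transcript <= cutoff) or distal."""
    if len(transcripts) == 0:
        raise ValueError("transcript set must be non-empty")
    d = _min_distances(sites.intervals, transcripts.intervals)
    return pd.Series(
        np.where(d <= cutoff, "proximal", "distal"),
        index=sites.intervals.index, name="proximity",
    )


def classify_repeats(
    repeats: FeatureSet, transcripts: FeatureSet, cutoff: int = 2000
) -> pd.Series:
    """Label each repeat genic (within cutoff of a transcript) or non_genic."""
    if len(transcripts) == 0:
        raise ValueError("transcript set must be non-empty")
    d = _min_distances(repeats.intervals, transcripts.intervals)
    return pd.Series(
        np.where(d <= cutoff, "genic", "non_genic"),
        index=repeats.intervals.index, name="repeat_class",
    )


def _overlaps_any(sites: pd.DataFrame, peaks: pd.DataFrame, min_overlap: int) -> np.ndarray:
    """Boolean per site: overlaps any peak by >= min_overlap bp."""
    hit = np.zeros(len(sites), dtype=bool)
    if not len(sites) or not len(peaks):
        return hit
    by_chrom = {c: p for c, p in peaks.groupby("chrom", sort=False)}
    for chrom, sub in sites.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        p = by_chrom[chrom]
        ps = p["start"].to_numpy(np.int64)
        pe = p["end"].to_numpy(np.int64)
        for idx, s, e in zip(sub.index, sub["start"], sub["end"]):
            ov = np.minimum(e, pe) - np.maximum(s, ps)
            if (ov >= min_overlap).any():
                hit[idx] = True
    return hit


def bound_fraction(n_bound: int, n_total: int) -> float:
    """Fraction of elements bound, as a proportion in [0, 1]."""
    if n_total <= 0:
        raise ValueError("total element count must be positive")
    if not 0 <= n_bound <= n_total:
        raise ValueError("bound count must lie in [0, total]")
    return n_bound / n_total


def tf_binding_overlap(
    repeats: FeatureSet,
    peak_sets: list[FeatureSet],
    min_overlap: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag repeats bound by each TF peak set and by at least one.

    Returns (flags, fractions): ``flags`` has one boolean column per peak
    set plus 'any_tf' (the union); ``fractions`` reports bound/total per
    peak set and for the union.
    """
    if not peak_sets:
        raise ValueError("at least one peak set required")
    flags = pd.DataFrame(index=repeats.intervals.index)
    for fs in peak_sets:
        flags[fs.name] = _overlaps_any(repeats.intervals, fs.intervals, min_overlap)
    flags["any_tf"] = flags.any(axis=1) if len(flags) else pd.Series(dtype=bool)
    n = len(repeats)
    frac_rows = [
        {"peak_set": col, "n_bound": int(flags[col].sum()), "n_total": n,
         "fraction": bound_fraction(int(flags[col].sum()), n) if n else np.nan}
        for col in flags.columns
    ]
    return flags, pd.DataFrame(frac_rows)


def binding_summary(
    repeats: FeatureSet,
    repeat_class: pd.Series,
    peak_sets: list[FeatureSet],
    family_column: str = "name",
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Bound fractions per repeat family x genic/non-genic class x peak set."""
    flags, _ = tf_binding_overlap(repeats, peak_sets, min_overlap)
    df = repeats.intervals.copy()
    df["family"] = df[family_column]
    df["repeat_class"] = repeat_class
    rows = []
    for (family, cls), sub in df.groupby(["family", "repeat_class"]):
        for col in flags.columns:
            nb = int(flags.loc[sub.index, col].sum())
            rows.append({
                "family": family, "repeat_class": cls, "peak_set": col,
                "n_bound": nb, "n_total": len(sub),
                "fraction": bound_fraction(nb, len(sub)),
            })
    return pd.DataFrame(rows)
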