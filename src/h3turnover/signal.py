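"""Windowed signal tracks from read alignments.

The counting unit is the *dyad*: each aligned read is extended to a
nucleosome footprint (150 bp by default) from its 5′ end, and the floor
midpoint of the extended interval is the inferred nucleosome centre. Dyads
are counted on a window grid, smoothed with a weighted three-window
low-pass filter, and windows significantly enriched over input DNA at the
start of the time course form the analysis universe for all rate
estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import ChromSizes, GenomicInterval, validate_reads

DEFAULT_EXTENSION = 150
DEFAULT_WINDOW = 250


class WindowGrid:
    """Fixed windows tiling every chromosome from coordinate 0.

    Windows of ``width`` bp are laid every ``step`` bp (``step == width``
    gives the usual non-overlapping tiling); the last, possibly partial,
    window is kept so every base is covered.
    """

    def __init__(self, chroms: ChromSizes, width: int, step: int | None = None):
        step = width if step is None else step
        if width <= 0 or step <= 0:
            raise ValueError("width and step must be positive")
        if step > width:
            raise ValueError("step must not exceed width")
        self.chroms = chroms
        self.width = int(width)
        self.step = int(step)
        self._n = {c: -(-length // self.step) for c, length in chroms.items()}
        self._offset = {}
        total = 0
        for c in chroms.names:
            self._offset[c] = total
            total += self._n[c]
        self.n_windows = total

    @property
    def overlapping(self) -> bool:
        return self.step < self.width

    def n_chrom_windows(self, chrom: str) -> int:
        return self._n[chrom]

    def chrom_offset(self, chrom: str) -> int:
        return self._offset[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offset[chrom]
        return slice(off, off + self._n[chrom])

    def window_bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        starts = np.arange(self._n[chrom], dtype=np.int64) * self.step
        ends = np.minimum(starts + self.width, self.chroms[chrom])
        return starts, ends

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WindowGrid)
            and self.chroms == other.chroms
            and self.width == other.width
            and self.step == other.step
        )

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for c in self.chroms.names:
            starts, ends = self.window_bounds(c)
            parts.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
        return pd.concat(parts, ignore_index=True)


@dataclass
class SignalTrack:
    """One value per grid window, plus the library size for count tracks."""

    grid: WindowGrid
    values: np.ndarray
    library_size: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_windows,):
            raise ValueError(
                f"expected {self.grid.n_windows} values, got {self.values.shape}"
            )

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.grid.chrom_slice(chrom)]

    def copy_with(self, values: np.ndarray, library_size: float | None = None) -> "SignalTrack":
        return SignalTrack(
            self.grid,
            values,
            self.library_size if library_size is None else library_size,
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["value"] = self.values
        return df

    def write_bedgraph(self, path, drop_missing: bool = True) -> None:
        df = self.to_frame()
        if drop_missing:
            df = df[np.isfinite(df["value"])]
        with open(path, "w") as fh:
            for chrom, start, end, value in df.itertuples(index=False):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.6f}\n")

    @classmethod
    def read_bedgraph(cls, path, grid: WindowGrid, library_size: float = 0.0) -> "SignalTrack":
        values = np.full(grid.n_windows, np.nan)
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        for chrom, sub in df.groupby("chrom", sort=False):
            idx = grid.chrom_offset(chrom) + sub["start"].to_numpy() // grid.step
            values[idx] = sub["value"].to_numpy()
        return cls(grid, values, library_size)


def extend_read(
    chrom: str,
    five_prime: int,
    strand: str,
    chroms: ChromSizes,
    length: int = DEFAULT_EXTENSION,
) -> GenomicInterval:
    """Extend a read ``length`` bp from its 5′ end, clipped to the chromosome.

    Plus strand: [five_prime, five_prime+length); minus strand:
    [five_prime-length+1, five_prime+1).
    """
    if length <= 0:
        raise ValueError("extension length must be positive")
    if chrom not in chroms:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if strand == "+":
        start, end = five_prime, five_prime + length
    elif strand == "-":
        start, end = five_prime - length + 1, five_prime + 1
    else:
        raise ValueError(f"read strand must be '+' or '-', got {strand!r}")
    start = max(start, 0)
    end = min(end, chroms[chrom])
    return GenomicInterval(chrom, start, end, strand)


def dyad_position(extended: GenomicInterval) -> int:
    """Floor midpoint of the extended read — the inferred nucleosome centre."""
    return extended.start + (extended.end - extended.start) // 2


def _dyads_vector(
    five_prime: np.ndarray, strand: np.ndarray, chrom_len: int, length: int
) -> np.ndarray:
    """Vectorized extend+midpoint for one chromosome's reads."""
    plus = strand == "+"
    start = np.where(plus, five_prime, five_prime - length + 1)
    end = np.where(plus, five_prime + length, five_prime + 1)
    start = np.maximum(start, 0)
    end = np.minimum(end, chrom_len)
    return start + (end - start) // 2


def count_dyads(
    reads: pd.DataFrame,
    grid: WindowGrid,
    extension: int = DEFAULT_EXTENSION,
) -> SignalTrack:
    """Count extended-read dyads per grid window.

    Each read contributes 1 to every window containing its dyad position
    (exactly one window when ``step == width``).
    """
    validate_reads(reads, grid.chroms)
    values = np.zeros(grid.n_windows)
    for chrom, sub in reads.groupby("chrom", sort=False):
        dyads = _dyads_vector(
            sub["five_prime"].to_numpy(np.int64),
            sub["strand"].to_numpy(),
            grid.chroms[chrom],
            extension,
        )
        off = grid.chrom_offset(chrom)
        n = grid.n_chrom_windows(chrom)
        if not grid.overlapping:
            idx = np.minimum(dyads // grid.step, n - 1)
            values[off : off + n] += np.bincount(idx, minlength=n)
        else:
            # a dyad d lies in window w iff w*step <= d < w*step + width
            max_span = -(-grid.width // grid.step)
            for j in range(max_span):
                w = dyads // grid.step - j
                keep = (w >= 0) & (w < n) & (w * grid.step + grid.width > dyads)
                values[off : off + n] += np.bincount(w[keep], minlength=n)
    return SignalTrack(grid, values, library_size=float(len(reads)))


def lowpass_filter(track: SignalTrack) -> SignalTrack:
    """Weighted three-window smoothing of a count track.

    Each window is replaced by the weighted average of itself (weight 1)
    and its two flanking windows (weight 0.5 each), divided by the sum of
    in-bounds weights — 2 in the interior, 1.5 at chromosome edges — so
    constant tracks pass through unchanged. Chromosomes are filtered
    independently; the grid is unchanged.
    """
    if track.grid.overlapping:
        raise ValueError("low-pass filter expects a non-overlapping grid")
    out = np.empty_like(track.values)
    for chrom in track.grid.chroms.names:
        v = track.chrom_values(chrom)
        n = len(v)
        if n < 1:
            raise ValueError(f"chromosome {chrom!r} has no windows")
        num = v.astype(float).copy()
        den = np.ones(n)
        if n > 1:
            num[1:] += 0.5 * v[:-1]
            num[:-1] += 0.5 * v[1:]
            den[1:] += 0.5
            den[:-1] += 0.5
        out[track.grid.chrom_slice(chrom)] = num / den
    return track.copy_with(out)


def call_enriched(
    chip0: SignalTrack,
    input0: SignalTrack,
    alpha: float = 0.05,
    min_fold: float = 2.0,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Windows significantly enriched in ChIP over input at the first timepoint.

    A window passes when the exact Poisson upper-tail probability of its
    ChIP count, given the library-size-scaled input expectation (floored
    at ``pseudocount``), survives Benjamini-Hochberg control at ``alpha``
    and the normalized fold change is at least ``min_fold``. The returned
    boolean mask is the analysis universe for all rate computations.
    """
    if chip0.grid != input0.grid:
        raise ValueError("chip and input tracks must share a grid")
    if chip0.library_size <= 0 or input0.library_size <= 0:
        raise ValueError("library sizes must be positive")
    mu = np.maximum(
        input0.values * (chip0.library_size / input0.library_size), pseudocount
    )
    chip = chip0.values
    pvals = sps.poisson.sf(chip - 1, mu)
    qvals = sps.false_discovery_control(pvals, method="bh")
    fold = chip / mu
    return (qvals <= alpha) & (fold >= min_fold)


def enrichment_pvalue(chip_count: float, expected: float) -> float:
    """Exact Poisson upper-tail probability P(X >= chip_count | expected)."""
    return float(sps.poisson.sf(chip_count - 1, expected))


def resample_track(track: SignalTrack, width: int) -> SignalTrack:
    """Re-express a non-overlapping track on a finer non-overlapping grid.

    Each new window takes the value of the source window containing its
    midpoint — the convention used to report 250-bp rates in 10-bp windows.
    """
    if track.grid.overlapping:
        raise ValueError("resampling requires a non-overlapping source grid")
    new_grid = WindowGrid(track.grid.chroms, width)
    values = np.empty(new_grid.n_windows)
    for chrom in new_grid.chroms.names:
        starts, ends = new_grid.window_bounds(chrom)
        mids = starts + (ends - starts) // 2
        src_idx = np.minimum(
            mids // track.grid.width, track.grid.n_chrom_windows(chrom) - 1
        )
        values[new_grid.chrom_slice(chrom)] = track.chrom_values(chrom)[src_idx]
    return SignalTrack(new_grid, values, track.library_size)


def mask_to_features(mask: np.ndarray, grid: WindowGrid, name: str = "enriched"):
    """Export a boolean window mask as a FeatureSet of enriched windows."""
    from .genome import FeatureSet

    parts = []
    for chrom in grid.chroms.names:
        m = mask[grid.chrom_slice(chrom)]
        starts, ends = grid.window_bounds(chrom)
        parts.append(
            pd.DataFrame({"chrom": chrom, "start": starts[m], "end": ends[m]})
        )
    return FeatureSet(name, pd.concat(parts, ignore_index=True))
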