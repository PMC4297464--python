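"""Per-locus H3.3 dissociation rates and equilibrium levels.

The TET-OFF design shuts off synthesis of the tagged histone, so the
chromatin-bound signal at a locus decays exponentially,

    N(t) = N(0) * exp(-lambda * t),

and two timepoints determine the rate: lambda_raw = ln(N(0)/N(6)) / 6 h.
Rates are reported on a bounded scale via the logistic of the log count
ratio,

    lambda_out = (N(0)+eps) / ((N(0)+eps) + (N(6)+eps))
               = 1 / (1 + exp(-lambda_raw * dt)),

which maps no net change to 0.5, complete dissociation to 1 and net gain
toward 0. Equilibrium levels are the 0-h ChIP/input enrichment on a log2
scale. The Haldane-Anscombe pseudocount ``eps`` (default 0.5) guards
empty windows.

`TurnoverModel` / `TurnoverResults` wrap these primitives in a
fit-then-inspect interface over whole-genome window tracks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .signal import SignalTrack, lowpass_filter, resample_track

DEFAULT_DT = 6.0
DEFAULT_EPS = 0.5
DEFAULT_TARGET_DEPTH = 1_000_000.0


def normalize_counts(track: SignalTrack, target_depth: float = DEFAULT_TARGET_DEPTH) -> SignalTrack:
    """Scale a count track to a common sequencing depth."""
    if track.library_size <= 0:
        raise ValueError("cannot normalize a track with zero library size")
    factor = target_depth / track.library_size
    return track.copy_with(track.values * factor, library_size=target_depth)


def raw_decay_rate(n0, n6, dt: float = DEFAULT_DT, eps: float = DEFAULT_EPS):
    """Exponential decay rate ln((n0+eps)/(n6+eps))/dt in h^-1.

    Negative when the count rises — net incorporation outweighed loss over
    the interval.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if eps < 0:
        raise ValueError("eps must be non-negative")
    n0 = np.asarray(n0, dtype=float)
    n6 = np.asarray(n6, dtype=float)
    return np.log((n0 + eps) / (n6 + eps)) / dt


def scaled_dissociation(n0, n6, dt: float = DEFAULT_DT, eps: float = DEFAULT_EPS):
    """Dissociation rate scaled to [0, 1].

    Algebraically the logistic 1/(1+exp(-lambda_raw*dt)): 0.5 means no net
    change, above 0.5 net loss, below net gain.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if eps < 0:
        raise ValueError("eps must be non-negative")
    n0 = np.asarray(n0, dtype=float)
    n6 = np.asarray(n6, dtype=float)
    return (n0 + eps) / ((n0 + eps) + (n6 + eps))


def equilibrium_level(n0, i0, eps: float = DEFAULT_EPS, log2: bool = True):
    """Steady-state enrichment of tagged H3.3 over input at 0 h.

    Inputs must be depth-normalized. Reported as log2((n0+eps)/(i0+eps))
    by default; ``log2=False`` returns the linear ratio.
    """
    if eps < 0:
        raise ValueError("eps must be non-negative")
    n0 = np.asarray(n0, dtype=float)
    i0 = np.asarray(i0, dtype=float)
    ratio = (n0 + eps) / (i0 + eps)
    return np.log2(ratio) if log2 else ratio


def turnover_tracks(
    lib0: SignalTrack,
    lib6: SignalTrack,
    input0: SignalTrack,
    mask: np.ndarray,
    dt: float = DEFAULT_DT,
    eps: float = DEFAULT_EPS,
) -> tuple[SignalTrack, SignalTrack, SignalTrack]:
    """Per-window (lambda_out, lambda_raw, lambda_equ) tracks.

    Tracks must be depth-normalized and share a grid; windows outside the
    enrichment mask carry NaN.
    """
    for t in (lib6, input0):
        if t.grid != lib0.grid:
            raise ValueError("all tracks must share a grid")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != lib0.values.shape:
        raise ValueError("mask length must match window count")
    out = np.full_like(lib0.values, np.nan)
    raw = np.full_like(lib0.values, np.nan)
    equ = np.full_like(lib0.values, np.nan)
    n0, n6, i0 = lib0.values[mask], lib6.values[mask], input0.values[mask]
    out[mask] = scaled_dissociation(n0, n6, dt, eps)
    raw[mask] = raw_decay_rate(n0, n6, dt, eps)
    equ[mask] = equilibrium_level(n0, i0, eps)
    return lib0.copy_with(out), lib0.copy_with(raw), lib0.copy_with(equ)


class TurnoverModel:
    """H3.3 turnover model over windowed count tracks.

    Parameters
    ----------
    chip_t0, chip_t6 : SignalTrack
        Dyad-count tracks for the tagged-histone ChIP at 0 h and 6 h
        after shutting off expression.
    input_t0 : SignalTrack
        Input-DNA dyad counts at 0 h.
    mask : ndarray of bool, optional
        Analysis universe; computed with `signal.call_enriched` when not
        given.
    dt : float
        Interval between the two timepoints, hours.
    eps : float
        Pseudocount added to every count before ratios.
    apply_filter : bool
        Smooth counts with the three-window low-pass filter before rate
        estimation (default True).
    target_depth : float, optional
        Common depth all libraries are scaled to before ratios; defaults
        to the mean of the two ChIP library sizes so values stay on the
        raw count scale and ``eps`` keeps its Haldane-correction meaning.
    """

    def __init__(
        self,
        chip_t0: SignalTrack,
        chip_t6: SignalTrack,
        input_t0: SignalTrack,
        mask: np.ndarray | None = None,
        dt: float = DEFAULT_DT,
        eps: float = DEFAULT_EPS,
        apply_filter: bool = True,
        target_depth: float | None = None,
        alpha: float = 0.05,
        min_fold: float = 2.0,
    ):
        if dt <= 0:
            raise ValueError("dt must be positive")
        for t in (chip_t6, input_t0):
            if t.grid != chip_t0.grid:
                raise ValueError("all tracks must share a grid")
        self.chip_t0 = chip_t0
        self.chip_t6 = chip_t6
        self.input_t0 = input_t0
        self.dt = float(dt)
        self.eps = float(eps)
        self.apply_filter = bool(apply_filter)
        if target_depth is None:
            target_depth = 0.5 * (chip_t0.library_size + chip_t6.library_size)
        self.target_depth = float(target_depth)
        self.alpha = float(alpha)
        self.min_fold = float(min_fold)
        self._mask = None if mask is None else np.asarray(mask, dtype=bool)

    @classmethod
    def from_reads(
        cls,
        reads_t0: pd.DataFrame,
        reads_t6: pd.DataFrame,
        reads_input: pd.DataFrame,
        chroms,
        window: int = 250,
        step: int | None = None,
        extension: int = 150,
        **kwargs,
    ) -> "TurnoverModel":
        """Build the model directly from read tables (chrom/five_prime/strand).

        ``step < window`` gives sliding windows (no low-pass filter in
        that case — the overlap already smooths).
        """
        from .signal import WindowGrid, count_dyads

        grid = WindowGrid(chroms, window, step)
        return cls(
            count_dyads(reads_t0, grid, extension),
            count_dyads(reads_t6, grid, extension),
            count_dyads(reads_input, grid, extension),
            **kwargs,
        )

    def fit(self) -> "TurnoverResults":
        from .signal import call_enriched

        if self._mask is None:
            mask = call_enriched(
                self.chip_t0, self.input_t0, alpha=self.alpha, min_fold=self.min_fold
            )
        else:
            mask = self._mask
        t0, t6, i0 = self.chip_t0, self.chip_t6, self.input_t0
        if self.apply_filter:
            t0, t6, i0 = lowpass_filter(t0), lowpass_filter(t6), lowpass_filter(i0)
        t0 = normalize_counts(t0, self.target_depth)
        t6 = normalize_counts(t6, self.target_depth)
        i0 = normalize_counts(i0, self.target_depth)
        lam_out, lam_raw, lam_equ = turnover_tracks(
            t0, t6, i0, mask, dt=self.dt, eps=self.eps
        )
        return TurnoverResults(self, mask, t0, t6, i0, lam_out, lam_raw, lam_equ)


class TurnoverResults:
    """Fitted per-window dissociation rates and equilibrium levels.

    Attributes
    ----------
    lambda_out, lambda_raw, lambda_equ : SignalTrack
        Scaled dissociation rate in [0,1], raw decay rate (h^-1) and
        log2 ChIP/input equilibrium level; NaN outside the enriched mask.
    """

    def __init__(self, model, mask, n0, n6, i0, lam_out, lam_raw, lam_equ):
        self.model = model
        self.mask = mask
        self.n0 = n0
        self.n6 = n6
        self.i0 = i0
        self.lambda_out = lam_out
        self.lambda_raw = lam_raw
        self.lambda_equ = lam_equ

    @property
    def grid(self):
        return self.lambda_out.grid

    @property
    def n_enriched(self) -> int:
        return int(self.mask.sum())

    def half_life(self) -> SignalTrack:
        """Per-window half-life ln2/lambda_raw in hours (inf where rate <= 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            hl = np.where(self.lambda_raw.values > 0,
                          np.log(2) / self.lambda_raw.values, np.inf)
        return self.lambda_raw.copy_with(hl)

    def resample(self, width: int = 10) -> "TurnoverResults":
        """Re-express all rate tracks on a finer grid (midpoint assignment)."""
        fine_mask_track = resample_track(
            self.lambda_out.copy_with(self.mask.astype(float)), width
        )
        return TurnoverResults(
            self.model,
            fine_mask_track.values > 0.5,
            resample_track(self.n0, width),
            resample_track(self.n6, width),
            resample_track(self.i0, width),
            resample_track(self.lambda_out, width),
            resample_track(self.lambda_raw, width),
            resample_track(self.lambda_equ, width),
        )

    def to_frame(self, masked_only: bool = True) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["n0"] = self.n0.values
        df["n6"] = self.n6.values
        df["i0"] = self.i0.values
        df["lambda_raw"] = self.lambda_raw.values
        df["lambda_out"] = self.lambda_out.values
        df["lambda_equ"] = self.lambda_equ.values
        if masked_only:
            df = df[self.mask].reset_index(drop=True)
        return df

    def summary(self) -> str:
        m = self.mask
        lam = self.lambda_out.values[m]
        raw = self.lambda_raw.values[m]
        equ = self.lambda_equ.values[m]
        lines = [
            "H3.3 turnover model results",
            "===========================",
            f"windows (grid {self.grid.width} bp):      {self.grid.n_windows}",
            f"enriched windows (universe): {self.n_enriched}",
            f"dt = {self.model.dt} h, eps = {self.model.eps}, "
            f"low-pass filter = {self.model.apply_filter}",
            "",
            f"{'':16s}{'mean':>10s}{'median':>10s}{'sd':>10s}",
        ]
        for name, v in (("lambda_out", lam), ("lambda_raw", raw), ("lambda_equ", equ)):
            if len(v):
                lines.append(
                    f"{name:16s}{np.nanmean(v):10.4f}{np.nanmedian(v):10.4f}"
                    f"{np.nanstd(v):10.4f}"
                )
            else:
                lines.append(f"{name:16s}{'--':>10s}{'--':>10s}{'--':>10s}")
        return "\n".join(lines)

    def plot_rate_vs_equilibrium(self, ax=None, gridsize: int = 60):
        """Density plot of lambda_out against lambda_equ over masked windows."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.lambda_equ.values[self.mask]
        y = self.lambda_out.values[self.mask]
        ok = np.isfinite(x) & np.isfinite(y)
        ax.hexbin(x[ok], y[ok], gridsize=gridsize, cmap="viridis", mincnt=1)
        ax.set_xlabel("equilibrium level, log2(ChIP/input)")
        ax.set_ylabel("scaled dissociation rate")
        return ax
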