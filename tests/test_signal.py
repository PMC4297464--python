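"""Read extension, dyad counting, low-pass smoothing and enrichment calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from h3turnover.genome import ChromSizes
from h3turnover.signal import (
    WindowGrid, SignalTrack, extend_read, dyad_position, count_dyads,
    lowpass_filter, call_enriched, enrichment_pvalue, resample_track,
)
from conftest import make_reads

CHROMS = ChromSizes({"chrT": 100_000})


class TestExtendRead:
    @pytest.mark.parametrize("strand,pos,expected", [
        ("+", 100, (100, 250)),
        ("-", 400, (251, 401)),
        ("+", 99_990, (99_990, 100_000)),   # clipped at chromosome end
        ("-", 50, (0, 51)),                  # clipped at chromosome start
    ])
    def test_extension_interval(self, strand, pos, expected):
        iv = extend_read("chrT", pos, strand, CHROMS, length=150)
        assert (iv.start, iv.end) == expected

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chromosome"):
            extend_read("chrZ", 100, "+", CHROMS)

    @pytest.mark.parametrize("interval,expected", [
        ((100, 250), 175),
        ((0, 150), 75),
        ((90, 100), 95),
    ])
    def test_dyad_is_floor_midpoint(self, interval, expected):
        from h3turnover.genome import GenomicInterval

        assert dyad_position(GenomicInterval("chrT", *interval)) == expected

    @given(pos=st.integers(min_value=200, max_value=99_000))
    def test_dyad_strand_symmetry(self, pos):
        # a plus read at p and a minus read at p+149 cover the same
        # 150-bp footprint, hence the same dyad
        plus = dyad_position(extend_read("chrT", pos, "+", CHROMS))
        minus = dyad_position(extend_read("chrT", pos + 149, "-", CHROMS))
        assert plus == minus


class TestCountDyads:
    def test_empty_reads_give_zero_track(self):
        grid = WindowGrid(CHROMS, 250)
        track = count_dyads(make_reads("chrT", [], ""), grid)
        assert track.values.sum() == 0
        assert track.library_size == 0

    def test_single_read_lands_in_containing_window(self):
        grid = WindowGrid(CHROMS, 250)
        track = count_dyads(make_reads("chrT", [100], "+"), grid)
        # dyad at 175 -> window [0, 250)
        assert track.values[0] == 1
        assert track.values[1:].sum() == 0

    @given(st.lists(st.tuples(st.integers(200, 99_000),
                              st.sampled_from("+-")), max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_reads_conserved_on_nonoverlapping_grid(self, items):
        grid = WindowGrid(CHROMS, 250)
        reads = make_reads("chrT", [p for p, _ in items], [s for _, s in items])
        track = count_dyads(reads, grid)
        assert track.values.sum() == len(items)
        assert track.library_size == len(items)

    def test_sliding_windows_each_contain_dyad(self):
        grid = WindowGrid(CHROMS, width=50, step=10)
        track = count_dyads(make_reads("chrT", [500], "+"), grid)
        # dyad 575: windows [w*10, w*10+50) containing 575 -> w in 53..57
        starts, _ = grid.window_bounds("chrT")
        hit = np.nonzero(track.chrom_values("chrT"))[0]
        assert list(hit) == [53, 54, 55, 56, 57]
        assert all(starts[w] <= 575 < starts[w] + 50 for w in hit)

    def test_unknown_chromosome_rejected(self):
        grid = WindowGrid(CHROMS, 250)
        with pytest.raises(ValueError, match="chromosomes absent"):
            count_dyads(make_reads("chrZ", [10], "+"), grid)


def brute_force_lowpass(values):
    """Direct (1, 0.5, 0.5)/sum-of-in-bounds-weights convolution."""
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        num, den = 1.0 * values[i], 1.0
        if i > 0:
            num += 0.5 * values[i - 1]
            den += 0.5
        if i < n - 1:
            num += 0.5 * values[i + 1]
            den += 0.5
        out[i] = num / den
    return out


class TestLowpassFilter:
    def _track(self, values, width=250):
        # widen windows so the chromosome meets the 10-kb minimum while
        # keeping exactly len(values) windows
        width = max(width, -(-10_000 // len(values)))
        chroms = ChromSizes({"chrT": len(values) * width})
        return SignalTrack(WindowGrid(chroms, width), np.asarray(values, float))

    def test_constant_track_preserved(self):
        track = self._track([3.0] * 8)
        assert np.allclose(lowpass_filter(track).values, 3.0)

    def test_interior_weighted_average(self):
        out = lowpass_filter(self._track([0, 4, 0]))
        assert out.values[1] == pytest.approx(4 / 2)

    def test_edge_divisor(self):
        out = lowpass_filter(self._track([4, 0, 0, 0]))
        assert out.values[0] == pytest.approx(4 / 1.5)

    @given(st.lists(st.floats(0, 1000, allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_convolution(self, values):
        out = lowpass_filter(self._track(values))
        assert np.array_equal(out.values, brute_force_lowpass(np.asarray(values)))

    def test_chromosomes_filtered_independently(self):
        chroms = ChromSizes({"c1": 100_000, "c2": 100_000})
        grid = WindowGrid(chroms, 50_000)
        track = SignalTrack(grid, np.array([8.0, 0.0, 0.0, 8.0]))
        out = lowpass_filter(track)
        # last window of c1 must not see first window of c2
        assert out.values[1] == pytest.approx((0 + 0.5 * 8) / 1.5)
        assert out.values[2] == pytest.approx((0 + 0.5 * 8) / 1.5)

    def test_overlapping_grid_rejected(self):
        grid = WindowGrid(CHROMS, width=50, step=10)
        with pytest.raises(ValueError, match="non-overlapping"):
            lowpass_filter(SignalTrack(grid, np.zeros(grid.n_windows)))


def poisson_upper_tail_brute(k, mu, terms=400):
    """Sum of Poisson pmf from k upward (independent oracle)."""
    from math import exp

    term = exp(-mu)
    total = 0.0
    for i in range(terms):
        if i >= k:
            total += term
        term *= mu / (i + 1)
    return total


class TestEnrichment:
    @pytest.mark.parametrize("k,mu", [(20, 2.0), (3, 2.0), (0, 0.5), (7, 1.0)])
    def test_pvalue_matches_tail_sum(self, k, mu):
        assert enrichment_pvalue(k, mu) == pytest.approx(
            poisson_upper_tail_brute(k, mu), rel=1e-9
        )

    def test_strong_window_called_weak_window_not(self):
        chroms = ChromSizes({"chrT": 10_000})
        grid = WindowGrid(chroms, 250)
        chip = np.ones(grid.n_windows)
        inp = np.full(grid.n_windows, 2.0)
        chip[5] = 20.0   # P(X>=20 | mu=2) ~ 5.4e-13
        chip[7] = 3.0    # P(X>=3  | mu=2) ~ 0.32
        chip_t = SignalTrack(grid, chip, library_size=chip.sum())
        inp_t = SignalTrack(grid, inp, library_size=inp.sum())
        # equalize library scaling so mu == input value
        inp_t.library_size = chip_t.library_size
        mask = call_enriched(chip_t, inp_t, alpha=0.05, min_fold=2)
        assert mask[5]
        assert not mask[7]

    def test_zero_chip_never_enriched(self):
        grid = WindowGrid(ChromSizes({"chrT": 10_000}), 250)
        chip = SignalTrack(grid, np.zeros(grid.n_windows), library_size=100)
        inp = SignalTrack(grid, np.ones(grid.n_windows), library_size=100)
        assert not call_enriched(chip, inp).any()

    def test_grid_mismatch_rejected(self):
        g1 = WindowGrid(CHROMS, 250)
        g2 = WindowGrid(CHROMS, 500)
        a = SignalTrack(g1, np.zeros(g1.n_windows), 10)
        b = SignalTrack(g2, np.zeros(g2.n_windows), 10)
        with pytest.raises(ValueError, match="grid"):
            call_enriched(a, b)


class TestResample:
    def test_midpoint_assignment(self):
        chroms = ChromSizes({"chrT": 100_000})
        grid = WindowGrid(chroms, 250)
        rng = np.random.default_rng(0)
        track = SignalTrack(grid, rng.random(grid.n_windows))
        fine = resample_track(track, 10)
        starts, ends = fine.grid.window_bounds("chrT")
        mids = starts + (ends - starts) // 2
        expected = track.values[np.minimum(mids // 250, grid.n_windows - 1)]
        assert np.array_equal(fine.values, expected)
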