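"""Generator contracts: determinism, archetype ordering, decay expectations."""

import numpy as np
import pandas as pd
import pytest

from h3turnover.genome import ChromSizes, read_reads_bed, write_reads_bed
from h3turnover.signal import WindowGrid
from h3turnover.synthio import (
    ARCHETYPES, CapacityError, GeneratorParams, TruthTable,
    build_annotation, simulate_reads, expected_track, write_fixture,
    default_chroms,
)


class TestBuildAnnotation:
    def test_same_seed_identical_output(self):
        (a1, t1) = build_annotation(seed=42)
        (a2, t2) = build_annotation(seed=42)
        pd.testing.assert_frame_equal(t1.df, t2.df)
        pd.testing.assert_frame_equal(a1.transcripts, a2.transcripts)
        pd.testing.assert_frame_equal(a1.repeats.intervals, a2.repeats.intervals)

    def test_different_seeds_differ(self):
        t1 = build_annotation(seed=1)[1]
        t2 = build_annotation(seed=2)[1]
        assert not t1.df.equals(t2.df)

    def test_archetype_rate_ordering(self, annotation_truth):
        _, truth = annotation_truth
        means = truth.df.groupby("archetype")["true_lambda"].mean()
        assert means["ndr"] > means["distal_site"] > means["tss_flank"]
        assert means["tss_flank"] > means["gene_body"] > means["heterochromatin"]

    def test_loci_non_overlapping_within_chrom(self, annotation_truth):
        _, truth = annotation_truth
        for _, sub in truth.df.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].values[1:] >= sub["end"].values[:-1]).all()

    def test_loci_within_chromosome_bounds(self, annotation_truth):
        annotation, truth = annotation_truth
        for chrom, sub in truth.df.groupby("chrom"):
            assert (sub["start"] >= 0).all()
            assert (sub["end"] <= annotation.chroms[chrom]).all()

    def test_ndr_band_upstream_of_tss(self, annotation_truth):
        annotation, truth = annotation_truth
        ndr = truth.df[truth.df["archetype"] == "ndr"]
        tx = annotation.transcripts.set_index("chrom", drop=False)
        # each NDR occupies [TSS-100, TSS-50) in transcription coordinates
        for _, row in ndr.iterrows():
            near = annotation.transcripts[
                annotation.transcripts["chrom"] == row["chrom"]
            ]
            plus = near[(near["strand"] == "+") & (near["start"] == row["end"] + 50)]
            minus = near[(near["strand"] == "-") & (near["end"] == row["start"] - 50)]
            assert len(plus) + len(minus) == 1

    def test_zero_count_archetype_absent(self):
        params = GeneratorParams()
        params.counts = dict(params.counts, satellite_repeat=0)
        _, truth = build_annotation(params=params, seed=0)
        assert "satellite_repeat" not in set(truth.df["archetype"])

    def test_capacity_error(self):
        tiny = ChromSizes({"chrT": 10_000})
        with pytest.raises(CapacityError):
            build_annotation(tiny, GeneratorParams(), seed=0)

    def test_more_flanks_than_genes_rejected(self):
        params = GeneratorParams(n_genes=2)
        with pytest.raises(ValueError, match="genes"):
            build_annotation(params=params, seed=0)


class TestSimulateReads:
    def test_same_seed_identical_reads(self, annotation_truth):
        annotation, truth = annotation_truth
        r1 = simulate_reads(truth, annotation.chroms, seed=7)
        r2 = simulate_reads(truth, annotation.chroms, seed=7)
        for key in r1.chip:
            pd.testing.assert_frame_equal(r1.chip[key], r2.chip[key])
        pd.testing.assert_frame_equal(r1.input[0], r2.input[0])

    def test_replicates_use_distinct_subseeds(self, annotation_truth):
        annotation, truth = annotation_truth
        r = simulate_reads(truth, annotation.chroms, seed=7, n_replicates=2)
        assert not r.chip[(0.0, 0)].equals(r.chip[(0.0, 1)])

    def test_negative_timepoint_rejected(self, annotation_truth):
        annotation, truth = annotation_truth
        with pytest.raises(ValueError):
            simulate_reads(truth, annotation.chroms, timepoints=(-1, 6))
        with pytest.raises(ValueError):
            simulate_reads(truth, annotation.chroms, depth=0)

    def _one_locus_truth(self, lam, occupancy=100.0):
        df = pd.DataFrame({
            "chrom": ["chrT"], "start": [40_000], "end": [40_200],
            "archetype": ["distal_site"], "occupancy0": [occupancy],
            "true_lambda": [lam],
        })
        return TruthTable(df), ChromSizes({"chrT": 100_000})

    def test_halving_rate_reaches_half_counts(self):
        # lambda = ln2/6: mean N(6)/N(0) converges to 0.5 over 200 replicates
        truth, chroms = self._one_locus_truth(np.log(2) / 6)
        reads = simulate_reads(truth, chroms, seed=1, n_replicates=200,
                               input_rate=0.0)
        n0 = np.mean([len(reads.chip[(0.0, r)]) for r in range(200)])
        n6 = np.mean([len(reads.chip[(6.0, r)]) for r in range(200)])
        assert n6 / n0 == pytest.approx(0.5, rel=0.05)

    def test_zero_rate_counts_stable(self):
        truth, chroms = self._one_locus_truth(0.0)
        reads = simulate_reads(truth, chroms, seed=2, n_replicates=200,
                               input_rate=0.0)
        n0 = np.mean([len(reads.chip[(0.0, r)]) for r in range(200)])
        n6 = np.mean([len(reads.chip[(6.0, r)]) for r in range(200)])
        assert n6 / n0 == pytest.approx(1.0, rel=0.05)

    def test_depth_scales_counts_linearly(self):
        truth, chroms = self._one_locus_truth(0.1)
        r1 = simulate_reads(truth, chroms, seed=3, n_replicates=100, input_rate=0)
        r2 = simulate_reads(truth, chroms, depth=2.0, seed=3, n_replicates=100,
                            input_rate=0)
        n1 = np.mean([len(r1.chip[(0.0, r)]) for r in range(100)])
        n2 = np.mean([len(r2.chip[(0.0, r)]) for r in range(100)])
        assert n2 / n1 == pytest.approx(2.0, rel=0.05)

    def test_dyads_recovered_inside_locus(self):
        # extended-read dyads must fall within the generating locus
        from h3turnover.signal import _dyads_vector

        truth, chroms = self._one_locus_truth(0.0)
        reads = simulate_reads(truth, chroms, seed=4, input_rate=0.0)
        lib = reads.library(0)
        dyads = _dyads_vector(lib["five_prime"].to_numpy(np.int64),
                              lib["strand"].to_numpy(), 100_000, 150)
        assert (dyads >= 40_000).all() and (dyads < 40_200).all()


class TestExpectedTrack:
    def test_mass_conserved_and_decay_law(self, annotation_truth):
        annotation, truth = annotation_truth
        grid = WindowGrid(annotation.chroms, 250)
        t0 = expected_track(truth, grid, 0)
        t6 = expected_track(truth, grid, 6)
        assert t0.values.sum() == pytest.approx(truth.expected_counts(0).sum())
        assert t6.values.sum() == pytest.approx(truth.expected_counts(6).sum())
        # every truth row obeys N(t) = occupancy0 * e^(-lambda t)
        expect = truth.df["occupancy0"] * np.exp(-6 * truth.df["true_lambda"])
        assert np.allclose(truth.expected_counts(6), expect)


class TestFixtureIO:
    def test_round_trip_read_multiset(self, tmp_path, annotation_truth):
        annotation, truth = annotation_truth
        reads = simulate_reads(truth, annotation.chroms, seed=5)
        write_fixture(tmp_path, annotation, truth, reads,
                      params=GeneratorParams(), seed=5)
        back = read_reads_bed(tmp_path / "reads_t0h_rep0.bed")
        orig = reads.library(0)
        key = ["chrom", "five_prime", "strand"]
        pd.testing.assert_frame_equal(
            back.sort_values(key).reset_index(drop=True)[key],
            orig.sort_values(key).reset_index(drop=True)[key],
        )

    def test_truth_table_schema_on_disk(self, tmp_path, annotation_truth):
        annotation, truth = annotation_truth
        reads = simulate_reads(truth, annotation.chroms, seed=5)
        write_fixture(tmp_path, annotation, truth, reads)
        loaded = TruthTable.read(tmp_path / "truth.tsv")
        assert "true_lambda" in loaded.df.columns
        assert len(loaded) == len(truth)

    def test_empty_read_collection_valid_bed(self, tmp_path):
        empty = pd.DataFrame(columns=["chrom", "five_prime", "strand"])
        path = tmp_path / "empty.bed"
        write_reads_bed(empty, path)
        assert len(read_reads_bed(path)) == 0
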