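"""Annotation parsing, overlap exclusion, binning and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rifdecay as rd
from rifdecay import preprocess
from rifdecay.synthetic_data import write_annotation_bed12, write_annotation_gff3

from conftest import make_units


class TestAnnotation:
    def test_gff3_two_units(self, tmp_path):
        units = make_units([("a", 0, 900), ("b", 2000, 3500, "-")])
        path = tmp_path / "ann.gff3"
        write_annotation_gff3(units, path)
        loaded = preprocess.load_annotation(path)
        assert len(loaded) == 2
        pd.testing.assert_frame_equal(loaded, units)

    def test_bed12_matches_gff3(self, tmp_path):
        units = make_units([("a", 10, 910), ("b", 2000, 3500, "-"),
                            ("c", 5000, 5600)])
        write_annotation_gff3(units, tmp_path / "ann.gff3")
        write_annotation_bed12(units, tmp_path / "ann.bed")
        g = preprocess.load_annotation(tmp_path / "ann.gff3")
        b = preprocess.load_annotation(tmp_path / "ann.bed")
        pd.testing.assert_frame_equal(g, b)

    def test_minus_strand_five_prime_is_genomic_right(self):
        # one read at the genomic right edge of a minus-strand unit must land
        # in the 5'-most bin
        unit = make_units([("m", 1000, 1600, "-")]).iloc[0]
        r0, r1 = preprocess._to_relative(unit, np.array([1599]),
                                         np.array([1600]))
        assert (r0[0], r1[0]) == (0, 1)
        binned = preprocess.bin_intervals(r0, r1, np.array([7.0]), 600, 300)
        assert binned.tolist() == [7.0, 0.0]

    def test_malformed_records_rejected(self, tmp_path):
        bad = tmp_path / "bad.gff3"
        bad.write_text("##gff-version 3\nchr\tsrc\tgene\t1\t100\t.\t+\n")
        with pytest.raises(ValueError, match="malformed"):
            preprocess.load_annotation(bad)
        zero = tmp_path / "zero.bed"
        zero.write_text("chr\t100\t100\tz\t0\t+\n")
        with pytest.raises(ValueError, match="zero-length|inverted"):
            preprocess.load_annotation(zero)


class TestOverlapExclusion:
    def test_disjoint_pair_kept(self):
        units = make_units([("a", 0, 100), ("b", 100, 200)])
        assert len(preprocess.exclude_overlapping(units)) == 2

    def test_nested_pair_both_removed(self):
        units = make_units([("outer", 0, 1000), ("inner", 100, 200)])
        assert len(preprocess.exclude_overlapping(units)) == 0

    def test_three_units_one_overlapping_pair(self):
        # brute-force check: only the unit not intersecting anything survives
        units = make_units([("a", 0, 150), ("b", 100, 300), ("c", 500, 700)])
        kept = preprocess.exclude_overlapping(units)
        assert kept["transcript_id"].tolist() == ["c"]

    def test_strand_blind_by_default_with_flag(self):
        units = make_units([("p", 0, 300, "+"), ("m", 100, 400, "-")])
        assert len(preprocess.exclude_overlapping(units)) == 0
        assert len(preprocess.exclude_overlapping(
            units, same_strand_only=True)) == 2

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 30)),
                    min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, spans):
        units = make_units([(f"u{i}", s, s + w) for i, (s, w) in
                            enumerate(spans)])
        kept = set(preprocess.exclude_overlapping(units)["transcript_id"])
        expect = set()
        for i, (s1, w1) in enumerate(spans):
            if all(i == j or min(s1 + w1, s2 + w2) <= max(s1, s2)
                   for j, (s2, w2) in enumerate(spans)):
                expect.add(f"u{i}")
        assert kept == expect


class TestBinning:
    def test_1200nt_gives_exactly_four_bins(self):
        out = preprocess.bin_counts(np.arange(1200), np.ones(1200), 1200)
        assert len(out) == 4

    def test_trailing_partial_bin_dropped(self):
        out = preprocess.bin_counts(np.arange(899), np.ones(899), 899)
        assert len(out) == 2
        assert out.tolist() == [300.0, 300.0]  # positions 600-898 discarded

    def test_uniform_coverage_sums_to_300c(self):
        c = 7.5
        out = preprocess.bin_counts(np.arange(1500), np.full(1500, c), 1500)
        assert np.allclose(out, 300 * c)

    def test_bins_are_zero_based_half_open(self):
        # a single count at position 299 belongs to bin 0; at 300, to bin 1
        a = preprocess.bin_counts(np.array([299]), np.array([1.0]), 600)
        b = preprocess.bin_counts(np.array([300]), np.array([1.0]), 600)
        assert a.tolist() == [1.0, 0.0]
        assert b.tolist() == [0.0, 1.0]


class TestSpikeNormalization:
    @staticmethod
    def spikes(totals_by_time):
        rows = []
        for t, totals in totals_by_time.items():
            for name, reads in zip(("ssrA", "ssrS", "rnpB"), totals):
                rows.append({"name": name, "time_min": t, "reads": reads})
        return pd.DataFrame(rows)

    def test_constant_spikes_are_identity(self):
        sp = self.spikes({0.0: (100, 100, 100), 2.0: (100, 100, 100)})
        counts = np.array([[300.0, 150.0]])
        out = preprocess.spike_normalize(counts, sp, [0.0, 2.0])
        np.testing.assert_allclose(out, counts)

    def test_halved_spikes_double_counts(self):
        sp = self.spikes({0.0: (100, 100, 100), 2.0: (50, 50, 50)})
        out = preprocess.spike_normalize(np.array([[300.0, 150.0]]), sp,
                                         [0.0, 2.0])
        np.testing.assert_allclose(out, [[300.0, 300.0]])

    def test_factor_is_mean_over_species(self):
        # totals 60/90/150 average to 100
        sp = self.spikes({0.0: (100, 100, 100), 2.0: (60, 90, 150)})
        factors = preprocess.spike_scale_factors(sp, [0.0, 2.0])
        np.testing.assert_allclose(factors, [1.0, 1.0])
        sp2 = self.spikes({0.0: (100, 100, 100), 2.0: (30, 45, 75)})
        np.testing.assert_allclose(
            preprocess.spike_scale_factors(sp2, [0.0, 2.0]), [1.0, 0.5])

    def test_zero_spike_total_is_hard_error(self):
        sp = self.spikes({0.0: (100, 100, 100), 2.0: (0, 90, 150)})
        with pytest.raises(ValueError, match="zero total"):
            preprocess.spike_normalize(np.ones((1, 2)), sp, [0.0, 2.0])

    def test_missing_time_point_is_error(self):
        sp = self.spikes({0.0: (100, 100, 100)})
        with pytest.raises(ValueError, match="lacks time"):
            preprocess.spike_normalize(np.ones((1, 2)), sp, [0.0, 2.0])


class TestRelativeAbundance:
    def test_constant_series_normalizes_to_one(self):
        raw = np.array([[100.0, 100.0, 100.0]])
        m = preprocess.relative_abundance("t", [0], raw, raw, [0, 1, 2])
        np.testing.assert_allclose(m.normalized, 1.0)
        assert np.all(m.sigma > 0)

    def test_halving_series(self):
        raw = np.array([[100.0, 50.0, 25.0]])
        m = preprocess.relative_abundance("t", [0], raw, raw, [0, 1, 2])
        np.testing.assert_allclose(m.normalized, [[1.0, 0.5, 0.25]])

    def test_low_t0_bins_dropped(self):
        raw = np.array([[100.0, 50.0, 25.0], [10.0, 5.0, 2.0]])
        m = preprocess.relative_abundance("t", [0, 300], raw, raw, [0, 1, 2],
                                          min_t0_count=20)
        assert m.bin_starts.tolist() == [0]
        assert m.normalized.shape == (1, 3)

    def test_normalization_order_equals_joint_closed_form(self):
        # spike scaling then t=0 division == n_bt * f_0 / (f_t * n_b0)
        rng = np.random.default_rng(0)
        raw = rng.integers(50, 500, size=(4, 5)).astype(float)
        sp = TestSpikeNormalization.spikes(
            {t: tuple(rng.integers(50, 150, 3)) for t in range(5)})
        grid = list(range(5))
        factors = preprocess.spike_scale_factors(sp, grid)
        scaled = preprocess.spike_normalize(raw, sp, grid)
        m = preprocess.relative_abundance("t", [0, 300, 600, 900], raw,
                                          scaled, grid, min_t0_count=0)
        joint = raw / factors[None, :] / (raw[:, [0]] / factors[0])
        np.testing.assert_allclose(m.normalized, joint, rtol=1e-12)

    def test_noiseless_pipeline_is_identity_on_model_surface(self, kin):
        ds = rd.simulate_expected([kin], rd.ExperimentConfig(rng_seed=0))
        m = rd.matrices_from_dataset(ds)[kin.transcript_id]
        np.testing.assert_allclose(m.normalized,
                                   ds.expected_rel[kin.transcript_id],
                                   atol=1e-14)
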