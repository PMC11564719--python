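"""Tests for statistical moments, LBP baseline and the multilevel extractor."""

import numpy as np
import pytest

from bwhpat.features import (N_TOTAL_FEATURES, build_feature_matrix,
                             extract_input_features, extract_segment_features,
                             feature_names, lbp_features, statistical_features)
from bwhpat.tqwt import tqwt_decompose

IDX = {name: i for i, name in enumerate(
    ("tsallis", "shannon", "renyi", "sure", "log_energy", "energy", "higuchi",
     "std", "var", "range", "mean", "median", "min", "max"))}


class TestStatisticalFeatures:
    def test_output_length(self, rng):
        assert statistical_features(rng.standard_normal(100)).size == 14

    def test_constant_signal_moments(self):
        f = statistical_features(np.full(50, 3.0))
        assert f[IDX["std"]] == 0 and f[IDX["var"]] == 0
        assert f[IDX["range"]] == 0
        for k in ("mean", "median", "min", "max"):
            assert f[IDX[k]] == 3.0

    def test_energy_of_123(self):
        f = statistical_features(np.array([1.0, 2.0, 3.0]))
        assert f[IDX["energy"]] == 14.0          # sum of squares

    def test_all_finite_on_zero_signal(self):
        f = statistical_features(np.zeros(64))
        assert np.all(np.isfinite(f))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            statistical_features(np.array([1.0]))

    def test_shift_behavior(self, rng):
        x = rng.standard_normal(200)
        f0 = statistical_features(x)
        f1 = statistical_features(x + 5.0)
        for k in ("mean", "median", "min", "max"):     # shift-equivariant
            assert f1[IDX[k]] == pytest.approx(f0[IDX[k]] + 5.0)
        for k in ("std", "var", "range"):              # shift-invariant
            assert f1[IDX[k]] == pytest.approx(f0[IDX[k]])

    def test_shannon_entropy_oracle(self, rng):
        x = rng.standard_normal(64)
        p = x**2 / np.sum(x**2)
        expected = -np.sum(p * np.log(p))
        assert statistical_features(x)[IDX["shannon"]] == pytest.approx(expected)

    def test_higuchi_of_noise_near_two(self, rng):
        # white noise has a Higuchi dimension close to 2
        f = statistical_features(rng.standard_normal(5000))
        assert 1.7 < f[IDX["higuchi"]] <= 2.1


class TestLbp:
    def test_constant_signal(self):
        hist = lbp_features(np.full(100, 2.0))
        assert hist[255] == 92 and hist.sum() == 92    # lng - 8 windows

    def test_strictly_increasing_series(self):
        # left neighbors below the center (bits 0), right above (bits 1)
        hist = lbp_features(np.arange(50.0))
        assert hist[0b00001111] == 42 and hist.sum() == 42

    def test_histogram_mass(self, rng):
        x = rng.standard_normal(400)
        assert lbp_features(x).sum() == 392

    def test_short_signal_warns(self):
        with pytest.warns(UserWarning):
            hist = lbp_features(np.zeros(5))
        assert hist.sum() == 0


class TestMultilevelExtraction:
    def test_input_feature_layout(self, rng):
        x = rng.standard_normal(300)
        f = extract_input_features(x)
        assert f.size == 270
        assert np.array_equal(f[256:], statistical_features(x))

    def test_constant_series_single_bin(self):
        f = extract_input_features(np.full(150, 1.0))
        assert np.count_nonzero(f[:256]) == 1

    def test_segment_features_shape_and_order(self, rng):
        x = rng.standard_normal(2000)
        fv = extract_segment_features(x)
        assert len(fv.f) == 11                      # raw + 10 subbands
        assert fv.X.size == N_TOTAL_FEATURES == 2970
        assert np.array_equal(fv.X[:270], extract_input_features(x))
        assert fv.provenance[0] == "raw"

    def test_zero_signal_subband_histograms(self):
        x = np.zeros(2000)
        fv = extract_segment_features(x)
        lengths = [2000] + [w.size for w in tqwt_decompose(x).bands]
        for vec, n in zip(fv.f, lengths):
            if n >= 69:                             # constant input -> bin 255
                assert vec[255] == n - 68
                assert vec[:255].sum() == 0

    def test_feature_matrix_shape(self, rng):
        segs = [rng.standard_normal(600) for _ in range(10)]
        labels = np.tile([1, 2], 5)
        fm = build_feature_matrix(segs, labels)
        assert fm.X.shape == (10, 2970)
        assert len(fm.columns) == 2970

    def test_row_independence_under_permutation(self, rng):
        segs = [rng.standard_normal(600) for _ in range(4)]
        labels = np.array([1, 2, 1, 2])
        fm = build_feature_matrix(segs, labels)
        perm = [2, 0, 3, 1]
        fm_p = build_feature_matrix([segs[i] for i in perm], labels[perm])
        assert np.array_equal(fm_p.X, fm.X[perm])

    def test_empty_and_mismatched_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            build_feature_matrix([], np.array([]))
        with pytest.raises(ValueError):
            build_feature_matrix([rng.standard_normal(600)], np.array([1, 2]))

    def test_feature_names_provenance(self):
        names = feature_names()
        assert len(names) == 2970
        assert names[0] == "raw_bwh_bin000"
        assert names[269] == "raw_stat_max"
        assert names[270] == "band01_bwh_bin000"
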