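import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chanwise import (
    EmotionLabel,
    RawRecording,
    WindowingParams,
    channel_wise_feature,
    extract_window,
    feature_sequence,
    flatten_upper_triangle,
    make_training_examples,
    n_pairs,
    single_channel_features,
    unflatten_upper_triangle,
)
from chanwise.features import SingleChannelFeatures, _pearson_matrix

from conftest import brute_force_pearson


class TestWindowingParams:
    def test_window_arithmetic(self):
        p = WindowingParams(2, 8, 10)
        assert p.window_samples == 160
        assert p.stride_samples == 16

    def test_duration_at_128hz(self):
        assert WindowingParams(2, 8, 10).window_seconds(128.0) == pytest.approx(1.25)

    def test_duration_at_200hz(self):
        assert WindowingParams(2, 8, 10).window_seconds(200.0) == pytest.approx(0.8)

    @pytest.mark.parametrize("kwargs", [{"L": 0}, {"K": 1}, {"N": 0}])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            WindowingParams(**{"L": 2, "K": 8, "N": 10, **kwargs})


class TestExtractWindow:
    def test_shape_and_sample_consumption(self, rng, params):
        rec = RawRecording(data=rng.standard_normal((4, 160)), rate=128.0)
        E = extract_window(rec, 0, params)
        assert E.values.shape == (4, 2, 8, 10)
        # flattened back in (n, k, l) order it must reproduce samples [0, 160)
        back = E.values.transpose(0, 3, 2, 1).reshape(4, 160)
        np.testing.assert_array_equal(back, rec.data)

    def test_indexing_convention(self, rng):
        # E[c, l, k, n] == data[c, start + ((n*K)+k)*L + l]
        params = WindowingParams(3, 4, 5)
        rec = RawRecording(data=rng.standard_normal((2, 200)), rate=1.0)
        E = extract_window(rec, 17, params)
        for c, l, k, n in [(0, 0, 0, 0), (1, 2, 3, 4), (0, 1, 2, 3)]:
            assert E.values[c, l, k, n] == rec.data[c, 17 + ((n * 4) + k) * 3 + l]

    def test_window_exceeds_recording(self, rng, params):
        rec = RawRecording(data=rng.standard_normal((2, 160)), rate=1.0)
        with pytest.raises(ValueError, match="exceeds"):
            extract_window(rec, 1, params)

    def test_metadata_carried(self, recording, params):
        E = extract_window(recording, 16, params)
        assert E.subject_id == "s00"
        assert E.start_sample == 16


class TestSingleChannelFeatures:
    def test_known_mean(self, params):
        data = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (2, 40))
        rec = RawRecording(data=data, rate=1.0)
        S = single_channel_features(extract_window(rec, 0, WindowingParams(4, 8, 5)))
        np.testing.assert_allclose(S.values, 2.5)

    def test_constant_segment(self):
        rec = RawRecording(data=np.full((2, 160), 7.0), rate=1.0)
        S = single_channel_features(extract_window(rec, 0, WindowingParams(2, 8, 10)))
        np.testing.assert_array_equal(S.values, 7.0)

    def test_matches_sum_oracle(self, rng, params):
        rec = RawRecording(data=rng.standard_normal((3, 160)), rate=1.0)
        E = extract_window(rec, 0, params)
        S = single_channel_features(E)
        for c in range(3):
            for k in range(8):
                for n in range(10):
                    expected = sum(E.values[c, :, k, n]) / 2
                    assert S.values[c, k, n] == pytest.approx(expected, abs=1e-15)


class TestChannelWiseFeature:
    def _from_matrix(self, X):
        X = np.asarray(X, dtype=float)
        C, K = X.shape
        return SingleChannelFeatures(
            values=X[:, :, None], params=WindowingParams(2, K, 1)
        )

    def test_perfect_positive(self):
        S = self._from_matrix([[1, 2, 3, 4], [1, 2, 3, 4]])
        F = channel_wise_feature(S, 0)
        assert F.matrix[0, 1] == pytest.approx(1.0)

    def test_perfect_negative(self):
        S = self._from_matrix([[1, 2, 3, 4], [-1, -2, -3, -4]])
        F = channel_wise_feature(S, 0)
        assert F.matrix[0, 1] == pytest.approx(-1.0)

    def test_frozen_oracle_value(self):
        # brute-force textbook Pearson of these two 8-vectors is 19/21
        S = self._from_matrix(
            [[1, 2, 3, 4, 5, 6, 7, 8], [2, 1, 4, 3, 6, 5, 8, 7]]
        )
        F = channel_wise_feature(S, 0)
        assert F.matrix[0, 1] == pytest.approx(19 / 21, abs=1e-12)
        assert F.matrix[0, 1] == pytest.approx(0.9047619047619048, abs=1e-12)

    def test_oracle_equivalence_random(self, rng):
        # acceptance-grade check: 100+ random small instances vs the
        # independent loop oracle
        for _ in range(120):
            C = int(rng.integers(2, 7))
            K = int(rng.integers(2, 11))
            X = rng.standard_normal((C, K))
            F = channel_wise_feature(
                SingleChannelFeatures(X[:, :, None], WindowingParams(2, K, 1)), 0
            )
            for x in range(C):
                for y in range(x + 1, C):
                    expected = brute_force_pearson(list(X[x]), list(X[y]))
                    assert F.matrix[x, y] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_convention(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            F = channel_wise_feature(
                self._from_matrix([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]), 0
            )
        assert F.matrix[0, 1] == 0.0
        assert F.matrix[0, 0] == 1.0
        assert F.matrix[1, 1] == 1.0

    def test_symmetric_unit_diag_bounded(self, rng):
        for _ in range(20):
            X = rng.standard_normal((5, 6))
            F = _pearson_matrix(X)
            np.testing.assert_array_equal(F, F.T)
            np.testing.assert_allclose(np.diag(F), 1.0)
            assert (np.abs(F) <= 1.0).all()

    def test_affine_invariance(self, rng):
        X = rng.standard_normal((4, 8))
        a = _pearson_matrix(X)
        scaled = X * np.array([2.0, 0.5, 3.0, 1.5])[:, None] + np.array(
            [1.0, -2.0, 0.0, 5.0]
        )[:, None]
        b = _pearson_matrix(scaled)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_negation_flips_row(self, rng):
        X = rng.standard_normal((4, 8))
        a = _pearson_matrix(X)
        X2 = X.copy()
        X2[1] *= -1
        b = _pearson_matrix(X2)
        np.testing.assert_allclose(b[1, [0, 2, 3]], -a[1, [0, 2, 3]], atol=1e-12)
        assert b[1, 1] == 1.0

    def test_population_vs_sample_normalization_identical(self, rng):
        # r is invariant to the 1/K vs 1/(K-1) convention: it cancels
        X = rng.standard_normal((2, 7))
        r = _pearson_matrix(X)[0, 1]
        cov_pop = np.mean((X[0] - X[0].mean()) * (X[1] - X[1].mean()))
        r_pop = cov_pop / (X[0].std() * X[1].std())
        cov_smp = cov_pop * 7 / 6
        r_smp = cov_smp / (X[0].std(ddof=1) * X[1].std(ddof=1))
        assert r == pytest.approx(r_pop, abs=1e-12)
        assert r == pytest.approx(r_smp, abs=1e-12)

    def test_time_index_bounds(self, rng):
        S = SingleChannelFeatures(rng.standard_normal((3, 8, 2)), WindowingParams(2, 8, 2))
        with pytest.raises(IndexError):
            channel_wise_feature(S, 2)


class TestFlattening:
    @pytest.mark.parametrize("C,expected", [(32, 496), (62, 1891), (2, 1)])
    def test_lengths(self, C, expected):
        assert n_pairs(C) == expected
        m = np.eye(C)
        assert flatten_upper_triangle(m).shape == (expected,)

    def test_two_channel_single_pair(self):
        m = np.array([[1.0, 0.3], [0.3, 1.0]])
        np.testing.assert_array_equal(flatten_upper_triangle(m), [0.3])

    def test_row_major_order(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.1
        m[0, 2] = m[2, 0] = 0.2
        m[1, 2] = m[2, 1] = 0.3
        np.testing.assert_array_equal(flatten_upper_triangle(m), [0.1, 0.2, 0.3])

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            flatten_upper_triangle(np.zeros((3, 4)))

    def test_unflatten_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            unflatten_upper_triangle(np.zeros(4), 3)

    def test_unflatten_smallest(self):
        F = unflatten_upper_triangle(np.array([0.1, 0.2, 0.3]), 3)
        assert F.matrix.shape == (3, 3)
        np.testing.assert_array_equal(F.matrix, F.matrix.T)
        np.testing.assert_allclose(np.diag(F.matrix), 1.0)

    @given(st.integers(min_value=2, max_value=12), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_exact(self, C, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(-1, 1, size=n_pairs(C))
        F = unflatten_upper_triangle(v, C)
        np.testing.assert_array_equal(flatten_upper_triangle(F), v)


class TestFeatureSequence:
    def test_shapes_c32(self, rng):
        rec = RawRecording(data=rng.standard_normal((32, 160)), rate=128.0)
        seq = feature_sequence(extract_window(rec, 0, WindowingParams(2, 8, 10)))
        assert seq.vectors.shape == (10, 496)

    def test_degenerate_n1(self, rng):
        rec = RawRecording(data=rng.standard_normal((4, 16)), rate=1.0)
        seq = feature_sequence(extract_window(rec, 0, WindowingParams(2, 8, 1)))
        assert seq.vectors.shape == (1, 6)

    def test_channel_permutation_equivariance(self, rng):
        params = WindowingParams(2, 8, 3)
        data = rng.standard_normal((5, 48))
        perm = np.array([3, 0, 4, 1, 2])
        seq = feature_sequence(
            extract_window(RawRecording(data=data, rate=1.0), 0, params)
        )
        seq_p = feature_sequence(
            extract_window(RawRecording(data=data[perm], rate=1.0), 0, params)
        )
        # permuted vectors must equal a fixed permutation of the originals,
        # derived from the flattened index map
        for n in range(3):
            M = unflatten_upper_triangle(seq.vectors[n], 5).matrix
            Mp = unflatten_upper_triangle(seq_p.vectors[n], 5).matrix
            np.testing.assert_allclose(Mp, M[np.ix_(perm, perm)], atol=1e-12)


class TestMakeTrainingExamples:
    LABEL = EmotionLabel("valence2", 1)

    def test_window_count_oracle(self, rng, params):
        rec = RawRecording(data=rng.standard_normal((3, 1600)), rate=128.0)
        examples = make_training_examples(rec, params, self.LABEL)
        # explicit loop oracle over start samples
        starts = []
        s = 0
        while s + 160 <= 1600:
            starts.append(s)
            s += 16
        assert len(starts) == 91
        assert len(examples) == len(starts)

    def test_count_formula(self, rng, params):
        for M in (160, 161, 175, 176, 320, 1600):
            rec = RawRecording(data=rng.standard_normal((2, M)), rate=1.0)
            expected = (M - 160) // 16 + 1
            assert len(make_training_examples(rec, params, self.LABEL)) == expected

    def test_exact_fit_single_window(self, rng, params):
        rec = RawRecording(data=rng.standard_normal((2, 160)), rate=1.0)
        assert len(make_training_examples(rec, params, self.LABEL)) == 1

    def test_too_short_errors(self, rng, params):
        rec = RawRecording(data=rng.standard_normal((2, 159)), rate=1.0)
        with pytest.raises(ValueError, match="shorter"):
            make_training_examples(rec, params, self.LABEL)

    def test_adjacent_windows_share_n_minus_1_features(self, rng, params):
        rec = RawRecording(data=rng.standard_normal((4, 400)), rate=1.0)
        examples = make_training_examples(rec, params, self.LABEL)
        for a, b in zip(examples, examples[1:]):
            np.testing.assert_allclose(
                b.sequence.vectors[:-1], a.sequence.vectors[1:], atol=1e-12
            )

    def test_label_inherited(self, rng, params):
        rec = RawRecording(data=rng.standard_normal((2, 320)), rate=1.0)
        for ex in make_training_examples(rec, params, self.LABEL):
            assert ex.label == self.LABEL
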