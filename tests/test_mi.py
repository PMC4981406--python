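"""Unit and property tests for the MI estimators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import evokedmi as em
from oracles import brute_knn_mi_bits

LN2 = np.log(2.0)


# -- neighbour estimator ----------------------------------------------


class TestKnn:
    def test_single_class_is_exactly_zero(self):
        """One stimulus class carries no information: psi terms cancel."""
        data = em.SampleSet([1] * 6, [0.0, 0.3, 0.9, 2.0, 3.3, 5.1])
        assert em.knn_mi(data, k=3).value_bits == 0.0

    def test_hand_worked_two_class_example(self):
        """Two well-separated triplets, k=1: every contribution is psi(6)-psi(3)."""
        data = em.SampleSet([1, 1, 1, 2, 2, 2], [0.0, 0.1, 0.25, 10.0, 10.1, 10.25])
        est = em.knn_mi(data, k=1)
        assert est.value_bits == pytest.approx(47 / 60 / LN2, abs=1e-12)
        assert np.all(est.diagnostics.m_i == 1)

    def test_estimate_metadata(self):
        data = em.SampleSet([1, 1, 2, 2], [0.0, 1.0, 2.0, 3.0])
        est = em.knn_mi(data, k=1)
        assert est.estimator == "knn"
        assert est.params == {"k": 1}
        assert est.n_samples == 4
        assert not est.clamped

    def test_k_reduced_in_small_classes(self):
        """k_i = min(k, N_Si - 1) keeps unbalanced designs estimable."""
        data = em.SampleSet([1, 1, 2, 2, 2, 2, 2], [0.0, 0.7, 3.0, 3.2, 3.9, 4.4, 5.0])
        est = em.knn_mi(data, k=3)
        diag = est.diagnostics
        assert set(diag.k_i[diag.n_si == 2]) == {1}
        assert set(diag.k_i[diag.n_si == 5]) == {3}

    def test_singleton_classes_skipped_with_warning(self):
        data = em.SampleSet([1, 1, 1, 2], [0.0, 0.5, 1.5, 9.0])
        with pytest.warns(UserWarning, match="skipped 1"):
            est = em.knn_mi(data, k=1)
        assert est.diagnostics.skipped_points == 1
        assert len(est.diagnostics.i_i) == 3

    def test_all_singleton_classes_error(self):
        data = em.SampleSet([1, 2, 3], [0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="no estimable points"):
            em.knn_mi(data, k=1)

    def test_nonfinite_response_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            em.SampleSet([1, 1], [0.0, np.inf])

    def test_diagnostics_invariants(self, rng):
        data = em.SampleSet(rng.integers(0, 3, 60), rng.normal(size=60))
        diag = em.knn_mi(data, k=3).diagnostics
        assert np.all(diag.m_i >= diag.k_i)
        assert np.all(diag.n_si >= 2)
        assert np.all(np.isfinite(diag.i_i))

    @given(
        a=st.floats(min_value=0.01, max_value=100).filter(lambda v: v != 0),
        b=st.floats(min_value=-50, max_value=50),
        flip=st.booleans(),
    )
    def test_affine_invariance(self, a, b, flip):
        """r -> a*r + b (a != 0) preserves neighbour sets, hence the estimate."""
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 3, 40)
        r = rng.normal(size=40)
        scale = -a if flip else a
        base = em.knn_mi(em.SampleSet(labels, r), k=3).value_bits
        mapped = em.knn_mi(em.SampleSet(labels, scale * r + b), k=3).value_bits
        assert mapped == pytest.approx(base, abs=1e-9)

    def test_shuffled_labels_raw_mean_near_zero(self):
        """Destroying the label-response link should give a ~0 raw estimate."""
        rng = np.random.default_rng(11)
        r = rng.normal(size=200)
        vals = []
        for _ in range(50):
            labels = rng.permutation(np.repeat(np.arange(4), 50))
            vals.append(em.knn_mi(em.SampleSet(labels, r), k=3).value_bits)
        assert abs(np.mean(vals)) < 0.02

    def test_matches_bruteforce_on_random_instances(self, rng):
        """Fast path == O(N^2) definition scan, including tie-prone data."""
        for _ in range(50):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, int(rng.integers(1, 5)), n)
            r = np.round(rng.normal(size=n), int(rng.integers(0, 4)))
            k = int(rng.integers(1, 5))
            try:
                fast = em.knn_mi(em.SampleSet(labels, r), k=k).value_bits
            except ValueError:
                with pytest.raises(ValueError):
                    brute_knn_mi_bits(labels, r, k)
                continue
            assert fast == pytest.approx(brute_knn_mi_bits(labels, r, k), abs=1e-12)


# -- binned plugin estimator ------------------------------------------


class TestBinned:
    @pytest.mark.parametrize(
        "labels, responses, n_bins, expected",
        [
            # perfectly correlated binary case
            ([1, 1, 2, 2], [0.0, 0.0, 1.0, 1.0], 2, 1.0),
            # a single bin carries no information
            ([1, 1, 2, 2], [0.0, 0.3, 1.0, 2.0], 1, 0.0),
            # hand-computed contingency table {(3,0),(1,2)}
            ([1, 1, 1, 2, 2, 2], [0.0, 0.1, 0.2, 0.15, 0.8, 0.9], 2, 0.45915),
        ],
    )
    def test_worked_examples(self, labels, responses, n_bins, expected):
        est = em.binned_mi_naive(em.SampleSet(labels, responses), n_bins)
        assert est.value_bits == pytest.approx(expected, abs=5e-6)

    def test_invalid_bin_count(self):
        with pytest.raises(ValueError):
            em.binned_mi_naive(em.SampleSet([1, 2], [0.0, 1.0]), 0)

    def test_identical_responses_collapse_to_one_bin(self):
        est = em.binned_mi_naive(em.SampleSet([1, 2, 1, 2], [5.0] * 4), 10)
        assert est.value_bits == 0.0

    @given(st.integers(min_value=1, max_value=40), st.integers(min_value=0, max_value=10_000))
    def test_bounds(self, n_bins, seed):
        """0 <= I_hat <= min(log2 bins, log2 alphabet)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 80))
        n_lab = int(rng.integers(1, 6))
        data = em.SampleSet(rng.integers(0, n_lab, n), rng.normal(size=n))
        v = em.binned_mi_naive(data, n_bins).value_bits
        assert -1e-12 <= v <= min(np.log2(n_bins), np.log2(len(data.alphabet))) + 1e-9

    def test_positive_scale_invariance(self, rng):
        labels = rng.integers(0, 3, 100)
        r = rng.normal(size=100)
        v1 = em.binned_mi_naive(em.SampleSet(labels, r), 13).value_bits
        v2 = em.binned_mi_naive(em.SampleSet(labels, 3.5 * r + 2.0), 13).value_bits
        assert v2 == pytest.approx(v1, abs=1e-12)

    def test_small_sample_overshoot_with_many_bins(self):
        """Fine binning at N=400 inflates the estimate above the truth."""
        spec = em.gaussian_calibration_spec()
        truth = em.true_mi(spec)
        vals = [
            em.binned_mi_naive(em.sample_mixture(spec, 400, seed), 100).value_bits
            for seed in range(10)
        ]
        assert min(vals) > truth


# -- quadratic extrapolation ------------------------------------------


class TestQE:
    @pytest.mark.parametrize(
        "stub, expected",
        [
            # bias-free case: flat naive curve extrapolates to itself
            ([(400, 2.5), (200, 2.5), (100, 2.5)], (2.5, 0.0, 0.0)),
            # pure 1/N bias
            ([(400, 2.0), (200, 3.0), (100, 5.0)], (1.0, 400.0, 0.0)),
            # pure 1/N^2 bias
            ([(400, 1.5), (200, 4.5), (100, 16.5)], (0.5, 0.0, 160000.0)),
        ],
    )
    def test_stubbed_naive_curves(self, stub, expected):
        fit = em.qe_fit(stub)
        assert (fit.i_true, fit.a, fit.b) == pytest.approx(expected, abs=1e-7)

    @given(
        i0=st.floats(-2, 5),
        a=st.floats(-500, 500),
        b=st.floats(-1e5, 1e5),
    )
    def test_fit_passes_through_its_inputs(self, i0, a, b):
        """The 3x3 system is exactly determined, so the curve interpolates."""
        pts = [(n, i0 + a / n + b / n**2) for n in (400.0, 200.0, 100.0)]
        fit = em.qe_fit(pts)
        for n, y in pts:
            assert fit.predict(n) == pytest.approx(y, abs=1e-9)

    def test_identical_sample_sizes_singular(self):
        with pytest.raises(ValueError, match="singular"):
            em.qe_fit([(100, 1.0), (100, 2.0), (100, 3.0)])

    def test_correct_is_seed_deterministic(self):
        spec = em.gaussian_calibration_spec()
        data = em.sample_mixture(spec, 400, 0)
        v1 = em.qe_correct(data, 20, rng_seed=5)
        v2 = em.qe_correct(data, 20, rng_seed=5)
        assert v1.value_bits == v2.value_bits
        assert v1.diagnostics.inputs == v2.diagnostics.inputs

    def test_too_small_to_partition(self):
        data = em.SampleSet([1, 2, 1, 2, 1, 2, 1], np.arange(7.0))
        with pytest.raises(ValueError, match="partition"):
            em.qe_correct(data, 2, rng_seed=0)


# -- clamping ----------------------------------------------------------


@pytest.mark.parametrize(
    "value, expected",
    [(-0.013, 0.0), (0.0, 0.0), (0.16, 0.16)],
)
def test_clamp_negative_estimates_to_zero(value, expected):
    est = em.MIEstimate(value, "knn", {"k": 3}, 100)
    clamped = em.clamp_mi(est)
    assert clamped.value_bits == expected
    assert clamped.clamped
    assert not est.clamped  # original untouched
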