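"""Imaginary coherence and the connectivity feature pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from syncdecode._seeds import child_rng
from syncdecode.cohort import (
    CouplingSpec,
    GroundTruth,
    RoiLayout,
    simulate_cohort,
)
from syncdecode.connectivity import (
    connectivity_features,
    equalize_epochs,
    imcoh,
    load_features,
    save_features,
)
from syncdecode.spectral import FrequencyGrid, morlet_tfr


def brute_force_imcoh(Sx, Sy):
    """Loop implementation of the ImCoh definition, kept independent of the
    vectorized estimator."""
    K, F, T = Sx.shape
    out = np.empty((F, T))
    for f in range(F):
        for t in range(T):
            cross = 0j
            px = py = 0.0
            for k in range(K):
                cross += Sx[k, f, t] * np.conj(Sy[k, f, t])
                px += abs(Sx[k, f, t]) ** 2
                py += abs(Sy[k, f, t]) ** 2
            out[f, t] = (cross / K).imag / np.sqrt((px / K) * (py / K))
    return out


def random_coeffs(rng, K=8, F=2, T=5):
    return rng.standard_normal((K, F, T)) + 1j * rng.standard_normal((K, F, T))


class TestImcoh:
    def test_self_coherence_is_zero(self):
        S = random_coeffs(np.random.default_rng(0))
        np.testing.assert_allclose(imcoh(S, S), 0.0, atol=1e-12)

    def test_quarter_cycle_rotation_saturates(self):
        S = random_coeffs(np.random.default_rng(1))
        rot = S * np.exp(1j * np.pi / 2)
        # conjugation in the cross-spectrum puts the -pi/2 there: ImCoh = -1,
        # and the swapped order gives +1
        np.testing.assert_allclose(imcoh(S, rot), -1.0, atol=1e-12)
        np.testing.assert_allclose(imcoh(rot, S), 1.0, atol=1e-12)

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(2)
        Sx, Sy = random_coeffs(rng), random_coeffs(rng)
        np.testing.assert_array_equal(imcoh(Sx, Sy), -imcoh(Sy, Sx))

    def test_bounded_by_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            v = imcoh(random_coeffs(rng), random_coeffs(rng))
            assert np.all(np.abs(v) <= 1.0)

    def test_positive_gain_invariance_and_sign_flip(self):
        rng = np.random.default_rng(4)
        Sx, Sy = random_coeffs(rng), random_coeffs(rng)
        base = imcoh(Sx, Sy)
        np.testing.assert_allclose(imcoh(3.5 * Sx, 0.2 * Sy), base, rtol=1e-12)
        np.testing.assert_allclose(imcoh(-Sx, Sy), -base, rtol=1e-12)

    def test_matches_brute_force_on_lagged_driver(self):
        """K = 200 epochs sharing a driver at lag pi/4: the estimator must
        agree with a direct loop evaluation to 1e-10 and approximate
        coherence * sin(pi/4)."""
        rng = np.random.default_rng(5)
        K, F, T = 200, 2, 6
        driver = rng.standard_normal((K, F, T)) + 1j * rng.standard_normal((K, F, T))
        nx = rng.standard_normal((K, F, T)) + 1j * rng.standard_normal((K, F, T))
        ny = rng.standard_normal((K, F, T)) + 1j * rng.standard_normal((K, F, T))
        Sx = driver + 0.5 * nx
        Sy = driver * np.exp(-1j * np.pi / 4) + 0.5 * ny
        fast = imcoh(Sx, Sy)
        np.testing.assert_allclose(fast, brute_force_imcoh(Sx, Sy), atol=1e-10)
        # expectation: coh = 1/(1+0.25) for unit driver with 0.5-amplitude noise
        coh = 1.0 / 1.25
        assert np.mean(fast) == pytest.approx(coh * np.sin(np.pi / 4), abs=0.05)

    def test_undefined_coherence_errors(self):
        S = random_coeffs(np.random.default_rng(6))
        with pytest.raises(ValueError, match="2 epochs"):
            imcoh(S[:1], S[:1])
        with pytest.raises(ValueError, match="zero power"):
            imcoh(S, np.zeros_like(S))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounds_and_antisymmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        Sx, Sy = random_coeffs(rng, K=4), random_coeffs(rng, K=4)
        v = imcoh(Sx, Sy)
        assert np.all(np.abs(v) <= 1.0)
        np.testing.assert_array_equal(v, -imcoh(Sy, Sx))


class TestEqualizeEpochs:
    def _cohort_with_counts(self, counts):
        layout = RoiLayout.reduced(1, 1, 1)
        truth = GroundTruth(bands={"alpha": (8.0, 12.0)})
        base = simulate_cohort(layout, truth, n_subjects=1,
                               epochs_per_condition=max(counts),
                               epoch_length=0.5, sample_rate=250.0, seed=0)
        for c, k in enumerate(counts):
            base.epochs[(0, c)] = base.epochs[(0, c)][:k]
            base.impulse[(0, c)] = base.impulse[(0, c)][:k]
        return base

    def test_all_conditions_cut_to_minimum(self):
        cohort = self._cohort_with_counts([10, 8, 12, 9, 8, 11])
        eq = equalize_epochs(cohort, seed=1)
        assert all(eq.n_epochs(0, c) == 8 for c in range(6))

    def test_already_equal_unchanged(self, null_cohort):
        eq = equalize_epochs(null_cohort, seed=1)
        for key in null_cohort.epochs:
            np.testing.assert_array_equal(eq.epochs[key], null_cohort.epochs[key])

    def test_same_seed_same_selection(self):
        cohort = self._cohort_with_counts([10, 8, 12, 9, 8, 11])
        a = equalize_epochs(cohort, seed=2)
        b = equalize_epochs(cohort, seed=2)
        for key in a.epochs:
            np.testing.assert_array_equal(a.epochs[key], b.epochs[key])


class TestConnectivityFeatures:
    def test_feature_length_13_by_9(self):
        """A 13-sub-ROI seed paired with a 9-sub-ROI target yields 117
        features, seed-major."""
        layout = RoiLayout(
            rois=(("STC-rh", "rh", 13), ("IFG-rh", "rh", 9)), seed_rois=("STC-rh",)
        )
        truth = GroundTruth(bands={"high_gamma": (61.0, 120.0)})
        cohort = simulate_cohort(layout, truth, n_subjects=1,
                                 epochs_per_condition=8, epoch_length=1.5,
                                 sample_rate=250.0, seed=0)
        grid = FrequencyGrid.from_bands({"high_gamma": (61.0, 120.0)}, 2)
        feats = connectivity_features(
            cohort, grid, windows={"mid": (0.3, 1.2)}, seed=0
        )
        arr = feats.features[("STC-rh", "IFG-rh", "high_gamma", "mid")]
        assert arr.shape == (1, 6, 4, 117)
        assert np.all(np.abs(arr) <= 1.0)

    def test_band_window_average_matches_per_bin_oracle(self, null_cohort, two_band_grid):
        """One feature re-derived bin-by-bin from raw epochs equals the
        pipeline output."""
        feats = connectivity_features(null_cohort, two_band_grid, seed=3)
        s, c, q = 0, 2, 1
        arr = null_cohort.epochs[(s, c)]
        rng = child_rng(3, "quarters", s, c)
        per = arr.shape[0] // 4
        order = rng.permutation(arr.shape[0])
        idx = order[q * per : (q + 1) * per]
        seed_i, targ_i = 0, 2  # first seed sub-ROI, first IFG sub-ROI
        Sx = morlet_tfr(arr[idx, seed_i, :].astype(float), 250.0, two_band_grid).data
        tens = morlet_tfr(arr[idx, targ_i, :].astype(float), 250.0, two_band_grid)
        ic = imcoh(Sx, tens.data)
        t0, t1 = 0.5, 1.25
        tmask = (tens.times >= t0) & (tens.times < t1)
        fidx = two_band_grid.band_indices("alpha")
        ok = tens.valid[np.ix_(fidx, tmask)]
        want = ic[np.ix_(fidx, tmask)][ok].mean()
        got = feats.features[("STC-rh", "IFG-rh", "alpha", "early")][0, c, q, 0]
        assert got == pytest.approx(want, rel=1e-10)

    def test_null_features_scatter_shrinks_with_quarter_size(self, small_layout, two_band_grid):
        """ImCoh noise scales roughly as 1/sqrt(epochs per quarter)."""
        truth = GroundTruth(bands={"alpha": (8.0, 12.0), "high_gamma": (61.0, 120.0)})
        spreads = {}
        for K in (8, 32):
            cohort = simulate_cohort(small_layout, truth, n_subjects=2,
                                     epochs_per_condition=K, epoch_length=2.5,
                                     sample_rate=250.0, seed=11)
            feats = connectivity_features(cohort, two_band_grid, seed=11)
            arr = feats.features[("STC-rh", "IFG-rh", "high_gamma", "early")]
            spreads[K] = np.std(arr)
        ratio = spreads[8] / spreads[32]
        assert 1.3 < ratio < 3.1  # ideal 2.0 with Monte-Carlo slack

    def test_quarter_below_two_epochs_rejected(self, small_layout, two_band_grid):
        truth = GroundTruth(bands={"alpha": (8.0, 12.0), "high_gamma": (61.0, 120.0)})
        cohort = simulate_cohort(small_layout, truth, n_subjects=1,
                                 epochs_per_condition=6, epoch_length=2.5,
                                 sample_rate=250.0, seed=0)
        with pytest.raises(ValueError, match="quarters"):
            connectivity_features(cohort, two_band_grid, seed=0)

    def test_mean_imcoh_monotone_in_kappa(self, two_band_grid):
        """For a fixed lag in (0, pi), the planted-pair ImCoh magnitude grows
        with the von Mises concentration."""
        layout = RoiLayout.reduced(1, 1, 1)
        means = []
        for kappa in (0.5, 4.0, 50.0):
            truth = GroundTruth(
                couplings=[CouplingSpec(0, 1, "high_gamma", (np.pi / 3,) * 6,
                                        kappa=kappa, amplitude=2.0)],
                bands={"alpha": (8.0, 12.0), "high_gamma": (61.0, 120.0)},
            )
            cohort = simulate_cohort(layout, truth, n_subjects=2,
                                     epochs_per_condition=24, epoch_length=2.5,
                                     sample_rate=250.0, seed=21)
            feats = connectivity_features(cohort, two_band_grid, seed=21)
            arr = feats.features[("STC-rh", "IFG-rh", "high_gamma", "early")]
            means.append(np.mean(np.abs(arr)))
        assert means[0] < means[1] < means[2]


def test_features_hdf5_roundtrip(tmp_path, null_cohort, two_band_grid):
    feats = connectivity_features(null_cohort, two_band_grid, seed=5)
    path = tmp_path / "features.h5"
    save_features(path, feats)
    back = load_features(path)
    assert back.tests == feats.tests
    assert back.windows == feats.windows
    for test in feats.tests:
        np.testing.assert_allclose(back.features[test], feats.features[test])
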