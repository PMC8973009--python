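"""Coherence estimators, lag scans, peak logic, pairwise matrices."""

import numpy as np
import pytest

from dirflow.spectral import (
    LagCoherenceProfile,
    _ensemble_spectra,
    band_coherence,
    coherence,
    lagged_coherence,
    pairwise_matrix,
    peak_lag,
)
from dirflow.synth import generate_epochs

from conftest import coupled_config


class TestCoherence:
    fs = 512.0

    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(4096)
        _, c = coherence(x, x, self.fs)
        assert np.abs(c - 1.0).max() < 1e-10

    def test_independent_noise_mean_is_one_over_k(self, rng):
        """Small-sample bias of Welch coherence: E[C] = 1/K for
        independent signals with K non-overlapping segments."""
        seg, n_seg, reps = 128, 16, 100
        means = []
        for _ in range(reps):
            x = rng.standard_normal(seg * n_seg)
            y = rng.standard_normal(seg * n_seg)
            _, c = coherence(x, y, self.fs, segment=seg, overlap=0.0)
            means.append(c[1:].mean())  # skip DC
        obs = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(reps)
        assert abs(obs - 1.0 / n_seg) < 3 * se

    def test_pure_delay_preserves_coherence(self, rng):
        x = rng.standard_normal(8192)
        y = np.roll(x, 5)
        _, c = coherence(x, y, self.fs)
        assert c[2:-2].mean() > 0.9

    def test_single_segment_rejected(self, rng):
        with pytest.raises(ValueError, match="K >= 2"):
            coherence(rng.standard_normal(300), rng.standard_normal(300), self.fs)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal((10, 512))
        y = rng.standard_normal((10, 512)) + 0.5 * x
        v1 = band_coherence(x, y, self.fs, (20, 40), segment=128)
        v2 = band_coherence(3.0 * x + 7.0, y, self.fs, (20, 40), segment=128)
        assert abs(v1 - v2) < 1e-10

    def test_swap_symmetry(self, rng):
        x = rng.standard_normal((8, 512))
        y = rng.standard_normal((8, 512))
        v1 = band_coherence(x, y, self.fs, (10, 50), segment=128)
        v2 = band_coherence(y, x, self.fs, (10, 50), segment=128)
        assert abs(v1 - v2) < 1e-12

    def test_coherence_bounded_on_random_inputs(self, rng):
        for _ in range(10):
            est = _ensemble_spectra(
                rng.standard_normal((4, 300)), rng.standard_normal((4, 300)), self.fs,
                segment=64,
            )
            c = est.coherence()
            assert (c >= 0).all() and (c <= 1).all()

    def test_empty_band_rejected(self, rng):
        x = rng.standard_normal(2048)
        with pytest.raises(ValueError, match="no frequency bins"):
            band_coherence(x, x, self.fs, (1.0, 1.5), segment=256, nfft=256)


class TestLaggedCoherence:
    def test_planted_delay_recovered(self):
        """Coupled generator: the band-coherence peak sits at the delay."""
        cfg = coupled_config(delay_samples=16, fs=512.0, n_trials=60, seed=5)
        ep = generate_epochs(cfg)
        prof = lagged_coherence(
            ep.data[:, 0], ep.data[:, 3], ep.fs, ep.times,
            (20.0, 40.0), (-400.0, 400.0), lag_range_ms=(-50.0, 50.0),
        )
        lag_ms, value, degenerate = peak_lag(prof)
        assert not degenerate
        assert round(lag_ms * ep.fs / 1000.0) == 16

    @pytest.mark.parametrize("delay", [3, 11, 29])
    def test_pure_delay_plus_noise_recovery(self, rng, delay):
        fs = 512.0
        n, trials = 512, 40
        times = (np.arange(n) - n // 2) / fs
        x = rng.standard_normal((trials, n))
        y = np.roll(x, delay, axis=-1) + 0.3 * rng.standard_normal((trials, n))
        prof = lagged_coherence(
            x, y, fs, times, (10.0, 100.0), (-300.0, 300.0),
            lag_range_ms=(-70.0, 70.0), prefilter=False,
        )
        lag_ms, _, _ = peak_lag(prof)
        assert abs(round(lag_ms * fs / 1000.0) - delay) <= 1

    def test_relabel_symmetry(self, rng):
        """C(x@W, y@W+tau) equals C(y@W+tau, x@W) exactly."""
        fs = 512.0
        n = 512
        times = (np.arange(n) - n // 2) / fs
        x = rng.standard_normal((10, n))
        y = rng.standard_normal((10, n)) + 0.5 * x
        tau_ms = 10 * 1000.0 / fs
        fwd = lagged_coherence(
            x, y, fs, times, (10, 60), (-200, 200), lag_range_ms=(tau_ms, tau_ms)
        )
        rev = lagged_coherence(
            y, x, fs, times, (10, 60), (-200 + tau_ms, 200 + tau_ms),
            lag_range_ms=(-tau_ms, -tau_ms),
        )
        assert fwd.values[0] == pytest.approx(rev.values[0], abs=1e-6)

    def test_out_of_epoch_lag_rejected(self, rng):
        fs = 256.0
        n = 256
        times = (np.arange(n) - n // 2) / fs
        x = rng.standard_normal((5, n))
        with pytest.raises(ValueError, match="outside the epoch"):
            lagged_coherence(
                x, x, fs, times, (10, 60), (-450, 450), lag_range_ms=(0, 100)
            )

    def test_independent_signals_peak_below_null(self, rng):
        """Max lagged coherence of independent pairs stays under the
        95th percentile of its own simulated null."""
        fs = 256.0
        n, trials = 256, 10
        times = (np.arange(n) - n // 2) / fs

        def max_profile():
            x = rng.standard_normal((trials, n))
            y = rng.standard_normal((trials, n))
            prof = lagged_coherence(
                x, y, fs, times, (20, 60), (-200, 200),
                lag_range_ms=(-40, 40), lag_step=2,
            )
            return prof.values.max()

        null = np.sort([max_profile() for _ in range(100)])
        q95 = null[int(0.95 * len(null))]
        below = sum(max_profile() < q95 for _ in range(20))
        assert below >= 15


class TestPeakLag:
    def _profile(self, lags_ms, values):
        return LagCoherenceProfile(
            lags_ms=np.asarray(lags_ms, float),
            values=np.asarray(values, float),
            band=(8.0, 16.0),
            window_ms=(0.0, 100.0),
            fs=1000.0,
        )

    def test_single_maximum(self):
        lag, val, deg = peak_lag(self._profile([0, 11, 22, 33], [0.1, 0.2, 0.9, 0.3]))
        assert (lag, val, deg) == (22.0, 0.9, False)

    def test_flat_profile_degenerate_zero(self):
        lag, _, deg = peak_lag(self._profile([-10, 0, 10], [0.5, 0.5, 0.5]))
        assert lag == 0.0 and deg

    def test_tie_prefers_positive(self):
        lag, _, deg = peak_lag(
            self._profile([-15, -5, 5, 15], [0.9, 0.1, 0.1, 0.9])
        )
        assert lag == 15.0 and not deg

    def test_tie_prefers_smallest_magnitude(self):
        lag, _, _ = peak_lag(self._profile([-20, -5, 10], [0.9, 0.9, 0.2]))
        assert lag == -5.0


class TestPairwiseMatrix:
    def test_shape_symmetry_diagonal(self, rng):
        cfg = coupled_config(n_trials=12)
        ep = generate_epochs(cfg)
        cm = pairwise_matrix(ep, band=(20, 40), lag_ms=0.0, window_ms=(-300, 300))
        assert cm.values.shape == (6, 6)
        iu = np.triu_indices(6, k=1)
        assert iu[0].size == 15
        np.testing.assert_allclose(cm.values, cm.values.T)
        np.testing.assert_allclose(np.diag(cm.values), 1.0)
        assert (cm.values >= 0).all() and (cm.values <= 1).all()

    def test_planted_pair_is_argmax(self):
        hits = 0
        for seed in range(5):
            cfg = coupled_config(n_trials=30, gain=2.0, seed=seed)
            ep = generate_epochs(cfg)
            cm = pairwise_matrix(ep, band=(20, 40), lag_ms=16 * 1000.0 / 512.0,
                                 window_ms=(-300, 300))
            vals = cm.values.copy()
            np.fill_diagonal(vals, 0)
            i, j = np.unravel_index(np.argmax(vals), vals.shape)
            hits += {i, j} == {0, 3}
        assert hits >= 4

    def test_per_trial_mode_shape(self, rng):
        cfg = coupled_config(n_trials=10)
        ep = generate_epochs(cfg)
        cm = pairwise_matrix(ep, band=(20, 40), per_trial=True, window_ms=(-250, 250))
        assert cm.per_trial.shape == (10, 6, 6)
        np.testing.assert_allclose(cm.values, cm.per_trial.mean(axis=0))

    def test_pooled_mode_separates_coupling_from_null_better(self, rng):
        """Per-trial coherence with few within-trial segments carries a
        large small-K null bias; pooling trials as the averaging ensemble
        keeps the null floor near zero, so a phase-locked coupling stands
        out by a much wider margin — why the pooled mode is the default."""
        fs, n, trials = 256.0, 256, 60
        times = (np.arange(n) - n // 2) / fs
        evoked = 1.5 * np.cos(2 * np.pi * 20.0 * times)
        coupled = rng.standard_normal((trials, 2, n))
        coupled[:, 0] += evoked
        coupled[:, 1] += np.roll(evoked, 4)
        independent = rng.standard_normal((trials, 2, n))

        def value(data, per_trial):
            cm = pairwise_matrix(
                data, fs=fs, times=times, band=(15, 25), window_ms=(-400, 400),
                channels=["L0", "R0"], per_trial=per_trial,
            )
            return cm.values[0, 1]

        margin_pooled = value(coupled, False) - value(independent, False)
        margin_per_trial = value(coupled, True) - value(independent, True)
        assert value(independent, True) > 0.3  # the small-K bias is real
        assert value(independent, False) < 0.1
        assert margin_pooled > margin_per_trial


class TestGeneratorBandSpecificity:
    def test_coupled_band_exceeds_other_bands(self):
        hits = 0
        for seed in range(8):
            cfg = coupled_config(
                delay_samples=8, fs=512.0, band=(24.0, 32.0), gain=1.5,
                n_trials=30, seed=seed, background_osc=((60.0, 100.0, 0.5),),
            )
            ep = generate_epochs(cfg)
            x, y = ep.data[:, 0], ep.data[:, 3]
            win = ep.window_slice((-300, 300))
            in_band = band_coherence(x[:, win], y[:, win], ep.fs, (24, 32), segment=128)
            out_band = band_coherence(x[:, win], y[:, win], ep.fs, (60, 100), segment=128)
            hits += in_band > out_band
        assert hits >= 7
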