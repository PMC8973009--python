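"""Granger scans, transfer entropy, and network inference."""

import numpy as np
import pytest

from dirflow.containers import EpochSet
from dirflow.directed import (
    granger_lag,
    granger_scan,
    infer_network,
    order_robustness,
    transfer_entropy,
)
from dirflow.synth import CouplingSpec, generate_epochs

from conftest import quiet_config


def _coupled_pair(rng, n_trials=8, n=400, d=6, gain=1.0, noise=0.3):
    """y driven by x at lag d (white-noise innovation, strong SNR)."""
    x = rng.standard_normal((n_trials, n))
    y = noise * rng.standard_normal((n_trials, n))
    y[:, d:] += gain * x[:, :-d]
    return x, y


def _coupled_walk_pair(rng, n_trials=8, n=400, d=6, gain=1.0, noise=0.3):
    """Integrated pair: after first differencing, the driver is white and
    the target's innovation contains the driver at lag d only — so
    reverse-direction causality is genuinely absent."""
    x = np.cumsum(rng.standard_normal((n_trials, n)), axis=-1)
    y = np.cumsum(noise * rng.standard_normal((n_trials, n)), axis=-1)
    y[:, d:] += gain * x[:, :-d]
    return x, y


def _source_epochs(data, fs=512.0, names=None):
    n_tr, n_src, n = data.shape
    import pandas as pd

    return EpochSet(
        data=data,
        fs=fs,
        times=(np.arange(n) - n // 2) / fs,
        channels=names or [f"S{k}:L" for k in range(n_src)],
        labels=pd.DataFrame({"valence": "correct", "learned": "learned",
                             "phase": "early"}, index=range(n_tr)),
    )


class TestGrangerScan:
    fs = 512.0

    def _times(self, n):
        return (np.arange(n) - n // 2) / self.fs

    def test_planted_lag_is_f_maximum(self, rng):
        hits_lag, hits_rev = 0, 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            x, y = _coupled_walk_pair(r, d=6)
            times = self._times(x.shape[1])
            fwd = granger_scan(x, y, self.fs, times, (-200, 300), (0.0, 30.0), order=8)
            rev = granger_scan(y, x, self.fs, times, (-200, 300), (0.0, 30.0), order=8)
            lag, _, p = fwd.peak()
            hits_lag += lag == 6 and p < 1e-6
            hits_rev += rev.peak()[2] > 0.01
        assert hits_lag >= 4
        assert hits_rev >= 4

    def test_null_type_one_error_rate(self, rng):
        alpha, cells = 0.05, 0
        hits = 0
        for _ in range(100):
            x = rng.standard_normal((4, 300))
            y = rng.standard_normal((4, 300))
            times = self._times(300)
            for a, b in ((x, y), (y, x)):
                res = granger_scan(a, b, self.fs, times, (-100, 250), (0, 20), order=4,
                                   lag_step=2)
                hits += int((res.p < alpha).sum())
                cells += res.p.size
        rate = hits / cells
        se = np.sqrt(alpha * (1 - alpha) / cells)
        assert rate < alpha + 3 * se

    def test_fast_path_equals_two_regression_oracle(self, rng):
        """F from the scan equals an explicit two-OLS-fit oracle, 1e-8."""
        import statsmodels.api as sm

        for _ in range(20):
            n, order, tau = 240, rng.integers(2, 8), int(rng.integers(1, 10))
            x = rng.standard_normal((2, n))
            y = rng.standard_normal((2, n)) + 0.4 * np.roll(x, 3, axis=-1)
            i0, i1 = 40, n - 5
            f_fast, p_fast, _, _ = granger_lag(x, y, i0, i1, int(order), tau)

            idx = np.arange(i0, i1 + 1)
            target = y[:, idx].ravel()
            ar = np.stack([y[:, idx - k] for k in range(1, order + 1)], -1).reshape(
                target.size, -1
            )
            exo = x[:, idx - tau].ravel()[:, None]
            rest = sm.OLS(target, sm.add_constant(ar)).fit()
            full = sm.OLS(target, sm.add_constant(np.hstack([ar, exo]))).fit()
            df_f = target.size - (order + 2)
            f_oracle = (rest.ssr - full.ssr) / (full.ssr / df_f)
            assert f_fast == pytest.approx(f_oracle, abs=1e-8, rel=1e-8)

    def test_affine_and_trend_invariance(self, rng):
        x = rng.standard_normal((3, 300))
        y = rng.standard_normal((3, 300)) + 0.5 * np.roll(x, 4, axis=-1)
        times = self._times(300)
        base = granger_scan(x, y, self.fs, times, (-100, 250), (0, 15), order=4)
        trend = 0.7 * np.arange(300)
        scaled = granger_scan(
            2.5 * x + 3.0 + trend, 0.5 * y - 1.0 + trend, self.fs, times,
            (-100, 250), (0, 15), order=4,
        )
        np.testing.assert_allclose(base.f, scaled.f, atol=1e-6)

    def test_window_too_early_rejected(self, rng):
        x = rng.standard_normal((2, 200))
        with pytest.raises(ValueError, match="history"):
            granger_scan(x, x.copy(), self.fs, self._times(200), (-190, 100),
                         (0, 20), order=30)

    def test_observation_count_guard(self, rng):
        x = rng.standard_normal((1, 300))
        with pytest.raises(ValueError, match="parameters"):
            granger_scan(x, x.copy(), self.fs, self._times(300), (-10, 10),
                         (0, 10), order=60)


class TestGrangerBlock:
    def test_block_detects_coupling_and_validates_range(self):
        from dirflow.directed import granger_block

        fs = 512.0
        x, y = _coupled_walk_pair(np.random.default_rng(3), n_trials=8, d=5)
        times = (np.arange(x.shape[1]) - 200) / fs
        f, p = granger_block(x, y, fs, times, (-200, 300), p=1, q=10, order=8)
        assert p < 1e-6
        f_rev, p_rev = granger_block(y, x, fs, times, (-200, 300), p=1, q=10, order=8)
        assert f > f_rev
        with pytest.raises(ValueError, match="p <= q"):
            granger_block(x, y, fs, times, (-200, 300), p=5, q=2)


class TestOrderRobustness:
    fs = 512.0

    def test_planted_coupling_is_robust(self, rng):
        x, y = _coupled_walk_pair(np.random.default_rng(1), n_trials=10, d=5)
        times = (np.arange(x.shape[1]) - 200) / self.fs
        rep = order_robustness(
            x, y, self.fs, times, (-200, 300), orders=(4, 8, 12),
            lag_range_ms=(0, 25), names=("L", "R"),
        )
        assert rep.robust
        assert rep.direction == ("L", "R")

    def test_independent_signals_not_robust(self):
        flags = 0
        for seed in range(5):
            r = np.random.default_rng(100 + seed)
            x = r.standard_normal((6, 400))
            y = r.standard_normal((6, 400))
            times = (np.arange(400) - 200) / self.fs
            rep = order_robustness(
                x, y, self.fs, times, (-200, 300), orders=(4, 8),
                lag_range_ms=(0, 25),
            )
            flags += rep.robust
        assert flags <= 1

    def test_single_order_rejected(self, rng):
        x = rng.standard_normal((4, 300))
        with pytest.raises(ValueError, match=">= 2 model orders"):
            order_robustness(x, x.copy(), self.fs, (np.arange(300) - 150) / self.fs,
                             (-100, 200), orders=(8,))

    def test_infeasible_orders_skipped(self, rng):
        x = rng.standard_normal((6, 400))
        y = rng.standard_normal((6, 400))
        times = (np.arange(400) - 200) / self.fs
        rep = order_robustness(
            x, y, self.fs, times, (-200, 300), orders=(4, 8, 500),
            lag_range_ms=(0, 25),
        )
        assert rep.orders == [4, 8]


class TestValenceModulation:
    def test_incorrect_trials_show_stronger_forward_flow(self):
        """A coupling whose gain is larger on incorrect trials yields a
        larger left->right F on the incorrect subset at the planted lag."""
        fs = 512.0
        hits = 0
        for seed in range(5):
            cfg = quiet_config(
                fs=fs, n_trials=40, pre=0.5, post=0.5, noise_sd=0.5, seed=seed,
                couplings=(
                    CouplingSpec("L0", "R0", 10 * 1000.0 / fs, None,
                                 {"incorrect": 1.5, "correct": 0.4},
                                 window_ms=(-450.0, 450.0)),
                ),
            )
            ep = generate_epochs(cfg)
            x, y = ep.data[:, 0], ep.data[:, 3]
            f_by_valence = {}
            for valence in ("correct", "incorrect"):
                sel = (ep.labels["valence"] == valence).to_numpy()
                res = granger_scan(x[sel], y[sel], fs, ep.times, (-400, 400),
                                   (0.0, 40.0), order=6)
                f_by_valence[valence] = res.f.mean()
            hits += f_by_valence["incorrect"] > f_by_valence["correct"]
        assert hits >= 4


class TestTransferEntropy:
    def test_independent_pair_not_significant(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            data = r.standard_normal((2, 2, 600))
            est = transfer_entropy(
                data, target=1, source=0, hist=3, conditioning="pairwise",
                n_surrogates=100, rng=r,
            )
            hits += est.p > 0.05
        assert hits >= 8

    def test_gaussian_te_matches_granger_identity(self, rng):
        """T = 0.5 * ln(RSS_r / RSS_f) against an independent OLS fit."""
        import statsmodels.api as sm

        for seed in range(5):
            r = np.random.default_rng(seed)
            n, hist = 800, 3
            x = np.zeros(n)
            y = np.zeros(n)
            ex = r.standard_normal(n)
            ey = r.standard_normal(n)
            for t in range(1, n):
                x[t] = 0.5 * x[t - 1] + ex[t]
                y[t] = 0.4 * y[t - 1] + 0.6 * x[t - 1] + ey[t]
            data = np.stack([x, y])[None]
            est = transfer_entropy(data, target=1, source=0, hist=hist, tau=1,
                                   conditioning="pairwise")
            idx = np.arange(hist + 1, n)
            target = y[idx]
            ar = np.stack([y[idx - k] for k in range(1, hist + 1)], -1)
            exo = np.stack([x[idx - k] for k in range(1, hist + 1)], -1)
            rest = sm.OLS(target, sm.add_constant(ar)).fit()
            full = sm.OLS(target, sm.add_constant(np.hstack([ar, exo]))).fit()
            expected = 0.5 * np.log(rest.ssr / full.ssr)
            assert est.raw == pytest.approx(expected, rel=0.05)

    def test_directional_asymmetry(self, rng):
        x, y = _coupled_pair(rng, n_trials=4, n=600, d=2)
        data = np.stack([x, y], axis=1)
        fwd = transfer_entropy(data, target=1, source=0, hist=4, tau=1,
                               conditioning="pairwise")
        rev = transfer_entropy(data, target=0, source=1, hist=4, tau=1,
                               conditioning="pairwise")
        assert fwd.value > 5 * max(rev.value, 1e-3)

    def test_ksg_detects_coupling(self, rng):
        x, y = _coupled_pair(rng, n_trials=1, n=800, d=1)
        data = np.stack([x[0], y[0]])[None]
        fwd = transfer_entropy(data, 1, 0, hist=2, estimator="ksg",
                               conditioning="pairwise")
        rev = transfer_entropy(data, 0, 1, hist=2, estimator="ksg",
                               conditioning="pairwise")
        assert fwd.value > rev.value + 0.1

    def test_parameter_validation(self, rng):
        data = rng.standard_normal((1, 2, 500))
        with pytest.raises(ValueError, match="estimator"):
            transfer_entropy(data, 1, 0, estimator="magic")
        with pytest.raises(ValueError, match="too short"):
            transfer_entropy(data, 1, 0, hist=50)
        with pytest.raises(ValueError, match="surrogates"):
            transfer_entropy(data, 1, 0, hist=3, n_surrogates=50)


def _network_config(reverse=False, seed=0, fs=512.0):
    """Two broadband planted edges; white components keep the latent
    history finite so the planted edges are the only information flow."""
    lags = (10, 16)
    pairs = [("L0", "R0", lags[0]), ("L1", "R1", lags[1])]
    if reverse:
        pairs = [(b, a, d) for a, b, d in pairs]
    return quiet_config(
        fs=fs,
        n_trials=8,
        pre=0.5,
        post=0.5,
        noise_sd=0.5,
        seed=seed,
        couplings=tuple(
            CouplingSpec(a, b, d * 1000.0 / fs, None, {"*": 1.2},
                         window_ms=(-450.0, 450.0))
            for a, b, d in pairs
        ),
    )


class TestInferNetwork:
    def _infer(self, cfg):
        ep = generate_epochs(cfg)
        src = _source_epochs(ep.data, fs=cfg.fs,
                             names=[f"{c}" for c in cfg.channels])
        return infer_network(
            src, tau_range=(1, 24), hist=6, n_surrogates=200, seed=99,
        )

    def test_planted_two_edge_network_recovered(self):
        net = self._infer(_network_config(seed=4))
        assert net.edge_set() == {("L0", "R0"), ("L1", "R1")}
        lags = {(e.source, e.target): e.lag_samples for e in net.edges}
        assert abs(lags[("L0", "R0")] - 10) <= 2
        assert abs(lags[("L1", "R1")] - 16) <= 2

    def test_reversed_generator_reverses_directions(self):
        net = self._infer(_network_config(reverse=True, seed=4))
        assert net.edge_set() == {("R0", "L0"), ("R1", "L1")}

    def test_independent_sources_empty_network(self):
        net = self._infer(quiet_config(fs=512.0, n_trials=12, pre=0.5, post=0.5, seed=8))
        assert net.edges == []

    def test_validation(self, rng):
        src = _source_epochs(rng.standard_normal((4, 2, 600)))
        with pytest.raises(ValueError, match="surrogates"):
            infer_network(src, n_surrogates=50)
        one = _source_epochs(rng.standard_normal((4, 1, 600)))
        with pytest.raises(ValueError, match="2 sources"):
            infer_network(one)
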