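"""Magnitude-squared coherence, lag-scanned directional coherence, and
pairwise coherence matrices.

Coherence is C_xy(f) = |G_xy(f)|^2 / (G_xx(f) G_yy(f)) with G the cross-
and auto-spectral densities.  Two estimators are used:

* Welch (Hann taper, 50 % overlap) when the analysis window holds at
  least two segments, pooling segments across trials;
* a 3-taper DPSS multitaper estimate on the whole window, per trial, for
  short windows (e.g. the 410-sample pre-event window at 2048 Hz), where
  trials act as the averaging ensemble.

Directional ("lagged") coherence re-windows the second signal at a signed
offset tau and scans tau; because the generator's coupling components are
confined in time, the band coherence peaks when the offset matches the
true transmission delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import EpochSet

CANONICAL_BANDS = {
    "theta": (4.0, 8.0),
    "beta": (12.5, 30.0),
    "low_gamma": (30.0, 60.0),
    "high_gamma": (60.0, 100.0),
}

DEFAULT_SEGMENT = 256


@dataclass
class SpectralEstimate:
    """Cross- and auto-spectra on a common frequency grid."""

    f: np.ndarray
    gxx: np.ndarray
    gyy: np.ndarray
    gxy: np.ndarray
    params: dict = field(default_factory=dict)

    def coherence(self) -> np.ndarray:
        denom = self.gxx * self.gyy
        c = np.zeros_like(self.gxx)
        ok = denom > 0
        c[ok] = np.abs(self.gxy[ok]) ** 2 / denom[ok]
        return np.clip(c, 0.0, 1.0)


@dataclass
class LagCoherenceProfile:
    """Band coherence as a function of signed lag (ms).

    Positive lag means the second signal's window is shifted later in
    time, i.e. a peak at +tau supports first->second transmission with
    delay tau.
    """

    lags_ms: np.ndarray
    values: np.ndarray
    band: tuple[float, float]
    window_ms: tuple[float, float]
    fs: float
    params: dict = field(default_factory=dict)


@dataclass
class CoherenceMatrix:
    """Pairwise band coherence at a fixed lag; (channels x channels)."""

    values: np.ndarray
    channels: list[str]
    band: tuple[float, float]
    lag_ms: float
    per_trial: np.ndarray | None = None  # trials x channels x channels


def _band_bins(f: np.ndarray, band) -> np.ndarray:
    lo, hi = band
    sel = (f >= lo) & (f < hi)
    if not sel.any():
        raise ValueError(f"band {band} contains no frequency bins on grid step {f[1] - f[0]:.3g} Hz")
    return sel


def _segment_starts(n: int, seg: int, overlap: float) -> np.ndarray:
    step = max(1, int(round(seg * (1 - overlap))))
    return np.arange(0, n - seg + 1, step)


def _ensemble_spectra(
    xw: np.ndarray,
    yw: np.ndarray,
    fs: float,
    segment: int = DEFAULT_SEGMENT,
    overlap: float = 0.5,
    n_tapers: int = 3,
    nfft: int | None = None,
) -> SpectralEstimate:
    """Averaged cross/auto spectra for trial ensembles (trials x samples).

    Welch segments pooled over trials when the window permits K >= 2
    segments per trial, otherwise whole-window multitaper per trial.
    """
    xw = np.atleast_2d(xw)
    yw = np.atleast_2d(yw)
    if xw.shape != yw.shape:
        raise ValueError("x and y must share shape (trials x samples)")
    n = xw.shape[1]
    if n >= 2 * segment:
        win = signal.windows.hann(segment)
        starts = _segment_starts(n, segment, overlap)
        segs_x = np.stack([xw[:, s : s + segment] for s in starts], axis=1)
        segs_y = np.stack([yw[:, s : s + segment] for s in starts], axis=1)
        # constant detrend per segment: offsets must not leak into the bins
        segs_x = (segs_x - segs_x.mean(axis=-1, keepdims=True)) * win
        segs_y = (segs_y - segs_y.mean(axis=-1, keepdims=True)) * win
        mode = {"estimator": "welch", "segment": segment, "overlap": overlap,
                "n_segments": int(xw.shape[0] * len(starts))}
        nfft = nfft or segment
    else:
        tapers = signal.windows.dpss(n, NW=2.0, Kmax=n_tapers)
        segs_x = (xw - xw.mean(axis=-1, keepdims=True))[:, None, :] * tapers
        segs_y = (yw - yw.mean(axis=-1, keepdims=True))[:, None, :] * tapers
        mode = {"estimator": "multitaper", "n_tapers": n_tapers,
                "n_segments": int(xw.shape[0] * n_tapers)}
        nfft = nfft or n
    fx = np.fft.rfft(segs_x, n=nfft, axis=-1)
    fy = np.fft.rfft(segs_y, n=nfft, axis=-1)
    gxx = (fx * np.conj(fx)).real.mean(axis=(0, 1))
    gyy = (fy * np.conj(fy)).real.mean(axis=(0, 1))
    gxy = (fx * np.conj(fy)).mean(axis=(0, 1))
    f = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return SpectralEstimate(f=f, gxx=gxx, gyy=gyy, gxy=gxy, params=mode)


def coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    segment: int = DEFAULT_SEGMENT,
    overlap: float = 0.5,
    nfft: int | None = None,
) -> tuple[SpectralEstimate, np.ndarray]:
    """Welch magnitude-squared coherence of two continuous 1-D signals.

    Requires at least two segments: single-segment coherence is
    identically 1 and carries no information.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    if x.size < 2 * segment:
        raise ValueError(
            f"need >= 2 segments of {segment} samples (K >= 2); got {x.size} samples"
        )
    est = _ensemble_spectra(
        x[None, :], y[None, :], fs, segment=segment, overlap=overlap, nfft=nfft
    )
    return est, est.coherence()


def band_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: tuple[float, float],
    **kwargs,
) -> float:
    """Mean coherence over frequency bins with centers in [lo, hi).

    Accepts 1-D continuous signals or (trials x samples) ensembles.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim == 1:
        est, c = coherence(x, y, fs, **kwargs)
    else:
        est = _ensemble_spectra(x, y, fs, **kwargs)
        c = est.coherence()
    return float(c[_band_bins(est.f, band)].mean())


def lagged_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    times: np.ndarray,
    band: tuple[float, float],
    window_ms: tuple[float, float],
    lag_range_ms: tuple[float, float] = (-50.0, 50.0),
    lag_step: int = 1,
    prefilter: bool = True,
    segment: int | None = None,
    nfft: int | None = None,
    **est_kwargs,
) -> LagCoherenceProfile:
    """Band coherence of (x, y) with y's window offset by each lag.

    x and y are (trials x samples) epoch ensembles on the common ``times``
    axis.  x keeps the fixed analysis window; for each integer-sample lag
    tau, y is re-windowed at window + tau.  Lags that would push the
    window outside the epoch raise, naming the violating lag.

    The lag axis is only as sharp as the spectral segments are short: a
    content mismatch of m samples costs about m/segment of the segment
    correlation, so short segments localize the peak, while long segments
    see a delay as a mere phase ramp.  The default therefore uses ~31 ms
    Welch segments (zero-padded FFT for in-band frequency bins) and
    zero-phase band-pass prefiltering of both signals, which stops strong
    trial-coherent activity at neighboring frequencies (e.g. an evoked
    phase reset) from leaking through the short-segment taper into the
    scanned band.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    n = x.shape[1]
    if prefilter:
        sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, x, axis=-1)
        y = signal.sosfiltfilt(sos, y, axis=-1)
    if segment is None:
        segment = max(32, int(round(0.031 * fs)))
    if nfft is None:
        width = band[1] - band[0]
        nfft = int(2 ** np.ceil(np.log2(max(segment, 4.0 * fs / width))))
    i0 = int(np.searchsorted(times, window_ms[0] / 1e3 - 0.5 / fs))
    i1 = int(np.searchsorted(times, window_ms[1] / 1e3 - 0.5 / fs))
    lag_lo = int(np.floor(lag_range_ms[0] * fs / 1000.0))
    lag_hi = int(np.ceil(lag_range_ms[1] * fs / 1000.0))
    lags = np.arange(lag_lo, lag_hi + 1, lag_step)
    for tau in (lags[0], lags[-1]):
        if i0 + tau < 0 or i1 + tau + 1 > n:
            raise ValueError(
                f"lag {tau / fs * 1e3:.2f} ms pushes the window outside the epoch"
            )
    xw = x[:, i0 : i1 + 1]
    vals = np.empty(lags.size)
    params: dict = {}
    for k, tau in enumerate(lags):
        est = _ensemble_spectra(
            xw, y[:, i0 + tau : i1 + tau + 1], fs,
            segment=segment, nfft=nfft, **est_kwargs,
        )
        c = est.coherence()
        vals[k] = c[_band_bins(est.f, band)].mean()
        params = est.params
    return LagCoherenceProfile(
        lags_ms=lags * 1000.0 / fs,
        values=vals,
        band=tuple(band),
        window_ms=tuple(window_ms),
        fs=fs,
        params=params,
    )


def peak_lag(profile: LagCoherenceProfile) -> tuple[float, float, bool]:
    """(lag ms, coherence, degenerate flag) of the profile maximum.

    Ties are broken toward the smallest |lag|, then toward positive lag.
    An all-equal profile returns lag 0 (or the grid point nearest 0) with
    the degeneracy flag set.
    """
    v = profile.values
    if v.size == 0:
        raise ValueError("empty profile")
    vmax = v.max()
    degenerate = bool(np.all(v == vmax))
    if degenerate:
        idx = int(np.argmin(np.abs(profile.lags_ms)))
        return float(profile.lags_ms[idx]), float(vmax), True
    tie = np.flatnonzero(v == vmax)
    # smallest |lag| first, positive preferred on exact magnitude ties
    order = sorted(tie, key=lambda i: (abs(profile.lags_ms[i]), profile.lags_ms[i] < 0))
    idx = order[0]
    return float(profile.lags_ms[idx]), float(vmax), False


def pairwise_matrix(
    epochs: EpochSet | np.ndarray,
    fs: float | None = None,
    band: tuple[float, float] = (24.0, 32.0),
    lag_ms: float = 0.0,
    window_ms: tuple[float, float] | None = None,
    times: np.ndarray | None = None,
    channels: list[str] | None = None,
    per_trial: bool = False,
    segment: int | None = None,
    **est_kwargs,
) -> CoherenceMatrix:
    """Band coherence for every unordered channel pair at a fixed lag.

    In the default (trial-ensemble) mode one matrix is returned, pooling
    trials in the spectral average.  With ``per_trial=True`` a coherence
    matrix is computed for each trial from within-trial Welch segments —
    the per-trial values feed the condition-comparison stage.
    """
    if isinstance(epochs, EpochSet):
        data, fs = epochs.data, epochs.fs
        times = epochs.times if times is None else times
        channels = epochs.channels if channels is None else channels
    else:
        data = np.asarray(epochs, float)
        if fs is None or times is None:
            raise ValueError("fs and times are required for array input")
        channels = channels or [f"ch{i}" for i in range(data.shape[1])]
    n_tr, n_ch, n = data.shape
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    if window_ms is None:
        window_ms = (float(times[0] * 1e3), float(times[-1] * 1e3))
    i0 = int(np.searchsorted(times, window_ms[0] / 1e3 - 0.5 / fs))
    i1 = int(np.searchsorted(times, window_ms[1] / 1e3 - 0.5 / fs))
    tau = int(round(lag_ms * fs / 1000.0))
    if i0 + min(0, tau) < 0 or i1 + max(0, tau) + 1 > n:
        raise ValueError(f"lag {lag_ms} ms pushes the window outside the epoch")
    win_len = i1 - i0 + 1
    if segment is None:
        # per-trial mode needs >= 2 within-trial segments
        segment = DEFAULT_SEGMENT if win_len >= 2 * DEFAULT_SEGMENT else max(8, win_len // 2)
    if "nfft" not in est_kwargs:
        # zero-pad so narrow bands keep at least ~2 bins on the grid
        width = band[1] - band[0]
        est_kwargs["nfft"] = int(2 ** np.ceil(np.log2(max(segment, 4.0 * fs / width))))

    xw = data[:, :, i0 : i1 + 1]
    yw = data[:, :, i0 + tau : i1 + tau + 1]

    def _one(xt: np.ndarray, yt: np.ndarray) -> float:
        est = _ensemble_spectra(xt, yt, fs, segment=segment, **est_kwargs)
        return float(est.coherence()[_band_bins(est.f, band)].mean())

    if per_trial:
        mats = np.ones((n_tr, n_ch, n_ch))
        for i in range(n_ch):
            for j in range(i + 1, n_ch):
                for tr in range(n_tr):
                    v = _one(xw[tr : tr + 1, i], yw[tr : tr + 1, j])
                    mats[tr, i, j] = mats[tr, j, i] = v
        mean = mats.mean(axis=0)
        return CoherenceMatrix(mean, list(channels), tuple(band), lag_ms, per_trial=mats)

    mat = np.ones((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            mat[i, j] = mat[j, i] = _one(xw[:, i], yw[:, j])
    return CoherenceMatrix(mat, list(channels), tuple(band), lag_ms)
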