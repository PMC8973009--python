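"""Synthetic event-locked LFP sessions with planted directed coupling.

The generator emulates a bilateral six-channel bipolar montage sampled at
2048 Hz during a feedback-learning task.  Each trial epoch is a sum of

* Gaussian-windowed event-related components (pre-event negativity,
  double-peaked post-event response),
* band-limited stochastic background oscillations (filtered white noise,
  independent per channel and trial),
* an oscillatory phase-reset component whose phase at the reset time is
  shared across channels with von-Mises jitter,
* directed coupling: the target channel(s) receive a delayed, scaled copy
  of a band-limited component that is confined to a time window on the
  source channel(s), and
* white observation noise.

Every sampled quantity derives from one master seed through per-trial
``SeedSequence`` children, so output is a pure function of the config and
independent of trial evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, special, optimize

from .containers import (
    ConfigError,
    DirectedNetwork,
    EVENT_COLUMNS,
    EpochSet,
    NetworkEdge,
    Recording,
)

DEFAULT_CHANNELS = ("L0", "L1", "L2", "R0", "R1", "R2")

#: background oscillation bands as (lo Hz, hi Hz, sd): theta, beta, gamma
DEFAULT_BACKGROUND = ((4.0, 8.0, 0.5), (15.0, 25.0, 0.45), (30.0, 60.0, 0.35))

#: event-related components as (side, center ms, sd ms, amplitude, polarity)
DEFAULT_ERPS = (
    ("both", -250.0, 120.0, 0.8, -1),
    ("both", 200.0, 50.0, 1.0, +1),
    ("both", 400.0, 70.0, 0.7, +1),
)


@dataclass
class CouplingSpec:
    """One directed, band-limited, windowed coupling.

    ``source``/``target`` are either a channel label or a hemisphere
    ("L"/"R", meaning every channel on that side).  ``delay_ms`` must be a
    whole number of samples at the session rate.  ``band=None`` plants a
    broadband (white) component instead of a band-limited one.  ``gain``
    maps a condition label value (e.g. "incorrect") to a coupling
    coefficient; the key "*" is the default.  A gain of 0 removes the
    edge for that condition.
    """

    source: str
    target: str
    delay_ms: float
    band: tuple[float, float] | None
    gain: dict[str, float] = field(default_factory=lambda: {"*": 1.0})
    window_ms: tuple[float, float] = (-200.0, 0.0)

    def __post_init__(self) -> None:
        if self.delay_ms < 0:
            raise ConfigError("coupling delay must be >= 0")
        if self.band is not None and not self.band[0] < self.band[1]:
            raise ConfigError(f"band must satisfy lo < hi, got {self.band}")
        if not self.window_ms[0] < self.window_ms[1]:
            raise ConfigError("coupling window start must precede end")
        if any(g < 0 for g in self.gain.values()):
            raise ConfigError("coupling gains must be >= 0")

    def delay_samples(self, fs: float) -> int:
        d = self.delay_ms * fs / 1000.0
        # sub-0.1-sample mismatch (tens of µs) is treated as rounding noise
        if abs(d - round(d)) > 0.1:
            raise ConfigError(
                f"coupling delay {self.delay_ms} ms is not a whole number of "
                f"samples at {fs} Hz"
            )
        return int(round(d))

    def gain_for(self, labels: pd.Series) -> float:
        for col in ("valence", "learned", "phase"):
            val = labels[col]
            if val in self.gain:
                return float(self.gain[val])
        return float(self.gain.get("*", 0.0))


@dataclass
class SynthConfig:
    """Full description of a synthetic session; see module docstring."""

    fs: float = 2048.0
    n_trials: int = 100
    pre: float = 1.0
    post: float = 1.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    erp_components: tuple = DEFAULT_ERPS
    phase_reset: tuple | None = (-200.0, (8.0, 12.0), 0.8)
    reset_amplitude: float = 1.0
    reset_duration_ms: float = 250.0
    couplings: tuple[CouplingSpec, ...] = ()
    background_osc: tuple = DEFAULT_BACKGROUND
    noise_sd: float = 1.0
    label_model: dict = field(
        default_factory=lambda: {"p_incorrect": 0.35, "p_learned": 0.5, "p_late": 0.5}
    )
    inter_trial_gap: float = 1.0
    stim_to_feedback: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError(f"fs must be positive, got {self.fs}")
        if self.n_trials < 0:
            raise ConfigError("n_trials must be >= 0")
        if self.pre <= 0 or self.post <= 0:
            raise ConfigError("pre and post padding must be positive")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        for side, c, w, a, pol in self.erp_components:
            if not math.isfinite(a) or not math.isfinite(c) or w <= 0:
                raise ConfigError("ERP components must have finite center/amplitude and width > 0")
        self.couplings = tuple(
            c if isinstance(c, CouplingSpec) else CouplingSpec(**c) for c in self.couplings
        )
        for c in self.couplings:
            c.delay_samples(self.fs)  # raises on non-integer delay

    @property
    def n_samples(self) -> int:
        return int(round(self.pre * self.fs)) + int(round(self.post * self.fs)) + 1

    @property
    def times(self) -> np.ndarray:
        n_pre = int(round(self.pre * self.fs))
        n_post = int(round(self.post * self.fs))
        return np.arange(-n_pre, n_post + 1) / self.fs

    def channel_indices(self, name: str) -> list[int]:
        """Expand a channel label or hemisphere name to channel indices."""
        if name in self.channels:
            return [self.channels.index(name)]
        idx = [i for i, c in enumerate(self.channels) if c.startswith(name)]
        if not idx:
            raise ConfigError(f"unknown channel or population {name!r}")
        return idx


# ---------------------------------------------------------------------------
# building blocks


def _band_noise(rng: np.random.Generator, shape, band, fs: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise along the last axis."""
    lo, hi = band
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _kappa_from_plv(plv: float) -> float:
    """Invert the von-Mises mean resultant length R(kappa) = I1/I0."""
    if plv <= 0:
        return 0.0
    if plv >= 0.999:
        return 1e3
    f = lambda k: special.i1e(k) / special.i0e(k) - plv
    return float(optimize.brentq(f, 1e-6, 1e3))


def _tukey_window_mask(times: np.ndarray, window_s, fs: float) -> np.ndarray:
    """Tapered 0/1 mask confining a component to a time window."""
    lo, hi = window_s
    mask = np.zeros_like(times)
    sel = (times >= lo - 0.5 / fs) & (times <= hi + 0.5 / fs)
    n = int(sel.sum())
    if n:
        mask[sel] = signal.windows.tukey(n, alpha=0.25)
    return mask


def _draw_labels(rng: np.random.Generator, n: int, model: dict) -> pd.DataFrame:
    p_inc = float(model.get("p_incorrect", 0.35))
    p_lrn = float(model.get("p_learned", 0.5))
    p_late = float(model.get("p_late", 0.5))
    return pd.DataFrame(
        {
            "valence": np.where(rng.random(n) < p_inc, "incorrect", "correct"),
            "learned": np.where(rng.random(n) < p_lrn, "learned", "unlearned"),
            "phase": np.where(rng.random(n) < p_late, "late", "early"),
        }
    )


def _render_trial(
    rng: np.random.Generator,
    labels: pd.Series,
    config: SynthConfig,
    include_noise: bool = True,
) -> np.ndarray:
    """Render one trial's event-locked components, (channels x samples)."""
    t = config.times
    n_ch, n = len(config.channels), config.n_samples
    x = np.zeros((n_ch, n))

    if include_noise:
        x += config.noise_sd * rng.standard_normal((n_ch, n))

    for lo, hi, sd in config.background_osc:
        x += sd * _band_noise(rng, (n_ch, n), (lo, hi), config.fs)

    for side, center_ms, width_ms, amp, pol in config.erp_components:
        bump = amp * pol * np.exp(-0.5 * ((t - center_ms / 1e3) / (width_ms / 1e3)) ** 2)
        if side == "both":
            x += bump
        else:
            x[config.channel_indices(side)] += bump

    if config.phase_reset is not None:
        t_r_ms, band, plv = config.phase_reset
        f0 = 0.5 * (band[0] + band[1])
        kappa = _kappa_from_plv(plv)
        phi = rng.vonmises(0.0, kappa) if kappa > 0 else rng.uniform(-np.pi, np.pi)
        env = _tukey_window_mask(
            t, (t_r_ms / 1e3, (t_r_ms + config.reset_duration_ms) / 1e3), config.fs
        )
        x += config.reset_amplitude * env * np.cos(
            2 * np.pi * f0 * (t - t_r_ms / 1e3) + phi
        )

    for spec in config.couplings:
        g = spec.gain_for(labels)
        d = spec.delay_samples(config.fs)
        if spec.band is None:
            s = rng.standard_normal(n)  # broadband (white) component
        else:
            s = _band_noise(rng, n, spec.band, config.fs)
        s *= _tukey_window_mask(
            t, (spec.window_ms[0] / 1e3, spec.window_ms[1] / 1e3), config.fs
        )
        x[config.channel_indices(spec.source)] += s
        if g > 0:
            delayed = np.zeros(n)
            if d < n:
                delayed[d:] = s[: n - d] if d else s
            x[config.channel_indices(spec.target)] += g * delayed
    return x


def _trial_streams(config: SynthConfig, n_extra: int = 2):
    children = np.random.SeedSequence(config.seed).spawn(config.n_trials + n_extra)
    extra = [np.random.default_rng(s) for s in children[: n_extra]]
    trials = [np.random.default_rng(s) for s in children[n_extra:]]
    return extra, trials


# ---------------------------------------------------------------------------
# public operations


def generate_epochs(config: SynthConfig, event_type: str = "feedback") -> EpochSet:
    """Directly emit event-locked epochs for ``event_type``.

    Epoch length is ``round(pre*fs) + round(post*fs) + 1`` samples
    (inclusive endpoints), so the default 2 s window at 2048 Hz has 4097
    samples.  Raises on an empty design or an unknown event type.
    """
    if event_type not in ("feedback", "stimulus"):
        raise ValueError(f"unknown event type {event_type!r}")
    if config.n_trials < 1:
        raise ConfigError("empty design: n_trials must be >= 1")
    (label_rng, _), trial_rngs = _trial_streams(config)
    labels = _draw_labels(label_rng, config.n_trials, config.label_model)
    data = np.empty((config.n_trials, len(config.channels), config.n_samples))
    for i, rng in enumerate(trial_rngs):
        data[i] = _render_trial(rng, labels.iloc[i], config)
    return EpochSet(
        data=data,
        fs=config.fs,
        times=config.times,
        channels=list(config.channels),
        labels=labels,
    )


def generate_session(config: SynthConfig) -> tuple[Recording, pd.DataFrame]:
    """Continuous recording plus an event table (one stimulus and one
    feedback event per trial).

    Trials are separated by ``inter_trial_gap`` seconds of pure noise;
    event-locked components are placed at the feedback time, and a small
    stimulus-locked bump at ``stim_to_feedback`` seconds before it.
    """
    if config.n_trials < 1:
        raise ConfigError("empty design: n_trials must be >= 1")
    fs = config.fs
    n_pre = int(round(config.pre * fs))
    block = int(round((config.inter_trial_gap + config.pre + config.stim_to_feedback + config.post) * fs))
    total = config.n_trials * block + int(round(config.post * fs))
    (label_rng, noise_rng), trial_rngs = _trial_streams(config)
    labels = _draw_labels(label_rng, config.n_trials, config.label_model)

    data = config.noise_sd * noise_rng.standard_normal((len(config.channels), total))
    t_epoch = config.times
    stim_bump = 0.8 * np.exp(-0.5 * ((t_epoch - 0.12) / 0.05) ** 2)

    rows = []
    gap = int(round(config.inter_trial_gap * fs))
    lead = int(round(config.stim_to_feedback * fs))
    for i, rng in enumerate(trial_rngs):
        stim = i * block + gap + n_pre
        fb = stim + lead
        comp = _render_trial(rng, labels.iloc[i], config, include_noise=False)
        data[:, fb - n_pre : fb - n_pre + config.n_samples] += comp
        data[:, stim - n_pre : stim - n_pre + config.n_samples] += stim_bump
        for ev_type, onset in (("stimulus", stim), ("feedback", fb)):
            rows.append(
                {
                    "onset_sample": onset,
                    "onset_s": onset / fs,
                    "type": ev_type,
                    **labels.iloc[i].to_dict(),
                }
            )
    events = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    rec = Recording(data=data, fs=fs, channels=list(config.channels))
    return rec, events


def planted_network(config: SynthConfig) -> DirectedNetwork:
    """Ground-truth directed network implied by the coupling list."""
    nodes: list[str] = []
    edges = []
    for spec in config.couplings:
        for name in (spec.source, spec.target):
            if name not in nodes:
                nodes.append(name)
        edges.append(
            NetworkEdge(
                source=spec.source,
                target=spec.target,
                lag_samples=spec.delay_samples(config.fs),
                strength=max(spec.gain.values(), default=0.0),
            )
        )
    hemis = {n: ("L" if str(n).startswith("L") else "R") for n in nodes}
    return DirectedNetwork(nodes=nodes, edges=edges, hemispheres=hemis)


# ---------------------------------------------------------------------------
# presets

#: lag of 45 samples at 2048 Hz — the pre-event inter-hemispheric coupling
ANTICIPATION_DELAY_MS = 45 * 1000.0 / 2048.0  # 21.97265625 ms
#: lag of 31 samples at 2048 Hz — the post-event response coupling
RESPONSE_DELAY_MS = 31 * 1000.0 / 2048.0  # 15.13671875 ms


def preset(name: str, n_trials: int = 200, seed: int = 0, fs: float = 2048.0) -> SynthConfig:
    """Named study-condition presets.

    ``paper_fb_anticipation``: left→right coupling in the 24–32 Hz band
    confined to the −200–0 ms pre-feedback window, lag 45 samples; the
    coupling gain does not depend on trial condition.

    ``paper_fb_response``: left→right coupling at 8–16 Hz in the
    100–500 ms post-feedback window, lag 31 samples, with a larger gain on
    incorrect than correct trials.
    """
    if name == "paper_fb_anticipation":
        couplings = (
            CouplingSpec(
                source="L",
                target="R",
                delay_ms=ANTICIPATION_DELAY_MS * 2048.0 / fs,
                band=(24.0, 32.0),
                gain={"*": 1.2},
                window_ms=(-200.0, 0.0),
            ),
        )
    elif name == "paper_fb_response":
        couplings = (
            CouplingSpec(
                source="L",
                target="R",
                delay_ms=RESPONSE_DELAY_MS * 2048.0 / fs,
                band=(8.0, 16.0),
                gain={"incorrect": 1.5, "correct": 0.8},
                window_ms=(100.0, 500.0),
            ),
        )
    else:
        raise ConfigError(f"unknown preset {name!r}")
    return SynthConfig(fs=fs, n_trials=n_trials, couplings=couplings, seed=seed)
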