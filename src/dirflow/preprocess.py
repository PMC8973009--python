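"""Continuous-recording preprocessing: filtering, epoching, per-trial
normalization, robust artifact screening, and mean interpolation.

The fixed stage order is filter -> epoch -> normalize -> reject ->
interpolate.  Normalization standardizes each trial-channel to zero mean
and unit variance (x_hat = (x - mu) / sigma over the epoch), so that
epochs are comparable across sessions and subjects; the removed (mu,
sigma) are kept for audit.  Artifact screening is a robust per-channel
peak-amplitude criterion (median + k * MAD over trials); rejected
trial-channels are replaced by the mean of the surviving trials on that
channel so per-condition trial counts stay balanced.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochSet, Recording, validate_events

logger = logging.getLogger(__name__)

BESSEL_ORDER = 4
NOTCH_HALF_WIDTH_HZ = 2.0


def highpass_notch(
    rec: Recording,
    hp_hz: float = 0.5,
    notch_hz_list: tuple[float, ...] = (50.0, 100.0, 150.0),
) -> Recording:
    """Zero-phase Bessel high-pass plus fixed band-stop notches.

    Fourth-order Bessel designs applied as second-order sections
    forward-backward (``sosfiltfilt``), so the net filter has no group
    delay.  Each notch is a band-stop of +-2 Hz around the line frequency.
    """
    nyq = rec.fs / 2.0
    for f0 in notch_hz_list:
        if f0 >= nyq:
            raise ValueError(f"notch {f0} Hz at or above Nyquist ({nyq} Hz)")
    if not hp_hz < min(notch_hz_list, default=nyq):
        raise ValueError("high-pass edge must lie below the notch frequencies")
    data = rec.data
    history = list(rec.filter_history)
    sos = signal.bessel(BESSEL_ORDER, hp_hz, btype="highpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, data, axis=-1)
    history.append(f"bessel order {BESSEL_ORDER} highpass {hp_hz} Hz zero-phase")
    for f0 in notch_hz_list:
        sos = signal.bessel(
            BESSEL_ORDER,
            [f0 - NOTCH_HALF_WIDTH_HZ, f0 + NOTCH_HALF_WIDTH_HZ],
            btype="bandstop",
            fs=rec.fs,
            output="sos",
        )
        data = signal.sosfiltfilt(sos, data, axis=-1)
        history.append(f"bessel order {BESSEL_ORDER} bandstop {f0}+-{NOTCH_HALF_WIDTH_HZ} Hz zero-phase")
    return Recording(data=data, fs=rec.fs, channels=list(rec.channels), filter_history=history)


def extract_epochs(
    rec: Recording,
    events: pd.DataFrame,
    pre_s: float = 1.0,
    post_s: float = 1.0,
    event_type: str = "feedback",
) -> EpochSet:
    """Cut fixed-length epochs around each event of ``event_type``.

    The window is inclusive of both endpoints: ``round(pre*fs) +
    round(post*fs) + 1`` samples (4097 for 1 s + 1 s at 2048 Hz).  Events
    too close to a recording edge are skipped with a warning, not an
    error.
    """
    validate_events(events, rec.n_samples)
    sel = events[events["type"] == event_type]
    n_pre = int(round(pre_s * rec.fs))
    n_post = int(round(post_s * rec.fs))
    rows, chunks = [], []
    for _, row in sel.iterrows():
        onset = int(row["onset_sample"])
        if onset - n_pre < 0 or onset + n_post >= rec.n_samples:
            logger.warning(
                "skipping %s event at sample %d: window exceeds recording bounds",
                event_type,
                onset,
            )
            continue
        chunks.append(rec.data[:, onset - n_pre : onset + n_post + 1])
        rows.append(row)
    if not chunks:
        raise ValueError(f"no usable {event_type!r} events")
    labels = pd.DataFrame(rows)[["valence", "learned", "phase"]]
    return EpochSet(
        data=np.stack(chunks),
        fs=rec.fs,
        times=np.arange(-n_pre, n_post + 1) / rec.fs,
        channels=list(rec.channels),
        labels=labels,
    )


def normalize(epochs: EpochSet) -> EpochSet:
    """Standardize every trial-channel to zero mean, unit variance.

    Uses the sample standard deviation (ddof=1).  A constant trial-channel
    (sigma = 0) cannot be standardized; it is flagged rejected and left
    untouched rather than divided.
    """
    out = epochs.copy()
    mu = out.data.mean(axis=-1)
    sd = out.data.std(axis=-1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d constant trial-channels flagged rejected", int(degenerate.sum()))
        out.rejected = out.rejected | degenerate
    safe_sd = np.where(degenerate, 1.0, sd)
    out.data = (out.data - mu[..., None]) / safe_sd[..., None]
    out.data[degenerate] = epochs.data[degenerate]
    out.norm_mu = mu
    out.norm_sd = sd
    return out


def reject_artifacts(epochs: EpochSet, k_mad: float = 5.0, pool: str = "per_channel") -> EpochSet:
    """Flag trial-channels whose peak |amplitude| is an outlier.

    A trial-channel is rejected when its peak absolute amplitude strictly
    exceeds ``median + k_mad * MAD`` of the peak amplitudes, computed per
    channel (default) or pooled over all channels (``pool="global"``).
    With MAD = 0 (e.g. identical trials) the threshold degenerates to the
    median and the strict inequality keeps everything.  The data are
    untouched; only the mask is updated.
    """
    if epochs.n_trials < 8:
        raise ValueError(
            f"need >= 8 trials for stable thresholds on channels {epochs.channels}; "
            f"got {epochs.n_trials}"
        )
    if pool not in ("per_channel", "global"):
        raise ValueError(f"unknown pooling {pool!r}")
    out = epochs.copy()
    peaks = np.abs(out.data).max(axis=-1)  # trials x channels
    if pool == "global":
        med = np.median(peaks)
        mad = np.median(np.abs(peaks - med))
    else:
        med = np.median(peaks, axis=0)
        mad = np.median(np.abs(peaks - med), axis=0)
    thresh = med + k_mad * mad
    out.rejected = out.rejected | (peaks > thresh)
    rate = out.rejected.mean()
    logger.info("artifact screening rejected %.2f%% of trial-channels", 100 * rate)
    return out


def interpolate_rejected(epochs: EpochSet) -> EpochSet:
    """Replace rejected trial-channels by the channel's surviving-trial mean.

    Keeps per-condition trial counts balanced for within-subject
    comparisons.  A channel with no surviving trials is unrecoverable and
    raises.
    """
    out = epochs.copy()
    for ch in range(out.n_channels):
        bad = out.rejected[:, ch]
        if not bad.any():
            continue
        if bad.all():
            raise ValueError(f"channel {out.channels[ch]!r} has no surviving trials")
        out.data[bad, ch, :] = out.data[~bad, ch, :].mean(axis=0)
    return out


def preprocess_epochs(
    rec: Recording,
    events: pd.DataFrame,
    event_type: str = "feedback",
    pre_s: float = 1.0,
    post_s: float = 1.0,
    hp_hz: float = 0.5,
    notch_hz_list: tuple[float, ...] = (50.0, 100.0, 150.0),
    k_mad: float = 5.0,
    interpolate: bool = True,
) -> EpochSet:
    """Full fixed-order preprocessing chain for one event type."""
    rec = highpass_notch(rec, hp_hz, notch_hz_list)
    epochs = extract_epochs(rec, events, pre_s, post_s, event_type)
    epochs = normalize(epochs)
    epochs = reject_artifacts(epochs, k_mad=k_mad)
    if interpolate:
        epochs = interpolate_rejected(epochs)
    return epochs
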