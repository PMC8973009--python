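"""Pointwise time-domain significance testing of event-locked responses.

Every test is run independently at each sample of the epoch and corrected
for multiplicity by Bonferroni division of the significance level by the
number of samples tested: a full 2 s epoch at 2048 Hz has 4097 samples,
so alpha = 1e-4 becomes an effective threshold of about 2.44e-8 per
sample.  Maximal runs of consecutively significant samples are reported
as intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class SignificanceTrace:
    """Per-sample statistic, p-value and Bonferroni-corrected verdicts."""

    times: np.ndarray
    statistic: np.ndarray
    p: np.ndarray
    alpha: float
    alpha_corrected: float
    intervals: list[tuple[float, float]] = field(default_factory=list)

    @property
    def significant(self) -> np.ndarray:
        return self.p < self.alpha_corrected


def significant_intervals(mask: np.ndarray, times: np.ndarray) -> list[tuple[float, float]]:
    """Maximal runs of True in ``mask`` as (start s, end s) intervals."""
    mask = np.asarray(mask, bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return [(float(times[a]), float(times[b])) for a, b in zip(starts, ends)]


def _finish(times, stat, p, alpha, n_samples) -> SignificanceTrace:
    alpha_c = alpha / n_samples
    trace = SignificanceTrace(
        times=times, statistic=stat, p=p, alpha=alpha, alpha_corrected=alpha_c
    )
    trace.intervals = significant_intervals(trace.significant, times)
    return trace


def _channel_average(epochs: EpochSet, channels) -> np.ndarray:
    """(trials x samples) mean over a channel subset (all channels if None)."""
    if channels is None:
        idx = np.arange(epochs.n_channels)
    else:
        idx = np.asarray([epochs.channels.index(c) if isinstance(c, str) else c for c in channels])
    return epochs.data[:, idx, :].mean(axis=1)


def pointwise_onesample(
    epochs: EpochSet,
    channels=None,
    alpha: float = 1e-4,
) -> SignificanceTrace:
    """Per-sample one-sample t-test of the across-trial mean against 0.

    Degenerate samples with zero across-trial variance get p = 0 when the
    mean is nonzero and p = 1 otherwise (logged).
    """
    x = _channel_average(epochs, channels)
    if x.shape[0] < 3:
        raise ValueError("need >= 3 trials")
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    if degenerate.any():
        logger.warning("%d samples with zero across-trial variance", int(degenerate.sum()))
        p[degenerate] = np.where(mean[degenerate] != 0, 0.0, 1.0)
        t[degenerate] = np.where(mean[degenerate] != 0, np.inf, 0.0)
    return _finish(epochs.times, t, p, alpha, x.shape[1])


def pointwise_contrast(
    epochs_a: EpochSet,
    epochs_b: EpochSet,
    channels=None,
    alpha: float = 1e-4,
) -> SignificanceTrace:
    """Per-sample Welch two-sample t-test between two epoch sets."""
    if epochs_a.times.shape != epochs_b.times.shape or not np.allclose(
        epochs_a.times, epochs_b.times
    ):
        raise ValueError("epoch sets must share the same time axis")
    a = _channel_average(epochs_a, channels)
    b = _channel_average(epochs_b, channels)
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    return _finish(epochs_a.times, t, p, alpha, a.shape[1])


def pointwise_anova(
    groups: list[EpochSet] | list[np.ndarray],
    times: np.ndarray | None = None,
    alpha: float = 1e-4,
) -> SignificanceTrace:
    """Per-sample one-way F-test across >= 2 groups (e.g. electrodes).

    Each group is an EpochSet (averaged over its channels) or a
    (trials x samples) array.
    """
    mats = []
    for g in groups:
        if isinstance(g, EpochSet):
            mats.append(_channel_average(g, None))
            if times is None:
                times = g.times
        else:
            mats.append(np.asarray(g, float))
    if len(mats) < 2:
        raise ValueError("need >= 2 groups")
    for m in mats:
        if m.shape[0] < 3:
            raise ValueError("every group needs >= 3 trials")
    if times is None:
        raise ValueError("times required for array groups")
    f, p = stats.f_oneway(*mats, axis=0)
    f = np.nan_to_num(f, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    return _finish(np.asarray(times), f, p, alpha, mats[0].shape[1])
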