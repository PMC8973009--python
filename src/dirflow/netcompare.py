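"""Condition-level comparison of network communication.

Two complementary views:

* ``pca_compare`` treats each trial's vectorized pairwise-coherence
  matrix as a point in pair space, reduces the pooled cloud with PCA,
  and tests condition differences on the leading component scores —
  avoiding a forest of correlated pairwise tests.
* ``band_compare`` is the band-wise two-sample contrast (learned vs
  unlearned and similar), on per-trial band coherence averaged over a
  pair set: inter-hemispheric pairs only ("cross_talk") or every pair
  ("all_pairs").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .containers import EpochSet
from .spectral import CANONICAL_BANDS, pairwise_matrix

logger = logging.getLogger(__name__)


@dataclass
class NetworkPCAResult:
    """PCA over per-trial pair-coherence vectors plus per-component tests."""

    scores: np.ndarray  # trials x n_components, pooled over groups
    group: np.ndarray  # 0/1 per trial
    loadings: np.ndarray  # n_components x n_pairs
    explained_variance_ratio: np.ndarray
    t: np.ndarray  # per component
    p_raw: np.ndarray
    p_corrected: np.ndarray
    alpha: float
    pair_names: list[str] = field(default_factory=list)

    @property
    def significant(self) -> np.ndarray:
        return self.p_corrected < self.alpha


@dataclass
class BandComparison:
    """Two-sample band-coherence contrast between trial groups."""

    band_name: str
    band: tuple[float, float]
    mode: str
    mean_a: float
    mean_b: float
    diff: float
    t: float
    p_raw: float
    p_corrected: float
    ci: tuple[float, float]
    n_a: int
    n_b: int


def _upper_triangle(mats: np.ndarray) -> np.ndarray:
    """(trials x n_pairs) vector of each matrix's upper triangle."""
    n = mats.shape[-1]
    iu = np.triu_indices(n, k=1)
    return mats[:, iu[0], iu[1]]


def pca_compare(
    mats_a: np.ndarray,
    mats_b: np.ndarray,
    n_components: int = 3,
    alpha: float = 1e-4,
    pair_names: list[str] | None = None,
) -> NetworkPCAResult:
    """PCA of pooled per-trial pair vectors; t-test per retained component.

    ``mats_a``/``mats_b`` are (trials x channels x channels) per-trial
    coherence matrices (or already-vectorized (trials x n_pairs) arrays).
    Scores are centered over the pooled trials; the per-component Welch
    t-test is Bonferroni-corrected over ``n_components``.  Constant pairs
    carry no information and are dropped with a warning.
    """
    va = _upper_triangle(mats_a) if mats_a.ndim == 3 else np.asarray(mats_a, float)
    vb = _upper_triangle(mats_b) if mats_b.ndim == 3 else np.asarray(mats_b, float)
    if va.shape[0] < 10 or vb.shape[0] < 10:
        raise ValueError("need >= 10 trials per condition")
    if va.shape[1] != vb.shape[1]:
        raise ValueError("pair orderings do not match")
    pooled = np.vstack([va, vb])
    keep = pooled.std(axis=0) > 0
    if not keep.all():
        logger.warning("dropping %d constant pair(s)", int((~keep).sum()))
        pooled = pooled[:, keep]
    n_components = min(n_components, pooled.shape[1], pooled.shape[0])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(pooled)
    group = np.concatenate([np.zeros(va.shape[0], int), np.ones(vb.shape[0], int)])
    t = np.empty(n_components)
    p = np.empty(n_components)
    for k in range(n_components):
        t[k], p[k] = stats.ttest_ind(scores[group == 0, k], scores[group == 1, k], equal_var=False)
    p_corr = np.minimum(1.0, p * n_components)
    names = pair_names or [f"p{i}" for i in range(va.shape[1])]
    return NetworkPCAResult(
        scores=scores,
        group=group,
        loadings=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        t=t,
        p_raw=p,
        p_corrected=p_corr,
        alpha=alpha,
        pair_names=[n for n, k in zip(names, keep) if k],
    )


def _pair_mask(channels: list[str], mode: str) -> np.ndarray:
    n = len(channels)
    mask = np.zeros((n, n), bool)
    for i in range(n):
        for j in range(i + 1, n):
            cross = channels[i][0] != channels[j][0]
            if mode == "all_pairs" or (mode == "cross_talk" and cross):
                mask[i, j] = True
    return mask


def per_trial_band_values(
    epochs: EpochSet,
    band: tuple[float, float],
    mode: str = "cross_talk",
    lag_ms: float = 0.0,
    window_ms: tuple[float, float] | None = None,
    **kwargs,
) -> np.ndarray:
    """Per-trial band coherence averaged over the selected pair set."""
    if mode not in ("cross_talk", "all_pairs"):
        raise ValueError(f"unknown mode {mode!r}")
    cm = pairwise_matrix(
        epochs, band=band, lag_ms=lag_ms, window_ms=window_ms, per_trial=True, **kwargs
    )
    mask = _pair_mask(cm.channels, mode)
    if not mask.any():
        raise ValueError(f"no pairs selected by mode {mode!r}")
    return cm.per_trial[:, mask].mean(axis=1)


def band_compare(
    epochs: EpochSet,
    group_by: str = "learned",
    band: tuple[float, float] | str = "beta",
    mode: str = "cross_talk",
    alpha: float = 0.05,
    n_comparisons: int = 1,
    lag_ms: float = 0.0,
    window_ms: tuple[float, float] | None = None,
    values: np.ndarray | None = None,
    unit: str = "trial",
    **kwargs,
) -> BandComparison:
    """Welch t contrast of per-trial band coherence between two groups.

    ``group_by`` names a label column with exactly two values; the first
    group in sorted order is "A" (e.g. learned < unlearned).  The p value
    is Bonferroni-corrected by ``n_comparisons`` (the number of band x
    mode contrasts run in the session).  The 95 % CI is on the mean
    difference A - B.  ``values`` may supply precomputed per-trial
    values to avoid recomputing coherence for every band.

    The sampling unit is the trial (pair-set mean per trial); with
    ``unit="pair"`` it is the contact pair instead (per-group mean
    coherence per pair), for the tabulation that treats pairs as
    replicates.
    """
    band_name = band if isinstance(band, str) else f"{band[0]:g}-{band[1]:g}Hz"
    band_hz = CANONICAL_BANDS[band] if isinstance(band, str) else tuple(band)
    groups = sorted(epochs.labels[group_by].unique())
    if len(groups) != 2:
        raise ValueError(f"{group_by!r} must have exactly 2 values, got {groups}")
    if unit == "pair":
        cm = pairwise_matrix(
            epochs, band=band_hz, lag_ms=lag_ms, window_ms=window_ms,
            per_trial=True, **kwargs
        )
        mask = _pair_mask(cm.channels, mode)
        if not mask.any():
            raise ValueError(f"no pairs selected by mode {mode!r}")
        sel_a = (epochs.labels[group_by] == groups[0]).to_numpy()
        a = cm.per_trial[sel_a][:, mask].mean(axis=0)
        b = cm.per_trial[~sel_a][:, mask].mean(axis=0)
    elif unit == "trial":
        if values is None:
            values = per_trial_band_values(
                epochs, band_hz, mode=mode, lag_ms=lag_ms, window_ms=window_ms,
                **kwargs
            )
        a = values[(epochs.labels[group_by] == groups[0]).to_numpy()]
        b = values[(epochs.labels[group_by] == groups[1]).to_numpy()]
    else:
        raise ValueError(f"unknown sampling unit {unit!r}")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 trials")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    diff = float(a.mean() - b.mean())
    # Welch CI on the mean difference
    se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    df = se**4 / (
        (a.var(ddof=1) / len(a)) ** 2 / (len(a) - 1)
        + (b.var(ddof=1) / len(b)) ** 2 / (len(b) - 1)
    )
    half = stats.t.ppf(0.975, df) * se
    return BandComparison(
        band_name=band_name,
        band=band_hz,
        mode=mode,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        diff=diff,
        t=float(t),
        p_raw=float(p),
        p_corrected=float(min(1.0, p * n_comparisons)),
        ci=(diff - half, diff + half),
        n_a=len(a),
        n_b=len(b),
    )


def band_table(
    epochs: EpochSet,
    group_by: str = "learned",
    bands: tuple[str, ...] = ("low_gamma", "high_gamma", "beta", "theta"),
    modes: tuple[str, ...] = ("cross_talk", "all_pairs"),
    **kwargs,
) -> list[BandComparison]:
    """All band x mode contrasts, Bonferroni over their total count."""
    n_comp = len(bands) * len(modes)
    out = []
    for mode in modes:
        for band in bands:
            out.append(
                band_compare(
                    epochs, group_by=group_by, band=band, mode=mode,
                    n_comparisons=n_comp, **kwargs
                )
            )
    return out
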