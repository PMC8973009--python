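"""ICA source decomposition of epoch sets.

Channels are unmixed into statistically independent sources with
fixed-point ICA (log-cosh contrast, PCA whitening), fitted on trials
concatenated along time so that per-trial source time courses remain
available downstream.  Components are ordered by explained variance and
sign-fixed so each source's largest-magnitude deflection is positive.
Sources are "functional" objects: no anatomical localization is implied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA

from .containers import EpochSet

logger = logging.getLogger(__name__)

#: below this mean |excess kurtosis| the mixture looks Gaussian and the
#: rotation is not identifiable
_GAUSSIAN_KURTOSIS_LIMIT = 0.25


@dataclass
class SourceModel:
    """Linear unmixing/mixing pair plus fit provenance.

    ``unmixing`` maps channel data (channels x samples, mean removed) to
    sources; ``mixing`` maps back.  ``explained_variance`` is per source,
    in the fit data, descending.
    """

    unmixing: np.ndarray  # n_sources x n_channels
    mixing: np.ndarray  # n_channels x n_sources
    mean: np.ndarray  # per-channel mean removed before unmixing
    channels: list[str]
    explained_variance: np.ndarray
    seed: int
    converged: bool
    n_iter: int
    low_confidence: bool = False
    source_epochs: EpochSet | None = None

    @property
    def n_sources(self) -> int:
        return self.unmixing.shape[0]

    def hemisphere_of(self, k: int) -> str:
        """Hemisphere carrying > 50 % of source k's mixing-weight L2 mass."""
        col = self.mixing[:, k]
        left = sum(col[i] ** 2 for i, c in enumerate(self.channels) if c.startswith("L"))
        return "L" if left > 0.5 * float(col @ col) else "R"


def _concatenate(epochs: EpochSet) -> np.ndarray:
    """channels x (trials * samples) matrix for fitting."""
    return epochs.data.transpose(1, 0, 2).reshape(epochs.n_channels, -1)


def fit_sources(
    epochs: EpochSet,
    n_sources: int | None = None,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    fit_on: str = "concatenated",
) -> SourceModel:
    """Fit fixed-point ICA on concatenated trials.

    ``n_sources`` defaults to the channel count and is reduced to the
    numerical rank of the data when the channels are linearly dependent.
    ``fit_on="average"`` fits on the across-trial mean instead of
    concatenated single trials (per-trial source time courses are still
    produced by projecting the trials through the fitted transform).
    The model records convergence and flags a low-confidence fit when all
    recovered sources look Gaussian (the ICA rotation is then not
    identifiable).
    """
    if fit_on == "concatenated":
        x = _concatenate(epochs)
    elif fit_on == "average":
        x = epochs.data.mean(axis=0)
    else:
        raise ValueError(f"unknown fit mode {fit_on!r}")
    n_ch, n_obs = x.shape
    n_sources = n_ch if n_sources is None else int(n_sources)
    if n_obs < 20 * n_ch**2:
        raise ValueError(
            f"need >= {20 * n_ch ** 2} observations for {n_ch} channels, got {n_obs}"
        )
    rank = int(np.linalg.matrix_rank(x - x.mean(axis=1, keepdims=True)))
    if n_sources > rank:
        logger.warning("rank-deficient data: reducing n_sources %d -> %d", n_sources, rank)
        n_sources = rank

    ica = FastICA(
        n_components=n_sources,
        algorithm="deflation",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    import warnings

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sources = ica.fit_transform(x.T).T  # n_sources x n_obs
        converged = not any("did not converge" in str(w.message) for w in caught)

    unmixing = ica.components_
    mixing = ica.mixing_
    mean = ica.mean_

    # order by variance explained in channel space: ||a_k||^2 * var(s_k)
    var = (mixing**2).sum(axis=0) * sources.var(axis=1)
    order = np.argsort(var)[::-1]
    unmixing, mixing, sources, var = unmixing[order], mixing[:, order], sources[order], var[order]

    # sign convention: largest |deflection| of each source is positive
    signs = np.sign(sources[np.arange(n_sources), np.abs(sources).argmax(axis=1)])
    signs[signs == 0] = 1.0
    unmixing *= signs[:, None]
    sources *= signs[:, None]
    mixing *= signs[None, :]

    kurt = np.abs(stats.kurtosis(sources, axis=1, fisher=True))
    low_confidence = bool(np.all(kurt < _GAUSSIAN_KURTOSIS_LIMIT)) or not converged
    if low_confidence:
        logger.warning(
            "low-confidence decomposition (converged=%s, mean |kurtosis|=%.3f)",
            converged,
            float(kurt.mean()),
        )

    total_var = x.var(axis=1).sum()
    model = SourceModel(
        unmixing=unmixing,
        mixing=mixing,
        mean=mean,
        channels=list(epochs.channels),
        explained_variance=var / total_var,
        seed=seed,
        converged=converged,
        n_iter=int(np.max(ica.n_iter_)) if np.ndim(ica.n_iter_) else int(ica.n_iter_),
        low_confidence=low_confidence,
    )
    model.source_epochs = project(epochs, model)
    return model


def project(epochs: EpochSet, model: SourceModel) -> EpochSet:
    """Apply the unmixing to an epoch set, keeping trial labels.

    The result is an EpochSet in source space ("channels" are source
    names, with hemisphere attribution in the label).  Inverse of
    :func:`backproject` to within numerical precision when
    ``n_sources == n_channels``.
    """
    if list(epochs.channels) != list(model.channels):
        raise ValueError("channel labels do not match the fitted model")
    centered = epochs.data - model.mean[None, :, None]
    src = np.einsum("kc,tcs->tks", model.unmixing, centered)
    names = [f"S{k}:{model.hemisphere_of(k)}" for k in range(model.n_sources)]
    return replace(
        epochs.copy(),
        data=src,
        channels=names,
        rejected=np.zeros((epochs.n_trials, model.n_sources), bool),
        norm_mu=None,
        norm_sd=None,
    )


def backproject(source_epochs: EpochSet, model: SourceModel) -> np.ndarray:
    """Map source-space epochs back to channel space."""
    return (
        np.einsum("ck,tks->tcs", model.mixing, source_epochs.data)
        + model.mean[None, :, None]
    )
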