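"""End-to-end orchestration of the analysis stages.

``run_full`` executes preprocess -> evoked -> sources -> coherence ->
directed inference -> network comparison on either a synthetic preset or
an on-disk recording + event table, writing every stage artifact and a
manifest (stage list, input hashes, seed, package version) into the
output directory.  Stages communicate only through serialized artifacts;
a stage failure aborts the run with the stage name while keeping the
partial outputs and log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, io, synth
from .containers import ConfigError
from .directed import granger_scan, infer_network
from .evoked import pointwise_contrast, pointwise_onesample
from .netcompare import band_table, pca_compare
from .preprocess import preprocess_epochs
from .sources import fit_sources
from .spectral import lagged_coherence, pairwise_matrix, peak_lag

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "evoked", "sources", "coherence", "directed", "compare")


@dataclass
class PipelineConfig:
    """Everything one run needs; echoed verbatim into the output."""

    out_dir: str
    recording: str | None = None
    events: str | None = None
    preset: str | None = "paper_fb_anticipation"
    n_trials: int = 100
    event_type: str = "feedback"
    window_ms: tuple[float, float] = (-200.0, 0.0)
    band: tuple[float, float] = (24.0, 32.0)
    lag_range_ms: tuple[float, float] = (0.0, 50.0)
    granger_order: int = 20
    te_history: int = 5
    te_tau_range: tuple[int, int] = (1, 64)
    te_tau_step: int = 4
    n_surrogates: int = 200
    alpha: float = 1e-4
    alpha_edge: float = 0.05
    seed: int = 0
    interpolate: bool = True
    fs: float = 2048.0

    def validate(self) -> None:
        if self.preset is None:
            for p in (self.recording, self.events):
                if p is None or not Path(p).exists():
                    raise ConfigError(f"input file missing: {p}")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_full(config: PipelineConfig) -> dict:
    """Run every stage; return the manifest dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(dataclasses.asdict(config), indent=1))
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "artifacts": {},
    }
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("dirflow")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    def record(stage: str, artifacts: dict) -> None:
        entry = {
            "stage": stage,
            "completed": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "inputs": {
                k: _hash_file(Path(v)) for k, v in manifest["artifacts"].items()
            },
        }
        manifest["stages"].append(entry)
        manifest["artifacts"].update({k: str(v) for k, v in artifacts.items()})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    current = "preprocess"
    try:
        # ------------------------------------------------------ preprocess
        if config.preset is not None:
            cfg = synth.preset(config.preset, n_trials=config.n_trials,
                               seed=config.seed, fs=config.fs)
            rec, events = synth.generate_session(cfg)
            logger.info("synthetic session: preset=%s n_trials=%d", config.preset, config.n_trials)
        else:
            rec = io.read_recording(config.recording)
            events = io.read_events(config.events)
        epochs = preprocess_epochs(
            rec, events, event_type=config.event_type, interpolate=config.interpolate
        )
        ep_path = io.write_epochs(epochs, out, "epochs")
        record("preprocess", {"epochs": ep_path})

        # ---------------------------------------------------------- evoked
        current = "evoked"
        trace = pointwise_onesample(epochs, alpha=config.alpha)
        io.write_significance_trace(trace, out / "evoked_onesample.tsv")
        by_val = {
            v: epochs.data[(epochs.labels["valence"] == v).to_numpy()]
            for v in ("correct", "incorrect")
        }
        if all(len(v) >= 3 for v in by_val.values()):
            import dataclasses as dc

            a = dc.replace(epochs.copy(), data=by_val["correct"],
                           labels=epochs.labels[epochs.labels.valence == "correct"],
                           rejected=None)
            b = dc.replace(epochs.copy(), data=by_val["incorrect"],
                           labels=epochs.labels[epochs.labels.valence == "incorrect"],
                           rejected=None)
            trace_c = pointwise_contrast(a, b, alpha=config.alpha)
            io.write_significance_trace(trace_c, out / "evoked_valence_contrast.tsv")
        record("evoked", {"evoked": out / "evoked_onesample.tsv"})

        # --------------------------------------------------------- sources
        current = "sources"
        model = fit_sources(epochs, seed=config.seed)
        io.write_source_model(model, out / "source_model.json")
        record("sources", {"source_model": out / "source_model.json"})

        # ------------------------------------------------------- coherence
        current = "coherence"
        profile = lagged_coherence(
            epochs.side_mean("L"), epochs.side_mean("R"), epochs.fs, epochs.times,
            config.band, config.window_ms, lag_range_ms=config.lag_range_ms,
        )
        lag_ms, value, degenerate = peak_lag(profile)
        io.dataclass_to_json(
            {
                "lags_ms": profile.lags_ms,
                "coherence": profile.values,
                "peak_lag_ms": lag_ms,
                "peak_coherence": value,
                "degenerate": degenerate,
            },
            out / "lag_coherence.json",
        )
        cm = pairwise_matrix(
            epochs, band=config.band, lag_ms=lag_ms, window_ms=config.window_ms
        )
        io.dataclass_to_json(cm, out / "pairwise_coherence.json")
        record("coherence", {"lag_coherence": out / "lag_coherence.json"})

        # -------------------------------------------------------- directed
        current = "directed"
        gr = granger_scan(
            epochs.side_mean("L"), epochs.side_mean("R"), epochs.fs, epochs.times,
            config.window_ms, lag_range_ms=config.lag_range_ms,
            order=config.granger_order, names=("L", "R"),
        )
        io.dataclass_to_json(gr, out / "granger_LR.json")
        src_epochs = model.source_epochs
        net = infer_network(
            src_epochs,
            tau_range=config.te_tau_range,
            tau_step=config.te_tau_step,
            hist=config.te_history,
            alpha_edge=config.alpha_edge,
            n_surrogates=config.n_surrogates,
            seed=config.seed,
        )
        io.write_network(net, out / "te_network.json")
        record("directed", {"te_network": out / "te_network.json"})

        # --------------------------------------------------------- compare
        current = "compare"
        labels = epochs.labels["valence"]
        cm_trials = pairwise_matrix(
            epochs, band=config.band, lag_ms=lag_ms, window_ms=config.window_ms,
            per_trial=True,
        )
        mask_a = (labels == "correct").to_numpy()
        results = {}
        if mask_a.sum() >= 10 and (~mask_a).sum() >= 10:
            pca_res = pca_compare(
                cm_trials.per_trial[mask_a], cm_trials.per_trial[~mask_a]
            )
            results["pca_valence"] = {
                "explained_variance_ratio": pca_res.explained_variance_ratio,
                "t": pca_res.t,
                "p_corrected": pca_res.p_corrected,
            }
        table = band_table(epochs, group_by="learned", window_ms=config.window_ms)
        results["band_table"] = [dataclasses.asdict(row) for row in table]
        io.dataclass_to_json(results, out / "network_compare.json")
        record("compare", {"network_compare": out / "network_compare.json"})
    except Exception:
        logger.exception("stage %r failed; partial outputs kept in %s", current, out)
        manifest["failed_stage"] = current
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        root.removeHandler(handler)
        raise
    root.removeHandler(handler)
    return manifest
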