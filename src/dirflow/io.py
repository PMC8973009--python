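"""File I/O: recordings, event tables, epochs, models and networks.

Recordings travel either as EDF (read via MNE when available) or as a
plain-text format: a TSV numeric matrix (one column per channel) next to
a JSON sidecar holding the sampling rate and channel labels.  Epoch sets
are stored as a compressed ``.npz`` array container with a JSON sidecar
for the metadata.  Everything else (events, networks, models, result
tables) is TSV or JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    DirectedNetwork,
    EVENT_COLUMNS,
    EpochSet,
    NetworkEdge,
    Recording,
    validate_events,
)


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as ``<stem>.tsv`` plus ``<stem>.json`` sidecar."""
    path = Path(path)
    stem = path.with_suffix("")
    tsv = stem.with_suffix(".tsv")
    np.savetxt(tsv, rec.data.T, delimiter="\t", fmt="%.6f", header="\t".join(rec.channels), comments="")
    sidecar = {
        "fs": rec.fs,
        "channels": rec.channels,
        "filter_history": rec.filter_history,
        "units": "uV",
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return tsv


def read_recording(path: str | Path) -> Recording:
    """Read an EDF file or a TSV matrix with its JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(
            data=raw.get_data() * 1e6,  # volts -> µV
            fs=float(raw.info["sfreq"]),
            channels=list(raw.ch_names),
        )
    sidecar = json.loads(path.with_suffix(".json").read_text())
    frame = pd.read_csv(path, sep="\t")
    return Recording(
        data=frame.to_numpy().T,
        fs=float(sidecar["fs"]),
        channels=sidecar.get("channels", list(frame.columns)),
        filter_history=sidecar.get("filter_history", []),
    )


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    events[list(EVENT_COLUMNS)].to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    return validate_events(events)


def write_epochs(epochs: EpochSet, directory: str | Path, name: str = "epochs") -> Path:
    """Array container (.npz) + JSON sidecar for one epoch set."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {"data": epochs.data, "times": epochs.times, "rejected": epochs.rejected}
    if epochs.norm_mu is not None:
        arrays["norm_mu"] = epochs.norm_mu
        arrays["norm_sd"] = epochs.norm_sd
    np.savez_compressed(directory / f"{name}.npz", **arrays)
    sidecar = {
        "fs": epochs.fs,
        "channels": epochs.channels,
        "labels": epochs.labels.to_dict(orient="list"),
    }
    (directory / f"{name}.json").write_text(json.dumps(sidecar, indent=1))
    return directory / f"{name}.npz"


def read_epochs(directory: str | Path, name: str = "epochs") -> EpochSet:
    directory = Path(directory)
    arrays = np.load(directory / f"{name}.npz")
    sidecar = json.loads((directory / f"{name}.json").read_text())
    return EpochSet(
        data=arrays["data"],
        fs=float(sidecar["fs"]),
        times=arrays["times"],
        channels=sidecar["channels"],
        labels=pd.DataFrame(sidecar["labels"]),
        rejected=arrays["rejected"],
        norm_mu=arrays["norm_mu"] if "norm_mu" in arrays else None,
        norm_sd=arrays["norm_sd"] if "norm_sd" in arrays else None,
    )


def write_network(net: DirectedNetwork, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "nodes": [
            {"id": n, "hemisphere": net.hemispheres.get(n)} for n in net.nodes
        ],
        "edges": [
            {
                "from": e.source,
                "to": e.target,
                "lag_samples": e.lag_samples,
                "strength": e.strength,
                "p": e.p,
            }
            for e in net.edges
        ],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_network(path: str | Path) -> DirectedNetwork:
    payload = json.loads(Path(path).read_text())
    nodes = [n["id"] for n in payload["nodes"]]
    hemis = {n["id"]: n.get("hemisphere") for n in payload["nodes"]}
    edges = [
        NetworkEdge(
            source=e["from"],
            target=e["to"],
            lag_samples=int(e["lag_samples"]),
            strength=float(e.get("strength", 0.0)),
            p=e.get("p"),
        )
        for e in payload["edges"]
    ]
    return DirectedNetwork(nodes=nodes, edges=edges, hemispheres=hemis)


def write_source_model(model, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "unmixing": model.unmixing.tolist(),
        "mixing": model.mixing.tolist(),
        "mean": model.mean.tolist(),
        "channels": model.channels,
        "explained_variance": model.explained_variance.tolist(),
        "seed": model.seed,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "low_confidence": model.low_confidence,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_source_model(path: str | Path):
    from .sources import SourceModel

    payload = json.loads(Path(path).read_text())
    return SourceModel(
        unmixing=np.asarray(payload["unmixing"]),
        mixing=np.asarray(payload["mixing"]),
        mean=np.asarray(payload["mean"]),
        channels=payload["channels"],
        explained_variance=np.asarray(payload["explained_variance"]),
        seed=payload["seed"],
        converged=payload["converged"],
        n_iter=payload["n_iter"],
        low_confidence=payload["low_confidence"],
    )


def write_significance_trace(trace, path: str | Path) -> Path:
    """TSV (time, statistic, p, significant) + JSON interval summary."""
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": trace.times,
            "statistic": trace.statistic,
            "p": trace.p,
            "significant": trace.significant.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)
    summary = {
        "alpha": trace.alpha,
        "alpha_corrected": trace.alpha_corrected,
        "intervals_s": trace.intervals,
    }
    path.with_suffix(".intervals.json").write_text(json.dumps(summary, indent=1))
    return path


def dataclass_to_json(obj, path: str | Path) -> Path:
    """Serialize a simple results dataclass (numpy-aware) to JSON."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not serializable: {type(o)}")

    path = Path(path)
    payload = dataclasses.asdict(obj) if dataclasses.is_dataclass(obj) else obj
    path.write_text(json.dumps(payload, indent=1, default=default))
    return path
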