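"""Condition-level network comparison.

PCA over per-trial pairwise-coherence vectors tests whether the overall
communication pattern differs by feedback valence; the band table runs
the learned-vs-unlearned coherence contrasts for the canonical bands,
inter-hemispheric cross-talk and all pairs separately.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np

from dirflow import io
from dirflow.netcompare import band_table, pca_compare
from dirflow.spectral import pairwise_matrix

RESULTS = Path(__file__).resolve().parent.parent / "results"

session = RESULTS / "paper_fb_response"
epochs = io.read_epochs(session)
window_ms = (100.0, 500.0)

cm = pairwise_matrix(epochs, band=(8.0, 16.0), lag_ms=15.0,
                     window_ms=window_ms, per_trial=True)
sel = (epochs.labels["valence"] == "correct").to_numpy()
res = pca_compare(cm.per_trial[sel], cm.per_trial[~sel])
print("valence PCA: explained variance "
      f"{np.round(res.explained_variance_ratio, 3).tolist()}, "
      f"corrected p per component {[f'{p:.3g}' for p in res.p_corrected]}")
(session / "pca_valence.json").write_text(json.dumps({
    "explained_variance_ratio": res.explained_variance_ratio.tolist(),
    "t": res.t.tolist(),
    "p_corrected": res.p_corrected.tolist(),
}, indent=1))

table = band_table(epochs, group_by="learned", window_ms=window_ms)
(session / "band_table.json").write_text(
    json.dumps([dataclasses.asdict(r) for r in table], indent=1))
print(f"{'mode':<11} {'band':<11} {'learned':>8} {'unlearned':>10} "
      f"{'p(corr)':>9}  95% CI")
for r in table:
    print(f"{r.mode:<11} {r.band_name:<11} {r.mean_a:8.4f} {r.mean_b:10.4f} "
          f"{r.p_corrected:9.3g}  [{r.ci[0]:.4f}, {r.ci[1]:.4f}]")
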