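"""Pointwise significance of the event-locked waveforms.

Across-trial one-sample tests localize the planted response components
(pre-feedback negativity, post-feedback double peak); the left-right
contrast and the per-electrode analysis of variance probe the spatial
structure.  All tests use alpha = 1e-4 Bonferroni-corrected over the
4097 samples of the 2 s epoch.
"""

import dataclasses
from pathlib import Path

from dirflow import io
from dirflow.evoked import pointwise_anova, pointwise_contrast, pointwise_onesample

RESULTS = Path(__file__).resolve().parent.parent / "results"
session = RESULTS / "paper_fb_anticipation"

epochs = io.read_epochs(session)

trace = pointwise_onesample(epochs)
io.write_significance_trace(trace, session / "evoked_onesample.tsv")
print(f"across-trial response: alpha_c = {trace.alpha_corrected:.2e}, "
      f"significant intervals (s): {[(round(a, 3), round(b, 3)) for a, b in trace.intervals]}")

left = dataclasses.replace(
    epochs.copy(), data=epochs.data[:, epochs.side_indices("L"), :],
    channels=[c for c in epochs.channels if c.startswith("L")], rejected=None,
)
right = dataclasses.replace(
    epochs.copy(), data=epochs.data[:, epochs.side_indices("R"), :],
    channels=[c for c in epochs.channels if c.startswith("R")], rejected=None,
)
contrast = pointwise_contrast(left, right)
io.write_significance_trace(contrast, session / "evoked_left_vs_right.tsv")
print(f"left vs right: {len(contrast.intervals)} significant interval(s)")

groups = [epochs.data[:, ch, :] for ch in range(epochs.n_channels)]
anova = pointwise_anova(groups, times=epochs.times)
io.write_significance_trace(anova, session / "evoked_electrode_anova.tsv")
print(f"between-electrode F: {len(anova.intervals)} significant interval(s)")
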