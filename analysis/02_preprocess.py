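"""Filter, epoch, normalize and screen the simulated sessions.

Reads the continuous recordings from step 01, applies the fixed chain
(zero-phase high-pass + notches -> 2 s feedback-locked epochs ->
per-trial z-normalization -> median+5*MAD peak screening -> mean
interpolation) and stores the epoch sets every later step consumes.
"""

from pathlib import Path

from dirflow import io
from dirflow.preprocess import preprocess_epochs

RESULTS = Path(__file__).resolve().parent.parent / "results"

for name in ("paper_fb_anticipation", "paper_fb_response"):
    session = RESULTS / name
    rec = io.read_recording(session / "recording.tsv")
    events = io.read_events(session / "events.tsv")
    epochs = preprocess_epochs(rec, events, event_type="feedback")
    io.write_epochs(epochs, session)
    n_rej = int(epochs.rejected.sum())
    print(
        f"{name}: {epochs.n_trials} trials x {epochs.n_channels} channels x "
        f"{epochs.n_samples} samples; {n_rej} trial-channels "
        f"({100 * n_rej / epochs.rejected.size:.1f}%) screened and interpolated"
    )
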