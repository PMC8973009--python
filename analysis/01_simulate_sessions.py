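"""Simulate the two study sessions and write them to disk.

One session per coupling preset: the pre-feedback (anticipation) session
plants a left->right 24-32 Hz coupling lagged 45 samples in the -200-0 ms
window; the post-feedback (response) session plants an 8-16 Hz coupling
lagged 31 samples in the 100-500 ms window whose gain is larger on
incorrect trials.  Trial counts are reduced for a desk-scale run; the
statistical structure is unchanged.
"""

from pathlib import Path

from dirflow import io, synth

OUT = Path(__file__).resolve().parent.parent / "results"
N_TRIALS = 60
SEED = 1

for name in ("paper_fb_anticipation", "paper_fb_response"):
    cfg = synth.preset(name, n_trials=N_TRIALS, seed=SEED)
    rec, events = synth.generate_session(cfg)
    out = OUT / name
    out.mkdir(parents=True, exist_ok=True)
    io.write_recording(rec, out / "recording.tsv")
    io.write_events(events, out / "events.tsv")
    io.write_network(synth.planted_network(cfg), out / "ground_truth.json")
    print(
        f"{name}: {rec.n_channels} channels x {rec.n_samples} samples "
        f"({rec.duration:.0f} s at {rec.fs:.0f} Hz), {len(events)} events, "
        f"ground truth {sorted(synth.planted_network(cfg).edge_set())}"
    )
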