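# dirflow

Directed-connectivity analysis of event-locked bilateral local field
potentials (LFPs).

Invasive recordings from the human dorsal anterior cingulate cortex
(dACC) — six bipolar channels, three per hemisphere, sampled at
2048 Hz during a feedback-learning task — show event-locked responses
whose timing differs between hemispheres, suggesting that the left side
signals the right with a short transmission delay. `dirflow` implements
the full analysis chain needed to quantify that claim, for anyone
working with event-locked multichannel electrophysiology:

1. **Preprocessing** — zero-phase Bessel filtering (0.5 Hz high-pass,
   50/100/150 Hz notches), 2 s event-locked epoching, per-trial
   z-normalization `x̂_t = (x_t − μ)/σ`, robust artifact screening
   (median + 5·MAD on peak amplitudes), mean interpolation of rejected
   trials.
2. **Evoked statistics** — pointwise t/F tests with Bonferroni
   correction over the samples tested (α/4097 for a 2 s epoch).
3. **Source decomposition** — fixed-point ICA into statistically
   independent sources with hemisphere attribution.
4. **Lag-scanned coherence** — magnitude-squared coherence
   `C_xy(f) = |G_xy(f)|² / (G_xx(f)·G_yy(f))` with the second signal's
   analysis window offset by τ, scanned over ±50 ms to localize the
   timing of inter-hemispheric communication.
5. **Granger causality** — F-tests of whether lagged source values
   improve an AR prediction of the (first-differenced) target, scanned
   over single lags and checked across model orders 20–50.
6. **Transfer entropy** —
   `T_{X→Y} = H(Y_t|Y_{t−1:t−L}) − H(Y_t|Y_{t−1:t−L}, X_{t−1:t−L})`,
   multivariate (all other sources in the conditioning set), with
   circular-shift surrogate significance; used to infer a directed
   network with per-edge lags.
7. **Network comparison** — PCA over per-trial pairwise-coherence
   vectors and band-wise (theta/beta/low-gamma/high-gamma) contrasts
   between trial conditions.

Patient recordings of this kind are not publicly distributable, so the
package includes a synthetic session generator (`dirflow.synth`) that
plants every structure the pipeline measures — ERP components, a
pre-event phase reset, band-limited oscillations, and directed
inter-hemispheric coupling with configurable delay and
condition-dependent gain — along with the ground-truth network, so each
stage has a known recovery target. See `docs/methods.md` for the model
and estimator details.

## Worked example

Simulate a session with the pre-feedback coupling preset (left→right,
24–32 Hz, planted delay 45 samples ≈ 22 ms at 2048 Hz) and recover the
delay:

```python
from dirflow import synth
from dirflow.spectral import lagged_coherence, peak_lag

cfg = synth.preset("paper_fb_anticipation", n_trials=200, seed=0)
epochs = synth.generate_epochs(cfg)
profile = lagged_coherence(
    epochs.side_mean("L"), epochs.side_mean("R"),
    epochs.fs, epochs.times,
    band=(24.0, 32.0), window_ms=(-200.0, 0.0), lag_range_ms=(0.0, 50.0),
)
lag_ms, value, _ = peak_lag(profile)
print(f"peak left->right coherence {value:.3f} at {lag_ms:.2f} ms")
```

```
peak left->right coherence 0.977 at 21.97 ms
```

The peak sits at the planted 45-sample delay: the left hemisphere's
band-limited activity reappears on the right 22 ms later, and the lag
scan localizes that delay to the sample.

The same session end to end, from the shell:

```sh
dirflow simulate --preset paper_fb_anticipation --n-trials 60 --seed 1 --out session/
dirflow run-full --preset paper_fb_anticipation --n-trials 60 --seed 1 --out run/
```

The numbered scripts under `analysis/` run the complete study on both
presets — simulation, preprocessing, evoked statistics, ICA, lag-scanned
coherence, Granger/transfer-entropy inference, and the condition-level
network comparison — writing their tables under `results/`.

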