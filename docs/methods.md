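# Methods

`dirflow` analyzes event-locked directed communication in bilateral
multichannel local field potential (LFP) recordings: six bipolar
channels (three per hemisphere), sampled at 2048 Hz, epoched around
behavioral events (stimulus or feedback) with condition labels per trial
(outcome valence, rule learned/unlearned, early/late phase).  Because
such recordings are rare and restricted, the package ships a synthetic
session generator whose planted structure gives every analysis stage a
known recovery target.  This note records the models, the parameters
that matter, and the numerical choices that were genuinely open.

## Synthetic sessions

Each trial epoch is the sum of independent parts, per channel:

* **Event-related components** — Gaussian bumps
  `a · p · exp(−(t−c)²/2w²)` with side, center `c` (ms), width `w` (ms),
  amplitude `a` and polarity `p`.  Defaults: a negativity centered at
  −250 ms (movement/anticipation), positive peaks at +200 and +400 ms
  (the double-peaked post-feedback response).  Widths ≥ 50 ms keep their
  spectral content below ~8 Hz, outside the coherence analysis bands.
* **Background oscillations** — band-limited Gaussian noise (zero-phase
  Butterworth-filtered white noise, unit variance) in theta (4–8 Hz),
  beta (15–25 Hz) and gamma (30–60 Hz), independent per channel and
  trial: they contribute realistic spectra but no cross-channel
  coherence.
* **Phase reset** — a 10 Hz cosine whose phase at the reset time
  (−200 ms) is shared across channels, drawn per trial from a von Mises
  distribution whose concentration is solved from the requested
  phase-locking value (mean resultant length `I₁(κ)/I₀(κ)`); a Tukey
  envelope confines it to the 250 ms after the reset.  This reproduces
  rising inter-trial phase locking without a biophysical model.
* **Directed coupling** — a stochastic component `s(t)` (band-limited,
  or white when `band=None`), Tukey-confined to the coupling window, is
  added to the source channel(s); the target channel(s) receive
  `gain · s(t − d)`.  The delay `d` must be a whole number of samples
  (a mismatch below 0.1 sample — tens of microseconds — is treated as
  rounding noise).  The gain may depend on a condition label, which is
  how valence- and learning-dependent communication is planted.
* **White observation noise**, `noise_sd` per sample.

All randomness descends from one master seed through per-trial
`SeedSequence` children, so sessions are bitwise reproducible and
independent of trial evaluation order.  Continuous sessions concatenate
trials with 1 s noise gaps (stimulus 1.2 s before feedback), preventing
epoch overlap at the default ±1 s padding.

Two presets encode the study conditions: `paper_fb_anticipation`
(left→right, 24–32 Hz, −200–0 ms window, delay 45 samples ≈ 22 ms,
condition-independent gain 1.2) and `paper_fb_response` (left→right,
8–16 Hz, 100–500 ms window, delay 31 samples ≈ 15 ms, gain 1.5 on
incorrect vs 0.8 on correct trials).  The delays are stored as exact
sample counts at 2048 Hz; the gains and noise scale are calibration
choices — the source recordings report no effect sizes — fixed once at
values giving peak band coherence ≈ 0.9 at 200 trials.

What the generator does **not** emulate: volume conduction and common
reference artifacts, 1/f background spectra, nonstationary impedance
drift, true oscillatory bursting, or any biophysical dynamics.  Passing
recovery tests therefore demonstrates that the estimators measure what
they claim on signals with planted ground truth — not that real dACC
recordings contain such structure.

## Preprocessing

Fixed order: filter → epoch → normalize → reject → interpolate.

* Zero-phase filtering: fourth-order Bessel designs (high-pass 0.5 Hz;
  band-stop ±2 Hz at 50/100/150 Hz) as second-order sections applied
  forward–backward.  The filter order is not dictated by the upstream
  description; order 4 is recorded in the recording's filter history.
* Epochs include both endpoints: `round(pre·fs) + round(post·fs) + 1`
  samples — 4097 for ±1 s at 2048 Hz, which is the Bonferroni
  denominator used throughout.
* Normalization is per trial-channel: subtract the epoch mean, divide by
  the sample standard deviation (ddof 1).  The removed (μ, σ) are kept.
  A constant epoch is flagged rejected rather than divided.
* Artifact screening is a robust peak-amplitude criterion: per channel,
  a trial is rejected when its peak |amplitude| strictly exceeds
  `median + k·MAD` over trials (default k = 5).  The criterion operates
  on normalized data, per channel; both choices are exposed because the
  source description fixes neither.  On Gaussian noise this tail
  criterion rejects ~1–3 % of clean trials — the regime the default was
  chosen for; k = 8 is effectively zero-false-positive.
* Rejected trial-channels are replaced by the mean of surviving trials
  on that channel (on the normalized scale, where a cross-trial mean is
  meaningful), keeping per-condition trial counts balanced.  Every
  analysis can be re-run with interpolation disabled; the acceptance
  suite checks that doing so flips no verdict.

## Pointwise waveform statistics

One-sample t (across trials vs 0), Welch two-sample t (between
conditions or sides), and one-way F (across electrodes) at every epoch
sample, with Bonferroni correction `α_c = α / n_samples` (α = 1e-4
default; 1e-4/4097 ≈ 2.4e-8).  Parametric tests were chosen because the
analysis tradition this follows reports classical thresholds, and
cluster-based correction is deliberately not used.  Zero-variance
samples get p = 0 (nonzero mean) or 1.  Significant samples are reported
as maximal runs; the run extraction is property-tested against a
run-length-encoding reference.

## Source decomposition

Fixed-point ICA (scikit-learn FastICA, deflation, log-cosh contrast,
PCA whitening, ≤ 200 iterations, tolerance 1e-6) on trials concatenated
along time — concatenation rather than the across-trial average, so
per-trial source time courses exist for the directed stages.  Components
are ordered by explained channel-space variance and sign-fixed (largest
deflection positive).  Sources are attributed to the hemisphere holding
> 50 % of their mixing-weight L2 mass.  A fit is flagged low-confidence
when it fails to converge or all sources look Gaussian (|excess
kurtosis| < 0.25), where the rotation is unidentifiable.  Sources are
statistical objects; no anatomical claim is attached.

## Coherence and the lag scan

Magnitude-squared coherence `C = |G_xy|²/(G_xx G_yy)` from averaged
cross-/auto-spectra.  Estimator by context:

* **Continuous signals**: Welch, Hann segments of 256 samples, 50 %
  overlap, constant detrend per segment; at least two segments required
  (single-segment coherence is identically 1).
* **Trial ensembles**: segments pooled across trials; windows shorter
  than two segments fall back to a 3-taper DPSS multitaper per trial
  with trials as the averaging ensemble.
* **Per-trial matrices**: within-trial segments only, so every trial
  yields its own pairwise matrix for the condition comparisons.  With
  K within-trial segments the null expectation is ≈ 1/K — these values
  are comparable across conditions, not against zero.

The **lag scan** fixes the first signal's analysis window and offsets
the second signal's window by τ (every sample, both signs), averaging
C(f) over bins whose centers lie in [lo, hi).  Two choices matter and
were set after explicit error analysis:

* Segments must be short (~31 ms) for the peak to be sharp: a content
  mismatch of m samples costs ≈ m/segment of the segment correlation,
  whereas over a long segment a delay is a pure phase ramp that
  magnitude coherence cannot see.
* Both signals are band-pass prefiltered (zero-phase Butterworth order
  4) to the scan band first: short segments otherwise leak strong
  trial-coherent neighbors — the 10 Hz phase reset — into the band
  through the taper's main lobe, which biased the peak by up to ~20
  samples before prefiltering.  The FFT is zero-padded so narrow bands
  retain at least two bins.

Peak ties break toward the smallest |τ|, then toward positive τ; an
all-equal profile returns 0 with a degeneracy flag.

## Granger causality

Signals are first-differenced (event-locked responses are nonstationary
in mean; differencing also removes linear trends exactly).  The
restricted model regresses the target on its own `n` lags; the full
model adds the source at a **single** scanned lag τ — isolating the
timing of information flow, which is the point of the scan; a contiguous
exogenous block is available for conventional fits.  Trials pool as
independent realizations; lagged regressors may reach back before the
analysis window into the epoch.  F = ((RSS_r − RSS_f)/1)/(RSS_f/df) with
df = N − (n+2); the design must satisfy N ≥ 5 × parameters, and
rank-deficient designs are refused rather than regularized.  Order
robustness repeats the scan over {20, 30, 40, 50} (or any ≥ 2 feasible
orders): a direction is robust when sign(F_fwd − F_bwd) at the peak
agrees across orders and every peak p passes threshold.

## Transfer entropy and network inference

`T_{X→Y} = H(Y_t | Y-history) − H(Y_t | Y-history, X-history)`, with all
other sources' histories added to the conditioning set in multivariate
mode.  The default estimator is Gaussian (covariance/OLS-based): exact
for linear dynamics, where `T = ½ ln(RSS_r/RSS_f)` — equal to half the
Granger log-variance-ratio, an identity the tests verify against an
independent regression oracle.  A Kraskov-style k-nearest-neighbor
estimator (k = 4) is available for nonlinear use.  TE operates on raw
(undifferenced) source signals: the conditioning on full histories does
not require the linear-stationarity repair that the Granger F does.

Network inference scans, for every ordered source pair, the
**single-source-lag** TE over τ (a source block of L lags is flat over a
τ plateau of width L and biases the edge lag low; the conditioning
histories remain full-length).  Significance uses circular time-shift
surrogates of the source (preserving autocorrelation, destroying
directed coupling; ≥ 100 required).  Three calibration choices, each
forced by a measured failure mode:

* A rank-based surrogate p cannot pass a Bonferroni-corrected edge
  threshold (1/(n_surr+1) exceeds α/(pairs·lags)), so edge decisions use
  a parametric tail: a gamma distribution moment-matched to the
  surrogate null (the linear-Gaussian TE null is a scaled chi-square, so
  the gamma captures the skew).  The rank p is still reported.
* Surrogate nulls are pooled across ordered pairs before the tail fit —
  the null is homogeneous (same sample count and conditioning dimension)
  and per-pair 100-surrogate moment fits are too noisy in the far tail.
* The observed statistic is a maximum over scanned lags while surrogates
  are evaluated at the best lag only; the edge threshold is therefore
  Bonferroni-corrected over the lag grid as well.  The default
  family-wise `alpha_edge` is 0.01.

A caveat the recovery tests made explicit: with a *band-limited* shared
component, backward information flow is genuinely nonzero — the target's
copy of the component helps denoise the source's latent history at
oscillation-period offsets — so "planted edges only" is the true ground
truth only for broadband (white) components.  The planted-network
recovery conditions use white components for exactly that reason;
band-limited sessions are expected to show such secondary edges, as
real recordings plausibly would.

## Condition-level comparison

Per-trial pairwise coherence matrices are vectorized (upper triangle),
pooled, centered and reduced by PCA; the first three components' scores
are compared between conditions with Welch t-tests, Bonferroni over 3.
Constant pairs are dropped.  Band-wise contrasts (`cross_talk` =
inter-hemispheric pairs, `all_pairs` = all 15) average per-trial band
coherence over the pair set and compare trial groups with a Welch t and
a 95 % CI on the mean difference; the trial, not the pair, is the
sampling unit, because trials are the replicated observations.
Bonferroni runs over the number of band × mode contrasts in the session.

## Problem sizes

Unit and property tests run at reduced scale (typically 128–512 Hz,
8–60 trials, 0.5 s padding) with the structure — bands, windows, delays
in samples — preserved; the two preset recovery runs and the analysis
drivers use the native 2048 Hz and 60–200 trials.  Type-I-control
checks use 200 simulated nulls per test family.

## Known limitations

* The Gaussian TE and the Granger F share linearity assumptions; the
  KSG estimator is provided but not used in the default pipeline.
* The gamma tail for edge significance is an approximation; its
  empirical type-I behavior is verified at the levels the tests use, not
  at arbitrarily extreme quantiles.
* Frequency-domain (spectral) Granger, state-space methods, imaginary
  coherence and phase-slope index are out of scope.
* ICA on near-Gaussian data is unidentifiable; the model says so rather
  than failing, and downstream results on such fits should not be
  trusted.
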