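# Methods

This note documents the models, estimators, and design choices behind
`taptone`: a pipeline that relates spontaneous smartphone touchscreen usage
to concurrent EEG markers — tone-evoked potentials, band power, and
aperiodic (1/f) spectral parameters — on fully synthetic sessions with
known ground truth.

## The study design being emulated

A participant sits with their own phone for a long session (~1.5 h) while
task-irrelevant 1 kHz tones play at uniformly distributed 1–3 s intervals.
Every touchscreen interaction is timestamped (UTC ms). Behavior and EEG are
characterized in 1-minute bins; the momentary-usage regressor for bin *k*
is

    u_k = sqrt(number of touches in bin k),

and elapsed time is the bin index *k*. Three EEG feature families are
extracted per bin and channel: the trimmed-mean tone-locked ERP, the
aperiodic-corrected (flattened) log-power spectrum, and the aperiodic
exponent and offset of the 1/f fit.

## Synthetic sessions (`synthgen`)

The generator is first-class, tested code: it defines the conditions under
which every downstream estimator is validated.

**Touch process.** A two-state (active/idle) renewal process with
exponential dwell times (defaults: mean 40 s active, 30 s idle). During
active bouts, inter-touch intervals are Gamma(2, 0.35 s) truncated to
[0.1, 5] s. This is the simplest process producing the bursty
minute-to-minute count variation characteristic of real usage; the
truncation bounds apply *within* bouts — gaps spanning idle periods are
longer by construction. Defaults give per-minute counts ranging from 0 to
~90, so the usage regressor's SD comfortably clears the >1 inclusion
filter.

**Tone schedule.** Uniform(1, 3) s inter-stimulus intervals after a 1 s
lead-in, stopping early enough that the last −200..+500 ms epoch fits in
the recording.

**Montage.** Channels on concentric rings of the unit disc; adjacency =
pairs within 1.5× the median nearest-neighbour distance, bridged if needed
so the graph is connected. "Central" topographies are defined by distance
from the disc center.

**EEG.** Per channel and bin, three components are summed:

1. *Aperiodic background*: white noise shaped in the frequency domain to a
   one-sided PSD `10^{b_k} f^{−χ_k}` (µV²/Hz), with per-bin exponent and
   offset linear in the regressors:
   `χ_k = χ₀ + β_exp,usage·u_k + β_exp,time·k` (and analogously `b_k`).
   The 1/f divergence is clamped below 0.3 Hz. Defaults `χ₀ = 1.0`,
   `b₀ = 0.5` give a realistic ~5 µV RMS background.
2. *Theta oscillation*: narrowband Gaussian-spectrum noise (center 6 Hz,
   σ 1 Hz) whose total log10 power is `θ₀ + β_theta,usage·u_k`, applied to
   central channels. The within-bin variance is normalized exactly on the
   bin interior, so regressing realized interior log-power on `u_k`
   recovers the slope to machine precision by construction.
3. *Evoked responses*: at each tone onset a template of four time-Gaussians
   at 50/100/160/280 ms (defaults +1, −3, +2, −1.5 µV; widths 10/15/20/40
   ms) is added through a smooth central topography. The ~100 ms component's
   amplitude is `A₀ + β_N100,usage·u_k + β_N100,time·k`. Template placement
   is locked to the sample grid so that epoch extraction aligns exactly.

Bins are synthesized independently and cross-faded over 1 s (raised
cosine) to avoid boundary discontinuities. All slope parameters use a
uniform additive sign convention; the defaults encode the directions of
interest (theta power and the N100 magnitude grow with usage; exponent and
offset fall with usage and rise with time). The evoked and oscillatory
amplitude scales are generator defaults — no absolute µV scale is imposed
by the design being emulated — so all acceptance checks are phrased as
*recovery* of planted slopes, not absolute amplitudes.

What the generator does **not** emulate: ocular/muscle artifacts, bad or
bridged channels, volume-conduction forward models, inter-subject
topography variability, clock drift (a constant per-session offset only),
and app-level behavioral structure. Passing tests therefore demonstrate
correctness of the estimators under clean, stationary-per-bin conditions,
not robustness to real-world artifacts.

## Session I/O and binning (`sessionio`)

Touch logs are CSV (`timestamp_ms`), tone events TSV (`onset_s`), EEG an
HDF5 container with montage and a JSON parameter sidecar (EDF reading is
available through the optional mne dependency; EDF writing is not
supported). Clock alignment is a constant per-session shift; offsets above
the ~4 s bound expected of smartphone-vs-PC clock mismatch trigger a
warning but are applied.

Bins are half-open `[start, end)` intervals anchored at the EEG recording
start (not wall-clock minutes), 0-based; each touch is counted exactly
once; a trailing partial bin is dropped rather than padded, since a
partial bin would bias the count regressor.

## ERP path (`erp`)

A single Hamming-window linear-phase FIR band-pass (0.1–45 Hz default,
transition width `max(lo, 0.5)` Hz, ≥40 dB stopband) is applied in one
FFT pass with group-delay compensation — exactly zero-phase because the
filter is symmetric. This replaces a sequential 0.1–70 Hz band-pass plus
45 Hz low-pass with one equivalent band and a single filtering-artifact
budget; both stages can still be run separately for strict emulation.
After common-average referencing, epochs span [−200, +500) ms around each
tone (half-open, onset sample on the post-stimulus side), are baselined by
the per-epoch mean over (−200, 0) ms, and are excluded if their window
crosses a bin boundary *or* the recording edge (the stricter reading of
edge elimination). Bins keep their 20% trimmed-mean ERP only if ≥10 epochs
survive. The trim count is g = ⌊0.2·n⌋ per tail.

## Spectral path (`spectral`)

**CWT.** Analytic generalized Morse wavelet with γ = 3 and time-bandwidth
P² = 120 (β = P²/γ = 40), 30 voices per octave, L1 normalization (a unit
sinusoid yields |W| ≈ 1 at its ridge). Implemented in the frequency
domain; per-scale energy normalization converts time-averaged |W|² to a
one-sided PSD so that white noise integrates to its variance and the CWT
and Welch routes agree on stationary signals. A per-frequency
cone-of-influence (numerically computed e-folding width of the wavelet
envelope) masks recording-edge samples out of the bin averages. "Squared
mean magnitudes" over a bin is read as the time-average of squared
magnitudes (standard average power); the literal square-of-mean is
available behind `mode="sq_mean"`.

**Welch.** 4 s Hann windows, 50% overlap, density normalization, applied
within each 1-minute bin.

**Aperiodic fit.** Knee-free: `log10 P = offset − exponent·log10 f` over
1–40 Hz. The lower edge is 1 Hz (not 0.1): below 1 Hz wavelet edge effects
and the 0.1 Hz high-pass corrupt the slope estimate. The fit is a robust
two-pass least squares — fit, drop the top-quartile positive residuals
(putative peak regions), refit — and is fully vectorized over
(bin, channel) for pipeline use.

**Peak decomposition.** `parameterize_spectrum` follows the
specparam-style iterative scheme: locate the largest flattened residual
above `max(0.05, 2·SD)`, fit a Gaussian (width limits 1–12 Hz, i.e.
σ 0.5–6 Hz), subtract, repeat up to 6 peaks; jointly refit all Gaussians;
refit the aperiodic component on the peak-subtracted spectrum. The
*flattened spectrum* is log-power minus the final aperiodic fit. The
pipeline's level-1 surface uses the vectorized aperiodic-only flattening
(identical definition of "flattened"; Gaussian peaks are not needed to
flatten), which keeps the per-bin × channel cost trivial. Corrected band
power is the mean flattened log-power over the band; the theta band
defaults to 4–8 Hz (configurable, since 4–7 Hz is also in circulation).

## Two-level statistics (`masstats`)

**Level 1.** Per (channel, point), OLS of the per-bin feature on
[1, k, u_k]. Subjects need ≥10 bins and a full-rank design; an
iteratively-reweighted bisquare mode is available behind
`method="irls"` since "iterative least squares" admits both readings —
OLS is the default, and on clean data the two agree. Subjects enter
level 2 only with usage-regressor SD strictly >1 (on the sqrt-count
scale, which is how the usage variable is defined).

**Level 2.** At each point, Yuen's one-sample t for the 20% trimmed mean
of subject slopes: `t = t̄ / (s_w / ((1−2γ)·√n))` with winsorized SD `s_w`
(n−1 denominator) and df = n − 2g − 1. F = T² pointwise. Suprathreshold
points (two-tailed p < 0.05 on the trimmed t — the cluster-forming
threshold, configurable) are clustered under the montage adjacency
(spatial links at equal point index) plus neighbouring points within a
channel; no diagonal links. The cluster statistic is the mass Σ F.

**Null distribution.** Default `null="bootstrap"`: subject maps are
centered by the pointwise group trimmed mean and resampled with
replacement, one shared resampling vector per replicate across all points
(preserving the spatial/temporal correlation structure); the maximum
cluster mass per replicate (0 if none) forms the null, and cluster
p = (1 + #{max_b ≥ mass}) / (B + 1), which never returns 0. Clustering on
F merges positive and negative effects; a signed mode (separate
positive/negative masks) is available, default off.

A caveat the test suite quantifies: on weakly correlated (i.i.d.) maps the
centered-bootstrap max-mass null is *conservative* — replicates that draw
few distinct subjects inflate |t| across all points at once and fatten the
null's upper tail, so the empirical familywise error rate falls well below
nominal and power against spatially confined effects is reduced. A
sign-flip null (`null="signflip"`: multiply each centered subject map by a
random ±1) is provided as an alternative whose calibration on i.i.d. maps
is near-nominal (verified by its own test). The bootstrap remains the
default because it is the resampling scheme of the procedure being
reimplemented.

## Pipeline (`pipeline`)

Per-subject seeds derive from the master seed via `SeedSequence`, so
subjects are independent yet bit-reproducible; the whole `run_pipeline`
output is deterministic given (config, seed), which a test asserts via a
result hash. The aperiodic exponent and offset enter level 1 as one-point
features per channel, regressed like any other spectral point. ERP and
spectral analyses report their own inclusion counts rather than forcing a
single subject roster. Every tunable defaults to the study's stated value
where one exists (60 s bins, −200..500 ms epochs, −200..0 ms baseline,
≥10 trials, ≥10 bins, usage SD > 1, 20% trim, B = 1000, α = 0.05, CWT
30 voices/octave and time-bandwidth 120 over 0.1–40 Hz).

## Problem sizes used in tests

Test and calibration runs use scaled-down sessions chosen as the package's
own defaults for validation work: 125 Hz sampling (all analysis
frequencies are ≤45 Hz), 5–30 minute sessions, 8–16 channels, and the
Welch spectral route with B = 200 for the 20-replicate end-to-end recovery
study; the FWER calibration uses 200 simulated null datasets of 20
subjects × 16 channels × 40 points at B = 200. The CWT route is validated
separately (ridge localization, Parseval, agreement with Welch within 0.2
log10 units over 1–40 Hz).

## Known limitations

* The centered-bootstrap cluster correction's conservatism on low-smoothness
  maps (above) is a property of the procedure, not of this implementation;
  analyses of spatially confined effects should consider the sign-flip null.
* The aperiodic fit is knee-free; spectra with a genuine knee will bias the
  exponent.
* The generator's planted effects share one topography across subjects, so
  between-subject topographic variability is not exercised.
* Sub-minute spectral dynamics are out of scope; bins are the smallest
  analysis unit.
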