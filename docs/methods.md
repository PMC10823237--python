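# Methods

This note documents the models, estimators and numerical choices behind
`tangentia`, and what the synthetic fixtures do and do not establish about
real recordings.

## Probe model

Layouts are generated deterministically.  The default
`two-column-stagger` preset places two channels per 20-µm row with row
x-positions alternating between (0, 32) and (16, 48) µm — the
checkerboard of 384-channel probes; a 384-channel layout spans
(192 − 1) × 20 = 3820 µm.  ADC multiplexing follows the hardware
convention: within each 24-channel block, even and odd channels belong to
one 12-channel ADC each, and the channel of rank *r* within its ADC is
digitised *r* × 2.78 µs after rank 0.  Because the stored trace of a
late-sampled channel *leads* the uniform sample grid, the offset
correction applies a compensating fractional *delay*.  All fractional
shifts use an FFT phase ramp — the ideal band-limited interpolator; the
2.78-µs offsets are far sub-sample at 30 kHz, so circular wrap-around is
negligible for any window longer than a few samples.

Recordings are stored as frame-interleaved little-endian int16 with a
`key=value` meta file (gain default 0.195 µV/bit); spike tables are TSV
(per-spike and per-unit files).  Round-trips are bit-exact at 16-bit
resolution.

## Ground-truth simulator

The simulator provides the conditions under which every estimator is
tested:

- **Spike trains** are homogeneous Poisson processes thinned by an
  absolute refractory period (default 1 ms).  Thalamic burst/tonic
  statistics are *not* modelled; trains are Poisson by declaration, not
  by claimed fidelity to thalamic firing.
- **Transmission**: each presynaptic spike independently evokes at most
  one extra postsynaptic spike with probability *p* at delay + N(0,
  jitter SD); evoked spikes bypass refractoriness so that the efficacy
  equals *p* exactly in expectation.  The price is a slightly
  unphysiological ISI statistic in connected postsynaptic units, which
  can trip the strict 0.05% ISI criterion; the pipeline therefore exposes
  `qc.gate` to report QC without excluding units in synthetic scenes.
- **Templates**.  Somata are difference-of-Gaussians time courses
  (trough SD 0.08 ms at t = 0; overshoot at +0.6 ms, SD 0.12 ms — well
  under the 1-ms rebound criterion, so somata can never classify as
  axons) with Gaussian spatial decay whose scale is solved so that
  exactly `spread_channels` channels exceed 0.1 of the normalised
  peak-to-peak profile (exact up to distance ties on the grid).  Axons
  combine a narrow axonal field (AF; its own overshoot is kept at 35% of
  the rebound amplitude so the late rebound dominates) with a broad
  positive rebound (DF) whose half-height duration equals
  `rebound_duration_ms` by construction (Gaussian FWHM).  The AF spatial
  profile is a flat-top super-Gaussian along the probe — an axon running
  along the column — which also keeps threshold-crossing times
  amplitude-unbiased for the conduction-speed analysis.  Default
  amplitudes sit at the recorded population means (soma −54.9/+24.6 µV;
  AF −26.1 µV, DF +12.1 µV).
- **Conduction**: a finite speed shifts the AF per channel by (vertical
  distance)/speed, channels nearer the tip leading; the DF, a synaptic
  field, is not shifted.
- **Rendering** superposes templates at spike times, applies the ADC
  stagger by shifting each template once per channel (the stagger is a
  per-channel linear time-invariant operation and i.i.d. noise is
  invariant under resampling, so this equals resampling the whole clean
  signal at ~1/1000 of the cost), and adds Gaussian noise (default
  10 µV SD, the regime of quiet in vivo spike-band recordings).

What passing tests on these fixtures show: the estimators recover planted
parameters under the stated statistical model.  What they do not show:
robustness to drift, overlapping-spike sorting errors, bursting, or
non-Gaussian noise, none of which the simulator emulates.

## Waveform analysis

MCWs average up to 50,000 peri-spike snippets (seed-deterministic
subsample beyond that) over a −5 to +5 ms window — the window is not
dictated by the averaging itself but by the propagation analysis, which
needs a −5 to −2.5 ms noise baseline.  The offset correction commutes
with averaging across spikes (same per-channel shift for every snippet),
so it is applied once to the mean.  The peak channel is the largest
trough, ties to the lowest index.

The per-channel SNR profile is read as the peak-to-peak amplitude of the
mean waveform normalised to its maximum; the spatial spread is the
channel count above 0.1 and the vertical extent of those channels plus
one pitch (a single supra-threshold row spans 20 µm, not 0).  The
rebound is the largest positive excursion after the peak-channel trough,
searched across *all* channels (the rebound can centre rows away from
the trough); its duration is measured at half height — a choice this
package makes, since only the ">1 ms" criterion itself is standard — and
its spread from the profile of the half-height time window.
Classification: TCA iff rebound duration > 1 ms *and* rebound spread >
10 channels (the spread criterion is applied to the rebound, i.e. the
DF); otherwise V1N if the trough reaches 15 µV; otherwise unclassified.
AF/DF are split at the first zero crossing after the trough on the peak
channel; with the template shapes used here the AF segment carries the
trough and the DF segment the rebound.  The decomposition refuses
compact somatic waveforms.

Conduction speed: per probe column, the AP arrival time on each channel
is the first threshold crossing (4 SD of the −5 to −2.5 ms baseline)
inside −2.5 to −0.1 ms, linearly interpolated between samples; channels
within 5 channels of the peak or of the tip, and channels already
supra-threshold at the window start (censored arrivals), are excluded.  A
line is fitted to position-versus-time; columns need ≥ 5 points,
non-degenerate time spread (rejecting the simultaneous-arrival,
infinite-slope case) and |r| > 0.725; the best column's |slope| is the
speed.  Fixtures at 0.3/0.92/2.0 m/s are recovered with median error
well under 5%.

## Quality control

Double-counted spikes (within-unit pairs closer than 0.2 ms) are removed
greedily (idempotent) before the ISI-violation rate (< 1.5 ms; the
refractory window is a package default, configurable) is computed.  A
unit passes at ≤ 0.05% violations — the threshold is exclusive, so a
rate of exactly 0.05% passes — and, when feature vectors are available,
an isolation distance strictly above 10 a.u.  The isolation distance is
the squared Mahalanobis distance (metric: the unit's own feature
covariance, ridge-regularised at 1e-6 × trace/dims if singular) of the
n-th closest non-unit spike, n = unit spike count; undefined when
non-unit spikes are fewer.

## Connectivity inference

CCGs use half-open 0.1-ms bins over ±10 ms.  The sub-millisecond bin is
required for "4 consecutive bins" to be meaningful inside a 3.5-ms
window; 0.1 ms makes the minimum detectable peak width 0.4 ms, matching
sharp monosynaptic peaks.  The implementation enumerates only spike
pairs within the maximal relevant lag (sorted-train window search), and
is tested for exact equality against an all-pairs brute force.

The null is estimated by **interval jitter**: 50 surrogates redraw each
postsynaptic spike uniformly within its own fixed 10-ms wall-clock
window [kW, (k+1)W).  Only the post train is jittered (equivalent in
expectation, half the cost).  Surrogates reuse the pre-computed pair set
within ±(max lag + W), which is exhaustive because a jittered spike
moves less than W.  The corrected CCG is raw − surrogate mean;
`corrected + jitter_mean == raw` holds exactly.  The baseline SD is
taken over −4.5 to +0.5 ms of the *corrected* CCG (ddof 1).

Detection: ≥ 4 consecutive bins above 3 baseline SD with centres in
[0.5, 4] ms.  On 500 independent Poisson pairs (10–20 Hz, 1800 s) the
detector fires on none; common 1-Hz rate co-modulation without a
connection yields no detections in 100/100 seeds, confirming that the
10-ms jitter removes slow co-modulation.

**Efficacy.**  Interval jitter spreads a connection's own evoked
coincidences into the surrogate at density ≈ mass/W across the jitter
window, so subtracting the surrogate removes a fraction w/W of the true
evoked mass from any integration window of width w — an 11–20% shortfall
for realistic windows that no window choice avoids.  The estimator
therefore integrates the corrected CCG over the significant run extended
to adjacent bins above 1 SD plus a fixed 0.4-ms margin per side (corrected
bins are zero-mean under the null, so the margin captures the peak's
tails at the cost of variance, not bias), divides by (1 − w/W), then by
the presynaptic spike count, clipping at zero.  Planted transmission
probabilities of 0.01–0.5 are recovered with a residual bias of 1–3%
(mean over scenes); single scenes at p = 0.01 carry ~5–7% combined
binomial and counting noise.  When the window approaches the jitter
window (shrink ≤ 0.05) the correction is skipped with a warning.

Divergence (contacts per connected TCA) and convergence (per connected
V1N) are plain graph bookkeeping over the detected map; distances are
Euclidean between peak channels.  Per-pair surrogate seeds derive from
(master seed, pre id, post id), so adding units never changes other
pairs' results.

## STA footprints

The STA averages the postsynaptic probe's spike band over up to 20,000
presynaptic triggers (seed-deterministic subsample), after removing
triggers within ±1 ms of any postsynaptic spike so the postsynaptic soma
cannot contaminate the average.  The footprint is read at lag = CCG peak
lag − 1 ms, rounded to the nearest sample: the amplitude at the
postsynaptic peak channel and the width as the number of channels below
−0.75 µV at that single lag column.  Width 0 is reported as not
detected.  Planted thalamocortical-scale footprints (−1.114 µV over 23
channels) and cortico-cortical-scale ones (−0.047 µV) separate as
detected vs n.d. in 20/20 seeds at 10 µV noise with 5,000 triggers
(mean-SE 0.14 µV: the weak field sits 5 SE below threshold).

## Visual characterisation

Receptive fields accumulate per-target spike counts over each 100-ms
frame of a sparse-noise log onto the stimulus grid (36 × 22 by default),
optionally latency-shifted.  The map is cubic-interpolated at 2×
(36 × 22 → 72 × 44) and its SNR computed as 1/SD of the peak-normalised
map — the normalisation is a declared package choice; units pass at
SNR > 15.  The Fano factor is the unbiased variance over the mean of
per-trial spike counts; deterministic trains give 0, Poisson counts
converge to 1, and the sub-/super-Poisson fixture pair
(binomial-thinned regular train, Fano = 1 − p; rate-mixed Poisson,
Fano = 1 + Var(λ)/E[λ]) reproduces the axon-below-cortex ordering.

## Pipeline and determinism

`run_pipeline` executes scene simulation (or table loading), optional
rendering + MCW classification, QC, and the TCA→V1N connectivity map,
writing TSV tables and a plain-text summary with a parameter echo.
Every stage draws from a named substream seeded by (master seed,
crc32(stage name)); identical config + seed reproduces every table byte
for byte.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: 64–128
channel layouts, 25–60 s rendered recordings, 1800–3600 s spike-train
scenes, 5,000 STA triggers, 500 false-positive pairs.  Each size is set
so the relevant sampling error is several times smaller than the
tolerance being asserted (e.g. 2,000-spike MCWs leave 0.22 µV residual
noise against a 12-µV rebound criterion).

## Known limitations

- The simulator omits drift, bursting, spike-sorting errors and
  correlated noise; all recovery results are conditional on its model.
- Exact supra-threshold channel counts are guaranteed only up to exact
  distance ties on the probe grid.
- The efficacy shrink correction assumes the evoked-lag distribution is
  narrow relative to the 10-ms jitter window (true for monosynaptic
  jitter ≲ 0.5 ms).
- Inhibitory (trough) connections are not detected.
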