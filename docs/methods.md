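# Methods

## The measurement problem

A single larva crawls in a circular arena (~30 mm on the real rig) while a
PMT integrates photon counts from a genetically targeted aequorin reporter.
Photon counts are kept in arbitrary units (au) equal to raw counts per bin;
no gain or flux calibration is applied. The video, PMT and gas streams are
started independently, so analysis must first recover their relative clock
offset before any joint statement ("the luminescence rose when the animal
stopped") is meaningful.

## Synthetic rig

The simulator generates the three streams from one latent state so that
every downstream stage can be scored against exact ground truth.

**Kinematics.** A correlated random walk: constant crawl speed
(`larva_speed_px_s`, default 6 px/s — roughly 1 mm/s at the rig's
magnification), per-frame Gaussian heading noise (`turn_sigma_rad`, 0.25),
and a reflecting arena boundary that mirrors the radial overshoot. A CO₂
puff arrests crawling with probability `stop_response.prob` (default 1,
the response is described as robust) after a configurable latency (2 s
default; the true latency is not characterised, so it is a parameter, not
a claim), for a configurable bout (20 s). Air puffs never alter
kinematics.

**Photons.** Per-bin counts are Poisson with rate (au/s, integrated over
the bin):

* dark counts `dark_rate_au_s` (40 au/s) — present with the shutter closed;
* resting luminescence `baseline_lum_au_s` (100 au/s) — gated by the
  shutter;
* prior-light contamination `A·exp(−(t−t_shutter)/τ)` (60 au/s, τ = 40 s) —
  the slowly decaying elevated background left by light exposure before
  the recording, visible only once the shutter opens;
* CO₂-evoked transients: a difference-of-exponentials kernel
  `exp(−t/τ_d) − exp(−t/τ_r)` normalised to unit peak, with rise τ_r = 60 s
  and decay τ_d = 90 s, so the evoked response peaks ~73 s after the puff —
  slower than one minute, matching the qualitative timescale of the
  preparation. The amplitude is either set directly (au/s at kernel peak)
  or derived from a desired expected post/pre window ratio via
  `amplitude_for_response_ratio` (closed form from the kernel mean over the
  post window).

The prior-light term is integrated analytically per bin; the calcium term
at the midpoint of the shutter-open overlap (its timescale is minutes,
three orders slower than any bin). Spontaneous transients are available
(`spontaneous_per_min`) but default to zero so stimulus epochs have a
clean expected value.

**Video.** Dark background (level 10) with Gaussian sensor noise (σ = 2 by
default), the larva as an anti-aliased ellipse (12×5 px full axes) aligned
with heading — the symmetric profile makes the intensity-weighted centroid
equal the true position up to 8-bit quantization — and an 8×8 px corner
marker that switches from dark to 230 at the shutter frame.

**Gas.** True ppm follows 400 ppm baseline with first-order accumulation
toward a plateau (5000 ppm, τ = 20 s) after each CO₂ puff; no clearing
within a session. Voltage is the same log-linear law the analysis inverts
(simulation calibration: 1.6 V at 400 ppm, −0.6 V/decade, comfortably
inside the module's 0–2 V range), plus Gaussian noise (5 mV) and 10-bit
ADC quantization.

All randomness flows from `rng_seed` through independent spawned
sub-streams (path, photons, video, gas, spontaneous events), so identical
configs are bit-identical and perturbing one stream leaves the others
untouched.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real recordings: peristaltic body shape change and
head sweeps (the blob is rigid, so real centroid jitter is underestimated),
position-dependent PMT collection efficiency, PMT dead time and
afterpulsing, clock *drift* between devices (only a constant offset is
simulated), illumination inhomogeneity, and multi-animal scenes.

## Analysis choices

**Coordinates.** Origin at the top-left pixel centre, x along columns,
y along rows, sub-pixel floats.

**Segmentation.** Foreground = (frame − temporal-median background) above
a threshold; bright-on-dark polarity fixed by the FTIR-style illumination
(configurable). The adaptive threshold is the median plus 4 robust
standard deviations (MAD × 1.4826) of the *signed* difference image,
floored at 2 intensity units; it is estimated once per video from five
sampled frames since the noise is stationary. Components outside
[20, 2000] px are rejected; the largest surviving component is the larva
(single-animal assumption). Gaps of ≤ 5 frames are bridged linearly and
flagged; longer gaps stay invalid.

**Speed and stops.** Speed is the displacement between consecutive valid
frames over elapsed time, smoothed by a 5-frame centred moving average
(missing entries stay missing). Stop bouts are maximal runs below
1 px/s lasting ≥ 2 s, with bouts separated by < 500 ms merged.

**Shutter step.** The change point minimises the summed within-segment sum
of squares over all two-segment splits (computed in O(n) with prefix
sums; verified against the exhaustive O(n²) scan). A step is accepted
only if the post/pre mean ratio is ≥ 3 — the shutter opening is a large
step by construction, and the threshold rejects drift. In the full
pipeline the search is confined to pre-stimulus bins: a CO₂ response
later in the trace is a bigger mean shift than the shutter step and would
otherwise capture the split.

**Prior-light correction.** `counts ≈ A·exp(−t/τ) + c` fitted by bounded
least squares (`scipy.optimize.curve_fit`) on the window from the shutter
step to the first CO₂ puff — air puffs evoke no luminescence, so they do
not shorten the window; the corrected trace subtracts only the decaying
term, floored at zero. A flat window short-circuits to amplitude 0,
offset = mean. τ is bounded above by the window span: a decay slower than
the window is not identifiable against the constant offset, and an
unbounded fit can trade the resting baseline into a quasi-constant
"decay" whose subtraction then grossly inflates downstream ratios. Even
bounded, the fit is the main source of percent-change uncertainty when
the contamination is comparable to the resting signal, and trials whose
fitted τ sits at the bound carry a small upward percent-change bias.

**Transients.** Baseline is a rolling median over 10 min (long relative to
the minutes-scale transients it must ride under); events are runs above
baseline + 6·MAD·1.4826 lasting ≥ 10 s. The definition is
baseline-relative, hence invariant to additive offsets.

**Synchronization.** The start of the shutter bin is anchored to the start
of the shutter frame. The residual misalignment is bounded by one bin
plus one frame because the true opening lies somewhere inside both; the
sub-bin phase is unrecoverable and accepted. The scale is kept as an
exact `Fraction` (40 frames per 2000 ms bin; 2 per 100 ms bin). Clock
drift correction is not implemented.

**Fusion.** Luminescence is assigned to frames by zero-order hold — a bin
is a photon *sum* over its interval, so interpolation would fabricate
sub-bin structure. Gas uses the nearest sample (sensor period ≪ response
timescales). Rendering maps luminescence linearly onto a configurable
colormap (default "jet") over `[0, max_au]` with values above the ceiling
clamped to the top colour; the deliberately low ceiling boosts contrast
for dim traces.

**Epochs.** Percent change = `100 · mean(post) / mean(pre)` with windows
adjacent to the puff (60 s pre, 120 s post by default, spanning the slow
rise). A ratio rather than a delta: "no response" reads as ~100% and the
statistic is invariant to overall photon-channel gain. Undefined (NaN)
when the pre mean is not positive. Group summaries are mean ± SEM with
the n−1 sample standard deviation; inferential statistics are out of
scope. CO₂ epoch times use the gas-detected onset (first sustained rise
of 100 ppm over the leading-window median) when available; air puffs
leave no gas signature, so their scheduled times are used.

## Problem sizes

Verification runs use sessions of 400–4200 frames (20 s–3.5 min at 20 fps)
in arenas of 28–100 px radius, cohorts of 7 trials per condition, and
100-seed ensembles for fit-recovery statistics; these sizes give stable
recovery estimates while keeping a full verification pass to a few
minutes.

## Known limitations

* Percent change is computed on decay-corrected traces by default; on raw
  traces (supported via `AnalysisParams(correct_prior_light=False)`) any
  residual prior light inflates the pre-window mean and biases the ratio
  toward 100%.
* The single-target assumption silently picks the largest component;
  debris brighter and larger than the larva would be tracked instead.
* Absolute ppm accuracy depends entirely on the per-rig calibration; the
  defaults in `GasCalibration` are placeholders and must be replaced.
* A stop bout is detected from smoothed speed, so bout edges blur by about
  half the smoothing window (~125 ms at defaults).
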