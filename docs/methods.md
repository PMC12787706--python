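# Methods

`thermovitals` implements a single-camera thermal-video pipeline for
noncontact vital signs: breath visualization, respiratory and heart rate,
inner-canthus body temperature, and exhaled-airflow velocimetry, together
with the agreement statistics used to validate such methods and a synthetic
phantom that provides ground truth for every stage.  This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Breath visualization

Exhaled air carries ~4 % CO2, which absorbs mid-wave infrared radiation near
4.3 um; a breath plume therefore appears as a faint dark region in front of
the face in an MWIR recording.  `mean_subtract` removes the static scene by
subtracting the temporal mean image from every frame.  The subtraction is
global over the stack by default: the output then has exactly zero temporal
mean and the operation is idempotent, which the tests exploit as invariants.
A sliding-window variant (odd window, local temporal mean) is available for
recordings with slow drift, at the cost of those properties.  Display
normalization maps global percentiles (default 1-99) to [0, 1]; percentiles
are global rather than per-frame because per-frame scaling would erase the
inter-frame respiratory contrast.  A constant stack maps to 0.5 by
convention.

## Rate estimation

All rates share one chain: ROI spatial-mean trace -> zero-phase second-order
Butterworth bandpass -> readout.

* Bands: respiration 0.1-0.4 Hz, pulse 0.8-1.5 Hz (both configurable).
* Zero-phase (forward-backward) filtering doubles the effective attenuation
  order and introduces no phase distortion, but inflates amplitudes near the
  record boundaries; the first and last 2 s are therefore excluded from
  time-domain peak counting by default (`edge_trim_s`).
* Time domain: peaks with minimum separation half the shortest in-band
  period and prominence 0.3x the filtered trace's interquartile range (a
  scale-free default, overridable); rate = 60 / mean inter-peak interval.
  Flat crests resolve deterministically to their first sample.
* Frequency domain: magnitude FFT of the full filtered record at its native
  length — no zero padding, no window — so the bin width is exactly
  1/duration (0.025 Hz = 1.5 bpm at 40 s).  The in-band argmax is reported;
  ties resolve to the lowest frequency.  Band edges are inclusive.
* MWIR exhalation appears as intensity minima; `invert` negates the trace so
  breaths are counted as peaks.  The same operators applied to a PPG trace
  provide the reference heart and respiratory rates.

Breath-by-breath averaging (`segment_cycles` / `normalize_cycles`) anchors
cycles at troughs of the exhale-positive signal (expiration onset), linearly
resamples each cycle to a common length (default 100 points), min-max scales
to [0, 1], and reports the pointwise mean and SD.  Zero-amplitude cycles are
excluded with a warning rather than propagating NaNs.

## Thermometry and pulse

The inner canthi coincide with the hottest facial regions, so the
measurement area is segmented by thresholding the temporal mean image:
either a predetermined absolute temperature (the primary mode) or, when none
is supplied, the 99.5th percentile of the mean image.  Components are
8-connected; those under 4 px are dropped and the two largest are kept (one
per canthus).  An empty mask is an explicit error.  Body temperature is the
mean over masked pixels and all frames.  The same mask's per-frame mean,
band-limited to 0.8-1.5 Hz, yields the heart rate through the time-domain
readout.

Note on the percentile mode: the percentile threshold ranks mean-image
values, so when it falls inside the canthus plateau it selects pixels partly
by their residual noise rank.  That introduces a selection bias of a few
tenths of a millikelvin in the temperature estimate — harmless in practice,
but the recovery tests use the absolute-threshold mode, whose mask is
noise-independent, so the estimator can be checked against the pure
standard-error bound of the noise model.

## Space-time image velocimetry

A line ROI is placed along the plume axis below a nostril and the
(mean-subtracted) stack is bilinearly resliced along it at 1-px spacing,
giving a space-time image (STI): rows time, columns distance, scales
Sx (m/px) and St = 1/fps (s/px).  A feature advected at speed U traces a
streak at angle theta from the space axis with

    U = (Sx / St) * 1 / tan(theta),

so theta -> 90 deg is a stationary pattern (U -> 0).  Processing before
orientation analysis: a 15-px one-dimensional median filter along the space
axis (suppresses static clutter such as a lip crossing the line) and CLAHE
(clip limit 0.01, 8x8 tiles) to equalize the luminance gradient; both
parameters are exposed and echoed into reports.  The STI is then cropped to
each exhalation window and one angle is estimated per breath.

Orientation is estimated from the luminance gradient (structure) tensor:
Gaussian-derivative gradients at scale sigma = 2 px, tensor components
averaged at the same scale, per-pixel streak orientation
0.5*atan2(2<IxIt>, <Ix^2>-<It^2>) + 90 deg accumulated into a 90-bin
histogram over [0, 180) weighted by tensor anisotropy (the eigenvalue
difference, which suppresses isotropic noise).  The peak bin is refined with
a three-point parabola and folded into (0, 90).  A constant region raises an
error (no gradient energy).  An independent brute-force check — scoring
candidate angles by the summed variance of intensity profiles along rotated
sampling lines — agrees with the tensor estimate within 1 deg on clean
synthetic STIs and serves as the oracle in the test suite.

Velocities are aggregated across exhalations by their mean; per-exhalation
values are kept on the estimate because the streak pattern is dominated by
the early, peak-flow phase of each breath.  Volume conversions are exact
identities on the `FlowEstimate` object: V = U*A with A the user-supplied
nostril cross-section (area estimation from images is out of scope), and
V_CO2 = 0.04*V from the CO2 fraction of exhaled breath; `per_hour`
multiplies by 3600.

## Agreement statistics

`bland_altman` reports, for paired method/reference values: bias (mean
difference), SD of differences (sample, n-1), limits of agreement
bias +/- 1.96 SD (the fixed normal multiplier, not a t quantile), the
agreement rate (percentage of differences inside the LOA, boundaries
inclusive — the inclusive reading changes small-n rates, so it is fixed and
documented), Pearson r and p (reported as not-computable when either series
is constant), and RMSE.  The identity rmse^2 = bias^2 + ((n-1)/n) sd^2 is
used as a numerical cross-check.  Group comparison is a fixed decision tree:
Shapiro-Wilk on each group; both normal (p >= 0.05) -> Bartlett; variances
equal -> Student's t; any failure -> Mann-Whitney U.  A zero-range group is
routed directly to the nonparametric branch (Shapiro-Wilk is undefined
there).  The path taken is recorded in the report.

## The synthetic phantom

The phantom emulates the statistical structure the pipeline assumes, not the
physics that produces it:

* Scene: ambient background (24 C) with a smoothed face ellipse at 34 C;
  two flat canthus disks (radius 3 px) at 36.5 C.  Flat disks (not Gaussian
  bumps) make the canthus plateau homogeneous, so the segmentation mask is
  well defined and the configured pulse amplitude survives masked averaging.
* Cardiac signal: the disks oscillate by `pulse_amp_mK` (default 30 mK,
  roughly the amplitude of perfusion-driven skin temperature variation) at
  the configured heart rate.
* Plume: a parcel-advection model.  The pixel at distance x below a nostril
  is darkened at time t iff its emission time t - x/v fell inside an
  expiration; expiration occupies the first half of each respiratory cycle
  by default (duty cycle configurable; real duty cycles are asymmetric but
  no standard value exists, so the symmetric default is the simplest
  defensible one).  Depth 0.5 C with a Gaussian cross-section (sigma
  2.5 px) and a 2-Hz sinusoidal texture on the emission time, which produces
  parallel streaks of slope exactly v in the STI with slanted leading and
  trailing edges (no spurious horizontal structure at breath boundaries).
  The generator refuses configurations whose puff would exit the frame
  before an expiration ends; the default pixel scale is auto-fitted so one
  puff exactly spans the sub-nostril field.  This makes the phantom's
  spatial scale deliberately coarse (cm-scale metres/pixel) — the geometry
  is a test surface for the velocimetry algebra, not a rendering of a face.
* Noise: white Gaussian per pixel per frame, SD 18 mK — the NETD-style
  specification of a cooled MWIR sensor.  The LWIR phantom uses 5x that,
  reflecting uncooled-microbolometer noise.
* LWIR reference: nostril patches follow a capnogram-like cycle (sharp
  upstroke to 0.85 of the 1.0 C amplitude, slow plateau climb, sharp
  downstroke, baseline) at 30 fps, in phase with expiration and hence
  opposite in sign to the MWIR plume trace.
* PPG: cardiac fundamental plus a 0.3-amplitude second harmonic, a
  0.25-amplitude respiratory baseline modulation, and 0.05 white noise at
  409.6 Hz.

All randomness derives from the single `seed`; identical configurations are
bit-identical.  What passing recovery tests shows: the estimators are
unbiased and stable under the phantom's noise model at realistic SNRs.  What
it does not show: robustness to head motion, blinking or speech, to
non-stationary breathing, to radiometric effects (emissivity, reflection,
atmospheric attenuation), or to plume turbulence and diffusion — none of
which the phantom models.

## Problem sizes

The recovery suites use 40-s recordings at 60 fps on a 64x56 frame
(respiratory grid 10-25 bpm and pulse grid 60-90 bpm, five seeds each) and
20-s recordings on a 96x80 frame for velocimetry (0.5/1.0/1.5 m/s, five
seeds each, short expirations so each puff fits the frame).  These sizes
keep the full suite under a minute while leaving every estimate's error an
order of magnitude inside its tolerance band.

## Known limitations

* ROIs and the STIV sampling line are user-specified; there is no face or
  landmark detection (the targeted protocol fixes the head).
* Nostril cross-sectional areas are user inputs; flow volumes inherit the
  idealized unidirectional, non-diffusive flow assumption and should be read
  as order-of-magnitude estimates.
* The frequency-domain rate is quantized to 60/duration bpm; prefer the
  time-domain readout for short records.
* The percentile segmentation mode assumes the hottest `100 - p` percent of
  the mean image is canthus; faces with hot spots elsewhere (glasses edges,
  hair) need the absolute-threshold mode.
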