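# Methods

`glottovib` re-implements, as a tested pipeline, the analysis chain used in
excised-larynx phonation experiments on bats: high-speed video of the
glottis, a calibrated microphone signal, and bronchial pressure are reduced
to a glottovibrogram, fundamental-frequency (f_o) tracks of vibration and
sound, an identity regression linking the two, and the phonation threshold
pressure (PTP) with the pressure rate of change at onset (S_ptp). Because
no real recordings ship with the package, a synthetic-trial generator with
exact ground truth defines the conditions under which every stage is
validated.

## The synthetic trial generator

**What it emulates.** One trial is a synchronized bundle: a grayscale
high-speed video (10,000–250,000 fps equivalent; default frame 128×64 px,
8-bit) showing a dark elongated glottal opening between two brighter
oscillating edges; a harmonic sound-pressure signal in Pa phase-locked to
the opening oscillation; and a bronchial pressure protocol in kPa at
250 kHz — either a slow linear ramp 0→6 kPa at 1 kPa/s or a train of four
300 ms trapezoidal pulses between 0 and 4 kPa with a configurable slew
(default 30 ms rise, ≈133 kPa/s).

**Kinematics are prescribed, not simulated.** The half-opening of scan
line *i* is `slit + A_i (1 − cos(θ(t) + φ_i))/2`, with `θ′ = 2π f_o(t)`,
a Gaussian amplitude envelope across the 8–10 anterior–posterior (AP)
lines, and a linear AP phase lag (default 0.6 rad total) that mimics a
travelling mucosal wave. A self-oscillating tissue model would add realism
but destroy exact ground truth; prescribed motion makes every per-frame
edge position, onset time and instantaneous frequency known. The phase
relationship along the AP axis of real bat vocal membranes is not known to
us; the lag parameter is a modelling convenience, not a claim about bats.

**Onset gating.** Oscillation starts at the first instant the (filtered)
pressure reaches `ptp_true` while, if a `rate_gate` is set, the pressure
speed also exceeds it. This reproduces, by construction, the two-condition
onset behaviour of vocal membranes: a slow 1 kPa/s ramp never satisfies a
30 kPa/s gate, fast pulses do. The gate value is a free choice inside the
bracket that the experimental contrast implies (slow ramps fail at
1 kPa/s; fast pulses with slews of order 10²  kPa/s succeed).

**f_o profiles.** Constant, linear sweep, or *ramp-locked*
(`f_o = f_o(PTP) + k·(p − PTP)`, defaults 500 Hz/kPa ventricular,
1000 Hz/kPa membrane). The named recipes use ramp-locked profiles so a
single trial spans a small f_o range and its sound-vs-vibration regression
is non-degenerate. Video generation refuses profiles with
`fps < 4 × max f_o` (sampling adequacy).

**Rendering.** *Opaque* mode (ventricular folds): the opening is uniformly
dark (default glottis 40, fold 160), so any threshold between the levels
segments it exactly. *Translucent* mode (vocal membranes): a band of
`membrane_px` (default 6 px) inside each true edge is drawn at a gray level
that must lie within one noise standard deviation of the fold gray
(defaults 156 vs 160 at noise sd 4). Thresholding then sees only the inner
dark core and under-reports the opening width by ≈ 2·`membrane_px` — the
failure mode that motivates scan-line edge tracking. Noise is additive
Gaussian gray noise, clipped to the 8-bit range.

**Sound.** A 1/h-weighted harmonic series (default 3 harmonics,
auto-truncated below 0.45 fs) with instantaneous frequency f_o(t), sharing
the kinematics' phase integral so vibration and sound are locked by
construction; the envelope rises linearly over an attack time (default
10 ms ventricular, 5 ms membrane) to a peak of 20 mPa, over a noise floor
of 0.02 mPa. Microphone propagation delay (≤0.13 ms at ≤44 mm) is ignored
by default but configurable for robustness tests.

**Pressure noise.** Sensor noise is modelled as broadband Gaussian noise
high-passed above 2 kHz. Real transducer chains carry their noise power
well above the physiological band — which is what the analysis-side 500 Hz
low-pass exists to remove. This matters quantitatively: the pressure speed
is `diff × 250 kHz`, and *in-band* white noise of sd σ would contribute
≈119·σ kPa/s of derivative noise that no realizable filtering could
remove; out-of-band noise leaves the filtered derivative intact at any
permitted noise level (≤0.05 kPa).

**Determinism.** All randomness derives from one integer seed through
`numpy.random.SeedSequence`; identical (recipe, seed) produce byte-identical
on-disk bundles (multi-page TIFF, float WAV in Pa, CSV pressure, JSON
truth/metadata).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: tissue self-oscillation (no jitter, subharmonics
or chaos in the source), left–right asymmetry or lateral motion of the
midline, illumination gradients and specular highlights, camera blur and
rolling shutter, room acoustics, and microphone coloration. Results on
real recordings will degrade in proportion to how far these effects exceed
the synthetic noise model.

## Segmentation

**Threshold path** (opaque structures). Glottis = all pixels strictly
below the manually set gray threshold from trial metadata (an Otsu
suggestion is available but never applied silently). The binary image is
dilated with a 2-pixel line horizontally then vertically, hole-filled, and
the largest connected component kept (ties broken toward the darker blob).
The "2-pixel line" element is interpreted as 1×2 then 2×1; the ≈1 px width
margin this adds is *measured* on a calibration fixture
(`measure_dilation_margin()`) and subtracted explicitly by the pipeline,
never silently. Width per AP row is the count of mask pixels along the
row, scaled by the pixel pitch; the horizontal extent (right−left) is also
computed as a secondary reading.

**Edge path** (translucent membranes). On 8–10 equidistant horizontal scan
lines (default: 1/8-height margins, shared with the renderer), per frame:

1. the row band (±3 rows; one-sided at the outermost lines, where the
   opening tapers and a symmetric band would bias the average) is
   averaged and lightly smoothed; the dark glottal core is located by its
   strong contrast against the mid-level between fold and glottis grays;
2. the true edge is found by change-point localization in the raw band
   profile over the 12 columns outside the core: the split maximizing a
   Welch-type statistic between an outer (fold) and inner (membrane)
   plateau. A gradient extremum cannot find a step at noise level, and
   the *strongest* gradient always sits on the inner membrane/air
   boundary, which would reproduce exactly the under-segmentation the
   method is meant to avoid; plateau-mean splitting localizes a step of
   height comparable to the pixel noise to well under a pixel;
3. where the line shows a consistent membrane band (median split
   statistic above threshold), a second pass learns the fold and membrane
   gray levels from the whole line's history and relocates each boundary
   by maximum likelihood with known levels;
4. frames without a significant split (opaque material, where the core
   edge *is* the edge) fall back to the subpixel crossing of the core
   mid-level. Detections are fixed vertically to their line rows, carry a
   confidence in [0,1], hold the previous position for up to 3 frames
   when the core vanishes, and are NaN beyond that.

Accuracy at the default translucent conditions (membrane–fold step equal
to the noise sd — the hardest contrast the renderer permits): per-line
mean-width bias ≤ 0.3 px, per-frame mean absolute width error ≈ 1.2 px
(quantization plus noise-limited split scatter), versus a systematic
≈11–12 px under-report from thresholding. On noiseless opaque fixtures
edge positions match truth to ≤ 0.5 px, and the two paths agree to
≤ 0.5 px in the mean (95th percentile ≤ 1.5 px; single-frame extremes near
1.5 px arise from pixel-count quantization alone). An adapter
(`read_edge_tracks_csv`) ingests externally produced per-line edge
coordinates, e.g. from a pose-estimation network, in the same CSV layout.

## Glottovibrogram and opening waveform

The GVG is the (time × AP position) matrix of opening width in mm; from
edge tracks, width per line is `right_x − left_x` scaled to mm. Dropouts
of ≤3 frames are linearly interpolated and flagged; longer gaps abort
loudly (silent interpolation across long gaps is a classic source of
spurious pitch halving), and an all-undefined line is a degenerate input.
Vibration f_o is read at the AP position of maximal time-mean opening
(exact ties resolve anterior-most, a deterministic rule), from the plain
column slice at the video frame rate; the demeaned copy is used for pitch
(the difference function is offset-invariant, so demeaning only affects
the power gate).

## f_o estimation

**yin.** Per hop: squared-difference function d(τ), cumulative-mean
normalized difference (CMND), first dip below the absolute threshold
(default 0.1), parabolic lag refinement. Three implementation choices that
matter:

- refinement interpolates the *raw* difference function, not the CMND:
  the cumulative normalization is asymmetric about the period minimum and
  biases the CMND vertex by up to ~0.5 % (measured on pure tones);
- the candidate-lag range is bounded by `fs / f0_min` rather than by the
  window, and any window surplus extends the difference integration. This
  keeps period multiples of in-range f_o out of the candidate set
  (subharmonic protection) and suppresses window-edge bias on
  harmonic-rich signals — the pipeline uses 4 periods of the lowest
  expected f_o (f0_min 800 Hz for ventricular folds, 9 kHz for vocal
  membranes, just below each structure's band);
- a shortest-lag guard accepts the first dip within 0.05 of the global
  CMND minimum, so a dip at the true period that narrowly misses the
  absolute threshold still beats a slightly deeper dip at a multiple.

Validity per hop requires AC power ≥ a class-specific floor (set from the
synthetic noise floor: 10⁻⁶ mm² for opening waveforms, 10⁻⁹ Pa² for
sound), aperiodicity (CMND at the chosen lag) ≤ 0.1, and f_o ≤ fs/4 — the
regime boundary above which yin locks onto period multiples, which is the
documented reason the ridge engine exists. For opening waveforms the hop
is 10 video frames; for raw audio a 256-sample hop is the convention.

**Ridge.** Hamming spectrogram (nfft 2048, 50 % overlap); the ridge is the
frequency path maximizing summed log magnitude minus a jump penalty of 1
log unit per bin per column, found by dynamic programming (the linear
penalty admits an O(bins) per-column distance-transform recursion);
per-column parabolic refinement over log magnitude gives sub-bin f_o. The
penalty default was calibrated once against the 20→70 kHz sweep-recovery
property (RMS error ≈0.001 %) and holds tones steady 1 kHz apart; it is
config-exposed.

**Engine choice.** yin when the expected f_o maximum is ≤ fs/4 (inclusive
at the boundary), else ridge. In the pipeline yin runs on sound resampled
to the video frame rate (polyphase, anti-aliased), so its fs is the fps;
ridge runs on raw audio.

## Phonation threshold pressure

Pressure is low-pass filtered at 500 Hz with a 6th-order Butterworth
applied forward–backward (zero phase; a causal single pass would delay the
pressure relative to the sound and bias PTP on rising ramps — the measured
step delay of the zero-phase filter is <0.2 ms). Pressure speed is the
first difference times the acquisition rate, timestamped at midpoints.
Sound onset is the first time the running RMS (1 ms window) crosses
0.2 mPa and stays above for ≥2 ms (debounce); "sound power crossing
0.2 mPa" is read as an RMS amplitude criterion — the alternative
(instantaneous amplitude) would fire √2 earlier on a ramp, a sensitivity
of ~1.4× the local envelope slope, i.e. ≈0.014 kPa at 1 kPa/s. PTP is the
filtered pressure at onset; S_ptp the speed at the nearest midpoint.
Window and hold defaults are config-exposed. Recovery at the study
conditions: mean |PTP error| ≈ 3·10⁻⁵ kPa over 20 ramps with thresholds in
[2, 6] kPa; S_ptp within 0.01 % of the commanded 1 kPa/s, and within a few
percent of the ≈133 kPa/s slew on fast pulses (limited by the smoothing of
the pulse corner and the ~0.5 ms onset-window bias).

## Synchronization and statistics

All modalities share the trigger clock; sound is sliced to the video span
and resampled to the frame rate before yin, so vibration and sound tracks
share hop times exactly. The identity regression is ordinary least squares
of sound f_o on vibration f_o *with* an intercept (an identity relation is
a hypothesis to test, not to force), over hops valid in both tracks; a
perfectly constant vibration track is handled as a degenerate case. Range
summaries are five-number (min, quartiles by linear interpolation between
closest ranks — the convention is fixed here because toolbox conventions
differ — and max; whiskers are the full range, no outlier trimming). Call
segmentation for in-vivo-style recordings thresholds the running RMS and
merges intervals across sub-`min_gap` silences; the paper's equivalent
step was manual selection, so floor and gap are plain config values.

## Problem sizes and runtime

Synthetic video durations are 0.12 s at 20,000 fps (2,400 frames) for
ventricular trials and 0.024 s at 125,000 fps (3,000 frames) for membrane
trials — a few hundred oscillation cycles and f_o hops each, comfortably
enough for stable medians and regressions while keeping a full trial
generation + analysis under ~10 s on one CPU. Pressure/sound-only trials
(PTP sweeps, protocol contrasts) skip rendering entirely.

## Known limitations

- The edge tracker's second pass assumes the membrane band's gray level is
  stationary over the trial; slow illumination drift would need a running
  estimate.
- Near closure, a membrane band wider than the slit leaves no visible dark
  core; such frames fall back to held positions and are bridged by the
  ≤3-frame GVG interpolation.
- The per-trial identity regression is meaningful only when f_o actually
  varies within the trial; for constant-f_o recordings only pooled,
  multi-trial regressions are informative (the errors-in-variables
  attenuation on a narrow f_o range biases per-trial slopes low).
- yin above fs/4 fails by period-multiple locking rather than by refusing;
  the validity gate bounds reported f_o but cannot recover the true one —
  use the ridge engine there.
- `fo_range_summary` describes a sample; with 3–5 larynges per condition
  no inter-individual inference is attempted.
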