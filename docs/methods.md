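# Methods

`recruitkit` quantifies protein recruitment kinetics at laser-induced DNA
damage stripes from simultaneous dual-channel ("split-view") time-lapse
fluorescence movies. This note describes the quantification model, the
synthetic-movie generator used for validation, the numerical choices, and
the known limitations.

## The quantification pipeline

The stage order is fixed:

1. **Difference-of-Gaussians (DoG) prefilter**, applied per frame:
   `G(σ_small)∗I − G(σ_large)∗I` with defaults σ_small = 0.065 µm and
   σ_large = 13 µm, converted to pixels by the acquisition pixel size.
   The small scale suppresses salt-and-pepper camera noise; the large
   scale removes slowly varying background — out-of-focus emission,
   excitation heterogeneity and, importantly, the camera dark offset,
   which would otherwise break the ratio-based bleaching correction
   (a non-bleaching additive term does not cancel in a ratio).
   Negative filtered values are retained: clipping would bias the
   top-20 statistic below. Filter scales can alternatively be declared
   as variances (`interpretation="variance"`), since GUI "DoG radius"
   dialogs are ambiguous about sigma vs variance.
2. **medMax extraction.** Per frame, the damage-site intensity is the
   median of the 20 brightest pixels in a rectangular damage ROI drawn
   around the stripe with a margin of undamaged nucleus (tolerating
   subtle cell movement). The median-of-top-20 is far more stable than
   the single maximum at low excitation power, while the plain ROI mean
   would be diluted by the included undamaged area. The whole-nucleus
   mean is extracted from the same filtered frame, keeping one
   consistent intensity scale.
3. **Bleaching correction.** `corrected[t] = medMax[t] / nucleus_mean[t]`.
   Global photobleaching multiplies both series equally and cancels.
4. **Smoothing (standard mode only).** 3-point moving average
   (`(s[i−1]+s[i]+s[i+1])/3`, two-term means at the ends). Disabled in
   the fast-imaging mode, where temporal resolution is the point.
5. **Normalization.** With `I0` the mean corrected intensity over all
   pre-damage frames: RFI = corrected/I0 (fold change), ΔI = corrected −
   I0, and FMR = (RFI − 1)/(max RFI − 1), which rescales the curve so
   the pre-damage level is 0 and the maximum is 1 — an amplitude-free
   kinetics descriptor. The FMR baseline is the pre-damage *mean* RFI
   (exactly 1 by construction) rather than the single frame at t0,
   which would inject single-frame noise into every FMR value.
6. **Scalars.** max RFI and its time (earliest frame on ties), t50 (time
   from damage of the first post-damage frame with FMR ≥ 0.5; linear
   interpolation between bracketing frames is available but off by
   default, since the discrete "time point" convention is the common
   one), final FMR (last frame).

Time is measured from damage: `time_s = (frame − damage_frame) ·
frame_interval`, so pre-damage frames have negative times and t50 is
unambiguous. Coordinates are 0-based with half-open rectangles.

Population analyses operate on per-cell records: intensity-range QC
(defaults: green initial intensity 140–200, red 200–400, red > green —
the red-above-green rule keeps green→red bleed-through small relative
to the red signal), rank clustering into k equally sized groups by
final FMR (sizes differing by at most one, larger groups first),
heatmap row ordering by mean FMR over a frame window (default frames
15–150 inclusive, read as frame indices; descending so strong
recruiters are on top — both choices configurable), ordinary
least-squares regressions (R² of a constant response is defined as 0),
per-cell red/green FMR-ratio series (masked before `start` frames
after damage and wherever the denominator FMR is below δ = 0.05,
because the ratio of two near-zero FMRs is pure noise), and per-frame
mean ± SEM (sd/√n, ddof = 1) summaries. Only descriptive statistics
are produced; no hypothesis testing or multiplicity correction is in
scope.

Two intensity scales coexist deliberately: QC ranges refer to *raw*
camera counts (pre-damage nucleus mean on unfiltered frames), while the
curves' `I0` is on the corrected (filtered, ratio-normalized) scale.
The intensity–kinetics scatter uses the raw scale by default
(`x_source="raw"`), matching how cells are selected at the microscope.

## Split-view handling

A split-view stack carries the two emission colours on two halves of
one camera frame. `split_channels` cuts along the configured axis and
aligns the second half by an integer-pixel offset; the offset is a
fixed per-hardware-session constant, either supplied in the
configuration or estimated once by exhaustive normalized
cross-correlation over ±max_shift on a pre-damage frame (ties broken
toward the smaller shift, then smaller dx, then dy). Registration is
integer-pixel only: the medMax statistic is insensitive to sub-pixel
misalignment at stripe scale, and sub-pixel resampling would correlate
noise between pixels. An odd split dimension drops the last line of
the larger half with a warning.

## The synthetic-movie generator

Because no public raw movies exist for this kind of experiment, every
stage is validated against simulated movies with known ground truth.
The generator renders, per channel:

- recorded counts = `dark_offset + fluorescence` (default offset 100
  counts). Only the fluorescence bleaches (`e^(−k_b·frame)`, defaults
  3×10⁻⁴/frame green, 1.5×10⁻⁴/frame red — the low-excitation regime);
  the electronic offset is constant. Bleed-through (default 2%) is
  optical, so it transfers green *fluorescence* (not offset) into red.
- a uniform elliptical nucleus whose measured baseline (offset
  included) is drawn per cell from the QC ranges (green 140–200, red
  200–400), emulating expression variability;
- a damage stripe whose fold-increase follows the two-rate
  phenomenological curve `f(t) = A·(1 − e^(−k_on t))·e^(−k_off t)`
  after the damage frame. This is not a mechanistic binding model; its
  job is to produce recruitment curves with controllable amplitude,
  half-rise time (closed form `ln2/k_on` when k_off = 0, otherwise
  solved by bracketed root finding) and dissociation. Default rates
  make the green channel peak near 92 s and the red near 179 s,
  mirroring a fast recruiter–eraser pair versus a slow, persistent
  clamp;
- linear drift (default (0.008, 0.004) px/frame) with nearest-pixel
  rendering;
- camera noise. The default model is constant-SNR Gaussian noise,
  σ(x,t) = fluorescence(x,t)/SNR with SNR = 10 — the Gaussian
  approximation of signal-dependent shot noise; fixed-sigma Gaussian
  and Poisson models are options. SNR always refers to the
  fluorescence signal, not to signal + offset.

Geometry defaults are a self-consistent scaled scene: 0.11 µm/px (an
11 µm stripe spans 100 px), a ~10.6 × 8.8 µm nucleus in a 128 × 128
crop, 600 frames at 0.5 s after 10 pre-damage frames (standard mode)
or 0.1 s sampling with 3 pre-damage frames (fast mode). A 64 × 64
"small" preset backs fast-running property tests.

What the generator does *not* emulate: chromatin texture (the nucleus
is uniform, so the medMax rests purely on noise order statistics in
no-recruitment scenes — harder than real data in that specific
respect), mass conservation (recruitment does not deplete the
nucleoplasm), focus drift, rotation or shape change, spectrally
varying bleed-through, and read-noise on the dark background under the
constant-SNR model. Passing tests therefore demonstrate correctness of
the estimators and normalizations under controlled conditions, not
performance on any particular real dataset.

## Numerical choices

- Gaussian blurs use reflect boundary handling. Above σ = 16 px the
  blur is evaluated by FFT on the symmetric extension, which is the
  exact reflect-boundary convolution with the untruncated kernel;
  below, the separable spatial filter (truncated at 4σ). The paths
  agree to ~1e-5 relative.
- medMax uses a partial sort (`np.partition`); even counts take the
  midpoint of the central order statistics. Fewer than 20 pixels falls
  back to the median of all, with a warning.
- FMR is undefined (flagged `no_recruitment`) when max RFI ≤ 1 + 1e-6.
- FMR is invariant under a global gain on the raw intensities: the gain
  cancels in the bleach-correction ratio and in RFI. In floating-point
  arithmetic the invariance is bit-exact for power-of-two gains (exact
  scalings of every intermediate) and holds to ~1e-9 for arbitrary
  gains, where convolution sums do not distribute bitwise.
- Trace CSVs are written with 17 significant digits and read back with
  round-trip float parsing, so write→read is value-exact.
- All randomness flows through `numpy.random.Generator`; cohorts use
  `SeedSequence.spawn` so cells are independent but reproducible.

## Validation battery and problem sizes

`recruitkit.benchmarks` (run by `scripts/acceptance.py` and mirrored in
`tests/test_acceptance.py`) measures, from scratch at a given seed:
medMax against a full-sort oracle (1000 random inputs); DoG against a
direct dense-convolution oracle (33 × 33 impulse) and on constants;
bleach-correction recovery on a no-recruitment movie (k_b =
0.002/frame, SNR 10, 610 frames — worst |RFI − 1| typically ≈ 0.016);
the FMR contract over 100 random cells; t50 recovery over 20 cells
with randomized kinetics (A ∈ [0.3, 2], k_on ∈ [0.05, 0.5]/s, k_off ∈
[0, 0.05]/s); final-FMR clustering of fast-dissociating vs persistent
subpopulations (10 + 10 cells); the red/green FMR-ratio plateau under
identical kinetics (20 cells); recruitment-order resolution of a 0.3 s
onset shift at 0.1 s sampling without smoothing (50 cells); QC against
an independent predicate on boundary-straddling intensity pairs; and
split-view registration of 50 planted offsets (noise-free and at
texture SNR 5). The battery completes in roughly 4 minutes on one CPU.

Two measured quantities sit close to their natural thresholds by
construction: the every-frame |RFI − 1| bound (0.02) is ≈ 4 standard
deviations of the medMax sampling noise at SNR 10, and the t50 rank
correlation over 20 cells is sensitive to 0.5 s quantization ties.
Both are deterministic at a fixed seed.

## Known limitations

- The estimated max RFI is the maximum of a noisy series and is
  therefore biased slightly upward (and the FMR threshold with it);
  with heavy bleaching and low SNR, the medMax order-statistic noise
  floor additionally inflates amplitude measures. FMR-based *kinetic*
  quantities (t50, ratio, ordering) are robust to these effects; RFI
  *amplitudes* should be compared only between conditions processed
  identically.
- Drift is corrected for only by the ROI margin, not by tracking; with
  large drift the fixed nucleus mask leaks background into the
  bleaching correction.
- t50 without interpolation is quantized to the frame interval; the
  first-crossing convention biases it upward by at most one interval.
- Proprietary microscope formats, sub-pixel/nonrigid registration,
  flat-field calibration and interactive ROI drawing are out of scope.
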