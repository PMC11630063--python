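# Methods

## Model and assumptions

The measurement model: in a bright-field movie of a transparent embryo,
the heart is the only strongly *periodic* source of pixel-intensity
change. Blood flow, gut motion and drift are temporally irregular;
illumination varies between frames but multiplicatively and globally.
Under these assumptions the beat frequency is identifiable from
per-pixel spectra alone, with no segmentation of the heart's anatomy:
pixels over the heart share one dominant Fourier frequency, and the two
chambers share that frequency while differing in phase (counter-beating
chambers sit ≈ π radians apart). Everything downstream — band filter,
SNR filter, largest-connected-region rule, KDE mode — is a way of
finding that shared frequency robustly.

The estimate is intrinsically discrete: with `N` frames at `fps` Hz the
spectral resolution is `Δf = fps/N` (6 bpm for 130 frames at 13 fps), so
a correct call is "within one bin of truth", never exact off-bin.

## Pipeline stages and parameters

All defaults live in `fishbeat.config.PipelineConfig` and can be
overridden per run (YAML or API).

**Empty-frame gate.** A frame is *empty* when its mean intensity (on
[0, 1]) is below `empty_threshold = 0.01`; a well is voided when the
empty fraction reaches `max_empty_fraction = 0.05` (the boundary
rejects: 7/130 fails, 6/130 passes). Empty frames in a surviving stack
are replaced by the nearest preceding good frame: holding the last good
frame preserves the temporal grid (hence `Δf`) and injects no spurious
motion, at the cost of a slightly damped spectrum when a black frame
falls mid-beat. Deleting the frames instead would shift every later
sample in time; interpolation would manufacture data. This replacement
policy is this package's choice; the gate threshold itself is the
method's.

**Embryo localization.** Every `frame_stride = 5`-th non-empty frame is
edge-detected (Canny, σ = 2, hysteresis thresholds at Otsu of the
gradient and half of it) and voted through a circular Hough transform
with radii spanning `radius_range = (0.15, 0.45)` of the short image
side in steps of 4 px. Detection runs at `downscale = 2` for speed;
coordinates map back to full resolution. Candidate circles are binned
(8-px centers, 4-px radii); the modal bin's members are averaged, ties
broken by the lexicographically smallest bin for determinism. The crop
adds `margin_fraction = 0.10` of the radius on each side. Uniform
frames, or frames with no Hough peak, yield `no_embryo`.

**Brightness normalization.** Each frame is affinely mapped so its
1st–99th percentile spread becomes 0.9 and its *median* 0.5. All three
anchors are robust statistics: the obvious alternative — anchoring the
frame mean — couples the normalizer to the heart itself (the frame mean
oscillates at the beat frequency), which injects a faint but perfectly
periodic antiphase copy of the beat into every static pixel and
manufactures a spurious π-offset phase cluster. The map is idempotent,
order-preserving within a frame, and removes per-frame gain exactly;
constant frames pass through with a logged warning.

**Motion mask.** Rolling absolute difference with `window = 2` frames
after Gaussian blur (`blur_sigma = 2` px). The per-pixel score is the
*temporal mean* of the differences — the mean is robust to single-frame
glitches, whereas a max would promote them. The score is thresholded by
the triangle algorithm (suited to the heavily skewed histograms motion
scores produce: most pixels are static), opened with a 2-px disc, and
components under `min_object_px = 50` are dropped (8-connectivity; the
diagonal wall of a heart section must not split a region).

**Spectra and the periodic region.** Mean removal only, rectangular
window: with hundreds of pixels voting, the KDE mode is insensitive to
leakage, and windowing would trade bin-sharpness on exact-bin signals
for sidelobe suppression the method does not need. SNR is the dominant
peak over the mean of all other non-DC bins (peak excluded); the filter
keeps `snr ≥ 2` with an open upper bound. Band default 0.5–5 Hz
(30–300 bpm, the plausible range for fish embryo hearts across
temperatures). The largest 8-connected region of surviving pixels is
the heart; an amplitude-weighted frequency vote is available
(`estimate_heart_rate` operates on dominant frequencies only by
default, unweighted, as each pixel is one observation of the same
underlying rate).

**Rate estimate.** Fixed-bandwidth Gaussian KDE over the region's
dominant frequencies, bandwidth = one bin width, evaluated on a 512-
point grid over the band *plus the observed atoms* — so when most
pixels share one bin (the usual case) the returned mode is that bin's
frequency exactly, not the nearest grid point.

**Phase clustering.** Restricted to pixels whose dominant bin equals
the region's modal bin, so phases are comparable. k-means on
`(cos φ, sin φ)`, k from 1–3: silhouette is undefined at k = 1, so one
cluster is declared when the phases are nearly concentrated (circular
resultant length > 0.95) or when no k ≥ 2 reaches silhouette 0.4;
otherwise the silhouette-best k wins. Clustering is attempted from
`min_pixels = 100` (the three-cluster chamber structure is typically
visible only in large regions, but smaller ones still yield a usable
spread). Reported: (circular mean, count) per cluster plus the maximal
circular distance between cluster means.

**Movement QC.** Consecutive frames are registered by FFT
cross-correlation; a shift above `movement_px_fraction = 0.05` of the
crop width is a whole-embryo movement. Before
`min_stable_seconds = 5.0` the well is voided (`early_movement`: the
remaining stable window is too short for a useful spectrum); after, the
analysis window is truncated to the stable prefix (`late_movement`),
with correspondingly coarser bins (60·fps/n_kept bpm).

**Harmonic correction.** With two loops called (lo ≤ hi) and group
reference g (the *lower median* of the cohort's called rates —
deterministic for even counts and robust to uncorrected doubles;
available from 3 called estimates):

| condition | result | flag |
|---|---|---|
| `|hi/lo − 2| ≤ 0.15` and lo within 20 % of g | (hi/2 + lo)/2 | `halved` |
| both within 20 % of g | (hi + lo)/2 | `averaged` |
| both ≈ 2 g | (hi/2 + lo/2)/2 | `both_halved` |
| otherwise | no-call | `discordant` |

`ratio_tol = 0.15` absorbs bin discretization (234 vs 120 is a genuine
double at 6-bpm bins). `both_halved` extends the published one-double
rule to the both-axial case and is flagged distinctly for audit.
Without a group reference the ratio tests run alone (near-2 → halved,
near-1 → averaged). The correction presumes a *homogeneous* cohort: g
is only meaningful within one experimental group (strain ×
temperature), and rates spreading beyond ±`group_tol` of their median
will be reported discordant by construction. Finally `floor_bpm = 70`
(inclusive boundary: exactly 70 is kept) discards implausibly slow
calls; the floor is experiment-specific and user-configurable.

## Synthetic scenes: what they do and do not show

The generator renders a darker embryo disc (radius 30 % of the short
side) with smooth static texture on a bright well background, chambers
as discs with a flat-core/cosine-rim radial profile whose intensity is
modulated `A·sin(2πft + φ)` (A = 0.15 by default), distractors as
regions whose intensity follows a random walk smoothed to a ~1 s
timescale (a steep red spectrum concentrated below the detection band —
emulating slow blood-flow and gut drift; an unsmoothed walk retains
enough in-band energy to be mistaken for a weak heart in a quarter of
scenes, which real aperiodic drift does not), global per-frame gain
flicker, seeded all-black frames, and an optional rigid translation
event. Frames are quantized to the uint16 grid so written TIFFs
round-trip bit-exactly. Two-chamber scenes join the chambers through a
small junction region in phase quadrature with both — otherwise exact
counter-phase cancellation would split the periodic region along a
nodal line, which real (non-sinusoidal, asymmetric) chamber motion does
not do.

Harmonic plates double exactly one seeded loop of each affected well
(frequency × 2, chamber area halved), mimicking the axial view in which
both chamber contractions register per beat. The plate used for
validating the correction draws true rates uniform in 100–130 bpm: one
strain-and-temperature cohort, consistent with the group-homogeneity
assumption above. Doubles of rates above ~150 bpm would leave the 5-Hz
band and be rejected rather than corrected.

What passing on these scenes shows: the chain of segmentation,
filtering, spectral estimation, phase analysis and QC is correct for
signals with the assumed structure, across the full physiologic range
and against the modelled artifacts. What it does not show: robustness
to deforming heart boundaries, non-sinusoidal beat waveforms,
out-of-focus optics, eye/yolk dark regions that can also vote as Hough
circles, or genuinely aperiodic hearts (arrhythmia). Real acquisitions
remain the only test of those.

## Numerical choices and problem sizes

Default scene size is 512×512; the validation suites run at 256×256
(frequency/phase scenes), 160×160 (whole plates) and 128×128
(plumbing), chosen so the full suite and the acceptance script complete
on a single CPU at desk scale while every region stays far above
`min_object_px`. Scene geometry scales with image size. One master seed
fans out through `numpy.random.SeedSequence` substreams per well and
loop, so any single well is reproducible in isolation and all randomness
derives from one integer. Degenerate inputs are defined, not special-
cased ad hoc: constant frames skip normalization, an effectively
constant pixel (spectrum at roundoff level) has SNR 0, constant samples
have no triangle threshold (error), and a KDE over a single unique
frequency returns that frequency exactly.

## Known limitations

- One circle per well: multi-embryo wells and empty wells without any
  circular object are out of scope (`no_embryo`).
- The harmonic correction is defined for one or two loops; more loops
  are processed but not cross-corrected.
- Rates whose second harmonic exceeds the band cannot exhibit (and so
  cannot test) the doubling artifact.
- Phase structure is reported, not validated against anatomy; the
  intermediate-phase cluster is a boundary-interaction effect in both
  the model and, plausibly, the data.
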