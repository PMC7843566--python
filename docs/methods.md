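# Methods

## Signal model

The forward model is multiplicative light absorption on a static retinal
scene: the grey level of an ONH-tissue pixel at frame *n* is
`S(p) · (1 − g(p) · a(n)/100)`, where `S` is the static scene, `a(n)` the
pulsatile absorption in %A and `g` a per-pixel gain (1 on tissue, 0 on
large vessels). The analysis inverts exactly this model:
`A(n) = 1 − I(n)/I_avg(n)` applied to the ROI-mean intensity recovers
`a(n)` up to the trend normalization. Because the definition is a ratio,
the signal is invariant to global gain (illumination level, exposure) and
robust to slow drift.

## Trend estimation

`I_avg(n)` is a centred moving average with reflect padding; frames
flagged as artifacts are excluded from each window. The construction of
the trend is an estimator choice, and the window length matters more than
it looks: a moving average of length `W` attenuates a beat of period `T`
by `sinc(W/T)`, which is zero only when `W` is an integer multiple of
`T`. A fixed `W` = 1.5 s leaves −21 % of a 1.0 s beat's fundamental in
the trend (sign-flipped), which inflates the re-referenced beat amplitude
by ~17 %. The default is therefore adaptive: the beat period is estimated
from the autocorrelation of the coarsely detrended intensity trace
(plausible range 0.33–2.0 s) and the window is set to two beat periods,
which nulls the fundamental at any heart rate; 1.5 s remains the fallback
when no periodicity is detectable, and any fixed window can be configured.
Scale invariance and drift rejection (±10 % linear drift changes the
recovered amplitude by < 2 %) are asserted by tests.

## Registration

Eye movements are modelled as per-frame rigid motion (subpixel shift plus
rotation about the frame centre). Translation is estimated by phase
correlation with 1/50-pixel upsampling; rotation by a coarse grid over
derotation angles (default ±3° in 0.5° steps) scored by masked normalized
cross-correlation after alignment, refined by a bounded one-dimensional
search inside the winning bracket. The reference frame is the temporally
middle ok-flagged frame. Frames are resampled bilinearly; out-of-field
pixels are reflect-filled so the output carries no moving dark band (which
would bias any subsequent correlation), but they are marked invalid and
excluded from all ROI statistics. Artifact frames are flagged, never
dropped: blink frames by the frame mean exceeding a high quantile of the
sequence's temporal-median frame, blur frames by gradient energy below
half the sequence median. Measured accuracy on noise-free phantoms:
translation < 0.1 px RMS, rotation ≈ 0.12° RMS.

## Segmentation

The ONH mask is manual-first: a supplied mask is validated (non-empty,
single connected component) and used as-is, since the analysis region of
the original protocol is drawn by hand on the averaged registered image.
The automatic fallback thresholds the averaged image at a brightness
quantile (default 0.90; for scenes where the disc fills a large fraction
of the frame the quantile should be set from the expected disc fraction),
closes small texture gaps, keeps the largest component and takes its
convex hull. Vessels are detected by multiscale Sato ridge filtering
gated by a morphological black top-hat: a vessel is a *thin* dark
structure with a local dip of at least 15 % of the dynamic range, which
excludes the disc rim — the edge of a large dark region excites a ridge
filter but not the top-hat. The vessel mask is dilated with a circular
element of diameter 5 px ("5 pixels in size" is read as diameter;
configurable) and subtracted from the ONH mask; the resulting tissue ROI
must keep at least 500 px (configurable) or the run fails rather than
produce a noise-dominated trace.

## Pulses and parameters

Heartbeat starts are local minima of the %A trace (minimum separation
0.33 s, prominence ≥ 0.3 of the median beat amplitude, not adjacent to
flagged frames). Manual label files are the primary path and are refused
if they carry any diagnosis field (labelling is masked to grouping).
Automatic screening drops beats spanning flagged frames or with duration
(±25 %) or amplitude (±50 %) outliers; 2–7 beats are retained, trimming
to the 7 closest to the median duration if more survive. Beats are
re-referenced to their first sample, linearly resampled to the rounded
median beat length (truncation to the shortest beat is available), and
averaged pointwise; the SD across beats (ddof 1) accompanies the mean,
and the pulse duration is the mean of the individual beat durations.

Threshold crossings for steepness and FWHM are located by linear
interpolation between samples — at 25 frames/s, nearest-sample
quantization (±0.02 s) would be coarse against the population SDs of the
timing parameters. Ties at the peak resolve to the earliest sample. The
four steepness estimators (30–70 % rise, min-max, 47–53 % rise, maximum
central-difference derivative) agree exactly on a linear rise, which the
triangle family exploits as an oracle.

## Synthetic data

Two parametric beat families with exactly known descriptors close the
generator→extractor loop. The `triangle` family (linear rise to the apex
at `time_to_peak`, linear fall to zero at `2·fwhm`, flat tail to
`duration`) is analytically checkable: its FWHM equals half the
return-to-zero time, so feasibility requires `time_to_peak/2 < fwhm ≤
duration/2`. The `gamma` family is a gamma-variate
`A·(t/tp)^α·exp(α(1−t/tp))` — the standard smooth model for a fast rise
with slow decay — whose shape exponent is solved numerically so the
half-maximum width matches the requested FWHM. Sampling places the sample
nearest the apex exactly at the apex value, so a sampled beat carries the
specified amplitude and amplitude-recovery tests measure the pipeline
rather than the sampling grid.

The scene phantom is a bright disc (gain 1.4) with a darker vessel tree
(45 % absorption) on a smoothly textured background (3 % SD). Two
rendering details matter for realism. First, frames are windows onto a
larger retina: rendering happens on a reflect-padded scene which is
cropped after motion, because a zero-filled border that moves with the
frame is an artificial landmark that biases any correlation-based
registration by pixels. Second, the pulsatile gain does not stop abruptly
at the disc contour but falls off smoothly over a ~4 px apron beyond it:
perfused tissue does not honour a drawn boundary, and a hard modulation
step exactly at the ROI edge leaks into boundary pixels under subpixel
resampling, diluting the recovered amplitude. Blink frames are rendered
as uniform near-saturated grey, blur frames as Gaussian-blurred, and
sensor noise is added last from a seeded generator; identical specs and
seeds give bit-identical videos.

The default acquisition emulates the study conditions: 250 frames at
25 frames/s (10 s), ±4 px sinusoidal fixational drift, ~1 grey level of
sensor noise, and a 100×100 px field with a 35 px disc radius. The disc
fills a much larger fraction of the frame than in real fundus video — the
frame is kept small so the test suite and the acceptance run stay fast —
which makes boundary effects proportionally harsher than in real data,
not milder.

The cohort generator draws per-subject parameters from zero-truncated
normal marginals matching the published per-group means and SDs at the
published sample sizes (norm 19, OHT 17, prep 24, perim 50), and couples
peak amplitude and steepness to RNFL thickness through a Gaussian copula
at the requested within-group Spearman correlation (defaults 0.523 and
0.568, the pooled correlations of the real cohort). Repeated-measurement
sessions are generated with a known per-measurement relative noise SD,
which under the two-repeat ANOVA definition equals the expected CV.

What the phantoms deliberately do not model: wavelength-dependent
reflectance and pupil optics, choroidal or peripapillary signal, vessel
pulsation (large vessels are static), non-rigid intra-frame distortion,
and rolling shutter. Passing tests therefore show that the pipeline
inverts its own forward model under rigid motion, artifacts and sensor
noise — not that it handles every property of clinical recordings.

## Group statistics

Kruskal-Wallis (tie-corrected H, chi-square p), two-sided Mann-Whitney U
of each patient group against normals with Bonferroni correction (family
of 3 comparisons per parameter by default; a global family is
configurable), Spearman correlation with average ranks, OLS regression
reported per 10 µm RNFL, and the repeated-measures CV
`sqrt(within-subject MS)/grand mean` (exactly two repeats per subject
required). The implementations are thin layers over scipy.stats; tests
cross-check them against brute-force rank arithmetic and full enumeration
oracles for total n ≤ 12, against closed-form copula targets, and against
a type-I-error simulation at the study's sample sizes.

A caveat established by the replicate analysis
(`analysis/04_significance_pattern.py`): resimulating cohorts from the
published summary table treats every printed between-group difference as
a true effect. For the timing parameters the printed means differ by up
to ~0.8 SD, so simulated cohorts reject their null far more often than
the original data did (where those differences were judged
non-significant); conversely peak amplitude reaches p < 0.001 in ~85 % of
replicates, not all of them. The typical (median) replicate reproduces
the headline verdicts; the tail does not. This is a property of
summary-statistics resimulation, not of the test implementations.

## Numerical choices and degenerate inputs

Crossing searches fail loudly (naming the missing crossing) on
non-monotone rises or beats that end above half maximum; constant frames
register as identity with confidence 0; constant images yield empty
vessel masks; an all-flagged sequence, an empty ROI, a too-small ROI and
a non-positive trend are hard errors. Video I/O is lossless multi-page
TIFF (8/16-bit); codec-based containers are rejected because sub-percent
intensity signals do not survive lossy compression. All randomness — in
phantoms, cohorts and noise — flows through explicit integer seeds.
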