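# Methods

This note documents the models and estimators implemented in `condquant`,
the defaults chosen where the procedure left a choice, and what the
synthetic-data validation does and does not demonstrate about real data.

## Image model and synthetic scenes

A condensate scene is a two-phase object model: dense spherical objects
(intensity `I_d`) over a dilute background (`I_b < I_d`), with a client
channel carrying `P·c_out` inside and `c_out` outside (partition
coefficient `P`) plus a bleedthrough fraction `β` of the scaffold channel.
Rendering applies, in order:

1. an isotropic Gaussian PSF, σ given in nm and converted through the
   pixel size (default σ = 250 nm, a typical confocal lateral PSF width;
   default pixel size 207.6 nm/px, i.e. a 106.3 µm field sampled at
   512 px). The blur kernel is normalized and applied with periodic
   boundary handling so total intensity is conserved exactly; objects are
   kept away from the border so wrap-around is negligible;
2. Poisson photon noise on the blurred intensity (default 20 photons per
   intensity unit) followed by additive Gaussian read noise (default
   σ = 0.2 intensity units) — the standard fluorescence-camera model.

Object placement is rejection sampling with a 10,000-attempt cap and a
minimum centre separation; failure is reported, never silently packed.
Every generator is a pure function of (config, seed), with per-object
sub-streams so adding an object does not perturb earlier ones. All
ground-truth values (true separation factor, partition coefficient,
recovery half-time, conservation fraction, hydrolysis rate) are computed
from the noiseless pre-blur object model, never re-estimated from the
rendered image.

The filament generator renders smoothed persistent random walks of fixed
total intensity; with probability `b` a path is re-drawn along one of a
few shared centerlines plus sub-pixel jitter. This emulates the *readout*
of bundling (signal concentration raises the image CV monotonically in
`b`) without any physical model of filament mechanics. Bundling decisions
draw from a sub-stream separate from path shapes, so `b` is a strict
no-op for a single path.

## Segmentation and screening

The reference procedure used a pretrained star-convex deep-learning
segmenter; this package deliberately substitutes a deterministic pipeline
(its own design choice, for reproducibility without model weights):
Gaussian smoothing (configurable σ, default 1 px; 0 for unblurred data),
thresholding at `median + k_seg · 1.4826·MAD` of the **raw** image (a
robust background pre-estimate usable before any segmentation exists;
taking the level from the raw rather than the smoothed image keeps
smoothing from lowering the bar and ballooning masks), 8-connected
component labelling, and an optional distance-transform watershed to
split touching objects. External label maps can be screened and
quantified through the same functions.

Screening removes objects with area strictly below 9 px (a ~300 nm
diameter spot at this sampling) or mean intensity strictly below
`background mean + 3·STDEV`; objects exactly at a threshold are
retained. "Intensity" in the screen is the object **mean** (consistent
with the mean-based enrichment definitions). The background for
screening and enrichment is all pixels outside the label map, with no
dilation buffer. Screening is idempotent and survivors are relabelled
contiguously.

Conventions fixed throughout: population standard deviation (`ddof = 0`;
for whole images the sample/population difference is negligible, but the
convention must be fixed), 8-connectivity, pixel-centre 0-based
(row, col) coordinates. The separation factor is measured on the
maximum-intensity projection and applies no background subtraction; the
enrichment is measured on the best-focus slice (maximal per-slice
intensity STDEV, ties to the lowest index). Whether a bleedthrough
correction applies to the separation factor is left to the caller (none
by default).

## FRAP

In vivo traces are double-normalized:
`r(t) = (ROI − ROI_bg)/(cell − cell_bg)`, anchored so the mean of **all**
pre-bleach frames is 100% (the procedure specifies "before bleaching"
without a frame count; the all-frames mean is the lowest-variance choice).
Any multiplicative, frame-wise acquisition decay shared by ROI and
whole-cell signals cancels exactly — verified numerically to < 1e−10.
In vitro traces (no whole-cell reference in a droplet field) anchor the
background-corrected ROI alone.

Recovery is fitted on post-bleach points only with
`y = y₀ + A·e^(−x/t)` (A < 0 for recovery), by deterministic
least squares: `y₀` initialized from the mean of the last 10% of points,
`A` from the first post-bleach value, `t` from the first 1/e crossing
(else half the span), bounds `t ∈ (0, 100 × span]`, no random restarts.
`t½ = t·ln 2` exactly. Flat or unidentifiable series return
`converged=False` with a diagnostic instead of raising. The immobile
fraction is exposed as a clearly-labelled derived convenience, not part
of the original readout. Aggregation resamples events onto a common grid
(the shared acquisition grid when identical, else linear interpolation),
reports the per-timepoint mean ± STDEV, and fits the mean curve.

## Per-cell accounting and division

Cell outlines and midline lengths are inputs (outline extraction from
phase contrast is out of scope). The per-image scalar background (mean
outside all cell masks) is subtracted before summing. Intensities and
areas satisfy `total = cluster + cytoplasm` exactly; fluorescence
concentration is intensity/area; the enrichment factor is cluster over
cytoplasm concentration (NaN-flagged without a cluster). Cluster axes are
ellipse-equivalent major/minor axis lengths from intensity-unweighted
mask moments — adequate for mask-based scaling analyses, but not claimed
to reproduce axis values measured on super-resolution images with an
unknown estimator. Conversion of enrichment factors to absolute molar
concentrations requires volume assumptions the 2D measurement cannot
supply; it is exposed as a formula with a caller-supplied volume
fraction.

Division conservation is
`100 · Σ daughter intensity / mother intensity`, background-corrected,
computed separately for cluster and total signal. In the generator,
the conservation parameter `c` applies to the cluster signal in fission
mode (daughters receive `c·f·M` and `c·(1−f)·M`) and to the total signal
in disintegration mode (no daughter clusters; `c` of the mother's total
redistributed diffusely) — matching the two distinct conservation
statistics the assay reports. Cluster counting averages only over cells
with at least one cluster; constriction colocalization uses a
configurable axial tolerance (default 0.5 µm — the underlying procedure
states none).

Snapshot populations sample cell lengths uniformly on 3–8 µm (a typical
rod-cell length range over the cell cycle) with cluster long axis
`a + m·length + ε` and total intensity `κ · area`, i.e. constant
fluorescence concentration — the condensate size-scaling regime.

## GTPase assay

The coupled assay consumes one NADH per GTP hydrolysed, so the hydrolysis
rate equals the NADH oxidation rate. After pointwise subtraction of the
no-enzyme control (interpolated onto the reaction grid), the rate is the
OLS slope of A340 converted by Beer–Lambert with ε₃₄₀ = 6220 M⁻¹cm⁻¹ and
light path 0.248 cm (instrument defaults, overridable). The fitted window
is the contiguous stretch (default 20 min, ≥ 10 points) with maximal
|slope|, skipping lag phases, and is reported in the result. A corrected
slope that is positive beyond 3 standard errors is flagged as an assay
artifact rather than reported as a negative rate.

## Validation scope and problem sizes

The test suite and `scripts/acceptance.py` validate recovery of generator
ground truth: exact (≤ 1e−6 relative) on noiseless, unblurred data, and
within stated bands under the default acquisition model (separation
factor within ±5 percentage points over 20 scenes; corrected enrichment
within 10% at β = 0.1 over 20 scenes; FRAP median `t` bias < 5% over 200
events at 2% noise; fission conservation mean within 87 ± 2% over 50
events; GTPase rate < 1% on clean traces). Problem sizes (128×128 scenes,
20 seeds, 200 FRAP events, 50 divisions, 300 snapshot cells) were chosen
as the smallest populations at which the Monte-Carlo error of these
summaries is comfortably below the bands being checked.

What passing does **not** show: the generators share the estimators'
additive two-phase world view — they do not emulate out-of-focus haze,
uneven illumination, drift, detector nonlinearity, cell autofluorescence
or segmentation ambiguity of irregular condensates. Recovery here
demonstrates internal consistency and absence of estimator bias under
the stated noise model, not performance on arbitrary real acquisitions.
The systematic +1–2 point separation-factor offset under blur (PSF halo
counted into masks) is visible in the acceptance output and is inherent
to threshold segmentation of blurred two-phase images.
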