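# Methods

This note documents the models, numerical choices and known limitations of
`cryoraman`. It is the package's own account of its science; every number
quoted here is computed by the test suite or the analysis scripts.

## Spectral quantification

Each pixel's spectrum lives on a shared, strictly increasing wavenumber axis
with near-uniform spacing (nominal 4.83 cm⁻¹ per step; the step is derived
from the axis, and every step-denominated rule uses the derived value, so
coarser or finer gratings work unchanged). Four marker bands are built in:

| band  | search range (cm⁻¹) | start (cm⁻¹) | assignment |
|-------|---------------------|--------------|------------|
| ice   | 3,087–3,162         | 3,125        | OH stretching |
| amide | 1,610–1,710         | 1,660        | amide I / alkyl C=C |
| dmso  | 650–740             | 673          | symmetric C–S stretch |
| dna   | 760–810             | 785          | O–P–O backbone |

The amide range is symmetric about the 1,660 cm⁻¹ center with a span
comparable to the other bands.

**Window finding.** Within the band range the local maximum nearest the
band's starting wavenumber is the peak (plateaus tolerated; samples at the
in-band minimum are never peaks, so a flat baseline cannot masquerade as
one). Each flank is walked outward; the boundary sits at the first
first-difference (taken toward the peak) whose magnitude falls to
`derivative_sensitivity` (default 0.1) times the difference one step further
in. The scan direction of the published rule is ambiguous for asymmetric
peaks; the outward walk was chosen because it is well defined on both flanks
and lands in the documented 4–8-step width regime. Boundaries are clamped to
the band range, then the total width is clamped into
`[min_peak_steps, max_peak_steps]` (default 4–8) by trimming the longer
flank / growing the shorter one, keeping the maximum central. A fully
constant in-band spectrum is flagged flat and given a minimal window whose
integrand is identically zero.

**Integration.** The within-window minimum is subtracted (no fitted
baseline — deliberately literal) and the remainder integrated by the
trapezoid rule on true wavenumber spacing. This makes the integral exactly
linear in amplitude, invariant to constant offsets, exact on
piecewise-linear peaks, and nonnegative.

**Cosmic-ray handling.** Spikes are single-pixel outliers of the integrated
map. A pixel is flagged when it exceeds its 8-neighborhood median by more
than `k·1.4826·scale` with k = 5, where the scale is the neighborhood MAD
floored at 10% of the neighborhood median and 1% of the map maximum. The
floors matter: an 8-sample MAD is a very noisy scale estimate, and without
them the detector flags ~1% of pixels on any realistically noisy map —
enough to trip the 10-pixel rejection on every image. With them, false
positives are confined to a handful of sharp-boundary pixels whose
neighborhood is dominated by the other compartment (at most the four
axis-extreme boundary pixels of a compact cell), while true cosmic rays sit
orders of magnitude above any threshold. Flagged pixels are replaced by the
mean of their available 8 neighbors; detection and replacement repeat up to
3 passes. If the first pass flags more than `scatter_reject_threshold`
(default 10) pixels the map is marked rejected and left untouched. The
pipeline-level rejection counts spikes on the DMSO map by default
(`spike_qc_band`); a union over the DMSO and ice maps is available but is
twitchier at compartment boundaries.

## Segmentation

The cell outline is found on the amide I map: Sobel gradient magnitude,
thresholded at `edge_sensitivity` (0.5–0.9, default 0.65) times Otsu's
threshold on the gradients (lower sensitivity ⇒ more edges); dilation with
perpendicular line structuring elements of length 3; hole filling; clearing
of border-touching components; smoothing; largest 4-connected component.
Cells touching the image border are thereby rejected, as are components
under 50 pixels (the validation regime of the mask-based estimate).

Two choices here were genuinely open and were settled by measurement on
ground-truthed phantoms:

- **Smoothing erosions.** One radius-1 diamond erosion leaves the mask
  dilated by roughly a 1.5-pixel ring (disk-phantom IoU ≈ 0.83). Two 3×3
  square erosions cancel the dilation introduced by the edge band and the
  line elements (IoU ≥ 0.97). Both the count and the element are config
  (`smooth_erosions`, `smooth_strel`).
- **Boundary refinement** (`boundary_refine`, default on). Structuring
  elements localize the outline only to about half a pixel; the residual
  bias leaks a handful of cell pixels into the channel mean, which at
  strong partitioning (P ≈ 0.2) biased P by up to ~6% on some seeds. After
  the erosions, each pixel in the one-pixel band around the outline is
  re-classified by amide intensity against the midpoint of the median cell
  and background levels. Worst-case P error across 60 phantoms drops to
  2.8%, with cell IoU ≥ 0.987 and centroid error well under a pixel.

Ice is thresholded on the OH map with Otsu's method followed by a few
ISODATA refinements (threshold ← midpoint of the two class means). The
refinement is needed because Otsu returns the first bin of its optimal
plateau: with a wide empty gap between the OH background and the ice mode,
that is the gap's bottom edge, where integration jitter occasionally pushes
stray background pixels across. A manual threshold can be supplied
(`ice_threshold`). Supra-threshold pixels inside the cell are intracellular
ice; single-pixel intracellular components are discarded as shot noise.
Channels are defined by complement: extracellular space that is not ice, so
cell + extracellular ice + channel tile the image exactly once.

## Metrics

- **P = C_o/C_i** with C_o over channel pixels only (ice carries no solute)
  and C_i over all cell pixels, including intracellular ice — the
  physically meaningful per-area average for an ice-bearing cell;
  `include_ice_in_ci=False` switches to the liquid-only mean.
- **CV** uses the sample (n−1) standard deviation over cell pixels divided
  by their mean; scale-free by construction.
- **AIC** is the pixel-count ratio |intracellular ice| / |cell|.
- **Line scans** label each pixel of an image row by compartment. The
  cross-validation estimator `line_scan_ratio` pools 5 rows centered on the
  cell centroid and excludes samples at cell/channel membrane crossings: a
  single row crosses only ~2R cell pixels, whose mean carries the full
  intracellular heterogeneity (≈3.4% SE at the default 15% CV), and
  membrane-straddling samples are representative of neither side.
- **Gap profiles** bin channel pixels by Chebyshev distance to the nearest
  extracellular-ice pixel (default 6 equal-width bins) and report the mean
  DMSO intensity per bin; a rising profile is solute polarization.
- **Nucleus/cytosol ratio** segments the nucleus as the Otsu-supra-threshold
  DNA region inside the cell and divides the nuclear DMSO mean by the
  cytosolic one.
- **Replicate summaries** report mean ± SE (SD/√n) and, between two groups,
  a two-sided Welch t-test (unequal variances; the safer default where the
  equal-variance assumption is unverified), with significance at p < 0.05.
  A pooled-variance Student variant is available (`welch_ttest=False`).

The lateral resolution check uses the Abbe diffraction limit λ/(2·NA) —
0.2956 µm ≈ 0.3 µm at 532 nm through NA 0.90. The Rayleigh form 0.61·λ/NA
is available behind a flag but does not reproduce the 0.3 µm figure.

## Synthetic phantoms

A scene is a disk cell (default radius 10 px with a radius-4 nucleus)
centered in a 45×45 raster, a one-pixel unfrozen halo hugging the membrane,
and the remaining extracellular space tiled by Voronoi cells around random
crystal seeds, with ridge pixels (second-nearest minus nearest seed distance
below `channel_width`, default 2 px) forming the unfrozen channels.
The tiling is smoothed so that no compartment keeps near-isolated pixels:
an isolated one- or two-pixel protrusion of ice into a channel is
statistically indistinguishable from a cosmic-ray spike for any local
outlier detector, a pathology of raster Voronoi ridges that smooth real
crystal boundaries do not exhibit. The smoother first shrinks ice pixels
lacking a neighborhood majority (monotone, hence convergent), then flips
channel slivers buried in ice.

Concentration fields: intracellular DMSO is lognormal with relative SD
`heterogeneity_sd` (default 0.15, matching reported intracellular CVs);
channel DMSO is flat at `dmso_channel` or rises with distance from the ice
interface when `gradient_toward_ice` is set; ice carries zero DMSO; the
nucleus is scaled by `nucleus_dmso_factor`. Amide marks the cell (with 8%
heterogeneity), OH is high and uniform on ice, DNA marks the nucleus. True
P, CV and AIC are recomputed from the stored fields, not stored as targets.

Intracellular ice pockets are compact lattice disks of 21 px (radius ~2.5)
plus at most one 13-px disk, sized so the realized area fraction lands
within 0.02 of the requested value; the shapes have no single-pixel tips,
for the same spike-detector reason as above.

The renderer emits one Gaussian line per band (SD = 2 axis steps, chosen so
the derivative rule lands in the 4–8-step width regime) on a constant
baseline of 0.5, adds zero-mean Gaussian noise with SD =
`noise_sd`·signal + floor (default 2% + 0.002; a Poisson shot-noise variant
is available), and finally injects `n_spikes` single-sample cosmic rays at
pixels separated by ≥2 px, placed within the DMSO band by default so their
effect on the analyzed map is deterministic. All randomness flows from one
seed through named substreams (geometry, field, noise, spikes), so stages
vary independently and a fixed seed reproduces a byte-identical cube file.

**What the phantoms do not emulate:** smooth membrane transitions (real
cells show a gradual intensity change across the membrane; phantom
boundaries are sharp, which is the *harder* case for mask-vs-manual
agreement), fluorescence backgrounds and baseline drift, correlated detector
noise, non-circular cell shapes, and any physics of ice growth or solute
transport. Passing tests therefore demonstrate the correctness and
stability of the analysis chain under the assumed statistical structure,
not instrument-level robustness.

## Problem sizes and determinism

The standard validation sweep is 20 phantoms (scene seeds 1–20; true P
cycling through 0.2/0.5/1.0/1.3/2.0 at default noise), about 0.7 s per
phantom end to end. On it the automated P agrees with a 150-pixel manual
region computation to within ~2% (max) and with the line-scan estimate to
within ~3.5%; median truth error is ~0.4% and the sign of P−1 is always
recovered. Noise-free phantoms recover P to ≤0.5% through the automated
masks (to machine precision through the truth masks — any single-pixel mask
difference on a ~317-px cell already moves P by ~0.3%, which is why the
tighter bound applies only to the quantification path), and AIC and CV to
within 0.002 with intracellular ice and heterogeneity switched on. All
tests are seeded; hypothesis runs derandomized.

## Known limitations

- The derivative-threshold reading (outward walk) is one of several
  consistent with the published description; it is recorded as a design
  choice, not asserted as the original implementation.
- The spike detector cannot distinguish a true spike from a genuine
  single-pixel structure; structures that thin are below the method's
  resolving intent.
- Otsu-based ice and nucleus thresholds assume bimodal histograms; weak ice
  contrast degrades the split (use `ice_threshold` to override).
- `run_analyze` quantifies one cell per image (the largest interior
  component); for rasters that captured several cells,
  `segment_all_cells` returns every interior component and the metrics can
  be applied per component.
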