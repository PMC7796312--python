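# Methods

`colorfaf` implements quantitative analysis of *color fundus
autofluorescence* (color-FAF): fundus autofluorescence excited at 450 nm
and recorded with a color sensor, so that each pixel carries a green
emission component (GEFC, 500–560 nm band — minor fluorophores such as
advanced glycation end products, FAD, collagen/elastin) and a red
emission component (REFC, 560–700 nm band — dominated by lipofuscin).
The package covers the full chain from raster to cohort statistics, plus
synthetic generators that stand in for clinical data, which are not
publicly available for this kind of study.

## Spectral model

The stored image is treated as raw 8-bit sensor counts: GEFC is the G
channel and REFC the R channel, taken as floats with no photometric
calibration (no qAF-style reference), white-balance or gamma correction.
The blue channel lies below the 500 nm emission cut-on and is ignored
for quantification. Derived per-pixel quantities:

- intensity `I = (REFC + GEFC) / 2`;
- green fraction `f = GEFC / (GEFC + REFC)`, undefined (NaN, never
  imputed) where both components are zero;
- estimated emission wavelength
  `λ(f) = λ_R · (λ_G / λ_R)^f`, with band centers `λ_G = 530 nm`,
  `λ_R = 630 nm`.

The wavelength map is a modeling choice, not a device calibration: the
device literature describes an exponential model in the component
proportion without giving its form. Geometric interpolation between the
band centers is exponential in `f`, maps the endpoints to the band
centers, and is strictly monotone; the constants are overridable via
`SpectralConstants`. Downstream statistics never depend on the exact
form, only on monotonicity.

Two diagnostic scatter sets are exposed as plain point lists: the
*segment graph* (wavelength vs intensity) and the *RG graph* (REFC vs
GEFC), one point per defined pixel, row-major.

## ETDRS grid and site selection

The standard ETDRS macular grid (ring diameters 1/3/6 mm, quadrant
boundaries on the ±45° diagonals) is centered on the fovea position
given in the metadata; physical distances use the per-image scale
(default 5 µm/pixel, the device's nominal resolution). Ring membership
is half-open (`d < 500`, `500 ≤ d < 1500`, `1500 ≤ d < 3000` µm) and a
pixel exactly on a diagonal belongs to the counter-clockwise sector, so
the nine sectors partition the 6-mm disc exactly. Nasal/temporal labels
derive from the stored image side of the optic disc (default: right for
OD, left for OS under the erect, non-mirrored camera presentation);
laterality relabeling therefore swaps nasal and temporal masks and
nothing else.

Human graders pick a measurement spot per sector that avoids vessels
and lesions. That manual step is formalized as the **largest inscribed
clean disc**: with an exclusion mask as input, every in-sector clean
pixel is scored by its Euclidean distance transform clearance (distance
to the nearest excluded or out-of-sector pixel), and the maximizer wins,
ties broken by smallest row then column. Measurement averages GEFC,
REFC and wavelength over the open disc (`d < r`) of default radius
100 µm around that site; a radius of one pixel selects exactly the
center pixel. The study does not state its ROI size, so the radius is
configuration, and a whole-sector mode (mean over all clean defined
sector pixels) is available for sensitivity analysis. A sector whose
best clearance is below the radius yields "no clean site" and is
reported missing rather than measured badly.

## Statistics

Group comparisons use the two-sided **pooled-variance (Student)
unpaired t-test** by default. The pooled choice is deliberate: applied
to the published foveal summaries (DM without edema, n = 152, vs
controls, n = 18) it reproduces the printed p = 0.015 (GEFC) and
p = 0.006 (REFC), whereas Welch's test does not; Welch remains available
via `variant="welch"`. The summary-statistic form (mean/SD/n per group)
and the raw-sample form agree to machine precision, so printed cohort
tables can be re-analyzed without raw data.

One-way ANOVA reports least-squares means (equal to group means in a
one-way layout) and Scheffé pairwise p-values
`p_ij = SF_F((Δm)² / ((k−1)·MSW·(1/nᵢ+1/nⱼ)); k−1, N−k)`, which are
conservative relative to unadjusted contrasts and collapse to the pooled
t-test when k = 2 (F = t²). Pearson correlation uses the standard
product-moment estimate with the two-sided t-approximation p-value.
Significance is judged at p ≤ 0.05 with no multiplicity correction
across sectors, matching the source analysis. Degenerate inputs
(zero-variance samples, constant correlates, strata with n < 2) are
flagged or skipped with log entries, never silently tested.

## Synthetic images

`generate_eye_image` paints sector-wise constant GEFC/REFC means into
the grid (defaults: the published no-DME sector summaries; a `dme` flag
adds the published DME-minus-no-DME foveal uplift of +25.9 / +28.6),
adds additive Gaussian noise truncated to [0, 255], rounds to 8 bits,
and overlays:

- vessels: smooth random-walk curves entering from the image border
  (default 4, width 60 µm, channels scaled by 0.35);
- lesions: discs — microaneurysms (small, dark), hemorrhages (dark in
  both channels), hard exudates (bright).

The exclusion mask is the union of vessel and lesion footprints dilated
by one pixel, so every altered pixel is excluded and the clean pixels
still carry the programmed field; with zero noise and no artifacts the
measured sector values equal the programmed ones exactly, which anchors
the end-to-end identity test. Vessel and lesion geometry is cosmetic —
enough to exercise site selection, with no biological calibration — and
no optics, media opacity or acquisition-quality failures are modeled.

## Synthetic cohorts

`generate_cohort` draws one-row-per-eye tables with the study's group
structure: 18 controls and 193 diabetic eyes (39 no DR, 22 mild, 100
moderate, 32 sight-threatening), 41 of the retinopathy eyes carrying
center-involving DME. Sector intensities come from the published
DME-stratified mean ± SD values (controls use the published control
foveal values; their non-foveal summaries are unpublished and reuse the
no-DME values). Central retinal thickness is 275 ± 25 µm without DME
and 360 ± 55 µm floored at 300 µm with DME (the center-involving
definition); inner/outer ring thicknesses use plausible per-status
normals. HbA1c, diabetes duration and visual acuity are drawn per DR
grade from the published demographics. Intraretinal-fluid flags are
cosmetic: foveal IRF accompanies DME, other sectors get small per-status
probabilities.

**Marginals.** Intensities and the DME thickness are "Gaussians
truncated at the lower bound", but naive truncation would shift the
moments (at the foveal no-DME marginal, 17.4 ± 14.1, the mean would
move by about +2.9). The generator instead *moment-matches*: it solves
for the parent normal whose truncated distribution has exactly the
configured mean and SD (the sd/mean ratio determines the truncation
point by a 1-D root-find). Two published sector summaries
(73.5 ± 79.8 and 104.4 ± 88.9) have SD/mean ratios no truncated normal
can reach (the family's ratio is bounded by 1); those fall back to a
gamma marginal with the exact configured moments. Sample moments
therefore converge to the configured values for every sector.

**Intensity–thickness coupling.** The published pooled Pearson
correlations over the 193 diabetic eyes — 0.37 (foveal GEFC vs central
thickness), 0.42 (foveal REFC), 0.49 (inner-nasal GEFC) — are the
configured quantities. Because DME eyes have both higher foveal
intensity and higher thickness, the DME/no-DME mixture alone already
induces a pooled correlation near 0.4; the generator calibrates the
within-status latent correlation of a Gaussian copula so that the
*pooled population* correlation equals the configured value. The pooled
covariance is written as the weighted within-stratum covariance — a
polynomial in the latent ρ via the Hermite expansion of each marginal's
quantile map — plus the between-stratum term, and `brentq` solves for
the latent ρ (slightly negative for the foveal defaults, about 0.68 for
inner-nasal). GEFC and REFC share the thickness latent and are
conditionally independent given it; infeasible targets raise a
configuration error. Controls are left uncoupled. Sectors are otherwise
mutually independent: the cross-sector covariance of real retinas is
unreported and not emulated, so tests exercising cross-sector structure
say nothing about real data.

## Determinism and numerics

Every generator takes a seed and is bit-reproducible under it; the
replicate drivers derive per-replicate seeds as
`(base · 1 000 003 + i) mod (2³¹ − 1)`. Hermite expansions use order 12
with a 4001-point trapezoid quadrature on z ∈ [−8, 8]; quantile maps
clip latent CDF values to [1e-16, 1 − 1e-16]. Marginal objects are
cached by parameters so replicate draws share the calibration work.

## Problem sizes

Tests run on reduced rasters (15–100 µm/pixel, 61–1205 px images) —
the geometry scales exactly, so nothing is lost relative to the
device's native 3680 × 3288 at 5 µm/pixel, which the generator also
supports. Replicate studies use 200 cohorts of 211 eyes; exhaustive
site-search oracles run on ≤ 201 × 201 instances.

## Known limitations

- The wavelength model is an assumption (see above); absolute
  wavelength values should not be compared across devices.
- No photometric calibration: intensities are device counts, so
  cross-device or cross-session comparisons inherit gain differences.
- Vessel/lesion segmentation is out of scope — exclusion masks are
  inputs (the generator provides ground-truth masks).
- The generator draws intensities by DME status only; DR-grade effects
  appear solely through the DME mixture, and cohort-level demographic
  structure (age, eye-quality exclusions) is not modeled.
- OCT processing is out of scope; retinal thickness enters as numbers.
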