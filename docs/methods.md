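# Methods

## The downgrading cascade

The pipeline estimates how many individuals of a large grazer an Arctic
landscape's annual digestible forage production can support.  Its core is a
per-pixel chain of multiplicative reductions applied to aboveground biomass
carbon:

1. **Unit canonicalisation.** The internal biomass unit is Mg km⁻²
   (1 Mg ha⁻¹ = 100 Mg km⁻²; 1 g m⁻² = 1 Mg km⁻²).  The declared input unit
   is converted on load; the default input unit is Mg C ha⁻¹.
2. **Carbon → total biomass**, × 2.03.  Biomass-carbon maps report carbon,
   not tissue; the factor inverts the carbon fraction assumed by such maps.
3. **Preferred-forage restriction with digestibility.**  Only forbs,
   graminoids and deciduous shrubs are treated as forage; evergreen shrubs,
   trees, mosses, lichens and algae contribute nothing (their dietary role
   is too poorly constrained, and omitting them is conservative).  Each
   preferred type contributes cover × digestibility (0.8 forb, 0.5
   graminoid, 0.6 deciduous shrub), with the shrub term halved again to
   reflect proboscidean preference for herbaceous forage and to avoid
   letting abundant shrub biomass dominate availability.  Percent cover is
   used as a proxy weight on total pixel biomass — i.e. biomass is assumed
   proportional to cover; no per-PFT biomass model is attempted.
4. **Forage/utilisation rate**, × 0.10: the fraction of digestible biomass
   assumed sustainably croppable without degrading the stand or the
   resident herbivore guild.  Reported utilisation spans roughly 7–87%
   across systems; the default takes the conservative low end.
5. **NPP conversion**, × 0.4: a grazer eats what grew this year, and in
   arctic vegetation annual production is roughly 0.4 of standing
   aboveground biomass.

All five steps are scalar multiplications, so the cascade is exactly
commutative and the result is exactly linear in every factor — properties
the test suite exploits (2.5 × the forage rate must give exactly 2.5 × every
total).  Stage tags (total_biomass → digestible → foraged → annual) exist
for reporting; their means shrink monotonically by construction.

Density is AgDB-annual divided by one animal's unrounded annual need from
the 2%-of-body-mass rule over a 365-day year.  Rounding (28/38 t yr⁻¹, the
nearest-thousand "~" headline counts) happens only at presentation;
half-up rounding is used when comparing against conventionally rounded
published figures, since banker's rounding turns ties the wrong way.

## Uncertainty and sensitivity

Biomass uncertainty enters through per-pixel standard errors: lower/upper
confidence limits are mean ∓ 1.96 × SE, the multiplier interpreting a 95%
prediction interval.  It is configurable because the aggregation behind
published "cumulative standard errors" varies between datasets.  The lower
limit is clipped at zero — negative biomass is physically meaningless.  The
sensitivity analysis is a deterministic 3 × 3 scenario grid ({LCL, mean,
UCL} × forage rate {0.05, 0.10, 0.25}), not a Monte Carlo propagation: with
a purely multiplicative model the extreme scenarios bound the response, and
the grid is monotone along both axes.  The low/high forage rates are
exposed in config rather than asserted, since reported utilisation rates
vary widely by system.

## The synthetic landscape generator

The generator emulates the first-order statistical structure of North
Slope-style input stacks so the pipeline can be exercised without real
data:

- **Latitudinal banding.** Ecological zones are horizontal bands (row 0 =
  north): coastal plain, foothills, mountains, boreal in the default
  four-band layout.  Band-mean biomass rises geometrically from north to
  south; the default south/north ratio is 2.0, matching the roughly
  two-fold contrast real Arctic biomass maps show across such transects.
- **Pixel texture.** Multiplicative lognormal noise (σ = 0.3 on the log
  scale) smoothed with a 2-pixel Gaussian kernel — lognormal keeps biomass
  positive and right-skewed, smoothing gives short-range spatial
  correlation.  No dataset states the true spatial covariance at 300 m, so
  the smoothing length is a free fixture parameter.  The noise field is
  normalised to unit mean within each band's land pixels: smoothing leaves
  few effective samples per band, and without the normalisation the
  realised band contrast would wander far from the configured ratio on
  small grids.
- **Cover.** Deciduous-shrub cover rises southward (0.10 north → 0.45
  south by default, approaching half of vegetated cover in the boreal
  band); graminoids dominate the north.  Per-pixel cover noise is small
  (σ = 0.02) and sums exceeding 1 are renormalised.
- **Water.** A smoothed random field thresholded at the configured area
  quantile; water pixels get zero biomass and zero vegetated cover and
  their own zone label (0).  Water is a true zero-forage habitat, not
  nodata.
- **SE.** A fixed fraction (0.15) of the pixel mean.
- **Calibration.** The default northern-band biomass level (1.2 Mg C ha⁻¹)
  is a calibration constant chosen so that default-pipeline densities land
  in a plausible 0–0.4 individuals km⁻² envelope; it is not a claim of
  fidelity to any real map.

What passing tests on synthetic stacks do show: the arithmetic of the
cascade, its exact linearity and conservation laws, determinism, and the
zonal bookkeeping.  What they do not show: fidelity of absolute densities
or totals for any real landscape — real biomass maps have spatially
structured error, cover–biomass relationships that are not proportional,
and landscape mosaics far richer than horizontal bands.

## Numerical and design choices

- Grids are abstract-georeferenced: row 0 is north, the pixel unit is
  metres, and no real CRS is asserted.  Layers persist as single-band TIFF
  (float32 continuous, int32 zones) with units, nodata value and pixel size
  recorded as JSON in the image-description tag; round trips are bit-exact.
- Nodata in any input layer propagates to nodata in outputs; water stays a
  real zero.  Zone areas count all valid pixels, so water counts toward
  area while contributing zero individuals.
- The all-zones summary row is the pooled computation over every valid
  pixel, which equals the area-weighted mean of zone means to 1e-10 (an
  invariant under test), never the unweighted mean of zone means.
- Damuth's law uses log base 10; the published coefficients reproduce the
  expected ~0.16–0.19 km⁻² range for a 3.9–5.2 t grazer only in that base.
- Counts and densities stay real-valued internally; every rounding is a
  rendering step.
- Deterministic ordering everywhere (zones sorted by label, JSON keys
  sorted) so repeated runs are byte-identical and diffs are stable.

## Problem sizes

The test suite exercises the full pipeline on grids from 8 × 8 (per-pixel
oracle comparisons) to 100 × 100 (property-based acceptance checks); the
packaged defaults generate 100 × 100 stacks.  The cascade is vectorised and
scales linearly in pixel count, so far larger rasters are limited only by
memory.

## Known limitations

- No seasonal intake variation or demographic structure (females and
  juveniles are folded into the adult-male body-mass range).
- No predation, disease, competition, fire, or landscape-exclusion
  adjustments: estimates are food-limited ceilings, not projections.
- The cover-proportionality assumption (step 3) is the least defensible
  link in the chain on real data; per-PFT biomass models would replace it
  where available.
- The generator models banding, gradients and water, but not realistic
  spatial covariance, riverine corridors, or the long right tail of real
  biomass distributions.
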