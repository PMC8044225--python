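# Methods

This note documents the models, the defaults and the design choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the numerical conventions used throughout.

## Units and conventions

Public APIs use the field's customary units — piezo position z in nm,
force in pN, heights and pixel sizes in µm, moduli in Pa, stresses in Pa,
times in s — and convert to SI internally for fitting. Pixel coordinates
are 0-based (row, col) with the origin top-left. All randomness flows
through `numpy.random.default_rng(seed)`; identical seeds and parameters
reproduce every dataset bit for bit.

## Contact mechanics

The forward model for a paraboloidal tip of radius R on an incompressible
(ν = 0.5) elastic layer of thickness h bonded to a rigid support is

    F(δ) = (4/3)·E/(1−ν²)·√R·δ^{3/2}·f(χ),  χ = √(Rδ)/h,
    f(χ) = 1 + 1.133χ + 1.283χ² + 0.769χ³ + 0.0975χ⁴.

f is the bonded-sample paraboloidal-tip thin-layer correction; it is
isolated in `bottom_effect_factor` so an alternative polynomial can be
swapped in one place. f(0) = 1 recovers the half-space Hertz law exactly.

Because the cantilever deflects by F/k, the indentation at piezo position
z obeys the implicit balance δ = (z − z₀) − F(δ)/k. The simulator solves
it per sample by monotone bisection to a relative tolerance of 1e−9
(g(δ) = F(δ) − k(z − z₀ − δ) is strictly increasing, so the root is
unique and bracketed).

Default probe: R = 35 nm, k = 0.068 N/m, ν = 0.5, 400 pN trigger — the
soft-cantilever, small-tip configuration typical of live-cell
quantitative-imaging AFM. The fitted quantity is an *apparent* elastic
modulus: indentation-rate and viscoelastic contributions are not modeled,
and nothing in the pipeline attempts power-law rheology or adhesion
(JKR/DMT) corrections.

## Force-volume pipeline

1. **Virtual deflection.** A line is least-squares fitted to the first
   30 % of samples (configurable) and subtracted from the whole trace.
   The baseline is "unidentifiable" when its residual SD exceeds 25 pN or
   when the corrected force at the end of the window rises above
   max(3×SD, 1 pN) — the data give no cleaner criterion, so these are
   documented defaults, and such curves are excluded from masking.
2. **Pass 1, linearized Hertz.** On the contact branch F^{2/3} is linear
   in the tip–sample separation s = z − F/k; a weighted line fit
   (weights ∝ F^{2/3}, three reweighting iterations, which counteracts the
   noise amplification of the 2/3-power transform at low force) yields
   z₀ = −b/a and E = (3/4)(1−ν²)a^{3/2}/√R. The contact branch starts at
   the first sustained (4-sample) crossing of a 3×baseline-noise force
   threshold and is refined once with the fitted intercept; fits use
   indentations ≤ 800 nm. Fewer than 8 usable points or a non-positive
   slope → `no_contact`.
3. **Substrate and flattening.** Pixels with pass-1 modulus > 65 kPa are
   the plastic dish. A plane α·row + β·col + γ fitted to their contact
   points defines the local substrate height; each pixel's height is the
   plane minus its own z₀ (the tip meets taller sample earlier). Small
   negative heights are clamped to 0 and counted. Fewer than three
   non-collinear substrate pixels aborts with a clear error.
4. **Pass 2, bottom effect.** Nonlinear least squares of the corrected
   model at the known height, with E free and z₀ constrained to ±20 nm of
   the pass-1 value — an unconstrained z₀ trades off degenerately against
   E on thin samples. A `refit_z0=False` mode fixes z₀ entirely (the
   modulus-only reading of the two-pass procedure); the default refits
   within the window. Pixels whose estimated height is below 50 nm are
   not refitted (χ diverges; they fall below the 100 nm mask anyway). On
   solver failure the pass-1 result is kept and flagged.
5. **Mask and bands.** Cell mask = height ≥ 100 nm AND modulus ≤ 65 kPa
   AND status ok. Band statistics are arithmetic means over masked pixels
   with height in [lo, hi) — lower-inclusive, upper-exclusive, so the
   2–5 µm and <2 µm bands partition cleanly at 2 µm.

## Colocalization

Channels are min-max normalized (the Phansalkar parameters assume [0, 1]
intensities), thresholded with t = m·(1 + p·e^{−qm} + k((s/r) − 1)) over a
square window with edge replication, and denoised with a binary median
(majority-vote) filter. Defaults k = 0.25, r = 0.5, p = 2, q = 10,
window 15 px are the method's published values as shipped by the common
auto-local-threshold implementations; all are configurable. The local
mean is clamped at zero: the separable running-sum filter can leave
−1e−18-scale means in empty regions, which would flip the threshold's
sign and mark exact-zero pixels as foreground.

The median filter's "neighborhood 16" is interpreted as a square window of
side 16 rounded up to 17 for a well-defined center; a radius
interpretation (side 2n+1) is available via `interpret="radius"`. The
filter operates on the segmentation mask, not the intensities — applying
it to intensities before thresholding was evaluated and degrades overlap
recovery several-fold, so the mask-filter order is kept.

Manders coefficients use the segmentation masks to realize the "signal
present in both channels" condition (raw confocal intensities are nowhere
exactly zero): M1 sums channel-1 intensity over mask1∧mask2 and divides by
its sum over mask1. Z-stacks are pooled — one coefficient pair per cell
from sums over all slices — with a per-slice-then-average option. For
conjunction (triple) colocalization the first-listed channel provides the
conjunction's intensity (`conjunction_intensity="min"` uses the pixel-wise
minimum instead), and the median filter is applied per channel before the
AND.

At SNR 5 the coefficients carry an intrinsic ~0.06 downward bias at full
overlap: the two channels' independent noise moves their mask borders
differently, so a border ring of genuine signal falls outside the partner
mask. This is a property of threshold-based object colocalization itself,
not of the implementation; the recovery tests budget for it.

## Quantification

- **Traction.** The summary region is the cell mask dilated by a margin
  (default 2 µm, via the Euclidean distance transform) to capture vectors
  "near" the cell. Total force = Σ|T|·spacing², mean stress = mean |T|
  over the region, so total = mean × area holds identically for any
  field. No PIV or inverse (FTTC) computation is performed — the package
  consumes traction fields.
- **FRET.** Cell ratio = ΣYFP/ΣCFP over the mask (a sum ratio, robust to
  dim pixels); the per-pixel ratio image flags CFP-zero pixels as NaN.
- **CTCF** = integrated density over the cell mask − cell area × mean
  background, with a required per-cell background mask.
- **Shape.** Aspect ratio from the second-moment best-fit ellipse
  (rotation-invariant within discretization); a Feret (caliper) ratio is
  available as an option. Nucleus polarization = distance between cell
  and nucleus mask centroids in µm.
- **Tracking.** Greedy mutual-nearest-neighbor frame-to-frame linking
  under a maximum step, ties broken on the lowest index; unmatched
  detections start new tracks. Track metrics report path length, net
  displacement and mean speed (path/elapsed) together, since "distance
  traveled" is ambiguous between the first two.
- **Residence.** A track sample is in contact when its position rounded
  to the nearest pixel lies on compartment foreground; every maximal run
  of consecutive contact samples is one record with duration =
  run length × frame interval (inclusive counting: a 1-frame touch at 1 s
  sampling is 1 s).

## Synthetic generators

The generators emulate the *structure* the analyses rely on, not optics:

- `make_virtual_cell`: spherical-cap topography (the simplest shape with
  both a 2–5 µm body and a <2 µm periphery band), piecewise-constant
  modulus with a configurable periphery factor, zero height on the dish.
- `simulate_force_curve` / `simulate_force_volume`: the exact forward
  contact model above with additive Gaussian force noise (photodiode
  noise; default SD 10 pN, 512 samples per curve — package defaults, with
  half the sweep pre-contact), a linear virtual-deflection baseline, a
  400 pN trigger and an optional stage-tilt plane on the contact points.
- `simulate_coloc_stack`: Gaussian-blurred disks (σ = 1.5 px, truncated
  at 3σ) as puncta; a rounded fraction of channel-2/3 vesicles share
  channel-1 centers, the rest keep a clearance of
  max(4·radius, 2·(radius + 3σ) + 1) from every channel-1 vesicle so
  "non-overlapping" truly segments as disjoint. Real tubulo-vesicular
  compartments are not disks, but disks suffice to validate the
  coefficient computation.
- `simulate_traction_field`: inward-pointing vectors of prescribed
  magnitude (uniform, or decaying from the mask edge), plus Gaussian
  noise; truth records the exact noiseless mean stress and total force.
- `simulate_vesicle_movie`: vesicle positions jitter around
  well-separated anchor pixels inside/outside the compartment,
  rejection-sampled so the rounded position respects the prescribed side
  of the mask on every frame — contacts are therefore exactly the stated
  inclusive intervals. This validates the residence-time bookkeeping; it
  does not emulate diffusive motion across the boundary, where contact
  assignment is genuinely ambiguous at any sampling rate.

Consequences for interpretation: passing tests show the pipelines recover
what they are defined to measure under controlled noise; they do not
certify performance on real recordings with uneven illumination,
anisotropic PSFs, drift, or viscoelastic indentation response.

## Problem sizes

The validation suite runs a 32×32 force-volume grid (1024 curves, 512
samples each) for end-to-end recovery, 16×16 grids for flattening checks,
192×192 two-channel stacks × 5 overlap levels × 10 seeds for Manders
recovery, and 128×128 images for the brute-force segmentation oracles —
sizes chosen so the full suite completes in minutes on one CPU while
keeping every per-pixel statistic well-populated (hundreds of masked
pixels, thousands of oracle pixels).
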