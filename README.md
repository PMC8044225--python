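# cellmech

Quantification toolkit for single-cell mechanics and trafficking imaging:
AFM force-volume nanoindentation with a finite-thickness (bottom-effect)
Hertz correction, object-based Manders colocalization with Phansalkar local
thresholding, and the surrounding mechano-morphometric summaries (traction
force, FRET ratio, corrected total fluorescence, cell shape, tracking and
vesicle residence times). Every analysis stage ships with a synthetic
ground-truth generator, so the whole pipeline is testable end to end
without any recordings.

It is written for cell-mechanics and quantitative-imaging labs that need
these bespoke measurements as reusable, tested library code rather than
one-off analysis scripts.

## The core models

**Force-volume AFM.** Each pixel of a scan holds an approach force-distance
curve F(z). After removing the linear "virtual deflection" baseline, the
contact branch follows the Hertz law for a paraboloidal tip of radius R on
a sample of thickness h bonded to a rigid substrate:

    F(δ) = (4/3) · E/(1−ν²) · √R · δ^{3/2} · f(χ),    χ = √(Rδ)/h
    f(χ) = 1 + 1.133χ + 1.283χ² + 0.769χ³ + 0.0975χ⁴

with indentation δ = (z − z₀) − F/k coupling to the cantilever deflection
F/k. The analysis is two-pass: (1) a linearized fit of F^{2/3} against
tip–sample separation gives the contact point z₀ and an uncorrected
apparent modulus; pixels stiffer than 65 kPa are taken as the plastic dish
and a plane through their contact points converts every z₀ into a height;
(2) a nonlinear refit with f(χ) at the now-known height gives the
substrate-corrected apparent modulus. Cells are masked (height ≥ 100 nm,
modulus ≤ 65 kPa, clean baseline) and summarized as mean modulus per
height band.

**Colocalization.** Channels are normalized, segmented with the Phansalkar
local threshold t = m·(1 + p·e^{−qm} + k(s/r − 1)) and denoised with a 2-D
binary median filter; the Manders split coefficients are

    M1 = Σ S1_{i,coloc} / Σ S1_i,    M2 = Σ S2_{j,coloc} / Σ S2_j

where a pixel counts as colocalized when both segmentation masks are set.
Triple ("conjunction") colocalization compares the AND of two masks
against a third channel.

**Summaries.** Total traction force = Σ|T|·a over the cell mask (plus a
"near" margin); FRET ratio = ΣYFP/ΣCFP; CTCF = integrated density − area ×
mean background; aspect ratio from the mask's second-moment ellipse;
residence time = inclusive frame count × frame interval for each maximal
run a tracked vesicle spends inside a compartment mask.

## Worked example

```sh
python examples/01_afm_force_volume.py
```

simulates a 16×16 force volume of a dome-shaped cell (10 kPa body, 1.6×
stiffer thin periphery, 10 pN force noise) and runs the full two-pass
analysis:

```
masked cell pixels:        120
substrate pixels:          132
mean modulus, height 2-5 um:   9.92 kPa  (n=80)
mean modulus, height 0-2 um:  15.82 kPa  (n=40)
pass-2 modulus RMS error:  1.33 % vs truth
```

The band means recover the generated 10 vs 16 kPa contrast, and the
bottom-effect-corrected moduli match the ground truth to ~1 % despite the
apparent stiffening that thin regions show before correction. The other
examples (`02_colocalization.py`, `03_traction_fret_ctcf_shape.py`,
`04_tracking_residence.py`) exercise the remaining stages the same way.

A thin CLI wraps the same functions for shell use:

```sh
cellmech simulate force-volume --seed 1 --out data/fv
cellmech afm process --in data/fv --out results/afm
cellmech simulate coloc --seed 1 --out data/co --overlap 0.5
cellmech coloc run --in data/co/stack.tif --channels ch1,ch2 --out results/co
```

Each run writes a `manifest.json` (stage, parameters, seed) and reruns with
the same seed are byte-identical.

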