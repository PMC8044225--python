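"""AFM force-volume analysis on a simulated cell.

Builds a dome-shaped virtual cell (10 kPa body, 16 kPa soft-height
periphery, 0-5 um tall) on a rigid dish, simulates one force-distance
curve per pixel (35 nm tip, 0.068 N/m cantilever, 400 pN trigger, 10 pN
noise) and runs the full two-pass pipeline: baseline correction,
linearized Hertz fit, substrate flattening, bottom-effect refit, masking
and height-band statistics.
"""

import numpy as np

import cellmech as cm

cell = cm.make_virtual_cell(
    shape=(16, 16), cell_radius_um=12.0, max_height_um=5.0,
    e_cell_pa=10e3, e_periphery_factor=1.6, pixel_size_um=1.875, seed=0,
)
fv, truth = cm.simulate_force_volume(cell, noise_sd_pn=10.0, seed=3)
result = cm.process_force_volume(fv)

mask = result.fv.mask
e_true = truth.payload["modulus_map_pa"]
rel = (result.fv.modulus_pa_pass2[mask] - e_true[mask]) / e_true[mask]

print(f"masked cell pixels:        {int(mask.sum())}")
print(f"substrate pixels:          {int(result.substrate.sum())}")
for (lo, hi), mean, n in zip(result.band_stats.bands_um,
                             result.band_stats.mean_modulus_pa,
                             result.band_stats.counts):
    print(f"mean modulus, height {lo:.0f}-{hi:.0f} um: {mean/1e3:6.2f} kPa  (n={n})")
print(f"pass-2 modulus RMS error:  {100*np.sqrt(np.mean(rel**2)):.2f} % vs truth")

# The thin (<2 um) periphery was generated 1.6x stiffer than the body;
# the band means recover that contrast, and the pass-2 (bottom-effect-
# corrected) moduli agree with the generated truth to a few percent
# despite the apparent stiffening the thin periphery shows in pass 1.
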