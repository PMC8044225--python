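"""Manders colocalization of synthetic vesicle images.

Generates two-channel vesicle images with a controlled fraction of truly
co-centered puncta (SNR 5), segments each channel with the Phansalkar
local threshold plus a binary median filter, and reports the Manders
split coefficients; then a three-channel conjunction ("A+B vs C") run.
"""

import cellmech as cm

print("overlap   true   M1      M2")
for overlap in (0.0, 0.25, 0.5, 0.75, 1.0):
    stack, truth = cm.simulate_coloc_stack(
        overlap_fraction=overlap, noise_sd=40.0, seed=42
    )
    res = cm.coloc_pipeline(stack, pair=("ch1", "ch2"), median_neighborhood=5)
    true = truth.payload["overlap_fraction"]["ch1_ch2"]
    print(f"  {overlap:4.2f}   {true:4.2f}   {res.m1:.3f}   {res.m2:.3f}")

# M1 is the intensity-weighted fraction of channel-1 signal on pixels
# where channel 2 is also segmented; it tracks the generated true overlap
# and rises monotonically with it.

stack3, _ = cm.simulate_coloc_stack(
    overlap_fraction=0.5, n_channels=3, noise_sd=40.0, seed=42
)
res3 = cm.coloc_pipeline(
    stack3, conjunction=(("ch1", "ch2"), "ch3"), median_neighborhood=5
)
print(f"\nconjunction ch1+ch2 vs ch3:  M1={res3.m1:.3f}  M2={res3.m2:.3f}")
# The conjunction mask (pixels positive for both ch1 and ch2) is compared
# against the third channel; the two coefficients are deliberately
# asymmetric, as in object-based triple-colocalization reporting.
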