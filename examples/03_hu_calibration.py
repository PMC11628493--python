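"""Standardize gray values to Hounsfield units with water/air references.

Generates noisy water and air calibration phantoms, samples a central
0.20 mm patch from each, fits the two-point affine map (air -> 0 HU,
water -> 1000 HU), and applies it to some organ-scale gray values.
"""

from ctcontrast import (
    PatchAnnotation,
    default_layout,
    default_uptake_params,
    fit_calibration,
    generate_calibration_phantom,
    sample_patch,
    to_hu,
)

layout = default_layout()
water = generate_calibration_phantom("water", layout, default_uptake_params(seed=5))
air = generate_calibration_phantom("air", layout, default_uptake_params(seed=6))

center = PatchAnnotation(
    "phantom", "midline", layout.shape[0] // 2,
    ((layout.shape[1] - 1) / 2.0, (layout.shape[2] - 1) / 2.0), 0.20,
)
water_mean = sample_patch(water, center).mean_gray
air_mean = sample_patch(air, center).mean_gray
model = fit_calibration(air_mean, water_mean)

print(f"air patch mean   : {air_mean:9.1f} gray  ->  {to_hu(air_mean, model):8.3f} HU")
print(f"water patch mean : {water_mean:9.1f} gray  ->  {to_hu(water_mean, model):8.3f} HU")
print(f"affine map       : HU(g) = {model.slope:.6f} * g + {model.intercept:.3f}\n")
for g in (8000.0, 14000.0, 20000.0, 30000.0):
    print(f"gray {g:8.0f}  ->  {to_hu(g, model):9.2f} HU")
print(
    "\nThe anchors are exact by construction; every scan calibrated against its\n"
    "own water/air references becomes comparable regardless of exposure settings."
)
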