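"""Render one synthetic stained scan and sample its annotated ROI patches.

Builds the default desk-scale phantom (160^3 voxels at 10 um) at the 48 h
staining peak, samples every 0.20 mm-circumference patch, and compares each
organ's measured mean gray value with the generator's ground truth.
"""

from ctcontrast import (
    ScanMeta,
    default_annotations,
    default_layout,
    default_uptake_params,
    generate_phantom,
    sample_patch,
    uptake_mean,
)
from ctcontrast.pipeline import organ_means_from_samples

layout = default_layout()
params = default_uptake_params(seed=1)
meta = ScanMeta(specimen_id="DEMO", protocol="FORMALIN_BLUGOL", staining_time_h=48.0)

gray, labels = generate_phantom(layout, meta, params)
annotations = default_annotations(layout)
samples = [sample_patch(gray, ann) for ann in annotations]
organ_means, mu_background = organ_means_from_samples(samples)

print(f"scan: {meta.protocol} at t = {meta.staining_time_h:g} h, "
      f"{gray.shape} voxels at {gray.voxel_size_um:g} um")
print(f"background mean (two air patches): {mu_background:8.1f} gray units\n")
print(f"{'organ':42s} {'measured':>10s} {'true mean':>10s}")
for organ, mu in sorted(organ_means.items()):
    truth = uptake_mean(organ, meta.protocol, meta.staining_time_h, params)
    print(f"{organ:42s} {mu:10.1f} {truth:10.1f}")
print("\nMeasured patch means track the generator's uptake model to within "
      "sampling noise (SD 400 over ~35-voxel patches, bilateral pairs averaged).")
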