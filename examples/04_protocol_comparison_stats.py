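"""Compare protocols at peak staining time with the nonparametric chain.

Simulates one scan per protocol at 48 h, takes the per-organ contrast
ratios as replicates within each protocol, and runs Kruskal-Wallis plus
Dunn's pairwise post-hoc tests with Benjamini-Hochberg adjustment.
"""

from ctcontrast import (
    ScanMeta,
    build_record,
    default_annotations,
    default_layout,
    default_uptake_params,
    dunn_bh,
    generate_phantom,
    kruskal_wallis,
    sample_patch,
)
from ctcontrast.pipeline import organ_means_from_samples

layout = default_layout()
params = default_uptake_params()
annotations = default_annotations(layout)

groups = {}
for k, protocol in enumerate(("FORMALIN_BLUGOL", "ETOH_BLUGOL", "ETOH_I2E")):
    meta = ScanMeta(f"SIM_{protocol}", protocol, 48.0)
    gray, _ = generate_phantom(layout, meta, params.with_seed(k))
    samples = [sample_patch(gray, a) for a in annotations]
    organ_means, mu_bg = organ_means_from_samples(samples)
    record = build_record(organ_means, mu_bg, meta)
    groups[protocol] = list(record.per_organ_R.values())
    print(f"{protocol:16s} mean R = {record.mean_R:6.2f} +/- {record.sd_R:.2f} "
          f"(n = {len(record.per_organ_R)} organs)")

h, p = kruskal_wallis(groups)
print(f"\nKruskal-Wallis: H = {h:.3f}, p = {p:.3g}")
for r in dunn_bh(groups):
    print(f"{r.group_a:16s} vs {r.group_b:16s} Z = {r.z:6.2f}  "
          f"p_raw = {r.p_raw:.3g}  p_adj = {r.p_adjusted:.3g}")
print(
    "\nA significant omnibus H with B-Lugol-vs-I2E pairs surviving BH adjustment\n"
    "mirrors the expected protocol ranking; the two B-Lugol variants are closer."
)
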