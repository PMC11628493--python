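"""Measure the contrast-ratio time course and find the peak staining time.

Simulates the six staining durations for all three fixation/staining
protocols, runs the sample -> contrast chain on each scan, and reports the
organ-averaged contrast ratio R = (mu_organ - mu_background)/mu_background
per time point, plus the detected peak.
"""

from ctcontrast import peak_staining_time, phantom_contrast_series

TIMES_H = (0.0, 12.0, 24.0, 48.0, 72.0, 96.0)
PROTOCOLS = ("FORMALIN_BLUGOL", "ETOH_BLUGOL", "ETOH_I2E")

print("mean contrast ratio R by staining duration (h):")
print(f"{'protocol':16s}" + "".join(f"{t:>8.0f}" for t in TIMES_H) + "   peak")
for k, protocol in enumerate(PROTOCOLS):
    series = phantom_contrast_series(protocol, TIMES_H, seed=k)
    peak = peak_staining_time(series)
    row = "".join(f"{r:8.2f}" for _, r in series)
    print(f"{protocol:16s}{row}{peak.time_h:7.0f}")

print(
    "\nBoth B-Lugol protocols rise to a maximum at 48 h and decline afterwards\n"
    "(overstaining: tissues approach iodine saturation and inter-tissue\n"
    "contrast collapses); alcoholic iodine stays far below them throughout."
)
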