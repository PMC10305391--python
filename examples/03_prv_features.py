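"""Compute the 18 time-domain PRV features of an NN-interval segment.

Uses one minute of simulated resting beats; the features are the standard
time-domain heart-rate-variability battery (interval statistics, successive-
difference statistics, and per-beat heart-rate statistics).
"""

from ppgstress import REST, compute_features, generate_nni_series

truth = generate_nni_series(REST, 60.0, seed=3)
vec = compute_features(truth.rr_intervals)

for name, value in vec.as_dict().items():
    print(f"{name:<12}{value:>10.3f}")

print(
    "\nmean_nni/sdnn are in ms, *_hr in beats per minute; rmssd reflects"
    "\nshort-term (breath-to-breath) variability, sdnn overall variability."
)
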