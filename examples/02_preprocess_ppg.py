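"""Recover NN intervals from a noisy rendered PPG waveform.

Renders a 6-minute recording with baseline wander, sensor noise and motion
artifacts, runs the full preprocessing chain (trim 30 s head/tail, 0.5-3.0 Hz
band-pass, peak detection, z-score outlier replacement at T = 2), and
compares the recovered intervals with the ground truth.
"""

import numpy as np

from ppgstress import REST, generate_nni_series, preprocess, render_ppg

truth = generate_nni_series(REST, 360.0, seed=12)
rec = render_ppg(
    truth, fs=255.0, noise_sd=0.03, baseline_amp=0.25,
    artifact_rate=1.0, seed=12, duration_s=360.0,
)
nni = preprocess(rec)

t = truth.pulse_times
true_rr = np.diff(t[(t >= 30.0) & (t <= 330.0)]) * 1000.0
m = min(len(nni), true_rr.size)
err = np.abs(nni.intervals[:m] - true_rr[:m])

print(f"ground-truth beats in the trimmed 300 s : {true_rr.size}")
print(f"recovered NN intervals                  : {len(nni)}")
print(f"intervals replaced by the outlier pass  : {int(nni.replaced.sum())}")
print(f"median |recovered - true|               : {np.median(err):.2f} ms")
print(
    "\nThe replaced count absorbs both injected artifacts and the"
    "\nGaussian tail of normal beat-to-beat jitter (|z| >= 2)."
)
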