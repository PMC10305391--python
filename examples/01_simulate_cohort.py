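"""Simulate a small synthetic cohort and summarize each physiological state.

Builds rest / post-exercise recordings (pulse waveforms plus ground-truth
beat intervals) and prints the mean heart rate and beat-to-beat variability
per state: exercise states should be faster and less variable.
"""

import numpy as np

from ppgstress import SynthConfig, generate_cohort

cfg = SynthConfig(n_subjects=3, duration_s=120.0, seed=7)
cohort = generate_cohort(cfg)
print(f"{len(cohort)} recordings ({cfg.n_subjects} subjects x {len(cfg.states)} states)\n")

print(f"{'state':<15}{'mean HR (bpm)':>15}{'SDNN (ms)':>12}")
for state in cfg.states:
    rrs = [t.rr_intervals for r, t in cohort if r.state == state.name]
    hr = np.mean([60000.0 / rr.mean() for rr in rrs])
    sdnn = np.mean([rr.std(ddof=1) for rr in rrs])
    print(f"{state.name:<15}{hr:>15.1f}{sdnn:>12.1f}")

print(
    "\nHigher heart rate with shrinking variability after exercise is what"
    "\ndrives the stress index up in the downstream analysis."
)
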