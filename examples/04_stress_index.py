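"""Baevsky stress index at rest versus after exercise.

SI = AMo / (2 * Mo * MxDMn): the percentage of intervals in the modal 50 ms
histogram bin over twice the product of the modal interval (s) and the
interval range (s).  A fast, metronomic post-exercise pulse concentrates the
histogram and shrinks the range, so SI rises sharply.
"""

from ppgstress import DEFAULT_STATES, compute_si, generate_nni_series

print(f"{'state':<15}{'Mo (s)':>8}{'AMo (%)':>9}{'MxDMn (s)':>11}{'SI':>9}{'sqrt SI':>9}")
for state in DEFAULT_STATES:
    truth = generate_nni_series(state, 120.0, seed=9)
    res = compute_si(truth.rr_intervals)
    print(
        f"{state.name:<15}{res.mo:>8.3f}{res.amo:>9.1f}{res.mxdmn:>11.3f}"
        f"{res.si:>9.1f}{res.sqrt_si:>9.2f}"
    )

print(
    "\nThe resting value lands at the conventional 80-150 'normal' band;"
    "\nexercise multiplies it severalfold.  The square root is the label"
    "\nthe regression stage predicts, damping these extremes."
)
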