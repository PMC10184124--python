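"""Trans-bond detection from a heavy-atom contact trace.

Generates a coupled protrusion/contact trajectory in which the molecule
stochastically enters and leaves a bound state (mean dwell 20 ns), then
segments the contact trace into bound intervals: maximal runs of
consecutive frames with nonzero contacts whose peak count reaches at
least 5. Intervals touching the trajectory edges are flagged truncated.
"""

import lipidspring as ls

params = ls.default_params(k=94.0, z0=-0.31, seed=7)
kinetics = ls.BindingKinetics(rate_on=0.02, rate_off=0.05, bound_shift=0.2)
zseries, trace = ls.simulate_bound_trace(params, kinetics, 5000.0)

intervals = ls.bond_intervals(trace, min_peak=5)
mask = ls.bound_mask(trace, intervals)
true_state = trace.meta["true_state"]

print(f"{trace.n_frames} frames, {len(intervals)} bound intervals, "
      f"{mask.sum()} bound frames ({mask.mean():.1%} of the trajectory)")
print("first five intervals (start, end, peak contacts, truncated):")
for iv in intervals.intervals[:5]:
    trunc = iv.truncated_start or iv.truncated_end
    print(f"  {iv.start_frame:6d} {iv.end_frame:6d} {iv.max_contacts:3d}  {trunc}")
agree = (mask == true_state).mean()
print(f"agreement with the generator's hidden bound state: {agree:.1%}")
print("The peak-count threshold rejects spurious single-frame contacts while")
print("keeping genuine bonds, so the mask isolates frames usable for force readout.")
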