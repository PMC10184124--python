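"""Bound-state transversal force as a function of membrane separation.

Emulates a separation sweep in which trans-binding pulls the anchor
further out of the membrane as the opposing surface recedes (bound-state
protrusion shift rising from 0.05 to 0.25 nm between D = 5.5 and 7.0 nm).
For each separation the pipeline detects bound intervals from contacts,
averages the protrusion over bound and unbound frames separately, and
converts both into forces through the calibrated spring. The unbound rows
are the null control and should read ~0 pN.
"""

import lipidspring as ls
from lipidspring.readout import force_table

TEMP_K = 303.0
SPRING = dict(k=94.0, z0=-0.31)

pool = [ls.simulate_ou(ls.default_params(temperature=TEMP_K, seed=500 + i, **SPRING), 5000.0)
        for i in range(8)]
cal = ls.boltzmann_calibrate(pool, temperature=TEMP_K)

sweep = []
for j, (D, shift) in enumerate([(5.5, 0.05), (6.0, 0.10), (6.5, 0.17), (7.0, 0.25)]):
    series_list, trace_list = [], []
    for i in range(4):
        p = ls.default_params(temperature=TEMP_K, seed=600 + 31 * j + i, **SPRING)
        kin = ls.BindingKinetics(rate_on=0.05, rate_off=0.05, bound_shift=shift)
        zs, tr = ls.simulate_bound_trace(p, kin, 4000.0)
        series_list.append(zs)
        trace_list.append(tr)
    sweep.append((D, series_list, trace_list))

estimates = ls.force_vs_separation(sweep, cal)
table = force_table(estimates)
cols = ["D_nm", "state", "dz_nm", "force_pN", "force_se_pN", "n_frames", "n_events"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nBound-state forces rise with D as the bond stretches the anchor's spring")
print("(tensile positive); the unbound control stays at zero within errors.")
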