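"""Boltzmann-inversion calibration of a lipid-anchor spring.

Simulates ten force-free trajectories of a harmonic anchor with known
spring parameters (k = 94 pN/nm, z0 = -0.31 nm at 303 K), fits a Gaussian
to each protrusion histogram and inverts k = kB*T / sigma^2. The printed
calibration should recover the generating parameters within a few standard
errors: that is the entire point of the equilibrium route -- no pulling
forces are needed while the anchor stays in its linear regime.
"""

import lipidspring as ls

K_TRUE, Z0_TRUE, TEMP_K = 94.0, -0.31, 303.0

pool = [
    ls.simulate_ou(ls.default_params(k=K_TRUE, z0=Z0_TRUE, temperature=TEMP_K, seed=i), 5000.0)
    for i in range(10)
]
cal = ls.boltzmann_calibrate(pool, temperature=TEMP_K)

print(f"ground truth        k = {K_TRUE:.1f} pN/nm, z0 = {Z0_TRUE:.3f} nm")
print(f"Boltzmann inversion k = {cal.k:.1f} +/- {cal.k_se:.1f} pN/nm, "
      f"z0 = {cal.z0:.3f} +/- {cal.z0_se:.3f} nm  ({cal.n_replicas} replicas)")
print("k is the transversal stiffness of the lipid anchoring; z0 the linker's")
print("force-free depth below the headgroup reference plane (hence negative).")
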