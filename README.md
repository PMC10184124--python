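# lipidspring

**Lipid anchors as pico-Newton force sensors for molecular dynamics data.**

Many weak biomolecular bonds — carbohydrate–carbohydrate contacts between
adjacent membranes being a prime example — exert forces of only a few pN,
too small to resolve with steered-MD rupture protocols. `lipidspring`
implements the complementary idea: the lipid anchor of a membrane-attached
molecule is itself a calibrated spring. The vertical displacement of the
anchor's linker group relative to the surrounding headgroup plane reads out
the transversal force acting on the molecule.

The package is aimed at membrane biophysicists analysing MD trajectories of
lipid-anchored molecules (glycolipids, lipid–DNA constructs, GPI-anchored
proteins). It covers the full chain:

1. **Geometry** — extract the protrusion coordinate *z* (mass-weighted
   linker center of mass, relative to the per-frame center of mass of the
   matrix-lipid headgroups in the same leaflet) from PDB/GRO + XTC/DCD
   trajectories via MDAnalysis, or from plain tabular time series.
2. **Calibration** — determine the spring constant *k* and force-free
   reference *z*₀ of the anchoring potential *V*(*z*) = (*k*/2)(*z* − *z*₀)²
   two ways:
   - *Boltzmann inversion*: in equilibrium ρ(*z*) is Gaussian with
     σ = √(k_B T / k), so a Gaussian fit gives k = k_B T / σ².
   - *Constant-force pulling*: an error-weighted linear fit of the
     time-averaged coordinate ⟨*z*⟩_t versus applied force *F* over the
     linear regime (≤ 20 pN by default) gives *z*₀ (intercept) and
     *k* (inverse slope).
3. **Bond detection** — trans-bound states are maximal runs of consecutive
   frames with nonzero heavy-atom contacts (minimum-image distance
   < 0.45 nm) whose peak contact count reaches ≥ 5.
4. **Force readout** — the time-averaged protrusion Δ*z* = ⟨*z*⟩_t − *z*₀
   of bound (or unbound) frames converts to the average external
   transversal force ⟨*F*⟩ = *k* Δ*z* (tensile positive), with replica-level
   standard errors propagated through the spring parameters.

A synthetic-trajectory generator (`sensor_sim`) reproduces the statistical
structure all of this assumes — Ornstein–Uhlenbeck protrusion fluctuations,
force-shifted means, quartic anharmonic hardening, two-state binding with
Poisson contact counts — and provides ground truth for every stage.

## Worked example

```python
import lipidspring as ls

# ten force-free trajectories of a k = 94 pN/nm anchor at 303 K
pool = [ls.simulate_ou(ls.default_params(k=94.0, z0=-0.31, seed=i), 5000.0)
        for i in range(10)]
cal = ls.boltzmann_calibrate(pool, temperature=303.0)
print(f"k = {cal.k:.1f} +/- {cal.k_se:.1f} pN/nm, "
      f"z0 = {cal.z0:.3f} +/- {cal.z0_se:.3f} nm")
```

prints

```
k = 94.2 +/- 1.1 pN/nm, z0 = -0.311 +/- 0.001 nm
```

i.e. the inversion recovers the generating stiffness (94 pN/nm) and
reference depth (−0.31 nm; negative because the linker sits slightly below
the headgroup plane) within one standard error. The scripts in `examples/`
walk through each capability the same way: equilibrium calibration, the
pulling route and its consistency with Boltzmann inversion, bond detection,
the force-versus-separation sweep, and geometry extraction from structures.
For instance `examples/04_force_vs_separation.py` ends in a bound-state
force that rises to ≈ 23 pN at the largest emulated separation while the
unbound control stays at 0 pN within errors — the sensor's working range.

There is also a thin CLI mirroring the pipeline stages
(`lipidspring simulate | calibrate-eq | calibrate-pull | detect-bonds |
measure-force`); every stage reads and writes plain tab-separated text, so
the pipeline can be driven entirely from files produced by other tools.

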