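# Methods

## The sensor model

A lipid-anchored molecule is restrained in the direction perpendicular to
the membrane plane by its anchor. Within the sensor's working range the
anchoring is modelled as a harmonic spring acting on the vertical
center-of-mass coordinate *z* of the linker group,

    V(z) = (k/2) (z - z0)^2,          F_z(z) = -k (z - z0),

with an optional quartic term (b/4)(z − z0)⁴ describing the anharmonic
hardening observed beyond ≈ 20 pN. *z* is measured relative to the
instantaneous (per-frame) mass-weighted center of the matrix-lipid
headgroup atoms in the same leaflet, which removes rigid membrane drift;
the sign is positive toward the aqueous phase in both leaflets. Tangential
forces are not analysed: membrane fluidity relaxes them, which is what
makes the transversal component the meaningful observable.

Two independent calibrations of (k, z0) are implemented:

- **Boltzmann inversion.** In equilibrium ρ(z) ∝ exp(−V/k_B T) is Gaussian
  with σ = √(k_B T/k). A Gaussian is fitted per replica to the normalized
  histogram of z (nonlinear least squares on the density; moment estimates
  as fallback), and k = k_B T/σ² with the first-order error
  k_se = 2 k σ_se/σ. Replica scatter, not within-trajectory scatter,
  defines all standard errors, because frames are autocorrelated while
  replicas are independent.
- **Constant-force pulling.** For each force level the first half of every
  replica is discarded (equilibration), replica means of z are averaged and
  their SE taken across replicas, and an error-weighted straight line
  ⟨z⟩_t = z0 + F/k is fitted over the levels with F ≤ 20 pN (weights 1/SE²,
  known-variance covariance (XᵀWX)⁻¹). When all level SEs are equal —
  including the degenerate all-zero case of noiseless input — the fit
  reduces to ordinary least squares.

The readout inverts the spring law: ⟨F⟩ = k·Δz with
Δz = ⟨z⟩_t − z0, SE = √((k·Δz_se)² + (Δz·k_se)²). Forces are reported as
external transversal forces, tensile positive (pulling the anchor out of
the membrane); the restoring-force sign convention is carried in a parallel
column. Readouts implying |F| beyond the calibrated linear range are
returned with an extrapolation warning rather than suppressed.

## Bound-state definition

Two saccharide headgroups are in contact when any pair of their
non-hydrogen atoms is closer than 0.45 nm (strict inequality, documented
for bit-reproducibility), with distances under the full 3D minimum-image
convention so that binding across the periodic boundary is captured. A
trans-bound state is a maximal run of consecutive frames with nonzero
contact count whose peak count reaches at least 5. A single zero-contact
frame splits a run — "consecutive" is taken literally; a configurable
gap tolerance exists but defaults to 0 and its use is recorded in output
metadata. Runs touching the trajectory ends are kept but flagged truncated
(their dwell time is censored); truncated intervals are included in force
averages by default and excludable by flag. Atoms lacking element metadata
are treated as heavy, with a warning.

## Synthetic data generator

`sensor_sim` emulates exactly the statistical structure the analysis
assumes, and nothing more:

- **Protrusion dynamics**: overdamped Langevin motion in the
  harmonic(+quartic) potential. The friction γ sets only the relaxation
  time; the default γ = k·(1 ns) gives a z autocorrelation time of ≈ 1 ns,
  a realistic lipid-protrusion relaxation scale, and is recorded in output
  metadata as a modelling choice — the stationary law is independent of it.
- **Units**: pN, nm, ns, K throughout; k_B = 0.0138065 pN·nm/K.
- **Defaults mirroring the study design**: 303 K; frame spacing 0.1 ns;
  pulling grid 2.5–30 pN in 2.5 pN steps plus force-free reference runs;
  half of each pulling replica discarded; replica-level seeds spawned
  deterministically from one run seed.
- **Binding**: a frame-resolution two-state Markov chain (entry/exit rates
  per ns) shifts the mean protrusion by `bound_shift` while bound and draws
  per-frame contact counts as Poisson around state-dependent means. This
  reproduces the bound/unbound contrast the readout analyses; it does not
  model the geometry-dependent binding probability or the saturation of
  protrusion with separation seen for long linear headgroups — separation
  sweeps are emulated by prescribing a shift per separation.

What passing tests on these data show: the estimators are unbiased and
their error propagation is calibrated *under the assumed statistical
model*. What they cannot show: force-field realism, curved or undulating
membranes (where a local lipid-disk reference would be needed; out of
scope), or non-Gaussian anchoring potentials beyond the quartic term.

## Numerical choices

- **Integrator.** For the harmonic case the generator uses the exact
  Ornstein–Uhlenbeck Gaussian transition, z_{n+1} = μ + a(z_n − μ) + s·ξ
  with a = exp(−k·dt/γ), μ = z0 + F/k, s² = (k_B T/k)(1 − a²), evaluated as
  a first-order IIR filter. An Euler–Maruyama step at any dt passing the
  stability guard would inflate the stationary variance by the factor
  2/(2 − k·dt/γ) (≈ 2.5 % in k at dt·k/γ = 0.05), a bias larger than the
  statistical errors at the sample sizes used here; the exact transition
  removes it entirely. The anharmonic path, which has no closed-form
  transition, uses Euler–Maruyama with the guard dt·k/γ < 0.1 enforced at
  parameter validation. Trajectories start from a draw of the force-free
  stationary distribution (the force is switched on at t = 0), so pulled
  runs contain the physical relaxation transient that the equilibration
  discard removes.
- **Histogram fit**: bin width 0.02 nm (≈ σ/10); bins are unweighted — an
  RMS-residual check flags clearly non-Gaussian (e.g. bimodal) input at
  10 % of the peak density.
- **Linear range**: default cutoff 20 pN; an optional run-of-signs detector
  (`detect_linear_range`) cross-checks the choice but is off by default,
  since the linear range is a property of the anchor chemistry best fixed
  by inspection once per system.
- **Leaflet assignment**: by the side of the mass-weighted midplane the
  residue's headgroup occupies in frame 0; residues within 0.2 nm of the
  midplane are left unassigned with a warning. Molecules are made whole
  along z by minimum-image reconnection before center-of-mass computation;
  the leaflet-wide reference group is assumed not to straddle the z
  boundary (true for a membrane centered in its box).
- **Degenerate inputs**: constant series are rejected ("zero variance");
  levels with fewer than two replicas, non-positive force-extension slopes,
  and states never observed raise errors rather than returning numbers; a
  single contributing replica yields NaN standard errors with a warning.
- **Tabular output**: 6 significant digits, fixed formatting, one seeded
  generator per run — reruns with the same seed are byte-identical.

## Problem sizes

The validation experiments use 10 replicas of 10⁵ frames (equilibrium
routes) and 13 force levels × 10 replicas × 5 × 10⁴ frames (pulling route),
which puts the spring-constant standard errors at the percent level —
comparable to the relative errors quoted for μs-scale atomistic data — while
running in seconds. The property suites use smaller sizes with 3-standard-
error assertions throughout.

## Known limitations

- The separation variable D is an input label (the design variable of a
  sweep), not measured from coordinates.
- Default linker/headgroup atom selections are documented guesses; real
  systems must supply selection expressions.
- No free-energy or binding-constant analysis; no cis-bond detection; no
  umbrella-sampling-scale extensions where anchors leave the harmonic
  regime entirely.
- Per-replica SEs assume replicas are exchangeable; no block averaging is
  applied within replicas.
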