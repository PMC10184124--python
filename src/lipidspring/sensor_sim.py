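"""Synthetic lipid-anchor sensor trajectories.

The statistical model mimicked here is the one the analysis stages assume:
the linker coordinate z fluctuates in an anchoring potential

    V(z) = (k/2) (z - z0)^2 + (b/4) (z - z0)^4 - F z

with spring constant k (pN/nm), reference position z0 (nm), optional
quartic hardening coefficient b (pN/nm^3) and constant external transversal
force F (pN). The dynamics are overdamped Langevin (Euler-Maruyama
integration), whose stationary distribution is the Boltzmann weight
exp(-V/kB T); for b = 0 this is the Ornstein-Uhlenbeck process with
Gaussian stationary law of mean z0 + F/k and variance kB*T/k.

The generator also emulates the statistics of transient trans-bonds: a
two-state (bound/unbound) Markov chain that shifts the mean protrusion
while bound and drives per-frame intermolecular heavy-atom contact counts,
so the bond-detection and force-readout stages can be validated against
known ground truth. Finally, :func:`make_toy_structure` builds a tiny
pseudo-atom bilayer with exactly known linker offsets for testing the
geometry stage.

Friction sets only the relaxation time scale, not the stationary law. The
default (chosen when constructing params via :func:`default_params`) makes
the z autocorrelation time ~1 ns, a typical lipid-protrusion relaxation
time; it is configurable and recorded in output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .calibration import PullingDataset
from .constants import KB
from .bonds import ContactTrace
from .geometry import (
    LEAFLET_UNASSIGNED,
    ROLE_LINKER,
    ROLE_MATRIX_HEAD,
    ROLE_OTHER,
    ROLE_SACCHARIDE,
    StructureFrameSet,
)
from .series import ZSeries

#: Euler-Maruyama stability guard: reject dt*k/friction at or above this.
STABILITY_LIMIT = 0.1


@dataclass(frozen=True)
class LangevinParams:
    """Ground-truth generator parameters.

    Units: k pN/nm, z0 nm, temperature K, friction pN ns/nm, dt and
    save_interval ns, quartic_coeff pN/nm^3, applied_force pN (positive =
    away from the membrane).
    """

    k: float
    z0: float
    temperature: float
    friction: float
    dt: float
    save_interval: float
    quartic_coeff: float = 0.0
    applied_force: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        vals = [self.k, self.z0, self.temperature, self.friction, self.dt,
                self.save_interval, self.quartic_coeff, self.applied_force]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("non-finite generator parameter")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.save_interval < self.dt:
            raise ValueError("save_interval must be >= dt")
        if self.quartic_coeff < 0:
            raise ValueError("quartic_coeff must be >= 0")
        if self.dt * self.k / self.friction >= STABILITY_LIMIT:
            raise ValueError(
                f"dt too large for stable integration: dt*k/friction = "
                f"{self.dt * self.k / self.friction:.3g} >= {STABILITY_LIMIT}; "
                "reduce dt or increase friction"
            )


def default_params(
    k: float,
    z0: float,
    temperature: float = 303.0,
    *,
    relaxation_ns: float = 1.0,
    save_interval: float = 0.1,
    quartic_coeff: float = 0.0,
    applied_force: float = 0.0,
    seed: int = 0,
) -> LangevinParams:
    """LangevinParams with friction set for a given z relaxation time
    (default 1 ns) and a stable integration step (dt = save_interval/2,
    capped at 5% of the relaxation time)."""
    friction = k * relaxation_ns
    dt = min(save_interval / 2.0, 0.05 * relaxation_ns)
    return LangevinParams(
        k=k, z0=z0, temperature=temperature, friction=friction, dt=dt,
        save_interval=save_interval, quartic_coeff=quartic_coeff,
        applied_force=applied_force, seed=seed,
    )


@dataclass(frozen=True)
class BindingKinetics:
    """Two-state bound/unbound kinetics and contact-count statistics.

    rate_on / rate_off are per-ns entry/exit rates; bound_shift (nm) is the
    mean protrusion added while bound; contact means parameterize the
    Poisson per-frame heavy-atom contact counts in each state.
    """

    rate_on: float
    rate_off: float
    bound_shift: float = 0.0
    contact_mean_bound: float = 8.0
    contact_mean_unbound: float = 0.05

    def __post_init__(self) -> None:
        if self.rate_on < 0 or self.rate_off < 0:
            raise ValueError("rates must be >= 0")
        if self.contact_mean_bound <= 0:
            raise ValueError("contact_mean_bound must be > 0")
        if self.contact_mean_unbound < 0:
            raise ValueError("contact_mean_unbound must be >= 0")
        if self.contact_mean_bound <= self.contact_mean_unbound:
            raise ValueError("contact_mean_bound must exceed contact_mean_unbound")


def _n_frames(params: LangevinParams, duration: float) -> int:
    n = int(round(duration / params.save_interval))
    if n < 100:
        raise ValueError("duration must cover at least 100 save intervals")
    return n


def _sim_core(params: LangevinParams, duration: float, rng: np.random.Generator) -> np.ndarray:
    """Integrate the overdamped Langevin equation and subsample every
    save_interval. Starts from a draw of the force-free harmonic stationary
    distribution (force switched on at t = 0).

    For quartic_coeff = 0 the process is an Ornstein-Uhlenbeck process and
    the exact Gaussian transition density is used (a = exp(-k dt/friction)),
    so the stationary mean z0 + F/k and variance kB*T/k hold without
    time-step bias; the anharmonic path uses Euler-Maruyama, whose
    stability guard is enforced at parameter validation.
    """
    n_save = _n_frames(params, duration)
    stride = max(1, int(round(params.save_interval / params.dt)))
    dt = params.save_interval / stride  # exact commensurability
    gamma = params.k * dt / params.friction
    n_steps = n_save * stride
    z_init = params.z0 + math.sqrt(KB * params.temperature / params.k) * rng.standard_normal()
    xi = rng.standard_normal(n_steps)
    if params.quartic_coeff == 0.0:
        # exact OU step z[n] = mu + a (z[n-1] - mu) + s xi[n]: a first-order
        # linear recursion, evaluated as an IIR filter (no Python loop)
        a = math.exp(-gamma)
        mu = params.z0 + params.applied_force / params.k
        noise_sd = math.sqrt(KB * params.temperature / params.k * (1.0 - a * a))
        x = (1.0 - a) * mu + noise_sd * xi
        z_full, _ = lfilter([1.0], [1.0, -a], x, zi=np.array([a * z_init]))
    else:
        noise_sd = math.sqrt(2.0 * KB * params.temperature * dt / params.friction)
        b_fac = params.quartic_coeff * dt / params.friction
        f_fac = params.applied_force * dt / params.friction
        z_full = np.empty(n_steps)
        z = z_init
        for i in range(n_steps):
            dz = z - params.z0
            z = z - gamma * dz - b_fac * dz**3 + f_fac + noise_sd * xi[i]
            z_full[i] = z
    return z_full[stride - 1 :: stride]


def simulate_ou(params: LangevinParams, duration: float) -> ZSeries:
    """Simulate one protrusion trajectory of ``duration`` ns.

    For quartic_coeff = 0 and applied_force = F the stationary law is
    Gaussian with mean z0 + F/k and variance kB*T/k; deterministic given
    params.seed.
    """
    rng = np.random.default_rng(params.seed)
    z = _sim_core(params, duration, rng)
    times = params.save_interval * np.arange(1, z.size + 1)
    meta = {
        "k_pN_per_nm": params.k, "z0_nm": params.z0, "temperature_K": params.temperature,
        "friction_pN_ns_per_nm": params.friction, "dt_ns": params.dt,
        "quartic_coeff_pN_per_nm3": params.quartic_coeff,
        "applied_force_pN": params.applied_force, "seed": params.seed,
        "note": "friction sets only the relaxation time (default ~1 ns); it is a modelling choice",
    }
    return ZSeries(times, z, label=f"synthetic F={params.applied_force:g} pN", meta=meta)


def simulate_pulling_set(
    params: LangevinParams,
    forces: list[float],
    replicas: int,
    duration: float,
    equilibration_fraction: float = 0.5,
) -> PullingDataset:
    """Constant-force pulling dataset: one trajectory per (force, replica).

    Per-trajectory seeds are spawned deterministically from params.seed, so
    the same params reproduce the dataset bit for bit. The force grid should
    include (or will typically be accompanied by) a force-free reference
    level, mirroring the standard protocol of a grid of constant pulling
    forces plus unbiased reference runs.
    """
    if not forces:
        raise ValueError("empty force list")
    if any(f < 0 for f in forces):
        raise ValueError("forces must be >= 0")
    if replicas < 2:
        raise ValueError("need at least 2 replicas per force level")
    children = np.random.SeedSequence(params.seed).spawn(len(forces) * replicas)
    entries = []
    i = 0
    for force in forces:
        for rep in range(replicas):
            seed = int(children[i].generate_state(1)[0] % (2**31))
            i += 1
            p = replace(params, applied_force=force, seed=seed)
            series = simulate_ou(p, duration)
            series.label = f"F={force:g} pN replica {rep}"
            entries.append((float(force), rep, series))
    return PullingDataset(entries=entries, equilibration_fraction=equilibration_fraction)


def simulate_bound_trace(
    params: LangevinParams, kinetics: BindingKinetics, duration: float
) -> tuple[ZSeries, ContactTrace]:
    """Coupled protrusion / contact-count trajectory with two-state binding.

    A frame-resolution Markov chain switches between unbound and bound with
    per-frame probabilities 1 - exp(-rate * save_interval). While bound the
    protrusion mean is shifted by ``bound_shift`` and per-frame contact
    counts are Poisson with mean contact_mean_bound; while unbound the
    counts are Poisson with mean contact_mean_unbound. The true state is
    recorded in the ContactTrace metadata for validation.
    """
    dt_frame = params.save_interval
    for rate in (kinetics.rate_on, kinetics.rate_off):
        if rate > 0 and 1.0 / (rate * dt_frame) < 10:
            raise ValueError("binding rates too fast: expected dwell < 10 frames")
    rng = np.random.default_rng(params.seed)
    z_base = _sim_core(params, duration, rng)
    n = z_base.size
    p_on = 1.0 - math.exp(-kinetics.rate_on * dt_frame)
    p_off = 1.0 - math.exp(-kinetics.rate_off * dt_frame)
    u = rng.random(n)
    state = np.zeros(n, dtype=bool)
    bound = False
    for i in range(n):
        if bound:
            if u[i] < p_off:
                bound = False
        else:
            if u[i] < p_on:
                bound = True
        state[i] = bound
    z = z_base + kinetics.bound_shift * state
    means = np.where(state, kinetics.contact_mean_bound, kinetics.contact_mean_unbound)
    counts = rng.poisson(means)
    times = dt_frame * np.arange(1, n + 1)
    zs = ZSeries(times, z, label="synthetic bound/unbound",
                 meta={"bound_shift_nm": kinetics.bound_shift, "seed": params.seed})
    trace = ContactTrace(counts=counts, frame_interval_ns=dt_frame,
                         meta={"true_state": state})
    return zs, trace


# ---------------------------------------------------------------------------
# toy structure fixture for the geometry stage

_LIPID_ATOMS = [  # name, element, mass, role, dz relative to headgroup plane
    ("P", "P", 30.97, ROLE_MATRIX_HEAD, 0.0),
    ("N", "N", 14.01, ROLE_MATRIX_HEAD, 0.0),
    ("C2", "C", 12.01, ROLE_OTHER, -0.8),
    ("C3", "C", 12.01, ROLE_OTHER, -1.4),
]


def make_toy_structure(
    n_lipids_per_leaflet: int,
    box: tuple[float, float, float] = (5.0, 5.0, 10.0),
    linker_offset: float = 0.31,
    n_frames: int = 3,
    headgroup_height: float = 1.8,
) -> StructureFrameSet:
    """Tiny pseudo-atom bilayer with one anchored molecule per leaflet.

    Matrix lipids sit on a square grid in each leaflet with their headgroup
    atoms exactly at z = midplane +/- ``headgroup_height``; the anchored
    molecule's linker pseudo-atom sits exactly ``linker_offset`` nm below
    its leaflet's headgroup plane (toward the midplane), with saccharide
    pseudo-atoms above the plane. The two leaflets are mirror images, so the
    geometry stage must report z = -linker_offset for both anchors.
    """
    if n_lipids_per_leaflet < 4:
        raise ValueError("need at least 4 lipids per leaflet")
    if any(edge <= 0 for edge in box):
        raise ValueError("box edges must be positive")
    mid = box[2] / 2.0
    grid = math.ceil(math.sqrt(n_lipids_per_leaflet + 1))
    spacing = min(box[0], box[1]) / grid
    names, elements, masses, resids, resnames, roles = [], [], [], [], [], []
    xyz = []
    resid = 0
    for leaflet_sign in (+1, -1):
        plane = mid + leaflet_sign * headgroup_height
        sites = [(gx, gy) for gy in range(grid) for gx in range(grid)]
        for placed, (gx, gy) in enumerate(sites[: n_lipids_per_leaflet + 1]):
            resid += 1
            x, y = (gx + 0.5) * spacing, (gy + 0.5) * spacing
            if placed == 0:  # the anchored molecule
                atoms = [
                    ("LNK", "C", 12.01, ROLE_LINKER, -linker_offset),
                    ("SC1", "C", 12.01, ROLE_SACCHARIDE, 0.5),
                    ("SC2", "O", 16.00, ROLE_SACCHARIDE, 0.8),
                ]
                resname = "ANCH"
            else:
                atoms = _LIPID_ATOMS
                resname = "LIP"
            for name, elem, mass, role, dz in atoms:
                names.append(name)
                elements.append(elem)
                masses.append(mass)
                resids.append(resid)
                resnames.append(resname)
                roles.append(role)
                xyz.append((x, y, plane + leaflet_sign * dz))
    coords0 = np.array(xyz)
    coords = np.repeat(coords0[None, :, :], n_frames, axis=0)
    box_arr = np.repeat(np.array([box], dtype=float), n_frames, axis=0)
    return StructureFrameSet(
        coords=coords,
        box=box_arr,
        masses=np.array(masses),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids),
        resnames=np.array(resnames, dtype=object),
        roles=np.array(roles, dtype=object),
        leaflets=np.full(len(masses), LEAFLET_UNASSIGNED, dtype=object),
    )
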