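"""Spring calibration of the lipid-anchoring potential.

The transversal anchoring of a lipid-anchored molecule is modelled as a
harmonic spring: the potential V(z) = (k/2)(z - z0)^2 restrains the vertical
linker coordinate z around its force-free reference z0. The spring
parameters (k, z0) can be obtained in two equivalent ways:

1. **Boltzmann inversion** of force-free equilibrium fluctuations: in
   thermal equilibrium the distribution of z is Gaussian with standard
   deviation sigma = sqrt(kB*T/k), so a Gaussian fit to the histogram of z
   yields z0 (the mean) and k = kB*T / sigma^2.
2. **Constant-force pulling**: a fixed transversal force F is applied to
   the headgroup and the time-averaged coordinate <z>_t is recorded; in the
   linear (Hookean) regime <z>_t = z0 + F/k, so an error-weighted linear
   fit of <z>_t versus F gives z0 as intercept and k as the inverse slope.

Both routes produce a :class:`SpringCalibration`, which downstream stages
use to convert protrusions into forces via F_z(z) = -k (z - z0).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .constants import KB
from .series import ZSeries

__all__ = [
    "GaussianFit",
    "SpringCalibration",
    "PullingDataset",
    "gaussian_fit",
    "boltzmann_calibrate",
    "pulling_calibrate",
    "spring_force",
    "external_force",
    "compare_calibrations",
    "CalibrationComparison",
]

#: Default histogram bin width for the Gaussian fit, nm (about sigma/10 for
#: typical lipid anchors).
DEFAULT_BIN_WIDTH_NM = 0.02

#: Default upper end of the linear force-extension regime, pN.
DEFAULT_LINEAR_MAX_FORCE_PN = 20.0

#: Default fraction of each pulling replica discarded as equilibration.
DEFAULT_EQUILIBRATION_FRACTION = 0.5


@dataclass
class GaussianFit:
    """Result of fitting Gaussians to per-replica protrusion histograms."""

    mu: float
    sigma: float
    mu_se: float
    sigma_se: float
    replica_fits: list[tuple[float, float]]
    warnings: list[str] = field(default_factory=list)


@dataclass
class SpringCalibration:
    """Spring parameters of the transversal anchoring potential.

    Attributes
    ----------
    k, k_se
        Spring constant and its standard error, pN/nm.
    z0, z0_se
        Force-free reference position of the linker group and its standard
        error, nm (relative to the leaflet headgroup plane).
    method
        'boltzmann' (inversion of equilibrium fluctuations) or 'pulling'
        (constant-force protocol).
    temperature
        Simulation temperature in K (required for the Boltzmann route;
        informational for pulling).
    linear_max_force
        Upper end of the force range used in the linear fit, pN
        (pulling route only).
    n_replicas
        Number of independent trajectories behind the standard errors.
    force_table
        Pulling route only: per-force-level table with columns
        force_pN, z_mean_nm, z_se_nm, n_replicas.
    """

    k: float
    k_se: float
    z0: float
    z0_se: float
    method: Literal["boltzmann", "pulling"]
    temperature: float | None = None
    linear_max_force: float | None = None
    n_replicas: int = 0
    warnings: list[str] = field(default_factory=list)
    force_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("spring constant must be positive")
        if self.k_se < 0 or self.z0_se < 0:
            raise ValueError("standard errors must be non-negative")
        if self.method == "boltzmann" and self.temperature is None:
            raise ValueError("Boltzmann calibration requires a temperature")
        if self.method == "pulling" and self.linear_max_force is None:
            raise ValueError("pulling calibration must record linear_max_force")


@dataclass
class PullingDataset:
    """Constant-force pulling trajectories: (force, replica, series) entries.

    Must contain at least two distinct force levels including a force-free
    (F = 0) reference, with at least two replicas per level.
    """

    entries: list[tuple[float, int, ZSeries]]
    equilibration_fraction: float = DEFAULT_EQUILIBRATION_FRACTION

    def __post_init__(self) -> None:
        if not 0.0 <= self.equilibration_fraction < 1.0:
            raise ValueError("equilibration_fraction must be in [0, 1)")
        forces = sorted({f for f, _, _ in self.entries})
        if len(forces) < 2:
            raise ValueError("need at least 2 distinct force levels")
        if min(forces) > 0:
            raise ValueError("a force-free (F=0) reference level is required")

    @property
    def forces(self) -> list[float]:
        return sorted({f for f, _, _ in self.entries})

    def replicas_at(self, force: float) -> list[ZSeries]:
        return [s for f, _, s in self.entries if f == force]


def _gauss_pdf(z: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-((z - mu) ** 2) / (2.0 * sigma**2)) / (sigma * math.sqrt(2.0 * math.pi))


def _fit_one(z: np.ndarray, bin_width: float, warnings: list[str]) -> tuple[float, float]:
    """Gaussian fit to the normalized histogram of one replica; moment
    fallback if the nonlinear fit does not converge."""
    m, s = float(np.mean(z)), float(np.std(z, ddof=1))
    if s <= 1e-12 * max(1.0, abs(m)):
        raise ValueError("zero variance: cannot fit a Gaussian to a constant series")
    lo, hi = z.min() - bin_width, z.max() + bin_width
    n_bins = max(8, int(np.ceil((hi - lo) / bin_width)))
    density, edges = np.histogram(z, bins=n_bins, range=(lo, hi), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        popt, _ = curve_fit(_gauss_pdf, centers, density, p0=(m, s))
        mu, sigma = float(popt[0]), abs(float(popt[1]))
    except RuntimeError:
        warnings.append("gaussian fit did not converge; using moment estimates")
        mu, sigma = m, s
    # goodness of fit: flag clearly non-Gaussian (e.g. bimodal) distributions
    resid = density - _gauss_pdf(centers, mu, sigma)
    if np.sqrt(np.mean(resid**2)) > 0.10 * density.max():
        warnings.append("poor Gaussian fit: distribution may be non-Gaussian (bimodal?)")
    return mu, sigma


def gaussian_fit(
    zseries_pool: Sequence[ZSeries], bin_width: float = DEFAULT_BIN_WIDTH_NM
) -> GaussianFit:
    """Fit a Gaussian to the protrusion histogram of each replica.

    The reported ``mu`` and ``sigma`` are means of the per-replica fit
    values and their standard errors are standard errors of the mean across
    replicas (the replicas being independent trajectories). With a single
    replica the standard errors are NaN and a warning is recorded.
    """
    if not zseries_pool:
        raise ValueError("empty trajectory pool")
    total = sum(s.n_frames for s in zseries_pool)
    if total < 1000:
        raise ValueError(f"need >= 1000 pooled frames for a histogram fit, got {total}")
    warnings: list[str] = []
    fits = [_fit_one(s.z, bin_width, warnings) for s in zseries_pool]
    mus = np.array([f[0] for f in fits])
    sigmas = np.array([f[1] for f in fits])
    n = len(fits)
    if n > 1:
        mu_se = float(np.std(mus, ddof=1) / math.sqrt(n))
        sigma_se = float(np.std(sigmas, ddof=1) / math.sqrt(n))
    else:
        mu_se = sigma_se = float("nan")
        warnings.append("single replica: replica standard errors unavailable")
    return GaussianFit(
        mu=float(np.mean(mus)),
        sigma=float(np.mean(sigmas)),
        mu_se=mu_se,
        sigma_se=sigma_se,
        replica_fits=fits,
        warnings=warnings,
    )


def boltzmann_calibrate(
    zseries_pool: Sequence[ZSeries],
    temperature: float,
    bin_width: float = DEFAULT_BIN_WIDTH_NM,
) -> SpringCalibration:
    """Spring calibration by Boltzmann inversion of equilibrium fluctuations.

    k = kB*T / sigma^2 and z0 = mu, where (mu, sigma) come from
    :func:`gaussian_fit`. The standard error of k follows from first-order
    propagation, k_se = 2 k sigma_se / sigma.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    fit = gaussian_fit(zseries_pool, bin_width=bin_width)
    k = KB * temperature / fit.sigma**2
    k_se = 2.0 * k * fit.sigma_se / fit.sigma if np.isfinite(fit.sigma_se) else float("nan")
    return SpringCalibration(
        k=k,
        k_se=k_se if np.isfinite(k_se) else 0.0,
        z0=fit.mu,
        z0_se=fit.mu_se if np.isfinite(fit.mu_se) else 0.0,
        method="boltzmann",
        temperature=temperature,
        n_replicas=len(zseries_pool),
        warnings=list(fit.warnings),
    )


def _weighted_linear_fit(
    x: np.ndarray, y: np.ndarray, se: np.ndarray
) -> tuple[float, float, float, float]:
    """Error-weighted straight-line fit y = intercept + slope*x.

    Weights are 1/se^2; the parameter covariance is the known-variance
    expression (X^T W X)^-1, so the supplied standard errors are taken at
    face value. Returns (intercept, slope, intercept_se, slope_se).
    """
    w = 1.0 / se**2
    X = np.column_stack([np.ones_like(x), x])
    xtwx = X.T @ (w[:, None] * X)
    cov = np.linalg.inv(xtwx)
    beta = cov @ (X.T @ (w * y))
    return float(beta[0]), float(beta[1]), float(math.sqrt(cov[0, 0])), float(math.sqrt(cov[1, 1]))


def pulling_calibrate(
    dataset: PullingDataset,
    linear_max_force: float = DEFAULT_LINEAR_MAX_FORCE_PN,
    temperature: float | None = None,
) -> SpringCalibration:
    """Spring calibration from constant-force pulling trajectories.

    For each force level the first ``equilibration_fraction`` of every
    replica is discarded; the per-replica time averages of z are combined
    into a level mean and its standard error across replicas. An
    error-weighted linear fit of <z>_t versus F over the levels with
    F <= ``linear_max_force`` then yields z0 (intercept) and k = 1/slope,
    with standard errors propagated from the fit covariance.
    """
    rows = []
    for force in dataset.forces:
        replicas = dataset.replicas_at(force)
        if len(replicas) < 2:
            raise ValueError(f"force level {force} pN has fewer than 2 replicas")
        means = np.array(
            [np.mean(s.discard_initial(dataset.equilibration_fraction).z) for s in replicas]
        )
        rows.append(
            {
                "force_pN": force,
                "z_mean_nm": float(np.mean(means)),
                "z_se_nm": float(np.std(means, ddof=1) / math.sqrt(len(means))),
                "n_replicas": len(means),
            }
        )
    table = pd.DataFrame(rows)
    in_range = table[table["force_pN"] <= linear_max_force]
    if len(in_range) < 3:
        raise ValueError("need >= 3 force levels within the linear fit range")
    se = in_range["z_se_nm"].to_numpy()
    if np.allclose(se, se[0]):
        # equal (possibly zero) errors: the weighted fit degenerates to OLS
        se = np.ones_like(se)
    elif (se <= 0).any():
        raise ValueError("zero standard error at a force level; cannot weight the fit")
    z0, slope, z0_se, slope_se = _weighted_linear_fit(
        in_range["force_pN"].to_numpy(),
        in_range["z_mean_nm"].to_numpy(),
        se,
    )
    if slope <= 0:
        raise ValueError("no restoring spring detected (non-positive force-extension slope)")
    k = 1.0 / slope
    k_se = slope_se / slope**2
    return SpringCalibration(
        k=k,
        k_se=k_se,
        z0=z0,
        z0_se=z0_se,
        method="pulling",
        temperature=temperature,
        linear_max_force=linear_max_force,
        n_replicas=int(in_range["n_replicas"].min()),
        force_table=table,
    )


def detect_linear_range(table: pd.DataFrame, alpha_runs: int = 3) -> float:
    """Heuristic linear-range detector (off by default in the calibrations).

    Scans prefixes of the force grid from the largest down and returns the
    highest maximum force whose weighted-fit residuals show no systematic
    sign trend: the longest run of equal-signed residuals in the prefix must
    be shorter than ``alpha_runs``. Intended as a cross-check of the default
    20 pN cut, not a replacement.
    """
    forces = table["force_pN"].to_numpy()
    z = table["z_mean_nm"].to_numpy()
    se = table["z_se_nm"].to_numpy()
    order = np.argsort(forces)
    forces, z, se = forces[order], z[order], se[order]
    for end in range(len(forces), 2, -1):
        z0, slope, _, _ = _weighted_linear_fit(forces[:end], z[:end], se[:end])
        resid_sign = np.sign(z[:end] - (z0 + slope * forces[:end]))
        longest = max(len(list(g)) for _, g in itertools.groupby(resid_sign))
        if longest < alpha_runs:
            return float(forces[end - 1])
    return float(forces[2])


def spring_force(z: float | np.ndarray, cal: SpringCalibration) -> float | np.ndarray:
    """Restoring force of the anchoring spring at coordinate z, in pN:
    F_z(z) = -k (z - z0). Negative for protrusions above z0 (the spring
    pulls the linker back toward the membrane)."""
    return -cal.k * (z - cal.z0)


def external_force(z: float | np.ndarray, cal: SpringCalibration) -> float | np.ndarray:
    """External (applied or bond) transversal force balancing the spring at
    coordinate z, in pN: +k (z - z0). Positive = tensile (pulling the anchor
    away from the membrane)."""
    return -spring_force(z, cal)


@dataclass
class CalibrationComparison:
    """Consistency report between two spring calibrations."""

    delta_k: float
    combined_se_k: float
    consistent_k: bool
    delta_z0: float
    combined_se_z0: float
    consistent_z0: bool
    n_se: float


def compare_calibrations(
    a: SpringCalibration, b: SpringCalibration, n_se: float = 2.0
) -> CalibrationComparison:
    """Check whether two calibrations agree within ``n_se`` combined
    standard errors, separately for k and z0."""
    if (
        a.temperature is not None
        and b.temperature is not None
        and not math.isclose(a.temperature, b.temperature)
    ):
        raise ValueError("calibrations at different temperatures are not comparable")
    dk = abs(a.k - b.k)
    se_k = math.hypot(a.k_se, b.k_se)
    dz0 = abs(a.z0 - b.z0)
    se_z0 = math.hypot(a.z0_se, b.z0_se)
    return CalibrationComparison(
        delta_k=dk,
        combined_se_k=se_k,
        consistent_k=bool(dk <= n_se * se_k),
        delta_z0=dz0,
        combined_se_z0=se_z0,
        consistent_z0=bool(dz0 <= n_se * se_z0),
        n_se=n_se,
    )
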