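"""Force readout: from bound/unbound protrusion statistics to pico-Newton
transversal forces.

With a calibrated spring (k, z0), the time-averaged protrusion
dz = <z>_t - z0 of a molecule translates into the average external
transversal force it experiences, <F> = k * dz (tensile positive, i.e.
pulling the anchor away from the membrane; the internal restoring-force
convention F_z = -k dz is reported in parallel). Applied separately to the
frames inside and outside detected trans-bound intervals, and repeated
across a series of membrane separations D, this yields the bound/unbound
force-versus-separation table that is the sensor's end product.

Standard errors of dz are computed across replicas (independent
trajectories), because frames within a replica are strongly autocorrelated;
bound-event counts are reported alongside so the statistics at sparsely
bound separations can be judged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bonds import ContactTrace, bond_intervals, bound_mask
from .calibration import SpringCalibration
from .series import ZSeries

__all__ = ["StateProtrusion", "ForceEstimate", "state_protrusion",
           "force_from_protrusion", "force_vs_separation", "force_table"]


@dataclass
class StateProtrusion:
    """Time-averaged protrusion of one state, pooled over replicas."""

    dz_mean: float
    dz_se: float
    n_frames: int
    n_replicas: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class ForceEstimate:
    """Average transversal force at one membrane separation and state.

    ``force`` is the external force in pN, tensile positive; the
    restoring-force value (opposite sign) is available as
    ``restoring_force``. ``n_events`` counts the bound intervals behind the
    estimate (0 for unbound rows and for separations without binding).
    """

    D: float
    state: str
    dz_mean: float
    dz_se: float
    force: float
    force_se: float
    n_frames: int
    n_events: int
    warnings: list[str] = field(default_factory=list)

    @property
    def restoring_force(self) -> float:
        return -self.force

    @property
    def tensile(self) -> bool:
        return self.dz_mean > 0


def state_protrusion(
    series_masks: Sequence[tuple[ZSeries, np.ndarray]],
    cal: SpringCalibration,
    state: str = "bound",
) -> StateProtrusion:
    """Pooled time-averaged protrusion dz = <z>_t - z0 over masked frames.

    ``series_masks`` pairs each replica trajectory with a boolean frame
    mask selecting the frames of the requested state. The mean pools all
    selected frames across replicas; the standard error is the SE of the
    per-replica means (replicas with no selected frames are excluded and
    counted). With a single contributing replica the SE is NaN and flagged.
    """
    warnings: list[str] = []
    rep_means, rep_counts = [], []
    pooled_sum = 0.0
    for series, mask in series_masks:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != series.z.shape:
            raise ValueError("mask and series are not aligned")
        n_sel = int(mask.sum())
        if n_sel == 0:
            continue
        sel = series.z[mask] - cal.z0
        rep_means.append(float(np.mean(sel)))
        rep_counts.append(n_sel)
        pooled_sum += float(np.sum(sel))
    if not rep_means:
        raise ValueError(f"state '{state}' never observed in any replica")
    n_frames = int(sum(rep_counts))
    dz_mean = pooled_sum / n_frames
    n_rep = len(rep_means)
    if n_rep > 1:
        dz_se = float(np.std(rep_means, ddof=1) / math.sqrt(n_rep))
    else:
        dz_se = float("nan")
        warnings.append("single replica with selected frames: SE unreliable")
    n_excluded = len(series_masks) - n_rep
    if n_excluded:
        warnings.append(f"{n_excluded} replica(s) had no '{state}' frames and were excluded")
    return StateProtrusion(dz_mean=dz_mean, dz_se=dz_se, n_frames=n_frames,
                           n_replicas=n_rep, warnings=warnings)


def force_from_protrusion(
    dz_mean: float, dz_se: float, cal: SpringCalibration
) -> tuple[float, float, list[str]]:
    """Convert a time-averaged protrusion into the external transversal
    force, <F> = k * dz (tensile positive), with first-order error
    propagation: se = sqrt((k dz_se)^2 + (dz k_se)^2).

    A warning is attached when |k dz| exceeds the calibration's validated
    linear range (the harmonic model is then an extrapolation).
    """
    force = cal.k * dz_mean
    force_se = math.hypot(cal.k * dz_se, dz_mean * cal.k_se)
    warnings = []
    linear_max = cal.linear_max_force
    if linear_max is not None and abs(force) > linear_max:
        warnings.append(
            f"|force| = {abs(force):.1f} pN exceeds the calibrated linear range "
            f"({linear_max:g} pN): linear extrapolation"
        )
    return force, force_se, warnings


def force_vs_separation(
    per_separation: Sequence[tuple[float, Sequence[ZSeries], Sequence[ContactTrace]]],
    cal: SpringCalibration,
    min_peak: int = 5,
    gap_tolerance: int = 0,
    include_truncated: bool = True,
) -> list[ForceEstimate]:
    """Bound and unbound force estimates across a membrane-separation sweep.

    For every (D, replicas of ZSeries, matching ContactTraces): detect
    bound intervals per replica, build bound/unbound frame masks, and
    convert the state-resolved protrusions into forces. Separations at
    which no replica shows a bound event yield a bound row with zero events
    and NaN statistics (binding becomes negligible at large D); the unbound
    row is always produced. ``include_truncated=False`` drops bound frames
    from intervals cut off at the trajectory edges.
    """
    out: list[ForceEstimate] = []
    for D, series_list, trace_list in per_separation:
        if len(series_list) != len(trace_list) or not series_list:
            raise ValueError(f"D={D}: need matching, non-empty series and trace lists")
        n_frames_set = {s.n_frames for s in series_list} | {t.n_frames for t in trace_list}
        if len(n_frames_set) != 1:
            raise ValueError(f"D={D}: inconsistent replica frame counts {sorted(n_frames_set)}")
        bound_pairs, unbound_pairs = [], []
        n_events = 0
        for series, trace in zip(series_list, trace_list):
            ivs = bond_intervals(trace, min_peak=min_peak, gap_tolerance=gap_tolerance)
            if not include_truncated:
                kept = [iv for iv in ivs if not (iv.truncated_start or iv.truncated_end)]
                ivs.intervals = kept
            n_events += len(ivs)
            mask = bound_mask(trace, ivs)
            bound_pairs.append((series, mask))
            unbound_pairs.append((series, ~mask))
        for state, pairs in (("bound", bound_pairs), ("unbound", unbound_pairs)):
            try:
                sp = state_protrusion(pairs, cal, state=state)
            except ValueError:
                out.append(ForceEstimate(
                    D=D, state=state, dz_mean=float("nan"), dz_se=float("nan"),
                    force=float("nan"), force_se=float("nan"), n_frames=0,
                    n_events=0, warnings=[f"no {state} frames at D={D:g} nm"],
                ))
                continue
            force, force_se, fw = force_from_protrusion(sp.dz_mean, sp.dz_se, cal)
            out.append(ForceEstimate(
                D=D, state=state, dz_mean=sp.dz_mean, dz_se=sp.dz_se,
                force=force, force_se=force_se, n_frames=sp.n_frames,
                n_events=n_events if state == "bound" else 0,
                warnings=sp.warnings + fw,
            ))
    return out


def force_table(estimates: Sequence[ForceEstimate]) -> pd.DataFrame:
    """Tabular report of a force-versus-separation sweep."""
    return pd.DataFrame(
        {
            "D_nm": [e.D for e in estimates],
            "state": [e.state for e in estimates],
            "dz_nm": [e.dz_mean for e in estimates],
            "dz_se_nm": [e.dz_se for e in estimates],
            "force_pN": [e.force for e in estimates],
            "force_se_pN": [e.force_se for e in estimates],
            "restoring_force_pN": [-e.force for e in estimates],
            "n_frames": [e.n_frames for e in estimates],
            "n_events": [e.n_events for e in estimates],
            "warnings": ["; ".join(e.warnings) for e in estimates],
        }
    )
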