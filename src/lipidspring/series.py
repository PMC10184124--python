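"""Protrusion time series.

A :class:`ZSeries` holds the vertical (out-of-plane) coordinate of a
membrane-anchored molecule's linker group, in nm, sampled at uniform
intervals in ns. It is the common currency between the synthetic generator,
the geometry extractor and the calibration / force-readout stages, and it
round-trips through a plain two-column tab-separated text format so every
stage can also be driven from files produced by other tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_SPACING_RTOL = 1e-9


@dataclass
class ZSeries:
    """Uniformly sampled protrusion-coordinate time series.

    Parameters
    ----------
    times
        Sample times in ns; strictly increasing, uniformly spaced.
    z
        Linker-group vertical coordinate in nm, one value per frame,
        measured relative to the leaflet headgroup reference plane.
    label
        Free-text provenance (molecule id, leaflet, applied force, ...).
    meta
        Optional key/value metadata written to ('#'-prefixed) file headers.
    """

    times: np.ndarray
    z: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.times.ndim != 1 or self.z.ndim != 1:
            raise ValueError("times and z must be one-dimensional")
        if self.times.size != self.z.size:
            raise ValueError("times and z must have equal length")
        if self.times.size < 2:
            raise ValueError("a ZSeries needs at least 2 frames")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.z))):
            raise ValueError("non-finite values in time series")
        dts = np.diff(self.times)
        if np.any(dts <= 0):
            raise ValueError("times must be strictly increasing")
        dt0 = dts[0]
        if not np.allclose(dts, dt0, rtol=_SPACING_RTOL, atol=_SPACING_RTOL * max(1.0, dt0)):
            raise ValueError("non-uniform frame spacing")

    @property
    def n_frames(self) -> int:
        return self.z.size

    @property
    def dt(self) -> float:
        """Frame spacing in ns."""
        return float(self.times[1] - self.times[0])

    def discard_initial(self, fraction: float) -> "ZSeries":
        """Return a copy with the first ``fraction`` of frames removed
        (equilibration discard)."""
        if not 0.0 <= fraction < 1.0:
            raise ValueError("fraction must be in [0, 1)")
        start = math.floor(fraction * self.n_frames)
        if self.n_frames - start < 2:
            raise ValueError("discard leaves fewer than 2 frames")
        return ZSeries(self.times[start:], self.z[start:], self.label, dict(self.meta))


def write_zseries(path: str | Path, series: ZSeries, fmt: str = "%.6g") -> None:
    """Write a ZSeries as tab-separated (time_ns, z_nm) text with a
    '#'-prefixed metadata header."""
    path = Path(path)
    lines = []
    if series.label:
        lines.append(f"# label={series.label}")
    for key, value in sorted(series.meta.items()):
        lines.append(f"# {key}={value}")
    lines.append("# columns=time_ns\tz_nm")
    for t, z in zip(series.times, series.z):
        lines.append(f"{fmt % t}\t{fmt % z}")
    path.write_text("\n".join(lines) + "\n")


def read_zseries(path: str | Path) -> ZSeries:
    """Read a ZSeries written by :func:`write_zseries` (or any two-column
    whitespace-separated time/z text file with optional '#' headers)."""
    path = Path(path)
    label = ""
    meta: dict = {}
    times, zs = [], []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                key = key.strip()
                if key == "label":
                    label = value.strip()
                elif key != "columns":
                    meta[key] = value.strip()
            continue
        parts = line.split()
        times.append(float(parts[0]))
        zs.append(float(parts[1]))
    return ZSeries(np.array(times), np.array(zs), label=label, meta=meta)
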