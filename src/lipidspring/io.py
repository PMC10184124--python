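"""File-based plumbing: calibration reports, manifests, tabular reports.

Every pipeline stage can be driven from plain text files, so trajectories
produced by any engine (or by the synthetic generator) can be analysed
without in-memory handoffs. Numbers in tabular outputs are written with 6
significant digits for byte-stable diffs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import PullingDataset, SpringCalibration
from .series import ZSeries, read_zseries

FLOAT_FMT = "%.6g"


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def write_calibration(path: str | Path, cal: SpringCalibration) -> None:
    """Write a SpringCalibration as structured text (JSON), including the
    per-force force-extension table for pulling calibrations."""
    payload = {
        "k_pN_per_nm": cal.k,
        "k_se_pN_per_nm": cal.k_se,
        "z0_nm": cal.z0,
        "z0_se_nm": cal.z0_se,
        "method": cal.method,
        "temperature_K": cal.temperature,
        "linear_max_force_pN": cal.linear_max_force,
        "n_replicas": cal.n_replicas,
        "warnings": cal.warnings,
    }
    if cal.force_table is not None:
        payload["force_table"] = [
            {k: _jsonable(v) for k, v in row.items()}
            for row in cal.force_table.to_dict(orient="records")
        ]
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def read_calibration(path: str | Path) -> SpringCalibration:
    payload = json.loads(Path(path).read_text())
    table = payload.pop("force_table", None)
    return SpringCalibration(
        k=payload["k_pN_per_nm"],
        k_se=payload["k_se_pN_per_nm"],
        z0=payload["z0_nm"],
        z0_se=payload["z0_se_nm"],
        method=payload["method"],
        temperature=payload.get("temperature_K"),
        linear_max_force=payload.get("linear_max_force_pN"),
        n_replicas=payload.get("n_replicas", 0),
        warnings=list(payload.get("warnings", [])),
        force_table=pd.DataFrame(table) if table else None,
    )


def read_pulling_manifest(
    path: str | Path, equilibration_fraction: float = 0.5
) -> PullingDataset:
    """Read a pulling-dataset manifest: tab-separated (force_pN, path)
    lines, one trajectory file per line; paths are resolved relative to the
    manifest's directory. Replica ids are assigned per force level in file
    order."""
    path = Path(path)
    entries: list[tuple[float, int, ZSeries]] = []
    counters: dict[float, int] = {}
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        force_s, rel = line.split("\t") if "\t" in line else line.split(None, 1)
        force = float(force_s)
        rep = counters.get(force, 0)
        counters[force] = rep + 1
        entries.append((force, rep, read_zseries(path.parent / rel.strip())))
    return PullingDataset(entries=entries, equilibration_fraction=equilibration_fraction)


def read_sweep_manifest(path: str | Path) -> list[tuple[float, list[Path], list[Path]]]:
    """Read a separation-sweep manifest: tab-separated
    (D_nm, zseries_path, contacts_path) lines; replicas of the same D are
    grouped in file order. Paths resolve relative to the manifest."""
    path = Path(path)
    grouped: dict[float, tuple[list[Path], list[Path]]] = {}
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        d_s, z_rel, c_rel = line.split("\t") if "\t" in line else line.split()
        d = float(d_s)
        zs, cs = grouped.setdefault(d, ([], []))
        zs.append(path.parent / z_rel.strip())
        cs.append(path.parent / c_rel.strip())
    return [(d, zs, cs) for d, (zs, cs) in sorted(grouped.items())]


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write a report table as tab-separated text with 6-significant-digit
    floats (byte-stable given identical inputs)."""
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def config_hash(config: dict) -> str:
    """Stable short hash of a run configuration, for run metadata."""
    blob = json.dumps(config, sort_keys=True, default=_jsonable).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
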