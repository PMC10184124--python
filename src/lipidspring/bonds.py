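"""Trans-bond detection from intermolecular heavy-atom contacts.

Two saccharide headgroups on opposing membrane surfaces are considered to
touch when a pair of their non-hydrogen atoms is closer than a cutoff
(default 0.45 nm, strict '<'), with distances evaluated under the full 3D
minimum-image convention so that contacts across the periodic boundary are
captured. A *trans*-bound state is a maximal run of consecutive frames with
nonzero contact count whose maximum count within the run reaches at least
``min_peak`` (default 5); runs that touch the start or end of the
trajectory are kept but flagged as truncated, since their true duration is
unknown.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_CUTOFF_NM = 0.45
DEFAULT_MIN_PEAK = 5


@dataclass
class ContactTrace:
    """Per-frame intermolecular heavy-atom contact counts."""

    counts: np.ndarray
    frame_interval_ns: float = 1.0
    start_frame: int = 0
    pairs: list | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be >= 0")
        if self.frame_interval_ns <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.counts.size

    @property
    def frames(self) -> np.ndarray:
        return self.start_frame + np.arange(self.n_frames)


@dataclass(frozen=True)
class BondInterval:
    """One maximal bound interval, inclusive frame indices."""

    start_frame: int
    end_frame: int
    max_contacts: int
    truncated_start: bool = False
    truncated_end: bool = False

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class BondIntervalSet:
    """Disjoint, ordered bound intervals derived from one ContactTrace."""

    intervals: list[BondInterval]
    min_peak: int
    n_trace_frames: int

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def n_bound_frames(self) -> int:
        return sum(iv.n_frames for iv in self.intervals)


def contact_count(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    box: tuple[float, float, float],
    cutoff: float = DEFAULT_CUTOFF_NM,
    elements_a: np.ndarray | None = None,
    elements_b: np.ndarray | None = None,
) -> int:
    """Number of (a, b) atom pairs closer than ``cutoff`` (strict '<')
    under the 3D minimum-image convention in an orthorhombic box.

    If element symbols are supplied, hydrogens are excluded; atoms without
    element information are treated as heavy, with a warning.
    """
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both atom sets must be non-empty")
    box_arr = np.asarray(box, dtype=float)
    if box_arr.shape != (3,) or np.any(box_arr <= 0):
        raise ValueError("box must be three positive edge lengths")

    def _heavy(coords: np.ndarray, elements: np.ndarray | None) -> np.ndarray:
        if elements is None:
            return coords
        el = np.asarray(elements, dtype=object)
        if np.any(el == ""):
            _warnings.warn(
                "atoms without element metadata are treated as heavy", stacklevel=3
            )
        keep = np.array([str(e).strip().upper() != "H" for e in el])
        return coords[keep]

    a = _heavy(a, elements_a)
    b = _heavy(b, elements_b)
    delta = a[:, None, :] - b[None, :, :]
    delta -= box_arr * np.round(delta / box_arr)
    dist2 = np.einsum("ijk,ijk->ij", delta, delta)
    return int(np.count_nonzero(dist2 < cutoff**2))


def contact_trace_from_frames(
    frames,
    resid_a: int,
    resid_b: int,
    cutoff: float = DEFAULT_CUTOFF_NM,
    frame_interval_ns: float = 1.0,
) -> ContactTrace:
    """Per-frame heavy-atom contact counts between the saccharide groups of
    two molecules in a :class:`~lipidspring.geometry.StructureFrameSet`.

    Uses the atoms tagged 'saccharide-heavy' of each residue; hydrogens are
    excluded via element metadata inside :func:`contact_count`.
    """
    sel_a = (frames.resids == resid_a) & (frames.roles == "saccharide-heavy")
    sel_b = (frames.resids == resid_b) & (frames.roles == "saccharide-heavy")
    if not sel_a.any() or not sel_b.any():
        raise ValueError("both molecules need atoms tagged 'saccharide-heavy'")
    counts = np.array(
        [
            contact_count(
                frames.coords[i, sel_a],
                frames.coords[i, sel_b],
                tuple(frames.box[i]),
                cutoff=cutoff,
                elements_a=frames.elements[sel_a],
                elements_b=frames.elements[sel_b],
            )
            for i in range(frames.n_frames)
        ],
        dtype=int,
    )
    interval = frames.frame_interval_ns or frame_interval_ns
    return ContactTrace(counts=counts, frame_interval_ns=interval)


def bond_intervals(
    trace: ContactTrace,
    min_peak: int = DEFAULT_MIN_PEAK,
    gap_tolerance: int = 0,
) -> BondIntervalSet:
    """Segment a contact trace into bound intervals.

    Maximal runs of consecutive frames with nonzero contact count are
    located; a run is flagged bound iff its maximum count is at least
    ``min_peak``. By default a single zero-count frame splits a run
    (consecutive frames taken literally); ``gap_tolerance`` > 0 merges runs
    separated by at most that many zero frames.
    """
    counts = np.asarray(trace.counts)
    positive = counts > 0
    n = counts.size
    starts = list(np.flatnonzero(np.diff(np.r_[0, positive.astype(np.int8)]) == 1))
    ends = list(np.flatnonzero(np.diff(np.r_[positive.astype(np.int8), 0]) == -1))
    runs = list(zip(starts, ends))
    if gap_tolerance > 0 and len(runs) > 1:
        merged = [runs[0]]
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if s - pe - 1 <= gap_tolerance:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        runs = merged
    intervals = []
    for s, e in runs:
        peak = int(counts[s : e + 1].max())
        if peak >= min_peak:
            intervals.append(
                BondInterval(
                    start_frame=int(s + trace.start_frame),
                    end_frame=int(e + trace.start_frame),
                    max_contacts=peak,
                    truncated_start=(s == 0),
                    truncated_end=(e == n - 1),
                )
            )
    return BondIntervalSet(intervals=intervals, min_peak=min_peak, n_trace_frames=n)


def bound_mask(trace: ContactTrace, intervals: BondIntervalSet) -> np.ndarray:
    """Boolean per-frame series: True inside a bound interval."""
    if intervals.n_trace_frames != trace.n_frames:
        raise ValueError("interval set was derived from a trace of different length")
    mask = np.zeros(trace.n_frames, dtype=bool)
    for iv in intervals:
        mask[iv.start_frame - trace.start_frame : iv.end_frame - trace.start_frame + 1] = True
    return mask


def write_contact_trace(path: str | Path, trace: ContactTrace, fmt: str = "%.6g") -> None:
    """Write a ContactTrace as tab-separated (frame, count) text."""
    lines = [f"# frame_interval_ns={fmt % trace.frame_interval_ns}", "# columns=frame\tcount"]
    for f, c in zip(trace.frames, trace.counts):
        lines.append(f"{f}\t{int(c)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_contact_trace(path: str | Path) -> ContactTrace:
    """Read a (frame, count) text file written by :func:`write_contact_trace`."""
    frame_interval = 1.0
    frames, counts = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("frame_interval_ns="):
                frame_interval = float(body.split("=", 1)[1])
            continue
        f, c = line.split()
        frames.append(int(f))
        counts.append(int(c))
    start = frames[0] if frames else 0
    return ContactTrace(
        counts=np.array(counts, dtype=int),
        frame_interval_ns=frame_interval,
        start_frame=start,
    )


def write_intervals(path: str | Path, intervals: BondIntervalSet) -> None:
    """Write bound intervals as tabular text
    (start_frame, end_frame, max_contacts, truncated)."""
    lines = [
        f"# min_peak={intervals.min_peak}",
        "# columns=start_frame\tend_frame\tmax_contacts\ttruncated",
    ]
    for iv in intervals:
        trunc = ("start" if iv.truncated_start else "") + ("end" if iv.truncated_end else "")
        lines.append(f"{iv.start_frame}\t{iv.end_frame}\t{iv.max_contacts}\t{trunc or '-'}")
    Path(path).write_text("\n".join(lines) + "\n")
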