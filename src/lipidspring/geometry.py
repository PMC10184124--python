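"""Protrusion extraction from coordinate trajectories.

The sensor readout is the vertical center-of-mass coordinate of the
anchor's *linker* group, measured per frame relative to the instantaneous
center of mass of the matrix-lipid headgroups in the same bilayer leaflet.
That per-frame, leaflet-wide reference makes the coordinate insensitive to
rigid drift of the whole membrane; the sign convention is positive toward
the aqueous phase (away from the bilayer midplane) for both leaflets.

Trajectories enter either as a :class:`StructureFrameSet` built in memory
(e.g. by :func:`lipidspring.sensor_sim.make_toy_structure`) or through the
MDAnalysis adapter :func:`load_structure`, which reads the usual MD formats
(PDB/GRO structures, XTC/DCD trajectories) and tags atoms with roles via
selection expressions.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .series import ZSeries

ROLE_MATRIX_HEAD = "matrix-headgroup"
ROLE_LINKER = "linker"
ROLE_SACCHARIDE = "saccharide-heavy"
ROLE_OTHER = "other"

LEAFLET_UPPER = "upper"
LEAFLET_LOWER = "lower"
LEAFLET_UNASSIGNED = "unassigned"

#: Default headgroup selection for PC matrix lipids (phosphate + choline
#: heavy atoms); overridable in selection configs.
DEFAULT_PC_HEADGROUP_SELECTION = (
    "name P O11 O12 O13 O14 C11 C12 N C13 C14 C15 and not name H*"
)

#: A residue whose headgroup lies closer than this to the midplane cannot
#: be assigned to a leaflet unambiguously (nm).
MIDPLANE_AMBIGUITY_NM = 0.2


@dataclass
class StructureFrameSet:
    """Per-frame coordinates plus static atom metadata.

    Attributes
    ----------
    coords
        (n_frames, n_atoms, 3) array, nm.
    box
        (n_frames, 3) orthorhombic box edges, nm.
    masses
        (n_atoms,) atomic masses, amu.
    elements
        (n_atoms,) element symbols ('' if unknown).
    resids
        (n_atoms,) residue numbers.
    resnames
        (n_atoms,) residue names.
    roles
        (n_atoms,) role tags: matrix-headgroup | linker | saccharide-heavy
        | other.
    leaflets
        (n_atoms,) leaflet labels: upper | lower | unassigned.
    """

    coords: np.ndarray
    box: np.ndarray
    masses: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    roles: np.ndarray
    leaflets: np.ndarray = field(default=None)  # type: ignore[assignment]
    frame_interval_ns: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        n_frames, n_atoms = self.coords.shape[:2]
        if self.box.shape != (n_frames, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        for name in ("masses", "elements", "resids", "resnames", "roles"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n_atoms,):
                raise ValueError(f"{name} must have one entry per atom")
            setattr(self, name, arr)
        if self.leaflets is None:
            self.leaflets = np.full(n_atoms, LEAFLET_UNASSIGNED, dtype=object)
        used = np.isin(self.roles, [ROLE_MATRIX_HEAD, ROLE_LINKER, ROLE_SACCHARIDE])
        if np.any(np.asarray(self.masses, dtype=float)[used] <= 0):
            raise ValueError("atoms used in center-of-mass groups must have positive mass")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def _residue_head_z(frames: StructureFrameSet, resid: int, frame: int) -> float | None:
    """Mass-weighted headgroup (or, for anchors, linker) z of one residue."""
    sel = (frames.resids == resid) & (
        (frames.roles == ROLE_MATRIX_HEAD) | (frames.roles == ROLE_LINKER)
    )
    if not sel.any():
        return None
    m = np.asarray(frames.masses, dtype=float)[sel]
    return float(np.average(frames.coords[frame, sel, 2], weights=m))


def assign_leaflets(frames: StructureFrameSet) -> StructureFrameSet:
    """Label every residue upper/lower by the side of the bilayer midplane
    its headgroup occupies in frame 0.

    The midplane is the mass-weighted center of all atoms; a residue whose
    headgroup sits within 0.2 nm of the midplane is labeled 'unassigned'
    with a warning. Labels are constant across frames.
    """
    masses = np.asarray(frames.masses, dtype=float)
    midplane = float(np.average(frames.coords[0, :, 2], weights=masses))
    leaflets = np.full(frames.n_atoms, LEAFLET_UNASSIGNED, dtype=object)
    n_upper = n_lower = 0
    for resid in np.unique(frames.resids):
        head_z = _residue_head_z(frames, resid, frame=0)
        if head_z is None:
            continue
        offset = head_z - midplane
        mask = frames.resids == resid
        if abs(offset) < MIDPLANE_AMBIGUITY_NM:
            _warnings.warn(
                f"residue {resid} straddles the bilayer midplane "
                f"(|offset| = {abs(offset):.3f} nm < {MIDPLANE_AMBIGUITY_NM} nm); "
                "left unassigned",
                stacklevel=2,
            )
            continue
        label = LEAFLET_UPPER if offset > 0 else LEAFLET_LOWER
        leaflets[mask] = label
        if label == LEAFLET_UPPER:
            n_upper += 1
        else:
            n_lower += 1
    if n_upper == 0 or n_lower == 0:
        raise ValueError("two leaflets required: lipids found on one side of the midplane only")
    return replace(frames, leaflets=leaflets)


def _unwrap_z(z: np.ndarray, lz: float) -> np.ndarray:
    """Make a molecule whole along z by minimum-image reconnection to its
    first atom (valid for molecules smaller than half the box height)."""
    ref = z[0]
    delta = z - ref
    delta -= lz * np.round(delta / lz)
    return ref + delta


def protrusion_series(frames: StructureFrameSet, molecule_id: int) -> ZSeries:
    """Per-frame protrusion coordinate of one anchored molecule.

    z(frame) = [mass-weighted linker COM z] - [mass-weighted COM z of all
    matrix-headgroup atoms in the molecule's leaflet], with the sign flipped
    for the lower leaflet so that positive always points toward the aqueous
    phase. The molecule is unwrapped along z before the COM computation so a
    molecule split across the periodic boundary gives the same answer as an
    unsplit copy; the (leaflet-wide) reference group is assumed not to
    straddle the z boundary, which holds for a membrane centered in its box.

    Frame times are taken from ``frames`` metadata if present; otherwise
    frames are numbered 1 ns apart.
    """
    if not np.isin(frames.leaflets, [LEAFLET_UPPER, LEAFLET_LOWER]).any():
        frames = assign_leaflets(frames)
    mol_mask = frames.resids == molecule_id
    if not mol_mask.any():
        raise ValueError(f"no atoms with residue id {molecule_id}")
    linker_mask = mol_mask & (frames.roles == ROLE_LINKER)
    if not linker_mask.any():
        raise ValueError(f"molecule {molecule_id} has no atoms tagged '{ROLE_LINKER}'")
    leaflet = frames.leaflets[mol_mask][0]
    if leaflet == LEAFLET_UNASSIGNED:
        raise ValueError(f"molecule {molecule_id} is in an unassigned leaflet")
    ref_mask = (frames.roles == ROLE_MATRIX_HEAD) & (frames.leaflets == leaflet)
    n_ref_lipids = len(np.unique(frames.resids[ref_mask]))
    if n_ref_lipids < 3:
        raise ValueError(
            f"leaflet '{leaflet}' has only {n_ref_lipids} matrix lipids; >= 3 required"
        )
    masses = np.asarray(frames.masses, dtype=float)
    m_link = masses[linker_mask]
    m_ref = masses[ref_mask]
    sign = 1.0 if leaflet == LEAFLET_UPPER else -1.0
    z = np.empty(frames.n_frames)
    mol_idx = np.flatnonzero(mol_mask)
    linker_in_mol = np.flatnonzero(linker_mask[mol_mask])
    for i in range(frames.n_frames):
        mol_z = _unwrap_z(frames.coords[i, mol_idx, 2], frames.box[i, 2])
        link_com = np.average(mol_z[linker_in_mol], weights=m_link)
        ref_com = np.average(frames.coords[i, ref_mask, 2], weights=m_ref)
        z[i] = sign * (link_com - ref_com)
    dt = float(frames.frame_interval_ns or 1.0)
    times = dt * np.arange(frames.n_frames, dtype=float)
    if len(times) < 2:  # single-frame structure: duplicate so ZSeries is valid
        times = np.array([0.0, dt])
        z = np.array([z[0], z[0]])
    return ZSeries(times, z, label=f"resid {molecule_id} ({leaflet} leaflet)")


def load_structure(
    topology: str,
    trajectory: str | None = None,
    *,
    selections: dict[str, str],
    frame_interval_ns: float | None = None,
) -> StructureFrameSet:
    """Read a structure/trajectory through MDAnalysis into a
    :class:`StructureFrameSet`.

    ``selections`` maps role tags ('matrix-headgroup', 'linker',
    'saccharide-heavy') to MDAnalysis selection strings; unselected atoms
    get role 'other'. Coordinates and box edges are converted from Å to nm.
    Atoms without element metadata are flagged '' and treated as heavy by
    the contact analysis (with a warning there).
    """
    import MDAnalysis as mda

    args = (topology,) if trajectory is None else (topology, trajectory)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # mass/element guessing chatter
        u = mda.Universe(*args)
    n_atoms = len(u.atoms)
    roles = np.full(n_atoms, ROLE_OTHER, dtype=object)
    for role in (ROLE_MATRIX_HEAD, ROLE_LINKER, ROLE_SACCHARIDE):
        expr = selections.get(role)
        if expr:
            roles[u.select_atoms(expr).indices] = role
    try:
        elements = np.asarray(u.atoms.elements, dtype=object)
    except Exception:
        # fall back to the leading letter of the atom name
        elements = np.array([(n[0] if n else "") for n in u.atoms.names], dtype=object)
    coords, boxes = [], []
    for ts in u.trajectory:
        coords.append(ts.positions / 10.0)
        boxes.append(np.asarray(ts.dimensions[:3], dtype=float) / 10.0)
    frames = StructureFrameSet(
        coords=np.array(coords),
        box=np.array(boxes),
        masses=np.asarray(u.atoms.masses, dtype=float),
        elements=elements,
        resids=np.asarray(u.atoms.resids),
        resnames=np.asarray(u.atoms.resnames, dtype=object),
        roles=roles,
        frame_interval_ns=frame_interval_ns,
    )
    return frames
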