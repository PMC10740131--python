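"""Geometric post-processing metrics for molecular trajectories.

Implements the standard structural descriptors computed from simulation
output: RMSD after optimal rigid superposition (Kabsch), per-atom RMSF
about the time-mean structure, Shrake-Rupley solvent-accessible surface
area with a hydrophobic/hydrophilic split, and geometric hydrogen-bond
counting (donor-acceptor distance + hydrogen-donor-acceptor angle).

Coordinates are in nanometres throughout; PDB files (Angstrom) are
converted on ingest.  These are post-hoc analyses of existing
coordinates — no dynamics is simulated here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError, QuenchBindWarning

__all__ = [
    "VDW_RADII_NM",
    "Frame",
    "Trajectory",
    "kabsch_rotation",
    "kabsch_rmsd",
    "superpose",
    "rmsf",
    "sasa",
    "SasaResult",
    "count_hbonds",
    "read_pdb",
    "read_xyz",
]

#: Van der Waals radii by element, nm.
VDW_RADII_NM = {"H": 0.12, "C": 0.17, "N": 0.155, "O": 0.152, "S": 0.18}
_DEFAULT_RADIUS_NM = 0.17

#: Covalent X-H bond-length cutoff used to attach hydrogens to donors, nm.
_COVALENT_H_CUTOFF_NM = 0.12


def _element_from_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


@dataclass(frozen=True)
class Frame:
    """One snapshot: parallel per-atom arrays.

    ``classes`` holds per-atom flag sets drawn from
    {donor, acceptor, hydrophobic, hydrophilic}; ``radii`` are van der
    Waals radii in nm.  Both may be omitted and filled from the element
    heuristic (N/O polar and acceptors, donors when a covalent hydrogen
    is present; C/S hydrophobic).
    """

    atom_names: tuple[str, ...]
    residue_ids: tuple[int, ...]
    coords: np.ndarray  # (n, 3) nm
    classes: tuple[frozenset, ...] | None = None
    radii: np.ndarray | None = None
    elements: tuple[str, ...] = ()

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        if coords.shape != (n, 3):
            raise InvalidInputError(f"coords must be ({n}, 3)")
        if len(self.residue_ids) != n:
            raise InvalidInputError("residue_ids length mismatch")
        if not np.all(np.isfinite(coords)):
            raise InvalidInputError("coordinates must be finite")
        elements = self.elements or tuple(
            _element_from_name(a) for a in self.atom_names
        )
        if len(elements) != n:
            raise InvalidInputError("elements length mismatch")
        if self.classes is not None:
            if len(self.classes) != n:
                raise InvalidInputError("classes length mismatch")
            object.__setattr__(
                self, "classes", tuple(frozenset(c) for c in self.classes)
            )
        if self.radii is not None:
            radii = np.asarray(self.radii, dtype=float)
            if radii.shape != (n,):
                raise InvalidInputError("radii length mismatch")
            object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "atom_names", tuple(self.atom_names))
        object.__setattr__(self, "residue_ids", tuple(int(r) for r in self.residue_ids))
        object.__setattr__(self, "elements", tuple(elements))

    def __len__(self) -> int:
        return len(self.atom_names)

    def with_default_annotations(self) -> "Frame":
        """Fill missing radii from the element table and missing classes
        from the element heuristic."""
        radii = self.radii
        if radii is None:
            radii = np.array(
                [VDW_RADII_NM.get(e, _DEFAULT_RADIUS_NM) for e in self.elements]
            )
        classes = self.classes
        if classes is None:
            classes = []
            h_idx = [i for i, e in enumerate(self.elements) if e == "H"]
            for i, e in enumerate(self.elements):
                if e in ("N", "O"):
                    flags = {"acceptor", "hydrophilic"}
                    for j in h_idx:
                        if np.linalg.norm(self.coords[i] - self.coords[j]) <= (
                            _COVALENT_H_CUTOFF_NM
                        ):
                            flags.add("donor")
                            break
                elif e in ("C", "S"):
                    flags = {"hydrophobic"}
                else:
                    flags = set()
                classes.append(frozenset(flags))
            classes = tuple(classes)
        return Frame(
            self.atom_names, self.residue_ids, self.coords, classes, radii,
            self.elements,
        )


@dataclass(frozen=True)
class Trajectory:
    """Ordered frames over an identical atom roster, with times in ps."""

    frames: tuple[Frame, ...]
    times: tuple[float, ...]

    def __post_init__(self):
        frames = tuple(self.frames)
        times = tuple(float(t) for t in self.times)
        if len(frames) != len(times):
            raise InvalidInputError("one time per frame required")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidInputError("times must be strictly increasing")
        if frames:
            roster = frames[0].atom_names
            for f in frames[1:]:
                if f.atom_names != roster:
                    raise InvalidInputError("all frames must share the atom roster")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return len(self.frames)

    def coords_array(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coords for f in self.frames])


# ---------------------------------------------------------------------------
# superposition / RMSD / RMSF
# ---------------------------------------------------------------------------


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centred ``p`` onto centred ``q``.

    SVD of the cross-covariance; a reflection (negative determinant) is
    corrected by flipping the smallest singular direction, so the result
    is always a proper rotation (det +1).
    """
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    return vt.T @ diag @ u.T


def _superposed_coords(
    ref_xyz: np.ndarray, mob_xyz: np.ndarray, fit_idx: np.ndarray
) -> np.ndarray:
    ref_c = ref_xyz[fit_idx].mean(axis=0)
    mob_c = mob_xyz[fit_idx].mean(axis=0)
    rot = kabsch_rotation(mob_xyz[fit_idx] - mob_c, ref_xyz[fit_idx] - ref_c)
    return (mob_xyz - mob_c) @ rot.T + ref_c


def superpose(ref: Frame, mobile: Frame, subset=None) -> np.ndarray:
    """Mobile coordinates after optimal superposition onto ``ref``
    (fit on ``subset`` indices when given, transform applied to all)."""
    if len(ref) != len(mobile):
        raise InvalidInputError("atom-count mismatch")
    idx = np.arange(len(ref)) if subset is None else np.asarray(subset, dtype=int)
    if len(idx) < 3:
        raise InvalidInputError("superposition needs >= 3 atoms")
    return _superposed_coords(ref.coords, mobile.coords, idx)


def kabsch_rmsd(ref: Frame, mobile: Frame, subset=None) -> float:
    """Minimum RMSD (nm) between two frames over rigid rotations and
    translations, optionally restricted to ``subset`` atom indices."""
    if len(ref) != len(mobile):
        raise InvalidInputError("atom-count mismatch")
    idx = np.arange(len(ref)) if subset is None else np.asarray(subset, dtype=int)
    if len(idx) < 3:
        raise InvalidInputError("superposition needs >= 3 atoms")
    moved = _superposed_coords(ref.coords, mobile.coords, idx)
    delta = moved[idx] - ref.coords[idx]
    return float(np.sqrt(np.mean(np.sum(delta**2, axis=1))))


def rmsf(
    traj: Trajectory,
    align_to: Frame | None = None,
    fit_subset=None,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (nm).

    Every frame is superposed onto the reference, then each atom's RMS
    deviation from its time-mean position is taken.  Without an explicit
    reference the time-mean structure after two alignment passes is used
    (first pass aligns to the first frame, second to the resulting mean).
    ``fit_subset`` restricts the superposition fit (e.g. to a rigid core
    so mobile atoms do not bias the alignment); fluctuations are still
    reported for all atoms.
    """
    if len(traj) < 2:
        raise InvalidInputError("RMSF needs >= 2 frames")
    xyz = traj.coords_array()
    idx = (
        np.arange(xyz.shape[1])
        if fit_subset is None
        else np.asarray(fit_subset, dtype=int)
    )
    if len(idx) < 3:
        raise InvalidInputError("superposition needs >= 3 atoms")
    if align_to is None:
        ref_xyz = xyz[0]
        for _ in range(2):
            aligned = np.stack(
                [_superposed_coords(ref_xyz, fr, idx) for fr in xyz]
            )
            ref_xyz = aligned.mean(axis=0)
    else:
        if len(align_to) != xyz.shape[1]:
            raise InvalidInputError("alignment frame atom-count mismatch")
        ref_xyz = align_to.coords
    aligned = np.stack([_superposed_coords(ref_xyz, fr, idx) for fr in xyz])
    mean_xyz = aligned.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - mean_xyz) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SasaResult:
    """Solvent-accessible surface areas in nm^2."""

    total: float
    hydrophobic: float
    hydrophilic: float
    per_atom: np.ndarray


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral / Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    frame: Frame, probe_radius: float = 0.14, n_points: int = 960
) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    Each atom is decorated with ``n_points`` quasi-uniform test points on
    its probe-inflated sphere of radius r_i + probe; a point is solvent
    accessible when it lies outside every other atom's inflated sphere.
    Per-atom area is the accessible fraction times 4 pi (r_i + probe)^2.
    Atoms flagged hydrophobic / hydrophilic contribute to the respective
    split; unflagged atoms only to the total.
    """
    frame = frame.with_default_annotations()
    if frame.radii is None:
        raise InvalidInputError("radii required for SASA")
    xyz = frame.coords
    inflated = frame.radii + probe_radius
    n = len(frame)
    unit = _sphere_points(n_points)
    per_atom = np.zeros(n)
    for i in range(n):
        pts = xyz[i] + inflated[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > inflated[j] ** 2
            if not accessible.any():
                break
        frac = accessible.mean()
        per_atom[i] = frac * 4.0 * math.pi * inflated[i] ** 2
    phob = sum(
        a for a, c in zip(per_atom, frame.classes) if "hydrophobic" in c
    )
    phil = sum(
        a for a, c in zip(per_atom, frame.classes) if "hydrophilic" in c
    )
    return SasaResult(
        total=float(per_atom.sum()),
        hydrophobic=float(phob),
        hydrophilic=float(phil),
        per_atom=per_atom,
    )


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


def count_hbonds(
    frame: Frame,
    dist_cutoff: float = 0.35,
    angle_cutoff_deg: float = 30.0,
) -> int:
    """Count hydrogen bonds by the conventional geometric criterion.

    A donor-acceptor pair is hydrogen bonded when the heavy-atom
    donor-acceptor distance is <= ``dist_cutoff`` (nm) and some hydrogen
    covalently attached to the donor (within 0.12 nm) makes a
    hydrogen-donor-acceptor angle <= ``angle_cutoff_deg``.  Each pair is
    counted at most once.
    """
    frame = frame.with_default_annotations()
    donors = [i for i, c in enumerate(frame.classes) if "donor" in c]
    acceptors = [i for i, c in enumerate(frame.classes) if "acceptor" in c]
    if not donors or not acceptors:
        warnings.warn(
            "no donor/acceptor atoms flagged; returning 0 hydrogen bonds",
            QuenchBindWarning,
            stacklevel=2,
        )
        return 0
    xyz = frame.coords
    hydrogens = [i for i, e in enumerate(frame.elements) if e == "H"]
    cos_cut = math.cos(math.radians(angle_cutoff_deg))
    count = 0
    for d in donors:
        attached = [
            h
            for h in hydrogens
            if np.linalg.norm(xyz[h] - xyz[d]) <= _COVALENT_H_CUTOFF_NM
        ]
        if not attached:
            continue
        for a in acceptors:
            if a == d:
                continue
            da = xyz[a] - xyz[d]
            dist = np.linalg.norm(da)
            if dist > dist_cutoff or dist == 0.0:
                continue
            for h in attached:
                dh = xyz[h] - xyz[d]
                nh = np.linalg.norm(dh)
                if nh == 0.0:
                    continue
                # angle at the donor between D->H and D->A
                if float(np.dot(dh, da)) / (nh * dist) >= cos_cut:
                    count += 1
                    break
    return count


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_pdb(path, times=None) -> Trajectory:
    """Read a (possibly multi-MODEL) PDB file into a :class:`Trajectory`.

    Coordinates are converted from Angstrom to nm.  Radii and
    donor/acceptor/hydrophobicity classes are filled from the element
    heuristic; ``times`` defaults to 0, 1, 2, ... ps.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    frames = []
    for model in structure:
        names, resids, coords, elements = [], [], [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    names.append(atom.get_name())
                    resids.append(residue.get_id()[1])
                    coords.append(atom.get_coord() / 10.0)  # A -> nm
                    el = (atom.element or "").strip().upper()
                    elements.append(el or _element_from_name(atom.get_name()))
        frames.append(
            Frame(
                tuple(names), tuple(resids), np.array(coords), elements=tuple(elements)
            ).with_default_annotations()
        )
    if not frames:
        raise InvalidInputError(f"no models found in {path}")
    if times is None:
        times = list(range(len(frames)))
    return Trajectory(frames=tuple(frames), times=tuple(times))


def read_xyz(path, times=None) -> Trajectory:
    """Read a multi-frame XYZ file (element x y z, Angstrom) into a
    :class:`Trajectory` (coordinates converted to nm)."""
    frames = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise InvalidInputError(f"bad XYZ atom count at line {pos + 1}") from exc
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) < n:
            raise InvalidInputError("truncated XYZ frame")
        names, coords = [], []
        for ln in block:
            parts = ln.split()
            if len(parts) < 4:
                raise InvalidInputError(f"bad XYZ atom line: {ln!r}")
            names.append(parts[0])
            coords.append([float(v) / 10.0 for v in parts[1:4]])  # A -> nm
        frames.append(
            Frame(
                tuple(names),
                tuple(range(1, n + 1)),
                np.array(coords),
            ).with_default_annotations()
        )
        pos += 2 + n
    if not frames:
        raise InvalidInputError(f"no frames found in {path}")
    if times is None:
        times = list(range(len(frames)))
    return Trajectory(frames=tuple(frames), times=tuple(times))
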