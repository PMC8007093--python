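"""Dihedral and ring-puckering collective variables.

This module computes the geometric descriptors used to characterise
conformations of a flexible five-membered lactone and its H-bonded dimer:

* signed dihedral (torsion) angles,
* the two-torsion pseudorotation phase/amplitude (P_theta, A_r) of a
  five-membered ring,
* Cremer-Pople puckering coordinates (phi, q2, q3, Q) of a six-membered
  (possibly intermolecular "pseudo") ring,
* per-frame collective-variable (CV) tables over a trajectory.

Conventions
-----------
All angles are degrees externally (radians internally).  Phases are reported
on (-180, 180].  Atom indices in user-facing ring/torsion definitions are
1-based (matching chemical numbering schemes); conversion to the internal
0-based storage happens in exactly one place (:func:`_to_zero_based`).

Torsion indexing: for a five-ring with atoms r1..r5 (1-based, cyclic),
``nu_j`` (j = 0..4) is the dihedral about the bond between ring atoms j+1 and
j+2, i.e. the dihedral of atoms (j, j+1, j+2, j+3) in 0-based cyclic indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "Trajectory",
    "RingDefinition",
    "PuckerState",
    "TorsionCV",
    "PuckerPhaseCV",
    "RingPhaseCV",
    "CVTable",
    "DegenerateGeometryError",
    "dihedral",
    "ring_torsions",
    "pseudorotation",
    "ring_pseudorotation",
    "cremer_pople",
    "cv_timeseries",
    "wrap_angle",
]

# Phase flagged undefined below these amplitudes: numerically safe thresholds
# far below chemically meaningful puckering.
PSEUDOROTATION_AMPLITUDE_TOL = 0.1  # degrees, on A_r
CREMER_POPLE_AMPLITUDE_TOL = 1.0e-4  # Angstrom, on q2

# Ring bonds longer than this indicate a broken (PBC-split) molecule.
MAX_RING_BOND = 3.0  # Angstrom


class DegenerateGeometryError(ValueError):
    """Raised when a geometric quantity is undefined for the input points."""


def wrap_angle(a):
    """Wrap angle(s) in degrees onto (-180, 180]."""
    w = -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)
    return w


# ---------------------------------------------------------------------------
# Frames and trajectories
# ---------------------------------------------------------------------------


@dataclass
class Frame:
    """One molecular snapshot: element labels, coordinates (Å), molecule ids."""

    labels: tuple
    coords: np.ndarray  # (n_atoms, 3) float64, Å
    mol_ids: np.ndarray  # (n_atoms,) int
    index: int = 0
    comment: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.mol_ids = np.asarray(self.mol_ids, dtype=int)
        self.labels = tuple(self.labels)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(self.labels) != len(self.coords) or len(self.mol_ids) != len(self.coords):
            raise ValueError("labels, coords and mol_ids must have equal length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.labels)

    def molecules(self):
        """Sorted unique molecule ids."""
        return sorted(set(self.mol_ids.tolist()))

    def select_molecules(self, mol_ids) -> "Frame":
        """Sub-frame containing only the given molecule ids (atom order kept)."""
        wanted = set(np.atleast_1d(mol_ids).tolist())
        mask = np.array([m in wanted for m in self.mol_ids])
        return Frame(
            labels=tuple(np.array(self.labels, dtype=object)[mask]),
            coords=self.coords[mask],
            mol_ids=self.mol_ids[mask],
            index=self.index,
            comment=self.comment,
        )


class Trajectory:
    """A stack of frames sharing one topology (labels + molecule ids)."""

    def __init__(self, labels, coords, mol_ids, frame_indices=None, comments=None):
        self.labels = tuple(labels)
        self.coords = np.asarray(coords, dtype=float)  # (n_frames, n_atoms, 3)
        self.mol_ids = np.asarray(mol_ids, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.labels):
            raise ValueError("atom count mismatch between labels and coords")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self.frame_indices = (
            np.arange(len(self.coords)) if frame_indices is None else np.asarray(frame_indices, dtype=int)
        )
        self.comments = list(comments) if comments is not None else [""] * len(self.coords)

    @classmethod
    def from_frames(cls, frames: Sequence[Frame]) -> "Trajectory":
        if not frames:
            raise ValueError("empty frame list")
        first = frames[0]
        for f in frames[1:]:
            if f.labels != first.labels:
                raise ValueError("atom labels differ across frames")
            if not np.array_equal(f.mol_ids, first.mol_ids):
                raise ValueError("molecule ids differ across frames")
        return cls(
            first.labels,
            np.stack([f.coords for f in frames]),
            first.mol_ids,
            frame_indices=[f.index for f in frames],
            comments=[f.comment for f in frames],
        )

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return len(self.labels)

    def __getitem__(self, i: int) -> Frame:
        return Frame(
            labels=self.labels,
            coords=self.coords[i],
            mol_ids=self.mol_ids,
            index=int(self.frame_indices[i]),
            comment=self.comments[i],
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


# ---------------------------------------------------------------------------
# Ring definitions and pucker states
# ---------------------------------------------------------------------------


def _to_zero_based(indices) -> np.ndarray:
    """The single 1-based -> 0-based conversion point for user atom indices."""
    idx = np.asarray(indices, dtype=int)
    if np.any(idx < 1):
        raise ValueError("atom indices are 1-based and must be >= 1")
    return idx - 1


@dataclass(frozen=True)
class RingDefinition:
    """Ordered, cyclic ring atom indices (1-based). Length 5 or 6."""

    atoms: tuple

    def __post_init__(self):
        atoms = tuple(int(a) for a in self.atoms)
        object.__setattr__(self, "atoms", atoms)
        if len(atoms) not in (5, 6):
            raise ValueError("ring must have 5 or 6 atoms")
        if len(set(atoms)) != len(atoms):
            raise ValueError("ring atom indices must be distinct")
        if min(atoms) < 1:
            raise ValueError("ring atom indices are 1-based")

    def __len__(self) -> int:
        return len(self.atoms)

    def zero_based(self) -> np.ndarray:
        return _to_zero_based(self.atoms)

    def validate(self, frame: Frame) -> None:
        idx = self.zero_based()
        if idx.max() >= frame.n_atoms:
            raise ValueError(
                f"ring atom index {idx.max() + 1} exceeds frame atom count {frame.n_atoms}"
            )
        pos = frame.coords[idx]
        bonds = np.linalg.norm(np.roll(pos, -1, axis=0) - pos, axis=1)
        if np.any(bonds > MAX_RING_BOND) and len(self) == 5:
            raise ValueError(
                f"ring bond of {bonds.max():.2f} Å exceeds {MAX_RING_BOND} Å: "
                "broken (PBC-split) molecule? Inputs must be whole molecules."
            )


@dataclass
class PuckerState:
    """Puckering descriptors of a ring.

    Five-rings carry (``P_theta``, ``A_r``) from the two-torsion
    pseudorotation; six-rings carry Cremer-Pople (``phi``, ``q2``, ``q3``,
    ``Q``).  A phase is ``None`` when the corresponding amplitude is below
    tolerance (planar ring: the phase is meaningless).
    """

    P_theta: Optional[float] = None
    A_r: Optional[float] = None
    phi: Optional[float] = None
    q2: Optional[float] = None
    q3: Optional[float] = None
    Q: Optional[float] = None

    @property
    def phase_defined(self) -> bool:
        return (self.P_theta is not None) or (self.phi is not None)


# ---------------------------------------------------------------------------
# Dihedrals and ring torsions
# ---------------------------------------------------------------------------


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) of four points, on (-180, 180].

    Sign follows the IUPAC convention: looking from p2 towards p3, the
    far bond p3->p4 rotated clockwise from the near bond p2->p1 is positive.

    Raises
    ------
    DegenerateGeometryError
        If any bond vector is (near) zero length or three consecutive points
        are collinear, where the dihedral is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-10:
            raise DegenerateGeometryError("undefined dihedral: zero-length bond")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 * np.linalg.norm(b1) * nb2:
        raise DegenerateGeometryError("undefined dihedral: collinear points p1,p2,p3")
    if np.linalg.norm(n2) < 1e-10 * np.linalg.norm(b3) * nb2:
        raise DegenerateGeometryError("undefined dihedral: collinear points p2,p3,p4")
    # atan2 form is numerically robust near 0 and 180 degrees
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    ang = math.degrees(math.atan2(y, x))
    return float(wrap_angle(ang))


def ring_torsions(frame: Frame, ring: RingDefinition) -> np.ndarray:
    """The five ring torsions nu_0..nu_4 of a five-membered ring, degrees.

    ``nu_j`` is the dihedral about the bond between ring atoms j+1 and j+2
    (1-based, cyclic), i.e. the dihedral of ring atoms (j-1+1, j+1, j+2, j+3)
    read cyclically.  Relabelling the ring start by one atom cyclically
    rotates the returned list.
    """
    if len(ring) != 5:
        raise ValueError("ring_torsions requires a five-membered ring")
    ring.validate(frame)
    idx = ring.zero_based()
    pos = frame.coords[idx]
    out = np.empty(5)
    for j in range(5):
        a, b, c, d = ((j - 1) % 5, j, (j + 1) % 5, (j + 2) % 5)
        out[j] = dihedral(pos[a], pos[b], pos[c], pos[d])
    return out


# ---------------------------------------------------------------------------
# Two-torsion pseudorotation (five-membered rings)
# ---------------------------------------------------------------------------

# Coefficients of the two-torsion pseudorotation transform.  With the cosine
# model nu_j = A_r * cos(P_theta + 144°·j)  (Sato/Altona-style torsional
# pseudorotation), inverting the pair (nu_1, nu_3) for (Z_x, Z_y) =
# (A_r cos P, A_r sin P) gives
#   Z_x = (sin144°·nu3 − sin72°·nu1) / sin72°
#   Z_y = (cos144°·nu3 − cos72°·nu1) / sin72°
_SIN72 = math.sin(math.radians(72.0))
_SIN144 = math.sin(math.radians(144.0))
_COS72 = math.cos(math.radians(72.0))
_COS144 = math.cos(math.radians(144.0))


def pseudorotation(nu1: float, nu3: float, amplitude_tol: float = PSEUDOROTATION_AMPLITUDE_TOL) -> PuckerState:
    """Pseudorotation phase P_theta and amplitude A_r from torsions nu1, nu3.

    Parameters are in degrees.  ``A_r`` (degrees, >= 0) is always returned;
    ``P_theta`` is ``None`` when ``A_r <= amplitude_tol`` (near-planar ring,
    phase undefined).
    """
    if not (np.isfinite(nu1) and np.isfinite(nu3)):
        raise ValueError("torsions must be finite")
    z_x = (_SIN144 * nu3 - _SIN72 * nu1) / _SIN72
    z_y = (_COS144 * nu3 - _COS72 * nu1) / _SIN72
    a_r = math.hypot(z_x, z_y)
    if a_r <= amplitude_tol:
        return PuckerState(P_theta=None, A_r=a_r)
    p = float(wrap_angle(math.degrees(math.atan2(z_y, z_x))))
    return PuckerState(P_theta=p, A_r=a_r)


def ring_pseudorotation(frame: Frame, ring: RingDefinition, amplitude_tol: float = PSEUDOROTATION_AMPLITUDE_TOL) -> PuckerState:
    """Convenience: ring torsions then :func:`pseudorotation` on (nu1, nu3)."""
    nu = ring_torsions(frame, ring)
    return pseudorotation(nu[1], nu[3], amplitude_tol=amplitude_tol)


# ---------------------------------------------------------------------------
# Cremer-Pople coordinates (six-membered rings)
# ---------------------------------------------------------------------------


def cremer_pople(frame: Frame, ring: RingDefinition, amplitude_tol: float = CREMER_POPLE_AMPLITUDE_TOL) -> PuckerState:
    """Cremer-Pople puckering coordinates of a six-membered ring.

    Returns phase ``phi`` (degrees on (-180, 180], ``None`` when q2 is below
    tolerance), amplitudes ``q2``, ``q3`` (signed for m=3) and total ``Q`` in
    Å.  The mean plane is the standard Cremer-Pople construction: ring
    centred at its geometric centre, plane normal from the two sine/cosine
    weighted position sums.
    """
    if len(ring) != 6:
        raise ValueError("cremer_pople requires a six-membered ring")
    idx = ring.zero_based()
    if idx.max() >= frame.n_atoms:
        raise ValueError("ring atom index exceeds frame atom count")
    pos = frame.coords[idx]
    n = 6
    center = pos.mean(axis=0)
    r = pos - center
    angles = 2.0 * np.pi * np.arange(n) / n
    r1 = (r * np.sin(angles)[:, None]).sum(axis=0)
    r2 = (r * np.cos(angles)[:, None]).sum(axis=0)
    # Normal oriented so that a ring numbered counterclockwise in its own
    # plane has the normal on the +z side: out-of-plane displacements planted
    # as z_j = c*cos(4*pi*j/6 + phi0) on such a ring are recovered as phi0.
    normal = np.cross(r2, r1)
    nrm = np.linalg.norm(normal)
    if nrm < 1e-10:
        raise DegenerateGeometryError("degenerate ring: atoms coincident or collinear")
    normal /= nrm
    z = r @ normal
    # m = 2 component
    c2 = math.sqrt(2.0 / n) * float(np.sum(z * np.cos(2 * angles)))
    s2 = -math.sqrt(2.0 / n) * float(np.sum(z * np.sin(2 * angles)))
    q2 = math.hypot(c2, s2)
    # m = 3 (chair) component, signed
    q3 = float(np.sum(z * np.cos(np.pi * np.arange(n))) / math.sqrt(n))
    big_q = math.sqrt(float(np.sum(z * z)))
    if q2 <= amplitude_tol:
        return PuckerState(phi=None, q2=q2, q3=q3, Q=big_q)
    phi = float(wrap_angle(math.degrees(math.atan2(s2, c2))))
    return PuckerState(phi=phi, q2=q2, q3=q3, Q=big_q)


# ---------------------------------------------------------------------------
# CV specifications and per-frame tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TorsionCV:
    """A dihedral CV defined by four 1-based atom indices (period 360°)."""

    name: str
    atoms: tuple  # four 1-based indices

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(int(a) for a in self.atoms))
        if len(self.atoms) != 4:
            raise ValueError(f"CV {self.name!r}: a torsion needs 4 atoms")

    periodic = True

    def evaluate(self, frame: Frame) -> float:
        idx = _to_zero_based(self.atoms)
        if idx.max() >= frame.n_atoms:
            raise ValueError(
                f"CV {self.name!r}: atom index {idx.max() + 1} exceeds "
                f"frame atom count {frame.n_atoms}"
            )
        p = frame.coords[idx]
        return dihedral(p[0], p[1], p[2], p[3])


@dataclass(frozen=True)
class PuckerPhaseCV:
    """Pseudorotation phase P_theta of a five-membered ring (period 360°)."""

    name: str
    ring: RingDefinition

    def __post_init__(self):
        if len(self.ring) != 5:
            raise ValueError(f"CV {self.name!r}: pseudorotation needs a 5-ring")

    periodic = True

    def evaluate(self, frame: Frame) -> float:
        try:
            state = ring_pseudorotation(frame, ring=self.ring)
        except ValueError as exc:
            raise ValueError(f"CV {self.name!r}: {exc}") from exc
        return math.nan if state.P_theta is None else state.P_theta


@dataclass(frozen=True)
class RingPhaseCV:
    """Cremer-Pople phase phi of a six-membered (pseudo-)ring (period 360°)."""

    name: str
    ring: RingDefinition

    def __post_init__(self):
        if len(self.ring) != 6:
            raise ValueError(f"CV {self.name!r}: Cremer-Pople needs a 6-ring")

    periodic = True

    def evaluate(self, frame: Frame) -> float:
        try:
            state = cremer_pople(frame, ring=self.ring)
        except ValueError as exc:
            raise ValueError(f"CV {self.name!r}: {exc}") from exc
        return math.nan if state.phi is None else state.phi


CVSpec = Union[TorsionCV, PuckerPhaseCV, RingPhaseCV]


@dataclass
class CVTable:
    """Per-frame CV values (degrees) with per-column periodicity flags.

    ``values`` is a DataFrame indexed by frame index, one column per CV;
    degenerate/undefined cells are NaN (flagged, never dropped).
    """

    values: pd.DataFrame
    periodic: dict = field(default_factory=dict)

    @property
    def names(self):
        return list(self.values.columns)

    def periodic_flags(self) -> np.ndarray:
        return np.array([bool(self.periodic.get(c, True)) for c in self.values.columns])

    def dropna(self) -> "CVTable":
        return CVTable(values=self.values.dropna(), periodic=dict(self.periodic))

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "frame", out.index)
        out.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path, periodic=None) -> "CVTable":
        df = pd.read_csv(path)
        if "frame" not in df.columns:
            raise ValueError("CV CSV must have a 'frame' column")
        df = df.set_index("frame")
        flags = dict(periodic) if periodic else {c: True for c in df.columns}
        return cls(values=df, periodic=flags)


def cv_timeseries(traj: Trajectory, cv_specs: Sequence[CVSpec]) -> CVTable:
    """Evaluate each CV on every frame of the trajectory.

    Degenerate geometries yield NaN in the affected cell (with the row kept);
    topology mismatches (index out of range) raise, naming the offending CV.
    """
    names = [cv.name for cv in cv_specs]
    if len(set(names)) != len(names):
        raise ValueError("CV names must be unique")
    # fail fast on topology mismatches before the frame loop
    probe = traj[0]
    for cv in cv_specs:
        try:
            cv.evaluate(probe)
        except DegenerateGeometryError:
            pass
        except ValueError as exc:
            raise ValueError(str(exc)) from exc
    data = np.full((len(traj), len(cv_specs)), np.nan)
    for i, frame in enumerate(traj):
        for j, cv in enumerate(cv_specs):
            try:
                data[i, j] = cv.evaluate(frame)
            except DegenerateGeometryError:
                data[i, j] = np.nan
    df = pd.DataFrame(data, columns=names, index=pd.Index(traj.frame_indices, name="frame"))
    return CVTable(values=df, periodic={cv.name: cv.periodic for cv in cv_specs})
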