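"""Geometric hydrogen-bond detection, monomer/dimer assignment, solvent shells.

H-bond convention
-----------------
The geometric criteria are a donor-acceptor distance cutoff (default 3.0 Å)
and an angular cutoff of 30 degrees.  The angular criterion is interpreted as
*deviation from linearity* in the convention of common trajectory-analysis
tools: the angle between the D->H and D->A vectors must be below the cutoff
(a literal D-H-A angle below 30 degrees is geometrically impossible for a
3 Å contact).  The literal D-H-A angle convention is available behind the
``convention="dha"`` flag, where the cutoff is then a *minimum* D-H-A angle
of ``180 - angle_max`` degrees.

All cutoff comparisons are inclusive (<=).  No minimum-image/periodic
treatment is applied: inputs are assumed to be whole, pre-wrapped clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import Frame, Trajectory, _to_zero_based

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "Donor",
    "AssociationState",
    "AssociationResult",
    "OccupancyResult",
    "detect_hbonds",
    "hbond_occupancy",
    "assign_association_state",
    "extract_shell",
]

DEFAULT_DIMER_THRESHOLD = 4.0  # Å donor-acceptor distance separating monomer/dimer

# Frames whose bounding box exceeds this are probably periodic-boundary
# artefacts; a warning (not an error) is emitted.
BOUNDING_BOX_WARN = 100.0  # Å


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond cutoffs: D-A distance (Å) and angle deviation (deg)."""

    max_da_distance: float = 3.0
    max_angle: float = 30.0

    def __post_init__(self):
        if not self.max_da_distance > 0:
            raise ValueError("max_da_distance must be positive")
        if not 0 < self.max_angle <= 180:
            raise ValueError("max_angle must be in (0, 180]")


@dataclass(frozen=True)
class Donor:
    """A donor heavy atom with its bonded hydrogens (1-based atom indices)."""

    atom: int
    hydrogens: tuple

    def __post_init__(self):
        object.__setattr__(self, "hydrogens", tuple(int(h) for h in self.hydrogens))
        if not self.hydrogens:
            raise ValueError(f"donor atom {self.atom} has no declared hydrogen")


@dataclass(frozen=True)
class HBondRecord:
    frame_index: int
    donor: int  # 1-based
    hydrogen: int  # 1-based
    acceptor: int  # 1-based
    da_distance: float  # Å
    angle: float  # degrees, in the convention under which it was produced


@dataclass(frozen=True)
class AssociationState:
    frame_index: int
    label: str  # "monomer" | "dimer"
    min_da_distance: float  # Å


@dataclass
class AssociationResult:
    states: list
    dimer_fraction: float
    threshold: float

    def labels(self):
        return [s.label for s in self.states]


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def detect_hbonds(
    frame: Frame,
    donors: Sequence[Donor],
    acceptors: Sequence[int],
    criteria: HBondCriteria = HBondCriteria(),
    convention: str = "deviation",
) -> list:
    """All donor-H-acceptor triples passing the geometric criteria.

    Records are ordered by (donor index, hydrogen index, acceptor index).
    ``convention="deviation"`` (default): angle(D->H, D->A) <= max_angle.
    ``convention="dha"``: literal D-H-A angle >= 180 - max_angle.
    """
    if convention not in ("deviation", "dha"):
        raise ValueError("convention must be 'deviation' or 'dha'")
    out = []
    for donor in sorted(donors, key=lambda d: d.atom):
        d_idx = int(_to_zero_based([donor.atom])[0])
        if d_idx >= frame.n_atoms:
            raise ValueError(f"donor atom {donor.atom} exceeds frame atom count")
        d_pos = frame.coords[d_idx]
        for h in donor.hydrogens:
            h_idx = int(_to_zero_based([h])[0])
            h_pos = frame.coords[h_idx]
            for acc in sorted(int(a) for a in acceptors):
                if acc == donor.atom:
                    continue
                a_idx = int(_to_zero_based([acc])[0])
                if a_idx >= frame.n_atoms:
                    raise ValueError(f"acceptor atom {acc} exceeds frame atom count")
                a_pos = frame.coords[a_idx]
                dist = float(np.linalg.norm(a_pos - d_pos))
                if dist > criteria.max_da_distance:
                    continue
                if convention == "deviation":
                    ang = _angle_deg(h_pos - d_pos, a_pos - d_pos)
                    if ang > criteria.max_angle:
                        continue
                else:
                    ang = _angle_deg(d_pos - h_pos, a_pos - h_pos)
                    if ang < 180.0 - criteria.max_angle:
                        continue
                out.append(
                    HBondRecord(
                        frame_index=frame.index,
                        donor=donor.atom,
                        hydrogen=h,
                        acceptor=acc,
                        da_distance=dist,
                        angle=ang,
                    )
                )
    return out


@dataclass
class OccupancyResult:
    """Per-class H-bond occupancy and simultaneous-bond count distribution."""

    occupancy: dict  # class -> fraction of frames with >= 1 bond
    count_distribution: dict  # class -> pd.Series over bond counts (sums to 1)
    n_frames: int


def hbond_occupancy(
    traj: Trajectory,
    donors: Sequence[Donor],
    acceptors: Sequence[int],
    criteria: HBondCriteria = HBondCriteria(),
    group_by: Optional[Callable] = None,
    convention: str = "deviation",
) -> OccupancyResult:
    """Fraction of frames with at least one H-bond per contact class, plus the
    distribution of the number of simultaneous bonds.

    ``group_by`` maps an :class:`HBondRecord` to a class label (default: a
    single class ``"all"``).  Classes with no bonds in any frame do not
    appear; the count distribution includes the zero-bond bin and sums to 1.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if group_by is None:
        group_by = lambda rec: "all"  # noqa: E731
    counts_per_frame: dict = {}
    classes = set()
    for frame in traj:
        recs = detect_hbonds(frame, donors, acceptors, criteria, convention=convention)
        per_class: dict = {}
        for rec in recs:
            label = group_by(rec)
            per_class[label] = per_class.get(label, 0) + 1
            classes.add(label)
        counts_per_frame[frame.index] = per_class
    if not classes:
        classes = {"all"}
    occupancy = {}
    distributions = {}
    n = len(traj)
    for label in sorted(classes):
        counts = np.array([counts_per_frame[i].get(label, 0) for i in counts_per_frame])
        occupancy[label] = float(np.mean(counts >= 1))
        dist = pd.Series(counts).value_counts(normalize=True).sort_index()
        distributions[label] = dist
    return OccupancyResult(occupancy=occupancy, count_distribution=distributions, n_frames=n)


def assign_association_state(
    traj: Trajectory,
    mol_a: int,
    mol_b: int,
    donors: Sequence[Donor],
    acceptors: Sequence[int],
    threshold: float = DEFAULT_DIMER_THRESHOLD,
) -> AssociationResult:
    """Label each frame monomer/dimer by the minimum intermolecular
    donor-acceptor distance (dimer iff <= threshold, inclusive).

    All declared donor-acceptor pairs with donor and acceptor on different
    molecules (one on ``mol_a``, the other on ``mol_b``) are considered.
    """
    mols = set(traj.mol_ids.tolist())
    for m in (mol_a, mol_b):
        if m not in mols:
            raise ValueError(f"molecule id {m} not present in trajectory")
    donor_idx = _to_zero_based([d.atom for d in donors])
    acc_idx = _to_zero_based(list(acceptors))
    mol_of = traj.mol_ids
    pairs = [
        (di, ai)
        for di in donor_idx
        for ai in acc_idx
        if {mol_of[di], mol_of[ai]} == {mol_a, mol_b}
    ]
    if not pairs:
        raise ValueError("no intermolecular donor-acceptor pairs between the two molecules")
    pairs = np.array(pairs)
    states = []
    n_dimer = 0
    for frame in traj:
        d = np.linalg.norm(frame.coords[pairs[:, 0]] - frame.coords[pairs[:, 1]], axis=1)
        dmin = float(d.min())
        label = "dimer" if dmin <= threshold else "monomer"
        n_dimer += label == "dimer"
        states.append(AssociationState(frame_index=frame.index, label=label, min_da_distance=dmin))
    return AssociationResult(states=states, dimer_fraction=n_dimer / len(traj), threshold=threshold)


def extract_shell(frame: Frame, solute, radius: float) -> Frame:
    """Solute plus all whole solvent molecules with any atom within ``radius``
    (inclusive) of any solute atom.

    Solvent molecules are kept or dropped atomically, never split; the solute
    is always kept.  Distances are plain Cartesian (no minimum image).
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    solute_ids = set(np.atleast_1d(solute).tolist())
    mols = set(frame.mol_ids.tolist())
    missing = solute_ids - mols
    if missing:
        raise ValueError(f"unknown solute molecule id(s): {sorted(missing)}")
    span = frame.coords.max(axis=0) - frame.coords.min(axis=0)
    if span.max() > BOUNDING_BOX_WARN:
        import warnings

        warnings.warn(
            f"frame bounding box spans {span.max():.0f} Å; periodic-boundary "
            "artefacts are not handled",
            stacklevel=2,
        )
    solute_mask = np.array([m in solute_ids for m in frame.mol_ids])
    solute_xyz = frame.coords[solute_mask]
    keep = set(solute_ids)
    for mol in mols - solute_ids:
        mol_xyz = frame.coords[frame.mol_ids == mol]
        d2 = ((mol_xyz[:, None, :] - solute_xyz[None, :, :]) ** 2).sum(axis=2)
        if d2.min() <= radius * radius:
            keep.add(mol)
    mask = np.array([m in keep for m in frame.mol_ids])
    return Frame(
        labels=tuple(np.array(frame.labels, dtype=object)[mask]),
        coords=frame.coords[mask],
        mol_ids=frame.mol_ids[mask],
        index=frame.index,
        comment=frame.comment,
    )
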