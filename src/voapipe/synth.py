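"""Synthetic fixtures with planted ground truth.

These generators stand in for the MD and quantum-chemistry outputs the
analysis modules normally consume: five-membered-ring trajectories with
planted pseudorotation states and hydroxyl torsions, H-bonded dimer frames
with a planted intermolecular pseudo-ring phase, solvated frames with a
planted contact probability, and stick spectra (including the bisignate
carbonyl couplet characteristic of an H-bonded dimer).

Every generator is deterministic per seed, and every planted quantity is
recoverable by the corresponding analysis operation within a stated
tolerance — that closed loop is what the test suite exercises.

Ring construction uses an out-of-plane displacement ansatz
(z_j proportional to cos of a phase-shifted ring angle) followed by a
uniform in-plane rescale restoring the mean bond length, iterated to
self-consistency against the measured phase and amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geometry import (
    CVTable,
    Frame,
    RingDefinition,
    Trajectory,
    cremer_pople,
    ring_pseudorotation,
    wrap_angle,
)
from .spectra import StickSpectrum

__all__ = [
    "PlantedState",
    "make_ring_geometry",
    "make_trajectory",
    "make_cv_samples",
    "make_dimer_frame",
    "make_stick_spectrum",
    "make_solvated_frames",
    "MONOMER_RING",
    "OH_TORSION_ATOMS",
    "DIMER_RING_A",
    "DIMER_RING_B",
    "DIMER_PSEUDO_RING",
]

# Atom layout of the synthetic monomer: C1..C5 ring, O6 (hydroxyl O on C2),
# H7 (hydroxyl H), O8 (carbonyl O on C1).  1-based, matching the chemical
# numbering the ring/torsion definitions use.
MONOMER_RING = RingDefinition(atoms=(1, 2, 3, 4, 5))
OH_TORSION_ATOMS = (7, 6, 2, 1)

# Dimer frame layout: molecule A atoms 1-8 as above, molecule B atoms 9-16.
DIMER_RING_A = RingDefinition(atoms=(1, 2, 3, 4, 5))
DIMER_RING_B = RingDefinition(atoms=(9, 10, 11, 12, 13))
# Intermolecular pseudo-ring closed by the two O-H...O=C hydrogen bonds:
# hydroxyl O, carbonyl C, carbonyl O of each molecule, alternating.
DIMER_PSEUDO_RING = RingDefinition(atoms=(6, 1, 8, 14, 9, 16))

_RING_BOND = 1.54  # Å, C-C
_CO_BOND = 1.43  # Å, C-O(H)
_OH_BOND = 0.97  # Å
_C_DOUBLE_O = 1.23  # Å, C=O
_MAX_AMPLITUDE = 55.0  # degrees of A_r beyond which the ansatz degenerates


@dataclass(frozen=True)
class PlantedState:
    """One planted conformational state: circular means (deg), von Mises
    concentrations, and mixture weight."""

    means: tuple
    kappas: tuple
    weight: float

    def __post_init__(self):
        object.__setattr__(self, "means", tuple(float(m) for m in self.means))
        object.__setattr__(self, "kappas", tuple(float(k) for k in self.kappas))
        if len(self.means) != len(self.kappas):
            raise ValueError("one kappa per CV mean required")
        if any(k <= 0 for k in self.kappas):
            raise ValueError("von Mises concentration kappa must be positive")
        if self.weight < 0:
            raise ValueError("state weight must be nonnegative")


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d bonded to c with angle(d,c,b)=angle and
    dihedral(d,c,b,a)=torsion (degrees); the NeRF construction."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _pentagon(bond_length: float, zeta: float, phi_z: float) -> np.ndarray:
    """Regular pentagon with out-of-plane displacements; the in-plane radius
    is rescaled so the root-mean-square bond length equals ``bond_length``."""
    j = np.arange(5)
    theta = 2.0 * np.pi * j / 5.0
    z = zeta * np.cos(4.0 * np.pi * j / 5.0 + math.radians(phi_z))
    radius = bond_length / (2.0 * math.sin(math.pi / 5.0))
    xy = np.c_[radius * np.cos(theta), radius * np.sin(theta)]
    pos = np.c_[xy, z]
    # uniform in-plane rescale restoring the RMS bond length
    mean_sq_dz = float(np.mean((np.roll(z, -1) - z) ** 2))
    planar = bond_length**2 - mean_sq_dz / 1.0
    if planar <= 0:
        raise ValueError("unrealizable amplitude: puckering exceeds bond length")
    scale = math.sqrt(planar) / (2.0 * radius * math.sin(math.pi / 5.0))
    pos[:, :2] *= scale
    return pos


def make_ring_geometry(
    P: float,
    A: float,
    bond_length: float = _RING_BOND,
    oh_torsion: Optional[float] = None,
    mol_id: int = 0,
    frame_index: int = 0,
) -> Frame:
    """A five-membered ring with planted pseudorotation phase/amplitude.

    The builder iterates an out-of-plane cosine ansatz until the *measured*
    (P_theta, A_r) of the output matches the request to 1e-4 deg.  With
    ``oh_torsion`` set, hydroxyl probe atoms O6/H7 (and carbonyl O8) are
    appended so the torsion CV (atoms 7-6-2-1) equals the planted value.

    Raises ``ValueError`` for amplitudes the ansatz cannot realise.
    """
    if not (0 <= A <= _MAX_AMPLITUDE):
        raise ValueError(f"unrealizable amplitude A_r={A}; supported range [0, {_MAX_AMPLITUDE}] deg")
    if A == 0:
        pos = _pentagon(bond_length, 0.0, 0.0)
    else:
        # fixed point: phase offset is nearly constant, amplitude nearly linear
        zeta = 0.01
        phi_z = float(P)
        pos = None
        for _ in range(80):
            pos = _pentagon(bond_length, zeta, phi_z)
            frame = Frame(labels=["C"] * 5, coords=pos, mol_ids=[mol_id] * 5)
            st = ring_pseudorotation(frame, MONOMER_RING, amplitude_tol=0.0)
            err_p = float(wrap_angle(P - st.P_theta)) if st.A_r > 1e-9 else 0.0
            err_a = A - st.A_r
            if abs(err_p) < 1e-4 and abs(err_a) < 1e-4:
                break
            phi_z = float(wrap_angle(phi_z + err_p))
            zeta *= min(4.0, max(0.25, A / max(st.A_r, 1e-12)))
        else:
            raise ValueError(f"unrealizable (P={P}, A={A}): builder did not converge")
    labels = ["C"] * 5
    if oh_torsion is not None:
        # O6 on C2 (positions are 0-based: C1=0, C2=1, C3=2, C5=4)
        o6 = _place_atom(pos[4], pos[0], pos[1], _CO_BOND, 109.5, 120.0)
        h7 = _place_atom(pos[0], pos[1], o6, _OH_BOND, 105.0, float(oh_torsion))
        o8 = _place_atom(pos[2], pos[1], pos[0], _C_DOUBLE_O, 125.0, 180.0)
        pos = np.vstack([pos, o6, h7, o8])
        labels += ["O", "H", "O"]
    return Frame(labels=labels, coords=pos, mol_ids=[mol_id] * len(labels), index=frame_index)


def make_cv_samples(
    states: Sequence[PlantedState],
    n: int,
    seed: int,
    cv_names: Sequence[str] = ("P_theta", "oh_torsion"),
) -> tuple:
    """CV table sampled directly from a von Mises mixture, plus truth labels.

    The fast path for clustering benchmarks: the planted truth concerns the
    CV distribution, so no geometry needs to be built.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    weights = np.array([s.weight for s in states], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("state weights must sum to a positive value")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(states), size=n, p=weights)
    d = len(cv_names)
    vals = np.empty((n, d))
    for si, state in enumerate(states):
        if len(state.means) != d:
            raise ValueError("state dimensionality does not match cv_names")
        mask = labels == si
        for j in range(d):
            vals[mask, j] = np.degrees(
                rng.vonmises(math.radians(state.means[j]), state.kappas[j], size=int(mask.sum()))
            )
    vals = wrap_angle(vals)
    df = pd.DataFrame(vals, columns=list(cv_names), index=pd.RangeIndex(n, name="frame"))
    table = CVTable(values=df, periodic={c: True for c in cv_names})
    truth = pd.DataFrame({"frame": np.arange(n), "state": labels})
    return table, truth


def make_trajectory(
    states: Sequence[PlantedState],
    n_frames: int,
    seed: int,
    amplitude: float = 42.0,
    bond_length: float = _RING_BOND,
) -> tuple:
    """Synthetic monomer trajectory sampled from a mixture of planted states.

    Each state's means are (P_theta, oh_torsion); each frame's ring is built
    at the sampled phase with fixed puckering amplitude and the hydroxyl
    probe placed at the sampled torsion.  Returns (Trajectory, truth table);
    the truth table records the generating state and sampled CVs per frame.
    """
    table, truth = make_cv_samples(states, n_frames, seed, cv_names=("P_theta", "oh_torsion"))
    frames = []
    for i in range(n_frames):
        p, t = table.values.iloc[i]
        frames.append(
            make_ring_geometry(float(p), amplitude, bond_length, oh_torsion=float(t), frame_index=i)
        )
    truth = truth.assign(P_theta=table.values["P_theta"].to_numpy(),
                         oh_torsion=table.values["oh_torsion"].to_numpy())
    return Trajectory.from_frames(frames), truth


# ---------------------------------------------------------------------------
# Dimer frames with a planted pseudo-ring phase
# ---------------------------------------------------------------------------


def _hexagon_with_phase(sides, q: float, phi: float) -> np.ndarray:
    """Planar-inscribed hexagon with prescribed 3D edge lengths and planted
    Cremer-Pople phase, iterated to self-consistency."""
    sides = np.asarray(sides, dtype=float)
    j = np.arange(6)
    phi_z = float(phi)
    pos = None
    for _ in range(60):
        z = q * np.cos(4.0 * np.pi * j / 6.0 + math.radians(phi_z))
        dz = np.roll(z, -1) - z
        planar_sq = sides**2 - dz**2
        if np.any(planar_sq <= 0):
            raise ValueError("infeasible geometry: puckering amplitude exceeds an edge length")
        planar = np.sqrt(planar_sq)

        def gap(radius):
            return float(np.sum(2.0 * np.arcsin(np.clip(planar / (2.0 * radius), -1, 1))) - 2.0 * np.pi)

        r_lo = planar.max() / 2.0 * (1.0 + 1e-12)
        if gap(r_lo) < 0:
            raise ValueError("infeasible geometry: edges cannot close a convex hexagon")
        radius = brentq(gap, r_lo, 1e3, xtol=1e-12)
        theta = np.concatenate([[0.0], np.cumsum(2.0 * np.arcsin(planar / (2.0 * radius)))])[:6]
        pos = np.c_[radius * np.cos(theta), radius * np.sin(theta), z]
        frame = Frame(labels=["X"] * 6, coords=pos, mol_ids=[0] * 6)
        st = cremer_pople(frame, RingDefinition(atoms=(1, 2, 3, 4, 5, 6)), amplitude_tol=0.0)
        err = float(wrap_angle(phi - st.phi))
        if abs(err) < 1e-3:
            return pos
        phi_z = float(wrap_angle(phi_z + err))
    raise ValueError("infeasible geometry: pseudo-ring phase did not converge")


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation matrix taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:  # pick any perpendicular axis for the half turn
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return -np.eye(3) + 2.0 * np.outer(axis, axis)
    w = np.cross(u, v)
    wx = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + wx + wx @ wx / (1.0 + c)


def make_dimer_frame(
    P_A: float,
    P_B: float,
    phi: float,
    hbond_distance: float = 2.8,
    pseudo_ring_amplitude: float = 0.35,
    ring_amplitude: float = 42.0,
    frame_index: int = 0,
) -> Frame:
    """Two five-rings bridged by an O-H...O=C pseudo-ring of planted phase.

    The six pseudo-ring atoms (hydroxyl O, carbonyl C, carbonyl O of each
    molecule, alternating) are placed on a hexagon whose two H-bond edges
    equal ``hbond_distance`` exactly and whose out-of-plane displacements
    realise the Cremer-Pople phase ``phi``; each molecule's five-ring is then
    rigidly attached at its carbonyl carbon with planted pseudorotation
    phase.  Measured P_A, P_B and phi match the inputs to well under the
    2-degree design tolerance; the donor-acceptor distances are exact.

    Atom layout: molecule A = C1..C5, O6, H7, O8 (atoms 1-8); molecule B the
    same (atoms 9-16).  See :data:`DIMER_PSEUDO_RING`.
    """
    # hexagon vertices in pseudo-ring order 6-1-8-6'-1'-8'
    d_oc = 2.4  # hydroxyl O ... carbonyl C (two bonds apart within a molecule)
    sides = [d_oc, _C_DOUBLE_O, hbond_distance, d_oc, _C_DOUBLE_O, hbond_distance]
    hexagon = _hexagon_with_phase(sides, pseudo_ring_amplitude, phi)
    v_o6, v_c1, v_o8, v_o6b, v_c1b, v_o8b = hexagon
    center = hexagon.mean(axis=0)

    def attach_ring(p_target: float, vertex: np.ndarray, mol_id: int) -> np.ndarray:
        ring = make_ring_geometry(p_target, ring_amplitude, mol_id=mol_id)
        pos = ring.coords - ring.coords[0]  # C1 at origin
        centroid = pos.mean(axis=0)
        outward = vertex - center
        outward = outward / np.linalg.norm(outward) + np.array([0.0, 0.0, 0.8 if mol_id == 0 else -0.8])
        rot = _rotation_between(centroid, outward)
        return pos @ rot.T + vertex

    ring_a = attach_ring(P_A, v_c1, 0)
    ring_b = attach_ring(P_B, v_c1b, 1)
    h7 = v_o6 + _OH_BOND * (v_o8b - v_o6) / np.linalg.norm(v_o8b - v_o6)
    h7b = v_o6b + _OH_BOND * (v_o8 - v_o6b) / np.linalg.norm(v_o8 - v_o6b)
    coords = np.vstack([ring_a, v_o6, h7, v_o8, ring_b, v_o6b, h7b, v_o8b])
    labels = (["C"] * 5 + ["O", "H", "O"]) * 2
    mol_ids = [0] * 8 + [1] * 8
    return Frame(labels=labels, coords=coords, mol_ids=mol_ids, index=frame_index)


# ---------------------------------------------------------------------------
# Stick spectra
# ---------------------------------------------------------------------------


def make_stick_spectrum(
    kind: str,
    seed: int = 0,
    structure_id: Optional[str] = None,
    couplet_center: float = 1760.0,
    couplet_splitting: float = 20.0,
    couplet_strength: float = 100.0,
    n_modes: int = 10,
    wavenumber_range: tuple = (900.0, 1800.0),
    energy: Optional[float] = None,
) -> StickSpectrum:
    """A synthetic stick spectrum.

    ``kind="monomer"``: a fixed mid-IR mode set with seeded intensities.
    ``kind="dimer-couplet"``: the bisignate VCD pair of two coupled carbonyl
    oscillators at ``couplet_center +/- couplet_splitting/2`` (VCD +/-,
    equal IR intensity), the signature a flexible dimer can average away.
    ``kind="random"``: ``n_modes`` uniform random modes.
    """
    rng = np.random.default_rng(seed)
    if kind == "dimer-couplet":
        half = couplet_splitting / 2.0
        wns = np.array([couplet_center - half, couplet_center + half])
        if couplet_splitting == 0:
            wns = np.array([couplet_center, couplet_center])
        intens = {
            "ir": np.array([couplet_strength, couplet_strength]),
            "vcd": np.array([+couplet_strength, -couplet_strength]),
        }
        sid = structure_id or f"dimer-couplet-{seed}"
        return StickSpectrum(sid, wns, intens, energy=energy)
    if kind == "monomer":
        base = np.linspace(wavenumber_range[0], wavenumber_range[1], n_modes)
        wns = base + rng.normal(0.0, 5.0, size=n_modes)
        intens = {
            "ir": rng.uniform(5.0, 100.0, size=n_modes),
            "vcd": rng.normal(0.0, 10.0, size=n_modes),
            "raman": rng.uniform(5.0, 100.0, size=n_modes),
            "roa": rng.normal(0.0, 10.0, size=n_modes),
        }
        sid = structure_id or f"monomer-{seed}"
        return StickSpectrum(sid, np.sort(wns), intens, energy=energy)
    if kind == "random":
        wns = np.sort(rng.uniform(*wavenumber_range, size=n_modes))
        intens = {
            "ir": rng.uniform(0.0, 100.0, size=n_modes),
            "vcd": rng.normal(0.0, 20.0, size=n_modes),
            "raman": rng.uniform(0.0, 100.0, size=n_modes),
            "roa": rng.normal(0.0, 20.0, size=n_modes),
        }
        sid = structure_id or f"random-{seed}"
        return StickSpectrum(sid, wns, intens, energy=energy)
    raise ValueError("kind must be 'monomer', 'dimer-couplet' or 'random'")


# ---------------------------------------------------------------------------
# Solvated frames
# ---------------------------------------------------------------------------


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _water(origin: np.ndarray, direction: np.ndarray, rng) -> np.ndarray:
    """A rigid 3-atom water (O, H, H) with O at origin; the first H points
    along ``direction``."""
    d = direction / np.linalg.norm(direction)
    perp = np.cross(d, _random_unit(rng))
    while np.linalg.norm(perp) < 1e-6:
        perp = np.cross(d, _random_unit(rng))
    perp /= np.linalg.norm(perp)
    h1 = origin + _OH_BOND * d
    ang = math.radians(104.5)
    h2 = origin + _OH_BOND * (math.cos(ang) * d + math.sin(ang) * perp)
    return np.vstack([origin, h1, h2])


def make_solvated_frames(
    n_frames: int,
    p_contact: float,
    seed: int,
    n_shell: int = 11,
    n_outer: int = 8,
    contact_distance: float = 2.85,
    shell_band: tuple = (2.9, 3.8),
    outer_band: tuple = (5.2, 8.0),
) -> Trajectory:
    """Solvated monomer frames with a planted H-bond contact probability.

    Molecule 0 is the solute (C1..C5, O6, H7, O8); molecules 1..N are waters.
    Water 1 donates an H-bond to the carbonyl O8 (D-A distance
    ``contact_distance``, near-linear) with probability ``p_contact`` per
    frame, and sits far otherwise.  ``n_shell`` further waters lie with their
    O atom inside ``shell_band`` of a solute atom (all within 4 Å), and
    ``n_outer`` waters beyond ``outer_band[0]`` — so a 4 Å shell holds
    ``n_shell`` (+1 when the contact is formed) waters.
    """
    if not 0 <= p_contact <= 1:
        raise ValueError("p_contact must be in [0, 1]")
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        solute = make_ring_geometry(-157.0, 42.0, oh_torsion=80.0, frame_index=i)
        coords = [solute.coords]
        labels = list(solute.labels)
        mol_ids = list(solute.mol_ids)
        centroid = solute.coords.mean(axis=0)
        o8 = solute.coords[7]
        mol = 1
        # contact water donating to the carbonyl oxygen
        out_dir = o8 - centroid
        out_dir /= np.linalg.norm(out_dir)
        if rng.random() < p_contact:
            o_pos = o8 + contact_distance * out_dir
            w = _water(o_pos, -out_dir, rng)  # first H points at the acceptor
        else:
            o_pos = o8 + rng.uniform(*outer_band) * out_dir
            w = _water(o_pos, _random_unit(rng), rng)
        coords.append(w)
        labels += ["O", "H", "H"]
        mol_ids += [mol] * 3
        mol += 1
        # shell and outer waters; resample until the O atom's distance to the
        # nearest solute atom falls inside the intended band
        for band, count in ((shell_band, n_shell), (outer_band, n_outer)):
            for _ in range(count):
                while True:
                    anchor = solute.coords[rng.integers(0, solute.n_atoms)]
                    direction = _random_unit(rng)
                    if np.dot(direction, anchor - centroid) < 0:
                        direction = -direction
                    o_pos = anchor + rng.uniform(*band) * direction
                    dmin = np.linalg.norm(solute.coords - o_pos, axis=1).min()
                    if band[0] <= dmin <= band[1]:
                        break
                w = _water(o_pos, _random_unit(rng), rng)
                coords.append(w)
                labels += ["O", "H", "H"]
                mol_ids += [mol] * 3
                mol += 1
        frames.append(Frame(labels=labels, coords=np.vstack(coords), mol_ids=mol_ids, index=i))
    return Trajectory.from_frames(frames)
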