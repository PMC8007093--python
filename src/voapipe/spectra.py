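"""Assembly of continuous IR/VCD/Raman/ROA band-shapes from stick spectra.

A *stick spectrum* is the discrete (wavenumber, intensity) list produced by a
harmonic frequency calculation on one structure.  This module turns sets of
such sticks into composite band-shapes:

* Lorentzian broadening (bandwidth = full width at half maximum, default
  6 cm^-1) with a wavenumber scaling factor applied to mode positions only,
* Boltzmann weighting from relative energies (default T = 300 K),
* convex (population-weighted) averaging over structures,
* monomer-dimer mixing from an association equilibrium K = [D]/[M]^2 at a
  total (monomer-equivalent) concentration c,
* a displacement scan of a geometry along selected normal modes, used to
  probe the sensitivity of intense VCD features to low-frequency distortions.

Intensities are accepted in plottable units; conversion from dipole and
rotational strengths is provided separately (:func:`ir_epsilon_from_dipole_strength`,
:func:`vcd_delta_epsilon_from_rotational_strength`) and never applied
implicitly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import Frame

__all__ = [
    "OBSERVABLES",
    "StickSpectrum",
    "CompositeSpectrum",
    "EquilibriumSpec",
    "make_grid",
    "broaden",
    "boltzmann_weights",
    "weighted_average",
    "equilibrium_fractions",
    "mix_monomer_dimer",
    "displace_along_modes",
    "read_sticks_csv",
    "write_sticks_csv",
    "ir_epsilon_from_dipole_strength",
    "vcd_delta_epsilon_from_rotational_strength",
]

OBSERVABLES = ("ir", "vcd", "raman", "roa")
SIGNED_OBSERVABLES = {"vcd", "roa"}  # circular-difference spectra may be negative

GAS_CONSTANT_KCAL = 1.987204258640832e-3  # kcal / (mol K)
DEFAULT_TEMPERATURE = 300.0  # K, the simulation temperature
DEFAULT_BANDWIDTH = 6.0  # cm^-1 FWHM Lorentzian
DEFAULT_GRID_SPACING = 1.0  # cm^-1


@dataclass
class StickSpectrum:
    """Discrete vibrational modes of one structure.

    ``intensities`` maps observable name ('ir', 'vcd', 'raman', 'roa') to a
    per-mode intensity array.  IR and Raman intensities must be nonnegative;
    VCD and ROA may carry either sign.  ``energy`` (kcal/mol) is the parent
    structure's relative energy, used for Boltzmann weighting.
    """

    structure_id: str
    wavenumbers: np.ndarray  # cm^-1
    intensities: Dict[str, np.ndarray]
    energy: Optional[float] = None

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if not np.all(np.isfinite(self.wavenumbers)) or np.any(self.wavenumbers <= 0):
            raise ValueError("wavenumbers must be finite and positive")
        clean = {}
        for obs, vals in self.intensities.items():
            if obs not in OBSERVABLES:
                raise ValueError(f"unknown observable {obs!r}; expected one of {OBSERVABLES}")
            vals = np.asarray(vals, dtype=float)
            if vals.shape != self.wavenumbers.shape:
                raise ValueError(f"intensity array for {obs!r} has wrong length")
            if obs not in SIGNED_OBSERVABLES and np.any(vals < 0):
                raise ValueError(f"{obs} intensities must be nonnegative")
            clean[obs] = vals
        self.intensities = clean

    @property
    def n_modes(self) -> int:
        return len(self.wavenumbers)


@dataclass
class CompositeSpectrum:
    """Continuous spectrum on a uniform wavenumber grid, with provenance."""

    grid: np.ndarray  # cm^-1, strictly increasing, uniform
    intensities: Dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        steps = np.diff(self.grid)
        if len(self.grid) < 2 or np.any(steps <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9):
            raise ValueError("grid must be uniform")
        self.intensities = {k: np.asarray(v, dtype=float) for k, v in self.intensities.items()}
        for k, v in self.intensities.items():
            if v.shape != self.grid.shape:
                raise ValueError(f"intensity array for {k!r} does not match the grid")

    @property
    def spacing(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def integral(self, observable: str) -> float:
        return float(np.trapezoid(self.intensities[observable], self.grid))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"wavenumber_cm-1": self.grid})
        for obs in OBSERVABLES:
            if obs in self.intensities:
                df[obs] = self.intensities[obs]
        return df


def make_grid(lo: float, hi: float, spacing: float = DEFAULT_GRID_SPACING) -> np.ndarray:
    """Uniform wavenumber grid [lo, hi] with the given spacing (cm^-1)."""
    if hi <= lo:
        raise ValueError("grid upper bound must exceed lower bound")
    n = int(round((hi - lo) / spacing)) + 1
    return lo + spacing * np.arange(n)


def grid_for(sticks, bandwidth: float = DEFAULT_BANDWIDTH, scale: float = 1.0,
             spacing: float = DEFAULT_GRID_SPACING, margin_bandwidths: float = 25.0) -> np.ndarray:
    """A grid covering the scaled modes of one or more stick spectra with margin."""
    if isinstance(sticks, StickSpectrum):
        sticks = [sticks]
    wns = np.concatenate([s.wavenumbers for s in sticks]) * scale
    m = margin_bandwidths * bandwidth
    return make_grid(max(0.0, wns.min() - m), wns.max() + m, spacing)


def broaden(
    stick: StickSpectrum,
    bandwidth: float = DEFAULT_BANDWIDTH,
    scale: float = 1.0,
    grid: Optional[np.ndarray] = None,
) -> CompositeSpectrum:
    """Lorentzian-broadened spectrum of one structure.

    Each mode contributes a unit-area Lorentzian of FWHM ``bandwidth``
    centred at ``scale * wavenumber`` and multiplied by the mode intensity,
    so peak height of an isolated unit-intensity mode is 2/(pi*FWHM).
    ``scale`` acts on wavenumbers only, never intensities.
    """
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    if not 0 < scale <= 1.1:
        raise ValueError("scale must be in (0, 1.1]")
    if grid is None:
        grid = grid_for(stick, bandwidth=bandwidth, scale=scale)
    grid = np.asarray(grid, dtype=float)
    centers = scale * stick.wavenumbers
    margin = 20.0 * bandwidth
    lo, hi = grid[0], grid[-1]
    for c, w in zip(centers, stick.wavenumbers):
        if c - margin < lo or c + margin > hi:
            raise ValueError(
                f"grid [{lo:g}, {hi:g}] cm^-1 does not cover mode at {w:g} "
                f"(scaled {c:g}) cm^-1 with a {margin:g} cm^-1 margin"
            )
    gamma = bandwidth / 2.0  # HWHM
    # unit-area Lorentzian: (1/pi) * gamma / ((x - x0)^2 + gamma^2)
    profile = (gamma / math.pi) / ((grid[None, :] - centers[:, None]) ** 2 + gamma**2)
    out = {obs: vals @ profile for obs, vals in stick.intensities.items()}
    return CompositeSpectrum(
        grid=grid,
        intensities=out,
        provenance={
            "structures": [stick.structure_id],
            "weights": [1.0],
            "bandwidth_fwhm_cm-1": bandwidth,
            "scale": scale,
        },
    )


def boltzmann_weights(energies, temperature: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Normalised Boltzmann populations from relative energies (kcal/mol).

    w_i proportional to exp(-(E_i - min E) / RT); shifting by the minimum
    keeps large energy gaps from underflowing the dominant weights.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("at least one energy required")
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    x = np.exp(-(e - e.min()) / (GAS_CONSTANT_KCAL * temperature))
    return x / x.sum()


def weighted_average(spectra: Sequence[CompositeSpectrum], weights) -> CompositeSpectrum:
    """Pointwise convex combination of spectra sharing one grid.

    Weights must be nonnegative and sum to 1 within 1e-9; otherwise they are
    renormalised with a warning.  Grids must match exactly (no resampling).
    """
    if not spectra:
        raise ValueError("no spectra to average")
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != len(spectra):
        raise ValueError("one weight per spectrum required")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if abs(total - 1.0) > 1e-9:
        warnings.warn(f"weights sum to {total:.6g}; renormalising", stacklevel=2)
        w = w / total
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid.shape != grid.shape or not np.array_equal(s.grid, grid):
            raise ValueError("spectra grids differ; resample explicitly before averaging")
    observables = set(spectra[0].intensities)
    for s in spectra[1:]:
        observables &= set(s.intensities)
    out = {obs: sum(wi * s.intensities[obs] for wi, s in zip(w, spectra)) for obs in sorted(observables)}
    prov = {
        "structures": [s.provenance.get("structures", ["?"]) for s in spectra],
        "weights": w.tolist(),
    }
    return CompositeSpectrum(grid=grid.copy(), intensities=out, provenance=prov)


@dataclass(frozen=True)
class EquilibriumSpec:
    """Monomer-dimer association equilibrium: K = [D]/[M]^2 (M^-1), total
    monomer-equivalent concentration c = [M] + 2[D] (M)."""

    K: float
    c: float

    def __post_init__(self):
        if self.K < 0:
            raise ValueError("association constant K must be >= 0")
        if not self.c > 0:
            raise ValueError("total concentration c must be positive")


def equilibrium_fractions(spec: EquilibriumSpec) -> tuple:
    """Fractions of molecules in monomeric and dimeric form.

    Solving K = [D]/[M]^2 with mass balance c = [M] + 2[D] gives
    [M] = (-1 + sqrt(1 + 8 K c)) / (4 K), with the K -> 0 limit [M] = c.
    Returned as (monomer fraction [M]/c, dimer fraction 2[D]/c); the two sum
    to 1 exactly.
    """
    K, c = spec.K, spec.c
    if K == 0:
        return 1.0, 0.0
    # rationalised form of (-1 + sqrt(1 + 8Kc)) / (4K): no cancellation at
    # small Kc, and the K -> 0 limit [M] = c is built in
    f_m = 2.0 / (1.0 + math.sqrt(1.0 + 8.0 * K * c))
    return f_m, 1.0 - f_m


def mix_monomer_dimer(
    monomer: CompositeSpectrum,
    dimer: CompositeSpectrum,
    spec: EquilibriumSpec,
    dimer_normalization: Optional[str] = None,
) -> CompositeSpectrum:
    """Combine monomer and dimer spectra by equilibrium populations.

    The monomer spectrum is weighted by the monomer molecule fraction
    [M]/c.  The dimer weight depends on how the dimer spectrum is
    normalised, which must be declared explicitly:

    * ``"per-molecule"``: the dimer spectrum is per pantolactone unit;
      weight 2[D]/c (weights sum to 1).
    * ``"per-dimer"``: the dimer spectrum is per dimer species; weight [D]/c.
    """
    if dimer_normalization not in ("per-molecule", "per-dimer"):
        raise ValueError(
            "dimer_normalization must be declared: 'per-molecule' or 'per-dimer'"
        )
    f_m, f_d = equilibrium_fractions(spec)
    w_d = f_d if dimer_normalization == "per-molecule" else f_d / 2.0
    if not np.array_equal(monomer.grid, dimer.grid):
        raise ValueError("monomer and dimer grids differ")
    observables = sorted(set(monomer.intensities) & set(dimer.intensities))
    out = {
        obs: f_m * monomer.intensities[obs] + w_d * dimer.intensities[obs]
        for obs in observables
    }
    return CompositeSpectrum(
        grid=monomer.grid.copy(),
        intensities=out,
        provenance={
            "K_M^-1": spec.K,
            "c_M": spec.c,
            "monomer_weight": f_m,
            "dimer_weight": w_d,
            "dimer_normalization": dimer_normalization,
        },
    )


def displace_along_modes(geometry: Frame, modes: Sequence[tuple], steps: Sequence[float]) -> list:
    """Geometries displaced along normalised normal-mode vectors.

    ``modes`` is a list of (wavenumber, displacement array (n_atoms, 3));
    each displacement is normalised to unit Frobenius norm, so a step s moves
    the geometry by s Å of collective displacement.  One frame per
    (mode, step) pair is returned, labelled in its comment; symmetric step
    sets (+/-s) average back to the input geometry.
    """
    steps = [float(s) for s in steps]
    if not all(math.isfinite(s) for s in steps):
        raise ValueError("steps must be finite")
    out = []
    for k, (wavenumber, disp) in enumerate(modes):
        disp = np.asarray(disp, dtype=float)
        if disp.shape != geometry.coords.shape:
            raise ValueError(
                f"mode {k} displacement shape {disp.shape} does not match "
                f"geometry {geometry.coords.shape}"
            )
        norm = np.linalg.norm(disp)
        if norm < 1e-12:
            raise ValueError(f"mode {k} has zero displacement")
        unit = disp / norm
        for s in steps:
            frame = Frame(
                labels=geometry.labels,
                coords=geometry.coords + s * unit,
                mol_ids=geometry.mol_ids,
                index=geometry.index,
                comment=f"mode {k} ({wavenumber:g} cm^-1) step {s:+g}",
            )
            out.append(frame)
    return out


# ---------------------------------------------------------------------------
# Stick-spectrum CSV schema (the sole interchange format with QM outputs)
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["structure_id", "wavenumber_cm-1"] + list(OBSERVABLES)


def write_sticks_csv(sticks: Sequence[StickSpectrum], path, energies_in_comment: bool = False) -> None:
    rows = []
    for s in sticks:
        for i, wn in enumerate(s.wavenumbers):
            row = {"structure_id": s.structure_id, "wavenumber_cm-1": wn}
            for obs in OBSERVABLES:
                row[obs] = s.intensities.get(obs, np.full(s.n_modes, np.nan))[i]
            if s.energy is not None:
                row["energy_kcal_mol"] = s.energy
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8g")


def read_sticks_csv(path) -> list:
    """Stick spectra from CSV (structure_id, wavenumber_cm-1, ir, vcd, raman,
    roa[, energy_kcal_mol]); missing observable columns are allowed."""
    df = pd.read_csv(path)
    for col in ("structure_id", "wavenumber_cm-1"):
        if col not in df.columns:
            raise ValueError(f"stick CSV missing required column {col!r}")
    out = []
    for sid, grp in df.groupby("structure_id", sort=True):
        intens = {}
        for obs in OBSERVABLES:
            if obs in grp.columns and not grp[obs].isna().all():
                intens[obs] = grp[obs].to_numpy(dtype=float)
        energy = None
        if "energy_kcal_mol" in grp.columns and not grp["energy_kcal_mol"].isna().all():
            energy = float(grp["energy_kcal_mol"].iloc[0])
        out.append(
            StickSpectrum(
                structure_id=str(sid),
                wavenumbers=grp["wavenumber_cm-1"].to_numpy(dtype=float),
                intensities=intens,
                energy=energy,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Optional unit conversions (never applied implicitly)
# ---------------------------------------------------------------------------

# A unit-area Lorentzian stick multiplied by these prefactors yields molar
# (differential) absorptivity in L mol^-1 cm^-1 per cm^-1 of bandwidth.
# Constants from the standard absorption/VCD intensity relations:
#   D = 9.184e-39 * Integral(eps/nu) dnu   [esu^2 cm^2]
#   R = 2.296e-39 * Integral(Deps/nu) dnu  [esu^2 cm^2]
_DIPOLE_STRENGTH_PREFACTOR = 1.0 / 9.184e-39
_ROTATIONAL_STRENGTH_PREFACTOR = 4.0 / 9.184e-39  # = 1 / 2.296e-39


def ir_epsilon_from_dipole_strength(wavenumber: float, dipole_strength_esu2cm2: float) -> float:
    """Integrated molar absorptivity (L mol^-1 cm^-2) of one IR mode."""
    return _DIPOLE_STRENGTH_PREFACTOR * wavenumber * dipole_strength_esu2cm2


def vcd_delta_epsilon_from_rotational_strength(wavenumber: float, rotational_strength_esu2cm2: float) -> float:
    """Integrated molar differential absorptivity of one VCD mode."""
    return _ROTATIONAL_STRENGTH_PREFACTOR * wavenumber * rotational_strength_esu2cm2
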