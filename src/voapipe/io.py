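"""Trajectory and table I/O, pipeline configuration, provenance sidecars.

Trajectory formats:

* multi-model XYZ — the mandatory dialect: atom-count line, free-text comment
  line, then ``element x y z`` records, repeated per model.  Molecule
  membership is not part of XYZ and is supplied by the caller (config block).
* PDB — MODEL/ENDMDL frames read through MDAnalysis; molecule membership
  from residue ids (or chain ids with ``membership="chain"``).

Every pipeline output gets a JSON provenance sidecar carrying the fully
serialised configuration and the package version, sufficient to rerun it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .geometry import Frame, Trajectory

__all__ = [
    "read_trajectory",
    "read_xyz",
    "write_xyz",
    "PipelineConfig",
    "write_provenance",
]


class XYZParseError(ValueError):
    pass


def read_xyz(path, mol_ids: Optional[Sequence[int]] = None, stride: int = 1) -> Trajectory:
    """Multi-model XYZ reader (strict dialect), with optional frame stride.

    With ``stride`` s, models 0, s, 2s, ... are kept and the frame count is
    floor(models / stride).  Malformed content raises
    :class:`XYZParseError` naming the offending line and the last complete
    model.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    path = Path(path)
    lines = path.read_text().splitlines()
    models = []
    labels0 = None
    i = 0
    n_model = 0
    while i < len(lines):
        if lines[i].strip() == "" and i == len(lines) - 1:
            break
        try:
            natoms = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise XYZParseError(
                f"{path}:{i + 1}: expected atom-count line after "
                f"{n_model} complete model(s), got {lines[i]!r}"
            )
        if i + 1 + natoms >= len(lines) + 1 and i + 1 + natoms > len(lines):
            raise XYZParseError(
                f"{path}: truncated file after {n_model} complete model(s); "
                f"model starting at line {i + 1} needs {natoms} atom records"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        labels, coords = [], []
        for j in range(natoms):
            ln = i + 2 + j
            if ln >= len(lines):
                raise XYZParseError(
                    f"{path}: truncated file after {n_model} complete model(s)"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(f"{path}:{ln + 1}: expected 'element x y z', got {lines[ln]!r}")
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise XYZParseError(f"{path}:{ln + 1}: non-numeric coordinate in {lines[ln]!r}")
            labels.append(parts[0])
            coords.append(xyz)
        if labels0 is None:
            labels0 = labels
        elif labels != labels0:
            raise XYZParseError(
                f"{path}: model {n_model + 1} atom labels/count differ from model 1"
            )
        models.append((comment, np.array(coords)))
        n_model += 1
        i += 2 + natoms
    if not models:
        raise XYZParseError(f"{path}: no models found")
    keep = models[::stride][: len(models) // stride]
    if not keep:
        raise ValueError(f"stride {stride} leaves no frames out of {len(models)} models")
    ids = np.zeros(len(labels0), int) if mol_ids is None else np.asarray(mol_ids, int)
    if len(ids) != len(labels0):
        raise ValueError("mol_ids length does not match atom count")
    return Trajectory(
        labels=labels0,
        coords=np.stack([c for _, c in keep]),
        mol_ids=ids,
        frame_indices=np.arange(0, len(models), stride)[: len(keep)],
        comments=[c for c, _ in keep],
    )


def write_xyz(frames, path) -> None:
    """Write frame(s) as multi-model XYZ (fixed 6-decimal coordinates)."""
    if isinstance(frames, (Frame, Trajectory)):
        frames = list(frames) if isinstance(frames, Trajectory) else [frames]
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{frame.n_atoms}\n")
            fh.write(f"{frame.comment or f'frame {frame.index}'}\n")
            for lab, (x, y, z) in zip(frame.labels, frame.coords):
                fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")


def _read_pdb(path, stride: int, membership: str = "residue") -> Trajectory:
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        labels = [
            a.element if getattr(a, "element", "") else "".join(c for c in a.name if c.isalpha())[:1]
            for a in u.atoms
        ]
        if membership == "chain":
            keys = [getattr(a, "chainID", "") or a.segid for a in u.atoms]
        else:
            keys = [(a.resid, a.segid) for a in u.atoms]
        uniq = {k: i for i, k in enumerate(dict.fromkeys(keys))}
        mol_ids = np.array([uniq[k] for k in keys])
        coords = np.stack([u.atoms.positions.astype(float).copy() for _ in u.trajectory])
    keep = coords[::stride][: len(coords) // stride]
    return Trajectory(
        labels=labels,
        coords=keep,
        mol_ids=mol_ids,
        frame_indices=np.arange(0, len(coords), stride)[: len(keep)],
    )


def read_trajectory(path, format: Optional[str] = None, stride: int = 1,
                    mol_ids: Optional[Sequence[int]] = None, membership: str = "residue") -> Trajectory:
    """Read a multi-model XYZ or PDB trajectory with a frame stride."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return read_xyz(path, mol_ids=mol_ids, stride=stride)
    if fmt == "pdb":
        traj = _read_pdb(path, stride, membership=membership)
        if mol_ids is not None:
            traj.mol_ids = np.asarray(mol_ids, int)
        return traj
    raise ValueError(f"unsupported trajectory format {fmt!r} (xyz or pdb)")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, loadable from YAML or JSON.

    Atom indices are 1-based.  ``cvs`` entries are mappings with a ``type``
    of ``torsion`` (4 ``atoms``), ``pucker_phase`` (5-atom ``ring``) or
    ``ring_phase`` (6-atom ``ring``), plus a ``name``.  ``donors`` entries
    are mappings ``{atom: i, hydrogens: [j, ...]}``.
    """

    trajectory: str = ""
    format: Optional[str] = None
    stride: int = 1
    mol_ids: Optional[list] = None
    cvs: list = field(default_factory=list)
    donors: list = field(default_factory=list)
    acceptors: list = field(default_factory=list)
    hbond_max_distance: float = 3.0
    hbond_max_angle: float = 30.0
    dimer_molecules: Optional[list] = None  # [mol_a, mol_b]
    dimer_threshold: float = 4.0
    k: int = 6
    seed: int = 0
    shell_radius: Optional[float] = None
    solute_molecules: Optional[list] = None
    sticks: Optional[str] = None  # stick-spectrum CSV path
    bandwidth: float = 6.0
    scale: float = 1.0
    temperature: float = 300.0
    K: Optional[float] = None  # association constant, M^-1 (no default)
    c: Optional[float] = None  # total concentration, M
    dimer_normalization: Optional[str] = None
    grid_spacing: float = 1.0
    output_dir: str = "voapipe_out"

    def __post_init__(self):
        for name, val in (("stride", self.stride), ("k", self.k),
                          ("hbond_max_distance", self.hbond_max_distance),
                          ("bandwidth", self.bandwidth), ("temperature", self.temperature),
                          ("grid_spacing", self.grid_spacing)):
            if val is not None and val <= 0:
                raise ValueError(f"config field {name} must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def build_cv_specs(self):
        from .geometry import PuckerPhaseCV, RingDefinition, RingPhaseCV, TorsionCV

        specs = []
        for entry in self.cvs:
            kind = entry.get("type")
            name = entry.get("name")
            if not name:
                raise ValueError("each CV entry needs a 'name'")
            if kind == "torsion":
                specs.append(TorsionCV(name=name, atoms=tuple(entry["atoms"])))
            elif kind == "pucker_phase":
                specs.append(PuckerPhaseCV(name=name, ring=RingDefinition(atoms=tuple(entry["ring"]))))
            elif kind == "ring_phase":
                specs.append(RingPhaseCV(name=name, ring=RingDefinition(atoms=tuple(entry["ring"]))))
            else:
                raise ValueError(f"CV {name!r}: unknown type {kind!r}")
        return specs

    def build_donors(self):
        from .interactions import Donor

        return [Donor(atom=int(d["atom"]), hydrogens=tuple(d["hydrogens"])) for d in self.donors]


def write_provenance(path, config: PipelineConfig, extra: Optional[dict] = None) -> None:
    """JSON sidecar with the full config (and stage metadata) next to an output."""
    payload = {"config": config.to_dict(), "package": "voapipe"}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
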