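"""Domain types and I/O: topologies, trajectory ensembles, run configuration.

Structures travel as (multi-model) PDB via biotite; the per-atom physical
parameters (charges, LJ, Born radii, screening factors, hydrogen-bond
roles) travel as a JSON sidecar next to the structure, because real
force-field topology files are out of scope.  Result tables are plain CSV
with a deterministic column order.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BindscapeError",
    "ParseError",
    "StructureError",
    "SelectionError",
    "SpecError",
    "ConfigError",
    "EmptyEnsembleError",
    "Atom",
    "Topology",
    "Replica",
    "TrajectoryEnsemble",
    "RunConfig",
    "read_structure",
    "write_structure",
    "write_results",
    "read_results",
    "build_smt",
]


class BindscapeError(Exception):
    """Base class for package errors."""


class ParseError(BindscapeError):
    """A file did not parse under its declared format."""


class StructureError(BindscapeError):
    """Structurally inconsistent input (e.g. model atom-count mismatch)."""


class SelectionError(BindscapeError):
    """An atom/residue selection is empty or invalid."""


class SpecError(BindscapeError):
    """A generator or analysis specification is infeasible."""


class ConfigError(BindscapeError):
    """Invalid run configuration value."""


class EmptyEnsembleError(BindscapeError):
    """No frames survive filtering."""


SEGMENTS = ("receptor", "ligand")
REGIONS = ("backbone", "sidechain", "ligand")
HB_ROLES = ("donor_heavy", "polar_hydrogen", "acceptor", "none")

#: Atom names conventionally counted as protein backbone.
BACKBONE_NAMES = frozenset({"N", "H", "CA", "HA", "C", "O"})


@dataclass
class Atom:
    """One atom with the per-atom physics the energy terms consume.

    ``charge`` is in elementary charges, ``lj_rmin_half``/``born_radius``
    in Angstrom, ``lj_epsilon`` in kcal/mol, ``screen`` the dimensionless
    HCT descreening scale, ``mass`` in amu.
    """

    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    segment: str
    charge: float = 0.0
    lj_rmin_half: float = 1.7
    lj_epsilon: float = 0.1
    born_radius: float = 1.5
    screen: float = 0.8
    mass: float = 12.01
    region: str = "sidechain"
    hb_role: str = "none"
    bonded_hydrogens: tuple[int, ...] = ()

    def validate(self) -> None:
        if not math.isfinite(self.charge):
            raise StructureError(f"atom {self.index}: non-finite charge")
        if self.lj_epsilon < 0:
            raise StructureError(f"atom {self.index}: negative LJ epsilon")
        if self.born_radius <= 0:
            raise StructureError(f"atom {self.index}: non-positive Born radius")
        if self.segment not in SEGMENTS:
            raise StructureError(f"atom {self.index}: unknown segment {self.segment!r}")
        if self.region not in REGIONS:
            raise StructureError(f"atom {self.index}: unknown region {self.region!r}")
        if self.hb_role not in HB_ROLES:
            raise StructureError(f"atom {self.index}: unknown hb_role {self.hb_role!r}")
        if self.segment == "ligand" and self.region != "ligand":
            raise StructureError(f"atom {self.index}: ligand atom with region {self.region!r}")
        if self.segment == "receptor" and self.region == "ligand":
            raise StructureError(f"atom {self.index}: receptor atom with region 'ligand'")


class Topology:
    """Ordered atom list plus residue/segment bookkeeping.

    Residue indices are 0-based and contiguous per segment; binding
    analyses require at least one receptor and one ligand atom.
    """

    def __init__(self, atoms: Sequence[Atom], bonds: Sequence[tuple[int, int]] = ()):
        self.atoms: list[Atom] = list(atoms)
        self.bonds: list[tuple[int, int]] = [tuple(b) for b in bonds]
        self._validate()
        self._build_arrays()

    def _validate(self) -> None:
        donors: dict[int, int] = {}
        for i, atom in enumerate(self.atoms):
            if atom.index != i:
                raise StructureError(f"atom order broken at position {i} (index {atom.index})")
            atom.validate()
            for h in atom.bonded_hydrogens:
                if h in donors:
                    raise StructureError(f"hydrogen {h} claimed by donors {donors[h]} and {i}")
                donors[h] = i
        for i, atom in enumerate(self.atoms):
            if atom.hb_role == "polar_hydrogen" and i not in donors:
                raise StructureError(f"polar hydrogen {i} not bonded to any donor")

    def _build_arrays(self) -> None:
        a = self.atoms
        self.charges = np.array([x.charge for x in a], dtype=float)
        self.lj_rmin_half = np.array([x.lj_rmin_half for x in a], dtype=float)
        self.lj_epsilon = np.array([x.lj_epsilon for x in a], dtype=float)
        self.born_radii = np.array([x.born_radius for x in a], dtype=float)
        self.screens = np.array([x.screen for x in a], dtype=float)
        self.masses = np.array([x.mass for x in a], dtype=float)
        self.residue_indices = np.array([x.residue_index for x in a], dtype=int)
        seg = np.array([x.segment for x in a])
        self.receptor_atoms = np.flatnonzero(seg == "receptor")
        self.ligand_atoms = np.flatnonzero(seg == "ligand")
        self.heavy_atoms = np.flatnonzero(np.array([x.element != "H" for x in a]))
        self.ca_atoms = np.flatnonzero(
            np.array([x.name == "CA" and x.segment == "receptor" for x in a])
        )
        seen: dict[tuple[int, str], tuple[int, str, str]] = {}
        for x in a:
            key = (x.residue_index, x.segment)
            seen.setdefault(key, (x.residue_index, x.residue_name, x.segment))
        self.residues: list[tuple[int, str, str]] = sorted(seen.values(), key=lambda r: (r[2], r[0]))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atoms_of_residue(self, residue_index: int, segment: str = "receptor") -> np.ndarray:
        mask = [
            x.residue_index == residue_index and x.segment == segment for x in self.atoms
        ]
        return np.flatnonzero(np.array(mask))

    def require_binding_partners(self) -> None:
        if len(self.receptor_atoms) == 0 or len(self.ligand_atoms) == 0:
            raise SelectionError("binding analyses need both receptor and ligand atoms")

    # -- sidecar serialization ------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "atoms": [dataclasses.asdict(x) for x in self.atoms],
            "bonds": [list(b) for b in self.bonds],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Topology":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"topology sidecar {path}: {exc}") from exc
        atoms = []
        for rec in payload["atoms"]:
            rec = dict(rec)
            rec["bonded_hydrogens"] = tuple(rec.get("bonded_hydrogens", ()))
            atoms.append(Atom(**rec))
        return cls(atoms, bonds=[tuple(b) for b in payload.get("bonds", [])])


@dataclass
class Replica:
    """One contiguous block of frames: coordinates (n_frames, n_atoms, 3) A, times in ns."""

    coords: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("replica coordinates must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.coords):
            raise StructureError("replica times and frames disagree in length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("replica times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.coords)


@dataclass
class TrajectoryEnsemble:
    """Replicated coordinate ensembles with per-replica burn-in markers (ns)."""

    replicas: list[Replica]
    burn_in: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicas:
            raise StructureError("ensemble needs at least one replica")
        n_atoms = self.replicas[0].coords.shape[1]
        for r in self.replicas:
            if r.coords.shape[1] != n_atoms:
                raise StructureError("replicas disagree in atom count")
        if not self.burn_in:
            # Default: discard the first half of each replica.
            self.burn_in = [
                float(r.times[0] + (r.times[-1] - r.times[0]) / 2.0) if r.n_frames > 1 else float(r.times[0])
                for r in self.replicas
            ]
        if len(self.burn_in) != len(self.replicas):
            raise ConfigError("burn_in must supply one threshold per replica")

    @property
    def n_atoms(self) -> int:
        return self.replicas[0].coords.shape[1]


def build_smt(ensemble: TrajectoryEnsemble) -> np.ndarray:
    """Concatenate the equilibrated portions of all replicas.

    Frames with time >= the replica's burn-in are retained, replica order
    preserved ("single merged trajectory" convention).  Returns an array of
    shape (n_kept, n_atoms, 3).
    """
    kept = []
    for replica, cut in zip(ensemble.replicas, ensemble.burn_in):
        mask = replica.times >= cut
        if mask.any():
            kept.append(replica.coords[mask])
    if not kept:
        raise EmptyEnsembleError("burn-in discarded every frame of every replica")
    return np.concatenate(kept, axis=0)


@dataclass
class RunConfig:
    """Knobs shared across analyses (units: K, Angstrom, degrees)."""

    temperature_sim: float = 300.0
    temperature_exp: float = 298.15
    pocket_cutoff: float = 7.0
    gb_model: str = "GB2"
    fel_bins: int = 60
    hb_distance_max: float = 3.5
    hb_angle_min: float = 120.0
    sasa_probe: float = 1.4
    sasa_points: int = 240
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("temperature_sim", "temperature_exp", "pocket_cutoff",
                     "hb_distance_max", "sasa_probe"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.fel_bins < 10:
            raise ConfigError("fel_bins must be >= 10")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


# -- structure I/O ------------------------------------------------------------


def _import_pdb():
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    return struc, pdbio


def read_structure(path: str | Path) -> tuple[Topology, np.ndarray]:
    """Read a single- or multi-model PDB file.

    Returns a topology *skeleton* (names, residues, segments; physical
    parameters left at defaults — supply them via a JSON sidecar) and the
    coordinate frames, shape (n_models, n_atoms, 3), in Angstrom.  Atoms in
    HETATM records or chain "L" become the ligand segment.
    """
    struc, pdbio = _import_pdb()
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises several exception types
        msg = str(exc)
        if "atom" in msg.lower() and ("model" in msg.lower() or "count" in msg.lower()):
            raise StructureError(f"{path}: inconsistent atom counts across models: {msg}") from exc
        raise ParseError(f"{path}: {msg}") from exc

    n_models = stack.stack_depth()
    arr = stack[0]
    atoms: list[Atom] = []
    res_map: dict[tuple[str, int], int] = {}
    counters = {"receptor": 0, "ligand": 0}
    for i in range(arr.array_length()):
        hetero = bool(arr.hetero[i])
        chain = str(arr.chain_id[i])
        segment = "ligand" if (hetero or chain == "L") else "receptor"
        key = (segment, int(arr.res_id[i]))
        if key not in res_map:
            res_map[key] = counters[segment]
            counters[segment] += 1
        name = str(arr.atom_name[i])
        region = "ligand" if segment == "ligand" else (
            "backbone" if name in BACKBONE_NAMES else "sidechain"
        )
        atoms.append(
            Atom(
                index=i,
                name=name,
                element=str(arr.element[i]) or "C",
                residue_index=res_map[key],
                residue_name=str(arr.res_name[i]),
                segment=segment,
                region=region,
            )
        )
    frames = np.asarray(stack.coord, dtype=float).reshape(n_models, arr.array_length(), 3)
    return Topology(atoms), frames


def write_structure(topology: Topology, frames: np.ndarray, path: str | Path) -> None:
    """Write one or more frames as a (multi-model) PDB file."""
    struc, pdbio = _import_pdb()
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[1] != topology.n_atoms:
        raise StructureError("frame atom count does not match topology")
    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = frames[0]
    for i, atom in enumerate(topology.atoms):
        arr.chain_id[i] = "L" if atom.segment == "ligand" else "A"
        arr.res_id[i] = atom.residue_index + 1
        arr.res_name[i] = atom.residue_name[:3]
        arr.atom_name[i] = atom.name[:4]
        arr.element[i] = atom.element
        arr.hetero[i] = atom.segment == "ligand"
    stack = struc.stack([arr] * len(frames))
    stack.coord = frames
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# -- result tables ------------------------------------------------------------


def write_results(table: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    """Write a result table as CSV with a deterministic column order.

    Columns keep their DataFrame order; values are printed at 6 significant
    digits so write -> read -> write is byte-identical.
    """
    path = Path(path)
    try:
        table.to_csv(path, index=False, float_format=float_format)
    except OSError as exc:
        raise BindscapeError(f"cannot write {path}: {exc}") from exc


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise BindscapeError(f"no such file: {path}")
    return pd.read_csv(path)
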