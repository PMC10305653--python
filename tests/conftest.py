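import numpy as np
import pytest

from bindscape.io_model import Atom, Topology
from bindscape.synthetic import EnsembleSpec, make_toy_complex


@pytest.fixture(scope="session")
def toy_complex():
    """Small helical receptor + ring ligand shared across tests."""
    spec = EnsembleSpec(n_residues=20, atoms_per_residue=5, n_ligand_atoms=12, seed=3)
    topology, reference = make_toy_complex(spec)
    return spec, topology, reference


@pytest.fixture(scope="session")
def toy_complex_60():
    """Larger receptor for statistics where the rigid-body fit bias matters."""
    spec = EnsembleSpec(n_residues=60, atoms_per_residue=5, n_ligand_atoms=12, seed=3)
    topology, reference = make_toy_complex(spec)
    return spec, topology, reference


def two_atom_topology(**overrides):
    """One receptor atom + one ligand atom with controllable parameters."""
    defaults_a = dict(charge=0.0, lj_rmin_half=1.7, lj_epsilon=0.1, born_radius=1.5)
    defaults_b = dict(defaults_a)
    defaults_a.update(overrides.get("a", {}))
    defaults_b.update(overrides.get("b", {}))
    atoms = [
        Atom(index=0, name="A", element="C", residue_index=0, residue_name="RES",
             segment="receptor", region="sidechain", **defaults_a),
        Atom(index=1, name="B", element="C", residue_index=0, residue_name="LIG",
             segment="ligand", region="ligand", **defaults_b),
    ]
    return Topology(atoms)


def random_mixed_topology(n_receptor, n_ligand, seed=0):
    """Random charges/LJ/radii for oracle comparisons."""
    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n_receptor + n_ligand):
        is_lig = i >= n_receptor
        atoms.append(
            Atom(
                index=i,
                name=f"X{i}",
                element="C",
                residue_index=0 if is_lig else i % 4,
                residue_name="LIG" if is_lig else "RES",
                segment="ligand" if is_lig else "receptor",
                region="ligand" if is_lig else ("backbone" if i % 2 else "sidechain"),
                charge=float(rng.uniform(-0.8, 0.8)),
                lj_rmin_half=float(rng.uniform(1.2, 2.1)),
                lj_epsilon=float(rng.uniform(0.02, 0.3)),
                born_radius=float(rng.uniform(1.2, 2.0)),
                screen=float(rng.uniform(0.7, 0.95)),
                mass=12.0,
            )
        )
    return Topology(atoms)
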