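"""Toy receptor-ligand systems and ensembles with planted statistics.

The generator emulates, at desk scale, the statistical structure the
analyses assume about equilibrated simulation ensembles: isotropic Gaussian
Calpha fluctuations of known sigma, optional dominant collective modes
(rank-one covariance terms), signed cross-correlated residue blocks,
reduced pocket fluctuation in the "bound" variant, and per-frame rigid-body
jitter so superposition is always exercised.  Sampling is Gaussian, not
dynamical: the downstream analyses consume ensembles, not kinetics.  An
AR(1) (Ornstein-Uhlenbeck-like) time-correlation option exists but is off
by default.

All outputs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import pdist

from .io_model import Atom, Topology, Replica, TrajectoryEnsemble, SpecError

__all__ = [
    "EnsembleSpec",
    "make_toy_complex",
    "simulate_ensemble",
    "script_hbond_frames",
    "internal_mode_direction",
]

# Fixed physical palettes (element -> value); constants for reproducibility.
_LJ_RMIN_HALF = {"C": 1.908, "N": 1.824, "O": 1.6612, "H": 0.6, "S": 2.0}
_LJ_EPS = {"C": 0.1094, "N": 0.17, "O": 0.21, "H": 0.0157, "S": 0.25}
_BORN_RADIUS = {"C": 1.7, "N": 1.55, "O": 1.5, "H": 1.3, "S": 1.8}
_SCREEN = {"C": 0.72, "N": 0.79, "O": 0.85, "H": 0.85, "S": 0.96}
_MASS = {"C": 12.01, "N": 14.01, "O": 16.00, "H": 1.008, "S": 32.06}
# Backbone palette sums to zero per residue so toy receptors stay
# near-neutral, as real proteins are.
_BACKBONE_CHARGE = {"N": -0.40, "CA": 0.37, "C": 0.60, "O": -0.57}
_RESIDUE_CYCLE = ("ALA", "SER", "LEU", "THR")


@dataclass
class EnsembleSpec:
    """Study conditions for one synthetic system.

    ``planted_modes`` are (unit direction over the 3N Calpha coordinates,
    amplitude in Angstrom) pairs adding rank-one covariance amplitude^2 u u^T.
    ``correlated_blocks`` are (residue range A, residue range B, sign, strength)
    tuples planting DCCM entries of sign*strength between the two ranges.
    """

    n_residues: int = 40
    atoms_per_residue: int = 5
    n_ligand_atoms: int = 12
    n_replicas: int = 3
    frames_per_replica: int = 200
    base_sigma: float = 0.5
    planted_modes: list = field(default_factory=list)
    correlated_blocks: list = field(default_factory=list)
    pocket_damping: float = 1.0
    pocket_cutoff: float = 7.0
    jitter_rot: float = 0.2
    jitter_trans: float = 2.0
    frame_dt: float = 1.0
    ou_tau: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_residues < 3 or self.atoms_per_residue < 4:
            raise SpecError("need >=3 residues with >=4 atoms each (N, CA, C, O)")
        if self.n_ligand_atoms < 4:
            raise SpecError("need >=4 ligand atoms")
        if not (0.0 < self.pocket_damping <= 1.0):
            raise SpecError("pocket_damping must lie in (0, 1]")
        for k, (_, amp) in enumerate(self.planted_modes):
            if amp < 0:
                raise SpecError(f"planted mode {k}: negative amplitude")
        for k, (_, _, sign, strength) in enumerate(self.correlated_blocks):
            if sign not in (-1, 1):
                raise SpecError(f"correlated block {k}: sign must be +1 or -1")
            if not (0.0 <= strength <= 1.0):
                raise SpecError(f"correlated block {k}: strength outside [0, 1]")


def _helix_ca(n: int) -> np.ndarray:
    radius, rise, twist = 2.3, 1.5, math.radians(100.0)
    i = np.arange(n)
    return np.column_stack(
        [radius * np.cos(i * twist), radius * np.sin(i * twist), rise * i]
    )


def make_toy_complex(spec: EnsembleSpec) -> tuple[Topology, np.ndarray]:
    """Build a helical receptor with sidechain beads and a ring ligand.

    The receptor backbone carries N, CA, C, O per residue plus
    (atoms_per_residue - 4) sidechain beads extending radially.  The ligand
    is a ring of heavy atoms (C/N/O cycle) with one polar hydrogen on its
    first nitrogen, placed against the helix face so that several residues
    fall within the pocket cutoff of its mass center.
    """
    spec.validate()
    n_side = spec.atoms_per_residue - 4
    ca = _helix_ca(spec.n_residues)

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    idx = 0

    def add(name, element, res_idx, res_name, segment, region, charge, pos, hb_role="none"):
        nonlocal idx
        atoms.append(
            Atom(
                index=idx,
                name=name,
                element=element,
                residue_index=res_idx,
                residue_name=res_name,
                segment=segment,
                charge=charge,
                lj_rmin_half=_LJ_RMIN_HALF[element],
                lj_epsilon=_LJ_EPS[element],
                born_radius=_BORN_RADIUS[element],
                screen=_SCREEN[element],
                mass=_MASS[element],
                region=region,
                hb_role=hb_role,
            )
        )
        coords.append(np.asarray(pos, dtype=float))
        idx += 1

    for r in range(spec.n_residues):
        res_name = _RESIDUE_CYCLE[r % len(_RESIDUE_CYCLE)]
        c = ca[r]
        axis_dir = np.array([c[0], c[1], 0.0])
        axis_dir /= np.linalg.norm(axis_dir)
        along = np.array([0.0, 0.0, 1.0])
        add("N", "N", r, res_name, "receptor", "backbone",
            _BACKBONE_CHARGE["N"], c - 1.45 * along + 0.4 * axis_dir)
        add("CA", "C", r, res_name, "receptor", "backbone",
            _BACKBONE_CHARGE["CA"], c)
        add("C", "C", r, res_name, "receptor", "backbone",
            _BACKBONE_CHARGE["C"], c + 1.52 * along - 0.3 * axis_dir)
        add("O", "O", r, res_name, "receptor", "backbone",
            _BACKBONE_CHARGE["O"], c + 1.75 * along + 0.9 * axis_dir,
            hb_role="acceptor")
        # Sidechain beads march radially outward; a hydroxyl pair (donor
        # oxygen + polar hydrogen) terminates SER/THR-like residues when
        # at least two beads are available.
        hydroxyl = res_name in ("SER", "THR") and n_side >= 2
        for k in range(n_side):
            pos = c + (1.5 * (k + 1)) * axis_dir
            if hydroxyl and k == n_side - 2:
                add(f"OG{k}", "O", r, res_name, "receptor", "sidechain", -0.55, pos,
                    hb_role="donor_heavy")
                donor_pos = idx - 1
            elif hydroxyl and k == n_side - 1:
                add(f"HG{k}", "H", r, res_name, "receptor", "sidechain", 0.40,
                    coords[donor_pos] + 0.96 * axis_dir, hb_role="polar_hydrogen")
                atoms[donor_pos].bonded_hydrogens = (idx - 1,)
            else:
                charge = 0.05 if (r + k) % 2 == 0 else -0.05
                add(f"CB{k}", "C", r, res_name, "receptor", "sidechain", charge, pos)

    # Ligand ring against the helix face near the middle residues.
    mid = spec.n_residues // 2
    c_mid = ca[mid]
    out_dir = np.array([c_mid[0], c_mid[1], 0.0])
    out_dir /= np.linalg.norm(out_dir)
    n_heavy = spec.n_ligand_atoms - 1
    ring_radius = max(1.25, 1.45 * n_heavy / (2 * math.pi))
    # Stand-off tuned so Gaussian fluctuations keep cross pairs outside the
    # steep LJ repulsive wall (real ensembles never sample hard overlaps).
    center = c_mid + (1.5 * n_side + 2.8 + ring_radius * 0.3) * out_dir
    # Ring plane contains the helix axis direction so the ring hugs the face.
    e1 = np.array([0.0, 0.0, 1.0])
    e2 = np.cross(out_dir, e1)
    elements = ["C", "N", "C", "O"]
    charges = {"C": 0.17, "N": -0.40, "O": -0.40}
    first_nitrogen = None
    for k in range(n_heavy):
        ang = 2 * math.pi * k / n_heavy
        pos = center + ring_radius * (math.cos(ang) * e1 + math.sin(ang) * e2)
        el = elements[k % len(elements)]
        role = "acceptor" if el == "O" else ("donor_heavy" if el == "N" else "none")
        add(f"L{k}", el, 0, "LIG", "ligand", "ligand", charges[el], pos, hb_role=role)
        if el == "N" and first_nitrogen is None:
            first_nitrogen = idx - 1
    if first_nitrogen is None:
        raise SpecError("ligand has no nitrogen to carry the polar hydrogen")
    h_dir = coords[first_nitrogen] - center
    h_dir /= np.linalg.norm(h_dir)
    add("LH", "H", 0, "LIG", "ligand", "ligand", 0.35,
        coords[first_nitrogen] + 1.01 * h_dir, hb_role="polar_hydrogen")
    atoms[first_nitrogen].bonded_hydrogens = (idx - 1,)

    reference = np.array(coords)
    if pdist(reference).min() < 0.8:
        raise SpecError("generated geometry contains an interatomic clash (< 0.8 A)")
    return Topology(atoms), reference


def internal_mode_direction(
    reference_ca: np.ndarray, direction: np.ndarray
) -> np.ndarray:
    """Project a 3N direction onto the internal-motion subspace and normalize.

    Removes the six rigid-body components (three translations, three
    rotation generators about the Calpha centroid).  Superposition removes
    exactly these from any ensemble, so a planted collective mode should
    live in their orthogonal complement to be recoverable at full
    amplitude.
    """
    x = np.asarray(reference_ca, dtype=float)
    n = len(x)
    centered = x - x.mean(axis=0)
    basis = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        basis.append(t.ravel())
    for axis in np.eye(3):
        basis.append(np.cross(centered, axis).ravel())
    q, _ = np.linalg.qr(np.column_stack(basis))
    u = np.asarray(direction, dtype=float).ravel().copy()
    u -= q @ (q.T @ u)
    norm = np.linalg.norm(u)
    if norm < 1e-12:
        raise SpecError("direction lies entirely in the rigid-body subspace")
    return u / norm


def pocket_residues(topology: Topology, reference: np.ndarray, cutoff: float) -> np.ndarray:
    """Receptor residues with a heavy atom within cutoff of the ligand mass center."""
    lig = topology.ligand_atoms
    w = topology.masses[lig]
    com = np.average(reference[lig], axis=0, weights=w)
    heavy = np.intersect1d(topology.receptor_atoms, topology.heavy_atoms)
    near = heavy[np.linalg.norm(reference[heavy] - com, axis=1) <= cutoff]
    return np.unique(topology.residue_indices[near])


def _ar1_filter(latent: np.ndarray, phi: float) -> np.ndarray:
    """Stationary AR(1) filtering along axis 0, preserving marginal variance."""
    out = np.empty_like(latent)
    out[0] = latent[0]
    scale = math.sqrt(1.0 - phi * phi)
    for t in range(1, len(latent)):
        out[t] = phi * out[t - 1] + scale * latent[t]
    return out


def simulate_ensemble(
    topology: Topology,
    reference: np.ndarray,
    spec: EnsembleSpec,
    bound: bool = True,
) -> TrajectoryEnsemble:
    """Draw Gaussian ensembles with the planted Calpha covariance.

    Each Calpha displacement is an isotropic N(0, sigma_i^2 I) draw, with
    sigma_i = base_sigma, damped by ``pocket_damping`` for pocket residues
    when ``bound``.  Correlated blocks replace a fraction ``strength`` of
    the variance by a latent 3-vector shared (with the requested sign)
    across both residue ranges; planted modes add amplitude^2 u u^T.
    Non-Calpha atoms ride along with their residue's Calpha plus small
    independent jitter.  A random rigid-body rotation/translation is
    applied per frame.
    """
    spec.validate()
    if reference.shape != (topology.n_atoms, 3):
        raise SpecError("reference does not match topology atom count")
    rng = np.random.default_rng(spec.seed if bound else spec.seed + 1_000_003)

    n_res = len(topology.ca_atoms)
    sigma = np.full(n_res, spec.base_sigma)
    if bound and spec.pocket_damping < 1.0:
        pocket = pocket_residues(topology, reference, spec.pocket_cutoff)
        sigma[pocket] = spec.base_sigma * spec.pocket_damping

    # Validate block structure: ranges must not overlap across blocks.
    claimed: set[int] = set()
    blocks = []
    for k, (range_a, range_b, sign, strength) in enumerate(spec.correlated_blocks):
        ids_a = np.arange(range_a[0], range_a[1])
        ids_b = np.arange(range_b[0], range_b[1])
        members = set(ids_a) | set(ids_b)
        if members & claimed:
            raise SpecError(
                f"correlated block {k} overlaps another block; the requested "
                "covariance would not be positive definite"
            )
        claimed |= members
        blocks.append((ids_a, ids_b, sign, strength))

    modes = []
    for direction, amplitude in spec.planted_modes:
        u = np.asarray(direction, dtype=float).reshape(n_res, 3)
        norm = np.linalg.norm(u)
        if norm == 0:
            raise SpecError("planted mode direction has zero norm")
        modes.append((u / norm, float(amplitude)))

    phi = math.exp(-spec.frame_dt / spec.ou_tau) if spec.ou_tau > 0 else 0.0

    non_ca = np.setdiff1d(np.arange(topology.n_atoms), topology.ca_atoms)
    res_of_atom = topology.residue_indices
    lig_mask = np.zeros(topology.n_atoms, dtype=bool)
    lig_mask[topology.ligand_atoms] = True

    replicas = []
    for _ in range(spec.n_replicas):
        nf = spec.frames_per_replica
        eps = rng.standard_normal((nf, n_res, 3))
        shared = rng.standard_normal((nf, len(blocks), 3))
        mode_z = rng.standard_normal((nf, len(modes)))
        local = rng.standard_normal((nf, topology.n_atoms, 3))
        rotvecs = rng.standard_normal((nf, 3)) * spec.jitter_rot
        trans = rng.standard_normal((nf, 3)) * spec.jitter_trans
        if phi > 0:
            eps = _ar1_filter(eps, phi)
            shared = _ar1_filter(shared, phi)
            mode_z = _ar1_filter(mode_z, phi)

        disp = eps * sigma[None, :, None]
        for b, (ids_a, ids_b, sign, strength) in enumerate(blocks):
            mix = math.sqrt(strength)
            keep = math.sqrt(1.0 - strength)
            for ids, s in ((ids_a, 1.0), (ids_b, float(sign))):
                disp[:, ids, :] = (
                    keep * eps[:, ids, :] + s * mix * shared[:, b, None, :]
                ) * sigma[None, ids, None]
        for m, (u, amplitude) in enumerate(modes):
            disp += amplitude * mode_z[:, m, None, None] * u[None, :, :]

        frames = np.repeat(reference[None], nf, axis=0)
        frames[:, topology.ca_atoms, :] += disp
        # Non-Calpha receptor atoms follow their residue's Calpha.
        follow = non_ca[~lig_mask[non_ca]]
        frames[:, follow, :] += disp[:, res_of_atom[follow], :]
        frames[:, follow, :] += 0.2 * spec.base_sigma * local[:, follow, :]
        frames[:, topology.ligand_atoms, :] += (
            0.15 * spec.base_sigma * local[:, topology.ligand_atoms, :]
        )

        com = frames.mean(axis=1, keepdims=True)
        rots = Rotation.from_rotvec(rotvecs).as_matrix()
        frames = np.einsum("fij,faj->fai", rots, frames - com) + com + trans[:, None, :]

        times = spec.frame_dt * np.arange(1, nf + 1)
        replicas.append(Replica(coords=frames, times=times))

    # Frames are stationary by construction: keep everything.
    return TrajectoryEnsemble(replicas=replicas, burn_in=[float(r.times[0]) for r in replicas])


def script_hbond_frames(
    topology: Topology,
    reference: np.ndarray,
    schedule: list[tuple[tuple[int, int], int, int, float, float]],
    n_frames: int | None = None,
) -> TrajectoryEnsemble:
    """Build frames whose D-H...A geometry is exactly scripted.

    ``schedule`` entries are ((start, stop), donor_index, acceptor_index,
    distance, angle): within the half-open frame range the acceptor-donor
    distance and acceptor...H-donor angle match the request to machine
    precision; in all other frames the acceptor is parked 6 A from the
    hydrogen so at least the distance criterion fails.
    """
    entries = []
    max_stop = 0
    for (start, stop), donor, acceptor, distance, angle in schedule:
        datom = topology.atoms[donor]
        aatom = topology.atoms[acceptor]
        if datom.hb_role != "donor_heavy" or not datom.bonded_hydrogens:
            raise SpecError(f"atom {donor} is not a donor with a bonded hydrogen")
        if aatom.hb_role != "acceptor":
            raise SpecError(f"atom {acceptor} is not an acceptor")
        h = datom.bonded_hydrogens[0]
        bond = float(np.linalg.norm(reference[donor] - reference[h]))
        theta = math.radians(angle)
        if distance <= bond:
            raise SpecError(
                f"requested D...A distance {distance} A not beyond the D-H bond ({bond:.2f} A)"
            )
        if distance < bond * math.sin(theta):
            raise SpecError("requested distance/angle pair is geometrically infeasible")
        entries.append(((start, stop), donor, h, acceptor, distance, theta, bond))
        max_stop = max(max_stop, stop)
    if n_frames is None:
        n_frames = max_stop
    if n_frames <= 0:
        raise SpecError("no frames requested")

    frames = np.repeat(reference[None], n_frames, axis=0)
    for (start, stop), donor, h, acceptor, distance, theta, bond in entries:
        d_pos, h_pos = reference[donor], reference[h]
        u = d_pos - h_pos
        u /= np.linalg.norm(u)
        # Any unit vector perpendicular to u.
        probe = np.array([1.0, 0.0, 0.0])
        if abs(u @ probe) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        w = np.cross(u, probe)
        w /= np.linalg.norm(w)
        ha = bond * math.cos(theta) + math.sqrt(
            max(distance**2 - (bond * math.sin(theta)) ** 2, 0.0)
        )
        direction = math.cos(theta) * u + math.sin(theta) * w
        on_pos = h_pos + ha * direction
        off_pos = h_pos + 6.0 * direction
        frames[:, acceptor, :] = off_pos
        frames[start:stop, acceptor, :] = on_pos

    times = 0.1 * np.arange(1, n_frames + 1)
    return TrajectoryEnsemble(
        replicas=[Replica(coords=frames, times=times)], burn_in=[float(times[0])]
    )
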