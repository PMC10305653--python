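"""End-point binding energetics: MM terms, GB solvation, SASA, SIE, MM-GBSA.

The single-trajectory end-point protocol is used throughout: complex,
receptor and ligand energies are evaluated on the same frames, so internal
energies cancel and the molecular-mechanics part reduces to
receptor-ligand cross terms, while the solvation terms are
complex - receptor - ligand differences per frame.

SIE composes  dG = alpha * (Ec + dG_R + EvdW + gamma * dMSA) + C  with the
calibrated global parameters (alpha=0.1048, rho=1.1, Din=2.25,
gamma=0.0129, C=-2.89).  When components are taken from a trajectory,
dG_R is computed with a generalized-Born surrogate at interior dielectric
Din on rho-scaled radii, and dMSA uses solvent-accessible surface area as
a surrogate for the molecular surface; exact composition from externally
supplied components is always available.

MM-GBSA composes  dG = dEele + dEvdW + dGgb + dGsurf - TdS  with the
entropy term supplied externally, under four GB parameterizations:
GB1 (HCT), GB2 (OBC-I), GB5 (OBC-II) and GB66 (numerical R6 integration).
Derived partitions follow the conventions  dGpol = dEele + dGgb,
dGhydro = dEvdW + dGsurf,  dH = dGpol + dGhydro.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import (
    COULOMB_CONSTANT,
    GAS_CONSTANT,
    GB_RADIUS_OFFSET,
    EPS_IN_DEFAULT,
    EPS_OUT_DEFAULT,
    TEMPERATURE_EXP_DEFAULT,
)
from .io_model import Topology, ConfigError, EmptyEnsembleError, SelectionError, SpecError

__all__ = [
    "GBModelSpec",
    "GB_MODELS",
    "SIEParameters",
    "SIEComponents",
    "GBSAComponents",
    "ExperimentalAffinity",
    "coulomb_pair_energy",
    "lj_pair_energy",
    "effective_born_radii",
    "gb_polar_energy",
    "gb_binding_polar",
    "sasa",
    "sie_score",
    "sie_from_trajectory",
    "gbsa_binding",
    "residue_decomposition",
    "delta_g_from_ki",
    "experimental_affinity",
    "compare_systems",
    "subsample_indices",
]


# -- model specifications -----------------------------------------------------


@dataclass(frozen=True)
class GBModelSpec:
    """One generalized-Born parameterization plus its nonpolar surface term.

    ``surf_gamma`` (kcal/mol/A^2) and ``surf_beta`` (kcal/mol) define
    dGsurf = gamma * dSASA + beta; ``radii_backend`` selects how effective
    Born radii are computed; ``obc_params`` are the (alpha, beta, gamma) of
    the tanh rescaling where applicable.
    """

    label: str
    surf_gamma: float
    surf_beta: float
    radii_set: str
    radii_backend: str
    obc_params: tuple[float, float, float] | None = None
    eps_in: float = EPS_IN_DEFAULT
    eps_out: float = EPS_OUT_DEFAULT

    def __post_init__(self) -> None:
        if self.surf_gamma <= 0:
            raise ConfigError("surf_gamma must be positive")
        if not self.eps_out > self.eps_in >= 1:
            raise ConfigError("need eps_out > eps_in >= 1")


GB_MODELS: dict[str, GBModelSpec] = {
    "GB1": GBModelSpec("GB1", 0.0072, 0.0, "mbondi", "HCT"),
    "GB2": GBModelSpec("GB2", 0.005, 0.0, "mbondi2", "OBC_I", (0.8, 0.0, 2.909125)),
    "GB5": GBModelSpec("GB5", 0.005, 0.0, "mbondi2", "OBC_II", (1.0, 0.8, 4.85)),
    "GB66": GBModelSpec("GB66", 0.005, 0.0, "bondi", "numerical_R6"),
}


def _resolve_model(gb_model: str | GBModelSpec) -> GBModelSpec:
    if isinstance(gb_model, GBModelSpec):
        return gb_model
    try:
        return GB_MODELS[gb_model]
    except KeyError:
        raise ConfigError(
            f"unknown GB model {gb_model!r}; known: {sorted(GB_MODELS)}"
        ) from None


@dataclass(frozen=True)
class SIEParameters:
    """Calibrated global SIE parameters."""

    alpha: float = 0.1048
    rho: float = 1.1
    d_in: float = 2.25
    gamma_msa: float = 0.0129
    constant: float = -2.89


@dataclass
class SIEComponents:
    """Additive SIE terms, kcal/mol (averages, with optional snapshot series)."""

    e_coulomb: float
    e_vdw: float
    g_reaction: float
    gamma_msa_term: float
    per_snapshot: pd.DataFrame | None = None
    stderr: dict[str, float] = field(default_factory=dict)


@dataclass
class GBSAComponents:
    """MM-GBSA terms and the derived partitions, kcal/mol.

    The derived fields are properties so they satisfy their defining sums
    identically: g_pol = d_ele + d_gb, g_hydro = d_vdw + d_surf,
    enthalpy = g_pol + g_hydro, g_bind = enthalpy + minus_t_ds.
    """

    d_ele: float
    d_vdw: float
    d_gb: float
    d_surf: float
    minus_t_ds: float = 0.0
    gb_model: str = "GB2"
    per_snapshot: pd.DataFrame | None = None
    stderr: dict[str, float] = field(default_factory=dict)

    @property
    def g_pol(self) -> float:
        return self.d_ele + self.d_gb

    @property
    def g_hydro(self) -> float:
        return self.d_vdw + self.d_surf

    @property
    def enthalpy(self) -> float:
        return self.g_pol + self.g_hydro

    @property
    def g_bind(self) -> float:
        return self.enthalpy + self.minus_t_ds

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "dEele": self.d_ele,
                "dEvdW": self.d_vdw,
                "dGgb": self.d_gb,
                "dGsurf": self.d_surf,
                "dGpol": self.g_pol,
                "dGhydro": self.g_hydro,
                "dH": self.enthalpy,
                "-TdS": self.minus_t_ds,
                "dGbind": self.g_bind,
            }
        )


@dataclass
class ExperimentalAffinity:
    """Inhibition constant converted to a binding free energy."""

    ki: float
    temperature: float
    delta_g_exp: float


# -- pairwise molecular-mechanics terms ---------------------------------------


def _cross_distances(frame: np.ndarray, group_a: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    diff = frame[group_a][:, None, :] - frame[group_b][None, :, :]
    r = np.sqrt(np.sum(diff**2, axis=2))
    if (r < 1e-6).any():
        raise SpecError("overlapping atoms in pairwise energy evaluation")
    return r


def _check_groups(group_a: np.ndarray, group_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if len(a) == 0 or len(b) == 0:
        raise SelectionError("empty atom group")
    if np.intersect1d(a, b).size:
        raise SelectionError("pairwise groups must be disjoint")
    return a, b


def coulomb_pair_energy(
    topology: Topology,
    frame: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    dielectric: float = 1.0,
) -> float:
    """Cross-group Coulomb energy, k q_i q_j / (eps r_ij), kcal/mol."""
    a, b = _check_groups(group_a, group_b)
    r = _cross_distances(frame, a, b)
    qq = np.outer(topology.charges[a], topology.charges[b])
    return float(COULOMB_CONSTANT / dielectric * np.sum(qq / r))


def lj_pair_energy(
    topology: Topology,
    frame: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
) -> float:
    """Cross-group 12-6 Lennard-Jones energy with Lorentz-Berthelot combination."""
    a, b = _check_groups(group_a, group_b)
    r = _cross_distances(frame, a, b)
    rmin = topology.lj_rmin_half[a][:, None] + topology.lj_rmin_half[b][None, :]
    eps = np.sqrt(np.outer(topology.lj_epsilon[a], topology.lj_epsilon[b]))
    ratio6 = (rmin / r) ** 6
    return float(np.sum(eps * (ratio6**2 - 2.0 * ratio6)))


def _residue_cross_energies(
    topology: Topology, frame: np.ndarray, dielectric: float = 1.0
) -> pd.DataFrame:
    """Per-receptor-atom Coulomb and LJ cross terms with the whole ligand."""
    rec, lig = topology.receptor_atoms, topology.ligand_atoms
    r = _cross_distances(frame, rec, lig)
    qq = np.outer(topology.charges[rec], topology.charges[lig])
    ele = COULOMB_CONSTANT / dielectric * np.sum(qq / r, axis=1)
    rmin = topology.lj_rmin_half[rec][:, None] + topology.lj_rmin_half[lig][None, :]
    eps = np.sqrt(np.outer(topology.lj_epsilon[rec], topology.lj_epsilon[lig]))
    ratio6 = (rmin / r) ** 6
    vdw = np.sum(eps * (ratio6**2 - 2.0 * ratio6), axis=1)
    return pd.DataFrame({"atom": rec, "ele": ele, "vdw": vdw})


# -- generalized Born ---------------------------------------------------------


def _hct_integral(
    coords: np.ndarray, rho_tilde: np.ndarray, scaled: np.ndarray
) -> np.ndarray:
    """Pairwise-descreening integral I_i (1/A) of the HCT model."""
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt(np.sum(diff**2, axis=2))
    integral = np.zeros(n)
    for i in range(n):
        rij = r[i]
        sj = scaled.copy()
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        # Neighbor fully engulfed by atom i's intrinsic sphere: no descreening.
        mask &= rho_tilde[i] < rij + sj
        if not mask.any():
            continue
        rij, sj = rij[mask], sj[mask]
        upper = rij + sj
        lower = np.maximum(rho_tilde[i], np.abs(rij - sj))
        term = 0.5 * (
            1.0 / lower
            - 1.0 / upper
            + 0.25 * (rij - sj**2 / rij) * (1.0 / upper**2 - 1.0 / lower**2)
            + 0.5 / rij * np.log(lower / upper)
        )
        # Atom i inside neighbor j's scaled sphere.
        inside = rho_tilde[i] < sj - rij
        term[inside] += 1.0 / rho_tilde[i] - 1.0 / lower[inside]
        integral[i] = np.sum(term)
    return integral


def _r6_integral(
    coords: np.ndarray, rho_tilde: np.ndarray, spacing: float = 0.45
) -> np.ndarray:
    """Numerical inverse-sixth-power integral over the solute volume.

    1/R_i^3 = 1/rho_i^3 - (3/4pi) * integral over the union-of-spheres
    volume outside atom i's own sphere of |r - r_i|^-6 dV, evaluated on a
    cubic grid.  Sized for toy systems (a few hundred atoms).
    """
    if len(coords) > 2000:
        raise ConfigError("numerical R6 backend is sized for <=2000 atoms")
    lo = (coords - rho_tilde[:, None]).min(axis=0) - spacing
    hi = (coords + rho_tilde[:, None]).max(axis=0) + spacing
    axes = [np.arange(lo[k], hi[k] + spacing, spacing) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    tree = cKDTree(coords)
    rmax = rho_tilde.max()
    candidates = tree.query_ball_point(grid, rmax, workers=-1)
    inside = np.zeros(len(grid), dtype=bool)
    for g, cand in enumerate(candidates):
        if cand and np.any(
            np.linalg.norm(grid[g] - coords[cand], axis=1) <= rho_tilde[cand]
        ):
            inside[g] = True
    pts = grid[inside]
    dv = spacing**3
    integrals = np.zeros(len(coords))
    for i in range(len(coords)):
        s2 = np.sum((pts - coords[i]) ** 2, axis=1)
        outside_self = s2 > rho_tilde[i] ** 2
        integrals[i] = dv * np.sum(1.0 / s2[outside_self] ** 3)
    return integrals


def effective_born_radii(
    topology: Topology,
    frame: np.ndarray,
    backend: str = "HCT",
    obc_params: tuple[float, float, float] | None = None,
    atom_subset: np.ndarray | None = None,
    radii: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom effective Born radii (A) in the molecular context.

    ``backend`` is HCT (pairwise descreening), OBC_I / OBC_II (HCT integral
    through the tanh rescaling) or numerical_R6 (volume quadrature).  An
    isolated atom recovers its reduced intrinsic radius; burying an atom
    increases its effective radius.  ``atom_subset`` restricts the
    molecular context (e.g. receptor-only); ``radii`` overrides intrinsic
    radii (e.g. rho-scaled for the SIE surrogate).
    """
    sel = np.arange(topology.n_atoms) if atom_subset is None else np.asarray(atom_subset)
    coords = np.asarray(frame, dtype=float)[sel]
    intrinsic = (topology.born_radii if radii is None else np.asarray(radii))[sel]
    rho_tilde = intrinsic - GB_RADIUS_OFFSET
    if (rho_tilde <= 0).any():
        bad = sel[rho_tilde <= 0]
        raise SpecError(f"intrinsic radii at or below the dielectric offset: atoms {bad}")
    if backend == "numerical_R6":
        i6 = _r6_integral(coords, rho_tilde)
        inv_r3 = 1.0 / rho_tilde**3 - 3.0 / (4.0 * math.pi) * i6
        inv_r3 = np.clip(inv_r3, 1e-12, 1.0 / rho_tilde**3)
        return 1.0 / np.cbrt(inv_r3)
    scaled = topology.screens[sel] * rho_tilde
    integral = _hct_integral(coords, rho_tilde, scaled)
    if backend == "HCT":
        inv = 1.0 / rho_tilde - integral
        if not np.all(np.isfinite(inv)):
            raise SpecError("non-finite HCT descreening integral")
        return 1.0 / np.clip(inv, 1e-12, 1.0 / rho_tilde)
    if backend in ("OBC_I", "OBC_II"):
        if obc_params is None:
            obc_params = (0.8, 0.0, 2.909125) if backend == "OBC_I" else (1.0, 0.8, 4.85)
        a, b, g = obc_params
        psi = integral * rho_tilde
        inv = 1.0 / rho_tilde - np.tanh(a * psi - b * psi**2 + g * psi**3) / intrinsic
        return 1.0 / np.clip(inv, 1e-12, 1.0 / rho_tilde)
    raise ConfigError(f"unknown Born-radius backend {backend!r}")


def _gb_pair_matrix(
    charges: np.ndarray,
    coords: np.ndarray,
    radii: np.ndarray,
    eps_in: float,
    eps_out: float,
) -> np.ndarray:
    """Full GB energy matrix E_ij (self terms on the diagonal); sum = total."""
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = np.sum(diff**2, axis=2)
    rr = np.outer(radii, radii)
    f = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    pref = -0.5 * COULOMB_CONSTANT * (1.0 / eps_in - 1.0 / eps_out)
    return pref * np.outer(charges, charges) / f


def gb_polar_energy(
    topology: Topology,
    frame: np.ndarray,
    radii: np.ndarray,
    eps_in: float = EPS_IN_DEFAULT,
    eps_out: float = EPS_OUT_DEFAULT,
    group_scope: np.ndarray | None = None,
) -> float:
    """Total GB polar solvation energy of a scope given its effective radii.

    For a single ion this reduces to the Born formula
    -(k/2)(1/eps_in - 1/eps_out) q^2 / R.
    """
    sel = np.arange(topology.n_atoms) if group_scope is None else np.asarray(group_scope)
    radii = np.asarray(radii, dtype=float)
    if radii.shape[0] == topology.n_atoms:
        radii = radii[sel]
    if (radii <= 0).any():
        raise SpecError("effective radii must be positive")
    e = _gb_pair_matrix(topology.charges[sel], np.asarray(frame, dtype=float)[sel], radii, eps_in, eps_out)
    return float(e.sum())


def gb_binding_polar(
    topology: Topology,
    frame: np.ndarray,
    backend: str = "OBC_I",
    obc_params: tuple[float, float, float] | None = None,
    eps_in: float = EPS_IN_DEFAULT,
    eps_out: float = EPS_OUT_DEFAULT,
    radii: np.ndarray | None = None,
    per_atom: bool = False,
):
    """dGgb of binding = G(complex) - G(receptor) - G(ligand) on one frame.

    Effective radii are recomputed for each scope (descreening differs
    between the complex and the isolated partners).  With ``per_atom``,
    also returns the per-atom attribution of the difference: each pair term
    split half to each partner, self terms to their own atom.
    """
    frame = np.asarray(frame, dtype=float)
    scopes = {
        "complex": np.arange(topology.n_atoms),
        "receptor": topology.receptor_atoms,
        "ligand": topology.ligand_atoms,
    }
    attribution = np.zeros(topology.n_atoms)
    totals = {}
    for name, sel in scopes.items():
        reff = effective_born_radii(
            topology, frame, backend=backend, obc_params=obc_params,
            atom_subset=sel, radii=radii,
        )
        e = _gb_pair_matrix(topology.charges[sel], frame[sel], reff, eps_in, eps_out)
        totals[name] = float(e.sum())
        if per_atom:
            sign = 1.0 if name == "complex" else -1.0
            attribution[sel] += sign * e.sum(axis=1)
    delta = totals["complex"] - totals["receptor"] - totals["ligand"]
    if per_atom:
        return delta, attribution
    return delta


# -- surface area -------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral quadrature points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def sasa(
    topology: Topology,
    frame: np.ndarray,
    probe: float = 1.4,
    n_points: int = 240,
    atom_subset: np.ndarray | None = None,
    radii: np.ndarray | None = None,
) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area, per atom, A^2.

    Spheres of radius r_i + probe are sampled on a golden-spiral grid; a
    point is accessible if no other expanded sphere covers it.  Intrinsic
    Born radii are used unless ``radii`` overrides them.
    """
    if n_points < 24:
        raise ConfigError("n_points must be >= 24")
    sel = np.arange(topology.n_atoms) if atom_subset is None else np.asarray(atom_subset)
    coords = np.asarray(frame, dtype=float)[sel]
    base = (topology.born_radii if radii is None else np.asarray(radii))[sel]
    expanded = base + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    out = np.zeros(topology.n_atoms)
    rmax = expanded.max()
    for k, i in enumerate(sel):
        pts = coords[k] + expanded[k] * unit
        neighbors = [j for j in tree.query_ball_point(coords[k], expanded[k] + rmax) if j != k]
        if neighbors:
            d = np.linalg.norm(pts[:, None, :] - coords[neighbors][None, :, :], axis=2)
            buried = (d < expanded[neighbors][None, :]).any(axis=1)
        else:
            buried = np.zeros(n_points, dtype=bool)
        frac = 1.0 - buried.mean()
        out[i] = 4.0 * math.pi * expanded[k] ** 2 * frac
    return out


def _sasa_binding(
    topology: Topology,
    frame: np.ndarray,
    probe: float,
    n_points: int,
    radii: np.ndarray | None = None,
    per_atom: bool = False,
):
    """dSASA of binding (complex - receptor - ligand), optionally per atom."""
    full = sasa(topology, frame, probe, n_points, radii=radii)
    rec = sasa(topology, frame, probe, n_points, atom_subset=topology.receptor_atoms, radii=radii)
    lig = sasa(topology, frame, probe, n_points, atom_subset=topology.ligand_atoms, radii=radii)
    delta_atoms = full - rec - lig
    delta = float(delta_atoms.sum())
    if per_atom:
        return delta, delta_atoms
    return delta


# -- SIE ----------------------------------------------------------------------


def sie_score(components: SIEComponents, params: SIEParameters = SIEParameters()) -> float:
    """Compose the SIE binding free energy from its components.

    dG = alpha * (Ec + dG_R + EvdW + gamma_msa_term) + C.  The surface term
    is expected already multiplied by gamma (the convention the component
    tables use).
    """
    inner = (
        components.e_coulomb
        + components.g_reaction
        + components.e_vdw
        + components.gamma_msa_term
    )
    return params.alpha * inner + params.constant


def sie_score_stderr(components: SIEComponents, params: SIEParameters = SIEParameters()) -> float:
    """Standard error of the composed score from per-snapshot scores."""
    if components.per_snapshot is None:
        raise ConfigError("no per-snapshot components available")
    snap = components.per_snapshot
    scores = params.alpha * (
        snap["Ec"] + snap["dGR"] + snap["EvdW"] + snap["gamma_dMSA"]
    ) + params.constant
    return float(scores.std(ddof=1) / math.sqrt(len(scores)))


def subsample_indices(n_frames: int, n_snapshots: int | None) -> np.ndarray:
    """Evenly spaced snapshot indices covering the trajectory."""
    if n_snapshots is None or n_snapshots >= n_frames:
        return np.arange(n_frames)
    return np.unique(np.linspace(0, n_frames - 1, n_snapshots).round().astype(int))


def sie_from_trajectory(
    topology: Topology,
    frames: np.ndarray,
    params: SIEParameters = SIEParameters(),
    n_snapshots: int | None = None,
    sasa_probe: float = 1.4,
    sasa_points: int = 240,
) -> tuple[SIEComponents, float]:
    """Assemble SIE components from an ensemble and compose the score.

    Ec uses the interior dielectric Din; dG_R uses the GB surrogate
    (HCT radii on rho-scaled LJ radii, eps_in = Din); the surface term is
    gamma * dSASA on rho-scaled LJ radii.
    """
    topology.require_binding_partners()
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if len(frames) == 0:
        raise EmptyEnsembleError("no frames supplied")
    idx = subsample_indices(len(frames), n_snapshots)
    rec, lig = topology.receptor_atoms, topology.ligand_atoms
    scaled_radii = params.rho * topology.lj_rmin_half
    rows = []
    for f in idx:
        frame = frames[f]
        ec = coulomb_pair_energy(topology, frame, rec, lig, dielectric=params.d_in)
        evdw = lj_pair_energy(topology, frame, rec, lig)
        g_r = gb_binding_polar(
            topology, frame, backend="HCT", eps_in=params.d_in,
            eps_out=EPS_OUT_DEFAULT, radii=scaled_radii,
        )
        dmsa = _sasa_binding(topology, frame, sasa_probe, sasa_points, radii=scaled_radii)
        rows.append({"Ec": ec, "EvdW": evdw, "dGR": g_r, "gamma_dMSA": params.gamma_msa * dmsa})
    snap = pd.DataFrame(rows)
    stderr = {c: float(snap[c].std(ddof=1) / math.sqrt(len(snap))) if len(snap) > 1 else 0.0 for c in snap}
    comp = SIEComponents(
        e_coulomb=float(snap["Ec"].mean()),
        e_vdw=float(snap["EvdW"].mean()),
        g_reaction=float(snap["dGR"].mean()),
        gamma_msa_term=float(snap["gamma_dMSA"].mean()),
        per_snapshot=snap,
        stderr=stderr,
    )
    return comp, sie_score(comp, params)


# -- MM-GBSA ------------------------------------------------------------------


def gbsa_binding(
    topology: Topology,
    frames: np.ndarray,
    gb_model: str | GBModelSpec = "GB2",
    minus_t_ds: float = 0.0,
    n_snapshots: int | None = None,
    sasa_probe: float = 1.4,
    sasa_points: int = 240,
) -> GBSAComponents:
    """Single-trajectory MM-GBSA components averaged over snapshots.

    dEele and dEvdW are receptor-ligand cross terms; dGgb and dGsurf are
    complex - receptor - ligand differences per frame.  ``minus_t_ds`` is
    the externally supplied entropy term (-T dS), kcal/mol.
    """
    model = _resolve_model(gb_model)
    topology.require_binding_partners()
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    idx = subsample_indices(len(frames), n_snapshots)
    rec, lig = topology.receptor_atoms, topology.ligand_atoms
    rows = []
    for f in idx:
        frame = frames[f]
        ele = coulomb_pair_energy(topology, frame, rec, lig, dielectric=model.eps_in)
        vdw = lj_pair_energy(topology, frame, rec, lig)
        ggb = gb_binding_polar(
            topology, frame, backend=model.radii_backend, obc_params=model.obc_params,
            eps_in=model.eps_in, eps_out=model.eps_out,
        )
        dsasa = _sasa_binding(topology, frame, sasa_probe, sasa_points)
        rows.append(
            {"dEele": ele, "dEvdW": vdw, "dGgb": ggb,
             "dGsurf": model.surf_gamma * dsasa + model.surf_beta}
        )
    snap = pd.DataFrame(rows)
    stderr = {c: float(snap[c].std(ddof=1) / math.sqrt(len(snap))) if len(snap) > 1 else 0.0 for c in snap}
    return GBSAComponents(
        d_ele=float(snap["dEele"].mean()),
        d_vdw=float(snap["dEvdW"].mean()),
        d_gb=float(snap["dGgb"].mean()),
        d_surf=float(snap["dGsurf"].mean()),
        minus_t_ds=minus_t_ds,
        gb_model=model.label,
        per_snapshot=snap,
        stderr=stderr,
    )


def residue_decomposition(
    topology: Topology,
    frames: np.ndarray,
    gb_model: str | GBModelSpec = "GB2",
    n_snapshots: int | None = None,
    sasa_probe: float = 1.4,
    sasa_points: int = 240,
) -> pd.DataFrame:
    """Per-residue sidechain/backbone decomposition of the binding terms.

    For every receptor residue: S*/B*/T* columns for vdW, electrostatic and
    GB terms (T = S + B by construction), a surface column, and the
    per-residue total dG = TvdW + Tele + Tgb + Tsurf.  A final LIG row
    carries the ligand-side GB and surface attribution so that column sums
    reproduce the complex totals.
    """
    model = _resolve_model(gb_model)
    topology.require_binding_partners()
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    idx = subsample_indices(len(frames), n_snapshots)
    n_atoms = topology.n_atoms
    acc_ele = np.zeros(n_atoms)
    acc_vdw = np.zeros(n_atoms)
    acc_gb = np.zeros(n_atoms)
    acc_surf = np.zeros(n_atoms)
    for f in idx:
        frame = frames[f]
        cross = _residue_cross_energies(topology, frame, dielectric=model.eps_in)
        acc_ele[cross["atom"].to_numpy()] += cross["ele"].to_numpy()
        acc_vdw[cross["atom"].to_numpy()] += cross["vdw"].to_numpy()
        _, gb_atoms = gb_binding_polar(
            topology, frame, backend=model.radii_backend, obc_params=model.obc_params,
            eps_in=model.eps_in, eps_out=model.eps_out, per_atom=True,
        )
        acc_gb += gb_atoms
        _, surf_atoms = _sasa_binding(topology, frame, sasa_probe, sasa_points, per_atom=True)
        acc_surf += model.surf_gamma * surf_atoms
    k = len(idx)
    acc_ele /= k
    acc_vdw /= k
    acc_gb /= k
    acc_surf /= k

    rows = []
    for res_idx, res_name, segment in topology.residues:
        if segment != "receptor":
            continue
        atoms = topology.atoms_of_residue(res_idx, "receptor")
        if len(atoms) == 0:
            continue
        side = np.array([topology.atoms[a].region == "sidechain" for a in atoms])
        s_atoms, b_atoms = atoms[side], atoms[~side]

        def split(acc):
            return float(acc[s_atoms].sum()), float(acc[b_atoms].sum())

        s_vdw, b_vdw = split(acc_vdw)
        s_ele, b_ele = split(acc_ele)
        s_gb, b_gb = split(acc_gb)
        s_surf, b_surf = split(acc_surf)
        total = (s_vdw + b_vdw) + (s_ele + b_ele) + (s_gb + b_gb) + (s_surf + b_surf)
        rows.append(
            {
                "residue_index": res_idx,
                "residue_name": res_name,
                "SvdW": s_vdw, "BvdW": b_vdw, "TvdW": s_vdw + b_vdw,
                "Sele": s_ele, "Bele": b_ele, "Tele": s_ele + b_ele,
                "Sgb": s_gb, "Bgb": b_gb, "Tgb": s_gb + b_gb,
                "Ssurf": s_surf, "Bsurf": b_surf, "Tsurf": s_surf + b_surf,
                "dG": total,
            }
        )
    lig = topology.ligand_atoms
    rows.append(
        {
            "residue_index": -1,
            "residue_name": "LIG",
            "SvdW": 0.0, "BvdW": 0.0, "TvdW": 0.0,
            "Sele": 0.0, "Bele": 0.0, "Tele": 0.0,
            "Sgb": float(acc_gb[lig].sum()), "Bgb": 0.0, "Tgb": float(acc_gb[lig].sum()),
            "Ssurf": float(acc_surf[lig].sum()), "Bsurf": 0.0,
            "Tsurf": float(acc_surf[lig].sum()),
            "dG": float(acc_gb[lig].sum() + acc_surf[lig].sum()),
        }
    )
    return pd.DataFrame(rows)


# -- experimental affinities and system comparison ----------------------------


def delta_g_from_ki(ki: float, temperature: float = TEMPERATURE_EXP_DEFAULT) -> float:
    """Binding free energy from an inhibition constant, kcal/mol.

    dG = -RT ln(1/Ki) = RT ln(Ki) with Ki in molar: sub-molar inhibition
    constants give negative (favourable) free energies, e.g. 1 nM at
    298.15 K gives -12.28.  Ki = 1 M gives exactly 0.
    """
    if ki <= 0:
        raise ValueError("Ki must be positive")
    return GAS_CONSTANT * temperature * math.log(ki)


def experimental_affinity(
    ki: float,
    temperature: float = TEMPERATURE_EXP_DEFAULT,
    reported_delta_g: float | None = None,
    tolerance: float = 0.2,
) -> tuple[ExperimentalAffinity, bool]:
    """Convert Ki and, when a printed dG is given, check consistency.

    Returns the affinity and a flag that is True when the reported value
    agrees with -RT ln(Ki) within ``tolerance`` kcal/mol.
    """
    aff = ExperimentalAffinity(ki=ki, temperature=temperature,
                               delta_g_exp=delta_g_from_ki(ki, temperature))
    consistent = True
    if reported_delta_g is not None:
        consistent = abs(aff.delta_g_exp - reported_delta_g) <= tolerance
    return aff, consistent


def compare_systems(
    results: dict[str, GBSAComponents], reference: str
) -> pd.DataFrame:
    """Component-wise differences of each system against a named reference.

    Rows are systems (reference excluded); columns the energy components
    and derived partitions, as (system - reference).  A negative difference
    means binding strengthened relative to the reference by that magnitude.
    """
    if len(results) < 2:
        raise ConfigError("need at least two labeled systems")
    if reference not in results:
        raise ConfigError(f"unknown reference system {reference!r}")
    labels = {r.gb_model for r in results.values()}
    if len(labels) > 1:
        raise ConfigError(f"systems mix GB models: {sorted(labels)}")
    ref = results[reference].as_series()
    rows = {}
    for name, comp in results.items():
        if name == reference:
            continue
        rows[name] = comp.as_series() - ref
    return pd.DataFrame(rows).T
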