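"""Structural statistics over ensembles.

Least-squares superposition (Kabsch), global and pocket RMSD series,
per-residue RMSF and bound-minus-apo difference profiles, radius of
gyration and probability distributions with smoothed peak detection.

Superposition is mass-unweighted on the fit selection (the common
trajectory-analysis convention); pocket membership is decided once in the
reference frame and then frozen so the RMSD series stays continuous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io_model import Topology, SelectionError, ConfigError

__all__ = [
    "FlexibilityProfile",
    "DistributionSummary",
    "kabsch_superpose",
    "superpose_frames",
    "rmsd_series",
    "select_pocket",
    "rmsf_profile",
    "delta_rmsf",
    "radius_of_gyration",
    "distribution",
]


@dataclass
class FlexibilityProfile:
    """Per-residue Calpha root-mean-square fluctuation, Angstrom."""

    residue_index: np.ndarray
    rmsf: np.ndarray
    delta_rmsf: np.ndarray | None = None


@dataclass
class DistributionSummary:
    """Normalized histogram with smoothed-peak locations."""

    bin_centers: np.ndarray
    probability: np.ndarray
    peaks: np.ndarray


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t mapping mobile onto reference.

    Minimizes the unweighted squared deviation over ``fit_selection``
    (default: all atoms).  Apply as ``x @ R.T + t``.  Returns
    (R, t, rmsd over the fit selection).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(len(mobile)) if fit_selection is None else np.asarray(fit_selection)
    if len(sel) == 0:
        raise SelectionError("empty fit selection")
    x = mobile[sel]
    y = reference[sel]
    if len(x) < 3:
        raise SelectionError("superposition needs >=3 fit atoms")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # Degenerate (collinear) selections leave the rotation underdetermined.
    if np.linalg.matrix_rank(xc, tol=1e-8) < 2:
        raise SelectionError("fit selection is degenerate (collinear atoms)")
    h = xc.T @ yc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rot = vt.T @ correction @ u.T
    trans = y.mean(axis=0) - x.mean(axis=0) @ rot.T
    fitted = x @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return rot, trans, rmsd


def superpose_frames(
    frames: np.ndarray,
    reference: np.ndarray,
    fit_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Superpose every frame onto the reference; returns transformed copies."""
    frames = np.asarray(frames, dtype=float)
    out = np.empty_like(frames)
    for f in range(len(frames)):
        rot, trans, _ = kabsch_superpose(frames[f], reference, fit_selection)
        out[f] = frames[f] @ rot.T + trans
    return out


def rmsd_series(
    frames: np.ndarray,
    reference: np.ndarray,
    fit_selection: np.ndarray,
    measure_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD after fitting on one selection, measured on another.

    Pocket RMSD uses a backbone fit with pocket-atom measurement; passing
    ``measure_selection=None`` measures on the fit selection itself.
    """
    if measure_selection is None:
        measure_selection = fit_selection
    measure_selection = np.asarray(measure_selection)
    if len(measure_selection) == 0:
        raise SelectionError("empty measure selection")
    fitted = superpose_frames(frames, reference, fit_selection)
    diff = fitted[:, measure_selection, :] - reference[None, measure_selection, :]
    return np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))


def select_pocket(
    topology: Topology,
    reference: np.ndarray,
    ligand_selection: np.ndarray | None = None,
    cutoff: float = 7.0,
) -> np.ndarray:
    """Receptor residues with >=1 heavy atom within cutoff of the ligand mass center.

    Decided in the reference frame and frozen thereafter.  An empty pocket
    is legal (returns an empty array) — the caller may warn.
    """
    lig = topology.ligand_atoms if ligand_selection is None else np.asarray(ligand_selection)
    if len(lig) == 0:
        raise SelectionError("empty ligand selection")
    com = np.average(reference[lig], axis=0, weights=topology.masses[lig])
    heavy = np.intersect1d(topology.receptor_atoms, topology.heavy_atoms)
    near = heavy[np.linalg.norm(reference[heavy] - com, axis=1) <= cutoff]
    return np.unique(topology.residue_indices[near])


def rmsf_profile(
    frames: np.ndarray,
    topology: Topology,
    fit_selection: np.ndarray | None = None,
) -> FlexibilityProfile:
    """Per-Calpha RMSF about the ensemble mean after superposition.

    Frames are first fitted to the ensemble-average structure (two passes:
    fit to the first frame, average, refit to the average) so rigid-body
    motion does not inflate the fluctuations.
    """
    frames = np.asarray(frames, dtype=float)
    if len(frames) < 2:
        raise SelectionError("RMSF needs at least two frames")
    ca = topology.ca_atoms
    if fit_selection is None:
        fit_selection = ca
    fitted = superpose_frames(frames, frames[0], fit_selection)
    mean = fitted.mean(axis=0)
    fitted = superpose_frames(fitted, mean, fit_selection)
    mean = fitted.mean(axis=0)
    disp = fitted[:, ca, :] - mean[None, ca, :]
    rmsf = np.sqrt(np.mean(np.sum(disp**2, axis=2), axis=0))
    residues = topology.residue_indices[ca]
    return FlexibilityProfile(residue_index=residues, rmsf=rmsf)


def delta_rmsf(bound: FlexibilityProfile, apo: FlexibilityProfile) -> FlexibilityProfile:
    """Bound-minus-apo RMSF difference, aligned by residue order."""
    if len(bound.rmsf) != len(apo.rmsf):
        raise SelectionError("profiles have unequal residue counts")
    return FlexibilityProfile(
        residue_index=bound.residue_index,
        rmsf=bound.rmsf,
        delta_rmsf=bound.rmsf - apo.rmsf,
    )


def radius_of_gyration(
    frame: np.ndarray, selection: np.ndarray, masses: np.ndarray
) -> float:
    """Mass-weighted RMS distance of the selection from its center of mass."""
    selection = np.asarray(selection)
    if len(selection) == 0:
        raise SelectionError("empty selection")
    w = np.asarray(masses, dtype=float)[selection]
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    x = np.asarray(frame, dtype=float)[selection]
    com = np.average(x, axis=0, weights=w)
    return float(np.sqrt(np.sum(w * np.sum((x - com) ** 2, axis=1)) / total))


def distribution(series: np.ndarray, n_bins: int = 50) -> DistributionSummary:
    """Normalized histogram with peaks of the kernel-smoothed profile.

    Peaks are local maxima of the histogram after Gaussian smoothing with
    bandwidth equal to one bin width, which stabilizes two-peak reporting
    on noisy bimodal series.
    """
    if n_bins < 2:
        raise ConfigError("n_bins must be >= 2")
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise SelectionError("empty series")
    counts, edges = np.histogram(series, bins=n_bins)
    prob = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = gaussian_filter1d(prob, sigma=1.0, mode="nearest")
    is_peak = np.zeros(n_bins, dtype=bool)
    for i in range(n_bins):
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i < n_bins - 1 else -np.inf
        is_peak[i] = smooth[i] > 0 and smooth[i] >= left and smooth[i] > right
    return DistributionSummary(
        bin_centers=centers, probability=prob, peaks=centers[is_peak]
    )
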