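"""Correlated motions and conformational free-energy analysis.

Covariance of the superposed Calpha coordinates, its eigendecomposition
(mass-unweighted PCA), the normalized displacement cross-correlation map
(DCCM, +1 correlated / -1 anti-correlated), a free-energy landscape over
the first two principal projections, F = -kB T ln(P / Pmax), and
persistence-based valley (conformational substate) detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import GAS_CONSTANT
from .io_model import Topology, SelectionError, ConfigError
from .metrics import superpose_frames

__all__ = [
    "DCCMatrix",
    "PCAResult",
    "FELGrid",
    "Valley",
    "covariance_matrix",
    "pca",
    "dccm",
    "fel",
    "find_valleys",
    "mode_displacements",
]


@dataclass
class DCCMatrix:
    """Normalized cross-correlation of Calpha displacement vectors."""

    matrix: np.ndarray
    zero_variance: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class PCAResult:
    """Eigenmodes of the Calpha coordinate covariance.

    ``eigenvalues`` in A^2 descending, ``eigenvectors`` columns of length 3N
    (orthonormal), ``projections`` (n_frames, n_modes) of the centered
    coordinates on each mode, ``mean`` the superposed mean structure over
    the Calpha selection.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    projections: np.ndarray
    mean: np.ndarray


@dataclass
class Valley:
    """One basin of the free-energy landscape."""

    bin_index: tuple[int, int]
    f_min: float
    persistence: float
    member_frames: np.ndarray
    representative_frame: int


@dataclass
class FELGrid:
    """Binned free-energy surface over (PC1, PC2), kcal/mol, occupied min at 0."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ma.MaskedArray
    counts: np.ndarray
    frame_bins: np.ndarray
    projections: np.ndarray
    temperature: float
    valleys: list[Valley] = field(default_factory=list)


def _superposed_ca(
    frames: np.ndarray, ca_selection: np.ndarray, superpose: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Fit all frames on the Calpha selection to their running mean."""
    frames = np.asarray(frames, dtype=float)
    if len(frames) < 2:
        raise SelectionError("need at least two frames")
    if superpose:
        fitted = superpose_frames(frames, frames[0], ca_selection)
        mean = fitted.mean(axis=0)
        fitted = superpose_frames(fitted, mean, ca_selection)
    else:
        fitted = frames
    ca = fitted[:, ca_selection, :]
    return ca, ca.mean(axis=0)


def covariance_matrix(frames: np.ndarray, ca_selection: np.ndarray) -> np.ndarray:
    """3N x 3N covariance of superposed Calpha coordinates about their mean."""
    ca, mean = _superposed_ca(frames, ca_selection)
    x = (ca - mean[None]).reshape(len(ca), -1)
    return x.T @ x / len(x)


def pca(frames: np.ndarray, ca_selection: np.ndarray, n_modes: int | None = None) -> PCAResult:
    """Eigendecomposition of the Calpha covariance plus frame projections."""
    ca, mean = _superposed_ca(frames, ca_selection)
    x = (ca - mean[None]).reshape(len(ca), -1)
    cov = x.T @ x / len(x)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if n_modes is not None:
        vals, vecs = vals[:n_modes], vecs[:, :n_modes]
    projections = x @ vecs
    return PCAResult(eigenvalues=vals, eigenvectors=vecs, projections=projections, mean=mean)


def pca_from_covariance(covariance: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending (eigenvalues, eigenvectors) of a symmetric covariance."""
    covariance = np.asarray(covariance, dtype=float)
    if not np.allclose(covariance, covariance.T, atol=1e-8):
        raise ConfigError("covariance matrix must be symmetric")
    vals, vecs = np.linalg.eigh(covariance)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def dccm(frames: np.ndarray, ca_selection: np.ndarray, superpose: bool = True) -> DCCMatrix:
    """C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>) over Calpha pairs.

    Zero-variance atoms get zero off-diagonal entries (flagged) and a unit
    diagonal, keeping the matrix usable downstream.  Pass
    ``superpose=False`` for frames that are already rigid-body aligned.
    """
    ca, mean = _superposed_ca(frames, ca_selection, superpose=superpose)
    disp = ca - mean[None]
    inner = np.einsum("fik,fjk->ij", disp, disp) / len(disp)
    var = np.diag(inner).copy()
    flagged = np.flatnonzero(var <= 1e-12)
    var_safe = np.where(var <= 1e-12, 1.0, var)
    matrix = inner / np.sqrt(np.outer(var_safe, var_safe))
    matrix[flagged, :] = 0.0
    matrix[:, flagged] = 0.0
    np.fill_diagonal(matrix, 1.0)
    matrix = np.clip(matrix, -1.0, 1.0)
    return DCCMatrix(matrix=matrix, zero_variance=flagged)


def fel(
    projections: np.ndarray,
    temperature: float = 300.0,
    n_bins: int = 60,
    pad_fraction: float = 0.05,
) -> FELGrid:
    """Free-energy landscape over the first two projection columns.

    F_bin = -kB T ln(P_bin / P_max); empty bins are masked; the occupied
    minimum sits at 0 by construction.
    """
    if n_bins < 10:
        raise ConfigError("n_bins must be >= 10")
    proj = np.asarray(projections, dtype=float)
    if proj.ndim != 2 or proj.shape[1] < 2:
        raise ConfigError("projections must provide at least two columns")
    pc1, pc2 = proj[:, 0], proj[:, 1]
    if np.ptp(pc1) < 1e-12 or np.ptp(pc2) < 1e-12:
        raise ConfigError("degenerate projections: no spread along a reaction coordinate")

    def padded_edges(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        pad = pad_fraction * (hi - lo)
        return np.linspace(lo - pad, hi + pad, n_bins + 1)

    x_edges, y_edges = padded_edges(pc1), padded_edges(pc2)
    counts, _, _ = np.histogram2d(pc1, pc2, bins=(x_edges, y_edges))
    ix = np.clip(np.searchsorted(x_edges, pc1, side="right") - 1, 0, n_bins - 1)
    iy = np.clip(np.searchsorted(y_edges, pc2, side="right") - 1, 0, n_bins - 1)
    frame_bins = np.column_stack([ix, iy])

    kt = GAS_CONSTANT * temperature
    with np.errstate(divide="ignore"):
        free = -kt * np.log(counts / counts.max())
    masked = np.ma.masked_array(free, mask=counts == 0)
    return FELGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        free_energy=masked,
        counts=counts.astype(int),
        frame_bins=frame_bins,
        projections=proj[:, :2],
        temperature=temperature,
    )


_NEIGHBORS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


def find_valleys(
    grid: FELGrid, depth_cut: float = 0.5, min_frames: int = 1
) -> list[Valley]:
    """Persistence-based basin detection on the landscape.

    Occupied bins are flooded in order of increasing free energy; when a
    shallower basin first touches a deeper one, its persistence is the
    merge level minus its bottom — basins with persistence below
    ``depth_cut`` are merged away, so the valley count is non-increasing in
    ``depth_cut``.  Surviving basins need ``min_frames`` member frames.
    The representative frame is the member nearest (in PC space) to the
    bottom-bin center.  Masked (empty) bins are never valleys.
    """
    free = grid.free_energy
    occ = np.argwhere(~free.mask)
    order = occ[np.argsort(free.data[tuple(occ.T)], kind="stable")]
    n_bins = free.shape
    label = -np.ones(n_bins, dtype=int)
    basin_min: list[float] = []
    basin_bottom: list[tuple[int, int]] = []
    persistence: dict[int, float] = {}
    parent: dict[int, int] = {}

    def find(b: int) -> int:
        while parent.get(b, b) != b:
            parent[b] = parent.get(parent[b], parent[b])
            b = parent[b]
        return b

    for i, j in order:
        level = free.data[i, j]
        touching = set()
        for di, dj in _NEIGHBORS:
            ni, nj = i + di, j + dj
            if 0 <= ni < n_bins[0] and 0 <= nj < n_bins[1] and label[ni, nj] >= 0:
                touching.add(find(label[ni, nj]))
        if not touching:
            b = len(basin_min)
            basin_min.append(level)
            basin_bottom.append((int(i), int(j)))
            parent[b] = b
            label[i, j] = b
            continue
        deepest = min(touching, key=lambda b: basin_min[b])
        label[i, j] = deepest
        for b in touching:
            if b == deepest:
                continue
            pers = level - basin_min[b]
            if pers < depth_cut:
                parent[b] = deepest  # merged away: too shallow to stand alone
            else:
                persistence.setdefault(b, pers)

    # Resolve labels to final roots.
    roots = sorted({find(b) for b in range(len(basin_min))}, key=lambda b: basin_min[b])
    fmax = float(free.max())
    valleys: list[Valley] = []
    for root in roots:
        members_mask = np.array(
            [find(label[ix, iy]) == root for ix, iy in grid.frame_bins]
        )
        member_frames = np.flatnonzero(members_mask)
        if len(member_frames) < min_frames:
            continue
        bi, bj = basin_bottom[root]
        center = np.array(
            [
                0.5 * (grid.x_edges[bi] + grid.x_edges[bi + 1]),
                0.5 * (grid.y_edges[bj] + grid.y_edges[bj + 1]),
            ]
        )
        dist = np.linalg.norm(grid.projections[member_frames] - center, axis=1)
        rep = int(member_frames[np.argmin(dist)])
        valleys.append(
            Valley(
                bin_index=(bi, bj),
                f_min=float(basin_min[root]),
                persistence=float(persistence.get(root, fmax - basin_min[root])),
                member_frames=member_frames,
                representative_frame=rep,
            )
        )
    valleys.sort(key=lambda v: v.f_min)
    return valleys


def mode_displacements(result: PCAResult, mode: int, scale: float = 1.0) -> np.ndarray:
    """Per-Calpha arrow vectors for one mode: eigenvector * sqrt(eigenvalue) * scale."""
    if not (0 <= mode < len(result.eigenvalues)):
        raise IndexError(f"mode {mode} out of range")
    amp = np.sqrt(max(result.eigenvalues[mode], 0.0)) * scale
    return amp * result.eigenvectors[:, mode].reshape(-1, 3)
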