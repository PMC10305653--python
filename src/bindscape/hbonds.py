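"""Geometric hydrogen-bond detection and occupancy statistics.

A candidate (donor, hydrogen, acceptor) triple counts in a frame iff the
acceptor-donor distance is below ``distance_max`` (strict) and the angle
at the hydrogen between the H->D and H->A vectors exceeds ``angle_min``
(strict, near-linear D-H...A).  Occupancy is the percentage of frames in
which a specific bond exists; distance and angle are averaged only over
those frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import Topology

__all__ = ["HBondRecord", "candidate_triples", "detect_hbonds", "occupancy_sensitivity"]


@dataclass
class HBondRecord:
    """One detected hydrogen bond over the ensemble."""

    donor: int
    hydrogen: int
    acceptor: int
    label: str
    mean_distance: float
    mean_angle: float
    occupancy: float


def candidate_triples(
    topology: Topology, scope: str = "receptor-ligand"
) -> list[tuple[int, int, int]]:
    """All (donor, bonded hydrogen, acceptor) triples within scope.

    Scope ``receptor-ligand`` keeps only cross-segment pairs (both
    directions); ``all`` keeps every donor/acceptor combination outside
    the donor's own atom.
    """
    donors = [a for a in topology.atoms if a.hb_role == "donor_heavy" and a.bonded_hydrogens]
    acceptors = [a.index for a in topology.atoms if a.hb_role == "acceptor"]
    triples = []
    for d in donors:
        for h in d.bonded_hydrogens:
            for acc in acceptors:
                if acc == d.index:
                    continue
                if scope == "receptor-ligand":
                    if topology.atoms[acc].segment == d.segment:
                        continue
                triples.append((d.index, h, acc))
    return triples


def _geometry(
    frames: np.ndarray, donor: int, hydrogen: int, acceptor: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame acceptor-donor distance and acceptor...H-donor angle (deg)."""
    d = frames[:, donor, :]
    h = frames[:, hydrogen, :]
    a = frames[:, acceptor, :]
    dist = np.linalg.norm(a - d, axis=1)
    v1 = d - h
    v2 = a - h
    cosang = np.sum(v1 * v2, axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return dist, angle


def detect_hbonds(
    topology: Topology,
    frames: np.ndarray,
    distance_max: float = 3.5,
    angle_min: float = 120.0,
    scope: str = "receptor-ligand",
) -> list[HBondRecord]:
    """Hydrogen bonds over the ensemble, sorted by descending occupancy.

    Zero-occupancy candidates are omitted.  An empty candidate set yields
    an empty list (the caller may warn).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    records = []
    for donor, hydrogen, acceptor in candidate_triples(topology, scope):
        dist, angle = _geometry(frames, donor, hydrogen, acceptor)
        present = (dist < distance_max) & (angle > angle_min)
        occ = 100.0 * present.mean()
        if occ == 0.0:
            continue
        da = topology.atoms[donor]
        aa = topology.atoms[acceptor]
        label = (
            f"{aa.residue_name}{aa.residue_index}-{aa.name}..."
            f"{da.residue_name}{da.residue_index}-{topology.atoms[hydrogen].name}-{da.name}"
        )
        records.append(
            HBondRecord(
                donor=donor,
                hydrogen=hydrogen,
                acceptor=acceptor,
                label=label,
                mean_distance=float(dist[present].mean()),
                mean_angle=float(angle[present].mean()),
                occupancy=float(occ),
            )
        )
    records.sort(key=lambda r: (-r.occupancy, r.label))
    return records


def occupancy_sensitivity(
    topology: Topology,
    frames: np.ndarray,
    distance_grid: np.ndarray,
    angle_grid: np.ndarray,
    scope: str = "receptor-ligand",
) -> pd.DataFrame:
    """Occupancy of every candidate across a criteria grid.

    Occupancy is non-decreasing as the distance cutoff relaxes or the
    angle threshold drops.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    rows = []
    for donor, hydrogen, acceptor in candidate_triples(topology, scope):
        dist, angle = _geometry(frames, donor, hydrogen, acceptor)
        for dmax in distance_grid:
            for amin in angle_grid:
                occ = 100.0 * float(np.mean((dist < dmax) & (angle > amin)))
                rows.append(
                    {
                        "donor": donor,
                        "hydrogen": hydrogen,
                        "acceptor": acceptor,
                        "distance_max": float(dmax),
                        "angle_min": float(amin),
                        "occupancy": occ,
                    }
                )
    return pd.DataFrame(rows)
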