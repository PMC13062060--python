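"""Residue contact maps, differential maps, and Shrake–Rupley SASA.

Contacts use the minimum heavy-atom distance between residue pairs; the
contact frequency of a pair is the fraction of frames in which that distance
falls below the cutoff (default 4.5 Å).  Differential maps subtract one
system's map from another's to localize regions whose packing changes, e.g.
between calcium- and sodium-bound ensembles.

SASA is computed by sphere-point sampling (Shrake–Rupley) with a 1.4 Å water
probe on a deterministic golden-section spiral — no RNG is involved, so
results are bit-reproducible at a given point count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajectory import Topology, Trajectory

__all__ = [
    "ContactMap",
    "DifferentialContactMap",
    "SASASeries",
    "contact_map",
    "differential_contact_map",
    "sasa_shrake_rupley",
    "sasa_series",
    "sasa_histogram",
    "VDW_RADII",
]

# element-keyed van der Waals radii (Å); fixed so results are reproducible
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20,
             "Ca": 2.31, "Na": 2.27}

PROBE_RADIUS = 1.4  # Å, water
N_SPHERE_POINTS = 960


@dataclass
class ContactMap:
    values: np.ndarray  # (n_res, n_res) frequency in [0, 1]
    residue_labels: list[tuple[str, int]]  # (chain_id, residue_number)
    cutoff: float
    label: str = ""


@dataclass
class DifferentialContactMap:
    values: np.ndarray  # map_B − map_A, in [-1, 1]
    residue_labels: list[tuple[str, int]]
    cutoff: float
    label_a: str = "A"
    label_b: str = "B"

    def top_changes(self, k: int = 10) -> pd.DataFrame:
        """Residue pairs with the largest |Δ frequency| (upper triangle)."""
        n = self.values.shape[0]
        iu = np.triu_indices(n, k=1)
        delta = self.values[iu]
        order = np.argsort(-np.abs(delta))[:k]
        return pd.DataFrame(
            {
                "res_i": [self.residue_labels[iu[0][o]] for o in order],
                "res_j": [self.residue_labels[iu[1][o]] for o in order],
                "delta": delta[order],
            }
        )


@dataclass
class SASASeries:
    values: np.ndarray  # per-frame SASA, Å²
    selection_name: str
    probe_radius: float = PROBE_RADIUS
    n_points: int = N_SPHERE_POINTS

    def in_nm2(self) -> np.ndarray:
        return self.values / 100.0


def _residue_atom_groups(topology: Topology, heavy_only: bool = True):
    labels = []
    groups = []
    for chain, resnum, _name, idx in topology.residues():
        if heavy_only:
            idx = [i for i in idx if topology.atoms[i].element != "H"]
        if idx:
            labels.append((chain, resnum))
            groups.append(np.array(idx, dtype=int))
    return labels, groups


def contact_map(traj: Trajectory, cutoff: float = 4.5, label: str = "") -> ContactMap:
    """Residue-residue contact frequency over all frames.

    Entry (i, j) is the fraction of frames where the minimum heavy-atom
    distance between residues i and j is below ``cutoff``; the diagonal is 1
    by convention.
    """
    labels, groups = _residue_atom_groups(traj.topology)
    n_res = len(labels)
    atom_res = np.empty(sum(len(g) for g in groups), dtype=int)
    flat_idx = np.concatenate(groups)
    start = 0
    for r, g in enumerate(groups):
        atom_res[start : start + len(g)] = r
        start += len(g)
    hits = np.zeros((n_res, n_res), dtype=int)
    for f in range(traj.n_frames):
        coords = traj.frames[f, flat_idx]
        tree = cKDTree(coords)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        frame_contact = np.zeros((n_res, n_res), dtype=bool)
        if pairs.size:
            ri = atom_res[pairs[:, 0]]
            rj = atom_res[pairs[:, 1]]
            frame_contact[ri, rj] = True
            frame_contact[rj, ri] = True
        hits += frame_contact
    values = hits / traj.n_frames
    np.fill_diagonal(values, 1.0)
    return ContactMap(values=values, residue_labels=labels, cutoff=float(cutoff), label=label)


def differential_contact_map(map_a: ContactMap, map_b: ContactMap) -> DifferentialContactMap:
    """``map_b − map_a``; positive entries are contacts gained in B."""
    if map_a.residue_labels != map_b.residue_labels:
        raise ValueError("contact maps have different residue axes")
    if map_a.cutoff != map_b.cutoff:
        raise ValueError("contact maps computed at different cutoffs")
    return DifferentialContactMap(
        values=map_b.values - map_a.values,
        residue_labels=map_a.residue_labels,
        cutoff=map_a.cutoff,
        label_a=map_a.label or "A",
        label_b=map_b.label or "B",
    )


def _golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform points on the unit sphere."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa_shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²).

    Each atom's sphere of radius r+probe is sampled at ``n_points``
    golden-spiral points; the exposed fraction times the sphere area is the
    atom's SASA.  Occlusion is tested against all atoms, so selection SASA
    is always evaluated in the context of the whole structure.
    """
    if n_points < 32:
        raise ValueError("n_points must be at least 32")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(~np.isfinite(radii)):
        raise ValueError("missing radius for some atom")
    n = coords.shape[0]
    sphere = _golden_spiral_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    areas = np.empty(n)
    max_r = expanded.max()
    for i in range(n):
        ri = expanded[i]
        pts = coords[i] + ri * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], ri + max_r) if j != i]
        if neigh:
            nb = np.array(neigh, dtype=int)
            d2 = np.sum((pts[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < expanded[nb][None, :] ** 2, axis=1)
            exposed = int((~buried).sum())
        else:
            exposed = n_points
        areas[i] = 4.0 * np.pi * ri * ri * exposed / n_points
    return areas


def atom_radii(topology: Topology, table: dict[str, float] | None = None) -> np.ndarray:
    table = table or VDW_RADII
    out = np.empty(topology.n_atoms)
    for a in topology.atoms:
        key = a.element if a.element in table else a.element.capitalize()
        if key not in table:
            raise KeyError(f"no van der Waals radius for element {a.element!r}")
        out[a.atom_index] = table[key]
    return out


def sasa_series(
    traj: Trajectory,
    selection_indices: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    name: str = "selection",
    radii_table: dict[str, float] | None = None,
) -> SASASeries:
    """Per-frame SASA of a selection, computed in the context of all atoms."""
    radii = atom_radii(traj.topology, radii_table)
    sel = np.asarray(selection_indices, dtype=int)
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        per_atom = sasa_shrake_rupley(traj.frames[f], radii, probe=probe, n_points=n_points)
        values[f] = per_atom[sel].sum()
    return SASASeries(values=values, selection_name=name, probe_radius=probe, n_points=n_points)


def sasa_histogram(series: SASASeries, bin_width: float, in_nm2: bool = False):
    """Probability-density histogram over SASA; densities integrate to 1."""
    values = series.in_nm2() if in_nm2 else series.values
    if values.size == 0:
        raise ValueError("empty SASA series")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    density, edges = np.histogram(values, bins=edges, density=True)
    return density, edges
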