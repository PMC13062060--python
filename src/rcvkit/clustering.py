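"""GROMOS (Daura-style) conformational clustering.

The greedy rule: repeatedly take the frame with the most neighbours within
the RMSD cutoff as the next cluster centroid, assign it and its neighbours to
that cluster, remove them from the pool, and continue until no frames remain.
Clusters are relabelled by descending population (id 0 = largest).  Ties in
neighbour count are broken by lowest frame index so the procedure is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .superpose import kabsch_fit, rmsd
from .trajectory import ComponentSelection, Trajectory, resolve_selection, write_pdb

__all__ = [
    "ClusterResult",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "cluster_report",
]

# per-component cutoffs (Å) calibrated on the active wild-type ensemble
DEFAULT_CUTOFFS = {
    "ntd": 2.4,
    "active_pocket": 1.4,
    "catalytic_loop": 3.0,
    "lid_rim": 1.8,
}


@dataclass
class ClusterResult:
    assignments: np.ndarray  # per-frame cluster id, 0 = largest
    centroid_frames: np.ndarray  # per-cluster frame index
    populations: np.ndarray  # per-cluster frame counts, non-increasing
    cutoff: float
    component_name: str = ""

    @property
    def n_clusters(self) -> int:
        return int(len(self.populations))


def pairwise_rmsd_matrix(
    traj: Trajectory,
    measure_sel: ComponentSelection,
    align_mode: str = "prealigned",
) -> np.ndarray:
    """Symmetric frame-frame RMSD matrix over a component.

    ``prealigned`` computes raw RMSD between frames assumed already superposed
    on the global alignment selection (the default workflow); ``pairwise_fit``
    performs a fresh Kabsch fit for every pair, matching the classic GROMOS
    tool's behaviour.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    idx = resolve_selection(traj.topology, measure_sel)
    X = traj.frames[:, idx, :]  # (n, m, 3)
    n, m, _ = X.shape
    if align_mode == "prealigned":
        flat = X.reshape(n, -1)
        sq = np.sum(flat**2, axis=1)
        gram = flat @ flat.T
        d2 = (sq[:, None] + sq[None, :] - 2.0 * gram) / m
        np.maximum(d2, 0.0, out=d2)
        mat = np.sqrt(d2)
    elif align_mode == "pairwise_fit":
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                _, _, r = kabsch_fit(X[j], X[i])
                mat[i, j] = mat[j, i] = r
    else:
        raise ValueError(f"unknown align_mode {align_mode!r}")
    np.fill_diagonal(mat, 0.0)
    return mat


def gromos_cluster(matrix: np.ndarray, cutoff: float, component_name: str = "") -> ClusterResult:
    """Cluster frames from a pairwise RMSD matrix at a fixed cutoff."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if np.any(np.isnan(matrix)):
        raise ValueError("NaN in distance matrix")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = matrix.shape[0]
    neighbor = matrix < cutoff  # includes self on the diagonal
    np.fill_diagonal(neighbor, True)
    remaining = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    centroids: list[int] = []
    pops: list[int] = []
    cid = 0
    while remaining.any():
        counts = (neighbor & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = neighbor[center] & remaining
        assignments[members] = cid
        centroids.append(center)
        pops.append(int(members.sum()))
        remaining &= ~members
        cid += 1
    # relabel by descending population; stable sort keeps extraction order on ties
    order = np.argsort(-np.asarray(pops), kind="stable")
    relabel = np.empty(len(order), dtype=int)
    relabel[order] = np.arange(len(order))
    return ClusterResult(
        assignments=relabel[assignments],
        centroid_frames=np.asarray(centroids)[order],
        populations=np.asarray(pops)[order],
        cutoff=float(cutoff),
        component_name=component_name,
    )


def cluster_report(
    result: ClusterResult,
    traj: Trajectory | None = None,
    output_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Per-cluster table of populations and fractions; optionally write centroid PDBs."""
    n_frames = int(result.populations.sum())
    if traj is not None and traj.n_frames != n_frames:
        raise ValueError("cluster result does not match trajectory frame count")
    df = pd.DataFrame(
        {
            "cluster_id": np.arange(result.n_clusters),
            "population": result.populations,
            "fraction": result.populations / n_frames,
            "centroid_frame": result.centroid_frames,
        }
    )
    if output_dir is not None and traj is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        for cid, frame in enumerate(result.centroid_frames):
            write_pdb(output_dir / f"centroid_{result.component_name or 'component'}_{cid}.pdb", traj, [int(frame)])
        df.to_csv(output_dir / f"clusters_{result.component_name or 'component'}.csv", index=False)
    return df
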