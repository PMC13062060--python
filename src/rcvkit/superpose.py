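"""Least-squares superposition and component-wise RMSD time series.

The central convention is *align on one selection, measure on another*: each
frame is rigidly superposed onto the reference using the alignment selection
(typically the dimeric core of the catalytic domain), and the RMSD is then
evaluated over the measured component **without refitting**.  This is how
deformation of a mobile element (a lid loop, a rim helix) is quantified
relative to a stationary core.

Summaries pool frames over monomers and replicas and report the median and
interquartile range; quartiles use linear interpolation (numpy's default,
"type 7") so that test values are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import ComponentSelection, Trajectory, resolve_selection

__all__ = [
    "RMSDSeries",
    "RMSDSummary",
    "kabsch_fit",
    "apply_transform",
    "rmsd",
    "rmsd_series",
    "summarize_pooled",
]


@dataclass
class RMSDSeries:
    component_name: str
    values: np.ndarray  # per-frame RMSD, Å
    align_selection: ComponentSelection | None
    measure_selection: ComponentSelection
    source: tuple[str, str] = ("r0", "A")  # (replica_id, monomer_label)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")


@dataclass
class RMSDSummary:
    median: float
    iqr: tuple[float, float]  # (q1, q3), Å
    n_samples: int
    pooled_sources: list[tuple[str, str]]


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, fitted_rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to ``reference``
    over all proper rigid transforms (Kabsch, via SVD with the determinant
    correction that excludes reflections).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"point-count mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    fitted = mobile @ R.T + t
    return R, t, rmsd(fitted, reference)


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unfitted) root-mean-square deviation between matched point sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("point-count mismatch")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    traj: Trajectory,
    reference: Trajectory,
    align_sel: ComponentSelection,
    measure_sel: ComponentSelection,
    source: tuple[str, str] | None = None,
) -> RMSDSeries:
    """Per-frame RMSD of ``measure_sel`` after superposing each frame on ``align_sel``.

    ``reference`` is a single-frame trajectory (e.g. the crystal structure).
    Both selections must resolve to equal atom counts in trajectory and
    reference topologies.
    """
    if reference.n_frames != 1:
        raise ValueError("reference must be a single-frame trajectory")
    ai = resolve_selection(traj.topology, align_sel)
    ar = resolve_selection(reference.topology, align_sel)
    mi = resolve_selection(traj.topology, measure_sel)
    mr = resolve_selection(reference.topology, measure_sel)
    if len(ai) != len(ar):
        raise ValueError(f"alignment selection resolves to {len(ai)} vs {len(ar)} atoms")
    if len(mi) != len(mr):
        raise ValueError(f"measure selection resolves to {len(mi)} vs {len(mr)} atoms")
    ref_align = reference.frames[0, ar]
    ref_measure = reference.frames[0, mr]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, t, _ = kabsch_fit(traj.frames[f, ai], ref_align)
        values[f] = rmsd(apply_transform(traj.frames[f, mi], R, t), ref_measure)
    return RMSDSeries(
        component_name=measure_sel.name,
        values=values,
        align_selection=align_sel,
        measure_selection=measure_sel,
        source=source or (traj.replica_id, "A"),
    )


def summarize_pooled(series_list: list[RMSDSeries]) -> RMSDSummary:
    """Median and quartiles over all frames pooled from all sources.

    Pooling concatenates frames from every series (e.g. two monomers from each
    of several replicas) before computing order statistics.
    """
    if not series_list:
        raise ValueError("need at least one series")
    names = {s.component_name for s in series_list}
    if len(names) > 1:
        raise ValueError(f"cannot pool different components: {sorted(names)}")
    pooled = np.concatenate([s.values for s in series_list])
    q1, med, q3 = np.percentile(pooled, [25, 50, 75])
    return RMSDSummary(
        median=float(med),
        iqr=(float(q1), float(q3)),
        n_samples=int(pooled.size),
        pooled_sources=[s.source for s in series_list],
    )
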