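"""Relative conformational variation (RCV) scoring.

A component's RMSD distribution in a variant system is affinely normalized
between two reference ensembles: the active reference's median RMSD maps to
0 and the inactive reference's to 1.  Scores are not clamped — a median at or
above 1 means the component is as deformed as, or more deformed than, the
inactive reference, and is flagged "severe".  The map is applied framewise,
so interquartile ranges of the transformed distribution are reported
alongside the median (the median itself is identical either way, since an
affine monotone map commutes with order statistics).

RCV is a conformational rating, not a quantitative predictor of enzymatic
activity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .superpose import RMSDSeries, RMSDSummary, summarize_pooled

__all__ = [
    "RCVScore",
    "rcv_normalize",
    "rcv_profile",
    "classify_mutant",
    "save_calibration",
    "load_calibration",
]

DEGENERACY_TOL = 1e-9  # Å; references closer than this cannot define a scale


@dataclass
class RCVScore:
    component_name: str
    score_median: float
    score_iqr: tuple[float, float]
    active_ref_median: float
    inactive_ref_median: float
    mutant_summary: RMSDSummary


def rcv_normalize(value: float, active_median: float, inactive_median: float) -> float:
    """Affine score: 0 at the active reference median, 1 at the inactive one.

    Values below 0 (tighter than the active reference) and above 1 (more
    deformed than the inactive reference) are meaningful and not clamped.
    """
    span = inactive_median - active_median
    if abs(span) < DEGENERACY_TOL:
        raise ValueError(
            f"degenerate references: active {active_median} ≈ inactive {inactive_median}"
        )
    return (value - active_median) / span


def rcv_profile(
    mutant_series: dict[str, list[RMSDSeries]],
    active_refs: dict[str, float],
    inactive_refs: dict[str, float],
) -> list[RCVScore]:
    """Score each component of a variant against the reference medians.

    ``mutant_series`` maps component name to the pooled list of RMSD series
    (monomers × replicas); the affine map is applied to every pooled frame
    value and the median/quartiles of the transformed distribution reported.
    """
    scores = []
    for component, series_list in mutant_series.items():
        if component not in active_refs or component not in inactive_refs:
            raise KeyError(f"component {component!r} missing from reference calibration")
        a = active_refs[component]
        b = inactive_refs[component]
        summary = summarize_pooled(series_list)
        pooled = np.concatenate([s.values for s in series_list])
        transformed = np.array([rcv_normalize(v, a, b) for v in np.atleast_1d(pooled)])
        q1, med, q3 = np.percentile(transformed, [25, 50, 75])
        lo, hi = (q1, q3) if q1 <= q3 else (q3, q1)  # map may be decreasing
        scores.append(
            RCVScore(
                component_name=component,
                score_median=float(med),
                score_iqr=(float(lo), float(hi)),
                active_ref_median=a,
                inactive_ref_median=b,
                mutant_summary=summary,
            )
        )
    return scores


def classify_mutant(profile: list[RCVScore], threshold: float = 1.0) -> dict[str, str]:
    """Advisory qualitative label per component.

    ``severe`` at or above ``threshold`` (as deformed as the inactive
    reference), ``perturbed`` between 0.5 and the threshold, ``native-like``
    below.  Labels describe conformation only, not activity.
    """
    if not profile:
        raise ValueError("empty profile")
    labels = {}
    for score in profile:
        m = score.score_median
        if m >= threshold:
            labels[score.component_name] = "severe"
        elif m >= 0.5:
            labels[score.component_name] = "perturbed"
        else:
            labels[score.component_name] = "native-like"
    return labels


def save_calibration(
    path: str | Path,
    active_refs: dict[str, float],
    inactive_refs: dict[str, float],
    cutoffs: dict[str, float] | None = None,
    meta: dict | None = None,
) -> None:
    payload = {
        "active_medians_A": active_refs,
        "inactive_medians_A": inactive_refs,
        "cluster_cutoffs_A": cutoffs or {},
        "meta": meta or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_calibration(path: str | Path) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    with open(path) as fh:
        payload = json.load(fh)
    return (
        payload["active_medians_A"],
        payload["inactive_medians_A"],
        payload.get("cluster_cutoffs_A", {}),
    )
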