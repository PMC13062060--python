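"""Michaelis–Menten fitting, fold-activation ratios, and melt-curve Tm.

Rates are consumed on the kcat scale (v/[E], s⁻¹).  The hyperbola
``v = kcat·S/(Km+S)`` is fit by nonlinear least squares; 95% confidence
intervals come from the linearized covariance with t quantiles by default,
or from a seeded residual-resampling bootstrap when asymmetric intervals are
wanted.  Fold activation is kcat(Ca)/kcat(Na); fold catalytic efficiency is
(kcat/Km)(Ca) / (kcat/Km)(Na); both are reported at one decimal with full
precision retained.

Melting temperatures come from fluorescence thermal-shift (ThermoFluor)
curves: the smoothed numerical derivative dF/dT is scanned for local
extrema ("wells"); all wells are returned sorted by depth and the deepest
one defines the primary Tm.  Multi-domain proteins can show several wells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KineticsDataset",
    "KineticsFit",
    "MeltCurve",
    "MeltResult",
    "michaelis_menten",
    "fit_michaelis_menten",
    "fold_activation",
    "fold_catalytic_efficiency",
    "melt_tm",
    "rates_from_product",
]


@dataclass
class KineticsDataset:
    """Substrate concentrations (µM) vs observed rates (s⁻¹, i.e. v/[E])."""

    concentrations_uM: np.ndarray
    rates_per_s: np.ndarray
    buffer: str = "calcium"  # or "sodium"
    enzyme_nM: float | None = None

    def __post_init__(self) -> None:
        self.concentrations_uM = np.asarray(self.concentrations_uM, dtype=float)
        self.rates_per_s = np.asarray(self.rates_per_s, dtype=float)
        if self.concentrations_uM.shape != self.rates_per_s.shape:
            raise ValueError("concentration and rate arrays differ in length")
        if np.any(self.concentrations_uM <= 0):
            raise ValueError("substrate concentrations must be positive")
        if np.any(self.rates_per_s < 0):
            raise ValueError("rates must be non-negative")
        if np.unique(self.concentrations_uM).size < 4:
            raise ValueError("need at least 4 distinct substrate concentrations")


@dataclass
class KineticsFit:
    kcat: float  # s⁻¹
    Km: float  # µM
    kcat_ci: tuple[float, float]
    Km_ci: tuple[float, float]
    rss: float
    n_points: int
    ci_method: str = "linearized-t"
    buffer: str = ""

    @property
    def catalytic_efficiency(self) -> float:
        """kcat/Km in µM⁻¹ s⁻¹."""
        return self.kcat / self.Km


def michaelis_menten(S: np.ndarray, kcat: float, Km: float) -> np.ndarray:
    return kcat * S / (Km + S)


def rates_from_product(product_uM_per_s: np.ndarray, enzyme_nM: float) -> np.ndarray:
    """Convert product-formation rates (µM/s) to kcat-scale v/[E] (s⁻¹)."""
    return np.asarray(product_uM_per_s, dtype=float) / (enzyme_nM * 1e-3)


def fit_michaelis_menten(
    data: KineticsDataset,
    ci_method: str = "linearized-t",
    weighting: str = "relative",
    n_bootstrap: int = 999,
    seed: int = 0,
) -> KineticsFit:
    """Nonlinear least-squares fit of the Michaelis–Menten hyperbola.

    ``weighting="relative"`` (default) weights residuals by 1/v, the standard
    choice when measurement error scales with the rate, and keeps the
    linearized confidence intervals calibrated under multiplicative noise;
    ``"uniform"`` is plain unweighted least squares.  Exact on noiseless data
    for any positive (kcat, Km); raises on non-convergence.
    """
    S = data.concentrations_uM
    v = data.rates_per_s
    vmax0 = float(v.max()) or 1.0
    # half-saturation initial guess from the concentration closest to vmax/2
    km0 = float(S[np.argmin(np.abs(v - vmax0 / 2))])
    if weighting == "relative":
        sigma = np.maximum(v, 1e-12 * vmax0)
    elif weighting == "uniform":
        sigma = None
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    try:
        popt, pcov = optimize.curve_fit(
            michaelis_menten, S, v, p0=[vmax0, max(km0, S.min())], sigma=sigma,
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    kcat, Km = float(popt[0]), float(popt[1])
    resid = v - michaelis_menten(S, kcat, Km)
    rss = float(np.sum(resid**2))
    dof = max(len(S) - 2, 1)
    if ci_method == "linearized-t":
        se = np.sqrt(np.diag(pcov))
        tq = stats.t.ppf(0.975, dof)
        kcat_ci = (kcat - tq * se[0], kcat + tq * se[0])
        Km_ci = (Km - tq * se[1], Km + tq * se[1])
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        fitted = michaelis_menten(S, kcat, Km)
        # resample on the scale the noise lives on
        rel = weighting == "relative"
        pool = resid / np.maximum(fitted, 1e-12) if rel else resid
        boots = []
        for _ in range(n_bootstrap):
            draw = rng.choice(pool, size=len(pool), replace=True)
            vb = fitted * (1.0 + draw) if rel else fitted + draw
            try:
                pb, _ = optimize.curve_fit(
                    michaelis_menten, S, np.clip(vb, 0, None), p0=[kcat, Km], sigma=sigma,
                    bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
                )
                boots.append(pb)
            except RuntimeError:
                continue
        boots = np.array(boots)
        kcat_ci = tuple(np.percentile(boots[:, 0], [2.5, 97.5]))
        Km_ci = tuple(np.percentile(boots[:, 1], [2.5, 97.5]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return KineticsFit(
        kcat=kcat, Km=Km,
        kcat_ci=(float(kcat_ci[0]), float(kcat_ci[1])),
        Km_ci=(float(Km_ci[0]), float(Km_ci[1])),
        rss=rss, n_points=len(S), ci_method=ci_method, buffer=data.buffer,
    )


def fold_activation(kcat_ca: float, kcat_na: float) -> float:
    """kcat(Ca)/kcat(Na); report at one decimal via round()."""
    if kcat_na <= 0 or kcat_ca <= 0:
        raise ValueError("kcat values must be positive")
    return kcat_ca / kcat_na


def fold_catalytic_efficiency(
    kcat_ca: float, km_ca: float, kcat_na: float, km_na: float
) -> float:
    """(kcat/Km)(Ca) / (kcat/Km)(Na)."""
    if min(kcat_ca, km_ca, kcat_na, km_na) <= 0:
        raise ValueError("all kinetic parameters must be positive")
    return (kcat_ca / km_ca) / (kcat_na / km_na)


# ---------------------------------------------------------------------------
# Thermal-shift melt curves
# ---------------------------------------------------------------------------


@dataclass
class MeltCurve:
    temperatures_C: np.ndarray  # strictly increasing
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures_C = np.asarray(self.temperatures_C, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures_C.size < 10:
            raise ValueError("melt curve needs at least 10 points")
        if np.any(np.diff(self.temperatures_C) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.temperatures_C.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence arrays differ in length")


@dataclass
class MeltResult:
    tm_C: float  # primary Tm: temperature of the deepest well
    wells: list[tuple[float, float]]  # (temperature, signed derivative) sorted by |depth|
    sign_convention: str


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, y[0]), y, np.full(window - 1 - pad, y[-1])])
    return np.convolve(padded, kernel, mode="valid")


def melt_tm(curve: MeltCurve, smoothing_window: int = 5, sign: str = "auto") -> MeltResult:
    """Tm from the melt curve's derivative.

    The fluorescence trace is smoothed with a moving average, differentiated
    numerically, and scanned for local extrema of the derivative.  With
    ``sign="negative"`` wells are local minima of dF/dT (curves that lose
    fluorescence on unfolding, or pre-negated derivative exports);
    ``"positive"`` takes local maxima (raw dye traces that gain fluorescence
    on unfolding); ``"auto"`` picks whichever side has the deeper extremum.
    All wells are returned sorted by depth; the deepest defines the primary
    Tm.
    """
    T = curve.temperatures_C
    F = _moving_average(curve.fluorescence, smoothing_window)
    dF = np.gradient(F, T)
    # extrema shallower than this are numerical jitter, not transitions
    tol = max(1e-12, 1e-9 * np.ptp(F) / max(np.ptp(T), 1e-12))
    minima = [i for i in _local_extrema(dF, mode="min") if abs(dF[i]) > tol]
    maxima = [i for i in _local_extrema(dF, mode="max") if abs(dF[i]) > tol]
    if sign == "negative":
        wells = minima
    elif sign == "positive":
        wells = maxima
    elif sign == "auto":
        depth_min = max((abs(dF[i]) for i in minima), default=0.0)
        depth_max = max((abs(dF[i]) for i in maxima), default=0.0)
        wells = minima if depth_min >= depth_max else maxima
    else:
        raise ValueError(f"unknown sign convention {sign!r}")
    if not wells:
        raise ValueError("no well found: derivative has no local extrema (flat curve?)")
    wells_sorted = sorted(wells, key=lambda i: -abs(dF[i]))
    return MeltResult(
        tm_C=float(T[wells_sorted[0]]),
        wells=[(float(T[i]), float(dF[i])) for i in wells_sorted],
        sign_convention=sign,
    )


def _local_extrema(y: np.ndarray, mode: str) -> list[int]:
    s = y if mode == "min" else -y
    idx = []
    for i in range(1, len(s) - 1):
        if s[i] < s[i - 1] and s[i] <= s[i + 1]:
            idx.append(i)
    return idx
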