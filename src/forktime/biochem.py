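"""In-vitro companion analyses: G4 UV-melting fits and gel densitometry.

G-quadruplex stability is assayed by UV melting followed at 295 nm, where
quadruplex unfolding gives a hypochromic shift: absorbance is high while the
structure is folded and drops through the melt.  The normalized curve is
described by a two-state (folded/unfolded) unimolecular equilibrium with a
van 't Hoff enthalpy, theta(T) = 1 / (1 + exp(-(dH/R) (1/T - 1/Tm))) in
absolute temperature, with dS = dH/Tm pinned at the midpoint.

Primer-extension products resolved on a denaturing gel are quantified from
1D lane intensity profiles: after a rolling-minimum baseline, band areas are
integrated over named windows and the full-length fraction is reported
relative to all extension products (the unextended primer band is excluded
from the denominator by default; an include-primer variant is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import curve_fit
from scipy.special import expit

__all__ = [
    "GAS_CONSTANT_KCAL",
    "MeltingCurve",
    "MeltingFit",
    "GelLaneProfile",
    "normalize_melting",
    "fit_two_state_melting",
    "band_fractions",
    "quantify_full_length_fraction",
]

#: gas constant in kcal / (mol K)
GAS_CONSTANT_KCAL = 1.987204258e-3

_KELVIN = 273.15


@dataclass
class MeltingCurve:
    """A normalized melting curve: temperature (degC) vs normalized A295."""

    temps: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.temps = np.asarray(self.temps, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temps.shape != self.signal.shape:
            raise ValueError("temps and signal must have the same shape")
        if np.any(np.diff(self.temps) <= 0):
            raise ValueError("temps must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")


def theta_two_state(temps_c: np.ndarray, tm_c: float, dh_kcal: float) -> np.ndarray:
    """Folded fraction of the two-state model at temperatures in degC."""
    t_k = np.asarray(temps_c, dtype=float) + _KELVIN
    tm_k = tm_c + _KELVIN
    x = (dh_kcal / GAS_CONSTANT_KCAL) * (1.0 / t_k - 1.0 / tm_k)
    return expit(x)


@dataclass
class MeltingFit:
    """Result of the two-state van 't Hoff fit."""

    tm_c: float
    dh_vh: float  # unfolding enthalpy, kcal/mol (positive = standard melt)
    r_squared: float
    converged: bool
    non_standard: bool = False  # theta increasing with T (refolding-like data)
    diagnostic: str = ""
    baseline_folded: tuple[float, float] | None = None  # (intercept, slope)
    baseline_unfolded: tuple[float, float] | None = None
    theta: Callable[[np.ndarray], np.ndarray] = field(default=None, repr=False)


def normalize_melting(raw_temps, raw_a295, *, label: str = "") -> MeltingCurve:
    """Normalize a raw A295 melting curve to folded fraction units.

    Linear baselines are fitted to the lowest- and highest-temperature
    quartiles of the data (folded baseline at low T, unfolded at high T) and
    the signal is mapped to (raw - unfolded)/(folded - unfolded).  Values
    outside [-0.1, 1.1] trigger a warning but are reported unclipped, since
    clipping would bias a subsequent fit.
    """
    t = np.asarray(raw_temps, dtype=float)
    y = np.asarray(raw_a295, dtype=float)
    if t.size < 8:
        raise ValueError("need at least 8 points to normalize a melting curve")
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperatures must be strictly increasing")
    k = max(2, t.size // 4)
    fold = np.polynomial.Polynomial.fit(t[:k], y[:k], 1).convert()
    unf = np.polynomial.Polynomial.fit(t[-k:], y[-k:], 1).convert()
    denom = fold(t) - unf(t)
    if np.any(np.abs(denom) < 1e-12 * max(1.0, np.abs(y).max())):
        raise ValueError("degenerate baselines: folded and unfolded coincide")
    norm = (y - unf(t)) / denom
    if np.any((norm < -0.1) | (norm > 1.1)):
        warnings.warn(
            "normalized melting signal outside [-0.1, 1.1]; check baselines",
            stacklevel=2,
        )
    return MeltingCurve(temps=t, signal=norm, label=label)


def _crossing(t: np.ndarray, y: np.ndarray, level: float = 0.5) -> float | None:
    """First linear-interpolated crossing of `level`, or None."""
    s = y - level
    sign = np.sign(s)
    for i in range(len(s) - 1):
        if sign[i] == 0:
            return float(t[i])
        if sign[i] * sign[i + 1] < 0:
            f = s[i] / (s[i] - s[i + 1])
            return float(t[i] + f * (t[i + 1] - t[i]))
    return None


def fit_two_state_melting(curve: MeltingCurve, *, fit_baselines: bool = False) -> MeltingFit:
    """Fit the two-state van 't Hoff model to a normalized melting curve.

    Initialization: Tm at the interpolated 0.5 crossing, |dH| = 40 kcal/mol
    with the sign taken from the overall trend of the data.  With
    ``fit_baselines=True`` residual linear folded/unfolded baselines are
    co-fitted: y = base_f(T) theta + base_u(T) (1 - theta).

    A curve that does not bracket the transition (never crosses 0.5) returns
    ``converged=False`` with a diagnostic instead of raising.
    """
    t, y = curve.temps, curve.signal
    tm0 = _crossing(t, y)
    if tm0 is None:
        return MeltingFit(
            tm_c=np.nan, dh_vh=np.nan, r_squared=np.nan, converged=False,
            diagnostic="transition not bracketed by the data (no 0.5 crossing)",
            theta=None,
        )
    decreasing = y[: max(2, len(y) // 4)].mean() > y[-max(2, len(y) // 4):].mean()
    dh0 = 40.0 if decreasing else -40.0

    if fit_baselines:
        def model(tc, tm, dh, cf, mf, cu, mu):
            th = theta_two_state(tc, tm, dh)
            return (cf + mf * tc) * th + (cu + mu * tc) * (1 - th)
        p0 = [tm0, dh0, 1.0, 0.0, 0.0, 0.0]
        lb = [t[0] - 20, -500, -2, -0.1, -2, -0.1]
        ub = [t[-1] + 20, 500, 3, 0.1, 2, 0.1]
    else:
        def model(tc, tm, dh):
            return theta_two_state(tc, tm, dh)
        p0 = [tm0, dh0]
        lb = [t[0] - 20, -500]
        ub = [t[-1] + 20, 500]

    try:
        popt, _ = curve_fit(model, t, y, p0=p0, bounds=(lb, ub), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return MeltingFit(
            tm_c=np.nan, dh_vh=np.nan, r_squared=np.nan, converged=False,
            diagnostic=f"optimizer failure: {exc}", theta=None,
        )
    resid = y - model(t, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    tm, dh = float(popt[0]), float(popt[1])
    fit = MeltingFit(
        tm_c=tm,
        dh_vh=dh,
        r_squared=r2,
        converged=True,
        non_standard=dh < 0,
        theta=lambda tc, _tm=tm, _dh=dh: theta_two_state(tc, _tm, _dh),
    )
    if fit_baselines:
        fit.baseline_folded = (float(popt[2]), float(popt[3]))
        fit.baseline_unfolded = (float(popt[4]), float(popt[5]))
    return fit


# ---------------------------------------------------------------------------
# gel densitometry


@dataclass
class GelLaneProfile:
    """A 1D gel lane intensity profile with named band windows.

    ``band_windows`` maps band names (e.g. ``full_length``, ``stall``,
    ``primer``) to (lo, hi) position intervals; they must not overlap.
    """

    positions: np.ndarray
    intensity: np.ndarray
    band_windows: dict[str, tuple[float, float]]
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.positions.shape != self.intensity.shape:
            raise ValueError("positions and intensity must match")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        wins = sorted(self.band_windows.values())
        for (a_lo, a_hi), (b_lo, b_hi) in zip(wins, wins[1:]):
            if b_lo < a_hi:
                raise ValueError("band windows must not overlap")


def _baseline_subtract(lane: GelLaneProfile, window: int | None) -> tuple[np.ndarray, int]:
    """Rolling-minimum baseline; returns (corrected, n_clipped_negative)."""
    n = lane.intensity.size
    w = window or max(5, n // 10)
    base = ndi.minimum_filter1d(lane.intensity, size=w, mode="nearest")
    base = ndi.uniform_filter1d(base, size=w, mode="nearest")
    corr = lane.intensity - base
    return corr, int((corr < 0).sum())


def band_fractions(
    lane: GelLaneProfile,
    *,
    include_primer: bool = False,
    baseline_window: int | None = None,
) -> dict[str, float]:
    """Fractional band areas over the lane's windows (trapezoidal integration).

    The denominator is the summed area over the included windows, so the
    returned fractions add to 1.  The ``primer`` window (unextended primer)
    is excluded unless ``include_primer``.
    """
    corr, _ = _baseline_subtract(lane, baseline_window)
    names = [
        nm for nm in lane.band_windows if include_primer or nm != "primer"
    ]
    areas = {}
    for nm in names:
        lo, hi = lane.band_windows[nm]
        m = (lane.positions >= lo) & (lane.positions <= hi)
        if m.sum() < 2:
            areas[nm] = 0.0
        else:
            areas[nm] = float(np.trapezoid(corr[m], lane.positions[m]))
    total = sum(areas.values())
    if total <= 0:
        raise ValueError("total band area is non-positive")
    return {nm: a / total for nm, a in areas.items()}


def quantify_full_length_fraction(
    lane: GelLaneProfile,
    *,
    include_primer: bool = False,
    baseline_window: int | None = None,
) -> float:
    """Fraction of full-length extension product in a lane.

    ``area(full_length) / sum(area over extension-product windows)``; by
    default the unextended-primer band does not enter the denominator
    (fraction *of extended products*), matching how completed synthesis is
    reported; ``include_primer=True`` gives the fraction of total lane
    signal instead.
    """
    fr = band_fractions(lane, include_primer=include_primer, baseline_window=baseline_window)
    if "full_length" not in fr:
        raise ValueError("lane has no 'full_length' window")
    return fr["full_length"]
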