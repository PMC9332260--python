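"""Differential scanning calorimetry: excess heat capacity and denaturation
thermodynamics.

Protein unfolding appears in a DSC scan as an endothermic peak riding on
sloping instrument baselines.  The excess heat capacity is obtained by
subtracting the linearly extrapolated native (pre-transition) and denatured
(post-transition) heat-capacity lines, blended by a sigmoid baseline — here
realized as the self-consistent progress-weighted blend in which the blend
weight is the normalized cumulative area of the current excess curve.  From
the corrected peak we report:

* ``T_m``      — temperature of the peak maximum (K),
* ``dT_half``  — full width of the peak at half maximum (K),
* ``dH_cal``   — calorimetric enthalpy, the integrated peak area (kJ/mol),
* ``asymmetry``— dQ-/dQ+, the ratio of heat absorbed below vs above T_m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

logger = logging.getLogger(__name__)

R_GAS = 8.314  # J/(mol K)
DEFAULT_MW_DA = 80_000.0  # luciferase alpha/beta dimer


@dataclass
class Thermogram:
    """Heat capacity versus temperature from a DSC scan.

    ``units`` is ``"molar"`` (kJ/(K mol)) or ``"specific"`` (J/(K g)).
    Metadata carries scan rate (K/min), protein concentration (mg/mL),
    molecular weight (Da) and partial specific volume (cm^3/g); the latter is
    kept for provenance but does not enter the excess-heat-capacity
    computation.
    """

    T: np.ndarray  # K, strictly increasing
    Cp: np.ndarray
    units: str = "molar"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.Cp = np.asarray(self.Cp, dtype=float)
        if self.T.shape != self.Cp.shape:
            raise ValueError("T and Cp must have equal length")
        if self.T.size < 50:
            raise ValueError("a thermogram needs at least 50 samples")
        if not np.all(np.diff(self.T) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.units not in ("molar", "specific"):
            raise ValueError("units must be 'molar' or 'specific'")


@dataclass
class ExcessHeatCapacity:
    """Baseline-corrected excess heat capacity curve."""

    T: np.ndarray  # K
    Cp_exc: np.ndarray  # kJ/(K mol)
    baseline: np.ndarray
    pre_region: tuple[int, int]
    post_region: tuple[int, int]


@dataclass
class DenaturationParams:
    T_m: float  # K
    dT_half: float  # K
    dH_cal: float  # kJ/mol
    asymmetry: float  # dQ- / dQ+


def to_molar(tg: Thermogram) -> Thermogram:
    """Convert a specific-units thermogram (J/(K g)) to molar (kJ/(K mol)).

    An already-molar thermogram is returned unchanged.  The molecular weight
    defaults to 80,000 Da (the luciferase heterodimer) with a logged notice
    when the metadata does not provide one.
    """
    if tg.units == "molar":
        return tg
    if "concentration_mg_ml" not in tg.meta:
        raise ValueError("specific-units thermogram lacks protein concentration")
    mw = tg.meta.get("mw_da")
    if mw is None:
        mw = DEFAULT_MW_DA
        logger.info("molecular weight missing; defaulting to %.0f Da", mw)
    meta = dict(tg.meta, mw_da=mw)
    return Thermogram(T=tg.T, Cp=tg.Cp * mw / 1000.0, units="molar", meta=meta)


def excess_heat_capacity(
    tg: Thermogram,
    pre_frac: float = 0.15,
    post_frac: float = 0.15,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> ExcessHeatCapacity:
    """Subtract the progress-blended sigmoid baseline from a thermogram.

    Linear fits over the leading ``pre_frac`` and trailing ``post_frac`` of
    the scan seed the native and denatured baselines B_N(T) and B_D(T).  The
    subtracted baseline is (1-a)*B_N + a*B_D where the progress a(T) is the
    normalized cumulative integral of the current excess curve, iterated to a
    fixed point (relative-area tolerance ``tol``).  The procedure runs twice:
    after the first convergence the transition is located from the progress
    quartile crossings, and the baselines are refit over every point more
    than several wing e-folding lengths outside it — this shortens the
    extrapolation lever arm of the short seed regions without letting the
    transition wings contaminate the linear fits.  The fixed point is then
    recomputed with the refit baselines.
    """
    T, cp = tg.T, tg.Cp
    n = T.size
    n_pre = max(int(round(pre_frac * n)), 2)
    n_post = max(int(round(post_frac * n)), 2)
    pre_mask = np.zeros(n, dtype=bool)
    pre_mask[:n_pre] = True
    post_mask = np.zeros(n, dtype=bool)
    post_mask[-n_post:] = True
    nat, den = pre_mask, post_mask

    for stage in range(2):
        bn = np.polyval(np.polyfit(T[nat], cp[nat], 1), T)
        bd = np.polyval(np.polyfit(T[den], cp[den], 1), T)
        alpha = np.zeros(n)
        prev_area = None
        for _ in range(max_iter):
            baseline = (1.0 - alpha) * bn + alpha * bd
            exc = cp - baseline
            cum = cumulative_trapezoid(exc, T, initial=0.0)
            area = cum[-1]
            if area <= 0:
                raise ValueError("no endothermic peak: non-positive excess area")
            alpha = np.clip(cum / area, 0.0, 1.0)
            if prev_area is not None and abs(area - prev_area) <= tol * abs(area):
                break
            prev_area = area
        else:
            raise ValueError(
                f"sigmoid baseline did not converge in {max_iter} iterations "
                f"(last area {area:.6g})"
            )
        if stage == 0:
            # locate the transition by its quartile crossings (the progress
            # slope is steep there, so noise barely moves them), infer the
            # wing e-folding length, and keep only points several e-folds
            # outside the transition for the baseline refits
            q25 = alpha >= 0.25
            q75 = alpha >= 0.75
            t25 = T[q25][0] if q25.any() else T[-1]
            t75 = T[q75][0] if q75.any() else T[-1]
            efold = max((t75 - t25) / 2.2, 1e-3 * (T[-1] - T[0]))
            nat = pre_mask | (T <= t25 - 7.5 * efold)
            den = post_mask | (T >= t75 + 7.5 * efold)
    return ExcessHeatCapacity(
        T=T, Cp_exc=exc, baseline=baseline,
        pre_region=(0, int(nat.sum())), post_region=(n - int(den.sum()), n),
    )


def _refine_peak(T: np.ndarray, y: np.ndarray, frac: float = 0.90) -> tuple[float, float]:
    """Vertex of a least-squares parabola through the points near the maximum.

    Using every sample above ``frac`` of the peak (at least 7) averages grid
    noise out of the vertex estimate; a literal 3-point parabola would be
    dominated by noise on a fine temperature grid.
    """
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        raise ValueError("peak lies on the edge of the scan (truncated)")
    near = np.nonzero(y >= frac * y[i])[0]
    lo, hi = near[0], near[-1] + 1
    if hi - lo < 7:
        lo, hi = max(i - 3, 0), min(i + 4, y.size)
    tt, yy = T[lo:hi], y[lo:hi]
    c2, c1, c0 = np.polyfit(tt - T[i], yy, 2)
    if c2 >= 0:
        return float(T[i]), float(y[i])
    dt = -c1 / (2.0 * c2)
    return float(T[i] + dt), float(c0 - c1**2 / (4.0 * c2))


def denaturation_params(ex: ExcessHeatCapacity) -> DenaturationParams:
    """Peak temperature, FWHM, calorimetric enthalpy and asymmetry.

    ``T_m`` is the parabola-refined abscissa of the maximum; ``dH_cal`` the
    trapezoidal integral of the corrected curve; ``dT_half`` the full width at
    half maximum with linear interpolation on each flank; ``asymmetry`` the
    ratio of the areas below and above T_m (same quadrature, so the two parts
    sum exactly to dH_cal).
    """
    T, y = ex.T, ex.Cp_exc
    if np.max(y) <= 0:
        raise ValueError("corrected curve has no positive peak")
    t_m, height = _refine_peak(T, y)
    i_max = int(np.argmax(y))

    half = height / 2.0
    t_left = _cross(T[: i_max + 1], y[: i_max + 1], half, rising=True)
    t_right = _cross(T[i_max:], y[i_max:], half, rising=False)
    dt_half = t_right - t_left

    dh_cal = float(np.trapezoid(y, T))
    # split the same trapezoidal quadrature at T_m
    y_at_tm = float(np.interp(t_m, T, y))
    below = T <= t_m
    t_lo = np.append(T[below], t_m)
    y_lo = np.append(y[below], y_at_tm)
    q_minus = float(np.trapezoid(y_lo, t_lo))
    q_plus = dh_cal - q_minus
    if q_plus <= 0:
        raise ValueError("no area above T_m (truncated peak)")
    return DenaturationParams(
        T_m=t_m, dT_half=float(dt_half), dH_cal=dh_cal, asymmetry=q_minus / q_plus
    )


def _cross(T: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float:
    """Temperature where the flank crosses ``level``, by linear interpolation.

    For the left flank (``rising``) the crossing nearest the peak is used;
    symmetrically for the right flank.
    """
    above = y >= level
    if rising:
        if above[0] or not above[-1]:
            raise ValueError("half maximum not crossed on the left flank")
        j = int(np.nonzero(~above)[0][-1])  # last point below, adjacent to peak run
        lo, hi = j, j + 1
    else:
        if above[-1] or not above[0]:
            raise ValueError("half maximum not crossed on the right flank")
        j = int(np.nonzero(above)[0][-1])  # last point above
        lo, hi = j, j + 1
    frac = (level - y[lo]) / (y[hi] - y[lo])
    return float(T[lo] + frac * (T[hi] - T[lo]))
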