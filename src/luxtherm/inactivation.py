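"""Thermal-inactivation kinetics and Arrhenius analysis.

Remaining activity R(t) of a heat-treated enzyme, expressed as percent of the
untreated control, typically shows three regimes: an induction lag during
which cooled enzyme still recovers full activity, a first-order exponential
decay R = A*exp(-k t), and (at the highest temperatures) a late slow phase
attributed to aggregation.  Only the exponential segment carries the
inactivation rate constant k; activation energies come from the slope of
ln k versus 1/T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

R_GAS = 8.314  # J/(mol K)
KELVIN_OFFSET = 273.15


@dataclass
class ActivitySeries:
    """Remaining activity (%) versus incubation time at one condition."""

    times: np.ndarray  # min
    R: np.ndarray  # percent of untreated control
    temperature: float | None = None  # deg C
    solvent: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.times.shape != self.R.shape:
            raise ValueError("times and R must have equal length")
        if self.times.size == 0:
            raise ValueError("empty activity series")
        if np.any(self.times < 0) or not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(self.R < 0):
            raise ValueError("remaining activity cannot be negative")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class InactivationFit:
    k: float  # min^-1
    A: float  # percent
    r2: float
    induction_idx: np.ndarray
    slow_idx: np.ndarray


@dataclass
class ArrheniusResult:
    E_a: float  # kJ/mol
    lnA0: float
    stderr_Ea: float  # kJ/mol
    n_points: int


def remaining_activity(q: float, q0: float) -> float:
    """Percent remaining activity R = 100 * Q*/Q0* from two light areas."""
    if q0 <= 0:
        raise ValueError("untreated-control area q0 must be positive")
    if q < 0:
        raise ValueError("treated area q cannot be negative")
    return 100.0 * q / q0


def segment_phases(
    series: ActivitySeries,
    induction_tol: float = 5.0,
    slow_detect: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a time course into induction, exponential and slow-phase indices.

    Induction: the leading run of points with R >= 100 - induction_tol —
    where heating has not yet inactivated the enzyme.  Noise robustness: a
    point also counts as lag-like when it sits within the tolerance of the
    median of the lag points so far, and a single below-threshold dip whose
    successor is back above threshold does not end the run.  A run of just
    the t=0 point does not count — R(0) is 100 by construction, so a lone
    initial point means decay began immediately.

    Slow phase: trailing points whose log-residuals from a provisional
    exponential fit exceed 3x their robust scale (1.4826*MAD); flagged only
    when at least 3 such trailing points exist.  Mirrors the practice of
    dropping late aggregation-dominated points rather than modelling them.
    """
    n = len(series)
    if n < 4:
        raise ValueError("need at least 4 points to segment an inactivation course")
    R = series.R
    t = series.times

    thr = 100.0 - induction_tol
    lead = 0
    while lead < n:
        ref = float(np.median(R[:lead])) if lead else 100.0
        # the t=0 point is the control ratio (~100% by construction)
        lag_like = lead == 0 or R[lead] >= thr or R[lead] >= ref - induction_tol
        dip = lead + 1 < n and R[lead + 1] >= thr
        if not (lag_like or dip):
            break
        lead += 1
    if lead == 1:
        lead = 0  # only the trivial t=0 point: no real induction phase
    induction_idx = np.arange(lead)

    rest = np.arange(lead, n)
    slow_idx = np.empty(0, dtype=int)
    if slow_detect and rest.size >= 6:
        slow_idx = _detect_slow_phase(t, R, rest)
    exp_idx = np.setdiff1d(rest, slow_idx)
    if exp_idx.size < 3:
        raise ValueError("no decaying phase: fewer than 3 exponential points")
    return induction_idx, exp_idx, slow_idx


def _detect_slow_phase(t: np.ndarray, R: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """Flag trailing points dominated by a late non-decaying phase.

    A provisional offset-exponential A*exp(-k t) + c is fit to the decay; a
    plateau-like slow phase shows up as an offset c that is both significant
    (> 3 standard errors) and non-negligible (> 1% activity).  The slow-phase
    points are the trailing ones where the offset exceeds the decaying
    component — where the simple exponential no longer describes the course.
    At least 3 such trailing points are required to call a slow phase, and at
    least 3 points must remain before it.
    """
    included = rest[R[rest] > 0]
    if included.size < 6:
        return np.empty(0, dtype=int)
    tt, yy = t[included], R[included]
    slope, intercept = np.polyfit(tt, np.log(yy), 1)

    def model(x: np.ndarray, a: float, k: float, c: float) -> np.ndarray:
        return a * np.exp(-k * x) + c

    try:
        popt, pcov = curve_fit(
            model, tt, yy,
            p0=(float(np.exp(intercept)), max(-slope, 1e-9), 0.0),
            maxfev=10000,
        )
    except RuntimeError:
        return np.empty(0, dtype=int)
    a_hat, k_hat, c_hat = popt
    c_err = float(np.sqrt(max(pcov[2, 2], 0.0)))
    if k_hat <= 0 or c_hat <= max(3.0 * c_err, 1.0):
        return np.empty(0, dtype=int)
    plateau_dominated = a_hat * np.exp(-k_hat * tt) < c_hat
    k = included.size
    while k > 0 and plateau_dominated[k - 1]:
        k -= 1
    if included.size - k < 3 or k < 3:
        return np.empty(0, dtype=int)
    return included[k:]


def fit_inactivation(
    series: ActivitySeries,
    induction_tol: float = 5.0,
    slow_detect: bool = True,
) -> InactivationFit:
    """Fit R = A*exp(-k t) on the exponential segment of a time course.

    The fit runs on the original time axis with A free, so A absorbs the
    induction lag; r2 is reported on the fitted segment only.
    """
    induction_idx, exp_idx, slow_idx = segment_phases(
        series, induction_tol=induction_tol, slow_detect=slow_detect
    )
    t = series.times[exp_idx]
    y = series.R[exp_idx]

    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        k0, a0 = max(-slope, 1e-9), float(np.exp(intercept))
    else:
        k0, a0 = 1.0, float(y[0])

    def model(tt: np.ndarray, a: float, k: float) -> np.ndarray:
        return a * np.exp(-k * tt)

    try:
        popt, _ = curve_fit(model, t, y, p0=(a0, k0), maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise ValueError(f"inactivation fit did not converge: {exc}") from exc
    a_hat, k_hat = popt
    if k_hat <= 0:
        raise ValueError("inactivation fit converged to a non-positive rate")
    resid = y - model(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return InactivationFit(
        k=float(k_hat), A=float(a_hat), r2=float(min(max(r2, 0.0), 1.0)),
        induction_idx=induction_idx, slow_idx=slow_idx,
    )


def arrhenius_fit(ks: np.ndarray, temps_c: np.ndarray) -> ArrheniusResult:
    """Activation energy from ordinary least squares of ln k on 1/T.

    ``E_a = -slope * R_gas`` reported in kJ/mol with the OLS standard error.
    Temperatures are given in deg C and converted to kelvin internally.
    Duplicate temperatures (replicate rates) are allowed.
    """
    ks = np.asarray(ks, dtype=float)
    temps_c = np.asarray(temps_c, dtype=float)
    if ks.shape != temps_c.shape:
        raise ValueError("ks and temps must have equal length")
    if np.any(ks <= 0):
        raise ValueError("all rate constants must be positive")
    if np.unique(temps_c).size < 2:
        raise ValueError("need at least 2 distinct temperatures")
    x = 1.0 / (temps_c + KELVIN_OFFSET)
    y = np.log(ks)
    res = linregress(x, y)
    e_a = -res.slope * R_GAS / 1000.0
    stderr = (res.stderr if np.isfinite(res.stderr) else 0.0) * R_GAS / 1000.0
    return ArrheniusResult(
        E_a=float(e_a), lnA0=float(res.intercept),
        stderr_Ea=float(stderr), n_points=int(ks.size),
    )
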