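"""Delayed-exponential response models and constrained non-linear least squares.

Capillary hemodynamic responses to a step change in local gas concentration
are described by delayed mono-exponential "on-kinetics"::

    Y(t) = Yb                                   for t <  X0
    Y(t) = Yb + Y0 * (1 - exp(-(t - X0)/tau))   for t >= X0

where ``Yb`` is the baseline magnitude, ``X0`` the onset delay (s), ``Y0``
the signed asymptotic amplitude and ``tau`` the time constant — the time
after onset to reach 63% (1 - 1/e) of the full response.  A combined
two-step challenge adds a second delayed component with its own delay,
amplitude and time constant.

Fitting minimises the sum of squared residuals over a fixed window subject
to box bounds and equality pins on parameters (e.g. ``X0 > 60`` or
``X0 = 60``).  The onset indicator makes the objective non-smooth in the
delay, so the optimiser combines a coarse delay grid (smooth bounded
fitting of the remaining parameters at each grid point) with a local polish
of all free parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

__all__ = [
    "MonoExpParams",
    "BiExpParams",
    "FitConstraints",
    "FitResult",
    "eval_mono",
    "eval_bi",
    "fit_mono",
    "fit_bi",
    "r_squared",
]

#: Open-bound epsilon used to encode strict inequalities such as "X0 > 60".
STRICT_EPS = 1e-6


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonoExpParams:
    """Parameters of the delayed mono-exponential response."""

    yb: float
    x0: float
    y0: float
    tau: float

    def as_dict(self) -> dict:
        return {"yb": self.yb, "x0": self.x0, "y0": self.y0, "tau": self.tau}


@dataclass(frozen=True)
class BiExpParams:
    """Parameters of the two-component delayed exponential response.

    Component 1 (``x1, y1, tau1``) describes the first gas step, component 2
    (``x2, y2, tau2``) the second; each contributes nothing before its own
    delay.  ``x2 >= x1`` by convention.
    """

    yb: float
    x1: float
    y1: float
    tau1: float
    x2: float
    y2: float
    tau2: float

    def as_dict(self) -> dict:
        return {
            "yb": self.yb, "x1": self.x1, "y1": self.y1, "tau1": self.tau1,
            "x2": self.x2, "y2": self.y2, "tau2": self.tau2,
        }


@dataclass
class FitConstraints:
    """Fit window, box bounds and equality pins for a kinetics fit.

    ``bounds`` maps parameter names to ``(lo, hi)`` with ``None`` for an open
    side; ``pins`` maps parameter names to fixed values.  The window is the
    closed interval of seconds entering the least-squares objective and is
    not a parameter bound.
    """

    window: tuple[float, float] = (51.0, 180.0)
    bounds: dict = field(default_factory=dict)
    pins: dict = field(default_factory=dict)

    def __post_init__(self):
        lo, hi = self.window
        if not lo < hi:
            raise ValueError(f"fit window must satisfy t_start < t_end, got {self.window}")
        for name, (blo, bhi) in self.bounds.items():
            if blo is not None and bhi is not None and blo > bhi:
                raise ValueError(f"inconsistent bounds for {name!r}: {blo} > {bhi}")

    def bound(self, name: str, default=(None, None)) -> tuple:
        return self.bounds.get(name, default)

    @classmethod
    def mono_default(cls, window=(51.0, 180.0), x0_gt=60.0) -> "FitConstraints":
        """Standard single-step constraints: delay strictly after the step."""
        return cls(window=window, bounds={"x0": (x0_gt + STRICT_EPS, None)})

    @classmethod
    def bi_default(cls, window=(51.0, 240.0), x1_gt=60.0, x2_gt=120.0) -> "FitConstraints":
        """Standard combined-challenge constraints (two strict delay bounds)."""
        return cls(window=window, bounds={
            "x1": (x1_gt + STRICT_EPS, None),
            "x2": (x2_gt + STRICT_EPS, None),
        })


@dataclass
class FitResult:
    """Outcome of a constrained kinetics fit.

    ``params`` is ``None`` when the fit did not converge.  When the amplitude
    is below the identifiability floor the time constant is unreliable and is
    reported as NaN in ``params`` (the raw optimiser solution is kept in
    ``raw_params`` for debugging).
    """

    params: MonoExpParams | BiExpParams | None
    r2: float
    ssr: float
    converged: bool
    identifiable: bool
    n_starts: int
    raw_params: MonoExpParams | BiExpParams | None = None


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def _delayed_exp(t: np.ndarray, x0: float, y0: float, tau: float) -> np.ndarray:
    """y0 * (1 - exp(-(t-x0)/tau)) gated at the onset delay (0 before x0)."""
    if tau <= 0:
        raise ValueError(f"time constant must be positive, got tau={tau}")
    dt = np.clip(t - x0, 0.0, None)
    return y0 * -np.expm1(-dt / tau)


def eval_mono(t, p: MonoExpParams):
    """Evaluate the delayed mono-exponential model; baseline before onset."""
    t_arr = np.asarray(t, dtype=float)
    out = p.yb + _delayed_exp(t_arr, p.x0, p.y0, p.tau)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def eval_bi(t, p: BiExpParams):
    """Evaluate the two-component model; each component gated by its delay."""
    t_arr = np.asarray(t, dtype=float)
    out = (p.yb + _delayed_exp(t_arr, p.x1, p.y1, p.tau1)
           + _delayed_exp(t_arr, p.x2, p.y2, p.tau2))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SSR/SST (SST about the series mean).

    May be negative for models worse than the mean.  NaN for a zero-variance
    series, for which R^2 is undefined.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("series and model curve must share a time grid")
    ssr = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    if sst == 0.0:
        return math.nan
    return 1.0 - ssr / sst


# ---------------------------------------------------------------------------
# Fitting machinery
# ---------------------------------------------------------------------------

def _window_mask(t: np.ndarray, y: np.ndarray, window) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = window
    m = (t >= lo) & (t <= hi) & np.isfinite(y)
    return t[m], y[m]


def _lin_solve(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares solve of the linear (amplitude) parameters; returns ssr."""
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(resid @ resid)


def _tau_bounds(c: FitConstraints, name: str, span: float) -> tuple[float, float]:
    lo, hi = c.bound(name)
    return (lo if lo is not None else 1e-3, hi if hi is not None else 10.0 * span)


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    if hi <= lo:
        return np.array([lo])
    n = int(math.floor((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def fit_mono(t, y, constraints: FitConstraints | None = None, *,
             x0_step: float = 0.5, noise_floor: float | None = None,
             max_nfev: int = 500) -> FitResult:
    """Constrained NLLS fit of the delayed mono-exponential model.

    Parameters
    ----------
    t, y : array-like
        Time (s) and the measure's per-second means.  Points outside the
        constraint window or non-finite are ignored.
    constraints : FitConstraints
        Window, bounds and pins; defaults to window 51-180 s with X0 > 60.
    x0_step : float
        Coarse delay-grid spacing in seconds.
    noise_floor : float, optional
        Absolute amplitude below which the fit is flagged unidentifiable
        (tau reported as NaN).  Defaults to a small multiple of the data
        scale, which flags essentially flat series.
    """
    c = constraints if constraints is not None else FitConstraints.mono_default()
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    tw, yw = _window_mask(t, y, c.window)
    if tw.size < 6:
        raise ValueError(f"need >= 6 points in the fit window, got {tw.size}")
    sst = float(np.sum((yw - yw.mean()) ** 2))
    span = c.window[1] - c.window[0]

    tau_lo, tau_hi = _tau_bounds(c, "tau", span)
    if "x0" in c.pins:
        x0_grid = np.array([float(c.pins["x0"])])
    else:
        blo, bhi = c.bound("x0")
        glo = blo if blo is not None else tw[0]
        ghi = min(bhi if bhi is not None else tw[-1] - 2.0, tw[-1] - 2.0)
        x0_grid = _grid(glo, ghi, x0_step)

    log_lo, log_hi = math.log(tau_lo), math.log(tau_hi)

    def inner(x0: float):
        """Best (yb, y0, tau) for a fixed delay: 1-D search over log tau with
        the linear parameters solved in closed form."""
        dt = np.clip(tw - x0, 0.0, None)

        def ssr_of(logtau: float) -> float:
            g = -np.expm1(-dt / math.exp(logtau))
            _, ssr = _lin_solve(np.column_stack([np.ones_like(tw), g]), yw)
            return ssr

        res = minimize_scalar(ssr_of, bounds=(log_lo, log_hi), method="bounded",
                              options={"xatol": 1e-6})
        tau = math.exp(res.x)
        g = -np.expm1(-dt / tau)
        coef, ssr = _lin_solve(np.column_stack([np.ones_like(tw), g]), yw)
        return ssr, coef[0], coef[1], tau

    best = None
    for x0 in x0_grid:
        ssr, yb, y0, tau = inner(float(x0))
        # tie-break: smallest SSR, then smallest delay (grid is ascending)
        if best is None or ssr < best[0] - 1e-15 * max(sst, 1.0):
            best = (ssr, yb, y0, tau, float(x0))
    ssr0, yb0, y00, tau0, x00 = best

    # local polish of all free parameters
    free = ["yb", "y0", "tau"] + ([] if "x0" in c.pins else ["x0"])
    start = {"yb": yb0, "y0": y00, "tau": tau0, "x0": x00}
    lo_v, hi_v = [], []
    for name in free:
        if name == "tau":
            blo, bhi = tau_lo, tau_hi
        else:
            blo, bhi = c.bound(name)
        lo_v.append(blo if blo is not None else -np.inf)
        hi_v.append(bhi if bhi is not None else np.inf)
    x_start = np.clip([start[n] for n in free], lo_v, hi_v)

    def resid(theta):
        p = dict(start)
        p.update(dict(zip(free, theta)))
        if "x0" in c.pins:
            p["x0"] = c.pins["x0"]
        dt = np.clip(tw - p["x0"], 0.0, None)
        return p["yb"] + p["y0"] * -np.expm1(-dt / p["tau"]) - yw

    scale = max(float(np.std(yw)), abs(float(np.mean(yw))), 1.0)
    try:
        sol = least_squares(resid, x_start, bounds=(lo_v, hi_v), method="trf",
                            ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=max_nfev)
        ok = bool(np.all(np.isfinite(sol.x)))
    except Exception:
        sol, ok = None, False

    if sol is not None and ok and 2.0 * sol.cost <= ssr0 + 1e-12:
        theta = dict(start)
        theta.update(dict(zip(free, sol.x)))
        if "x0" in c.pins:
            theta["x0"] = c.pins["x0"]
        ssr_fin = 2.0 * float(sol.cost)
    else:
        theta = {"yb": yb0, "y0": y00, "tau": tau0, "x0": x00}
        ssr_fin = ssr0
        ok = True  # grid stage always yields a feasible solution

    if not ok:
        return FitResult(None, math.nan, math.nan, False, False, len(x0_grid))

    floor = noise_floor if noise_floor is not None else 1e-6 * scale
    identifiable = abs(theta["y0"]) >= floor
    raw = MonoExpParams(theta["yb"], theta["x0"], theta["y0"], theta["tau"])
    params = raw if identifiable else replace(raw, tau=math.nan)
    r2 = math.nan if sst == 0.0 else 1.0 - ssr_fin / sst
    return FitResult(params, r2, ssr_fin, True, identifiable, len(x0_grid),
                     raw_params=raw)


def fit_bi(t, y, constraints: FitConstraints | None = None, *,
           x1_step: float = 2.0, x2_step: float = 4.0,
           x1_extent: float = 40.0, x2_extent: float = 60.0,
           noise_floor: float | None = None, max_nfev: int = 500) -> FitResult:
    """Constrained NLLS fit of the two-component delayed exponential model.

    A coarse grid over the two delays (fitting the amplitudes in closed form
    and the two time constants by bounded 2-D search at each grid point) is
    followed by a polish of all seven parameters.  Defaults follow the
    combined-challenge convention: window 51-240 s, X1 > 60, X2 > 120.
    """
    c = constraints if constraints is not None else FitConstraints.bi_default()
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    tw, yw = _window_mask(t, y, c.window)
    if tw.size < 8:
        raise ValueError(f"need >= 8 points in the fit window, got {tw.size}")
    sst = float(np.sum((yw - yw.mean()) ** 2))
    span = c.window[1] - c.window[0]
    t1_lo, t1_hi = _tau_bounds(c, "tau1", span)
    t2_lo, t2_hi = _tau_bounds(c, "tau2", span)

    def delay_grid(name, step, extent, default_lo):
        if name in c.pins:
            return np.array([float(c.pins[name])])
        blo, bhi = c.bound(name)
        glo = blo if blo is not None else default_lo
        ghi = min(bhi if bhi is not None else glo + extent, tw[-1] - 2.0)
        return _grid(glo, ghi, step)

    x1_grid = delay_grid("x1", x1_step, x1_extent, tw[0])
    x2_grid = delay_grid("x2", x2_step, x2_extent, tw[0])

    def inner(x1, x2):
        dt1 = np.clip(tw - x1, 0.0, None)
        dt2 = np.clip(tw - x2, 0.0, None)

        def resid_tau(logtaus):
            g1 = -np.expm1(-dt1 / math.exp(logtaus[0]))
            g2 = -np.expm1(-dt2 / math.exp(logtaus[1]))
            coef, _ = _lin_solve(np.column_stack([np.ones_like(tw), g1, g2]), yw)
            return np.column_stack([np.ones_like(tw), g1, g2]) @ coef - yw

        start = np.log([max(t1_lo * 1.01, min(span / 6, t1_hi * 0.99)),
                        max(t2_lo * 1.01, min(span / 3, t2_hi * 0.99))])
        sol = least_squares(resid_tau, start,
                            bounds=(np.log([t1_lo, t2_lo]), np.log([t1_hi, t2_hi])),
                            method="trf", ftol=1e-12, xtol=1e-12, max_nfev=200)
        tau1, tau2 = np.exp(sol.x)
        g1 = -np.expm1(-dt1 / tau1)
        g2 = -np.expm1(-dt2 / tau2)
        coef, ssr = _lin_solve(np.column_stack([np.ones_like(tw), g1, g2]), yw)
        return ssr, coef, tau1, tau2

    best = None
    for x1 in x1_grid:
        for x2 in x2_grid:
            if x2 < x1:
                continue
            ssr, coef, tau1, tau2 = inner(float(x1), float(x2))
            if best is None or ssr < best[0]:
                best = (ssr, coef, tau1, tau2, float(x1), float(x2))
    if best is None:
        return FitResult(None, math.nan, math.nan, False, False, 0)
    ssr0, (yb0, y10, y20), tau10, tau20, x10, x20 = best

    free = ["yb", "y1", "tau1", "y2", "tau2"]
    free += [n for n in ("x1", "x2") if n not in c.pins]
    start = {"yb": yb0, "y1": y10, "tau1": tau10, "y2": y20, "tau2": tau20,
             "x1": x10, "x2": x20}
    lo_v, hi_v = [], []
    for name in free:
        if name == "tau1":
            blo, bhi = t1_lo, t1_hi
        elif name == "tau2":
            blo, bhi = t2_lo, t2_hi
        else:
            blo, bhi = c.bound(name)
        lo_v.append(blo if blo is not None else -np.inf)
        hi_v.append(bhi if bhi is not None else np.inf)
    x_start = np.clip([start[n] for n in free], lo_v, hi_v)

    def resid(theta):
        p = dict(start)
        p.update(dict(zip(free, theta)))
        for name, v in c.pins.items():
            p[name] = v
        dt1 = np.clip(tw - p["x1"], 0.0, None)
        dt2 = np.clip(tw - p["x2"], 0.0, None)
        return (p["yb"] + p["y1"] * -np.expm1(-dt1 / p["tau1"])
                + p["y2"] * -np.expm1(-dt2 / p["tau2"]) - yw)

    scale = max(float(np.std(yw)), abs(float(np.mean(yw))), 1.0)
    try:
        sol = least_squares(resid, x_start, bounds=(lo_v, hi_v), method="trf",
                            ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=max_nfev)
        ok = bool(np.all(np.isfinite(sol.x)))
    except Exception:
        sol, ok = None, False

    if sol is not None and ok and 2.0 * sol.cost <= ssr0 + 1e-12:
        theta = dict(start)
        theta.update(dict(zip(free, sol.x)))
        for name, v in c.pins.items():
            theta[name] = v
        ssr_fin = 2.0 * float(sol.cost)
    else:
        theta = start
        ssr_fin = ssr0

    floor = noise_floor if noise_floor is not None else 1e-6 * scale
    identifiable = max(abs(theta["y1"]), abs(theta["y2"])) >= floor
    raw = BiExpParams(theta["yb"], theta["x1"], theta["y1"], theta["tau1"],
                      theta["x2"], theta["y2"], theta["tau2"])
    params = raw if identifiable else replace(raw, tau1=math.nan, tau2=math.nan)
    r2 = math.nan if sst == 0.0 else 1.0 - ssr_fin / sst
    n_starts = sum(1 for a in x1_grid for b in x2_grid if b >= a)
    return FitResult(params, r2, ssr_fin, True, identifiable, n_starts,
                     raw_params=raw)
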