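"""Kinetics of a repressive histone mark under deposition and division dilution.

Model: the mark occupancy fraction m in [0, 1] obeys

    dm/dt = alpha * E * (1 - m) - delta * m - g * ln(2) * m

where E is enzyme abundance (optionally coupled to the growth rate g through
E = c0 + c1 * g), delta is enzymatic turnover, and g * ln(2) is the effective
continuous dilution rate produced by cell division (each division halves the
marked fraction when new histones arrive unmarked).  A discrete variant
integrates the division-free ODE between divisions and halves m at each
division time k / g.

The steady state of the continuous model is

    m* = alpha * E / (alpha * E + delta + g * ln 2)

which is constant in g under proportional coupling (c0 = 0, delta = 0) and
strictly decreasing in g when the enzyme fails to scale (fixed E, or affine
coupling with a reduced slope) — the two regimes the sweep helper exposes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

LN2 = float(np.log(2.0))

__all__ = [
    "MarkKineticsParams",
    "MarkTrajectory",
    "LinearFitResult",
    "steady_state_mark",
    "simulate_mark_dynamics",
    "sweep_growth_rates",
    "fit_steady_state_params",
    "fit_linear",
    "discrete_fixed_point",
]


@dataclass(frozen=True)
class MarkKineticsParams:
    """Deposition/turnover/coupling parameters.

    Either give the enzyme level directly (``enzyme``) or an affine coupling
    ``enzyme = c0 + c1 * growth_rate``.
    """

    alpha: float = 1.0            # deposition rate per unit enzyme per hour
    delta: float = 0.0            # mark turnover per hour
    growth_rate: float = 0.05     # divisions per cell per hour
    enzyme: float | None = None   # arbitrary units; overrides coupling if set
    c0: float = 0.0
    c1: float = 1.0
    m0: float = 0.0               # initial occupancy for simulations

    def __post_init__(self):
        if self.alpha < 0 or self.delta < 0 or self.growth_rate < 0:
            raise ValueError("alpha, delta and growth_rate must be >= 0")
        if not (0.0 <= self.m0 <= 1.0):
            raise ValueError("m0 must lie in [0, 1]")

    @property
    def E(self) -> float:
        e = self.enzyme if self.enzyme is not None else self.c0 + self.c1 * self.growth_rate
        if e < 0:
            raise ValueError("enzyme abundance must be >= 0")
        return e


@dataclass
class MarkTrajectory:
    times: np.ndarray
    m: np.ndarray
    division_times: np.ndarray | None = None


@dataclass
class LinearFitResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def steady_state_mark(params: MarkKineticsParams) -> float:
    """m* = alpha E / (alpha E + delta + g ln2)."""
    aE = params.alpha * params.E
    denom = aE + params.delta + params.growth_rate * LN2
    if denom == 0:
        raise ValueError("all rates zero: steady state undefined")
    return aE / denom


def discrete_fixed_point(params: MarkKineticsParams) -> float:
    """Pre-division fixed point of the halving variant.

    Between divisions m relaxes toward m_eq = aE / r with rate r = aE + delta;
    halving every T = 1/g gives the pre-division fixed point
    m_hat = m_eq (1 - exp(-rT)) / (1 - exp(-rT)/2).
    """
    if params.growth_rate <= 0:
        raise ValueError("discrete fixed point needs growth_rate > 0")
    r = params.alpha * params.E + params.delta
    T = 1.0 / params.growth_rate
    if r == 0:
        return 0.0
    m_eq = params.alpha * params.E / r
    decay = np.exp(-r * T)
    return float(m_eq * (1 - decay) / (1 - decay / 2))


def _rhs(m, aE, loss):
    return aE * (1.0 - m) - loss * m


def simulate_mark_dynamics(params: MarkKineticsParams, t_end: float,
                           dt: float = 0.01,
                           variant: str = "continuous") -> MarkTrajectory:
    """Integrate the mark ODE.

    ``continuous``: fixed-step RK4 on dm/dt = aE(1-m) - (delta + g ln2) m.
    ``discrete_division``: exact exponential relaxation of
    dm/dt = aE(1-m) - delta m between divisions, halving m at times k/g.
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be > 0")
    if variant not in ("continuous", "discrete_division"):
        raise ValueError(f"unknown variant {variant!r}")
    aE = params.alpha * params.E
    n_steps = int(np.ceil(t_end / dt))
    dt = t_end / n_steps  # effective step <= requested dt, lands on t_end
    times = np.linspace(0.0, t_end, n_steps + 1)
    m = np.empty(n_steps + 1)
    m[0] = params.m0

    if variant == "continuous":
        loss = params.delta + params.growth_rate * LN2
        for i in range(n_steps):
            y = m[i]
            k1 = _rhs(y, aE, loss)
            k2 = _rhs(y + 0.5 * dt * k1, aE, loss)
            k3 = _rhs(y + 0.5 * dt * k2, aE, loss)
            k4 = _rhs(y + dt * k3, aE, loss)
            m[i + 1] = y + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        m = np.clip(m, 0.0, 1.0)
        return MarkTrajectory(times=times, m=m)

    # discrete_division
    g = params.growth_rate
    if g <= 0:
        raise ValueError("discrete variant needs growth_rate > 0")
    T_div = 1.0 / g
    if dt >= T_div:
        raise ValueError("dt must be smaller than the division interval 1/g")
    r = aE + params.delta
    m_eq = aE / r if r > 0 else 0.0

    def relax(y, span):
        if r == 0:
            return y
        return m_eq + (y - m_eq) * np.exp(-r * span)

    division_times = np.arange(T_div, times[-1] + 1e-12, T_div)
    y = params.m0
    t_prev = 0.0
    next_div = T_div
    for i in range(n_steps):
        t_next = times[i + 1]
        t_cur = t_prev
        yy = y
        while next_div <= t_next + 1e-12:
            yy = relax(yy, next_div - t_cur)
            yy *= 0.5
            t_cur = next_div
            next_div += T_div
        yy = relax(yy, t_next - t_cur)
        m[i + 1] = yy
        y = yy
        t_prev = t_next
    m = np.clip(m, 0.0, 1.0)
    return MarkTrajectory(times=times, m=m, division_times=division_times)


def sweep_growth_rates(params: MarkKineticsParams, rates) -> dict:
    """Steady-state mark across growth rates under the params' coupling.

    Returns a dict with arrays g, E, m_star and a qualitative 'monotone'
    flag in {"increasing", "decreasing", "constant", "mixed"}.
    """
    rates = np.asarray(list(rates), dtype=float)
    if rates.size == 0 or np.any(rates <= 0):
        raise ValueError("growth rates must be positive")
    E = np.empty(rates.size)
    m_star = np.empty(rates.size)
    for i, g in enumerate(rates):
        p = replace(params, growth_rate=float(g))
        E[i] = p.E
        m_star[i] = steady_state_mark(p)
    order = np.argsort(rates)
    diffs = np.diff(m_star[order])
    tol = 1e-12
    if np.all(np.abs(diffs) <= tol):
        monotone = "constant"
    elif np.all(diffs > tol):
        monotone = "increasing"
    elif np.all(diffs < -tol):
        monotone = "decreasing"
    else:
        monotone = "mixed"
    return {"g": rates, "E": E, "m_star": m_star, "monotone": monotone}


def fit_steady_state_params(observations) -> dict:
    """Recover (alpha, delta) from (g, E, m) triplets by least squares.

    The steady-state relation linearises as (1/m - 1) E = delta/alpha +
    (ln2 / alpha) g, which provides the starting point; a bounded nonlinear
    refinement on the raw m scale follows.
    """
    obs = np.asarray(list(observations), dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 3:
        raise ValueError("observations must be (g, E, m) triplets")
    if obs.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    g, E, m = obs[:, 0], obs[:, 1], obs[:, 2]
    if np.ptp(g) == 0 and np.ptp(E) == 0:
        raise ValueError("degenerate design: no variation in g or E")

    # linearized init needs m strictly inside (0, 1); the refinement does not
    m_init = np.clip(m, 1e-6, 1 - 1e-6)
    y = (1.0 / m_init - 1.0) * E
    slope, intercept = np.polyfit(g, y, 1)
    alpha0 = LN2 / slope if slope > 0 else 1.0
    delta0 = max(intercept * alpha0, 0.0)

    def resid(theta):
        a, d = theta
        aE = a * E
        return aE / (aE + d + g * LN2) - m

    sol = optimize.least_squares(
        resid, x0=[max(alpha0, 1e-9), delta0],
        bounds=([1e-12, 0.0], [np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    alpha_hat, delta_hat = sol.x
    return {
        "alpha": float(alpha_hat),
        "delta": float(delta_hat),
        "residual_norm": float(np.linalg.norm(sol.fun)),
        "success": bool(sol.success),
    }


def fit_linear(x, y) -> LinearFitResult:
    """OLS line with R^2 and a two-sided t-test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = np.sum(resid**2)
    ss_tot = np.sum((y - ym) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    df = n - 2
    if ss_res == 0:
        p = 0.0
    else:
        se = np.sqrt(ss_res / df / sxx)
        tstat = slope / se
        p = float(2 * stats.t.sf(abs(tstat), df))
    if ss_tot == 0:
        r2 = 0.0
        p = 1.0
    return LinearFitResult(slope=float(slope), intercept=float(intercept),
                           r_squared=float(max(min(r2, 1.0), 0.0)), p_value=p)
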