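"""Stiff integration of the culture DAE and chemostat steady states.

The system is an ODE in ``(X, x1, y)`` with the ancillary vector ``x2``
eliminated algebraically (it is substituted into every rate law at compile
time), so a standard stiff ODE solver applies.  ``simulate`` produces a
dense :class:`TimeCourse` carrying states, fluxes and the derived growth
quantities; ``steady_state`` locates a chemostat fixed point by damped
long-time integration followed by a Newton polish of the right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import ConvergenceError, DomainError, IntegrationError
from .model import CultureState, FluxVector, KineticModel

__all__ = ["CultureConfig", "TimeCourse", "simulate", "steady_state"]


@dataclass
class CultureConfig:
    """Culture mode and solver settings.

    ``mode`` is "batch" (D = 0) or "chemostat" (D > 0).  Default tolerances
    (rtol 1e-8, atol 1e-10 on the mM scale) keep reported trajectories
    stable to roughly four digits, which the flux-correlation analyses
    need.
    """

    mode: str = "batch"
    D: float = 0.0
    y_feed: tuple[float, ...] = ()
    t_span: tuple[float, float] = (0.0, 10.0)
    output_grid: np.ndarray | None = None
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf

    def __post_init__(self):
        if self.mode not in ("batch", "chemostat"):
            raise DomainError(f"unknown culture mode {self.mode!r}")
        if self.mode == "batch" and self.D != 0.0:
            raise DomainError("batch culture requires D = 0")
        if self.mode == "chemostat" and self.D <= 0.0:
            raise DomainError("chemostat requires D > 0")
        if self.t_span[1] <= self.t_span[0]:
            raise DomainError("t_span must satisfy t1 > t0")
        if self.rtol <= 0 or self.atol <= 0:
            raise DomainError("rtol and atol must be > 0")

    def grid(self) -> np.ndarray:
        if self.output_grid is not None:
            return np.asarray(self.output_grid, dtype=float)
        return np.linspace(self.t_span[0], self.t_span[1], 201)


@dataclass
class TimeCourse:
    """Dense trajectory of states, fluxes and derived growth quantities."""

    times: np.ndarray
    states: pd.DataFrame          # columns: X, x1..., y...
    ancillary: pd.DataFrame       # columns: x2 names
    fluxes: pd.DataFrame          # columns: reaction names
    drains: pd.DataFrame          # columns: biomass precursors
    mu: np.ndarray
    v_atp: np.ndarray
    provenance: dict = field(default_factory=dict)

    def state_at(self, model: KineticModel, t: float) -> CultureState:
        """Culture state at the grid point nearest to ``t``."""
        i = int(np.argmin(np.abs(self.times - t)))
        u = self.states.iloc[i].to_numpy()
        return model.unpack_state(float(self.times[i]), u)

    def flux_at(self, t: float) -> FluxVector:
        i = int(np.argmin(np.abs(self.times - t)))
        row = self.fluxes.iloc[i]
        return FluxVector(tuple(row.index), row.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        """Single wide table (time, states, fluxes, mu, v_ATP) for export."""
        out = pd.concat(
            [
                pd.DataFrame({"time": self.times}),
                self.states.reset_index(drop=True),
                self.ancillary.add_prefix("x2_").reset_index(drop=True),
                self.fluxes.add_prefix("v_").reset_index(drop=True),
                self.drains.add_prefix("vBM_").reset_index(drop=True),
                pd.DataFrame({"mu": self.mu, "v_ATP": self.v_atp}),
            ],
            axis=1,
        )
        return out


def _observe(model, times, ys, D, yfeed, pvec):
    """Recompute x2, fluxes, drains, mu, v_ATP on the output grid."""
    fn = model.compiled["eval"]
    n = len(times)
    x2 = np.empty((n, len(model.x2_names)))
    v = np.empty((n, len(model.flux_names)))
    vbm = np.empty((n, len(model.biomass_precursors)))
    mu = np.empty(n)
    vatp = np.empty(n)
    for i in range(n):
        _, x2i, vi, vbmi, mui, vatpi = fn(times[i], ys[:, i], pvec, D, yfeed)
        x2[i] = x2i
        v[i] = vi
        vbm[i] = vbmi
        mu[i] = mui
        vatp[i] = vatpi
    return x2, v, vbm, mu, vatp


def simulate(
    model: KineticModel,
    config: CultureConfig,
    initial: CultureState | None = None,
    parameters=None,
) -> TimeCourse:
    """Integrate the culture from its initial state over ``config.t_span``.

    Fluxes, ancillary variables, biomass drains, mu and v_ATP are evaluated
    at every output-grid point from the integrated state, so every record
    of the returned :class:`TimeCourse` is internally consistent.
    """
    u0 = model.initial_state_vector() if initial is None else model.pack_state(initial)
    pvec = model._pvec(parameters)
    yfeed = np.zeros(len(model.y_names))
    if config.y_feed:
        yfeed[: len(config.y_feed)] = config.y_feed
    D = config.D
    fn = model.compiled["eval"]

    def rhs(t, u):
        return fn(t, u, pvec, D, yfeed)[0]

    grid = config.grid()
    sol = solve_ivp(
        rhs,
        config.t_span,
        u0,
        method=config.method,
        t_eval=grid,
        rtol=config.rtol,
        atol=config.atol,
        max_step=config.max_step,
    )
    if not sol.success:
        t_last = sol.t[-1] if sol.t.size else config.t_span[0]
        u_last = sol.y[:, -1] if sol.t.size else u0
        du = np.asarray(rhs(t_last, u_last))
        scale = np.abs(u_last) + config.atol
        worst = np.argsort(-np.abs(du) / scale)[:5]
        names = model.state_names()
        raise IntegrationError(
            f"integration failed at t = {t_last:.4g} h: {sol.message}",
            t_last=float(t_last),
            worst_components=[names[i] for i in worst],
        )
    x2, v, vbm, mu, vatp = _observe(model, sol.t, sol.y, D, yfeed, pvec)
    return TimeCourse(
        times=sol.t,
        states=pd.DataFrame(sol.y.T, columns=model.state_names()),
        ancillary=pd.DataFrame(x2, columns=model.x2_names),
        fluxes=pd.DataFrame(v, columns=model.flux_names),
        drains=pd.DataFrame(vbm, columns=model.biomass_precursors),
        mu=mu,
        v_atp=vatp,
        provenance={
            "model": model.name,
            "model_hash": model.checksum(),
            "mode": config.mode,
            "D": D,
            "y_feed": list(yfeed),
            "t_span": list(config.t_span),
            "method": config.method,
            "rtol": config.rtol,
            "atol": config.atol,
        },
    )


def steady_state(
    model: KineticModel,
    D: float,
    y_feed,
    init: CultureState | None = None,
    t_max: float = 400.0,
    tol: float = 1e-8,
    parameters=None,
):
    """Locate a chemostat steady state at dilution rate ``D``.

    Integrates for up to ``t_max`` hours (in stretches, until the scaled
    right-hand side stops moving), then polishes the point with a Newton
    root solve.  Returns ``(state, fluxes, info)`` where ``info`` reports
    the residual norm and whether the culture is growing (X > 0; at a
    growing fixed point mu = D up to the residual tolerance) or washed out.

    Raises :class:`ConvergenceError` if the residual never falls below
    ``tol`` on the scaled norm.
    """
    if D <= 0:
        raise DomainError("steady_state requires D > 0")
    pvec = model._pvec(parameters)
    yfeed = np.asarray(y_feed, dtype=float)
    if yfeed.shape != (len(model.y_names),):
        raise DomainError(
            f"y_feed must have {len(model.y_names)} entries ({model.y_names})"
        )
    fn = model.compiled["eval"]

    def rhs(t, u):
        return fn(t, u, pvec, D, yfeed)[0]

    def scaled_residual(u):
        du = np.asarray(rhs(0.0, u))
        return np.max(np.abs(du) / (np.abs(u) + 1e-6))

    u = model.initial_state_vector() if init is None else model.pack_state(init)
    t_done, stretch = 0.0, 25.0
    res = scaled_residual(u)
    while t_done < t_max and res > tol:
        sol = solve_ivp(rhs, (0.0, stretch), u, method="LSODA", rtol=1e-9, atol=1e-11)
        if not sol.success:
            raise IntegrationError(
                f"steady-state relaxation failed at t = {t_done + sol.t[-1]:.3g} h",
                t_last=t_done + float(sol.t[-1]),
            )
        u_new = sol.y[:, -1]
        t_done += stretch
        res_new = scaled_residual(u_new)
        if not np.isfinite(res_new):
            raise ConvergenceError("relaxation produced non-finite state", residual=res_new)
        u, res = u_new, res_new
    # Newton polish on the rhs; keeps the relaxed point if polishing drifts.
    polish = root(lambda w: np.asarray(rhs(0.0, w)), u, method="hybr", tol=1e-12)
    if polish.success:
        u_p = polish.x
        if scaled_residual(u_p) <= res + tol and np.all(u_p[0:1] >= -1e-9):
            u = u_p
            res = scaled_residual(u)
    if res > tol:
        raise ConvergenceError(
            f"steady state not reached: scaled residual {res:.3g} > tol {tol:.3g} "
            f"after {t_done:.0f} h simulated",
            residual=float(res),
        )
    # solver overshoot can leave tiny negative concentrations on washout paths
    if u.min() < -1e-5:
        raise ConvergenceError(
            f"steady state has negative component {u.min():.3g}", residual=float(res)
        )
    u = np.clip(u, 0.0, None)
    u = np.where(np.abs(u) < 1e-15, 0.0, u)
    state = model.unpack_state(0.0, u)
    _, _, v, _, mu, _ = fn(0.0, u, pvec, D, yfeed)
    fluxes = FluxVector(tuple(model.flux_names), np.asarray(v, float))
    growing = state.X > 1e-9
    info = {
        "residual": float(res),
        "growing": bool(growing),
        "mu": float(mu),
        "D": float(D),
        "washout": not growing,
    }
    return state, fluxes, info
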