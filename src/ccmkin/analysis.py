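"""Dynamic sensitivity, synthesis ratios and flux-agreement scoring.

Three quantitative procedures sit on top of the simulator:

* **Dynamic sensitivity** — the normalized response of the cell
  concentration to a small multiplicative parameter perturbation,

      s(X, p_j) = (X(t, p_j + dp_j) - X(t, p_j)) / dp_j * p_j / X(t, p_j),
      dp_j = eta * p_j,

  a one-sided (forward) finite difference with one full re-simulation per
  parameter, sampled at a fixed time.

* **Synthesis ratio** — the ratio of time-integrated, biomass-weighted flux
  of a reaction in a mutant versus wild type over each strain's growth
  phase:

      ratio = int_0^T_VM v_VM X/rho dt / int_0^T_WT v_WT X/rho dt.

  The cell-density constant rho cancels; a ratio of one means the
  perturbation leaves that reaction's total metabolite synthesis unchanged.

* **Pearson agreement** — sample correlation between simulated and measured
  flux panels, with a two-sided p-value from the exact t transform
  t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.  p-values are
  reported raw (no multiplicity correction), matching common practice for
  these panel comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, DomainError, EvaluationError
from .growth import growth_phase_end
from .model import KineticModel
from .simulate import CultureConfig, TimeCourse, simulate

__all__ = [
    "SensitivityResult",
    "dynamic_sensitivity",
    "synthesis_ratio",
    "synthesis_ratio_report",
    "AgreementScore",
    "pearson_flux_agreement",
    "compare_to_experiment",
]


@dataclass
class SensitivityResult:
    """Ranked sensitivities of the cell concentration to parameters."""

    table: pd.DataFrame  # columns: parameter, sensitivity, ok
    t_sample: float
    eta: float

    def top(self, n=10) -> pd.DataFrame:
        return self.table.head(n)

    def __getitem__(self, parameter: str) -> float:
        row = self.table[self.table["parameter"] == parameter]
        if row.empty:
            raise KeyError(parameter)
        return float(row["sensitivity"].iloc[0])


def dynamic_sensitivity(
    model: KineticModel,
    params: list[str],
    t_sample: float,
    eta: float = 0.01,
    config: CultureConfig | None = None,
) -> SensitivityResult:
    """Forward finite-difference sensitivity of X with respect to each
    parameter, sorted by absolute value (stable sort).

    A failed perturbed simulation flags its row (``ok = False``,
    sensitivity NaN) rather than silently dropping it.
    """
    if eta <= 0:
        raise DomainError("eta must be > 0")
    cfg = config or CultureConfig(t_span=(0.0, t_sample + 0.5))
    if not (cfg.t_span[0] <= t_sample <= cfg.t_span[1]):
        raise DomainError("t_sample outside the simulated span")
    grid = np.array([cfg.t_span[0], t_sample, cfg.t_span[1]])
    base_cfg = CultureConfig(
        mode=cfg.mode, D=cfg.D, y_feed=cfg.y_feed, t_span=cfg.t_span,
        output_grid=grid, method=cfg.method, rtol=cfg.rtol, atol=cfg.atol,
    )
    tc0 = simulate(model, base_cfg)
    i = int(np.argmin(np.abs(tc0.times - t_sample)))
    X0 = float(tc0.states["X"].iloc[i])
    if X0 <= 0:
        raise DomainError("unperturbed X(t_sample) must be > 0")
    rows = []
    for name in params:
        if name not in model.parameters:
            raise ContractError(f"unknown parameter {name!r}")
        p = model.parameters.value(name)
        dp = eta * p
        try:
            pert = model.parameters.with_values({name: p + dp})
            tc1 = simulate(model, base_cfg, parameters=pert)
            X1 = float(tc1.states["X"].iloc[i])
            s = (X1 - X0) / dp * p / X0
            rows.append((name, s, True))
        except (EvaluationError, Exception) as exc:  # noqa: BLE001
            if isinstance(exc, (KeyboardInterrupt, SystemExit)):
                raise
            rows.append((name, np.nan, False))
    df = pd.DataFrame(rows, columns=["parameter", "sensitivity", "ok"])
    df["_abs"] = df["sensitivity"].abs().fillna(-1.0)
    df = df.sort_values("_abs", ascending=False, kind="stable").drop(columns="_abs")
    df = df.reset_index(drop=True)
    return SensitivityResult(table=df, t_sample=t_sample, eta=eta)


def _biomass_weighted_integral(tc: TimeCourse, reaction: str, T: float, rho: float) -> float:
    if reaction not in tc.fluxes.columns:
        raise ContractError(f"reaction {reaction!r} absent from trajectory")
    mask = tc.times <= T + 1e-12
    if not mask.any():
        raise DomainError("trajectory does not cover the requested window")
    v = tc.fluxes[reaction].to_numpy()[mask]
    X = tc.states["X"].to_numpy()[mask]
    return float(np.trapezoid(v * X / rho, tc.times[mask]))


def synthesis_ratio(
    tc_wt: TimeCourse,
    tc_vm: TimeCourse,
    reaction: str,
    T_wt: float,
    T_vm: float,
    rho: float = 1.0,
) -> float:
    """Mutant/WT ratio of time-integrated biomass-weighted flux
    (trapezoidal quadrature on the output grid; rho cancels)."""
    den = _biomass_weighted_integral(tc_wt, reaction, T_wt, rho)
    if den == 0.0:
        raise ZeroDivisionError(
            f"WT integral of {reaction!r} is zero over [0, {T_wt}]; "
            "synthesis ratio undefined"
        )
    num = _biomass_weighted_integral(tc_vm, reaction, T_vm, rho)
    return num / den


def synthesis_ratio_report(
    tc_wt: TimeCourse,
    tc_vm: TimeCourse,
    reactions: list[str],
    rho: float = 1.0,
    glucose: str = "GLCex",
    frac: float = 0.01,
) -> pd.DataFrame:
    """Synthesis ratios for many reactions with operational growth-phase
    ends (glucose below ``frac`` of its initial value) per strain.

    Reactions whose WT integral vanishes get a NaN ratio and a note.
    """
    T_wt = growth_phase_end(tc_wt.times, tc_wt.states[glucose].to_numpy(), frac)
    T_vm = growth_phase_end(tc_vm.times, tc_vm.states[glucose].to_numpy(), frac)
    rows = []
    for r in reactions:
        try:
            ratio = synthesis_ratio(tc_wt, tc_vm, r, T_wt, T_vm, rho)
            rows.append((r, ratio, ""))
        except ZeroDivisionError:
            rows.append((r, np.nan, "WT integral zero"))
    df = pd.DataFrame(rows, columns=["reaction", "ratio", "note"])
    df.attrs["T_wt"] = T_wt
    df.attrs["T_vm"] = T_vm
    df.attrs["rho"] = rho
    return df


@dataclass
class AgreementScore:
    r: float
    p: float
    n: int

    def __post_init__(self):
        if self.n < 3:
            raise DomainError("Pearson agreement needs n >= 3 pairs")


def pearson_flux_agreement(sim, exp) -> AgreementScore:
    """Pearson r between paired simulated and experimental fluxes with a
    two-sided t-test p-value; raises on degenerate (zero-variance) input."""
    sim = np.asarray(sim, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if sim.shape != exp.shape or sim.ndim != 1:
        raise ContractError("flux vectors must be paired 1-d arrays")
    n = sim.size
    if n < 3:
        raise DomainError("need at least 3 paired fluxes")
    if np.std(sim) == 0 or np.std(exp) == 0:
        raise ZeroDivisionError("zero variance: correlation undefined")
    res = stats.pearsonr(sim, exp)
    return AgreementScore(r=float(res.statistic), p=float(res.pvalue), n=n)


def compare_to_experiment(
    tc: TimeCourse,
    exp_table: pd.DataFrame,
    flux_quantities: set[str] | None = None,
    time_tol: float = 0.05,
) -> dict:
    """Pair a simulated trajectory with experimental records.

    ``exp_table`` columns: strain, time_h, quantity, value[, sd].  Each
    record is matched to the nearest output-grid time (within
    ``time_tol`` h, else dropped as uncovered).  Quantities are state
    columns or reaction names.  Returns a dict with the paired table,
    per-quantity residual summaries, and an :class:`AgreementScore` per
    time point over the flux panel (when >= 3 fluxes are measured at that
    time).
    """
    rows, uncovered = [], []
    cols = set(tc.states.columns) | set(tc.fluxes.columns)
    for _, rec in exp_table.iterrows():
        q = rec["quantity"]
        if q not in cols:
            uncovered.append(q)
            continue
        i = int(np.argmin(np.abs(tc.times - rec["time_h"])))
        if abs(tc.times[i] - rec["time_h"]) > time_tol + 1e-12:
            uncovered.append(f"{q}@{rec['time_h']}")
            continue
        simval = float(
            tc.states[q].iloc[i] if q in tc.states.columns else tc.fluxes[q].iloc[i]
        )
        rows.append(
            (rec.get("strain", ""), float(rec["time_h"]), q, float(rec["value"]),
             simval, simval - float(rec["value"]))
        )
    paired = pd.DataFrame(
        rows, columns=["strain", "time_h", "quantity", "exp", "sim", "residual"]
    )
    flux_names = set(tc.fluxes.columns) if flux_quantities is None else flux_quantities
    scores = {}
    if not paired.empty:
        panel = paired[paired["quantity"].isin(flux_names)]
        for t, grp in panel.groupby("time_h"):
            if len(grp) >= 3:
                try:
                    scores[float(t)] = pearson_flux_agreement(
                        grp["sim"].to_numpy(), grp["exp"].to_numpy()
                    )
                except ZeroDivisionError:
                    pass
    summary = (
        paired.groupby("quantity")["residual"]
        .agg(["count", "mean", "std", lambda s: s.abs().max()])
        .rename(columns={"<lambda_0>": "max_abs"})
        if not paired.empty
        else pd.DataFrame()
    )
    return {
        "paired": paired,
        "residual_summary": summary,
        "flux_agreement": scores,
        "uncovered": sorted(set(uncovered)),
        "note": "p-values are raw; no multiple-comparison correction applied",
    }
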