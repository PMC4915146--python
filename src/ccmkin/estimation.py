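"""Constrained parameter estimation with a real-coded genetic algorithm.

The estimation problem is

    minimize    obj_fun(p)        (class-weighted distance from literature)
    subject to  constraint_fun(p) <= 0   (rule-based behavioural scores)

Search parameters fall into three classes: I (measured values available),
II (estimable from references), III (no quantitative information), with
penalty weights lambda1 > lambda2 > lambda3 >= 0 so that drastic changes to
well-measured parameters are unlikely to survive.  The per-parameter
deviation is a squared log-ratio, making multiplicative deviations
symmetric for constants that span decades.

Constraints are if-then rules scored on simulated trajectories (0 when the
behaviour is consistent with the data, a continuous positive violation
otherwise).  Candidates are ranked lexicographically: total violation
first, then objective, so any feasible individual beats any infeasible
one.

The search uses unimodal normal distribution crossover (UNDX) — children
are sampled around the midpoint of two parents with primary variance along
their difference vector and orthogonal variance set by a third parent's
distance from that line — under minimal gap generation (MGG): each step
replaces just two population slots, the family elite plus one
roulette-selected member, which preserves diversity while never losing the
best feasible individual.  Search runs in log-space for positive
parameters.  Candidate evaluations are independent (an injectable ``map``
enables concurrent evaluation); results are reduced in submission order so
runs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, DomainError
from .growth import growth_phase_end
from .model import KineticModel, ParameterSet
from .simulate import CultureConfig, simulate

__all__ = [
    "ObjectiveSpec",
    "ConstraintRule",
    "Scenario",
    "GAConfig",
    "objective",
    "evaluate_constraints",
    "undx_crossover",
    "mgg_step",
    "run_estimation",
    "EstimationResult",
]

FAILURE_PENALTY = 1e6


@dataclass
class ObjectiveSpec:
    """Penalty weights and the parameter subset entering the objective."""

    lambda1: float = 10.0
    lambda2: float = 1.0
    lambda3: float = 0.1

    def __post_init__(self):
        if not (self.lambda1 > self.lambda2 > self.lambda3 >= 0):
            raise DomainError("weights must satisfy lambda1 > lambda2 > lambda3 >= 0")

    def weight(self, pclass: str) -> float:
        return {"I": self.lambda1, "II": self.lambda2, "III": self.lambda3}[pclass]


def objective(p: ParameterSet, spec: ObjectiveSpec, names=None) -> float:
    """Class-weighted sum of squared log-ratios from literature anchors.

    Class I/II parameters must carry a reference value; Class III
    parameters without a reference contribute nothing.
    """
    total = 0.0
    for name in (names if names is not None else p.names()):
        e = p[name]
        if e.literature_value is None:
            if e.pclass in ("I", "II"):
                raise ContractError(
                    f"class {e.pclass} parameter {name!r} lacks a literature value"
                )
            continue
        if e.value <= 0 or e.literature_value <= 0:
            dev = (e.value - e.literature_value) ** 2
        else:
            dev = np.log(e.value / e.literature_value) ** 2
        total += spec.weight(e.pclass) * dev
    return float(total)


@dataclass(frozen=True)
class Scenario:
    """A named (strain x culture) simulation setting used by rules."""

    name: str
    model: KineticModel
    config: CultureConfig


@dataclass(frozen=True)
class ConstraintRule:
    """One if-then behavioural rule scored on a simulated trajectory.

    kinds:
      below / above   — quantity at ``time`` must be below/above ``value``
      deplete_window  — quantity falls below frac*initial inside [t_lo, t_hi]
      timeseries_rmse — RMSE of quantity against (times, values) <= tol
    Scores are continuous in the simulated quantities to guide the search.
    """

    id: str
    scenario: str
    kind: str
    quantity: str = ""
    time: float = 0.0
    value: float = 0.0
    frac: float = 0.01
    t_lo: float = 0.0
    t_hi: float = 0.0
    times: tuple = ()
    values: tuple = ()
    tol: float = 0.0
    #: divisor for timeseries_rmse scores; set to the series' typical
    #: magnitude to make multi-quantity fits scale-free
    scale: float = 1.0

    def score(self, tc) -> float:
        q = self.quantity

        def series(name):
            if name in tc.states.columns:
                return tc.states[name].to_numpy()
            if name in tc.fluxes.columns:
                return tc.fluxes[name].to_numpy()
            raise ContractError(f"rule {self.id}: unknown quantity {name!r}")

        if self.kind in ("below", "above"):
            i = int(np.argmin(np.abs(tc.times - self.time)))
            val = float(series(q)[i])
            viol = val - self.value if self.kind == "below" else self.value - val
            return max(0.0, viol)
        if self.kind == "deplete_window":
            t_dep = growth_phase_end(tc.times, series(q), self.frac)
            return max(0.0, self.t_lo - t_dep) + max(0.0, t_dep - self.t_hi)
        if self.kind == "timeseries_rmse":
            s = series(q)
            sim = np.interp(np.asarray(self.times, float), tc.times, s)
            rmse = float(np.sqrt(np.mean((sim - np.asarray(self.values, float)) ** 2)))
            return max(0.0, rmse / self.scale - self.tol)
        raise ContractError(f"rule {self.id}: unknown kind {self.kind!r}")


def evaluate_constraints(
    p: ParameterSet, rules: list[ConstraintRule], scenarios: dict[str, Scenario]
) -> np.ndarray:
    """One nonnegative score per rule (simulation failures map to a large
    finite penalty for every rule of the failing scenario)."""
    needed = {r.scenario for r in rules}
    missing = needed - set(scenarios)
    if missing:
        raise ContractError(f"rules reference undefined scenario(s) {sorted(missing)}")
    tcs: dict[str, object] = {}
    for name in sorted(needed):
        sc = scenarios[name]
        try:
            tcs[name] = simulate(sc.model, sc.config, parameters=p)
        except Exception as exc:  # noqa: BLE001 — failures are penalized
            if isinstance(exc, (KeyboardInterrupt, SystemExit)):
                raise
            tcs[name] = None
    out = np.empty(len(rules))
    for i, r in enumerate(rules):
        tc = tcs[r.scenario]
        out[i] = FAILURE_PENALTY if tc is None else r.score(tc)
    return out


# --------------------------------------------------------------------- #
# genetic algorithm
# --------------------------------------------------------------------- #
@dataclass
class GAConfig:
    population: int = 50
    children: int = 16
    steps: int = 300
    sigma_xi: float = 0.5
    sigma_eta: float = 0.35
    seed: int = 0
    map_fn: callable = field(default=map, repr=False)

    def __post_init__(self):
        if self.population < 4:
            raise DomainError("population must be >= 4")
        if self.children < 2:
            raise DomainError("need at least 2 children per MGG family")


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect out-of-bounds components back into [lo, hi]."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def undx_crossover(parent1, parent2, parent3, rng, lo=None, hi=None,
                   sigma_xi=0.5, sigma_eta=0.35):
    """UNDX child from three parents (search-space coordinates).

    The child is normal around the midpoint of parents 1 and 2: variance
    sigma_xi^2 along their difference, and sigma_eta^2 * D^2 / n in the
    orthogonal complement, where D is parent3's distance from the parent
    line.  Identical parents collapse the distribution onto the midpoint.
    """
    x1 = np.asarray(parent1, float)
    x2 = np.asarray(parent2, float)
    x3 = np.asarray(parent3, float)
    if not (x1.shape == x2.shape == x3.shape):
        raise ContractError("parents must share a common length")
    n = x1.size
    center = 0.5 * (x1 + x2)
    d = x2 - x1
    nd = np.linalg.norm(d)
    e = d / nd if nd > 0 else np.zeros(n)
    rel = x3 - x1
    orth = rel - (rel @ e) * e if nd > 0 else rel
    D = np.linalg.norm(orth)
    xi = rng.normal(0.0, sigma_xi)
    child = center + xi * d
    if D > 0 and n > 1:
        t = rng.normal(0.0, sigma_eta * D / np.sqrt(n), size=n)
        t -= (t @ e) * e
        child = child + t
    if lo is not None:
        child = _reflect(child, np.asarray(lo, float), np.asarray(hi, float))
    return child


def _lex_key(violation: float, obj: float) -> tuple:
    return (violation, obj)


def mgg_step(population, fitness, evaluate, config: GAConfig, rng, lo, hi):
    """One minimal-gap-generation step, in place.

    ``population`` is (N, n) search-space coordinates, ``fitness`` a list of
    (violation, objective) tuples.  Two parent slots are chosen at random;
    a family of UNDX children (third parent also random) is evaluated and
    the two slots are refilled with the family elite and one
    roulette-selected member.  Returns the number of evaluations spent.
    """
    N = len(population)
    i1, i2 = rng.choice(N, size=2, replace=False)
    children = []
    for _ in range(config.children):
        i3 = int(rng.integers(N))
        children.append(
            undx_crossover(
                population[i1], population[i2], population[i3], rng, lo, hi,
                config.sigma_xi, config.sigma_eta,
            )
        )
    child_fit = list(config.map_fn(evaluate, children))
    family = [population[i1], population[i2]] + children
    family_fit = [fitness[i1], fitness[i2]] + child_fit
    order = sorted(range(len(family)), key=lambda k: _lex_key(*family_fit[k]))
    best = order[0]
    rest = order[1:]
    # roulette on inverse lexicographic rank among the remainder
    weights = np.array([1.0 / (r + 2) for r in range(len(rest))])
    pick = rest[int(rng.choice(len(rest), p=weights / weights.sum()))]
    population[i1] = family[best]
    fitness[i1] = family_fit[best]
    population[i2] = family[pick]
    fitness[i2] = family_fit[pick]
    return len(children)


@dataclass
class EstimationResult:
    best_parameters: ParameterSet
    best_violation: float
    best_objective: float
    feasible: bool
    audit: pd.DataFrame
    seed: int
    evaluations: int


def run_estimation(
    model: KineticModel,
    search_names: list[str],
    objective_spec: ObjectiveSpec,
    rules: list[ConstraintRule],
    scenarios: dict[str, Scenario],
    ga_config: GAConfig,
    max_evaluations: int | None = None,
    feasibility_tol: float = 0.0,
) -> EstimationResult:
    """Estimate ``search_names`` of ``model.parameters`` under behavioural
    constraints.  Deterministic given ``ga_config.seed``; the audit table
    records per-step best/median scores and cumulative evaluations."""
    rng = np.random.default_rng(ga_config.seed)
    base = model.parameters
    entries = [base[n] for n in search_names]
    logspace = np.array([e.positive for e in entries])
    lo = np.array([e.bounds[0] for e in entries])
    hi = np.array([e.bounds[1] for e in entries])
    lo_t = np.where(logspace, np.log(np.maximum(lo, 1e-300)), lo)
    hi_t = np.where(logspace, np.log(hi), hi)

    def decode(z) -> ParameterSet:
        vals = np.where(logspace, np.exp(z), z)
        return base.with_values(dict(zip(search_names, vals)))

    def evaluate(z):
        p = decode(z)
        viol = evaluate_constraints(p, rules, scenarios) if rules else np.zeros(0)
        total_viol = float(np.sum(np.maximum(viol, 0.0)))
        return (total_viol, objective(p, objective_spec, names=search_names))

    N = ga_config.population
    population = [lo_t + rng.random(len(search_names)) * (hi_t - lo_t) for _ in range(N)]
    # seed one individual at the current (literature-anchored) values
    z0 = np.array([
        np.log(e.value) if lg else e.value for e, lg in zip(entries, logspace)
    ])
    population[0] = np.clip(z0, lo_t, hi_t)
    fitness = list(ga_config.map_fn(evaluate, population))
    evals = N
    audit_rows = []

    def best_index():
        return min(range(N), key=lambda k: _lex_key(*fitness[k]))

    budget = max_evaluations if max_evaluations is not None else np.inf
    for step in range(ga_config.steps):
        if evals >= budget:
            break
        evals += mgg_step(population, fitness, evaluate, ga_config, rng, lo_t, hi_t)
        b = best_index()
        med_obj = float(np.median([f[1] for f in fitness]))
        audit_rows.append(
            (step, evals, fitness[b][0], fitness[b][1], med_obj)
        )
    b = best_index()
    best_viol, best_obj = fitness[b]
    audit = pd.DataFrame(
        audit_rows,
        columns=["step", "evaluations", "best_violation", "best_objective", "median_objective"],
    )
    audit.attrs["seed"] = ga_config.seed
    return EstimationResult(
        best_parameters=decode(population[b]),
        best_violation=float(best_viol),
        best_objective=float(best_obj),
        feasible=bool(best_viol <= feasibility_tol),
        audit=audit,
        seed=ga_config.seed,
        evaluations=evals,
    )
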