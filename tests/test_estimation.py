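"""Objective, constraint rules, UNDX crossover and MGG search."""

import numpy as np
import pytest

from ccmkin.errors import ContractError, DomainError
from ccmkin.estimation import (
    ConstraintRule,
    GAConfig,
    ObjectiveSpec,
    Scenario,
    evaluate_constraints,
    mgg_step,
    objective,
    run_estimation,
    undx_crossover,
)
from ccmkin.fixtures import toy_model
from ccmkin.model import ParameterEntry, ParameterSet
from ccmkin.simulate import CultureConfig, simulate


def pset(**entries):
    return ParameterSet(
        {
            k: ParameterEntry(value=v[0], pclass=v[1],
                              literature_value=v[2] if len(v) > 2 else None)
            for k, v in entries.items()
        }
    )


class TestObjective:
    def test_zero_at_reference(self):
        p = pset(a=(2.0, "I", 2.0), b=(0.3, "II", 0.3), c=(9.0, "III"))
        assert objective(p, ObjectiveSpec()) == 0.0

    def test_class_weight_ordering(self):
        """The same multiplicative deviation costs strictly more on a Class
        I parameter than on a Class III parameter."""
        spec = ObjectiveSpec()
        p1 = pset(a=(4.0, "I", 2.0))
        p3 = pset(a=(4.0, "III", 2.0))
        assert objective(p1, spec) > objective(p3, spec)

    def test_matches_independent_transcription(self):
        spec = ObjectiveSpec(lambda1=7.0, lambda2=2.0, lambda3=0.5)
        rng = np.random.default_rng(13)
        entries, expected = {}, 0.0
        lam = {"I": 7.0, "II": 2.0, "III": 0.5}
        for i, cls in enumerate(["I", "II", "III"] * 3):
            ref = float(rng.uniform(0.5, 5))
            val = float(rng.uniform(0.5, 5))
            entries[f"p{i}"] = (val, cls, ref)
            expected += lam[cls] * np.log(val / ref) ** 2
        assert objective(pset(**entries), spec) == pytest.approx(expected, rel=1e-12)

    def test_class_three_without_reference_contributes_nothing(self):
        spec = ObjectiveSpec(lambda1=10, lambda2=1, lambda3=0.0)
        p = pset(a=(1.0, "I", 1.0), c=(1e4, "III"))
        assert objective(p, spec) == 0.0

    def test_missing_reference_for_class_one_is_error(self):
        p = ParameterSet({"a": ParameterEntry(value=1.0, pclass="II")})
        with pytest.raises(ContractError):
            objective(p, ObjectiveSpec())

    def test_weight_ordering_enforced(self):
        with pytest.raises(DomainError):
            ObjectiveSpec(lambda1=1.0, lambda2=2.0, lambda3=0.1)


class TestConstraintRules:
    @pytest.fixture()
    def scenario(self):
        m = toy_model()
        return {"batch": Scenario("batch", m, CultureConfig(
            t_span=(0.0, 12.0), rtol=1e-6, atol=1e-8))}

    def test_satisfied_rule_scores_zero(self, scenario):
        rule = ConstraintRule(id="glc", scenario="batch", kind="below",
                              quantity="Sex", time=12.0, value=0.5)
        m = scenario["batch"].model
        v = evaluate_constraints(m.parameters, [rule], scenario)
        assert v[0] == 0.0

    def test_violation_monotone_in_residual(self, scenario):
        m = scenario["batch"].model
        scores = []
        for thresh in (5.0, 1.0, 0.1):
            rule = ConstraintRule(id="g", scenario="batch", kind="below",
                                  quantity="Sex", time=2.0, value=thresh)
            scores.append(evaluate_constraints(m.parameters, [rule], scenario)[0])
        assert scores[0] < scores[1] < scores[2]

    def test_depletion_window_rule(self, scenario):
        m = scenario["batch"].model
        ok = ConstraintRule(id="w", scenario="batch", kind="deplete_window",
                            quantity="Sex", frac=0.01, t_lo=4.0, t_hi=12.0)
        bad = ConstraintRule(id="w2", scenario="batch", kind="deplete_window",
                             quantity="Sex", frac=0.01, t_lo=0.0, t_hi=1.0)
        v = evaluate_constraints(m.parameters, [ok, bad], scenario)
        assert v[0] == 0.0
        assert v[1] > 0.0

    def test_known_feasible_parameters_score_zero(self, scenario):
        """The generating parameters satisfy rules built from their own
        simulation output."""
        m = scenario["batch"].model
        tc = simulate(m, scenario["batch"].config)
        times = (1.0, 4.0, 8.0)
        vals = tuple(np.interp(times, tc.times, tc.states["X"].to_numpy()))
        rule = ConstraintRule(id="fit", scenario="batch", kind="timeseries_rmse",
                              quantity="X", times=times, values=vals, tol=1e-6)
        v = evaluate_constraints(m.parameters, [rule], scenario)
        assert v[0] == 0.0

    def test_undefined_scenario_rejected(self, scenario):
        rule = ConstraintRule(id="x", scenario="chemostat", kind="below",
                              quantity="Sex", time=1.0, value=1.0)
        with pytest.raises(ContractError):
            evaluate_constraints(scenario["batch"].model.parameters, [rule], scenario)


class TestUndx:
    def test_identical_parents_collapse_to_the_point(self):
        rng = np.random.default_rng(0)
        x = np.array([1.0, 2.0, 3.0])
        child = undx_crossover(x, x, x, rng)
        np.testing.assert_array_equal(child, x)

    def test_children_centred_on_parent_midpoint(self):
        """Empirical mean of many children lies within 3 standard errors of
        the parents' midpoint, componentwise."""
        rng = np.random.default_rng(42)
        n = 5
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        x3 = rng.normal(size=n)
        N = 20000
        kids = np.array([undx_crossover(x1, x2, x3, rng) for _ in range(N)])
        mid = 0.5 * (x1 + x2)
        se = kids.std(axis=0, ddof=1) / np.sqrt(N)
        assert np.all(np.abs(kids.mean(axis=0) - mid) < 3 * se)

    def test_primary_variance_along_parent_axis(self):
        rng = np.random.default_rng(1)
        x1 = np.zeros(4)
        x2 = np.array([2.0, 0, 0, 0])
        x3 = np.array([1.0, 1.0, 0, 0])
        kids = np.array([undx_crossover(x1, x2, x3, rng) for _ in range(5000)])
        # variance along the difference axis is sigma_xi^2 * |d|^2
        assert kids[:, 0].std() == pytest.approx(0.5 * 2.0, rel=0.1)
        # orthogonal variance scales with D/sqrt(n)
        assert kids[:, 1].std() == pytest.approx(0.35 * 1.0 / 2.0, rel=0.1)

    def test_bounds_respected_after_reflection(self):
        rng = np.random.default_rng(3)
        lo = np.zeros(3)
        hi = np.ones(3)
        for _ in range(500):
            child = undx_crossover(
                rng.random(3), rng.random(3), rng.random(3), rng, lo, hi
            )
            assert np.all(child >= lo) and np.all(child <= hi)


def sphere_eval(z):
    return (0.0, float(np.sum(np.asarray(z) ** 2)))


class TestMgg:
    def test_uniform_population_score_unchanged(self):
        rng = np.random.default_rng(0)
        cfg = GAConfig(population=8, children=6, seed=0)
        pop = [np.ones(3) for _ in range(8)]
        fit = [sphere_eval(z) for z in pop]
        mgg_step(pop, fit, sphere_eval, cfg, rng, -5 * np.ones(3), 5 * np.ones(3))
        assert all(f == (0.0, 3.0) for f in fit)

    def test_sphere_minimisation_converges(self):
        """Best score is non-increasing and drops below 1e-3 of its initial
        value within 200 MGG steps on the 5-d sphere."""
        rng = np.random.default_rng(7)
        n = 5
        lo, hi = -5 * np.ones(n), 5 * np.ones(n)
        cfg = GAConfig(population=30, children=10, seed=7)
        pop = [lo + rng.random(n) * (hi - lo) for _ in range(30)]
        fit = [sphere_eval(z) for z in pop]
        best0 = min(f[1] for f in fit)
        trace = []
        for _ in range(200):
            mgg_step(pop, fit, sphere_eval, cfg, rng, lo, hi)
            trace.append(min(f[1] for f in fit))
        assert all(b <= a + 1e-15 for a, b in zip(trace, trace[1:]))  # elitism
        assert trace[-1] < 1e-3 * best0

    def test_feasible_ranks_above_infeasible(self):
        """Lexicographic ordering: any feasible individual beats any
        infeasible one regardless of objective."""
        rng = np.random.default_rng(5)
        cfg = GAConfig(population=4, children=4, seed=5)

        def eval_fn(z):
            z = np.asarray(z)
            viol = max(0.0, z[0])          # feasible iff z0 <= 0
            return (viol, float(np.sum(z**2)))

        lo, hi = -2 * np.ones(2), 2 * np.ones(2)
        pop = [np.array([-1.0, 1.5]), np.array([1.0, 0.0]),
               np.array([0.5, 0.1]), np.array([-0.1, 1.9])]
        fit = [eval_fn(z) for z in pop]
        for _ in range(50):
            mgg_step(pop, fit, eval_fn, cfg, rng, lo, hi)
        best = min(fit, key=lambda f: f)
        assert best[0] == 0.0  # the incumbent best is feasible


class TestRunEstimation:
    def make_problem(self):
        m = toy_model()
        sc = {"batch": Scenario("batch", m, CultureConfig(
            t_span=(0.0, 12.0), output_grid=np.linspace(0, 12, 25),
            rtol=1e-6, atol=1e-8))}
        tc = simulate(m, sc["batch"].config)
        times = tuple(np.linspace(0.5, 11.5, 12))
        rules = [
            ConstraintRule(id=f"fit_{q}", scenario="batch", kind="timeseries_rmse",
                           quantity=q, times=times,
                           values=tuple(np.interp(times, tc.times, tc.states[q])),
                           tol=0.0)
            for q in ("X", "Sex", "M")
        ]
        return m, sc, rules

    def test_same_seed_bit_identical_audit(self):
        m, sc, rules = self.make_problem()
        names = ["v_Upt_max", "k_Cat_cat"]
        kw = dict(
            model=m, search_names=names, objective_spec=ObjectiveSpec(),
            rules=rules, scenarios=sc,
        )
        a = run_estimation(ga_config=GAConfig(population=6, children=4, steps=5, seed=11), **kw)
        b = run_estimation(ga_config=GAConfig(population=6, children=4, steps=5, seed=11), **kw)
        assert a.audit.equals(b.audit)
        assert a.best_violation == b.best_violation
        c = run_estimation(ga_config=GAConfig(population=6, children=4, steps=5, seed=12), **kw)
        assert not a.audit.equals(c.audit)

    def test_budget_and_flagging(self):
        m, sc, rules = self.make_problem()
        res = run_estimation(
            m, ["v_Upt_max"], ObjectiveSpec(), rules, sc,
            GAConfig(population=6, children=4, steps=50, seed=1),
            max_evaluations=20, feasibility_tol=1e-9,
        )
        assert res.evaluations <= 24  # budget honoured (last family may finish)
        assert isinstance(res.feasible, bool)
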