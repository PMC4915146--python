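"""Core model machinery: ancillary algebra, rate laws, mass balances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccmkin.errors import DomainError, ModelDefinitionError
from ccmkin.model import (
    CultureState,
    GrowthSpec,
    KineticModel,
    ParameterEntry,
    ParameterSet,
    RateLaw,
    Species,
    compute_ancillary,
    compute_fluxes,
    mass_balance_rhs,
)


def state_of(model, x1=None, y=None, X=0.5, t=0.0):
    x1 = np.asarray(x1 if x1 is not None else
                    [model.initial_values[n] for n in model.x1_names], float)
    y = np.asarray(y if y is not None else
                   [model.initial_values[n] for n in model.y_names], float)
    return CultureState(t, X, x1, compute_ancillary(model, x1, y), y)


# --------------------------------------------------------------------- #
# ancillary algebra
# --------------------------------------------------------------------- #
class TestAncillary:
    def test_no_ligand_no_complex(self, ecoli):
        """With zero cAMP the Crp-cAMP complex is zero and free Crp equals
        the total."""
        x1 = np.array([ecoli.initial_values[n] for n in ecoli.x1_names])
        x1[ecoli.x1_names.index("cAMP")] = 0.0
        x2 = dict(zip(ecoli.x2_names, compute_ancillary(ecoli, x1, [20.0, 0.0])))
        assert x2["Crp_cAMP"] == 0.0
        assert x2["Crp"] == ecoli.parameters.value("Crp_total")

    def test_half_saturation_single_site(self, toy):
        """complex = T*L/(L+K) gives T/2 at L = K."""
        K = toy.parameters.value("K_T_M")
        T = toy.parameters.value("T_tot")
        x2 = dict(zip(toy.x2_names, compute_ancillary(toy, [K, 0.005], [5.0])))
        assert x2["T_M"] == pytest.approx(T / 2, rel=1e-12)

    def test_binding_constant_inflation_silences_complex(self, ecoli):
        """Inflating K_Cra_FBP 1e5-fold drops the complex below 1e-4 of its
        baseline at the same finite FBP level."""
        x1 = np.array([ecoli.initial_values[n] for n in ecoli.x1_names])
        y = np.array([20.0, 0.0])
        base = dict(zip(ecoli.x2_names, compute_ancillary(ecoli, x1, y)))["Cra_FBP"]
        inflated = ecoli.parameters.with_scaled({"K_Cra_FBP": 1e5})
        new = dict(zip(ecoli.x2_names,
                       compute_ancillary(ecoli, x1, y, parameters=inflated)))["Cra_FBP"]
        assert base > 0
        assert new < 1e-4 * base

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.0, 50.0), st.floats(0.0, 20.0), st.floats(0.0, 20.0))
    def test_tf_conservation(self, camp, fbp, pyr):
        """Free + complexed TF equals the constant total at any state."""
        ecoli = load_once()
        x1 = np.array([ecoli.initial_values[n] for n in ecoli.x1_names])
        for name, val in (("cAMP", camp), ("FBP", fbp), ("PYR", pyr)):
            x1[ecoli.x1_names.index(name)] = val
        x2 = dict(zip(ecoli.x2_names, compute_ancillary(ecoli, x1, [10.0, 1.0])))
        for tf, cplx, total in (
            ("Crp", "Crp_cAMP", "Crp_total"),
            ("Cra", "Cra_FBP", "Cra_total"),
            ("PdhR", "PdhR_PYR", "PdhR_total"),
        ):
            tot = ecoli.parameters.value(total)
            assert x2[tf] + x2[cplx] == pytest.approx(tot, rel=1e-10)

    def test_negative_input_rejected(self, toy):
        with pytest.raises(DomainError):
            compute_ancillary(toy, [-0.1, 0.005], [5.0])


_CACHE = {}


def load_once():
    if "ecoli" not in _CACHE:
        from ccmkin.ecoli import load_ecoli_model

        _CACHE["ecoli"] = load_ecoli_model()
    return _CACHE["ecoli"]


# --------------------------------------------------------------------- #
# flux evaluation
# --------------------------------------------------------------------- #
class TestFluxes:
    def test_no_enzyme_no_flux(self, ecoli):
        x1 = np.array([ecoli.initial_values[n] for n in ecoli.x1_names])
        x1[ecoli.x1_names.index("E_Pyk")] = 0.0
        st_ = state_of(ecoli, x1=x1)
        assert compute_fluxes(ecoli, st_)["Pyk"] == 0.0

    def test_michaelis_menten_half_saturation(self, toy):
        """A pure MM law returns Vmax/2 at substrate = Km."""
        Km = toy.parameters.value("K_Cat_M")
        E = 0.002
        st_ = state_of(toy, x1=[Km, E], y=[5.0])
        vmax = toy.parameters.value("k_Cat_cat") * E
        assert compute_fluxes(toy, st_)["Cat"] == pytest.approx(vmax / 2, rel=1e-12)

    def test_full_model_matches_symbolic_reevaluation(self, ecoli):
        """Every shipped rate law agrees with an independent sympy
        evaluation of its expression at the initial state (1e-6 relative)."""
        import sympy

        st_ = ecoli.initial_culture_state()
        fluxes = compute_fluxes(ecoli, st_)
        env = {}
        env.update({n: v for n, v in zip(ecoli.x1_names, st_.x1)})
        env.update({n: v for n, v in zip(ecoli.y_names, st_.y)})
        env.update({k: e.value for k, e in ecoli.parameters.items()})
        for name, expr in ecoli.ancillary_rules:
            env[name] = float(sympy.sympify(expr).evalf(subs=env))
        for law in ecoli.rate_laws:
            expected = float(sympy.sympify(law.expression).evalf(subs=env))
            assert fluxes[law.name] == pytest.approx(expected, rel=1e-6, abs=1e-12), law.name

    def test_knockout_zero_flux_every_reaction(self, ecoli):
        """Knocking out any gene forces its reaction flux to exactly zero."""
        from ccmkin.perturbation import apply_knockout

        st0 = ecoli.initial_culture_state()
        for law in ecoli.rate_laws:
            if law.gene is None:
                continue
            ko = apply_knockout(ecoli, law.gene)
            st_ = ko.unpack_state(0.0, ko.pack_state(st0))
            assert compute_fluxes(ko, st_)[law.name] == 0.0, law.name

    def test_enzyme_linear_laws_are_homogeneous(self, ecoli):
        """Doubling the catalysing enzyme concentration doubles the flux for
        every enzyme-linear rate law."""
        base = ecoli.initial_culture_state()
        v0 = compute_fluxes(ecoli, base)
        enzyme_linear = [
            law for law in ecoli.rate_laws
            if law.enzyme in set(ecoli.proteins) and law.name != "Pts4"
        ]
        assert len(enzyme_linear) >= 20
        for law in enzyme_linear:
            x1 = base.x1.copy()
            i = ecoli.x1_names.index(law.enzyme)
            x1[i] *= 2.0
            st_ = state_of(ecoli, x1=x1, y=base.y)
            assert compute_fluxes(ecoli, st_)[law.name] == pytest.approx(
                2.0 * v0[law.name], rel=1e-12
            ), law.name


# --------------------------------------------------------------------- #
# mass balance
# --------------------------------------------------------------------- #
class TestMassBalance:
    def test_no_cells_no_uptake(self, monod):
        st_ = state_of(monod, y=[4.0], X=0.0)
        du = mass_balance_rhs(monod, st_, D=0.3, y_feed=[10.0])
        assert du[0] == 0.0
        assert du[1] == pytest.approx(0.3 * (10.0 - 4.0), rel=1e-12)

    def test_batch_growth_positive(self, monod):
        st_ = state_of(monod, y=[10.0], X=0.1)
        du = mass_balance_rhs(monod, st_, D=0.0)
        assert du[0] > 0

    def test_toy_rhs_matches_closed_form(self, toy):
        """Hand-written closed form of the toy network at random states."""
        p = {k: e.value for k, e in toy.parameters.items()}
        rng = np.random.default_rng(42)
        for _ in range(10):
            M, E, Sex, X = rng.uniform(0.01, 5.0, size=4)
            st_ = state_of(toy, x1=[M, E], y=[Sex], X=X)
            du = mass_balance_rhs(toy, st_)
            v_upt = p["v_Upt_max"] * Sex / (Sex + p["K_Upt_S"]) / (1 + M / p["K_Upt_M"])
            v_cat = p["k_Cat_cat"] * E * M / (M + p["K_Cat_M"])
            mu = p["k_mu"] * v_cat
            t_m = p["T_tot"] * M / (M + p["K_T_M"])
            syn = p["k_s_E"] * (p["b_E"] + (1 - p["b_E"]) * t_m / (t_m + p["K_g_E"]))
            expect = [
                mu * X,
                p["rho_cyt"] * (v_upt - v_cat) - mu * M,
                syn - mu * E,
                -X * v_upt,
            ]
            np.testing.assert_allclose(du, expect, rtol=1e-12)

    def test_negative_dilution_rejected(self, toy):
        with pytest.raises(DomainError):
            mass_balance_rhs(toy, state_of(toy), D=-0.1)


# --------------------------------------------------------------------- #
# definition validation
# --------------------------------------------------------------------- #
class TestDefinitionErrors:
    def test_unresolved_symbol_is_named(self):
        with pytest.raises(ModelDefinitionError, match="K_missing"):
            KineticModel(
                species=[Species("A", "metabolite"), Species("Sx", "extracellular")],
                rate_laws=[RateLaw("R", "K_missing * A", {"A": -1})],
                ancillary_rules=[],
                protein_balances=[],
                biomass_precursors=[],
                parameters=ParameterSet({}),
                initial_state={"X": 0.1, "A": 1.0, "Sx": 1.0},
                growth=GrowthSpec("expression", "0.1"),
            )

    def test_class_one_requires_literature_value(self):
        with pytest.raises(ModelDefinitionError):
            ParameterEntry(value=1.0, pclass="I")

    def test_bounds_ordering_enforced(self):
        with pytest.raises(ModelDefinitionError):
            ParameterEntry(value=1.0, bounds=(2.0, 1.0))
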