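"""Self-contained toy models and synthetic experimental tables.

These fixtures exercise every operation of the package without external
data: a minimal regulated uptake/catabolism network (one TF, one allosteric
effector), a textbook Monod chemostat with a closed-form steady state, and
a constant-growth exponential model with an analytic sensitivity.  The
synthetic "experimental" tables mimic the layout of re-encoded batch
culture data files (strain, time_h, quantity, value, sd).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import (
    GrowthSpec,
    KineticModel,
    ParameterEntry,
    ParameterSet,
    ProteinBalance,
    RateLaw,
    Species,
)
from .simulate import CultureConfig, TimeCourse, simulate

__all__ = [
    "toy_model",
    "monod_model",
    "exponential_model",
    "generate_fixtures",
    "FixtureSet",
]


def _p(value, pclass="III", lit=None, bounds=(1e-6, 1e6), units=""):
    return ParameterEntry(
        value=value, pclass=pclass, literature_value=lit, bounds=bounds, units=units
    )


def toy_model(**overrides) -> KineticModel:
    """Regulated toy network: substrate uptake with product inhibition and a
    TF-controlled catabolic enzyme.

    Species: extracellular substrate Sex, intracellular metabolite M,
    enzyme E.  The TF T binds M (complex T_M = T_tot * M / (M + K_T_M));
    the complex activates expression of E.  Uptake is allosterically
    inhibited by M.  Growth is proportional to the catabolic flux.

    Keyword overrides replace parameter values (e.g. ``k_Cat_cat=3.0``).
    """
    species = [
        Species("M", "metabolite"),
        Species("E", "enzyme"),
        Species("Sex", "extracellular"),
    ]
    params = ParameterSet(
        {
            "v_Upt_max": _p(8.0, "II", lit=8.0, units="mmol/gDW/h"),
            "K_Upt_S": _p(0.1, "I", lit=0.1, units="mM"),
            "K_Upt_M": _p(4.0, units="mM"),
            "k_Cat_cat": _p(400.0, "II", lit=400.0, units="1/h"),
            "K_Cat_M": _p(1.0, "I", lit=1.0, units="mM"),
            "T_tot": _p(0.01, "I", lit=0.01, units="mM"),
            "K_T_M": _p(0.5, units="mM"),
            "k_s_E": _p(0.02, units="mM/h"),
            "b_E": _p(0.15, bounds=(1e-3, 1.0)),
            "K_g_E": _p(0.004, units="mM"),
            "k_mu": _p(0.075, "II", lit=0.075, units="gDW/mmol"),
            "rho_cyt": _p(1.0, "I", lit=1.0, units="gDW/L"),
        }
    )
    if overrides:
        params = params.with_values(overrides)
    laws = [
        RateLaw(
            "Upt",
            "v_Upt_max * Sex / (Sex + K_Upt_S) / (1 + M / K_Upt_M)",
            stoichiometry={"Sex": -1.0, "M": 1.0},
            gene="upt",
        ),
        RateLaw(
            "Cat",
            "k_Cat_cat * E * M / (M + K_Cat_M)",
            stoichiometry={"M": -1.0},
            enzyme="E",
            gene="cat",
        ),
    ]
    ancillary = [
        ("T_M", "T_tot * M / (M + K_T_M)"),
        ("T", "T_tot - T_M"),
    ]
    balances = [
        ProteinBalance("E", "k_s_E * (b_E + (1 - b_E) * T_M / (T_M + K_g_E))"),
    ]
    return KineticModel(
        species=species,
        rate_laws=laws,
        ancillary_rules=ancillary,
        protein_balances=balances,
        biomass_precursors=[],
        parameters=params,
        initial_state={"X": 0.01, "M": 0.1, "E": 0.005, "Sex": 20.0},
        growth=GrowthSpec(mode="expression", expression="k_mu * v_Cat"),
        name="toy",
    )


def monod_model(mu_max=0.8, K_S=0.5, Y=0.1) -> KineticModel:
    """Textbook chemostat: Monod growth on a single substrate.

    The chemostat steady state is closed-form: S* = K_S D / (mu_max - D),
    X* = Y (S_feed - S*); washout for D >= mu_max S_f/(S_f+K_S).
    """
    species = [Species("Sex", "extracellular")]
    params = ParameterSet(
        {
            "mu_max": _p(mu_max, "I", lit=mu_max, units="1/h"),
            "K_S": _p(K_S, "I", lit=K_S, units="mM"),
            "Y_X": _p(Y, "II", lit=Y, units="gDW/mmol"),
        }
    )
    laws = [
        RateLaw(
            "Upt",
            "(mu_max / Y_X) * Sex / (Sex + K_S)",
            stoichiometry={"Sex": -1.0},
        )
    ]
    return KineticModel(
        species=species,
        rate_laws=laws,
        ancillary_rules=[],
        protein_balances=[],
        biomass_precursors=[],
        parameters=params,
        initial_state={"X": 0.05, "Sex": 10.0},
        growth=GrowthSpec(mode="expression", expression="Y_X * v_Upt"),
        name="monod",
    )


def exponential_model(mu0=0.4) -> KineticModel:
    """Constant specific growth rate: X(t) = X0 exp(mu0 t).

    The relative sensitivity of X to mu0 at time t is mu0*t exactly, which
    anchors the finite-difference sensitivity oracle.  The parameter
    ``k_dead`` is wired to nothing and must report zero sensitivity.
    """
    species = [Species("Sex", "extracellular")]
    params = ParameterSet(
        {
            "mu0": _p(mu0, "I", lit=mu0, units="1/h"),
            "k_dead": _p(1.0, units=""),
        }
    )
    laws = [RateLaw("Null", "0 * Sex", stoichiometry={})]
    return KineticModel(
        species=species,
        rate_laws=laws,
        ancillary_rules=[],
        protein_balances=[],
        biomass_precursors=[],
        parameters=params,
        initial_state={"X": 0.02, "Sex": 1.0},
        growth=GrowthSpec(mode="expression", expression="mu0"),
        name="exponential",
    )


class FixtureSet:
    """Toy model plus synthetic experimental tables generated from it."""

    def __init__(self, model, true_parameters, timecourse_table, flux_table, seed, noise_sd):
        self.model = model
        self.true_parameters = true_parameters
        self.timecourse_table = timecourse_table
        self.flux_table = flux_table
        self.seed = seed
        self.noise_sd = noise_sd


def generate_fixtures(seed: int = 0, noise_sd: float = 0.0, t_end: float = 12.0) -> FixtureSet:
    """Simulate the toy model at its true parameters and emit noisy
    "experimental" tables (deterministic given ``seed``; ``noise_sd`` is a
    relative Gaussian noise level, 0 reproduces the simulation exactly)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    model = toy_model()
    grid = np.linspace(0.0, t_end, 25)
    tc = simulate(model, CultureConfig(t_span=(0.0, t_end), output_grid=grid))
    rng = np.random.default_rng(seed)

    def noisy(v):
        v = np.asarray(v, float)
        return v * (1.0 + noise_sd * rng.standard_normal(v.shape))

    rows = []
    for qty in ("X", "Sex", "M"):
        vals = noisy(tc.states[qty].to_numpy())
        for t, v in zip(tc.times, vals):
            rows.append(("toy_wt", float(t), qty, float(v), noise_sd * abs(v)))
    ts_table = pd.DataFrame(rows, columns=["strain", "time_h", "quantity", "value", "sd"])

    frows = []
    for rxn in model.flux_names:
        vals = noisy(tc.fluxes[rxn].to_numpy())
        for t, v in zip(tc.times, vals):
            frows.append(("toy_wt", float(t), rxn, float(v), noise_sd * abs(v)))
    flux_table = pd.DataFrame(frows, columns=["strain", "time_h", "quantity", "value", "sd"])
    true_parameters = {k: e.value for k, e in model.parameters.items()}
    return FixtureSet(model, true_parameters, ts_table, flux_table, seed, noise_sd)
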