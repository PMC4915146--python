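"""ATP-flux growth law and biomass precursor drains.

The specific growth rate is obtained from the total specific ATP production
flux: oxidative phosphorylation of the NADH and FADH2 produced by central
metabolism (weighted by the two P/O ratios) plus the substrate-level
phosphorylation terms of glycolysis, the TCA cycle and acetate exchange,
minus the ATP-consuming reactions (Glk, Pfk, Pps, Acs, Pck, AceK, Cya):

    v_ATP = OP_NADH + OP_FADH2 - v_Glk - v_Pfk + v_Gapdh + v_Pyk - v_Pps
            + v_Ack - v_Acs + v_akgdh - v_Pck - v_AceK_ki - v_Cya
    OP_NADH  = (v_Gapdh + v_Pdh + v_akgdh + v_Mdh) * (P/O)
    OP_FADH2 = v_Sdh * (P/O)'
    mu       = k_ATP * v_ATP

mu is a pure linear function of v_ATP with no floor or ceiling; a transient
negative ATP balance yields decay, which is what produces the slow biomass
decline after substrate exhaustion.

Biomass formation drains twelve precursor metabolites with first-order
kinetics, weighted by which carbon source is currently available:

    v_BM,m = (alpha_GLC * k_BM_GLC_m + alpha_ACE * k_BM_ACE_m) * [m]
    alpha_GLC = GLC_ex / (GLC_ex + K_Pts_GLC)
    alpha_ACE = ACE_ex / (ACE_ex + K_Acs_ACE) * (1 - alpha_GLC)

so that glucose, when present, represses acetate-driven biomass synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DomainError
from .model import ATP_DIRECT, ATP_FADH2, ATP_NADH, FluxVector, ParameterSet

__all__ = [
    "PRECURSORS",
    "GrowthParameters",
    "total_atp_flux",
    "specific_growth_rate",
    "carbon_source_weights",
    "biomass_drain_fluxes",
]

#: The twelve precursor metabolites feeding biomass synthesis.
PRECURSORS = (
    "G6P", "F6P", "GAP", "PEP", "PYR", "AcCoA",
    "aKG", "SUC", "FUM", "OAA", "R5P", "E4P",
)


@dataclass
class GrowthParameters:
    """Constants of the growth law and biomass drains.

    PO_NADH / PO_FADH2 are dimensionless P/O ratios; k_ATP (gDW/mmol)
    converts the specific ATP flux to 1/h; K_Pts_GLC and K_Acs_ACE (mM) are
    the carbon-source affinity constants of the availability weights; the
    k_BM_* maps hold the twelve first-order drain constants (1/h) per
    carbon source.
    """

    PO_NADH: float
    PO_FADH2: float
    k_ATP: float
    K_Pts_GLC: float
    K_Acs_ACE: float
    k_BM_GLC: dict[str, float] = field(default_factory=dict)
    k_BM_ACE: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("PO_NADH", "PO_FADH2", "k_ATP", "K_Pts_GLC", "K_Acs_ACE"):
            if getattr(self, name) <= 0:
                raise DomainError(f"growth parameter {name} must be > 0")

    @classmethod
    def from_parameters(cls, parameters: ParameterSet) -> "GrowthParameters":
        """Extract the growth block from a model parameter set (the growth
        constants are serialized inside the main parameter table)."""
        def val(name):
            if name not in parameters:
                raise ContractError(f"parameter set lacks growth constant {name!r}")
            return parameters.value(name)

        k_glc, k_ace = {}, {}
        for m in PRECURSORS:
            if f"k_BM_GLC_{m}" in parameters:
                k_glc[m] = parameters.value(f"k_BM_GLC_{m}")
                k_ace[m] = parameters.value(f"k_BM_ACE_{m}")
        return cls(
            PO_NADH=val("PO_NADH"),
            PO_FADH2=val("PO_FADH2"),
            k_ATP=val("k_ATP"),
            K_Pts_GLC=val("K_Pts_GLC"),
            K_Acs_ACE=val("K_Acs_ACE"),
            k_BM_GLC=k_glc,
            k_BM_ACE=k_ace,
        )


def total_atp_flux(v: FluxVector, gp: GrowthParameters) -> float:
    """Total specific ATP production flux (mmol/gDW/h).

    Raises :class:`ContractError` if any flux named in the balance is
    missing from ``v``.
    """
    for name in list(ATP_DIRECT) + list(ATP_NADH) + list(ATP_FADH2):
        if name not in v:
            raise ContractError(f"ATP balance needs flux {name!r}, absent from vector")
    op_nadh = sum(v[n] for n in ATP_NADH) * gp.PO_NADH
    op_fadh2 = sum(v[n] for n in ATP_FADH2) * gp.PO_FADH2
    direct = sum(c * v[n] for n, c in ATP_DIRECT.items())
    return op_nadh + op_fadh2 + direct


def specific_growth_rate(v_ATP: float, gp: GrowthParameters) -> float:
    """mu = k_ATP * v_ATP (1/h); linear through the origin, unclipped."""
    return gp.k_ATP * v_ATP


def carbon_source_weights(GLC_ex: float, ACE_ex: float, gp: GrowthParameters):
    """Availability weights (alpha_GLC, alpha_ACE), each in [0, 1] with
    alpha_GLC + alpha_ACE <= 1; glucose represses the acetate weight."""
    if GLC_ex < 0 or ACE_ex < 0:
        raise DomainError("extracellular concentrations must be >= 0")
    a_glc = GLC_ex / (GLC_ex + gp.K_Pts_GLC)
    a_ace = ACE_ex / (ACE_ex + gp.K_Acs_ACE) * (1.0 - a_glc)
    return a_glc, a_ace


def biomass_drain_fluxes(x1: dict[str, float], alpha, gp: GrowthParameters) -> dict[str, float]:
    """First-order drain flux (mM/h) of each of the twelve precursors.

    ``x1`` maps metabolite names to concentrations and must cover every
    precursor; ``alpha`` is the pair returned by
    :func:`carbon_source_weights`.
    """
    a_glc, a_ace = alpha
    out = {}
    for m in PRECURSORS:
        if m not in x1:
            raise ContractError(f"precursor {m!r} missing from intracellular state")
        k = a_glc * gp.k_BM_GLC.get(m, 0.0) + a_ace * gp.k_BM_ACE.get(m, 0.0)
        out[m] = k * x1[m]
    return out


def growth_phase_end(times: np.ndarray, glucose: np.ndarray, frac: float = 0.01) -> float:
    """Operational end of the growth phase: the first time at which
    extracellular glucose falls below ``frac`` of its initial value.

    Returns the final time if glucose never crosses the threshold.
    """
    times = np.asarray(times, float)
    glucose = np.asarray(glucose, float)
    thr = frac * glucose[0]
    below = np.flatnonzero(glucose < thr)
    if below.size == 0:
        return float(times[-1])
    return float(times[below[0]])
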