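"""Gene knockouts and virtual mutants.

A knockout removes a gene product entirely: the enzyme's initial
concentration and synthesis are zeroed and every flux it catalyses is
forced to exactly zero for all time.  A *virtual mutant* instead disables a
single regulatory interaction — the binding of a TF to its effector
metabolite, or of an allosteric effector to an enzyme — by inflating the
corresponding binding constant(s) by a large factor (default 1e5), leaving
every other parameter untouched.  All constructors are pure: the input
model is never modified.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

from .errors import DomainError
from .model import KineticModel

__all__ = [
    "MutantSpec",
    "apply_knockout",
    "suppress_tf_binding",
    "suppress_allosteric",
    "TF_COMPLEX_CONSTANTS",
    "ALLOSTERIC_CONSTANTS",
]

DEFAULT_FOLD = 1e5

#: TF-metabolite complex -> dissociation-constant parameter.
TF_COMPLEX_CONSTANTS = {
    "Crp-cAMP": "K_Crp_cAMP",
    "Cra-FBP": "K_Cra_FBP",
    "PdhR-PYR": "K_PdhR_PYR",
}

#: Allosteric enzyme -> effector-binding constants inflated together.
ALLOSTERIC_CONSTANTS = {
    "Pfk": ("K_Pfk_PEP",),
    "Pyk": ("K_Pyk_FBP",),
    "Cs": ("K_Cs_aKG",),
    "Pgi": ("K_Pgi_G6P_6pginh",),
    "Icl": ("K_Icl_PEP", "K_Icl_3PG", "K_Icl_aKG"),
    "Mez": ("K_Mez_AcCoA", "K_Mez_cAMP"),
    "Fbp": ("K_Fbp_PEP",),
    "Ppc": ("K_Ppc_FBP",),
}


@dataclass(frozen=True)
class MutantSpec:
    """Declarative description of a strain perturbation."""

    kind: str  # knockout | tf_binding_suppression | allosteric_suppression
    target: str
    fold: float = DEFAULT_FOLD

    def __post_init__(self):
        if self.kind not in (
            "knockout",
            "tf_binding_suppression",
            "allosteric_suppression",
        ):
            raise DomainError(f"unknown mutant kind {self.kind!r}")
        if self.kind != "knockout" and self.fold <= 1:
            raise DomainError("suppression fold must be > 1")

    def apply(self, model: KineticModel) -> KineticModel:
        if self.kind == "knockout":
            return apply_knockout(model, self.target)
        if self.kind == "tf_binding_suppression":
            return suppress_tf_binding(model, self.target, self.fold)
        return suppress_allosteric(model, self.target, self.fold)


def _clone(model: KineticModel) -> KineticModel:
    new = copy.copy(model)
    new.parameters = model.parameters.copy()
    new.initial_values = dict(model.initial_values)
    new.invalidate()
    return new


def apply_knockout(model: KineticModel, gene: str) -> KineticModel:
    """Strain lacking ``gene``: catalysed fluxes identically zero, enzyme
    concentration and synthesis zero, all parameters bit-identical to WT."""
    genes = {r.gene for r in model.rate_laws if r.gene}
    if gene not in genes:
        raise DomainError(
            f"unknown gene {gene!r}; knockable genes: {sorted(genes)}"
        )
    new = _clone(model)
    new.knocked_out = model.knocked_out | {gene}
    enzymes = {
        r.enzyme
        for r in model.rate_laws
        if r.gene == gene and r.enzyme in set(model.proteins)
    }
    for e in enzymes:
        new.initial_values[e] = 0.0
    new.name = f"{model.name}_d{gene}"
    return new


def restore_gene(model: KineticModel, gene: str, wt: KineticModel) -> KineticModel:
    """Knock a gene back in (inverse of :func:`apply_knockout`, using the
    WT model for the restored initial enzyme level)."""
    new = _clone(model)
    new.knocked_out = model.knocked_out - {gene}
    for r in model.rate_laws:
        if r.gene == gene and r.enzyme in set(model.proteins):
            new.initial_values[r.enzyme] = wt.initial_values[r.enzyme]
    new.name = model.name.replace(f"_d{gene}", "")
    return new


def suppress_tf_binding(
    model: KineticModel, complex_name: str, fold: float = DEFAULT_FOLD
) -> KineticModel:
    """Virtual mutant lacking one TF-metabolite complex.

    Only the complex's dissociation constant changes (multiplied by
    ``fold``); with the default 1e5 inflation the complex concentration
    becomes negligible at any physiological effector level.
    """
    if complex_name not in TF_COMPLEX_CONSTANTS:
        raise DomainError(
            f"unknown TF-metabolite complex {complex_name!r}; "
            f"choose from {sorted(TF_COMPLEX_CONSTANTS)}"
        )
    pname = TF_COMPLEX_CONSTANTS[complex_name]
    new = _clone(model)
    new.parameters = model.parameters.with_scaled({pname: fold})
    new.name = f"{model.name}_no_{complex_name.replace('-', '_')}"
    return new


def suppress_allosteric(
    model: KineticModel, enzyme: str, fold: float = DEFAULT_FOLD
) -> KineticModel:
    """Virtual mutant lacking the allosteric regulation of one enzyme.

    Every listed effector-binding constant of the enzyme is inflated
    together; catalytic constants are untouched.
    """
    if enzyme not in ALLOSTERIC_CONSTANTS:
        raise DomainError(
            f"unknown allosteric enzyme {enzyme!r}; "
            f"choose from {sorted(ALLOSTERIC_CONSTANTS)}"
        )
    names = [p for p in ALLOSTERIC_CONSTANTS[enzyme] if p in model.parameters]
    if not names:
        raise DomainError(
            f"model {model.name!r} defines no allosteric constants for {enzyme!r}"
        )
    new = _clone(model)
    new.parameters = model.parameters.with_scaled({p: fold for p in names})
    new.name = f"{model.name}_noallo_{enzyme}"
    return new
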