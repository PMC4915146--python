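"""Core representation of a kinetic model of central carbon metabolism.

A :class:`KineticModel` bundles the network structure (species, rate laws,
stoichiometry), the algebraic layer of transcription-factor binding
(ancillary rules defining the vector ``x2``), protein synthesis/dilution
balances, biomass precursor drains and a parameter set.  The model is fully
data-driven: the same machinery runs the shipped full-scale *E. coli* model
and small toy models used in tests.

State layout
------------
The integrated state vector ``u`` is ``[X, x1..., y...]`` where

* ``X`` — cell concentration (gDW/L),
* ``x1`` — intracellular, time-varying molecule concentrations (mM):
  metabolites first, then enzyme/Pts-protein concentrations,
* ``y`` — extracellular substrate concentrations (mM).

The ancillary vector ``x2`` (free TFs, TF–metabolite complexes, the
phosphorylated EIIA fraction) is never integrated; it is recomputed from
``(x1, y, p)`` wherever it is needed.

Rate laws and ancillary rules are plain algebraic expressions over species
and parameter names.  They are validated symbolically with :mod:`sympy` and
compiled once per model into a single Python function evaluating the whole
right-hand side, which keeps stiff integration of the full model affordable.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import sympy

from .errors import (
    ContractError,
    DomainError,
    EvaluationError,
    ModelDefinitionError,
)

__all__ = [
    "Species",
    "ParameterEntry",
    "ParameterSet",
    "RateLaw",
    "ProteinBalance",
    "GrowthSpec",
    "CultureState",
    "FluxVector",
    "KineticModel",
    "compute_ancillary",
    "compute_fluxes",
    "mass_balance_rhs",
]

ROLES = ("metabolite", "enzyme", "pts_protein", "tf", "tf_complex", "extracellular")

#: Name of the optional conversion constant (gDW per litre of cytoplasm)
#: coupling specific fluxes (mmol/gDW/h) to intracellular concentration
#: changes (mM/h).  A model without this parameter uses 1.0, i.e. keeps
#: intracellular balances in per-biomass units.
RHO_PARAM = "rho_cyt"


@dataclass(frozen=True)
class Species:
    """A named molecular species.

    The role decides which state vector houses the species: metabolites and
    enzyme/Pts proteins live in ``x1``, extracellular substrates in ``y``,
    free TFs and TF–metabolite complexes in the ancillary vector ``x2``.
    All concentrations are in mM.
    """

    name: str
    role: str
    display_name: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise ModelDefinitionError(
                f"species {self.name!r}: unknown role {self.role!r}; "
                f"expected one of {ROLES}"
            )
        if not self.name.isidentifier():
            raise ModelDefinitionError(
                f"species name {self.name!r} is not a valid identifier"
            )


@dataclass
class ParameterEntry:
    value: float
    pclass: str = "III"  # I: measured, II: literature-derived, III: unknown
    literature_value: float | None = None
    bounds: tuple[float, float] = (1e-9, 1e9)
    units: str = ""
    positive: bool = True

    def __post_init__(self):
        if self.pclass not in ("I", "II", "III"):
            raise ModelDefinitionError(f"bad parameter class {self.pclass!r}")
        if self.pclass == "I" and self.literature_value is None:
            raise ModelDefinitionError(
                "Class I parameters must carry a literature value"
            )
        lo, hi = self.bounds
        if not lo < hi:
            raise ModelDefinitionError(f"bounds must satisfy lo < hi, got {self.bounds}")
        if not math.isfinite(self.value):
            raise ModelDefinitionError("parameter value must be finite")
        if self.positive and self.value <= 0:
            raise ModelDefinitionError(
                f"positive-constrained parameter has value {self.value}"
            )


class ParameterSet:
    """Ordered mapping of parameter name -> :class:`ParameterEntry`.

    Iteration order is the definition order of the underlying table, which
    also fixes the layout of the packed value vector used by the compiled
    right-hand side and by the genetic-algorithm search.
    """

    def __init__(self, entries: dict[str, ParameterEntry] | None = None):
        self._entries: dict[str, ParameterEntry] = dict(entries or {})
        for name in self._entries:
            if not name.isidentifier():
                raise ModelDefinitionError(
                    f"parameter name {name!r} is not a valid identifier"
                )

    # -- mapping protocol -------------------------------------------------
    def __contains__(self, name):
        return name in self._entries

    def __getitem__(self, name) -> ParameterEntry:
        return self._entries[name]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self):
        return len(self._entries)

    def items(self):
        return self._entries.items()

    def names(self) -> tuple[str, ...]:
        return tuple(self._entries)

    def values_vector(self) -> np.ndarray:
        return np.array([e.value for e in self._entries.values()], dtype=float)

    def value(self, name) -> float:
        return self._entries[name].value

    # -- functional updates ----------------------------------------------
    def copy(self) -> "ParameterSet":
        return ParameterSet({k: replace(v) for k, v in self._entries.items()})

    def with_values(self, updates: dict[str, float]) -> "ParameterSet":
        """Return a copy with selected values replaced (entries otherwise
        untouched, so class labels, bounds and anchors survive)."""
        new = self.copy()
        for k, v in updates.items():
            if k not in new._entries:
                raise KeyError(f"unknown parameter {k!r}")
            new._entries[k].value = float(v)
        return new

    def with_scaled(self, scales: dict[str, float]) -> "ParameterSet":
        return self.with_values(
            {k: self._entries[k].value * s for k, s in scales.items()}
        )

    def diff(self, other: "ParameterSet") -> dict[str, tuple[float, float]]:
        """Names whose values differ between ``self`` and ``other``."""
        out = {}
        for k, e in self._entries.items():
            ov = other._entries[k].value if k in other else None
            if ov != e.value:
                out[k] = (e.value, ov)
        return out


@dataclass(frozen=True)
class RateLaw:
    """A reaction with a declarative kinetic expression.

    ``expression`` is algebra over species and parameter names; it must
    resolve completely against the owning model.  ``stoichiometry`` maps
    species names (intracellular or extracellular) to signed coefficients.
    ``kind`` is ``"metabolic"`` for the enzymatic reactions counted in the
    model's flux tally, or ``"transport"`` for passive exchange processes.
    ``enzyme`` names the catalysing species (or None for laws whose enzyme
    level is folded into a Vmax parameter); ``gene`` is the knockout handle.
    """

    name: str
    expression: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    enzyme: str | None = None
    gene: str | None = None
    reversible: bool = False
    kind: str = "metabolic"
    modifiers: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("metabolic", "transport"):
            raise ModelDefinitionError(f"{self.name}: bad reaction kind {self.kind!r}")


@dataclass(frozen=True)
class ProteinBalance:
    """Synthesis/dilution balance of an enzyme or Pts protein.

    ``synthesis`` is an expression (mM/h) over ancillary variables (TF and
    TF–complex concentrations) and parameters; growth dilution ``-mu*E`` is
    appended automatically.  ``regulated`` marks TF-controlled metabolic
    gene expression; constitutive balances (the EIIA carrier) are excluded
    from the gene-expression tally.
    """

    species: str
    synthesis: str
    regulated: bool = True


@dataclass(frozen=True)
class GrowthSpec:
    """How the specific growth rate is obtained.

    mode "atp": mu = k_ATP * v_ATP with v_ATP from the oxidative-
    phosphorylation balance over named fluxes (see :mod:`ccmkin.growth`).
    mode "expression": mu is an explicit expression over species, parameters
    and fluxes (referenced as ``v_<reaction>``) — used by toy models.
    """

    mode: str = "atp"
    expression: str | None = None

    def __post_init__(self):
        if self.mode not in ("atp", "expression"):
            raise ModelDefinitionError(f"bad growth mode {self.mode!r}")
        if self.mode == "expression" and not self.expression:
            raise ModelDefinitionError("growth mode 'expression' needs an expression")


# --- the Eq-5 ATP balance: coefficient of each named flux, plus the NADH
# and FADH2 groups multiplied by their P/O ratios.
ATP_DIRECT = {
    "Glk": -1.0,
    "Pfk": -1.0,
    "Gapdh": +1.0,
    "Pyk": +1.0,
    "Pps": -1.0,
    "Ack": +1.0,
    "Acs": -1.0,
    "akgdh": +1.0,
    "Pck": -1.0,
    "AceK_ki": -1.0,
    "Cya": -1.0,
}
ATP_NADH = ("Gapdh", "Pdh", "akgdh", "Mdh")
ATP_FADH2 = ("Sdh",)


@dataclass
class CultureState:
    """Snapshot of a culture at one time point (concentrations in mM, X in
    gDW/L).  ``x2`` is always a pure function of ``(x1, y, p)``."""

    t: float
    X: float
    x1: np.ndarray
    x2: np.ndarray
    y: np.ndarray

    def copy(self):
        return CultureState(self.t, self.X, self.x1.copy(), self.x2.copy(), self.y.copy())


class FluxVector:
    """Named specific reaction rates (mmol/gDW/h)."""

    def __init__(self, names: tuple[str, ...], values: np.ndarray):
        if len(names) != len(values):
            raise ContractError("flux names and values differ in length")
        self.names = tuple(names)
        self.values = np.asarray(values, dtype=float)
        self._index = {n: i for i, n in enumerate(self.names)}

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.values[self._index[name]])
        except KeyError:
            raise ContractError(
                f"flux {name!r} missing; known fluxes: {', '.join(self.names)}"
            ) from None

    def __contains__(self, name):
        return name in self._index

    def __len__(self):
        return len(self.names)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def _sympify(expr: str, allowed: set[str], context: str) -> sympy.Expr:
    """Parse ``expr`` and verify every free symbol is an allowed name."""
    try:
        sym = sympy.sympify(
            expr, locals={n: sympy.Symbol(n) for n in allowed}, evaluate=False
        )
    except (sympy.SympifyError, SyntaxError, TypeError) as exc:
        raise ModelDefinitionError(f"{context}: cannot parse {expr!r}: {exc}") from exc
    unknown = {str(s) for s in sym.free_symbols} - allowed
    if unknown:
        raise ModelDefinitionError(
            f"{context}: unresolved symbol(s) {sorted(unknown)} in {expr!r}"
        )
    return sym


class KineticModel:
    """Immutable-by-convention bundle of network structure + parameters.

    Mutant constructors in :mod:`ccmkin.perturbation` return modified
    copies; nothing in the package mutates a model in place after
    construction.
    """

    def __init__(
        self,
        species: list[Species],
        rate_laws: list[RateLaw],
        ancillary_rules: list[tuple[str, str]],
        protein_balances: list[ProteinBalance],
        biomass_precursors: list[str],
        parameters: ParameterSet,
        initial_state: dict[str, float],
        growth: GrowthSpec,
        name: str = "model",
    ):
        self.name = name
        self.species = list(species)
        self.rate_laws = list(rate_laws)
        self.ancillary_rules = list(ancillary_rules)
        self.protein_balances = list(protein_balances)
        self.biomass_precursors = list(biomass_precursors)
        self.parameters = parameters
        self.initial_values = dict(initial_state)
        self.growth = growth
        self.knocked_out: frozenset[str] = frozenset()
        self._validate()
        self._compiled = None

    # ------------------------------------------------------------------ #
    # structure
    # ------------------------------------------------------------------ #
    @property
    def metabolites(self) -> list[str]:
        return [s.name for s in self.species if s.role == "metabolite"]

    @property
    def proteins(self) -> list[str]:
        return [s.name for s in self.species if s.role in ("enzyme", "pts_protein")]

    @property
    def x1_names(self) -> list[str]:
        return self.metabolites + self.proteins

    @property
    def y_names(self) -> list[str]:
        return [s.name for s in self.species if s.role == "extracellular"]

    @property
    def x2_names(self) -> list[str]:
        return [n for n, _ in self.ancillary_rules]

    @property
    def flux_names(self) -> list[str]:
        return [r.name for r in self.rate_laws]

    @property
    def metabolic_flux_names(self) -> list[str]:
        return [r.name for r in self.rate_laws if r.kind == "metabolic"]

    def structural_counts(self) -> dict[str, int]:
        """Headline model-size tally (metabolites / enzyme+Pts proteins /
        metabolic fluxes / TF-regulated gene expressions / biomass drains)."""
        return {
            "metabolites": len(self.metabolites),
            "enzymes_pts": len(self.proteins),
            "fluxes": len(self.metabolic_flux_names),
            "gene_expressions": sum(1 for b in self.protein_balances if b.regulated),
            "biomass_drains": len(self.biomass_precursors),
        }

    def checksum(self) -> str:
        h = hashlib.sha256()
        for s in self.species:
            h.update(f"{s.name}|{s.role}".encode())
        for r in self.rate_laws:
            h.update(f"{r.name}|{r.expression}|{sorted(r.stoichiometry.items())}".encode())
        for n, e in self.ancillary_rules:
            h.update(f"{n}|{e}".encode())
        for b in self.protein_balances:
            h.update(f"{b.species}|{b.synthesis}|{b.regulated}".encode())
        for k, e in self.parameters.items():
            h.update(f"{k}|{e.value!r}|{e.pclass}".encode())
        for k in sorted(self.initial_values):
            h.update(f"{k}|{self.initial_values[k]!r}".encode())
        h.update(repr(sorted(self.knocked_out)).encode())
        return h.hexdigest()[:16]

    # ------------------------------------------------------------------ #
    # validation
    # ------------------------------------------------------------------ #
    def _validate(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ModelDefinitionError(f"duplicate species names: {dup}")
        known = set(names)
        pnames = set(self.parameters.names())
        clash = known & pnames
        if clash:
            raise ModelDefinitionError(f"names used as both species and parameter: {sorted(clash)}")

        anc_seen: set[str] = set()
        for rule_name, expr in self.ancillary_rules:
            allowed = known | pnames | anc_seen
            _sympify(expr, allowed, f"ancillary rule {rule_name!r}")
            anc_seen.add(rule_name)

        rnames = [r.name for r in self.rate_laws]
        if len(set(rnames)) != len(rnames):
            raise ModelDefinitionError("duplicate reaction names")
        allowed = known | pnames | anc_seen
        for r in self.rate_laws:
            _sympify(r.expression, allowed, f"rate law {r.name!r}")
            for sp in r.stoichiometry:
                if sp not in known:
                    raise ModelDefinitionError(
                        f"rate law {r.name!r}: stoichiometry names unknown species {sp!r}"
                    )
            if r.enzyme is not None and r.enzyme not in known and r.enzyme not in pnames:
                raise ModelDefinitionError(
                    f"rate law {r.name!r}: enzyme {r.enzyme!r} is neither species nor parameter"
                )
        for b in self.protein_balances:
            if b.species not in self.proteins:
                raise ModelDefinitionError(
                    f"protein balance for unknown protein {b.species!r}"
                )
            _sympify(b.synthesis, allowed, f"protein balance {b.species!r}")
        balanced = {b.species for b in self.protein_balances}
        for p in self.proteins:
            if p not in balanced:
                raise ModelDefinitionError(f"protein {p!r} has no synthesis balance")
        met = set(self.metabolites)
        for m in self.biomass_precursors:
            if m not in met:
                raise ModelDefinitionError(f"biomass precursor {m!r} is not a metabolite")
            for pref in ("k_BM_GLC_", "k_BM_ACE_"):
                if pref + m not in self.parameters:
                    raise ModelDefinitionError(
                        f"missing drain constant {pref + m!r} for precursor {m!r}"
                    )
        if self.biomass_precursors:
            for req in ("K_Pts_GLC", "K_Acs_ACE", "GLCex", "ACEex"):
                if req not in pnames and req not in known:
                    raise ModelDefinitionError(
                        f"biomass drains need {req!r} (carbon-source weighting)"
                    )
        if self.growth.mode == "atp":
            have = set(rnames)
            need = set(ATP_DIRECT) | set(ATP_NADH) | set(ATP_FADH2)
            missing = need - have
            if missing:
                raise ModelDefinitionError(
                    f"growth mode 'atp' requires fluxes {sorted(missing)}"
                )
            for req in ("PO_NADH", "PO_FADH2", "k_ATP"):
                if req not in pnames:
                    raise ModelDefinitionError(f"growth mode 'atp' requires parameter {req!r}")
        else:
            flux_syms = {f"v_{r.name}" for r in self.rate_laws}
            _sympify(self.growth.expression, allowed | flux_syms, "growth expression")
        for sp in self.x1_names + self.y_names:
            if sp not in self.initial_values:
                raise ModelDefinitionError(f"no initial value for species {sp!r}")
        if "X" not in self.initial_values:
            raise ModelDefinitionError("no initial cell concentration 'X'")

    # ------------------------------------------------------------------ #
    # compilation
    # ------------------------------------------------------------------ #
    def _compile(self):
        """Generate and exec a single evaluator for x2, fluxes, drains, mu
        and the full right-hand side.  Returns the compiled namespace."""
        x1 = self.x1_names
        y = self.y_names
        pnames = self.parameters.names()
        lines: list[str] = []
        add = lines.append
        add("def _eval(t, u, p, D, yfeed):")
        add("    X = u[0]")
        # clamped species locals (negative-overshoot guard, rate laws only)
        for i, n in enumerate(x1):
            add(f"    {n} = u[{1 + i}] if u[{1 + i}] > 0.0 else 0.0")
        off = 1 + len(x1)
        for j, n in enumerate(y):
            add(f"    {n} = u[{off + j}] if u[{off + j}] > 0.0 else 0.0")
        for k, n in enumerate(pnames):
            add(f"    {n} = p[{k}]")
        printer = sympy.printing.pycode
        allowed = set(x1) | set(y) | set(pnames)
        for rule_name, expr in self.ancillary_rules:
            sym = _sympify(expr, allowed, rule_name)
            add(f"    {rule_name} = {printer(sym)}")
            allowed.add(rule_name)
        ko_genes = self.knocked_out
        for r in self.rate_laws:
            sym = _sympify(r.expression, allowed, r.name)
            if r.gene is not None and r.gene in ko_genes:
                add(f"    v_{r.name} = 0.0")
            else:
                add(f"    v_{r.name} = {printer(sym)}")
        # carbon-source weights + biomass drains
        if self.biomass_precursors:
            add("    alpha_GLC = GLCex / (GLCex + K_Pts_GLC)")
            add("    alpha_ACE = ACEex / (ACEex + K_Acs_ACE) * (1.0 - alpha_GLC)")
            for m in self.biomass_precursors:
                add(
                    f"    vBM_{m} = (alpha_GLC * k_BM_GLC_{m}"
                    f" + alpha_ACE * k_BM_ACE_{m}) * {m}"
                )
        # growth rate
        if self.growth.mode == "atp":
            direct = " ".join(
                f"{'+' if c > 0 else '-'} v_{n}" for n, c in ATP_DIRECT.items()
            )
            nadh = " + ".join(f"v_{n}" for n in ATP_NADH)
            fadh = " + ".join(f"v_{n}" for n in ATP_FADH2)
            add(f"    OP_NADH = ({nadh}) * PO_NADH")
            add(f"    OP_FADH2 = ({fadh}) * PO_FADH2")
            add(f"    v_ATP = OP_NADH + OP_FADH2 {direct}")
            add("    mu = k_ATP * v_ATP")
        else:
            gsym = _sympify(
                self.growth.expression,
                allowed | {f"v_{r.name}" for r in self.rate_laws},
                "growth",
            )
            add("    v_ATP = 0.0")
            add(f"    mu = {printer(gsym)}")
        # derivatives
        rho = f"{RHO_PARAM}" if RHO_PARAM in self.parameters else "1.0"
        add(f"    du = [0.0] * {1 + len(x1) + len(y)}")
        add("    du[0] = (mu - D) * X")
        met = set(self.metabolites)
        syn = {b.species: b.synthesis for b in self.protein_balances}
        ko_enzymes = {
            r.enzyme
            for r in self.rate_laws
            if r.gene in ko_genes and r.enzyme in set(self.proteins)
        }
        drains = set(self.biomass_precursors)
        for i, n in enumerate(x1):
            terms = []
            if n in met:
                stoich_terms = []
                for r in self.rate_laws:
                    c = r.stoichiometry.get(n, 0.0)
                    if c:
                        stoich_terms.append(f"{c:+g} * v_{r.name}")
                if stoich_terms:
                    terms.append(f"{rho} * ({' '.join(stoich_terms)})")
                if n in drains:
                    terms.append(f"- vBM_{n}")
            else:  # protein
                if n in ko_enzymes:
                    terms.append("0.0")
                else:
                    sym = _sympify(syn[n], allowed, f"synthesis {n}")
                    terms.append(f"({printer(sym)})")
            terms.append(f"- mu * {n}")
            add(f"    du[{1 + i}] = {' '.join(terms)}")
        for j, n in enumerate(y):
            stoich_terms = []
            for r in self.rate_laws:
                c = r.stoichiometry.get(n, 0.0)
                if c:
                    stoich_terms.append(f"{c:+g} * v_{r.name}")
            ext = f"X * ({' '.join(stoich_terms)})" if stoich_terms else "0.0"
            add(f"    du[{off + j}] = D * (yfeed[{j}] - {n}) + {ext}")
        add(f"    x2 = [{', '.join(n for n, _ in self.ancillary_rules)}]")
        add(f"    v = [{', '.join('v_' + r.name for r in self.rate_laws)}]")
        if self.biomass_precursors:
            add(f"    vbm = [{', '.join('vBM_' + m for m in self.biomass_precursors)}]")
        else:
            add("    vbm = []")
        add("    return du, x2, v, vbm, mu, v_ATP")
        src = "\n".join(lines)
        ns: dict = {"math": math, "sqrt": math.sqrt, "exp": math.exp, "log": math.log}
        exec(compile(src, f"<ccmkin:{self.name}>", "exec"), ns)  # noqa: S102
        return {"eval": ns["_eval"], "source": src}

    @property
    def compiled(self):
        if self._compiled is None:
            self._compiled = self._compile()
        return self._compiled

    def invalidate(self):
        """Drop the compiled evaluator (call after structural edits)."""
        self._compiled = None

    # ------------------------------------------------------------------ #
    # evaluation entry points
    # ------------------------------------------------------------------ #
    def _pvec(self, parameters: ParameterSet | None) -> np.ndarray:
        ps = parameters if parameters is not None else self.parameters
        if ps is not self.parameters and ps.names() != self.parameters.names():
            raise ContractError("parameter set layout differs from the model's")
        return ps.values_vector()

    def evaluate(self, t, u, D=0.0, y_feed=None, parameters=None):
        """Low-level evaluation at a raw state vector.

        Returns ``(du, x2, v, vbm, mu, v_ATP)`` as plain lists/floats."""
        p = self._pvec(parameters)
        yf = np.zeros(len(self.y_names)) if y_feed is None else np.asarray(y_feed, float)
        out = self.compiled["eval"](t, u, p, D, yf)
        du = out[0]
        if not all(math.isfinite(d) for d in du):
            bad = [self.state_names()[i] for i, d in enumerate(du) if not math.isfinite(d)]
            raise EvaluationError(
                f"model {self.name!r}: non-finite derivative for {bad}"
            )
        return out

    def state_names(self) -> list[str]:
        return ["X"] + self.x1_names + self.y_names

    def initial_state_vector(self) -> np.ndarray:
        return np.array(
            [self.initial_values["X"]]
            + [self.initial_values[n] for n in self.x1_names]
            + [self.initial_values[n] for n in self.y_names]
        )

    def initial_culture_state(self) -> CultureState:
        u = self.initial_state_vector()
        x1 = u[1 : 1 + len(self.x1_names)]
        yv = u[1 + len(self.x1_names) :]
        x2 = compute_ancillary(self, x1, yv)
        return CultureState(0.0, u[0], x1, x2, yv)

    def pack_state(self, state: CultureState) -> np.ndarray:
        return np.concatenate(([state.X], state.x1, state.y))

    def unpack_state(self, t: float, u: np.ndarray) -> CultureState:
        n1 = len(self.x1_names)
        x1 = np.asarray(u[1 : 1 + n1], float)
        yv = np.asarray(u[1 + n1 :], float)
        return CultureState(t, float(u[0]), x1, compute_ancillary(self, x1, yv), yv)


# ---------------------------------------------------------------------- #
# module-level operations
# ---------------------------------------------------------------------- #
def compute_ancillary(model: KineticModel, x1, y, parameters=None) -> np.ndarray:
    """Evaluate the ancillary algebra: free TFs, TF–metabolite complexes and
    other fast-equilibrium variables as a pure function of ``(x1, y, p)``."""
    x1 = np.asarray(x1, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x1 < 0).any() or (y < 0).any():
        raise DomainError("negative concentration passed to compute_ancillary")
    u = np.concatenate(([0.0], x1, y))
    _, x2, _, _, _, _ = model.evaluate(0.0, u, parameters=parameters)
    return np.array(x2, dtype=float)


def compute_fluxes(model: KineticModel, state: CultureState, parameters=None) -> FluxVector:
    """Evaluate every rate law at a culture state.

    The ancillary vector is recomputed internally, so the returned fluxes
    are always consistent with ``(x1, y)``.  Raises
    :class:`EvaluationError` naming the reaction if a law goes non-finite.
    """
    u = model.pack_state(state)
    p = model._pvec(parameters)
    yf = np.zeros(len(model.y_names))
    _, _, v, _, _, _ = model.compiled["eval"](state.t, u, p, 0.0, yf)
    v = np.asarray(v, dtype=float)
    if not np.isfinite(v).all():
        bad = [model.flux_names[i] for i in np.flatnonzero(~np.isfinite(v))]
        raise EvaluationError(f"non-finite flux in reaction(s) {bad}")
    return FluxVector(tuple(model.flux_names), v)


def mass_balance_rhs(
    model: KineticModel,
    state: CultureState,
    D: float = 0.0,
    y_feed=None,
    parameters=None,
) -> np.ndarray:
    """Time derivatives of ``(X, x1, y)`` for a batch (D = 0) or chemostat
    (D > 0) culture: dX/dt = (mu - D) X, dy/dt = D (y_feed - y) - g(.) X and
    dx1/dt assembled from stoichiometry x fluxes, protein balances, biomass
    drains and growth dilution."""
    if D < 0:
        raise DomainError("dilution rate D must be >= 0")
    if y_feed is not None and (np.asarray(y_feed, float) < 0).any():
        raise DomainError("feed concentrations must be >= 0")
    u = model.pack_state(state)
    du, *_ = model.evaluate(state.t, u, D=D, y_feed=y_feed, parameters=parameters)
    return np.asarray(du, dtype=float)
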