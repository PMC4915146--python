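"""Reading and writing model bundles and tabular data.

A model bundle is a directory of delimited text tables (one per structural
aspect: species, reactions, stoichiometry, ancillary rules, protein
balances, biomass drains, parameters, initial state) plus a small
``model.yaml`` header.  ``load(save(model))`` reproduces the model
bit-identically; floats are serialized with ``repr`` to guarantee it.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
import yaml

from .errors import ModelDefinitionError
from .model import (
    GrowthSpec,
    KineticModel,
    ParameterEntry,
    ParameterSet,
    ProteinBalance,
    RateLaw,
    Species,
)

__all__ = ["save_model", "load_model", "bundle_checksums", "load_experiment_table"]

_TABLES = (
    "species",
    "reactions",
    "stoichiometry",
    "ancillary",
    "proteins",
    "drains",
    "parameters",
    "initial_state",
)


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)
    return str(x)


def _write_tsv(path: Path, header: list[str], rows: list[list]):
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(_fmt(c) for c in row))
    path.write_text("\n".join(lines) + "\n")


def _read_tsv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise ModelDefinitionError(f"bundle table missing: {path.name}")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def save_model(model: KineticModel, directory) -> Path:
    """Write a model bundle; returns the directory path."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _write_tsv(
        d / "species.tsv",
        ["name", "role", "display_name"],
        [[s.name, s.role, s.display_name] for s in model.species],
    )
    _write_tsv(
        d / "reactions.tsv",
        ["name", "kind", "enzyme", "gene", "reversible", "expression"],
        [
            [r.name, r.kind, r.enzyme or "", r.gene or "", int(r.reversible), r.expression]
            for r in model.rate_laws
        ],
    )
    _write_tsv(
        d / "stoichiometry.tsv",
        ["reaction", "species", "coeff"],
        [
            [r.name, sp, float(c)]
            for r in model.rate_laws
            for sp, c in r.stoichiometry.items()
        ],
    )
    _write_tsv(
        d / "ancillary.tsv",
        ["name", "expression"],
        [[n, e] for n, e in model.ancillary_rules],
    )
    _write_tsv(
        d / "proteins.tsv",
        ["species", "regulated", "synthesis"],
        [[b.species, int(b.regulated), b.synthesis] for b in model.protein_balances],
    )
    _write_tsv(d / "drains.tsv", ["precursor"], [[m] for m in model.biomass_precursors])
    _write_tsv(
        d / "parameters.tsv",
        ["name", "value", "class", "literature_value", "lo", "hi", "units", "positive"],
        [
            [
                k,
                float(e.value),
                e.pclass,
                None if e.literature_value is None else float(e.literature_value),
                float(e.bounds[0]),
                float(e.bounds[1]),
                e.units,
                int(e.positive),
            ]
            for k, e in model.parameters.items()
        ],
    )
    init_rows = [["X", float(model.initial_values["X"])]]
    init_rows += [[n, float(model.initial_values[n])] for n in model.x1_names]
    init_rows += [[n, float(model.initial_values[n])] for n in model.y_names]
    _write_tsv(d / "initial_state.tsv", ["name", "value"], init_rows)
    header = {
        "name": model.name,
        "growth": {"mode": model.growth.mode, "expression": model.growth.expression},
        "knocked_out": sorted(model.knocked_out),
    }
    (d / "model.yaml").write_text(yaml.safe_dump(header, sort_keys=False))
    return d


def load_model(directory) -> KineticModel:
    """Load and fully validate a model bundle.

    Errors name the offending table/row/symbol (validation happens in the
    :class:`KineticModel` constructor).
    """
    d = Path(directory)
    header = yaml.safe_load((d / "model.yaml").read_text()) if (d / "model.yaml").exists() else {}
    sp_df = _read_tsv(d / "species.tsv")
    species = [
        Species(r["name"], r["role"], r.get("display_name", ""))
        for _, r in sp_df.iterrows()
    ]
    st_df = _read_tsv(d / "stoichiometry.tsv")
    stoich: dict[str, dict[str, float]] = {}
    for _, r in st_df.iterrows():
        stoich.setdefault(r["reaction"], {})[r["species"]] = float(r["coeff"])
    rx_df = _read_tsv(d / "reactions.tsv")
    laws = []
    for _, r in rx_df.iterrows():
        laws.append(
            RateLaw(
                name=r["name"],
                expression=r["expression"],
                stoichiometry=stoich.get(r["name"], {}),
                enzyme=r["enzyme"] or None,
                gene=r["gene"] or None,
                reversible=bool(int(r["reversible"])),
                kind=r["kind"],
            )
        )
    orphan = set(stoich) - {r.name for r in laws}
    if orphan:
        raise ModelDefinitionError(f"stoichiometry.tsv names unknown reaction(s) {sorted(orphan)}")
    anc_df = _read_tsv(d / "ancillary.tsv")
    ancillary = [(r["name"], r["expression"]) for _, r in anc_df.iterrows()]
    pb_df = _read_tsv(d / "proteins.tsv")
    balances = [
        ProteinBalance(r["species"], r["synthesis"], bool(int(r["regulated"])))
        for _, r in pb_df.iterrows()
    ]
    dr_df = _read_tsv(d / "drains.tsv")
    precursors = list(dr_df["precursor"]) if len(dr_df) else []
    pa_df = _read_tsv(d / "parameters.tsv")
    entries = {}
    for _, r in pa_df.iterrows():
        entries[r["name"]] = ParameterEntry(
            value=float(r["value"]),
            pclass=r["class"],
            literature_value=float(r["literature_value"]) if r["literature_value"] else None,
            bounds=(float(r["lo"]), float(r["hi"])),
            units=r["units"],
            positive=bool(int(r.get("positive", "1"))),
        )
    init_df = _read_tsv(d / "initial_state.tsv")
    initial = {r["name"]: float(r["value"]) for _, r in init_df.iterrows()}
    growth_cfg = header.get("growth", {"mode": "atp", "expression": None})
    model = KineticModel(
        species=species,
        rate_laws=laws,
        ancillary_rules=ancillary,
        protein_balances=balances,
        biomass_precursors=precursors,
        parameters=ParameterSet(entries),
        initial_state=initial,
        growth=GrowthSpec(growth_cfg["mode"], growth_cfg.get("expression")),
        name=header.get("name", d.name),
    )
    ko = header.get("knocked_out") or []
    if ko:
        model.knocked_out = frozenset(ko)
        model.invalidate()
    return model


def bundle_checksums(directory) -> dict[str, str]:
    """sha256 of every table in a bundle (recorded in run manifests)."""
    d = Path(directory)
    out = {}
    for name in sorted(p.name for p in d.iterdir() if p.suffix in (".tsv", ".yaml")):
        out[name] = hashlib.sha256((d / name).read_bytes()).hexdigest()[:16]
    return out


def load_experiment_table(path) -> pd.DataFrame:
    """Read an experimental records table (strain, time_h, quantity, value,
    sd) as produced by the fixture generator or re-encoded from published
    batch/chemostat datasets."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain", "time_h", "quantity", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ModelDefinitionError(f"experiment table lacks column(s) {sorted(missing)}")
    if "sd" not in df.columns:
        df["sd"] = 0.0
    return df
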