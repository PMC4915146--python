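"""The shipped full-scale E. coli central-carbon-metabolism model.

A reconstruction of glucose/acetate batch and chemostat physiology:
glycolysis, gluconeogenesis, pentose phosphate and Entner-Doudoroff
pathways, TCA cycle, glyoxylate shunt, anaplerosis, acetate overflow and
re-assimilation, Pts and non-Pts glucose uptake, oxidative
phosphorylation-driven growth, and metabolic gene regulation by Crp, Cra,
PdhR and constant IclR.  Structure: 27 metabolites, 22 enzyme/Pts proteins,
38 metabolic fluxes, 21 TF-regulated gene expressions, 12 biomass precursor
drains.  Rate-law forms follow the standard enzyme-kinetic literature; the
parameter values are an in-house calibration to the canonical aerobic
batch-culture phenotype (growth-phase mu near 0.8 1/h, glucose exhausted
near 8 h from a 22.2 mM inoculum culture, acetate overflow then
re-consumption through the glyoxylate shunt) and are not fitted to any
proprietary dataset; treat quantitative outputs accordingly.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import load_model
from .model import KineticModel

__all__ = ["load_ecoli_model", "ecoli_bundle_path", "GENE_MAP", "BATCH_GRID"]

#: Gene -> (reaction names, enzyme species or None) used by knockout
#: construction for the mutants studied in batch culture.
GENE_MAP = {
    "pykF": (("Pyk",), "E_Pyk"),
    "pgi": (("Pgi",), None),
    "ppc": (("Ppc",), "E_Ppc"),
}

#: Output grids used for batch reproduction: 0-10 h at 0.05 h for WT and
#: the pykF knockout; 0-26 h for the slow-growing pgi/ppc knockouts.
BATCH_GRID = {"fast": (0.0, 10.0, 0.05), "slow": (0.0, 26.0, 0.05)}


def ecoli_bundle_path() -> Path:
    return Path(resources.files("ccmkin")) / "data" / "ecoli"


def load_ecoli_model() -> KineticModel:
    """Load and validate the shipped model bundle."""
    return load_model(ecoli_bundle_path())
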