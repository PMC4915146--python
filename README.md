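# ccmkin

Kinetic modelling of *Escherichia coli* central carbon metabolism in batch
and continuous culture, for systems biologists who want to simulate and
interrogate the coupled dynamics of metabolism, metabolic gene regulation
and cell growth — rather than a steady-state flux snapshot.

The package ships a full-scale model (glycolysis, gluconeogenesis, pentose
phosphate and Entner–Doudoroff pathways, TCA cycle, glyoxylate shunt,
anaplerosis, acetate overflow/re-assimilation, Pts and non-Pts glucose
uptake) with metabolic gene expression controlled by four transcription
factors (Crp, Cra, PdhR and constant IclR), and the analysis toolkit built
around it: virtual-mutant construction, dynamic sensitivity analysis,
synthesis-ratio quantification, flux-agreement scoring and constrained
genetic-algorithm parameter estimation. The same data-driven machinery runs
user-defined toy models.

## The model

A culture is the DAE system

```
dX/dt  = (mu - D) X                     cell concentration, gDW/L
dy/dt  = D (y_feed - y) - g(.) X        extracellular glucose/acetate, mM
dx1/dt = f(x1, x2, y, p)                intracellular molecules, mM
  x2   = h(x1, y, p)                    TFs and TF-metabolite complexes
```

with dilution rate `D = 0` for a batch culture. The algebraic layer `x2`
holds the regulatory state: binding isotherms such as
`[Crp·cAMP] = Crp_tot [cAMP]/([cAMP] + K_Crp_cAMP)` plus the
phosphorylation state of the Pts carrier EIIA, which senses the PEP/PYR
ratio. Each of 21 regulated enzymes obeys a synthesis–dilution balance
whose synthesis rate is a product of TF activation/repression factors, so
the growth-to-stationary phase transition *emerges* from the regulatory
algebra rather than being switched explicitly.

The specific growth rate derives from the total specific ATP production
flux (oxidative phosphorylation of NADH/FADH2 weighted by the two P/O
ratios, plus substrate-level terms, minus ATP-consuming reactions):

```
v_ATP = OP_NADH + OP_FADH2 - v_Glk - v_Pfk + v_Gapdh + v_Pyk - v_Pps
        + v_Ack - v_Acs + v_akgdh - v_Pck - v_AceK - v_Cya
mu    = k_ATP * v_ATP
```

Biomass formation drains twelve precursor metabolites with first-order
kinetics weighted by carbon-source availability
(`alpha_GLC = [GLC]/([GLC]+K)`, acetate use repressed by glucose).

The shipped parameterisation is an in-house calibration to the canonical
aerobic glucose/acetate batch phenotype and is **not** a fit to any
particular published dataset; see `docs/methods.md` for what it does and
does not represent.

## Worked example

```python
import numpy as np
from ccmkin import CultureConfig, simulate, steady_state
from ccmkin.ecoli import load_ecoli_model
from ccmkin.growth import growth_phase_end

model = load_ecoli_model()
print(model.structural_counts())

grid = np.arange(0.0, 12.0001, 0.05)
tc = simulate(model, CultureConfig(t_span=(0.0, 12.0), output_grid=grid))
t_dep = growth_phase_end(tc.times, tc.states["GLCex"].to_numpy())
i5 = int(np.argmin(np.abs(tc.times - 5.0)))
print(f"glucose exhausted at t = {t_dep:.2f} h")
print(f"growth-phase mu(5 h) = {tc.mu[i5]:.3f} 1/h, v_ATP = {tc.v_atp[i5]:.1f} mmol/gDW/h")
print(f"acetate peak = {tc.states['ACEex'].max():.2f} mM, final biomass = {tc.states['X'].iloc[-1]:.2f} gDW/L")

state, fluxes, info = steady_state(model, D=0.4, y_feed=[22.2, 0.0])
print(f"chemostat D=0.4: X = {state.X:.2f} gDW/L, residual glucose = {state.y[0]:.4f} mM, mu = {info['mu']:.4f} 1/h")
```

prints

```
{'metabolites': 27, 'enzymes_pts': 22, 'fluxes': 38, 'gene_expressions': 21, 'biomass_drains': 12}
glucose exhausted at t = 8.00 h
growth-phase mu(5 h) = 0.837 1/h, v_ATP = 67.0 mmol/gDW/h
acetate peak = 3.34 mM, final biomass = 1.82 gDW/L
chemostat D=0.4: X = 3.54 gDW/L, residual glucose = 0.0117 mM, mu = 0.4000 1/h
```

The batch culture grows exponentially on glucose, overflows acetate,
exhausts glucose at 8 h, then re-assimilates the acetate through Acs and
the glyoxylate shunt before entering stationary phase. At a growing
chemostat steady state the specific growth rate equals the dilution rate.

Virtual mutants disable one regulatory interaction by inflating its
binding constant 1e5-fold:

```python
from ccmkin.perturbation import suppress_tf_binding
from ccmkin.analysis import synthesis_ratio_report

vm = suppress_tf_binding(model, "Crp-cAMP")
tc_vm = simulate(vm, CultureConfig(t_span=(0.0, 12.0), output_grid=grid))
report = synthesis_ratio_report(tc, tc_vm, model.metabolic_flux_names)
```

A synthesis ratio of one means the mutant leaves that reaction's
time-integrated, biomass-weighted flux unchanged over the growth phase;
for the Crp–cAMP mutant the TCA-cycle, glyoxylate-shunt and Acs ratios
fall well below one.

The same operations are available from the shell:

```
ccmkin simulate --model ecoli --t-end 10 --out wt.tsv
ccmkin mutate --suppress-tf Crp-cAMP --out vm_crp/
ccmkin sensitivity --t-sample 6 --eta 0.01 --out sens.tsv
ccmkin synthesis-ratio --suppress-allosteric Fbp --out ratios.tsv
ccmkin fixtures --seed 1 --noise-sd 0.05 --out fixtures/
```

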