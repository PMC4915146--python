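# Methods

This note documents the model the package ships, the assumptions behind
it, the numerical machinery, and the design decisions taken where the
design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Scope of the shipped model

The full-scale *E. coli* bundle (`ccmkin.ecoli.load_ecoli_model`) is a
**structural and behavioural reconstruction**, not a transcription of any
published parameter set. Its network structure is fixed at 27
intracellular metabolites, 22 enzyme/Pts-protein species, 38 metabolic
fluxes, 21 TF-regulated gene-expression balances and 12 biomass precursor
drains; its rate laws use the standard enzyme-kinetic repertoire
(irreversible and reversible Michaelis–Menten forms, two-substrate laws,
competitive allosteric inhibition terms `1/(1 + I/K_I)`, partial
activation terms `b + (1-b)·A/(A+K_A)` with a basal fraction `b`); its
parameters are an in-house calibration to the canonical aerobic
glucose/acetate batch phenotype. Quantitative outputs (specific fluxes,
pool sizes, sensitivity magnitudes) therefore characterise *this*
parameterisation; qualitative regulatory behaviour (diauxie, catabolite
repression, phase transition, mutant orderings) is the level at which the
model is meant to be read. The bundle defines 190 parameters; the loader
accepts and reports whatever count a bundle defines rather than enforcing
one.

## State variables and units

* `X` — cell concentration, gDW/L.
* `x1` — 49 time-varying intracellular concentrations in mM: 27
  metabolites, 21 regulated enzymes, and the Pts carrier EIIA.
* `x2` — ancillary algebraic variables: free and complexed Crp, Cra and
  PdhR, the constant IclR, and the phosphorylated EIIA fraction.
* `y` — extracellular glucose and acetate, mM.

Specific fluxes are mmol/gDW/h. A single conversion constant `rho_cyt`
(gDW per litre of cytoplasm, default 400) couples specific fluxes to
intracellular concentration changes: `dx1/dt = rho_cyt · S·v + ...`. The
extracellular coupling `dy/dt = D(y_feed − y) − g(·)·X` needs no
conversion because mmol/gDW/h × gDW/L = mM/h. With `rho_cyt = 400`
metabolite pools turn over on a seconds timescale while the culture
evolves over hours, which is the physiologically correct (and numerically
stiff) separation.

One bookkeeping note: counting 27 metabolites plus 22 enzyme/Pts proteins
gives 49 integrated intracellular states, not a round 50; the EIIA
phosphorylation state, which some formulations integrate as a separate
molecule, is treated here as a fast-equilibrium ancillary variable (see
below), and the reconstruction documents 49.

## Regulatory layer

Each TF–metabolite complex follows a single-site binding isotherm, e.g.
`[Crp·cAMP] = Crp_tot·[cAMP]/([cAMP] + K_Crp_cAMP)`, so free + complexed
TF is conserved identically (asserted numerically to 1e-10 in the
suite). IclR is constant throughout any simulation.

The phosphorylated Pts carrier is a quasi-equilibrium function of the
PEP/PYR ratio, `EIIAP = EIIA·PEP/(PEP + K_r·PYR + K_0)` with a strictly
positive guard `K_0 = 1e-6 mM`: during fast glucose uptake PEP is drained
and EIIA is mostly dephosphorylated; when glucose runs out the ratio
flips, EIIA-P rises and activates adenylate cyclase. Cya synthesises cAMP
with a Hill-type dependence on EIIA-P (net of first-order degradation,
encoded as one signed flux), and the cAMP turnover time is deliberately
slow (~1.7 h at `rho_cyt = 400`) so the catabolite signal persists through
the growth-to-stationary transition instead of collapsing with the
metabolite pools. Gene-expression balances are synthesis–dilution–turnover
equations `dE/dt = k_s·f_reg(x2) − k_deg·E − mu·E` with multiplicative
activation/repression factors; the 0.08 1/h first-order protein turnover
both lets enzyme levels respond in stationary phase (where mu ≈ 0) and
feeds the maintenance anaplerosis described next.

## Diauxic transition and acetate growth

Three mechanisms make the acetate phase dynamically reachable, all with
direct physiological counterparts:

1. **AceK switch.** Icdh carries an inactivation factor
   `1/(1 + cAMP/K)`, a phenomenological stand-in for AceK-mediated Icdh
   phosphorylation: on acetate (high cAMP) isocitrate is routed through
   the glyoxylate shunt, whose enzymes are simultaneously induced through
   Crp/Cra (and repressed by constant IclR). The separate AceK flux in
   the ATP balance is a pure ATP cost.
2. **Maintenance anaplerosis.** The protein-turnover flux of all 22
   proteins is recycled into αKG (≈250 αKG equivalents per degraded
   enzyme molecule), a small constant seed (~6e-4 mmol/gDW/h)
   representing stationary-phase protein catabolism. Without it the TCA
   pools, which hold only seconds' worth of flux, can hit an absorbing
   all-zero state at the transition from which the autocatalytic cycle
   cannot restart.
3. **Passive acetate exchange.** Intracellular acetate equilibrates with
   the medium through a non-enzymatic transport process
   (`v = k·([ACE] − [ACE_ex])`). This process and the protein-recycle
   seed are flagged `kind: transport` in the reaction table and are not
   counted among the 38 metabolic fluxes.

## Growth law and biomass drains

`v_ATP` sums oxidative phosphorylation (NADH producers Gapdh, Pdh, αkgdh,
Mdh weighted by P/O = 2; FADH2 producer Sdh weighted by (P/O)′ = 1) and
the substrate-level terms, minus the ATP consumers Glk, Pfk, Pps, Acs,
Pck, AceK and Cya. `mu = k_ATP·v_ATP` with `k_ATP = 0.0125 gDW/mmol` and
no floor or ceiling: a transiently negative ATP balance yields decay,
which is what produces the slow biomass decline after substrate
exhaustion. The twelve precursor drains are first-order in their own
metabolite with glucose/acetate availability weights
(`K_Pts_GLC = 0.05 mM`, `K_Acs_ACE = 0.1 mM`); the glucose-phase drain
constants were sized so that at the calibration growth rate each drain
matches standard biomass precursor requirements (e.g. 0.205 mmol G6P per
gDW), and the acetate-phase constants are 6% of those, reflecting the
much slower growth on acetate.

## Calibration targets (the study conditions)

The shipped parameter values were fixed once against these targets and
then frozen:

* batch culture from 22.2 mM glucose, inoculum 0.0015 gDW/L: glucose
  exhausted at 8.0 h; acetate overflow peaking at a few mM during growth
  and re-consumed within ~3 h of glucose depletion; final biomass
  ~1.8 gDW/L;
* a growing chemostat steady state at every dilution rate in
  {0.2, 0.4, 0.5, 0.7} 1/h with glucose feed 22.2 mM — this forces
  mu_max ≈ 0.83 1/h, noticeably above typical literature values for
  glucose minimal medium (~0.6–0.7 1/h); supporting D = 0.7 was given
  priority over batch-phase realism, and the batch inoculum was chosen so
  the depletion time still lands at 8 h;
* knockout orderings: ∆pykF grows like wild type; ∆pgi grows slowly
  through the pentose-phosphate/Entner–Doudoroff routes (glucose gone
  near 23 h); ∆ppc is mildly delayed, limited by the OAA-starved TCA
  cycle while accumulated PEP sustains uptake;
* glucose-uptake capacity (`v_Pts4_max`) is the top-ranked parameter of
  the dynamic-sensitivity protocol.

## Numerical choices

* **Compilation.** Every rate law, ancillary rule and balance is parsed
  and validated with sympy (unresolved symbols are reported with the
  offending rule), then emitted into a single generated Python function
  evaluating the whole right-hand side; this keeps a full-model
  right-hand-side call at ~30 µs, which the 38-simulation sensitivity
  protocol and the GA depend on.
* **Negative-overshoot guard.** Species values are clamped at zero
  *inside* rate-law evaluation only; the integrated state is never
  modified. Trajectories stay above −10·atol.
* **Solver.** LSODA with rtol 1e-8, atol 1e-10 (mM scale) by default;
  flux-correlation analyses need trajectory stability to roughly four
  digits, verified by a tolerance-halving test. GA candidate evaluations
  use rtol 1e-6/atol 1e-8.
* **Steady states.** Damped long-time integration in stretches until the
  scaled residual `max |du|/(|u|+1e-6)` stops above tolerance, then a
  Newton (hybr) polish accepted only if it does not worsen the residual.
  Pure root-finding from cold starts is basin-sensitive because of the
  regulatory algebra. At a growing fixed point mu = D to the residual
  tolerance by construction of the X balance.
* **Degenerate inputs.** All shipped denominators carry strictly positive
  binding constants; division by zero in a user law surfaces as an
  evaluation error naming the reaction.

## Analysis procedures

* **Dynamic sensitivity**: forward (one-sided) finite difference
  `s = [X(t, p+ηp) − X(t,p)]/(ηp) · p/X` with η = 0.01, one full
  re-simulation per parameter, sampled at 6 h, ranked by |s|; a failed
  perturbed run flags its row rather than disappearing. Forward rather
  than central differencing halves the simulation count; the first-order
  bias is O(η) and visible in the suite's closed-form check.
* **Synthesis ratio**: trapezoidal quadrature of `v·X/rho` over each
  strain's growth phase, defined operationally as the time extracellular
  glucose falls below 1% of its initial value (the definition is
  config-exposed). `rho` cancels identically and defaults to 1. Ratios of
  reactions with near-zero wild-type net flux are ill-conditioned; the
  ratio of a reaction with an exactly zero denominator raises, and the
  batch report marks it instead of inventing a number. For the virtual
  mutant summaries the near-zero net cAMP-synthesis flux (Cya) is
  excluded on these grounds.
* **Agreement scoring**: sample Pearson r with the exact two-sided
  t-transform p-value on n−2 degrees of freedom; experimental records are
  matched to the nearest output-grid time within 0.05 h; p-values are
  reported raw, with no multiple-comparison correction, and the report
  says so.

## Parameter estimation

Parameters are classed I (measured), II (literature-derived), III
(unknown) with penalty weights λ1 > λ2 > λ3 ≥ 0 (defaults 10, 1, 0.1 —
only the ordering is principled; the magnitudes are config-exposed). The
deviation measure is the squared log-ratio from the literature anchor,
making multiplicative deviations symmetric for constants spanning
decades. Behavioural constraints are if–then rules scored continuously on
simulated trajectories (threshold, depletion-window and normalized-RMSE
rule kinds); candidates are ranked lexicographically (total violation,
then objective), so any feasible individual beats any infeasible one — no
penalty-mixing coefficient is needed.

The search is UNDX crossover under MGG generation alternation, in
log-space for positive parameters, with out-of-bounds components
reflected back into the box. UNDX samples children around the midpoint of
two parents with primary standard deviation 0.5·|d| along their
difference vector and orthogonal standard deviation 0.35·D/√n set by the
third parent's distance D from that line; MGG replaces exactly two
population slots per step (family elite plus a rank-roulette pick), which
preserves diversity and makes the best feasible score monotone.
Candidate evaluations are independent; the `map` used to evaluate them is
injectable for concurrent execution, and results are reduced in
submission order, so a run is bit-reproducible given its seed.

Desk-scale defaults: population 100, 8 children per family, a
2×10⁴-evaluation budget. The package's reference estimation experiment
recovers three kinetic constants of the toy model (uptake capacity,
catalytic constant, Michaelis constant) from 24-point noiseless time
courses of X, substrate and the internal metabolite, starting from a
blinded point up to ±1.5 decades away; across probe seeds the worst-case
recovery error is a few percent. Normalising each series' RMSE by its
mean magnitude matters here: with raw RMSE the substrate series (scale
~20 mM) dominates the biomass series (scale ~1) and the search stalls on
a compensation ridge between the catalytic and Michaelis constants.
No gradient-based or hybrid local refinement is used anywhere.

A CLI estimation config is YAML of the form:

```yaml
model: ecoli            # or a bundle directory
search_parameters: [v_Pts4_max, k_Pfk_cat]
objective: {lambda1: 10.0, lambda2: 1.0, lambda3: 0.1}
scenarios:
  wt_batch: {mode: batch, t_span: [0.0, 10.0], rtol: 1.0e-6, atol: 1.0e-8}
rules:
  - {id: glc_gone, scenario: wt_batch, kind: deplete_window,
     quantity: GLCex, frac: 0.01, t_lo: 7.0, t_hi: 9.0}
ga: {population: 50, children: 8, steps: 500}
max_evaluations: 5000
```

## Synthetic data generator

`ccmkin.fixtures.generate_fixtures` simulates the regulated toy network
(one TF, one allosteric inhibition, one expressed enzyme) at its true
parameters and emits experimental-style tables (strain, time_h, quantity,
value, sd) with relative Gaussian noise; regeneration with the same seed
is bit-identical, zero noise reproduces the simulation exactly, and the
true parameters are stored alongside. It emulates the *layout and
information content* of batch time-course data — it does not emulate
measurement-error correlation, missingness, calibration drift or
inter-replicate variability, so tests passing on these fixtures
demonstrate correctness of the machinery, not robustness to real
measurement pathology.

## Model exchange

SBML Level 3 export represents every integrated quantity as a species
under a rate rule and every derived quantity (x2, fluxes, drains, mu,
v_ATP) as a parameter under an assignment rule; documents pass libsbml
consistency checking, and an embedded annotation makes
`import(export(m))` lossless (foreign SBML import is rejected with an
explanatory error). Simulation settings travel in the bundle's
`model.yaml` and in per-run manifests written by every CLI command
(inputs, table checksums, seed, package version) rather than in SED-ML.

## Problem sizes used by the test and acceptance runs

Batch reproductions use a 0.05 h output grid over 0–10 h (wild type,
∆pykF) or 0–26 h (∆pgi, ∆ppc); chemostat steady states relax for at most
200 h of model time before polishing; the sensitivity protocol runs one
6.5 h simulation per activity parameter; the recovery experiment spends
2×10⁴ toy-model evaluations. A full-model batch simulation costs roughly
two seconds, which sets the scale of everything above.

## Known limitations

* Cofactor pools (ATP, NADH, NADPH) are not state variables; the ATP
  balance is purely flux-algebraic, so redox/energy feedback on kinetics
  is absent.
* Dissolved oxygen is not modelled; oxidative phosphorylation never
  oxygen-limits.
* The parameterisation is a calibration, not a fit: printed quantitative
  results from any specific laboratory dataset (flux-panel correlation
  coefficients, sensitivity magnitudes) should not be expected to
  reproduce, and the acceptance suite makes that visible rather than
  hiding it.
* mu_max ≈ 0.83 1/h is high for glucose minimal medium (a consequence of
  requiring growth at D = 0.7 1/h).
* Acetate-phase gluconeogenic flux magnitudes are weakly constrained;
  only their signs and orderings were calibrated.
* The Eq-style synthesis-ratio is undefined where the wild-type integral
  vanishes and ill-conditioned where it nearly does (Cya here; the
  glyoxylate-shunt reactions in general during the growth phase).
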