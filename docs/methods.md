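# Methods

## The model

`gemstream` analyses stoichiometric metabolic models under the standard
constraint-based assumptions: steady state (**S**·**v** = 0), flux bounds
lb ≤ **v** ≤ ub in mmol·gDW⁻¹·h⁻¹, and a biomass pseudo-reaction whose flux
(h⁻¹) is the growth rate. No kinetics, thermodynamic constraints, or enzyme
capacities are modelled; internal loops are not excluded except insofar as
parsimonious FBA suppresses them.

Bound conventions follow common practice for curated GEMs: every metabolic
reaction has upper bound 1000 (−1000 lower bound if reversible, 0 if not);
exchange reactions open for uptake at −100 for medium compounds and −10 for
oxygen, all other exchange lower bounds 0, exchange upper bounds 1000
(secretion always allowed). Negative exchange flux is uptake. A medium is
therefore a map from exchange reactions to maximum uptake rates; applying it
closes every exchange it does not name.

## In-silico genome streamlining

A deletion plan is an ordered list of stages, each holding genomic regions
(prophage / genomic island / nuclease gene / other; 0-based half-open
coordinates, with a flag to convert 1-based inclusive input). Deriving the
stage-*k* model from the wild type does two things:

1. **Gene-deletion propagation.** The union of member genes of stages 1..k
   is evaluated against every reaction's GPR (AND = complex, OR = isozymes,
   no negation). Reactions whose GPR evaluates false get both bounds set to
   0 but are *retained*, so flux vectors of all strains stay aligned
   reaction-by-reaction for differential comparison; deleted genes move to a
   `deleted_genes` record so GPRs still resolve. Reactions without a GPR are
   treated as spontaneous/orphan and are never disabled. Genes absent from
   the model (most prophage/island genes are non-metabolic) are ignored with
   a warning.
2. **Proportional BOF rescaling.** Less genome means proportionally less
   nucleotide/deoxynucleotide demand per gram biomass, so the biomass
   coefficients of ATP, GTP, CTP, UTP, dATP, dGTP, dCTP and dTTP are
   multiplied by the stage factor 1 − *p*. In the default
   `nominal_percent` mode stage *k* uses 1 − 0.01·k (the portions are
   designed as ~1% of the genome each, and the worked adjustment for one
   portion uses exactly ×0.99); `exact_bp` mode uses the exact cumulative
   deleted fraction instead and is provided for sensitivity analysis. Only
   biomass-reaction coefficients are scaled; a separately modelled growth-
   associated maintenance reaction, if any, is left untouched. Signs are
   preserved and magnitudes scaled, so 40.1654758653685 × 0.99 =
   39.7638211067148 (to printed precision).

Where the convention was genuinely open — disable-in-place vs removal of
knocked-out reactions, nominal vs exact stage factors — the choice above is
the package's own; both alternatives are reachable through the API
(`factor_mode`, reaction removal can be layered on by filtering
zero-bound reactions).

## Flux analysis

* **FBA** solves the LP with scipy's HiGHS (primal/dual feasibility
  tolerances 1e-9). Infeasibility and unboundedness are reported as
  statuses, not exceptions, except where an analysis requires an optimum.
* **pFBA** fixes the objective flux at its optimum, splits each flux into
  non-negative forward/backward parts, and minimises total absolute flux.
  FBA optima are typically degenerate; any flux vector used for
  strain-to-strain comparison is required to be parsimonious so that the
  differential-flux set does not depend on the solver's vertex choice.
* **FVA** fixes the objective at 100% of the optimum (a
  `fraction_of_optimum` parameter, default 1.0, relaxes this) and
  min/maximises each reaction in turn. A reaction is *strictly constrained*
  when `|maxFlux − minFlux| / max(|maxFlux|, |minFlux|)` is strictly below
  the threshold (default 0.01). The 0/0 case — a blocked reaction — is
  defined as relative change 0 and hence strict. Solver noise that leaves
  min marginally above max on a degenerate range is collapsed to the
  midpoint.
* **Differential flux** between two parsimonious solutions: shared reactions
  with |v_A − v_B| > ε (default ε = 1e-6 mmol·gDW⁻¹·h⁻¹, an implementation
  choice well above LP tolerance), plus reactions exclusive to one model
  that carry |v| > ε there.
* **Enrichment** of a differential set within pathway tags uses the
  one-sided hypergeometric over-representation test (scipy) with
  Benjamini–Hochberg adjustment across tags (statsmodels). The universe is
  all reactions of the reference model. The test choice is the package's
  own; the analysis it mirrors names only "enrichment".

## Carbon-source screening

Each panel entry is simulated as sole carbon source: base mineral medium
applied, the substrate's exchange opened at the standard −100 bound, every
other carbon exchange closed. If the entry names a metabolite without an
exchange path, a reversible free-diffusion transport plus exchange (bounds
±1000) is injected first — the convention used for substrates like phenol
whose transporter is not in the reconstruction. Growth is called at
MGR ≥ 1e-4 h⁻¹, a threshold chosen well above LP noise and far below any
biologically meaningful growth rate (the qualitative in-silico cutoff is
never stated alongside plate experiments; it is configurable). Predicted
vs observed calls populate a TP/FP/FN/TN confusion matrix with accuracy
(TP+TN)/n. Quantitative validation compares the MGR at a measured substrate
uptake bound (e.g. glucose at 6.1 mmol·gDW⁻¹·h⁻¹) with a measured rate and
passes when the relative difference is strictly below 20%.

## Growth-curve phenotyping

The estimators are non-parametric on purpose: the synthetic generator uses
a sigmoid family, and fitting the same family back would be an inverse
crime. μmax is the OLS slope of ln OD over sliding windows (≥ 4 points):
among windows whose R² is within 1e-3 of the best, the steepest wins —
near-ties between the quasi-linear stretches of a smooth sigmoid are thereby
resolved toward the inflection, whose tangent slope is the maximum specific
rate. Flat (zero-variance) windows score R² = 0; a fully flat curve yields
μ = 0. Lag is the classical geometric construction: where the tangent to
ln OD over the chosen window crosses the initial ln OD, clipped to the
observed time range. Maximum OD is taken after median-of-3 smoothing
(single-point spikes discounted; can be disabled). The maximum degradation
rate is the steepest negative OLS slope over 3-point sliding windows of a
concentration series, 0 if the series never falls. Lag is reported by this
estimator's definition; curve-derived lags from other conventions (visual
inspection, parametric fits) will differ by up to a sampling interval.

## Synthetic data and what passing tests show

The generators produce desk-scale fixtures with recomputable truths:

* **Toy networks** (chain, parallel branch, and a lumped
  glycolysis/pentose-phosphate/TCA loop with pathway tags): closed-form
  MGR = yield × uptake / Σ biomass coefficients, known strict/non-strict
  sets, optional blocked "padding" reactions, and GPRs with planted
  essential genes and isozyme pairs. Networks stay ≤ ~40 reactions so
  oracle LPs run sub-second.
* **Streamlining fixtures**: nine regions in the 4/2/3
  prophage/island/nuclease census, ~1% of a synthetic genome per stage,
  synthetic gene labels (optionally including one planted essential model
  gene), and the analytic post-derivation MGR per stage.
* **Panels**: positive sources wired into the network, negative sources as
  dead ends, so the planted truth is exact by construction.
* **Curves**: Zwietering-type Gompertz on the log scale
  ln(OD/OD₀) = A·exp(−exp(μe/A·(λ−t)+1)), A = ln(plateau/OD₀), so the
  planted μ is the true maximum specific growth rate; multiplicative
  lognormal noise. Default sampling 0–48 h at 0.5 h.

One integer seed drives a named stream per generator
(`default_rng([seed, crc32(name)])`), so fixtures are independent of
generation order and byte-reproducible.

These fixtures emulate structure, not scale: they do not reproduce the
thousands of reactions, cofactor coupling, redundancy, or annotation noise
of a real genome-scale reconstruction. Passing tests therefore demonstrate
that the operations are implemented correctly (exact arithmetic, LP optima,
classification boundaries, estimator recovery), not that a particular
organism's model achieves any particular accuracy; genome-scale claims
require the deposited models (see `evaluate_deposited_models`), which must
be downloaded separately.

## Numerical choices and degenerate inputs

* LP tolerances 1e-9 (HiGHS primal/dual); pFBA must reproduce the FBA
  optimum within 1e-6 relative or it errors.
* FVA strict threshold 0.01, strict inequality; relative change at 0/0 is 0.
* Differential-flux ε = 1e-6; growth-call threshold 1e-4 h⁻¹.
* Region overlaps are merged (with a warning) before totals; summaries are
  order-invariant.
* Empty media, empty panels, empty plans, and zero-growth models are valid
  inputs with well-defined (empty/zero) outputs.
* Curve windows are selected with R² rounded to 10 digits and slopes to 10
  digits for tie-breaking, so selection is stable under float noise.

## Problem sizes

The test suite and acceptance script use toy networks of 5–15 reactions,
100-seed screening sweeps (10 sources each), 200-curve recovery sweeps, and
25-panel accuracy averages; the full suite runs in well under a minute on a
single CPU. Genome-scale models load and solve through the same code paths
(sparse LP assembly), with FVA costing two LPs per reaction.

## Known limitations

* No gap filling, mass/charge balancing, or external model-quality scoring;
  models are taken as given and only structurally validated.
* No thermodynamic or regulatory constraints; FVA ranges may include
  thermodynamically infeasible loop fluxes (pFBA mitigates but does not
  eliminate this for the comparison vectors).
* The qualitative growth threshold, differential ε, and the lag definition
  are documented conventions, not measured constants; conclusions sensitive
  to them should be checked across the exposed parameters.
* `evaluate_deposited_models` computes improvement tables for deposited
  model pairs but depends on a user-supplied substrate mapping for the
  panel conditions.
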