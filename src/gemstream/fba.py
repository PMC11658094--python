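"""Flux balance analysis and derived analyses.

All linear programs are solved with HiGHS through
:func:`scipy.optimize.linprog` on the standard constraint set

    S · v = 0,   lb ≤ v ≤ ub,

where ``S`` is the stoichiometric matrix (metabolites × reactions) and ``v``
the flux vector in mmol·gDW⁻¹·h⁻¹. With the biomass reaction as objective the
optimum is the maximum growth rate (MGR, h⁻¹).

Because FBA optima are typically degenerate, flux vectors used for
model-to-model comparison come from parsimonious FBA (pFBA): the objective is
fixed at its optimum and total absolute flux Σ|v| is minimised, which picks a
reproducible point of the optimal face.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog
from scipy.stats import hypergeom

from .model import MetabolicModel, require_valid

logger = logging.getLogger("gemstream")

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-9
DEFAULT_STRICT_THRESHOLD = 0.01
DEFAULT_DIFF_EPSILON = 1e-6


class InfeasibleModelError(RuntimeError):
    """Raised when an analysis requires a feasible/optimal FBA solution."""


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------

def _lp_arrays(model: MetabolicModel):
    """Stoichiometric matrix S (sparse), bounds, and reaction index map."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    n_mets, n_rxns = len(model.metabolites), len(model.reactions)
    rows, cols, vals = [], [], []
    lb = np.empty(n_rxns)
    ub = np.empty(n_rxns)
    for j, rxn in enumerate(model.reactions):
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for met_id, coeff in rxn.stoichiometry.items():
            rows.append(met_index[met_id])
            cols.append(j)
            vals.append(coeff)
    S = sparse.csr_matrix((vals, (rows, cols)), shape=(n_mets, n_rxns))
    return S, lb, ub


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded",
           4: "numerical"}


def _solve(S, b, c, lb, ub):
    res = linprog(
        c, A_eq=S, b_eq=b, bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": 1e-9,
                 "dual_feasibility_tolerance": 1e-9},
    )
    return res


# ---------------------------------------------------------------------------
# FBA / pFBA
# ---------------------------------------------------------------------------

@dataclass
class FluxSolution:
    """An FBA (or pFBA) solution.

    ``objective_value`` equals the flux through the objective reaction; for a
    biomass objective this is the MGR in h⁻¹.
    """

    model_id: str
    status: str
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)
    is_parsimonious: bool = False

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def to_series(self) -> pd.Series:
        return pd.Series(self.fluxes, name=self.model_id)


def solve_fba(model: MetabolicModel, direction: str = "max") -> FluxSolution:
    """Maximise (or minimise) the objective reaction flux subject to
    steady-state mass balance and the flux bounds."""
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    require_valid(model)
    S, lb, ub = _lp_arrays(model)
    rxn_ids = [r.id for r in model.reactions]
    obj_idx = rxn_ids.index(model.objective_reaction_id)
    c = np.zeros(len(rxn_ids))
    c[obj_idx] = -1.0 if direction == "max" else 1.0
    res = _solve(S, np.zeros(S.shape[0]), c, lb, ub)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(model_id=model.id, status=status,
                            objective_value=np.nan)
    fluxes = dict(zip(rxn_ids, map(float, res.x)))
    return FluxSolution(
        model_id=model.id, status="optimal",
        objective_value=fluxes[model.objective_reaction_id], fluxes=fluxes)


def solve_pfba(model: MetabolicModel) -> FluxSolution:
    """Parsimonious FBA: fix the objective at its FBA optimum, then minimise
    total absolute flux via splitting v = f − b with f, b ≥ 0."""
    fba = solve_fba(model)
    if not fba.optimal:
        raise InfeasibleModelError(
            f"FBA on model {model.id!r} is {fba.status}; pFBA undefined")
    S, lb, ub = _lp_arrays(model)
    rxn_ids = [r.id for r in model.reactions]
    n = len(rxn_ids)
    obj_idx = rxn_ids.index(model.objective_reaction_id)
    opt = fba.objective_value

    # pin the objective flux at the optimum before splitting
    lb = lb.copy()
    ub = ub.copy()
    lb[obj_idx] = ub[obj_idx] = opt

    f_lb, f_ub = np.maximum(lb, 0.0), np.maximum(ub, 0.0)
    b_lb, b_ub = np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)
    S_split = sparse.hstack([S, -S], format="csr")
    c = np.ones(2 * n)
    res = _solve(S_split, np.zeros(S.shape[0]), c,
                 np.concatenate([f_lb, b_lb]), np.concatenate([f_ub, b_ub]))
    if res.status != 0:
        raise InfeasibleModelError(
            f"pFBA stage-two LP on model {model.id!r} returned status "
            f"{_STATUS.get(res.status, res.status)}; check LP tolerances")
    v = res.x[:n] - res.x[n:]
    fluxes = dict(zip(rxn_ids, map(float, v)))
    return FluxSolution(
        model_id=model.id, status="optimal",
        objective_value=fluxes[model.objective_reaction_id],
        fluxes=fluxes, is_parsimonious=True)


# ---------------------------------------------------------------------------
# FVA and strict-constraint classification
# ---------------------------------------------------------------------------

def classify_strict(
    min_flux: float, max_flux: float,
    threshold: float = DEFAULT_STRICT_THRESHOLD,
) -> tuple[float, bool]:
    """Relative flux-range change and the strictly-constrained call.

    relative_change = |max_flux − min_flux| / max(|max_flux|, |min_flux|);
    the 0/0 case (a blocked reaction) is defined as 0, hence strict. A
    reaction is strictly constrained when relative_change is strictly below
    the threshold.
    """
    if min_flux > max_flux:
        raise ValueError(f"min_flux {min_flux} exceeds max_flux {max_flux}")
    denom = max(abs(max_flux), abs(min_flux))
    relative_change = abs(max_flux - min_flux) / denom if denom > 0 else 0.0
    return relative_change, relative_change < threshold


@dataclass
class FVAResult:
    """Per-reaction flux ranges at fixed (optimal) growth, with the
    strictly-constrained classification."""

    model_id: str
    objective_value: float
    strict_threshold: float
    frame: pd.DataFrame  # index reaction_id; min_flux max_flux relative_change strict

    @property
    def strict_reactions(self) -> set[str]:
        return set(self.frame.index[self.frame["strict"]])

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "reaction_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def run_fva(
    model: MetabolicModel,
    strict_threshold: float = DEFAULT_STRICT_THRESHOLD,
    fraction_of_optimum: float = 1.0,
) -> FVAResult:
    """Flux variability analysis with the objective fixed at its FBA optimum.

    For every reaction the flux is minimised and maximised subject to mass
    balance, the bounds, and objective flux = fraction_of_optimum × optimum
    (an equality at the default fraction 1.0).
    """
    fba = solve_fba(model)
    if not fba.optimal:
        raise InfeasibleModelError(
            f"FBA on model {model.id!r} is {fba.status}; check that the medium "
            "supplies a usable carbon source before running FVA")
    S, lb, ub = _lp_arrays(model)
    rxn_ids = [r.id for r in model.reactions]
    obj_idx = rxn_ids.index(model.objective_reaction_id)
    opt = fba.objective_value
    lb = lb.copy()
    ub = ub.copy()
    if fraction_of_optimum >= 1.0:
        lb[obj_idx] = ub[obj_idx] = opt
    else:
        lb[obj_idx] = fraction_of_optimum * opt

    b = np.zeros(S.shape[0])
    records = []
    c = np.zeros(len(rxn_ids))
    for j, rid in enumerate(rxn_ids):
        c[:] = 0.0
        c[j] = 1.0
        res_min = _solve(S, b, c, lb, ub)
        c[j] = -1.0
        res_max = _solve(S, b, c, lb, ub)
        if res_min.status != 0 or res_max.status != 0:
            raise InfeasibleModelError(
                f"FVA sub-problem for reaction {rid!r} failed "
                f"(min status {res_min.status}, max status {res_max.status})")
        vmin, vmax = res_min.x[j], res_max.x[j]
        if vmin > vmax:  # solver noise on a degenerate range
            vmin = vmax = 0.5 * (vmin + vmax)
        rel, strict = classify_strict(vmin, vmax, strict_threshold)
        records.append((rid, vmin, vmax, rel, strict))

    frame = pd.DataFrame(
        records, columns=["reaction_id", "min_flux", "max_flux",
                          "relative_change", "strict"],
    ).set_index("reaction_id")
    return FVAResult(model_id=model.id, objective_value=opt,
                     strict_threshold=strict_threshold, frame=frame)


# ---------------------------------------------------------------------------
# Differential flux between two models
# ---------------------------------------------------------------------------

@dataclass
class DifferentialFluxSet:
    """Reactions whose pFBA fluxes differ between two models, plus reactions
    exclusive to one model that carry flux there."""

    model_a: str
    model_b: str
    shared_diff: set[str]
    exclusive_active: set[tuple[str, str]]
    epsilon: float

    def to_frame(self) -> pd.DataFrame:
        rows = [("shared", self.model_a + "|" + self.model_b, rid)
                for rid in sorted(self.shared_diff)]
        rows += [("exclusive", mid, rid)
                 for mid, rid in sorted(self.exclusive_active)]
        return pd.DataFrame(rows, columns=["kind", "model", "reaction_id"])


def compare_flux(
    sol_a: FluxSolution, sol_b: FluxSolution,
    model_a: MetabolicModel, model_b: MetabolicModel,
    epsilon: float = DEFAULT_DIFF_EPSILON,
) -> DifferentialFluxSet:
    """Differential-flux reactions between two pFBA solutions.

    Requires parsimonious solutions: degenerate plain-FBA vertices would make
    the differential set solver-dependent.
    """
    for sol in (sol_a, sol_b):
        if not sol.optimal:
            raise InfeasibleModelError(f"solution for {sol.model_id!r} not optimal")
        if not sol.is_parsimonious:
            raise ValueError(
                f"solution for {sol.model_id!r} is not parsimonious; use "
                "solve_pfba so the differential set is well defined")
    ids_a = {r.id for r in model_a.reactions}
    ids_b = {r.id for r in model_b.reactions}
    shared = ids_a & ids_b
    shared_diff = {
        rid for rid in shared
        if abs(sol_a.fluxes[rid] - sol_b.fluxes[rid]) > epsilon
    }
    exclusive_active = set()
    for mid, sol, only in ((model_a.id, sol_a, ids_a - ids_b),
                           (model_b.id, sol_b, ids_b - ids_a)):
        for rid in only:
            if abs(sol.fluxes[rid]) > epsilon:
                exclusive_active.add((mid, rid))
    return DifferentialFluxSet(
        model_a=model_a.id, model_b=model_b.id, shared_diff=shared_diff,
        exclusive_active=exclusive_active, epsilon=epsilon)


# ---------------------------------------------------------------------------
# Pathway over-representation of differential reactions
# ---------------------------------------------------------------------------

def enrich_pathways(
    diff: DifferentialFluxSet | set[str], model: MetabolicModel,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of differential-flux
    reactions within each pathway tag, Benjamini–Hochberg adjusted.

    The universe is every reaction of the model; for each tag with K member
    reactions and a differential set of size n drawn from the N-reaction
    universe with k members in the tag, the p-value is P[X ≥ k] for
    X ~ Hypergeometric(N, K, n).
    """
    from statsmodels.stats.multitest import multipletests

    diff_ids = diff.shared_diff if isinstance(diff, DifferentialFluxSet) else set(diff)
    universe = [r.id for r in model.reactions]
    N = len(universe)
    diff_in_universe = diff_ids & set(universe)
    n = len(diff_in_universe)
    tags = sorted({t for r in model.reactions for t in r.pathway_tags})
    if not tags:
        logger.warning("model %s carries no pathway tags; enrichment table "
                       "is empty", model.id)
        return pd.DataFrame(
            columns=["pathway", "k", "K", "n", "N", "p_value", "adjusted_p"])
    rows = []
    for tag in tags:
        members = {r.id for r in model.reactions if tag in r.pathway_tags}
        K = len(members)
        k = len(members & diff_in_universe)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((tag, k, K, n, N, min(p, 1.0)))
    frame = pd.DataFrame(rows, columns=["pathway", "k", "K", "n", "N", "p_value"])
    frame["adjusted_p"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    return frame.sort_values("p_value", kind="stable").reset_index(drop=True)
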