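"""Shared fixtures and the independent cobrapy/GLPK oracle.

The implementation under test solves its LPs with scipy's HiGHS; the oracle
rebuilds each toy model in cobrapy and solves with GLPK, a fully independent
code path, so agreement is meaningful.
"""

from __future__ import annotations

import pytest

from gemstream import synth


@pytest.fixture
def chain_model():
    return synth.make_toy_model(synth.ToyNetworkSpec(kind="chain", seed=11))


@pytest.fixture
def branch_model():
    return synth.make_toy_model(
        synth.ToyNetworkSpec(kind="parallel_branch", seed=11))


@pytest.fixture
def loop_model():
    return synth.make_toy_model(
        synth.ToyNetworkSpec(kind="core_loop", seed=11,
                             n_padding_reactions=2))


def to_cobra(model):
    """Rebuild a gemstream model in cobrapy (oracle use only)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment)
            for m in model.metabolites}
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[mid]: coeff for mid, coeff in r.stoichiometry.items()})
    cm.objective = model.objective_reaction_id
    cm.solver = "glpk"
    return cm


def cobra_mgr(model) -> float:
    sol = to_cobra(model).optimize()
    return float(sol.objective_value) if sol.status == "optimal" else float("nan")


def cobra_fva(model, fraction: float = 1.0):
    from cobra.flux_analysis import flux_variability_analysis

    return flux_variability_analysis(to_cobra(model),
                                     fraction_of_optimum=fraction)
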