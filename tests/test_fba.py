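"""FBA/pFBA/FVA against analytic optima and the independent cobrapy/GLPK
oracle; strict-constraint classification; differential flux; enrichment."""

import itertools
import math

import numpy as np
import pytest

from gemstream import (
    Medium,
    classify_strict,
    compare_flux,
    enrich_pathways,
    percent_mgr_improvement,
    rescale_bof,
    run_fva,
    set_medium,
    solve_fba,
    solve_pfba,
)
from gemstream.fba import InfeasibleModelError
from gemstream.model import ModelValidationError
from gemstream import synth

from conftest import cobra_mgr, cobra_fva


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def test_chain_mgr_is_uptake_over_biomass_cost(chain_model):
    """Substrate-limited chain: MGR = uptake / biomass coefficient = 10/2."""
    model, truth = chain_model
    sol = solve_fba(model)
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(5.0, abs=1e-9)
    assert sol.objective_value == pytest.approx(truth.mgr_expected, abs=1e-9)
    # objective value is literally the objective reaction's flux
    assert sol.objective_value == pytest.approx(sol.fluxes["BIO"], abs=1e-12)


def test_no_food_no_growth(chain_model):
    model, _ = chain_model
    starved = set_medium(model, Medium())
    sol = solve_fba(starved)
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_invalid_bounds_rejected_before_solving(chain_model):
    model, _ = chain_model
    model = model.copy()
    model.get_reaction("R1").lower_bound = 5.0
    model.get_reaction("R1").upper_bound = 1.0
    with pytest.raises(ModelValidationError):
        solve_fba(model)


def test_mass_balance_and_bounds_hold_at_optimum(loop_model):
    model, _ = loop_model
    sol = solve_fba(model)
    by_id = {m.id: 0.0 for m in model.metabolites}
    for r in model.reactions:
        v = sol.fluxes[r.id]
        assert r.lower_bound - 1e-7 <= v <= r.upper_bound + 1e-7
        for met, coeff in r.stoichiometry.items():
            by_id[met] += coeff * v
    vmax = max(abs(v) for v in sol.fluxes.values())
    assert all(abs(b) <= 1e-8 * max(1.0, vmax) for b in by_id.values())


@pytest.mark.parametrize("kind", ["chain", "parallel_branch", "core_loop"])
@pytest.mark.parametrize("seed", range(5))
def test_fba_matches_cobra_oracle(kind, seed):
    spec = synth.ToyNetworkSpec(kind=kind, seed=seed,
                                uptake_bound=5.0 + seed,
                                n_padding_reactions=seed % 4)
    model, truth = synth.make_toy_model(spec)
    ours = solve_fba(model).objective_value
    assert ours == pytest.approx(cobra_mgr(model), abs=1e-6)
    assert ours == pytest.approx(truth.mgr_expected, abs=1e-6)


def test_bof_scaling_law(chain_model):
    """Scaling every biomass substrate coefficient by f scales MGR by 1/f."""
    model, truth = chain_model
    for f in (0.99, 0.96, 0.5):
        scaled, _ = rescale_bof(model, f, components=["atp"])
        assert solve_fba(scaled).objective_value == pytest.approx(
            truth.mgr_expected / f, rel=1e-9)


# ---------------------------------------------------------------------------
# pFBA
# ---------------------------------------------------------------------------

def test_pfba_on_unique_optimum_equals_fba(chain_model):
    model, _ = chain_model
    fba, pfba = solve_fba(model), solve_pfba(model)
    assert pfba.is_parsimonious
    assert pfba.objective_value == pytest.approx(fba.objective_value, rel=1e-6)
    for rid, v in fba.fluxes.items():
        assert pfba.fluxes[rid] == pytest.approx(v, abs=1e-6)


def test_pfba_minimises_total_flux_on_parallel_branches(branch_model):
    """Both extreme routings of the two-branch toy carry the same total flux;
    pFBA must land exactly on that minimum."""
    model, truth = branch_model
    pfba = solve_pfba(model)
    # enumerate the two extreme routings of 10 units over the branches
    expected_total = min(
        10.0 + 10.0 + a + b + truth.mgr_expected
        for a, b in [(10.0, 0.0), (0.0, 10.0)])
    assert sum(abs(v) for v in pfba.fluxes.values()) == pytest.approx(
        expected_total, abs=1e-6)


def test_pfba_zero_growth_gives_zero_fluxes(chain_model):
    model, _ = chain_model
    pfba = solve_pfba(set_medium(model, Medium()))
    assert all(v == pytest.approx(0.0, abs=1e-9) for v in pfba.fluxes.values())


# ---------------------------------------------------------------------------
# classify_strict
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("vmin,vmax,rel,strict", [
    (9.95, 10.0, 0.005, True),
    (0.0, 10.0, 1.0, False),
    (99.0, 100.0, 0.01, False),  # boundary: strictly-less-than threshold
    (0.0, 0.0, 0.0, True),      # blocked reaction: 0/0 defined as 0
    (-10.0, -9.95, 0.005, True),
])
def test_classify_strict_formula(vmin, vmax, rel, strict):
    got_rel, got_strict = classify_strict(vmin, vmax)
    assert got_rel == pytest.approx(rel, abs=1e-12)
    assert got_strict is strict


def test_classify_strict_rejects_inverted_range():
    with pytest.raises(ValueError):
        classify_strict(1.0, 0.5)


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

def test_fva_branch_toy_ranges_and_strict_calls(branch_model):
    """Redundant branches have range [0, 10] (non-strict); the stem and
    biomass are pinned (strict)."""
    model, truth = branch_model
    fva = run_fva(model)
    frame = fva.frame
    for rid in ("R_branch1", "R_branch2"):
        assert frame.loc[rid, "min_flux"] == pytest.approx(0.0, abs=1e-6)
        assert frame.loc[rid, "max_flux"] == pytest.approx(10.0, abs=1e-6)
        assert frame.loc[rid, "relative_change"] == pytest.approx(1.0, abs=1e-6)
        assert not frame.loc[rid, "strict"]
    assert fva.strict_reactions == truth.strict_reactions


def test_fva_linear_chain_everything_strict(chain_model):
    model, truth = chain_model
    fva = run_fva(model)
    assert fva.strict_reactions == truth.strict_reactions == \
        {r.id for r in model.reactions}


def test_fva_blocked_reaction_is_strict():
    model, _ = synth.make_toy_model(
        synth.ToyNetworkSpec(seed=3, n_padding_reactions=2))
    fva = run_fva(model)
    for rid in ("PAD0", "PAD1"):
        assert fva.frame.loc[rid, "min_flux"] == pytest.approx(0.0, abs=1e-9)
        assert fva.frame.loc[rid, "max_flux"] == pytest.approx(0.0, abs=1e-9)
        assert fva.frame.loc[rid, "strict"]


@pytest.mark.parametrize("kind", ["parallel_branch", "core_loop"])
def test_fva_matches_cobra_oracle(kind):
    model, _ = synth.make_toy_model(synth.ToyNetworkSpec(kind=kind, seed=4))
    ours = run_fva(model).frame
    theirs = cobra_fva(model)
    for rid in ours.index:
        assert ours.loc[rid, "min_flux"] == pytest.approx(
            theirs.loc[rid, "minimum"], abs=1e-6)
        assert ours.loc[rid, "max_flux"] == pytest.approx(
            theirs.loc[rid, "maximum"], abs=1e-6)


def test_fva_sandwich_contains_pfba_flux(branch_model, loop_model):
    for model, _ in (branch_model, loop_model):
        pfba = solve_pfba(model)
        fva = run_fva(model)
        for rid in pfba.fluxes:
            assert fva.frame.loc[rid, "min_flux"] - 1e-6 <= pfba.fluxes[rid] \
                <= fva.frame.loc[rid, "max_flux"] + 1e-6


def test_fva_requires_feasible_growth(chain_model):
    model, _ = chain_model
    with pytest.raises(InfeasibleModelError, match="medium"):
        model = model.copy()
        model.get_reaction("BIO").lower_bound = 100.0  # impossible demand
        run_fva(model)


# ---------------------------------------------------------------------------
# Differential flux
# ---------------------------------------------------------------------------

def test_identical_models_have_empty_differential_set(chain_model):
    model, _ = chain_model
    sol = solve_pfba(model)
    diff = compare_flux(sol, sol, model, model)
    assert diff.shared_diff == set()
    assert diff.exclusive_active == set()


def test_bof_rescaling_shifts_every_scaling_reaction(chain_model):
    """Against the ×0.99 rescaled model, every reaction whose flux scales
    with the growth rate is differential; substrate-limited reactions
    (pinned at the uptake bound) are not."""
    model, _ = chain_model
    scaled, _ = rescale_bof(model, 0.99, components=["atp"])
    scaled.id = "scaled"
    sol_a, sol_b = solve_pfba(model), solve_pfba(scaled)
    diff = compare_flux(sol_a, sol_b, model, scaled)
    # chain: uptake-pinned reactions keep flux 10; BIO and SYN_atp scale
    assert "BIO" in diff.shared_diff
    assert "EX_s_e0" not in diff.shared_diff
    expected = {rid for rid in sol_a.fluxes
                if abs(sol_a.fluxes[rid] - sol_b.fluxes[rid]) > 1e-6}
    assert diff.shared_diff == expected


def test_differential_set_is_symmetric(chain_model):
    model, _ = chain_model
    scaled, _ = rescale_bof(model, 0.97, components=["atp"])
    scaled.id = "scaled"
    sol_a, sol_b = solve_pfba(model), solve_pfba(scaled)
    ab = compare_flux(sol_a, sol_b, model, scaled)
    ba = compare_flux(sol_b, sol_a, scaled, model)
    assert ab.shared_diff == ba.shared_diff


def test_exclusive_reaction_without_flux_not_reported(chain_model):
    model, _ = chain_model
    bigger, _ = synth.make_toy_model(
        synth.ToyNetworkSpec(seed=11, n_padding_reactions=1))  # adds PAD0
    sol_a, sol_b = solve_pfba(bigger), solve_pfba(model)
    diff = compare_flux(sol_a, sol_b, bigger, model)
    assert ("toy_chain_seed11", "PAD0") not in diff.exclusive_active
    assert diff.shared_diff == set()


def test_compare_flux_rejects_plain_fba(chain_model):
    model, _ = chain_model
    fba = solve_fba(model)
    with pytest.raises(ValueError, match="parsimonious"):
        compare_flux(fba, fba, model, model)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def _enumerated_p(N, K, n, k):
    """Brute-force oracle: exact P[overlap >= k] by enumerating all C(N, n)
    draws of the differential set."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for i in draw if i < K) >= k:
            hits += 1
    return hits / total


def test_hypergeometric_p_matches_enumeration_exactly():
    """N=10, K=4, n=5, k=4 gives p = C(4,4)C(6,1)/C(10,5) = 6/252."""
    model, _ = synth.make_toy_model(synth.ToyNetworkSpec(
        kind="chain", seed=0, chain_length=4, n_padding_reactions=2))
    assert len(model.reactions) == 10
    reactions = model.reactions
    tagged = {r.id for r in reactions[:4]}
    for r in reactions:
        r.pathway_tags = frozenset({"pw"} if r.id in tagged else {"other"})
    diff = set(r.id for r in reactions[:4]) | {reactions[9].id}  # k=4, n=5
    table = enrich_pathways(diff, model).set_index("pathway")
    assert table.loc["pw", "p_value"] == pytest.approx(6 / 252, abs=1e-12)
    assert table.loc["pw", "p_value"] == pytest.approx(
        _enumerated_p(10, 4, 5, 4), abs=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_hypergeometric_matches_enumeration_small_universes(seed):
    rng = np.random.default_rng(seed)
    N = int(rng.integers(4, 13))
    K = int(rng.integers(1, N + 1))
    n = int(rng.integers(1, N + 1))
    model, _ = synth.make_toy_model(synth.ToyNetworkSpec(
        kind="chain", seed=seed, chain_length=7, n_padding_reactions=2))
    model.reactions = model.reactions[:N]  # enrichment only reads ids + tags
    reactions = model.reactions
    ids = [r.id for r in reactions]
    in_pathway = set(rng.choice(ids, size=K, replace=False))
    for r in reactions:
        r.pathway_tags = frozenset({"pw"} if r.id in in_pathway else set())
    diff = set(rng.choice(ids, size=n, replace=False))
    k = len(diff & in_pathway)
    table = enrich_pathways(diff, model).set_index("pathway")
    assert table.loc["pw", "p_value"] == pytest.approx(
        _enumerated_p_sets(ids, in_pathway, n, k), abs=1e-10)


def _enumerated_p_sets(ids, in_pathway, n, k):
    hits = total = 0
    for draw in itertools.combinations(ids, n):
        total += 1
        if len(set(draw) & in_pathway) >= k:
            hits += 1
    return hits / total


def test_bh_adjustment_properties(loop_model):
    model, _ = loop_model
    diff = {"EMP", "PDH", "CS"}
    table = enrich_pathways(diff, model)
    assert (table["adjusted_p"] >= table["p_value"] - 1e-15).all()
    assert (table["p_value"] <= 1.0).all()
    # BH is monotone in p-value rank
    ordered = table.sort_values("p_value")
    assert ordered["adjusted_p"].is_monotonic_increasing


def test_single_tag_adjusted_equals_raw(chain_model):
    model, _ = chain_model
    for r in model.reactions:
        r.pathway_tags = frozenset({"only"})
    table = enrich_pathways({"BIO"}, model)
    assert len(table) == 1
    assert table.loc[0, "adjusted_p"] == table.loc[0, "p_value"]


def test_untagged_model_warns_and_returns_empty(caplog):
    model, _ = synth.make_toy_model(synth.ToyNetworkSpec(seed=2))
    for r in model.reactions:
        r.pathway_tags = frozenset()
    with caplog.at_level("WARNING", logger="gemstream"):
        table = enrich_pathways({"BIO"}, model)
    assert table.empty


# ---------------------------------------------------------------------------
# percent improvement
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("wt,sl,expected", [
    (5.0, 5.0505050505, 1.0101010100000),
    (2.0, 2.0, 0.0),
    (2.0, 1.0, -50.0),
])
def test_percent_mgr_improvement(wt, sl, expected):
    assert percent_mgr_improvement(wt, sl) == pytest.approx(expected, abs=1e-6)


def test_percent_mgr_improvement_needs_positive_reference():
    with pytest.raises(ValueError):
        percent_mgr_improvement(0.0, 1.0)
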