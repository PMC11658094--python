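"""Deletion-region bookkeeping, staged plans, proportional BOF rescaling,
and in-silico derivation of streamlined models."""

import pytest

from gemstream import (
    DeletionRegion,
    Reaction,
    add_heterologous_pathway,
    build_plan,
    derive_streamlined_model,
    load_regions,
    rescale_bof,
    solve_fba,
    summarize_targets,
)
from gemstream.streamline import RegionFileError, write_regions
from gemstream import synth


# ---------------------------------------------------------------------------
# Region tables
# ---------------------------------------------------------------------------

REGIONS_TSV = """region_id\tcategory\tstart\tend\tgenes
pro1\tprophage\t1000\t53400\tgA;gB
pro2\tprophage\t100000\t147300\t
pro3\tprophage\t200000\t255800\tgC
pro4\tprophage\t300000\t343900\t
gi1\tgenomic_island\t400000\t428600\t
gi2\tgenomic_island\t500000\t528200\t
nuc1\tnuclease_gene\t600000\t601200\tgD
nuc2\tnuclease_gene\t700000\t701100\t
nuc3\tnuclease_gene\t800000\t801200\t
"""


def test_load_regions_census(tmp_path):
    path = tmp_path / "regions.tsv"
    path.write_text(REGIONS_TSV)
    regions = load_regions(path)
    assert len(regions) == 9
    counts = summarize_targets(regions, 6_334_000).counts_by_category
    assert counts == {"prophage": 4, "genomic_island": 2, "nuclease_gene": 3}
    assert regions[0].genes == {"gA", "gB"}


def test_load_bed_dialect_half_open(tmp_path):
    path = tmp_path / "regions.bed"
    path.write_text("chr1\t100\t200\tprophage:p1\t0\t+\n")
    (region,) = load_regions(path)
    assert region.length == 100
    assert region.category == "prophage"
    assert region.id == "p1"


def test_one_based_inclusive_conversion(tmp_path):
    path = tmp_path / "regions.tsv"
    path.write_text("region_id\tcategory\tstart\tend\tgenes\n"
                    "r1\tother\t1\t100\t\n")
    (region,) = load_regions(path, one_based_inclusive=True)
    assert (region.start, region.end, region.length) == (0, 100, 100)


def test_inverted_interval_names_the_row(tmp_path):
    path = tmp_path / "regions.tsv"
    path.write_text("region_id\tcategory\tstart\tend\tgenes\n"
                    "bad\tprophage\t500\t100\t\n")
    with pytest.raises(RegionFileError, match="2"):
        load_regions(path)


def test_unknown_category_rejected(tmp_path):
    path = tmp_path / "regions.tsv"
    path.write_text("region_id\tcategory\tstart\tend\tgenes\n"
                    "r1\tplasmid\t0\t10\t\n")
    with pytest.raises((RegionFileError, ValueError), match="plasmid"):
        load_regions(path)


def test_regions_round_trip(tmp_path):
    path = tmp_path / "regions.tsv"
    path.write_text(REGIONS_TSV)
    regions = load_regions(path)
    back = load_regions(write_regions(regions, tmp_path / "copy.tsv"))
    assert back == regions


# ---------------------------------------------------------------------------
# Target summaries
# ---------------------------------------------------------------------------

def test_summary_arithmetic():
    regions = [DeletionRegion(f"r{i}", "other", s, s + l)
               for i, (s, l) in enumerate([(0, 1000), (5000, 2000),
                                           (10000, 3000)])]
    summary = summarize_targets(regions, 100_000)
    assert summary.total_bp == 6000
    assert summary.percent_of_genome == pytest.approx(6.0)


def test_summary_merges_overlaps_with_warning(caplog):
    regions = [DeletionRegion("a", "other", 0, 100),
               DeletionRegion("b", "other", 50, 150)]
    with caplog.at_level("WARNING", logger="gemstream"):
        summary = summarize_targets(regions, 1000)
    assert summary.total_bp == 150
    assert "overlap" in caplog.text


def test_summary_empty_and_order_invariant():
    assert summarize_targets([], 1000).total_bp == 0
    regions = [DeletionRegion(f"r{i}", "other", i * 1000, i * 1000 + 500)
               for i in range(5)]
    forward = summarize_targets(regions, 10_000).total_bp
    backward = summarize_targets(list(reversed(regions)), 10_000).total_bp
    assert forward == backward == 2500


# ---------------------------------------------------------------------------
# Plans
# ---------------------------------------------------------------------------

def _nine_regions():
    return [DeletionRegion(f"r{i}", "other", i * 20_000, i * 20_000 + 10_000,
                           genes=frozenset())
            for i in range(8)]


def test_nominal_percent_ladder():
    """Four roughly-1% portions get BOF factors 0.99, 0.98, 0.97, 0.96."""
    regions = _nine_regions()
    assignment = {r.id: f"stage{i // 2 + 1}" for i, r in enumerate(regions)}
    plan = build_plan(regions, 4_000_000, assignment,
                      factor_mode="nominal_percent")
    assert [s.bof_factor for s in plan.stages] == [0.99, 0.98, 0.97, 0.96]
    assert [s.cumulative_deleted_bp for s in plan.stages] == \
        [20_000, 40_000, 60_000, 80_000]


def test_exact_bp_factor_mode():
    regions = [DeletionRegion("all", "other", 0, 41_000)]
    plan = build_plan(regions, 1_000_000, {"all": "stage1"},
                      factor_mode="exact_bp")
    assert plan.stages[0].bof_factor == pytest.approx(1 - 0.041)


def test_empty_plan_is_valid():
    plan = build_plan([], 1_000_000, {})
    assert plan.stages == []


def test_unassigned_region_rejected():
    regions = _nine_regions()
    with pytest.raises(ValueError, match="r7"):
        build_plan(regions, 1_000_000,
                   {r.id: "stage1" for r in regions[:-1]})


# ---------------------------------------------------------------------------
# BOF rescaling
# ---------------------------------------------------------------------------

def test_bof_worked_example_at_printed_precision(chain_model):
    """The ATP biomass coefficient 40.1654758653685 scaled by 0.99 equals the
    published derived coefficient 39.7638211067148 at its printed
    precision."""
    model, _ = chain_model
    model.objective_reaction.stoichiometry["atp_c0"] = -40.1654758653685
    scaled, adjustment = rescale_bof(model, 0.99, components=["atp"])
    after = -scaled.objective_reaction.stoichiometry["atp_c0"]
    assert after == pytest.approx(39.7638211067148, abs=5e-13)
    assert float(f"{after:.13f}") == 39.7638211067148
    assert adjustment.before == {"atp_c0": -40.1654758653685}


def test_rescale_is_proportional_and_leaves_rest_alone(loop_model):
    model, _ = loop_model
    model.objective_reaction.stoichiometry["atp_c0"] = -10.0
    scaled, adj = rescale_bof(model, 0.96, components=["atp"])
    assert scaled.objective_reaction.stoichiometry["atp_c0"] == -9.6
    assert adj.after == {"atp_c0": -9.6}
    # bounds and other reactions untouched
    for r_old, r_new in zip(model.reactions, scaled.reactions):
        assert (r_old.lower_bound, r_old.upper_bound) == \
            (r_new.lower_bound, r_new.upper_bound)
        if r_old.id != model.objective_reaction_id:
            assert r_old.stoichiometry == r_new.stoichiometry


def test_rescale_identity_and_composition(chain_model):
    model, _ = chain_model
    same, adj = rescale_bof(model, 1.0, components=["atp"])
    assert adj.after == adj.before
    once, _ = rescale_bof(*[model, 0.9], components=["atp"])
    twice, _ = rescale_bof(once, 0.8, components=["atp"])
    direct, _ = rescale_bof(model, 0.72, components=["atp"])
    assert twice.objective_reaction.stoichiometry["atp_c0"] == pytest.approx(
        direct.objective_reaction.stoichiometry["atp_c0"], rel=1e-12)


def test_rescale_needs_a_matching_component(chain_model):
    model, _ = chain_model
    with pytest.raises(ValueError, match="biomass"):
        rescale_bof(model, 0.99, components=["unobtainium"])


# ---------------------------------------------------------------------------
# Derivation
# ---------------------------------------------------------------------------

def test_streamlined_mgr_ladder_matches_closed_form(chain_model):
    """With no metabolic genes deleted, stage k lifts the MGR to
    uptake / (0.99…0.96 × coefficient) exactly; the toy analogue of the
    percent-improvement readout."""
    model, truth = chain_model
    fixture = synth.make_streamlining_fixture(model, n_stages=4, seed=5)
    for stage, factor in zip(fixture.plan.stages, (0.99, 0.98, 0.97, 0.96)):
        derived = derive_streamlined_model(model, fixture.plan, stage.stage_id)
        mgr = solve_fba(derived).objective_value
        assert mgr == pytest.approx(truth.mgr_expected / factor, rel=1e-9)
        assert mgr == pytest.approx(fixture.truth.stage_mgr[stage.stage_id],
                                    rel=1e-9)
        assert derived.annotations["bof_factor"] == repr(factor)


def test_essential_gene_deletion_kills_growth(chain_model):
    model, _ = chain_model
    fixture = synth.make_streamlining_fixture(model, n_stages=3, seed=5,
                                              essential_stage=2)
    mgr1 = solve_fba(derive_streamlined_model(
        model, fixture.plan, "stage1")).objective_value
    mgr2 = solve_fba(derive_streamlined_model(
        model, fixture.plan, "stage2")).objective_value
    mgr3 = solve_fba(derive_streamlined_model(
        model, fixture.plan, "stage3")).objective_value
    assert mgr1 > 0
    assert mgr2 == pytest.approx(0.0, abs=1e-9)
    assert mgr3 == pytest.approx(0.0, abs=1e-9)  # deletions are cumulative


def test_mgr_never_increases_under_pure_gene_deletion(loop_model):
    """Gene deletion only removes feasible flux vectors, so MGR cannot go
    up; this holds for every single-gene knockout of the loop toy."""
    from gemstream import apply_gene_deletions

    model, truth = loop_model
    wt = solve_fba(model).objective_value
    for gene in sorted(model.genes):
        mgr = solve_fba(apply_gene_deletions(model, {gene})).objective_value
        assert mgr <= wt + 1e-9


# ---------------------------------------------------------------------------
# Heterologous pathway
# ---------------------------------------------------------------------------

def _phenol_reactions():
    """Phenol exchange + uptake + hydroxylation to the chain's entry
    metabolite (standing in for catechol feeding existing degradation)."""
    return [
        Reaction("EX_phenol_e0", {"phenol_e0": -1.0},
                 lower_bound=-10.0, upper_bound=1000.0),
        Reaction("T_phenol", {"phenol_e0": -1.0, "phenol_c0": 1.0},
                 lower_bound=-1000.0, upper_bound=1000.0),
        Reaction("PHE_HYD", {"phenol_c0": -1.0, "s_c0": 1.0}),
    ]


def test_heterologous_pathway_flips_growth_feasibility(chain_model):
    from gemstream import Medium, set_medium

    model, _ = chain_model
    starved = set_medium(model, Medium())
    assert solve_fba(starved).objective_value == pytest.approx(0.0, abs=1e-9)
    engineered = add_heterologous_pathway(starved, _phenol_reactions())
    mgr = solve_fba(engineered).objective_value
    assert mgr == pytest.approx(10.0 / 2.0, rel=1e-9)  # phenol-limited


def test_duplicate_reaction_id_rejected(chain_model):
    model, _ = chain_model
    with pytest.raises(ValueError, match="BIO"):
        add_heterologous_pathway(model, [Reaction("BIO", {"s_c0": -1.0})])
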