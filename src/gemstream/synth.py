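"""Seeded generators for every input the pipeline consumes.

Each generator plants a ground truth that is recomputable in closed form
without running the pipeline: toy stoichiometric networks with analytic
maximum growth rates and strict-reaction sets, deletion-region tables with
known totals, carbon panels with known positive/negative wiring, and
lag–exponential–plateau growth curves with known μ, lag, and plateau.

Determinism: one integer seed drives a named pseudo-random stream per
generator (``default_rng([seed, crc32(name)])``), so adding a generator never
perturbs the fixtures of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .curves import ConcentrationCurve, GrowthCurve
from .model import Medium, MetabolicModel, Metabolite, Reaction
from .screen import CarbonPanel, PanelEntry
from .streamline import (
    DEFAULT_BOF_COMPONENTS,
    DeletionRegion,
    StreamliningPlan,
    build_plan,
)

TOY_KINDS = ("chain", "parallel_branch", "core_loop")


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


@dataclass
class ToyNetworkSpec:
    """Recipe for a desk-scale toy network with a closed-form optimum.

    For ``chain`` and ``parallel_branch`` the maximum growth rate is
    uptake_bound / Σ biomass coefficients (one substrate unit per component
    unit); ``core_loop`` adds a glycolysis/PP/TCA-like topology with an ATP
    yield of 4 per substrate, so MGR = 4·uptake / Σ coefficients.
    """

    kind: str = "chain"
    uptake_bound: float = 10.0
    biomass_coefficients: dict[str, float] = field(
        default_factory=lambda: {"atp": 2.0})
    chain_length: int = 3
    n_padding_reactions: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in TOY_KINDS:
            raise ValueError(f"unknown toy kind {self.kind!r}")
        if self.uptake_bound <= 0:
            raise ValueError("uptake_bound must be > 0")
        if not self.biomass_coefficients:
            raise ValueError("biomass_coefficients must be non-empty")

    @property
    def atp_yield(self) -> float:
        return 4.0 if self.kind == "core_loop" else 1.0

    @property
    def mgr_closed_form(self) -> float:
        return self.atp_yield * self.uptake_bound / sum(
            self.biomass_coefficients.values())


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated fixture."""

    mgr_expected: Optional[float] = None
    strict_reactions: Optional[set[str]] = None
    nonstrict_reactions: Optional[set[str]] = None
    growth_truth: Optional[dict[str, bool]] = None
    curve_params: Optional[dict] = None
    stage_mgr: Optional[dict[str, float]] = None


# ---------------------------------------------------------------------------
# Toy models
# ---------------------------------------------------------------------------

def make_toy_model(spec: ToyNetworkSpec) -> tuple[MetabolicModel, SyntheticTruth]:
    """Build a toy model with planted MGR and strict-reaction truth."""
    rng = _stream(spec.seed, "toy_model")
    if spec.kind == "chain":
        model, nonstrict = _chain_model(spec)
    elif spec.kind == "parallel_branch":
        model, nonstrict = _branch_model(spec)
    else:
        model, nonstrict = _core_loop_model(spec)
    _add_padding(model, spec, rng)
    model.annotations.update({
        "toy_kind": spec.kind,
        "uptake_bound": repr(spec.uptake_bound),
        "atp_yield": repr(spec.atp_yield),
        "biomass_coefficients": ";".join(
            f"{k}:{v!r}" for k, v in sorted(spec.biomass_coefficients.items())),
    })
    all_ids = {r.id for r in model.reactions}
    truth = SyntheticTruth(
        mgr_expected=spec.mgr_closed_form,
        strict_reactions=all_ids - nonstrict,
        nonstrict_reactions=set(nonstrict),
    )
    return model, truth


def _biomass_reaction(spec: ToyNetworkSpec) -> tuple[list[Metabolite], Reaction]:
    mets = [Metabolite(id=f"{c}_c0", name=c, compartment="c0")
            for c in sorted(spec.biomass_coefficients)]
    bio = Reaction(
        id="BIO", name="biomass",
        stoichiometry={f"{c}_c0": -v
                       for c, v in spec.biomass_coefficients.items()},
    )
    return mets, bio


def _chain_model(spec: ToyNetworkSpec) -> tuple[MetabolicModel, set[str]]:
    mets = [Metabolite("s_e0", "substrate", "e0"),
            Metabolite("s_c0", "substrate", "c0")]
    rxns = [
        Reaction("EX_s_e0", {"s_e0": -1.0}, lower_bound=-spec.uptake_bound,
                 name="substrate exchange", pathway_tags={"transport"}),
        Reaction("T_s", {"s_e0": -1.0, "s_c0": 1.0}, name="substrate uptake",
                 gpr="g_t1", pathway_tags={"transport"}),
    ]
    prev = "s_c0"
    for i in range(1, spec.chain_length + 1):
        mid = f"m{i}_c0"
        mets.append(Metabolite(mid, f"intermediate {i}", "c0"))
        rxns.append(Reaction(
            f"R{i}", {prev: -1.0, mid: 1.0}, name=f"conversion {i}",
            gpr=f"g_r{i}", pathway_tags={"central"}))
        prev = mid
    bio_mets, bio = _biomass_reaction(spec)
    mets.extend(bio_mets)
    for comp in sorted(spec.biomass_coefficients):
        rxns.append(Reaction(
            f"SYN_{comp}", {prev: -1.0, f"{comp}_c0": 1.0},
            name=f"{comp} synthesis", gpr=f"g_{comp} or g_{comp}b",
            pathway_tags={"biosynthesis"}))
    rxns.append(bio)
    model = MetabolicModel(
        id=f"toy_chain_seed{spec.seed}", metabolites=mets, reactions=rxns,
        genes={g for r in rxns if r.gpr for g in r.gpr.genes},
        objective_reaction_id="BIO")
    return model, set()  # unique optimum: every reaction strict


def _branch_model(spec: ToyNetworkSpec) -> tuple[MetabolicModel, set[str]]:
    mets = [Metabolite("s_e0", "substrate", "e0"),
            Metabolite("s_c0", "substrate", "c0")]
    bio_mets, bio = _biomass_reaction(spec)
    mets.extend(bio_mets)
    comp = sorted(spec.biomass_coefficients)[0]
    if len(spec.biomass_coefficients) != 1:
        raise ValueError("parallel_branch supports a single biomass component")
    rxns = [
        Reaction("EX_s_e0", {"s_e0": -1.0}, lower_bound=-spec.uptake_bound,
                 name="substrate exchange", pathway_tags={"transport"}),
        Reaction("T_s", {"s_e0": -1.0, "s_c0": 1.0}, name="substrate uptake",
                 gpr="g_t1", pathway_tags={"transport"}),
        Reaction("R_branch1", {"s_c0": -1.0, f"{comp}_c0": 1.0},
                 name="route 1", gpr="g_b1", pathway_tags={"central"}),
        Reaction("R_branch2", {"s_c0": -1.0, f"{comp}_c0": 1.0},
                 name="route 2 (isozyme route)", gpr="g_b2",
                 pathway_tags={"central"}),
        bio,
    ]
    model = MetabolicModel(
        id=f"toy_branch_seed{spec.seed}", metabolites=mets, reactions=rxns,
        genes={g for r in rxns if r.gpr for g in r.gpr.genes},
        objective_reaction_id="BIO")
    return model, {"R_branch1", "R_branch2"}


def _core_loop_model(spec: ToyNetworkSpec) -> tuple[MetabolicModel, set[str]]:
    """EMP/PP/TCA-like loop: per substrate, EMP yields 2 pyruvate + 2 ATP and
    the TCA loop a further 2 ATP (yield 4); the PP route is a planted
    less-efficient alternative that carries no flux at optimality."""
    mets = [
        Metabolite("glc_e0", "glucose", "e0"),
        Metabolite("g6p_c0", "glucose-6-phosphate", "c0"),
        Metabolite("pyr_c0", "pyruvate", "c0"),
        Metabolite("accoa_c0", "acetyl-CoA", "c0"),
        Metabolite("oaa_c0", "oxaloacetate", "c0"),
        Metabolite("cit_c0", "citrate", "c0"),
        Metabolite("akg_c0", "2-oxoglutarate", "c0"),
        Metabolite("co2_c0", "CO2", "c0"),
        Metabolite("co2_e0", "CO2", "e0"),
    ]
    bio_mets, bio = _biomass_reaction(spec)
    mets.extend(bio_mets)
    if sorted(spec.biomass_coefficients) != ["atp"]:
        raise ValueError("core_loop plants an ATP-only biomass")
    rxns = [
        Reaction("EX_glc_e0", {"glc_e0": -1.0}, lower_bound=-spec.uptake_bound,
                 name="glucose exchange", pathway_tags={"transport"}),
        Reaction("PTS", {"glc_e0": -1.0, "g6p_c0": 1.0},
                 name="glucose PTS uptake", gpr="g_pts",
                 pathway_tags={"transport", "glycolysis"}),
        Reaction("EMP", {"g6p_c0": -1.0, "pyr_c0": 2.0, "atp_c0": 2.0},
                 name="EMP glycolysis (lumped)", gpr="g_pgi and g_pfk and g_pyk",
                 pathway_tags={"glycolysis", "carbon_metabolism"}),
        Reaction("PP", {"g6p_c0": -1.0, "pyr_c0": 2.0, "atp_c0": 1.0},
                 name="pentose-phosphate route (lumped, lower yield)",
                 gpr="g_zwf", pathway_tags={"pentose_phosphate",
                                            "carbon_metabolism"}),
        Reaction("PDH", {"pyr_c0": -1.0, "accoa_c0": 1.0, "co2_c0": 1.0},
                 name="pyruvate dehydrogenase", gpr="g_aceE and g_aceF",
                 pathway_tags={"tca", "carbon_metabolism"}),
        Reaction("CS", {"accoa_c0": -1.0, "oaa_c0": -1.0, "cit_c0": 1.0},
                 name="citrate synthase", gpr="g_gltA",
                 pathway_tags={"tca", "carbon_metabolism"}),
        Reaction("CIT_AKG", {"cit_c0": -1.0, "akg_c0": 1.0, "co2_c0": 1.0},
                 name="citrate to 2-oxoglutarate (lumped)", gpr="g_icd",
                 pathway_tags={"tca", "carbon_metabolism"}),
        Reaction("AKG_OAA", {"akg_c0": -1.0, "oaa_c0": 1.0, "atp_c0": 1.0,
                             "co2_c0": 1.0},
                 name="2-oxoglutarate to oxaloacetate (lumped)",
                 gpr="g_sucA or g_sucB", pathway_tags={"tca",
                                                       "carbon_metabolism"}),
        Reaction("T_co2", {"co2_c0": -1.0, "co2_e0": 1.0},
                 lower_bound=-1000.0, name="CO2 diffusion",
                 pathway_tags={"transport"}),
        Reaction("EX_co2_e0", {"co2_e0": -1.0}, name="CO2 exchange",
                 pathway_tags={"transport"}),
        bio,
    ]
    model = MetabolicModel(
        id=f"toy_loop_seed{spec.seed}", metabolites=mets, reactions=rxns,
        genes={g for r in rxns if r.gpr for g in r.gpr.genes},
        objective_reaction_id="BIO")
    return model, set()


def _add_padding(model: MetabolicModel, spec: ToyNetworkSpec,
                 rng: np.random.Generator) -> None:
    """Blocked dead-end reactions (forced zero flux, hence strict) that give
    toy models off-pathway bulk without touching the optimum."""
    anchor = model.reactions[1]  # first internal reaction
    anchor_met = list(anchor.stoichiometry)[-1]  # its cytosolic product
    tags = ["padding_a", "padding_b"]
    for i in range(spec.n_padding_reactions):
        dead = f"pad{i}_c0"
        model.metabolites.append(Metabolite(dead, f"dead end {i}", "c0"))
        gene = f"g_pad{i}"
        model.genes.add(gene)
        model.reactions.append(Reaction(
            f"PAD{i}", {anchor_met: -1.0, dead: 1.0},
            name=f"padding {i}", gpr=gene,
            pathway_tags={tags[int(rng.integers(len(tags)))]}))
    model.refresh_exchange_flags()


def toy_medium(model: MetabolicModel) -> Medium:
    """The medium matching a generated toy model's sole carbon source."""
    ex = [r for r in model.reactions if r.is_exchange and r.lower_bound < 0]
    return Medium(compounds={r.id: -r.lower_bound for r in ex})


# ---------------------------------------------------------------------------
# Streamlining fixtures
# ---------------------------------------------------------------------------

@dataclass
class StreamliningFixture:
    regions: list[DeletionRegion]
    plan: StreamliningPlan
    truth: SyntheticTruth
    genome_length: int


def make_streamlining_fixture(
    model: MetabolicModel,
    n_stages: int = 4,
    seed: int = 0,
    genome_length: int = 1_000_000,
    essential_stage: Optional[int] = None,
) -> StreamliningFixture:
    """Deletion regions, a staged plan, and the analytic post-derivation MGR.

    Regions follow the 4 prophage / 2 genomic-island / 3 nuclease census and
    sum to about 1% of the genome per stage. Member genes are synthetic
    (non-metabolic) except when ``essential_stage`` plants the deletion of a
    model gene that is essential by construction, driving the truth MGR to 0
    from that stage on.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    rng = _stream(seed, "streamlining_fixture")
    categories = (["prophage"] * 4 + ["genomic_island"] * 2
                  + ["nuclease_gene"] * 3)
    n_regions = max(len(categories), n_stages)
    while len(categories) < n_regions:
        categories.append("other")

    # spread regions over stages as evenly as possible, >= 1 per stage
    per_stage = [n_regions // n_stages] * n_stages
    for i in range(n_regions % n_stages):
        per_stage[i] += 1

    stage_bp = int(0.01 * genome_length)
    regions: list[DeletionRegion] = []
    assignment: dict[str, str] = {}
    cursor = 0
    idx = 0
    for k, count in enumerate(per_stage, start=1):
        weights = rng.dirichlet(np.ones(count))
        for w in weights:
            length = max(200, int(round(w * stage_bp)))
            rid = f"del_{idx:02d}"
            genes = frozenset({f"syn_gene_{idx:02d}_{j}"
                               for j in range(int(rng.integers(1, 4)))})
            if essential_stage == k and idx == sum(per_stage[:k]) - count:
                essential = _essential_model_gene(model)
                genes = genes | {essential}
            regions.append(DeletionRegion(
                id=rid, category=categories[idx], start=cursor,
                end=cursor + length, genes=genes))
            assignment[rid] = f"stage{k}"
            cursor += length + int(rng.integers(1000, 5000))
            idx += 1

    plan = build_plan(regions, genome_length, assignment,
                      factor_mode="nominal_percent",
                      stage_order=[f"stage{k}" for k in range(1, n_stages + 1)])
    truth = SyntheticTruth(stage_mgr=_analytic_stage_mgr(
        model, plan, essential_stage))
    return StreamliningFixture(regions=regions, plan=plan, truth=truth,
                               genome_length=genome_length)


def _essential_model_gene(model: MetabolicModel) -> str:
    """A gene whose deletion provably kills growth in a generated toy: the
    sole gene of a single-gene chain reaction."""
    for r in model.reactions:
        if r.gpr is not None and r.gpr.ast[0] == "gene" \
                and not r.id.startswith("PAD"):
            return r.gpr.ast[1]
    raise ValueError("model has no single-gene reaction to plant essentiality")


def _analytic_stage_mgr(
    model: MetabolicModel, plan: StreamliningPlan,
    essential_stage: Optional[int],
) -> dict[str, float]:
    """Closed-form MGR per stage for toy models: scaling the listed biomass
    components by f changes MGR from yield·uptake/Σc to
    yield·uptake/Σ(adjusted c)."""
    ann = model.annotations
    uptake = float(ann["uptake_bound"])
    atp_yield = float(ann["atp_yield"])
    coeffs = {}
    for pair in ann["biomass_coefficients"].split(";"):
        name, _, value = pair.rpartition(":")
        coeffs[name] = float(value)
    scaled = set(DEFAULT_BOF_COMPONENTS)
    out: dict[str, float] = {}
    for k, stage in enumerate(plan.stages, start=1):
        if essential_stage is not None and k >= essential_stage:
            out[stage.stage_id] = 0.0
            continue
        total = sum(v * (stage.bof_factor if name in scaled else 1.0)
                    for name, v in coeffs.items())
        out[stage.stage_id] = atp_yield * uptake / total
    return out


# ---------------------------------------------------------------------------
# Carbon panels
# ---------------------------------------------------------------------------

def make_panel(
    model: MetabolicModel, n_positive: int, n_negative: int, seed: int = 0,
) -> tuple[MetabolicModel, CarbonPanel, SyntheticTruth]:
    """Augment a toy model with planted carbon sources and return the panel.

    Positive sources are wired into the network (exchange + transport +
    conversion to the substrate entry metabolite), negative sources are
    dead-end metabolites; the planted truth doubles as the panel's observed
    growth calls.
    """
    if n_positive < 0 or n_negative < 0:
        raise ValueError("source counts must be >= 0")
    rng = _stream(seed, "carbon_panel")
    new = model.copy()
    entry = _entry_metabolite(new)
    entries: list[PanelEntry] = []
    truth: dict[str, bool] = {}
    for i in range(n_positive):
        sid = f"src_pos{i}"
        ext, cyt = f"{sid}_e0", f"{sid}_c0"
        new.metabolites.extend([
            Metabolite(ext, sid, "e0"), Metabolite(cyt, sid, "c0")])
        new.reactions.extend([
            Reaction(f"EX_{ext}", {ext: -1.0}, lower_bound=0.0),
            Reaction(f"T_{sid}", {ext: -1.0, cyt: 1.0}, lower_bound=-1000.0),
            Reaction(f"CONV_{sid}", {cyt: -1.0, entry: 1.0}),
        ])
        target = f"EX_{ext}" if rng.random() < 0.5 else cyt
        entries.append(PanelEntry(sid, target, observed_growth=True))
        truth[sid] = True
    for i in range(n_negative):
        sid = f"src_neg{i}"
        cyt = f"{sid}_c0"
        new.metabolites.append(Metabolite(cyt, sid, "c0"))
        if rng.random() < 0.5:
            # dead-end with its own transport/exchange already present
            ext = f"{sid}_e0"
            new.metabolites.append(Metabolite(ext, sid, "e0"))
            new.reactions.extend([
                Reaction(f"EX_{ext}", {ext: -1.0}, lower_bound=0.0),
                Reaction(f"T_{sid}", {ext: -1.0, cyt: 1.0},
                         lower_bound=-1000.0),
            ])
            target = f"EX_{ext}"
        else:
            target = cyt  # screener injects the free-diffusion route
        entries.append(PanelEntry(sid, target, observed_growth=False))
        truth[sid] = False
    new.refresh_exchange_flags()
    panel = CarbonPanel(entries=entries, base_medium=Medium())
    return new, panel, SyntheticTruth(growth_truth=truth)


def _entry_metabolite(model: MetabolicModel) -> str:
    for candidate in ("s_c0", "g6p_c0"):
        if any(m.id == candidate for m in model.metabolites):
            return candidate
    raise ValueError("model lacks a recognised substrate entry metabolite")


# ---------------------------------------------------------------------------
# Growth and degradation curves
# ---------------------------------------------------------------------------

def make_growth_curve(
    mu: float = 0.3,
    lag: float = 12.0,
    od0: float = 0.05,
    plateau: float = 2.0,
    noise_sigma: float = 0.0,
    n_points: int = 97,
    t_max: float = 48.0,
    seed: int = 0,
) -> tuple[GrowthCurve, SyntheticTruth]:
    """A lag–exponential–plateau OD600 curve with planted parameters.

    The deterministic backbone is the Zwietering-modified Gompertz form on
    the log scale, ln(OD/od0) = A·exp(−exp(μe/A·(lag−t)+1)) with
    A = ln(plateau/od0), so the planted μ is the true maximum specific
    growth rate (h⁻¹). Noise is multiplicative lognormal with parameter
    ``noise_sigma``.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if not (0 < od0 <= plateau):
        raise ValueError("need 0 < od0 <= plateau")
    rng = _stream(seed, "growth_curve")
    t = np.linspace(0.0, t_max, n_points)
    amplitude = np.log(plateau / od0)
    if amplitude <= 0 or mu == 0:
        od = np.full_like(t, od0)
    else:
        gomp = amplitude * np.exp(
            -np.exp(mu * np.e / amplitude * (lag - t) + 1.0))
        od = od0 * np.exp(gomp)
    if noise_sigma > 0:
        od = od * rng.lognormal(mean=0.0, sigma=noise_sigma, size=od.shape)
    curve = GrowthCurve(times=t, od600=od)
    return curve, SyntheticTruth(curve_params={
        "mu": mu, "lag": lag, "od0": od0, "plateau": plateau,
        "noise_sigma": noise_sigma})


def make_degradation_curve(
    initial_mm: float = 2.0,
    max_rate: float = 0.5,
    onset: float = 4.0,
    noise_sigma: float = 0.0,
    n_points: int = 41,
    t_max: float = 20.0,
    seed: int = 0,
) -> tuple[ConcentrationCurve, SyntheticTruth]:
    """A piecewise-linear substrate-depletion curve whose steepest segment
    has the planted slope −max_rate (mM·h⁻¹)."""
    if max_rate < 0 or initial_mm <= 0:
        raise ValueError("need max_rate >= 0 and initial_mm > 0")
    rng = _stream(seed, "degradation_curve")
    t = np.linspace(0.0, t_max, n_points)
    conc = np.empty_like(t)
    for i, ti in enumerate(t):
        if ti <= onset:
            conc[i] = initial_mm - 0.05 * max_rate * ti  # slow pre-phase
        else:
            conc[i] = conc_at_onset = (initial_mm - 0.05 * max_rate * onset)
            conc[i] = max(0.0, conc_at_onset - max_rate * (ti - onset))
    if noise_sigma > 0:
        conc = np.maximum(conc * rng.lognormal(0.0, noise_sigma, conc.shape),
                          0.0)
    curve = ConcentrationCurve(times=t, od600=conc)
    return curve, SyntheticTruth(curve_params={
        "max_rate": max_rate, "initial_mm": initial_mm, "onset": onset,
        "noise_sigma": noise_sigma})
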