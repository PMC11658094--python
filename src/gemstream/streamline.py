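"""In-silico genome streamlining.

Deletion targets (prophages, genomic islands, redundant nuclease genes) are
book-kept as genomic regions; a :class:`StreamliningPlan` groups them into
ordered stages (portions of roughly 1% of the genome each). A streamlined
model is derived from the wild type by (i) propagating the deletion of every
member gene through the GPRs and (ii) rescaling the energy-carrier
coefficients of the biomass objective function (BOF) by the stage factor
1 − p, p being the deleted genome fraction — less genome means
proportionally less nucleotide and deoxynucleotide demand per unit biomass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .model import (
    MetabolicModel,
    Reaction,
    Metabolite,
    apply_gene_deletions,
    require_valid,
)

logger = logging.getLogger("gemstream")

REGION_CATEGORIES = ("prophage", "genomic_island", "nuclease_gene", "other")

#: BOF components rescaled by default: the energy carriers and
#: (deoxy)nucleotides whose biomass demand scales with genome content.
DEFAULT_BOF_COMPONENTS = (
    "atp", "gtp", "ctp", "utp", "datp", "dgtp", "dctp", "dttp",
)


class RegionFileError(ValueError):
    """Raised for malformed deletion-region tables."""


@dataclass(frozen=True)
class DeletionRegion:
    """A genomic region slated for deletion; coordinates are 0-based,
    half-open."""

    id: str
    category: str
    start: int
    end: int
    genes: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.category not in REGION_CATEGORIES:
            raise ValueError(
                f"region {self.id!r}: unknown category {self.category!r} "
                f"(expected one of {REGION_CATEGORIES})")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"region {self.id!r}: invalid interval [{self.start}, {self.end})")
        object.__setattr__(self, "genes", frozenset(self.genes))

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Stage:
    stage_id: str
    regions: list[DeletionRegion]
    cumulative_deleted_bp: int
    cumulative_fraction: float
    bof_factor: float

    @property
    def genes(self) -> set[str]:
        return {g for r in self.regions for g in r.genes}


@dataclass
class StreamliningPlan:
    genome_length: int
    stages: list[Stage] = field(default_factory=list)

    def stage(self, stage_id: str) -> Stage:
        for s in self.stages:
            if s.stage_id == stage_id:
                return s
        raise KeyError(f"stage {stage_id!r} not in plan")

    def genes_through(self, stage_id: str) -> set[str]:
        """Union of member genes of all stages up to and including the given
        stage (deletions are cumulative)."""
        out: set[str] = set()
        for s in self.stages:
            out |= s.genes
            if s.stage_id == stage_id:
                return out
        raise KeyError(f"stage {stage_id!r} not in plan")


@dataclass
class BiomassAdjustment:
    """Record of a proportional BOF rescaling."""

    factor: float
    adjusted_components: list[str]
    before: dict[str, float]
    after: dict[str, float]


# ---------------------------------------------------------------------------
# Region tables
# ---------------------------------------------------------------------------

def load_regions(
    path: Union[str, Path], one_based_inclusive: bool = False
) -> list[DeletionRegion]:
    """Read a deletion-region table.

    Accepts either a headered TSV (``region_id  category  start  end  genes``
    with genes semicolon-separated) or headerless 6-column BED with the
    category carried in the name field. ``one_based_inclusive`` converts
    1-based inclusive coordinates to the internal 0-based half-open form.
    """
    path = Path(path)
    regions: list[DeletionRegion] = []
    lines = [l for l in path.read_text().splitlines() if l.strip()
             and not l.startswith("#")]
    if not lines:
        return regions
    header = lines[0].split("\t")
    has_header = header[0] == "region_id"
    rows = lines[1:] if has_header else lines
    for lineno, raw in enumerate(rows, start=2 if has_header else 1):
        cells = raw.split("\t")
        try:
            if has_header:
                rid, category = cells[0], cells[1]
                start, end = int(cells[2]), int(cells[3])
                genes = frozenset(
                    g for g in (cells[4].split(";") if len(cells) > 4 else ())
                    if g)
            else:  # BED: chrom start end name score strand — category in name
                if len(cells) < 4:
                    raise RegionFileError(
                        f"{path}:{lineno}: BED row needs >= 4 columns")
                start, end = int(cells[1]), int(cells[2])
                name = cells[3]
                category, _, rid_part = name.partition(":")
                rid = rid_part or f"{cells[0]}_{start}_{end}"
                genes = frozenset()
            if one_based_inclusive:
                start -= 1
            if start >= end:
                raise RegionFileError(
                    f"{path}:{lineno}: start {start} >= end {end}")
            regions.append(DeletionRegion(
                id=rid, category=category, start=start, end=end, genes=genes))
        except RegionFileError:
            raise
        except (ValueError, IndexError) as exc:
            raise RegionFileError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_regions(regions: Sequence[DeletionRegion], path: Union[str, Path]) -> Path:
    path = Path(path)
    lines = ["region_id\tcategory\tstart\tend\tgenes"]
    for r in regions:
        lines.append(
            f"{r.id}\t{r.category}\t{r.start}\t{r.end}\t"
            + ";".join(sorted(r.genes)))
    path.write_text("\n".join(lines) + "\n")
    return path


@dataclass
class TargetSummary:
    total_bp: int
    percent_of_genome: float
    counts_by_category: dict[str, int]


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def summarize_targets(
    regions: Iterable[DeletionRegion], genome_length: int
) -> TargetSummary:
    """Total deleted bp (after merging overlaps), percent of genome, and the
    per-category region census."""
    if genome_length <= 0:
        raise ValueError(f"genome_length must be > 0, got {genome_length}")
    regions = list(regions)
    intervals = [(r.start, r.end) for r in regions]
    merged = _merge_intervals(intervals)
    total = sum(e - s for s, e in merged)
    naive_total = sum(e - s for s, e in intervals)
    if total != naive_total:
        logger.warning(
            "deletion regions overlap: %d bp counted once instead of %d",
            total, naive_total)
    counts: dict[str, int] = {}
    for r in regions:
        counts[r.category] = counts.get(r.category, 0) + 1
    return TargetSummary(
        total_bp=total,
        percent_of_genome=100.0 * total / genome_length,
        counts_by_category=counts)


# ---------------------------------------------------------------------------
# Plans
# ---------------------------------------------------------------------------

def build_plan(
    regions: Sequence[DeletionRegion],
    genome_length: int,
    stage_assignment: dict[str, str],
    factor_mode: str = "nominal_percent",
    stage_order: Optional[Sequence[str]] = None,
) -> StreamliningPlan:
    """Group regions into ordered stages and compute cumulative accounting.

    ``nominal_percent`` assigns stage k the BOF factor 1 − 0.01·k (the
    each-portion-is-about-1% convention); ``exact_bp`` uses
    1 − cumulative_fraction instead.
    """
    if factor_mode not in ("nominal_percent", "exact_bp"):
        raise ValueError(f"unknown factor_mode {factor_mode!r}")
    by_id = {r.id: r for r in regions}
    unassigned = set(by_id) - set(stage_assignment)
    if unassigned:
        raise ValueError(
            "regions not assigned to any stage: " + ", ".join(sorted(unassigned)))
    unknown = set(stage_assignment) - set(by_id)
    if unknown:
        raise ValueError(
            "stage assignment names unknown regions: " + ", ".join(sorted(unknown)))
    if stage_order is None:
        stage_order = sorted(set(stage_assignment.values()))
    stages: list[Stage] = []
    cumulative = 0
    for k, stage_id in enumerate(stage_order, start=1):
        members = [by_id[rid] for rid in sorted(stage_assignment)
                   if stage_assignment[rid] == stage_id]
        cumulative += sum(r.length for r in members)
        fraction = cumulative / genome_length
        if factor_mode == "nominal_percent":
            factor = 1.0 - 0.01 * k
        else:
            factor = 1.0 - fraction
        if not (0.0 < factor <= 1.0):
            raise ValueError(
                f"stage {stage_id!r}: BOF factor {factor} outside (0, 1]")
        stages.append(Stage(
            stage_id=stage_id, regions=members,
            cumulative_deleted_bp=cumulative,
            cumulative_fraction=fraction, bof_factor=factor))
    return StreamliningPlan(genome_length=genome_length, stages=stages)


# ---------------------------------------------------------------------------
# BOF rescaling and model derivation
# ---------------------------------------------------------------------------

def _component_base(met_id: str) -> str:
    base, sep, _comp = met_id.rpartition("_")
    return (base if sep else met_id).lower()


def resolve_bof_components(
    model: MetabolicModel, components: Sequence[str]
) -> dict[str, str]:
    """Map requested component names to metabolite ids of the biomass
    reaction. A component matches a biomass metabolite by exact id, by
    compartment-stripped id (``atp`` ↔ ``atp_c0``), or by metabolite name."""
    biomass = model.objective_reaction
    mets = {mid: model.get_metabolite(mid) for mid in biomass.stoichiometry}
    mapping: dict[str, str] = {}
    missing: list[str] = []
    for comp in components:
        comp_l = comp.lower()
        match = None
        for mid, met in mets.items():
            if mid == comp or _component_base(mid) == comp_l \
                    or met.name.lower() == comp_l:
                match = mid
                break
        if match is None:
            missing.append(comp)
        else:
            mapping[comp] = match
    if missing:
        logger.warning(
            "BOF components not in biomass reaction of model %s (skipped): %s",
            model.id, ", ".join(missing))
    return mapping


def rescale_bof(
    model: MetabolicModel,
    factor: float,
    components: Sequence[str] = DEFAULT_BOF_COMPONENTS,
) -> tuple[MetabolicModel, BiomassAdjustment]:
    """Multiply the biomass coefficients of the listed components by
    ``factor`` (signs preserved, magnitudes scaled); all other coefficients
    and all bounds are untouched."""
    if not (0.0 < factor <= 1.0):
        raise ValueError(f"factor must be in (0, 1], got {factor}")
    mapping = resolve_bof_components(model, components)
    if not mapping:
        raise ValueError(
            f"none of the components {list(components)} occur in the biomass "
            f"reaction of model {model.id!r}")
    new = model.copy()
    biomass = new.objective_reaction
    before: dict[str, float] = {}
    after: dict[str, float] = {}
    for met_id in mapping.values():
        before[met_id] = biomass.stoichiometry[met_id]
        biomass.stoichiometry[met_id] = before[met_id] * factor
        after[met_id] = biomass.stoichiometry[met_id]
    return new, BiomassAdjustment(
        factor=factor, adjusted_components=sorted(mapping.values()),
        before=before, after=after)


def derive_streamlined_model(
    model: MetabolicModel,
    plan: StreamliningPlan,
    stage_id: str,
    components: Sequence[str] = DEFAULT_BOF_COMPONENTS,
) -> MetabolicModel:
    """Derive the streamlined model for a plan stage: delete the member genes
    of every stage up to and including this one, then rescale the BOF by the
    stage factor. Provenance is stored in the model annotations."""
    stage = plan.stage(stage_id)
    genes = plan.genes_through(stage_id)
    derived = apply_gene_deletions(model, genes)
    if stage.bof_factor < 1.0:
        derived, adjustment = rescale_bof(derived, stage.bof_factor, components)
    else:
        adjustment = None
    derived.id = f"{model.id}_{stage_id}"
    derived.annotations = dict(derived.annotations)
    derived.annotations.update({
        "derived_from": model.id,
        "stage_id": stage_id,
        "deleted_genes": ";".join(sorted(genes)),
        "cumulative_deleted_bp": str(stage.cumulative_deleted_bp),
        "cumulative_fraction": repr(stage.cumulative_fraction),
        "bof_factor": repr(stage.bof_factor),
    })
    return derived


def add_heterologous_pathway(
    model: MetabolicModel, reactions: Sequence[Reaction]
) -> MetabolicModel:
    """Append heterologous reactions (e.g. a phenol transport plus phenol
    hydroxylation route feeding catechol into existing degradation reactions).

    Metabolites referenced but absent from the model are created in the
    exterior compartment if their id carries an exterior suffix, otherwise in
    the cytosol.
    """
    existing = {r.id for r in model.reactions}
    for r in reactions:
        if r.id in existing:
            raise ValueError(f"reaction id {r.id!r} already present in model "
                             f"{model.id!r}")
    new = model.copy()
    met_ids = {m.id for m in new.metabolites}
    exterior = sorted(new.exterior_compartments)[0]
    for r in reactions:
        for met_id in r.stoichiometry:
            if met_id not in met_ids:
                comp = exterior if met_id.endswith(f"_{exterior}") else "c0"
                new.metabolites.append(Metabolite(id=met_id, compartment=comp))
                met_ids.add(met_id)
        new.reactions.append(r)
    new.refresh_exchange_flags()
    require_valid(new)
    return new


def percent_mgr_improvement(mgr_wt: float, mgr_streamlined: float) -> float:
    """Percent change in maximum growth rate relative to the wild type."""
    if mgr_wt <= 0:
        raise ValueError(
            f"wild-type MGR must be > 0 to compute an improvement, got {mgr_wt}")
    return 100.0 * (mgr_streamlined - mgr_wt) / mgr_wt
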