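"""Carbon-source utilization screening and quantitative growth validation.

A :class:`CarbonPanel` emulates a phenotype-microarray experiment (e.g. a
Biolog GEN III plate plus literature-reported substrates): each entry names a
substrate, the model exchange reaction or metabolite that represents it, and
the experimentally observed growth call. Screening simulates sole-carbon-
source growth for every entry — base mineral medium, the substrate's exchange
opened at the standard 100 mmol·gDW⁻¹·h⁻¹ uptake bound, all other carbon
exchanges closed — and compares the FBA growth call with the observation in a
2×2 confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .model import (
    DEFAULT_MEDIUM_UPTAKE,
    Medium,
    MetabolicModel,
    add_free_diffusion_transport,
    set_medium,
)
from .fba import solve_fba

logger = logging.getLogger("gemstream")

DEFAULT_GROWTH_THRESHOLD = 1e-4  # h^-1; well above LP noise, below any real MGR


@dataclass(frozen=True)
class PanelEntry:
    source_id: str
    target_id: str  # exchange reaction id or metabolite id in the model
    observed_growth: Optional[bool] = None


@dataclass
class CarbonPanel:
    entries: list[PanelEntry]
    base_medium: Medium = field(default_factory=Medium)

    def __post_init__(self):
        ids = [e.source_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate panel source ids: {', '.join(dupes)}")


@dataclass
class ScreenRow:
    source_id: str
    mgr: float
    predicted_growth: bool
    transport_added: bool = False
    reason: str = ""


@dataclass
class ScreenResult:
    model_id: str
    growth_threshold: float
    rows: list[ScreenRow]

    def row(self, source_id: str) -> ScreenRow:
        for r in self.rows:
            if r.source_id == source_id:
                return r
        raise KeyError(source_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.source_id, r.mgr, r.predicted_growth, r.transport_added,
              r.reason) for r in self.rows],
            columns=["source_id", "mgr", "predicted", "transport_added",
                     "reason"])


@dataclass
class ConfusionMatrix:
    """Predicted-vs-observed growth calls over the scored panel entries."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")


def screen_carbon_sources(
    model: MetabolicModel,
    panel: CarbonPanel,
    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
    uptake: float = DEFAULT_MEDIUM_UPTAKE,
) -> ScreenResult:
    """Simulate growth on each panel substrate as sole carbon source.

    For each entry the base medium is applied (closing every exchange it does
    not name), the substrate exchange is opened at ``uptake``; if the entry
    names a metabolite without an exchange path, a free-diffusion transport
    and exchange are injected first. Substrates absent from the model are
    called no-growth with reason ``absent``. The input model is never
    modified.
    """
    base = set_medium(model, panel.base_medium)
    rxn_ids = {r.id for r in base.reactions}
    met_ids = {m.id for m in base.metabolites}
    rows: list[ScreenRow] = []
    for entry in panel.entries:
        target = entry.target_id
        transport_added = False
        if target in rxn_ids:
            work = base.copy()
            ex_id = target
        elif target in met_ids:
            from .model import has_exchange_path

            if has_exchange_path(base, target):
                work = base.copy()
                ex_id = _existing_exchange_for(base, target)
            else:
                work = add_free_diffusion_transport(base, target)
                transport_added = True
                ex_id = f"EX_{_exterior_id(work, target)}"
        else:
            rows.append(ScreenRow(
                source_id=entry.source_id, mgr=0.0, predicted_growth=False,
                reason="absent"))
            continue
        ex = work.get_reaction(ex_id)
        ex.lower_bound = -uptake
        sol = solve_fba(work)
        mgr = sol.objective_value if sol.optimal else 0.0
        rows.append(ScreenRow(
            source_id=entry.source_id, mgr=mgr,
            predicted_growth=bool(sol.optimal and mgr >= growth_threshold),
            transport_added=transport_added))
    return ScreenResult(model_id=model.id, growth_threshold=growth_threshold,
                        rows=rows)


def _exterior_id(model: MetabolicModel, met_id: str) -> str:
    from .model import _exterior_counterpart_id

    return _exterior_counterpart_id(model, model.get_metabolite(met_id))


def _existing_exchange_for(model: MetabolicModel, met_id: str) -> str:
    """Exchange reaction backing an already-exchangeable metabolite."""
    exchanges = {next(iter(r.stoichiometry)): r.id
                 for r in model.reactions if r.is_exchange}
    if met_id in exchanges:
        return exchanges[met_id]
    for r in model.reactions:
        if met_id in r.stoichiometry and not r.is_exchange:
            for other in r.stoichiometry:
                if other != met_id and other in exchanges:
                    return exchanges[other]
    raise KeyError(f"no exchange path found for metabolite {met_id!r}")


def score_confusion(result: ScreenResult, panel: CarbonPanel) -> ConfusionMatrix:
    """2×2 confusion matrix of predicted vs observed growth; entries without
    an observation are excluded with a warning."""
    observed = {e.source_id: e.observed_growth for e in panel.entries}
    cm = ConfusionMatrix()
    for row in result.rows:
        obs = observed.get(row.source_id)
        if obs is None:
            logger.warning("panel entry %s has no observed growth call; "
                           "excluded from scoring", row.source_id)
            continue
        if row.predicted_growth and obs:
            cm.tp += 1
        elif row.predicted_growth and not obs:
            cm.fp += 1
        elif not row.predicted_growth and obs:
            cm.fn += 1
        else:
            cm.tn += 1
    return cm


def predict_mgr_quantitative(
    model: MetabolicModel,
    substrate_exchange_id: str,
    uptake_rate: float,
    base_medium: Optional[Medium] = None,
) -> float:
    """Maximum growth rate at a measured substrate uptake rate.

    Sets the substrate exchange lower bound to −uptake_rate (e.g. the
    literature glucose uptake of 6.1 mmol·gDW⁻¹·h⁻¹) with every other carbon
    exchange closed, and returns the FBA optimum in h⁻¹. When ``base_medium``
    is given it is applied first (supplying minerals and oxygen); otherwise
    the model's current bounds are kept and only the substrate bound changes.
    """
    if uptake_rate <= 0:
        raise ValueError(f"uptake_rate must be > 0, got {uptake_rate}")
    work = set_medium(model, base_medium) if base_medium is not None \
        else model.copy()
    ex = work.get_reaction(substrate_exchange_id)
    if not ex.is_exchange:
        raise ValueError(f"{substrate_exchange_id!r} is not an exchange reaction")
    ex.lower_bound = -uptake_rate
    sol = solve_fba(work)
    return sol.objective_value if sol.optimal else 0.0


def validate_quantitative(
    mgr_predicted: float,
    mu_measured: float,
    pass_threshold_percent: float = 20.0,
) -> dict:
    """Relative difference between predicted MGR and measured growth rate,
    with the pass call (difference strictly below the threshold)."""
    if mu_measured <= 0:
        raise ValueError(f"measured growth rate must be > 0, got {mu_measured}")
    rel = 100.0 * abs(mgr_predicted - mu_measured) / mu_measured
    return {"relative_difference_percent": rel,
            "pass": rel < pass_threshold_percent}


# ---------------------------------------------------------------------------
# Panel files and plate helper
# ---------------------------------------------------------------------------

def load_panel(path: Union[str, Path], base_medium: Optional[Medium] = None
               ) -> CarbonPanel:
    """Read a panel TSV: ``source_id  metabolite_or_exchange_id
    observed_growth`` with observed growth 0/1/NA."""
    path = Path(path)
    entries: list[PanelEntry] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cells = raw.split("\t")
        if cells[0] == "source_id":
            continue
        if len(cells) < 2:
            raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
        obs_raw = cells[2].strip() if len(cells) > 2 else "NA"
        if obs_raw in ("", "NA", "na", "NaN"):
            obs = None
        else:
            obs = bool(int(obs_raw))
        entries.append(PanelEntry(source_id=cells[0], target_id=cells[1],
                                  observed_growth=obs))
    return CarbonPanel(entries=entries, base_medium=base_medium or Medium())


def write_panel(panel: CarbonPanel, path: Union[str, Path]) -> Path:
    path = Path(path)
    lines = ["source_id\tmetabolite_or_exchange_id\tobserved_growth"]
    for e in panel.entries:
        obs = "NA" if e.observed_growth is None else str(int(e.observed_growth))
        lines.append(f"{e.source_id}\t{e.target_id}\t{obs}")
    path.write_text("\n".join(lines) + "\n")
    return path


def calls_from_plate(
    plate: pd.DataFrame, od_column: str = "od600",
    control_flag: str = "control_well",
) -> pd.DataFrame:
    """Growth calls from a raw plate table: OD above the mean of control
    (no-carbon) wells is called positive."""
    controls = plate.loc[plate[control_flag].astype(bool), od_column]
    if controls.empty:
        raise ValueError("plate table contains no control wells")
    baseline = controls.mean()
    out = plate.loc[~plate[control_flag].astype(bool)].copy()
    out["observed_growth"] = out[od_column] > baseline
    return out


def evaluate_deposited_models(
    wild_type_path: Union[str, Path],
    streamlined_path: Union[str, Path],
    panel: Optional[CarbonPanel] = None,
    phenol_metabolite_id: Optional[str] = None,
) -> pd.DataFrame:
    """Percent-MGR-improvement table for a deposited wild-type/streamlined
    SBML model pair.

    Computes the improvement on the models' deposited medium (LB), on each
    positive substrate of ``panel`` (sole carbon source at the standard
    uptake bound), and on phenol when ``phenol_metabolite_id`` is given
    (injecting the free-diffusion transport first). Returns a frame with
    columns ``condition``, ``mgr_wild_type``, ``mgr_streamlined``,
    ``improvement_percent``.
    """
    from .io import read_model
    from .streamline import percent_mgr_improvement

    wt = read_model(wild_type_path)
    sl = read_model(streamlined_path)
    rows = []

    def record(condition: str, m_wt: MetabolicModel, m_sl: MetabolicModel):
        mgr_wt = solve_fba(m_wt).objective_value
        mgr_sl = solve_fba(m_sl).objective_value
        rows.append((condition, mgr_wt, mgr_sl,
                     percent_mgr_improvement(mgr_wt, mgr_sl)))

    record("deposited_medium", wt, sl)
    if panel is not None:
        for entry in panel.entries:
            if entry.observed_growth:
                for_wt = screen_carbon_sources(
                    wt, CarbonPanel([entry], panel.base_medium))
                for_sl = screen_carbon_sources(
                    sl, CarbonPanel([entry], panel.base_medium))
                mgr_wt = for_wt.rows[0].mgr
                mgr_sl = for_sl.rows[0].mgr
                if mgr_wt > 0:
                    rows.append((entry.source_id, mgr_wt, mgr_sl,
                                 percent_mgr_improvement(mgr_wt, mgr_sl)))
    if phenol_metabolite_id is not None:
        wt_ph = add_free_diffusion_transport(wt, phenol_metabolite_id)
        sl_ph = add_free_diffusion_transport(sl, phenol_metabolite_id)
        record("phenol", wt_ph, sl_ph)
    return pd.DataFrame(rows, columns=[
        "condition", "mgr_wild_type", "mgr_streamlined", "improvement_percent"])
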