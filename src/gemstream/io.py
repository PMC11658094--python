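"""Model and medium file I/O.

Three model dialects are supported:

``native-json``
    The package's own schema, convenient for fixtures and round-tripping::

        {"id": ..., "metabolites": [{"id", "name", "compartment", "formula"}],
         "reactions": [{"id", "name", "stoich": {met: coeff}, "lb", "ub",
                        "gpr", "tags": []}],
         "genes": [...], "objective": ..., "annotations": {...},
         "exterior_compartments": [...]}

``native-tsv``
    A sectioned tab-separated file (``#section metabolites|reactions|genes``)
    carrying the same information.

``sbml-fbc``
    SBML Level 3 Version 1 with the FBC v2 extension: flux bounds as global
    parameters, GPRs as gene-product associations, the biomass objective as
    the active FBC objective.

Floats are serialised with ``repr`` so bound and coefficient values round-trip
at full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

from .model import (
    DEFAULT_OXYGEN_UPTAKE,
    GprRule,
    Medium,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    require_valid,
    validate_model,
)

DIALECTS = ("sbml-fbc", "native-json", "native-tsv")


class ModelParseError(ValueError):
    """Raised when a model file cannot be parsed in the requested dialect."""


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml-fbc"
    if suffix == ".json":
        return "native-json"
    if suffix in (".tsv", ".txt"):
        return "native-tsv"
    raise ValueError(f"cannot infer model dialect from {path.name!r}")


def read_model(path: Union[str, Path], dialect: Optional[str] = None) -> MetabolicModel:
    """Read a metabolic model; the dialect is inferred from the extension when
    not given. The returned model is validated against all structural
    invariants."""
    path = Path(path)
    if dialect is None:
        dialect = _infer_dialect(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "native-json":
        model = _read_json(path)
    elif dialect == "native-tsv":
        model = _read_tsv(path)
    else:
        model = _read_sbml(path)
    require_valid(model)
    return model


def write_model(
    model: MetabolicModel, path: Union[str, Path], dialect: Optional[str] = None
) -> Path:
    """Write a model losslessly in the given dialect; returns the path."""
    path = Path(path)
    if dialect is None:
        dialect = _infer_dialect(path)
    require_valid(model)
    if dialect == "native-json":
        _write_json(model, path)
    elif dialect == "native-tsv":
        _write_tsv(model, path)
    elif dialect == "sbml-fbc":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    return path


# ---------------------------------------------------------------------------
# native JSON
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             "formula": m.formula}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoich": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": r.gpr.expression if r.gpr is not None else None,
                **({"tags": sorted(r.pathway_tags)} if r.pathway_tags else {}),
            }
            for r in model.reactions
        ],
        "genes": sorted(model.genes),
        "deleted_genes": sorted(model.deleted_genes),
        "objective": model.objective_reaction_id,
        "annotations": model.annotations,
        "exterior_compartments": sorted(model.exterior_compartments),
    }


def _model_from_dict(data: dict, source: str) -> MetabolicModel:
    try:
        metabolites = [
            Metabolite(id=m["id"], name=m.get("name", ""),
                       compartment=m.get("compartment", "c0"),
                       formula=m.get("formula"))
            for m in data["metabolites"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoich"].items()},
                lower_bound=float(r["lb"]),
                upper_bound=float(r["ub"]),
                gpr=GprRule(r["gpr"]) if r.get("gpr") else None,
                pathway_tags=frozenset(r.get("tags", ())),
            )
            for r in data["reactions"]
        ]
        return MetabolicModel(
            id=data["id"],
            metabolites=metabolites,
            reactions=reactions,
            genes=set(data.get("genes", ())),
            deleted_genes=set(data.get("deleted_genes", ())),
            objective_reaction_id=data.get("objective", ""),
            annotations=dict(data.get("annotations", {})),
            exterior_compartments=set(data.get("exterior_compartments", ("e0",))),
        )
    except KeyError as exc:
        raise ModelParseError(f"{source}: missing required field {exc}") from exc


def _read_json(path: Path) -> MetabolicModel:
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path}: invalid JSON ({exc})") from exc
    return _model_from_dict(data, str(path))


def _write_json(model: MetabolicModel, path: Path) -> None:
    path.write_text(
        json.dumps(_model_to_dict(model), indent=1, sort_keys=False,
                   default=_json_default) + "\n"
    )


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# native TSV
# ---------------------------------------------------------------------------

def _write_tsv(model: MetabolicModel, path: Path) -> None:
    lines = [f"#gemstream-model\t{model.id}"]
    lines.append(f"#objective\t{model.objective_reaction_id}")
    lines.append("#exterior\t" + ";".join(sorted(model.exterior_compartments)))
    if model.deleted_genes:
        lines.append("#deleted_genes\t" + ";".join(sorted(model.deleted_genes)))
    for key in sorted(model.annotations):
        lines.append(f"#annotation\t{key}\t{model.annotations[key]}")
    lines.append("#section\tmetabolites")
    lines.append("id\tname\tcompartment\tformula")
    for m in model.metabolites:
        lines.append(f"{m.id}\t{m.name}\t{m.compartment}\t{m.formula or ''}")
    lines.append("#section\treactions")
    lines.append("id\tname\tlb\tub\tgpr\ttags\tstoichiometry")
    for r in model.reactions:
        stoich = ";".join(
            f"{met}:{coeff!r}" for met, coeff in sorted(r.stoichiometry.items())
        )
        gpr = r.gpr.expression if r.gpr is not None else ""
        tags = ";".join(sorted(r.pathway_tags))
        lines.append(
            f"{r.id}\t{r.name}\t{r.lower_bound!r}\t{r.upper_bound!r}\t"
            f"{gpr}\t{tags}\t{stoich}"
        )
    lines.append("#section\tgenes")
    for g in sorted(model.genes):
        lines.append(g)
    path.write_text("\n".join(lines) + "\n")


def _read_tsv(path: Path) -> MetabolicModel:
    model_id = ""
    objective = ""
    exterior: set[str] = {"e0"}
    annotations: dict = {}
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    genes: set[str] = set()
    deleted_genes: set[str] = set()
    section = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        cells = raw.split("\t")
        if cells[0] == "#gemstream-model":
            model_id = cells[1]
        elif cells[0] == "#objective":
            objective = cells[1]
        elif cells[0] == "#exterior":
            exterior = set(cells[1].split(";")) if cells[1] else {"e0"}
        elif cells[0] == "#deleted_genes":
            deleted_genes = set(g for g in cells[1].split(";") if g)
        elif cells[0] == "#annotation":
            annotations[cells[1]] = cells[2] if len(cells) > 2 else ""
        elif cells[0] == "#section":
            section = cells[1]
        elif section == "metabolites":
            if cells[0] == "id":
                continue
            if len(cells) < 3:
                raise ModelParseError(f"{path}:{lineno}: malformed metabolite row")
            metabolites.append(Metabolite(
                id=cells[0], name=cells[1], compartment=cells[2],
                formula=cells[3] or None if len(cells) > 3 else None))
        elif section == "reactions":
            if cells[0] == "id":
                continue
            if len(cells) < 7:
                raise ModelParseError(f"{path}:{lineno}: malformed reaction row")
            stoich: dict[str, float] = {}
            for pair in cells[6].split(";"):
                if not pair:
                    continue
                met, _, coeff = pair.rpartition(":")
                if not met:
                    raise ModelParseError(
                        f"{path}:{lineno}: malformed stoichiometry entry {pair!r}")
                stoich[met] = float(coeff)
            reactions.append(Reaction(
                id=cells[0], name=cells[1],
                lower_bound=float(cells[2]), upper_bound=float(cells[3]),
                gpr=GprRule(cells[4]) if cells[4] else None,
                pathway_tags=frozenset(t for t in cells[5].split(";") if t),
                stoichiometry=stoich))
        elif section == "genes":
            genes.add(cells[0])
        else:
            raise ModelParseError(f"{path}:{lineno}: row outside any section")
    if not model_id:
        raise ModelParseError(f"{path}: missing #gemstream-model header")
    return MetabolicModel(
        id=model_id, metabolites=metabolites, reactions=reactions, genes=genes,
        deleted_genes=deleted_genes, objective_reaction_id=objective,
        annotations=annotations, exterior_compartments=exterior)


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC v2
# ---------------------------------------------------------------------------

def _sbml_escape(value: float) -> float:
    return float(value)


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    fbc = sbml_model.getPlugin("fbc")
    fbc.setStrict(True)

    # free-form metadata (and the deleted-gene record) survive as SBML notes
    notes_entries = dict(sorted(model.annotations.items()))
    if model.deleted_genes:
        notes_entries["gemstream_deleted_genes"] = ";".join(
            sorted(model.deleted_genes))
    if notes_entries:
        notes = "<body xmlns='http://www.w3.org/1999/xhtml'>" + "".join(
            f"<p>{k}: {v}</p>" for k, v in notes_entries.items()
        ) + "</body>"
        sbml_model.setNotes(notes)

    compartments = sorted({m.compartment for m in model.metabolites})
    for comp_id in compartments:
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)
        comp.setSize(1.0)

    exterior = sorted(model.exterior_compartments)
    for m in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(m.id)
        if m.name:
            sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        if m.formula:
            sp_fbc = sp.getPlugin("fbc")
            sp_fbc.setChemicalFormula(m.formula)

    for g in sorted(model.genes | model.deleted_genes):
        gp = fbc.createGeneProduct()
        gp.setId(g)
        gp.setLabel(g)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            param = sbml_model.createParameter()
            param.setId(pid)
            param.setValue(value)
            param.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    def set_association(assoc_parent, node):
        kind = node[0]
        if kind == "gene":
            ref = assoc_parent.createGeneProductRef()
            ref.setGeneProduct(node[1])
        elif kind == "and":
            op = assoc_parent.createAnd()
            for child in node[1]:
                set_association(op, child)
        else:
            op = assoc_parent.createOr()
            for child in node[1]:
                set_association(op, child)

    for r in model.reactions:
        rxn = sbml_model.createReaction()
        rxn.setId(r.id)
        if r.name:
            rxn.setName(r.name)
        rxn.setFast(False)
        rxn.setReversible(r.lower_bound < 0)
        for met_id, coeff in sorted(r.stoichiometry.items()):
            if coeff < 0:
                ref = rxn.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = rxn.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(met_id)
            ref.setConstant(True)
        r_fbc = rxn.getPlugin("fbc")
        r_fbc.setLowerFluxBound(bound_param(_sbml_escape(r.lower_bound)))
        r_fbc.setUpperFluxBound(bound_param(_sbml_escape(r.upper_bound)))
        if r.gpr is not None:
            assoc = r_fbc.createGeneProductAssociation()
            set_association(assoc, r.gpr.ast)
        if r.pathway_tags:
            rxn.setNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'><p>tags: "
                + ";".join(sorted(r.pathway_tags)) + "</p></body>"
            )

    objective = fbc.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    flux_obj = objective.createFluxObjective()
    flux_obj.setReaction(model.objective_reaction_id)
    flux_obj.setCoefficient(1.0)
    fbc.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def _association_to_ast(assoc) -> tuple:
    import libsbml

    if isinstance(assoc, libsbml.GeneProductRef):
        return ("gene", assoc.getGeneProduct())
    if isinstance(assoc, libsbml.FbcAnd):
        return ("and", [_association_to_ast(assoc.getAssociation(i))
                        for i in range(assoc.getNumAssociations())])
    if isinstance(assoc, libsbml.FbcOr):
        return ("or", [_association_to_ast(assoc.getAssociation(i))
                       for i in range(assoc.getNumAssociations())])
    raise ModelParseError(f"unsupported gene association node: {assoc}")


def _ast_to_expression(node, top=True) -> str:
    kind = node[0]
    if kind == "gene":
        return node[1]
    joiner = f" {kind} "
    inner = joiner.join(_ast_to_expression(c, top=False) for c in node[1])
    return inner if top else f"({inner})"


def _notes_tags(notes_string: str) -> frozenset[str]:
    import re

    m = re.search(r"tags:\s*([^<]*)", notes_string)
    if not m:
        return frozenset()
    return frozenset(t for t in m.group(1).strip().split(";") if t)


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"{path}: SBML parse error: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: no <model> element")
    fbc = sbml_model.getPlugin("fbc")
    if fbc is None:
        raise ModelParseError(f"{path}: FBC package information missing")

    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sp_fbc = sp.getPlugin("fbc")
        formula = None
        if sp_fbc is not None and sp_fbc.isSetChemicalFormula():
            formula = sp_fbc.getChemicalFormula()
        metabolites.append(Metabolite(
            id=sp.getId(), name=sp.getName() or "",
            compartment=sp.getCompartment(), formula=formula))

    genes = set()
    for i in range(fbc.getNumGeneProducts()):
        genes.add(fbc.getGeneProduct(i).getId())

    params = {}
    for i in range(sbml_model.getNumParameters()):
        p = sbml_model.getParameter(i)
        params[p.getId()] = p.getValue()

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) \
                - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) \
                + ref.getStoichiometry()
        r_fbc = rxn.getPlugin("fbc")
        if r_fbc is None or not r_fbc.isSetLowerFluxBound():
            raise ModelParseError(
                f"{path}: reaction {rxn.getId()!r} lacks FBC flux bounds")
        lb = params[r_fbc.getLowerFluxBound()]
        ub = params[r_fbc.getUpperFluxBound()]
        gpr = None
        if r_fbc.isSetGeneProductAssociation():
            ast = _association_to_ast(
                r_fbc.getGeneProductAssociation().getAssociation())
            gpr = GprRule(_ast_to_expression(ast))
        tags = frozenset()
        if rxn.isSetNotes():
            tags = _notes_tags(rxn.getNotesString())
        reactions.append(Reaction(
            id=rxn.getId(), name=rxn.getName() or "",
            stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            gpr=gpr, pathway_tags=tags))

    objective_id = ""
    active = fbc.getActiveObjective()
    if active is not None and active.getNumFluxObjectives() > 0:
        objective_id = active.getFluxObjective(0).getReaction()
    if not objective_id:
        raise ModelValidationError(f"{path}: no active FBC objective set")

    annotations = {}
    if sbml_model.isSetNotes():
        import re

        for m in re.finditer(r"<p>\s*([^:<]+):\s*([^<]*)</p>",
                             sbml_model.getNotesString()):
            annotations[m.group(1).strip()] = m.group(2).strip()
    deleted_raw = annotations.pop("gemstream_deleted_genes", "")
    deleted_genes = {g for g in deleted_raw.split(";") if g}
    genes -= deleted_genes

    compartments = {
        sbml_model.getCompartment(i).getId()
        for i in range(sbml_model.getNumCompartments())
    }
    exterior = {c for c in compartments if c.startswith("e")} or {"e0"}

    return MetabolicModel(
        id=sbml_model.getId() or path.stem,
        metabolites=metabolites, reactions=reactions, genes=genes,
        deleted_genes=deleted_genes, objective_reaction_id=objective_id,
        annotations=annotations, exterior_compartments=exterior)


# ---------------------------------------------------------------------------
# medium TSV
# ---------------------------------------------------------------------------

def read_medium(path: Union[str, Path]) -> Medium:
    """Read a medium TSV with columns ``exchange_id``, ``max_uptake`` and an
    optional third ``role`` column; the row with role ``oxygen`` sets the
    oxygen exchange and its uptake bound."""
    path = Path(path)
    compounds: dict[str, float] = {}
    oxygen_id = None
    oxygen_uptake = DEFAULT_OXYGEN_UPTAKE
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cells = raw.split("\t")
        if cells[0] == "exchange_id":
            continue
        if len(cells) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
        role = cells[2].strip() if len(cells) > 2 else ""
        if role == "oxygen":
            oxygen_id = cells[0]
            oxygen_uptake = float(cells[1])
        else:
            compounds[cells[0]] = float(cells[1])
    return Medium(compounds=compounds, oxygen_exchange_id=oxygen_id,
                  oxygen_uptake=oxygen_uptake)


def write_medium(medium: Medium, path: Union[str, Path]) -> Path:
    path = Path(path)
    lines = ["exchange_id\tmax_uptake\trole"]
    for ex_id in sorted(medium.compounds):
        lines.append(f"{ex_id}\t{medium.compounds[ex_id]!r}\t")
    if medium.oxygen_exchange_id is not None:
        lines.append(
            f"{medium.oxygen_exchange_id}\t{medium.oxygen_uptake!r}\toxygen")
    path.write_text("\n".join(lines) + "\n")
    return path
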