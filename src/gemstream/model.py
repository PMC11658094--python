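"""Core data structures for constraint-based metabolic models.

A :class:`MetabolicModel` is the stoichiometric reconstruction analysed by the
rest of the package: metabolites, mass-balanced reactions with flux bounds in
mmol·gDW⁻¹·h⁻¹, boolean gene–protein–reaction (GPR) rules, and a biomass
objective reaction whose flux is the growth rate (h⁻¹).

Conventions
-----------
* Exchange reactions are single-metabolite boundary pseudo-reactions on an
  exterior-compartment species; negative flux is uptake, positive is secretion.
* Compartment ids follow the ``c0`` (cytosol) / ``e0`` (exterior) style; which
  compartments count as exterior is a model attribute.
* Reactions disabled by gene deletion are retained with zero bounds rather
  than removed, so flux vectors of wild-type and derived models stay aligned
  reaction-by-reaction.
"""

from __future__ import annotations

import copy as _copy
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

logger = logging.getLogger("gemstream")

DEFAULT_UPPER_BOUND = 1000.0
DEFAULT_OXYGEN_UPTAKE = 10.0
DEFAULT_MEDIUM_UPTAKE = 100.0


class GprParseError(ValueError):
    """Raised when a gene–protein–reaction expression cannot be parsed."""


class ModelValidationError(ValueError):
    """Raised when an operation receives a structurally invalid model."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize_gpr(expression: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            break
        tokens.append(m.group(1))
        pos = m.end()
    if expression[pos:].strip():
        raise GprParseError(f"unparseable GPR fragment: {expression[pos:]!r}")
    return tokens


class _GprParser:
    """Recursive-descent parser for ``gene``, ``and``, ``or``, parentheses.

    Keywords are case-insensitive; ``not`` is deliberately unsupported (GPR
    semantics have no negation).
    """

    def __init__(self, tokens: list[str], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GprParseError(f"unexpected end of GPR expression: {self.source!r}")
        self.pos += 1
        return tok

    def parse(self) -> tuple:
        node = self.parse_or()
        if self.peek() is not None:
            raise GprParseError(
                f"trailing token {self.peek()!r} in GPR expression {self.source!r}"
            )
        return node

    def parse_or(self) -> tuple:
        operands = [self.parse_and()]
        while (tok := self.peek()) is not None and tok.lower() == "or":
            self.next()
            operands.append(self.parse_and())
        return operands[0] if len(operands) == 1 else ("or", operands)

    def parse_and(self) -> tuple:
        operands = [self.parse_atom()]
        while (tok := self.peek()) is not None and tok.lower() == "and":
            self.next()
            operands.append(self.parse_atom())
        return operands[0] if len(operands) == 1 else ("and", operands)

    def parse_atom(self) -> tuple:
        tok = self.next()
        if tok == "(":
            node = self.parse_or()
            if self.next() != ")":
                raise GprParseError(f"unbalanced parenthesis in {self.source!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or", "not"):
            raise GprParseError(
                f"misplaced token {tok!r} in GPR expression {self.source!r}"
            )
        return ("gene", tok)


@dataclass(frozen=True)
class GprRule:
    """A boolean gene–protein–reaction association.

    ``and`` encodes enzyme complexes (every subunit gene required), ``or``
    encodes isozymes (any one suffices).
    """

    expression: str

    def __post_init__(self):
        object.__setattr__(self, "_ast", _GprParser(
            _tokenize_gpr(self.expression), self.expression).parse())

    @property
    def ast(self) -> tuple:
        return self._ast

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node):
            if node[0] == "gene":
                out.add(node[1])
            else:
                for child in node[1]:
                    walk(child)

        walk(self._ast)
        return frozenset(out)

    def evaluate(self, deleted_genes: Iterable[str]) -> bool:
        """True iff the reaction remains catalyzable after the deletions."""
        deleted = set(deleted_genes)

        def walk(node) -> bool:
            kind = node[0]
            if kind == "gene":
                return node[1] not in deleted
            if kind == "and":
                return all(walk(c) for c in node[1])
            return any(walk(c) for c in node[1])

        return walk(self._ast)


def evaluate_gpr(rule: Optional[GprRule | str], deleted_genes: Iterable[str]) -> bool:
    """Evaluate a GPR against a deletion set; an absent rule is always active.

    Reactions without a gene association are treated as spontaneous/orphan
    and can never be disabled by gene deletion.
    """
    if rule is None:
        return True
    if isinstance(rule, str):
        rule = GprRule(rule)
    return rule.evaluate(deleted_genes)


# ---------------------------------------------------------------------------
# Metabolites, reactions, models
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c0"
    formula: Optional[str] = None


@dataclass
class Reaction:
    """A mass-balanced reaction: negative stoichiometric coefficients are
    substrates, positive are products; bounds in mmol·gDW⁻¹·h⁻¹."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_UPPER_BOUND
    name: str = ""
    gpr: Optional[GprRule] = None
    pathway_tags: frozenset[str] = field(default_factory=frozenset)
    is_exchange: bool = False

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = GprRule(self.gpr) if self.gpr.strip() else None
        self.pathway_tags = frozenset(self.pathway_tags)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: set[str] = field(default_factory=set)
    objective_reaction_id: str = ""
    annotations: dict = field(default_factory=dict)
    exterior_compartments: set[str] = field(default_factory=lambda: {"e0"})
    #: genes removed by in-silico deletion; kept so the GPRs of disabled
    #: reactions still resolve (reactions are never dropped)
    deleted_genes: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.genes = set(self.genes)
        self.deleted_genes = set(self.deleted_genes)
        self.exterior_compartments = set(self.exterior_compartments)
        self.refresh_exchange_flags()

    # -- lookups -----------------------------------------------------------
    @property
    def metabolites_by_id(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    @property
    def reactions_by_id(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def get_reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(f"reaction {reaction_id!r} not in model {self.id!r}")

    def get_metabolite(self, metabolite_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == metabolite_id:
                return m
        raise KeyError(f"metabolite {metabolite_id!r} not in model {self.id!r}")

    @property
    def objective_reaction(self) -> Reaction:
        return self.get_reaction(self.objective_reaction_id)

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def _is_exchange(self, reaction: Reaction) -> bool:
        if len(reaction.stoichiometry) != 1:
            return False
        (met_id,) = reaction.stoichiometry
        met = self.metabolites_by_id.get(met_id)
        return met is not None and met.compartment in self.exterior_compartments

    def refresh_exchange_flags(self) -> None:
        """Recompute ``is_exchange`` after structural edits."""
        for r in self.reactions:
            r.is_exchange = self._is_exchange(r)

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)


@dataclass
class Medium:
    """A growth medium as maximum uptake rates on exchange reactions.

    Rates are positive; they are applied as negative lower bounds on the named
    exchange reactions (uptake convention). Oxygen is singled out because its
    uptake bound (default 10) differs from the bulk medium-compound bound
    (default 100).
    """

    compounds: dict[str, float] = field(default_factory=dict)
    oxygen_exchange_id: Optional[str] = None
    oxygen_uptake: float = DEFAULT_OXYGEN_UPTAKE

    def __post_init__(self):
        for ex_id, rate in self.compounds.items():
            if rate < 0:
                raise ValueError(f"uptake rate for {ex_id!r} must be >= 0, got {rate}")
        if self.oxygen_uptake < 0:
            raise ValueError("oxygen_uptake must be >= 0")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    violations: list[str]
    n_exchange_reactions: int = 0
    n_reactions_without_gpr: int = 0
    has_objective: bool = False

    @property
    def valid(self) -> bool:
        return not self.violations


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Structural validation; an empty violation list means the model is valid."""
    violations: list[str] = []
    met_ids = [m.id for m in model.metabolites]
    met_set = set(met_ids)
    if len(met_ids) != len(met_set):
        dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
        violations.append(f"duplicate metabolite ids: {', '.join(dupes)}")
    for m in model.metabolites:
        if not m.compartment:
            violations.append(f"metabolite {m.id!r} has empty compartment")

    rxn_ids = [r.id for r in model.reactions]
    if len(rxn_ids) != len(set(rxn_ids)):
        dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
        violations.append(f"duplicate reaction ids: {', '.join(dupes)}")

    n_no_gpr = 0
    for r in model.reactions:
        if not r.stoichiometry:
            violations.append(f"reaction {r.id!r} has empty stoichiometry")
        if r.lower_bound > r.upper_bound:
            violations.append(
                f"reaction {r.id!r} has lower_bound {r.lower_bound} > "
                f"upper_bound {r.upper_bound}"
            )
        for met_id in r.stoichiometry:
            if met_id not in met_set:
                violations.append(
                    f"reaction {r.id!r} references missing metabolite {met_id!r}"
                )
        if r.gpr is None:
            n_no_gpr += 1
        else:
            for g in sorted(r.gpr.genes - model.genes - model.deleted_genes):
                violations.append(
                    f"reaction {r.id!r} GPR references undeclared gene {g!r}"
                )

    has_objective = bool(model.objective_reaction_id)
    if not has_objective:
        violations.append("no objective reaction set")
    elif model.objective_reaction_id not in set(rxn_ids):
        violations.append(
            f"objective reaction {model.objective_reaction_id!r} not in model"
        )

    return ValidationReport(
        violations=violations,
        n_exchange_reactions=sum(1 for r in model.reactions if r.is_exchange),
        n_reactions_without_gpr=n_no_gpr,
        has_objective=has_objective,
    )


def require_valid(model: MetabolicModel) -> None:
    report = validate_model(model)
    if not report.valid:
        raise ModelValidationError(
            f"model {model.id!r} is invalid: " + "; ".join(report.violations)
        )


# ---------------------------------------------------------------------------
# Model-transforming operations (all non-mutating: they return a new model)
# ---------------------------------------------------------------------------

def apply_gene_deletions(
    model: MetabolicModel, deleted_genes: Iterable[str]
) -> MetabolicModel:
    """Propagate gene deletions through GPRs.

    Every reaction whose GPR evaluates false under the deletion set gets both
    bounds set to zero; reactions are retained so reaction ids stay aligned
    with the parent model. Genes are removed from the model's gene set.
    Unknown genes are ignored with a warning.
    """
    deleted = set(deleted_genes)
    unknown = deleted - model.genes
    if unknown:
        logger.warning(
            "gene deletions not in model %s (ignored): %s",
            model.id, ", ".join(sorted(unknown)),
        )
    new = model.copy()
    for r in new.reactions:
        if r.gpr is not None and not r.gpr.evaluate(deleted):
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    new.deleted_genes |= deleted & new.genes
    new.genes -= deleted
    return new


def set_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Apply a growth medium using the standard uptake-bound conventions.

    Medium compounds get lower bound −rate (default −100), the oxygen
    exchange gets −oxygen_uptake (default −10), every other exchange gets
    lower bound 0 (no uptake), and all exchange upper bounds are set to 1000
    (secretion always allowed). Internal reactions are untouched.
    """
    new = model.copy()
    exchange_ids = {r.id for r in new.reactions if r.is_exchange}
    for ex_id in medium.compounds:
        if ex_id not in exchange_ids:
            raise ValueError(
                f"medium names {ex_id!r}, which is not an exchange reaction of "
                f"model {model.id!r}"
            )
    if medium.oxygen_exchange_id is not None and \
            medium.oxygen_exchange_id not in exchange_ids:
        raise ValueError(
            f"oxygen exchange {medium.oxygen_exchange_id!r} is not an exchange "
            f"reaction of model {model.id!r}"
        )
    for r in new.reactions:
        if not r.is_exchange:
            continue
        r.upper_bound = DEFAULT_UPPER_BOUND
        if r.id == medium.oxygen_exchange_id:
            r.lower_bound = -medium.oxygen_uptake
        elif r.id in medium.compounds:
            r.lower_bound = -medium.compounds[r.id]
        else:
            r.lower_bound = 0.0
    return new


def _exterior_counterpart_id(model: MetabolicModel, met: Metabolite) -> str:
    exterior = sorted(model.exterior_compartments)[0]
    if met.id.endswith(f"_{met.compartment}"):
        base = met.id[: -len(met.compartment) - 1]
        return f"{base}_{exterior}"
    return f"{met.id}_{exterior}"


def has_exchange_path(model: MetabolicModel, metabolite_id: str) -> bool:
    """True if some exchange reaction drains/feeds an exterior species that is
    connected to the given cytosolic metabolite by a transport reaction."""
    exchanged_exterior = {
        next(iter(r.stoichiometry)) for r in model.reactions if r.is_exchange
    }
    for r in model.reactions:
        if metabolite_id in r.stoichiometry and not r.is_exchange:
            if any(m in exchanged_exterior for m in r.stoichiometry
                   if m != metabolite_id):
                return True
    # the metabolite itself may sit in an exterior compartment with an exchange
    return metabolite_id in exchanged_exterior


def add_free_diffusion_transport(
    model: MetabolicModel, metabolite_id: str
) -> MetabolicModel:
    """Open a free-diffusion route for a metabolite lacking one.

    Adds a reversible transport reaction (exterior ↔ cytosol) and a reversible
    exchange reaction for the exterior species, both with bounds
    (−1000, 1000), creating the exterior species if needed. If the metabolite
    already has an exchange path the model is returned unchanged.
    """
    if metabolite_id not in {m.id for m in model.metabolites}:
        raise KeyError(f"metabolite {metabolite_id!r} not in model {model.id!r}")
    if has_exchange_path(model, metabolite_id):
        logger.warning(
            "metabolite %s already has an exchange path in model %s; "
            "no transport added", metabolite_id, model.id,
        )
        return model

    new = model.copy()
    met = new.get_metabolite(metabolite_id)
    ext_id = _exterior_counterpart_id(new, met)
    exterior = sorted(new.exterior_compartments)[0]
    if ext_id not in {m.id for m in new.metabolites}:
        new.metabolites.append(
            Metabolite(id=ext_id, name=met.name, compartment=exterior,
                       formula=met.formula)
        )
    transport = Reaction(
        id=f"T_{metabolite_id}_diff",
        name=f"{met.name or metabolite_id} free diffusion",
        stoichiometry={ext_id: -1.0, metabolite_id: 1.0},
        lower_bound=-DEFAULT_UPPER_BOUND,
        upper_bound=DEFAULT_UPPER_BOUND,
    )
    exchange = Reaction(
        id=f"EX_{ext_id}",
        name=f"{met.name or metabolite_id} exchange",
        stoichiometry={ext_id: -1.0},
        lower_bound=-DEFAULT_UPPER_BOUND,
        upper_bound=DEFAULT_UPPER_BOUND,
    )
    new.reactions.extend([transport, exchange])
    new.refresh_exchange_flags()
    return new
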