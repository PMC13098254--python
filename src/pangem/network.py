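"""Compartmentalised stoichiometric metabolic networks with boolean gene rules.

The data model mirrors the COBRA JSON schema: metabolites with compartments,
reactions with bounds and stoichiometry, boolean gene-protein-reaction (GPR)
rules, and a single biomass objective reaction.  The pan-model and every
strain-specific model derived from it share this shape, and files written by
:func:`save_json` are readable by cobrapy.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import GprParseError, ModelError

EXTRACELLULAR = "e"
COMPARTMENTS = {"c": "cytosol", "p": "periplasm", "e": "extracellular space"}

# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRef:
    gene: str

    def evaluate(self, present: frozenset | set) -> bool:
        return self.gene in present

    def genes(self) -> set[str]:
        return {self.gene}

    def to_string(self) -> str:
        return self.gene


@dataclass(frozen=True)
class BoolOp:
    op: str  # "and" | "or"
    children: tuple

    def evaluate(self, present) -> bool:
        if self.op == "and":
            return all(c.evaluate(present) for c in self.children)
        return any(c.evaluate(present) for c in self.children)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if isinstance(c, BoolOp) and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(rule: str):
    """Parse a GPR rule string into an expression tree.

    ``and`` binds tighter than ``or`` (the usual convention); parentheses
    override.  An empty or whitespace-only rule returns ``None``, meaning the
    reaction is retained regardless of gene content.  Malformed rules raise
    :class:`GprParseError` at parse time so evaluation is always total.
    """
    tokens = _TOKEN.findall(rule)
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        return BoolOp("or", tuple(terms))

    def parse_and():
        factors = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_factor())
        if len(factors) == 1:
            return factors[0]
        return BoolOp("and", tuple(factors))

    def parse_factor():
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of GPR rule: {rule!r}")
        if tok == "(":
            take()
            expr = parse_or()
            if peek() != ")":
                raise GprParseError(f"unbalanced parentheses in GPR rule: {rule!r}")
            take()
            return expr
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {tok!r} in GPR rule: {rule!r}")
        return GeneRef(take())

    expr = parse_or()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in GPR rule: {rule!r}")
    return expr


def evaluate_gpr(expr, present) -> bool:
    """Evaluate a parsed GPR over a gene set; ``None`` (empty rule) is True."""
    if expr is None:
        return True
    return expr.evaluate(present if isinstance(present, (set, frozenset)) else set(present))


# ---------------------------------------------------------------------------
# Network containers
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    compartment: str
    name: str = ""


@dataclass
class Reaction:
    id: str
    metabolites: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gene_reaction_rule: str = ""
    subsystem: str = ""
    name: str = ""

    def __post_init__(self):
        self.gpr = parse_gpr(self.gene_reaction_rule)

    def genes(self) -> set[str]:
        return self.gpr.genes() if self.gpr is not None else set()

    def copy(self) -> "Reaction":
        return Reaction(
            self.id,
            dict(self.metabolites),
            self.lower_bound,
            self.upper_bound,
            self.gene_reaction_rule,
            self.subsystem,
            self.name,
        )


@dataclass
class Medium:
    """Always-open exchange reactions with their maximum uptake rates.

    Maps exchange reaction id to the allowed uptake magnitude in
    mmol/h/gCDW; carbon exchanges are excluded (they are toggled one at a
    time by the growth simulation).
    """

    uptakes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for rid, rate in self.uptakes.items():
            if rate < 0:
                raise ModelError(f"medium uptake rate for {rid} must be >= 0, got {rate}")


class MetabolicNetwork:
    """A stoichiometric model: metabolites, bounded reactions, GPRs, objective."""

    def __init__(
        self,
        model_id: str,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        objective: str,
        genes: list[str] | None = None,
    ):
        self.id = model_id
        self.metabolites: dict[str, Metabolite] = {m.id: m for m in metabolites}
        self.reactions: dict[str, Reaction] = {r.id: r for r in reactions}
        self.objective = objective
        inferred = sorted(set().union(*(r.genes() for r in reactions)) if reactions else set())
        self.genes: list[str] = sorted(set(genes) | set(inferred)) if genes else inferred
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if self.objective not in self.reactions:
            raise ModelError(f"objective reaction {self.objective!r} not in model")
        gene_set = set(self.genes)
        for r in self.reactions.values():
            if r.lower_bound > r.upper_bound:
                raise ModelError(f"reaction {r.id}: lower bound {r.lower_bound} > upper bound {r.upper_bound}")
            for mid in r.metabolites:
                if mid not in self.metabolites:
                    raise ModelError(f"reaction {r.id} references unknown metabolite {mid}")
            missing = r.genes() - gene_set
            if missing:
                raise ModelError(f"reaction {r.id} GPR references unknown genes {sorted(missing)}")
            if r.id.startswith("EX_"):
                bad = [m for m in r.metabolites if self.metabolites[m].compartment != EXTRACELLULAR]
                if bad:
                    raise ModelError(f"exchange reaction {r.id} touches non-extracellular metabolites {bad}")

    def is_exchange(self, rid: str) -> bool:
        r = self.reactions[rid]
        if len(r.metabolites) != 1:
            return False
        mid = next(iter(r.metabolites))
        return self.metabolites[mid].compartment == EXTRACELLULAR

    @property
    def exchanges(self) -> list[str]:
        return [rid for rid in self.reactions if self.is_exchange(rid)]

    def copy(self, model_id: str | None = None) -> "MetabolicNetwork":
        return MetabolicNetwork(
            model_id or self.id,
            [Metabolite(m.id, m.compartment, m.name) for m in self.metabolites.values()],
            [r.copy() for r in self.reactions.values()],
            self.objective,
            genes=list(self.genes),
        )

    def restrict_to_genes(self, present: set[str], model_id: str | None = None):
        """Return the sub-network catalysable by ``present`` genes.

        Reactions whose GPR evaluates False are removed (empty-GPR reactions
        are retained), then metabolites no longer touched by any reaction are
        pruned.  Returns ``(network, removed_reaction_ids)``.
        """
        kept, removed = [], []
        for r in self.reactions.values():
            if evaluate_gpr(r.gpr, present):
                kept.append(r.copy())
            else:
                removed.append(r.id)
        used = set()
        for r in kept:
            used |= set(r.metabolites)
        mets = [Metabolite(m.id, m.compartment, m.name) for m in self.metabolites.values() if m.id in used]
        surviving = sorted(set(self.genes) & set(present))
        net = MetabolicNetwork(model_id or self.id, mets, kept, self.objective, genes=surviving)
        return net, removed

    def counts(self) -> dict[str, int]:
        return {
            "genes": len(self.genes),
            "reactions": len(self.reactions),
            "metabolites": len(self.metabolites),
        }

    # -- JSON I/O ----------------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "id": self.id,
            "version": "1",
            "compartments": {c: COMPARTMENTS.get(c, c) for c in sorted({m.compartment for m in self.metabolites.values()})},
            "metabolites": [
                {"id": m.id, "name": m.name or m.id, "compartment": m.compartment}
                for m in self.metabolites.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name or r.id,
                    "metabolites": r.metabolites,
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "gene_reaction_rule": r.gene_reaction_rule,
                    "subsystem": r.subsystem,
                    "objective_coefficient": 1.0 if r.id == self.objective else 0.0,
                }
                for r in self.reactions.values()
            ],
            "genes": [{"id": g, "name": g} for g in self.genes],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "MetabolicNetwork":
        mets = [Metabolite(m["id"], m["compartment"], m.get("name", "")) for m in d["metabolites"]]
        rxns = []
        objective = None
        for r in d["reactions"]:
            rxns.append(
                Reaction(
                    r["id"],
                    {k: float(v) for k, v in r["metabolites"].items()},
                    float(r["lower_bound"]),
                    float(r["upper_bound"]),
                    r.get("gene_reaction_rule", ""),
                    r.get("subsystem", ""),
                    r.get("name", ""),
                )
            )
            if r.get("objective_coefficient"):
                objective = r["id"]
        if objective is None:
            raise ModelError("model JSON declares no objective reaction")
        genes = [g["id"] for g in d.get("genes", [])]
        return cls(d.get("id", "model"), mets, rxns, objective, genes=genes)


def save_json(network: MetabolicNetwork, path: str | Path) -> None:
    Path(path).write_text(json.dumps(network.to_json_dict(), indent=1, sort_keys=False) + "\n")


def load_json(path: str | Path) -> MetabolicNetwork:
    return MetabolicNetwork.from_json_dict(json.loads(Path(path).read_text()))
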