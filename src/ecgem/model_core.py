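"""Core data model for constraint-based metabolic networks.

A :class:`Model` is a plain stoichiometric reconstruction: metabolites,
reactions with flux bounds and gene–protein–reaction (GPR) rules, and a
biomass (or other) objective.  Enzyme-constrained models produced by
:mod:`ecgem.expansion` reuse the same container, tagging the extra species
(enzymes, isozyme pseudo-metabolites) and reactions (arm, enzyme-usage) with
``kind`` labels.

Conventions
-----------
* Fluxes are in mmol/gDW/h; exchange reactions are written as pure drains
  (``met -> ∅``), so uptake is a *negative* flux in a reversible model.  After
  :func:`to_irreversible`, the ``_rev`` copy of an exchange carries uptake as
  a non-negative flux.
* GPR rules use ``and`` for enzyme complexes and ``or`` for isozymes.
* The canonical on-disk format is a JSON dialect that round-trips every field
  (including ``kind`` tags and ``protein_map``); SBML Level 3 + fbc is
  supported for interchange, with ``kind`` tags stored in species/reaction
  annotations.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

__all__ = [
    "MetKind",
    "RxnKind",
    "Metabolite",
    "Reaction",
    "GPRNode",
    "Model",
    "ModelValidationError",
    "GPRParseError",
    "parse_gpr",
    "gpr_to_string",
    "gpr_genes",
    "eval_gpr",
    "to_irreversible",
    "read_sbml",
    "write_model",
    "read_model",
    "sanitize_id",
]

INF = math.inf


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class GPRParseError(ValueError):
    """Raised on malformed gene–protein–reaction expressions."""


class MetKind(str, Enum):
    CHEMICAL = "chemical"
    ENZYME = "enzyme"
    ARM = "arm"


class RxnKind(str, Enum):
    METABOLIC = "metabolic"
    EXCHANGE = "exchange"
    ARM = "arm"
    USAGE = "usage"


# ---------------------------------------------------------------------------
# GPR trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GPRNode:
    """Node of a boolean gene association tree.

    ``op`` is ``"AND"``, ``"OR"`` or ``"LEAF"``; a leaf carries a gene id and
    no children, internal nodes carry at least two children.
    """

    op: str
    children: Tuple["GPRNode", ...] = ()
    gene: str = ""

    def __post_init__(self) -> None:
        if self.op == "LEAF":
            if self.children or not self.gene:
                raise GPRParseError("LEAF node needs a gene and no children")
        elif self.op in ("AND", "OR"):
            if len(self.children) < 2:
                raise GPRParseError(f"{self.op} node needs >=2 children")
        else:
            raise GPRParseError(f"unknown GPR op {self.op!r}")

    @staticmethod
    def leaf(gene: str) -> "GPRNode":
        return GPRNode("LEAF", gene=gene)


_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> GPRNode:
    """Parse a boolean gene association like ``"(g1 and g2) or g3"``.

    ``and`` binds tighter than ``or`` (the usual convention); operators are
    case-insensitive.  Raises :class:`GPRParseError` on empty input or
    unbalanced parentheses.
    """
    tokens = _GPR_TOKEN.findall(text)
    if not tokens:
        raise GPRParseError("empty GPR expression")
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRNode:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GPRNode("OR", tuple(terms))

    def parse_and() -> GPRNode:
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else GPRNode("AND", tuple(factors))

    def parse_atom() -> GPRNode:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR in {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in {text!r}")
        return GPRNode.leaf(take())

    node = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in {text!r}")
    return node


def gpr_to_string(node: Optional[GPRNode]) -> str:
    """Serialize a GPR tree back to its boolean-expression form."""
    if node is None:
        return ""
    if node.op == "LEAF":
        return node.gene
    sep = " and " if node.op == "AND" else " or "
    parts = []
    for child in node.children:
        s = gpr_to_string(child)
        if child.op != "LEAF":
            s = f"({s})"
        parts.append(s)
    return sep.join(parts)


def gpr_genes(node: Optional[GPRNode]) -> List[str]:
    """All gene ids referenced by a GPR tree (sorted, unique)."""
    if node is None:
        return []
    if node.op == "LEAF":
        return [node.gene]
    out: set = set()
    for child in node.children:
        out.update(gpr_genes(child))
    return sorted(out)


def eval_gpr(node: Optional[GPRNode], knocked: Iterable[str]) -> bool:
    """Evaluate a GPR with the given genes deleted (absent GPR -> True)."""
    if node is None:
        return True
    knocked = set(knocked)

    def ev(n: GPRNode) -> bool:
        if n.op == "LEAF":
            return n.gene not in knocked
        if n.op == "AND":
            return all(ev(c) for c in n.children)
        return any(ev(c) for c in n.children)

    return ev(node)


# ---------------------------------------------------------------------------
# Metabolites, reactions, model
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    kind: MetKind = MetKind.CHEMICAL

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelValidationError(f"metabolite {self.id}: empty compartment")
        self.kind = MetKind(self.kind)

    @property
    def display(self) -> str:
        """Bracketed compartment form used in reports, e.g. ``ATP[c]``."""
        base = self.name or self.id
        return f"{base}[{self.compartment}]"


@dataclass
class Reaction:
    id: str
    stoich: Dict[str, float] = field(default_factory=dict)
    lb: float = 0.0
    ub: float = INF
    gpr: Optional[GPRNode] = None
    kind: RxnKind = RxnKind.METABOLIC

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if self.lb > self.ub:
            raise ModelValidationError(f"reaction {self.id}: lb > ub")
        self.kind = RxnKind(self.kind)

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub

    def genes(self) -> List[str]:
        return gpr_genes(self.gpr)


@dataclass
class Model:
    """A stoichiometric metabolic model.

    ``protein_map`` maps gene id -> protein id (UniProt-style), used by the
    enzyme expansion to resolve GPR leaves to enzyme species.
    """

    id: str = "model"
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    genes: List[str] = field(default_factory=list)
    objective: str = ""
    protein_map: Dict[str, str] = field(default_factory=dict)

    # -- lookups -----------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        try:
            return self._met_index[mid]
        except (AttributeError, KeyError):
            self._reindex()
            return self._met_index[mid]

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._rxn_index[rid]
        except (AttributeError, KeyError):
            self._reindex()
            return self._rxn_index[rid]

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    def _reindex(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise :class:`ModelValidationError`."""
        if not self.reactions:
            raise ModelValidationError("model has no reactions")
        mids = [m.id for m in self.metabolites]
        if len(set(mids)) != len(mids):
            dup = sorted({m for m in mids if mids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({r for r in rids if rids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        met_set = set(mids)
        for r in self.reactions:
            if r.kind in (RxnKind.METABOLIC, RxnKind.ARM) and not r.stoich:
                raise ModelValidationError(f"reaction {r.id}: empty stoichiometry")
            for mid in r.stoich:
                if mid not in met_set:
                    raise ModelValidationError(
                        f"reaction {r.id} references unknown metabolite {mid}"
                    )
        if self.objective and self.objective not in set(rids):
            raise ModelValidationError(
                f"objective {self.objective!r} is not a reaction id"
            )

    def copy(self) -> "Model":
        return Model(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[
                Reaction(r.id, dict(r.stoich), r.lb, r.ub, r.gpr, r.kind)
                for r in self.reactions
            ],
            genes=list(self.genes),
            objective=self.objective,
            protein_map=dict(self.protein_map),
        )

    def stoichiometric_matrix(self):
        """Sparse S (rows = metabolites, cols = reactions) plus index maps."""
        from scipy import sparse

        met_pos = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoich.items():
                rows.append(met_pos[mid])
                cols.append(j)
                vals.append(float(coef))
        S = sparse.coo_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        ).tocsc()
        return S, met_pos, {r.id: j for j, r in enumerate(self.reactions)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Model):
            return NotImplemented
        def met_key(m: Metabolite):
            return (m.id, m.name, m.compartment, m.kind)
        def rxn_key(r: Reaction):
            return (r.id, tuple(sorted(r.stoich.items())), r.lb, r.ub,
                    gpr_to_string(r.gpr), r.kind)
        return (
            [met_key(m) for m in self.metabolites]
            == [met_key(m) for m in other.metabolites]
            and [rxn_key(r) for r in self.reactions]
            == [rxn_key(r) for r in other.reactions]
            and sorted(self.genes) == sorted(other.genes)
            and self.objective == other.objective
            and self.protein_map == other.protein_map
        )


# ---------------------------------------------------------------------------
# Irreversible conversion
# ---------------------------------------------------------------------------


def to_irreversible(model: Model) -> Tuple[Model, Dict[str, str]]:
    """Split reversible reactions into forward/backward non-negative copies.

    A reaction with ``lb < 0 < ub`` becomes ``<id>_fwd`` (original
    stoichiometry, bounds ``[0, ub]``) and ``<id>_rev`` (negated
    stoichiometry, bounds ``[0, -lb]``).  A purely backward reaction
    (``ub <= 0``) is negated and renamed ``<id>_rev``.  Forward-only
    reactions are kept as is.

    Returns the converted model and a ``parent_map`` from every reaction id
    in the new model to its id in the input model, used later to pair flux
    variability between base and enzyme-constrained models.
    """
    model.validate()
    existing = {r.id for r in model.reactions}
    out: List[Reaction] = []
    parent: Dict[str, str] = {}

    def emit(rxn: Reaction, base: str) -> None:
        if rxn.id != base and rxn.id in existing:
            raise ModelValidationError(
                f"id collision: {rxn.id} already exists after splitting {base}"
            )
        out.append(rxn)
        parent[rxn.id] = base

    for r in model.reactions:
        if r.reversible:
            emit(Reaction(r.id + "_fwd", dict(r.stoich), 0.0, r.ub, r.gpr, r.kind), r.id)
            neg = {m: -c for m, c in r.stoich.items()}
            emit(Reaction(r.id + "_rev", neg, 0.0, -r.lb, r.gpr, r.kind), r.id)
        elif r.ub <= 0:
            neg = {m: -c for m, c in r.stoich.items()}
            emit(Reaction(r.id + "_rev", neg, -r.ub, -r.lb, r.gpr, r.kind), r.id)
        else:
            emit(Reaction(r.id, dict(r.stoich), max(r.lb, 0.0), r.ub, r.gpr, r.kind), r.id)

    objective = model.objective
    if objective and objective not in parent:
        # objective reaction was renamed: point at its forward copy
        if objective + "_fwd" in parent:
            objective = objective + "_fwd"
        elif objective + "_rev" in parent:
            objective = objective + "_rev"

    irr = Model(
        id=model.id + "_irrev",
        metabolites=[replace(m) for m in model.metabolites],
        reactions=out,
        genes=list(model.genes),
        objective=objective or model.objective,
        protein_map=dict(model.protein_map),
    )
    irr.validate()
    return irr, parent


# ---------------------------------------------------------------------------
# JSON dialect (canonical archive format)
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def _num(x: float):
    if x == INF:
        return "inf"
    if x == -INF:
        return "-inf"
    return x


def _denum(x) -> float:
    if x == "inf":
        return INF
    if x == "-inf":
        return -INF
    return float(x)


def model_to_dict(model: Model) -> dict:
    return {
        "schema": _SCHEMA_VERSION,
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             "kind": m.kind.value}
            for m in model.metabolites
        ],
        "reactions": [
            {"id": r.id, "stoich": {k: v for k, v in r.stoich.items()},
             "lb": _num(r.lb), "ub": _num(r.ub),
             "gpr": gpr_to_string(r.gpr) or None, "kind": r.kind.value}
            for r in model.reactions
        ],
        "genes": list(model.genes),
        "objective": model.objective,
        "protein_map": dict(model.protein_map),
    }


def model_from_dict(data: Mapping) -> Model:
    mets = [
        Metabolite(d["id"], d.get("name", ""), d.get("compartment", "c"),
                   MetKind(d.get("kind", "chemical")))
        for d in data["metabolites"]
    ]
    rxns = [
        Reaction(
            d["id"], {k: float(v) for k, v in d["stoich"].items()},
            _denum(d["lb"]), _denum(d["ub"]),
            parse_gpr(d["gpr"]) if d.get("gpr") else None,
            RxnKind(d.get("kind", "metabolic")),
        )
        for d in data["reactions"]
    ]
    return Model(
        id=data.get("id", "model"),
        metabolites=mets,
        reactions=rxns,
        genes=list(data.get("genes", [])),
        objective=data.get("objective", ""),
        protein_map=dict(data.get("protein_map", {})),
    )


def write_model(model: Model, path: str, format: str = "json") -> None:
    """Write a model to ``path`` as JSON (lossless) or SBML L3+fbc."""
    model.validate()
    if format == "json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
    elif format == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


def read_model(path: str) -> Model:
    """Read a model written by :func:`write_model` (sniffs JSON vs SBML)."""
    with open(path, "rb") as fh:
        head = fh.read(64).lstrip()
    if head.startswith(b"{"):
        with open(path) as fh:
            model = model_from_dict(json.load(fh))
        model.validate()
        return model
    return read_sbml(path)


# ---------------------------------------------------------------------------
# SBML Level 3 + fbc
# ---------------------------------------------------------------------------

_SANITIZE = re.compile(r"[^A-Za-z0-9_]")


def sanitize_id(raw: str) -> str:
    """Deterministically map an id to SBML SId form (non-alnum -> ``_``)."""
    sid = _SANITIZE.sub("_", raw)
    if not sid or sid[0].isdigit():
        sid = "_" + sid
    return sid


def _write_sbml(model: Model, path: str) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(sanitize_id(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites})
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(sanitize_id(comp))
        c.setConstant(True)

    translation: Dict[str, str] = {}

    def sid(raw: str, prefix: str) -> str:
        key = prefix + raw
        if key not in translation:
            translation[key] = prefix + sanitize_id(raw)
        return translation[key]

    for m in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(sid(m.id, "M_"))
        sp.setName(m.name or m.id)
        sp.setCompartment(sanitize_id(m.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp.appendAnnotation(
            f'<ecgem xmlns="https://ecgem.invalid/ns" kind="{m.kind.value}" '
            f'original_id="{m.id}"/>'
        )

    for gene in sorted(set(model.genes) | {g for r in model.reactions for g in r.genes()}):
        gp = mplug.createGeneProduct()
        gp.setId(sid(gene, "G_"))
        gp.setLabel(gene)

    def bound_param(value: float, tag: str) -> str:
        pid = sanitize_id(f"bnd_{tag}")
        if sbml_model.getParameter(pid) is None:
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setConstant(True)
            p.setValue(value if math.isfinite(value) else math.copysign(1e30, value))
        return pid

    for i, r in enumerate(model.reactions):
        rx = sbml_model.createReaction()
        rx.setId(sid(r.id, "R_"))
        rx.setName(r.id)
        rx.setFast(False)
        rx.setReversible(r.lb < 0)
        for mid, coef in sorted(r.stoich.items()):
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(sid(mid, "M_"))
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lb, f"lb_{i}"))
        rplug.setUpperFluxBound(bound_param(r.ub, f"ub_{i}"))
        if r.gpr is not None:
            gpa = rplug.createGeneProductAssociation()
            # resolve gene names against the pre-created GeneProduct labels
            gpa.setAssociation(gpr_to_string(r.gpr), False, False)
        rx.appendAnnotation(
            f'<ecgem xmlns="https://ecgem.invalid/ns" kind="{r.kind.value}" '
            f'original_id="{r.id}"/>'
        )

    if model.objective:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction(sid(model.objective, "R_"))
        fo.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise IOError(f"could not write SBML to {path}")


_ANNOT_KIND = re.compile(r'kind="([a-z]+)"')
_ANNOT_ORIG = re.compile(r'original_id="([^"]+)"')


def _annot_fields(node) -> Tuple[Optional[str], Optional[str]]:
    annot = node.getAnnotationString() if node.isSetAnnotation() else ""
    kind = _ANNOT_KIND.search(annot)
    orig = _ANNOT_ORIG.search(annot)
    return (kind.group(1) if kind else None, orig.group(1) if orig else None)


def read_sbml(path: str) -> Model:
    """Read an SBML Level 3 document with the fbc package into a Model.

    Flux bounds and the active objective are required; GPR associations are
    parsed into :class:`GPRNode` trees.  Raises on malformed XML (naming the
    offending element) and on missing bounds/objective.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelValidationError(
            f"SBML parse error in {path}: {err.getMessage().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelValidationError(f"SBML parse error: no <model> element in {path}")
    mplug = sbml_model.getPlugin("fbc")

    def strip_prefix(s: str, prefix: str) -> str:
        return s[len(prefix):] if s.startswith(prefix) else s

    mets = []
    for sp in sbml_model.getListOfSpecies():
        kind, orig = _annot_fields(sp)
        mid = orig or strip_prefix(sp.getId(), "M_")
        mets.append(Metabolite(
            mid, sp.getName() or mid, sp.getCompartment() or "c",
            MetKind(kind) if kind else MetKind.CHEMICAL,
        ))

    gene_label = {}
    if mplug is not None:
        for gp in mplug.getListOfGeneProducts():
            gene_label[gp.getId()] = gp.getLabel() or strip_prefix(gp.getId(), "G_")

    def param_value(pid: str, rid: str, which: str) -> float:
        p = sbml_model.getParameter(pid) if pid else None
        if p is None or not p.isSetValue():
            raise ModelValidationError(
                f"reaction {rid}: no flux bounds ({which} missing)"
            )
        v = p.getValue()
        if abs(v) >= 1e30:
            v = math.copysign(INF, v)
        return v

    def assoc_to_gpr(assoc) -> Optional[GPRNode]:
        import libsbml as _ls

        if assoc is None:
            return None
        if isinstance(assoc, _ls.GeneProductRef):
            gid = assoc.getGeneProduct()
            return GPRNode.leaf(gene_label.get(gid, strip_prefix(gid, "G_")))
        children = [assoc_to_gpr(assoc.getAssociation(i))
                    for i in range(assoc.getNumAssociations())]
        children = [c for c in children if c is not None]
        if not children:
            return None
        if len(children) == 1:
            return children[0]
        op = "AND" if isinstance(assoc, _ls.FbcAnd) else "OR"
        return GPRNode(op, tuple(children))

    rxns = []
    for rx in sbml_model.getListOfReactions():
        kind, orig = _annot_fields(rx)
        rid = orig or strip_prefix(rx.getId(), "R_")
        stoich: Dict[str, float] = {}
        for ref in rx.getListOfReactants():
            _, sorig = _annot_fields(sbml_model.getSpecies(ref.getSpecies()))
            mid = sorig or strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for ref in rx.getListOfProducts():
            _, sorig = _annot_fields(sbml_model.getSpecies(ref.getSpecies()))
            mid = sorig or strip_prefix(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        if rplug is None:
            raise ModelValidationError(f"reaction {rid}: no flux bounds (fbc missing)")
        lb = param_value(rplug.getLowerFluxBound(), rid, "lower")
        ub = param_value(rplug.getUpperFluxBound(), rid, "upper")
        gpr = None
        if rplug.isSetGeneProductAssociation():
            gpr = assoc_to_gpr(rplug.getGeneProductAssociation().getAssociation())
        rxns.append(Reaction(rid, stoich, lb, ub, gpr,
                             RxnKind(kind) if kind else RxnKind.METABOLIC))

    objective = ""
    if mplug is not None and mplug.getActiveObjective() is not None:
        ao = mplug.getActiveObjective()
        if ao.getNumFluxObjectives() > 0:
            fid = ao.getFluxObjective(0).getReaction()
            target = sbml_model.getReaction(fid)
            _, orig = _annot_fields(target) if target else (None, None)
            objective = orig or strip_prefix(fid, "R_")
    if not objective:
        raise ModelValidationError(f"SBML model in {path} declares no objective")

    genes = sorted(gene_label.values()) or sorted(
        {g for r in rxns for g in r.genes()}
    )
    model = Model(
        id=sbml_model.getId() or "model",
        metabolites=mets, reactions=rxns, genes=genes, objective=objective,
    )
    model.validate()
    return model
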