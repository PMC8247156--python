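"""GECKO-style expansion of a metabolic model with enzyme constraints.

Starting from an *irreversible* model, every reaction whose GPR resolves to
kinetically characterised proteins is rewritten so that the enzyme appears
as a consumed pseudo-species with stoichiometric coefficient 1/kcat:

    A + (1/kcat) enzyme -> B

Each enzyme species is supplied by a dedicated *usage* exchange reaction
whose upper bound is the measured enzyme abundance (mmol/gDW), so any flux
``v`` through the reaction obeys ``v <= kcat * [E]`` by mass balance of the
enzyme species.  Isozyme-catalysed reactions (OR branches in the GPR) are
split through an *arm* pseudo-metabolite: substrates feed the arm species
via one arm reaction, and one branch reaction per isozyme consumes the arm
species together with that isozyme, so each branch carries its own enzyme
cost.  AND branches (complexes) put every subunit on the same reaction; a
multifunctional protein keeps a single enzyme species and usage reaction
shared across all reactions it catalyses, which couples them through the
common abundance bound.

Reactions without a GPR, or whose enzymes lack kinetic evidence, are left
untouched (their constraints are removed rather than imputed).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

from .kinetics import AbundanceTable, KineticTable
from .model_core import (
    GPRNode,
    Metabolite,
    MetKind,
    Model,
    ModelValidationError,
    Reaction,
    RxnKind,
    model_from_dict,
    model_to_dict,
)

__all__ = [
    "ProteinEntry",
    "ECModel",
    "expand",
    "set_usage_bound",
    "add_protein_pool",
    "gpr_branches",
    "write_ecmodel",
    "read_ecmodel",
    "ARM_MET_PREFIX",
    "ARM_RXN_PREFIX",
    "ENZYME_MET_PREFIX",
    "USAGE_RXN_PREFIX",
    "POOL_MET",
    "POOL_RXN",
]

INF = math.inf

ARM_MET_PREFIX = "pmet_"
ARM_RXN_PREFIX = "arm_"
ENZYME_MET_PREFIX = "prot_"
USAGE_RXN_PREFIX = "usage_"
POOL_MET = "prot_pool"
POOL_RXN = "prot_pool_exchange"


@dataclass
class ProteinEntry:
    """Registry entry for one enzyme integrated into the model."""

    protein: str
    genes: List[str] = field(default_factory=list)
    mw: Optional[float] = None  # g/mol
    kcat_by_reaction: Dict[str, float] = field(default_factory=dict)  # 1/h
    abundance_bound: float = INF  # mmol/gDW
    abundance_source: str = ""  # taxon/rank provenance

    def __post_init__(self) -> None:
        if self.abundance_bound < 0:
            raise ValueError(f"{self.protein}: abundance bound must be >= 0")
        for rid, k in self.kcat_by_reaction.items():
            if k <= 0:
                raise ValueError(f"{self.protein}/{rid}: kcat must be > 0")


@dataclass
class ECModel:
    """An enzyme-constrained model plus its protein registry.

    ``parent_map`` maps every reaction id of the expanded model to the id of
    the base reaction it descends from (identity for untouched reactions;
    arm/branch reactions map to the reaction they replaced; usage reactions
    are absent from the map).
    """

    model: Model
    proteins: Dict[str, ProteinEntry] = field(default_factory=dict)
    arm_metabolites: List[str] = field(default_factory=list)
    usage_reactions: Dict[str, str] = field(default_factory=dict)
    parent_map: Dict[str, str] = field(default_factory=dict)
    report: List[dict] = field(default_factory=list)

    def copy(self) -> "ECModel":
        return ECModel(
            model=self.model.copy(),
            proteins={
                p: ProteinEntry(e.protein, list(e.genes), e.mw,
                                dict(e.kcat_by_reaction), e.abundance_bound,
                                e.abundance_source)
                for p, e in self.proteins.items()
            },
            arm_metabolites=list(self.arm_metabolites),
            usage_reactions=dict(self.usage_reactions),
            parent_map=dict(self.parent_map),
            report=[dict(r) for r in self.report],
        )


# ---------------------------------------------------------------------------
# GPR -> isozyme branches
# ---------------------------------------------------------------------------


def gpr_branches(gpr: Optional[GPRNode]) -> List[FrozenSet[str]]:
    """Flatten a GPR tree into its OR-branches as sets of required genes.

    Each branch is the gene set of one isozyme (a complex contributes all of
    its subunits to the branch).  Equivalent to disjunctive normal form;
    duplicate branches are merged, order is deterministic.
    """
    if gpr is None:
        return []

    def dnf(node: GPRNode) -> List[FrozenSet[str]]:
        if node.op == "LEAF":
            return [frozenset([node.gene])]
        if node.op == "OR":
            out: List[FrozenSet[str]] = []
            for child in node.children:
                out.extend(dnf(child))
            return out
        # AND: cross product of the children's branch lists
        combos = [frozenset().union(*parts)
                  for parts in product(*(dnf(c) for c in node.children))]
        return combos

    seen = set()
    branches = []
    for b in dnf(gpr):
        if b not in seen:
            seen.add(b)
            branches.append(b)
    return sorted(branches, key=lambda b: sorted(b))


# ---------------------------------------------------------------------------
# Expansion
# ---------------------------------------------------------------------------


def _resolve_kcat(
    kinetics: KineticTable, protein: str, rid: str, base_rid: Optional[str]
) -> Optional[float]:
    sel = kinetics.lookup(protein, rid)
    if sel is None and base_rid and base_rid != rid:
        sel = kinetics.lookup(protein, base_rid)
    return sel.kcat if sel is not None else None


def expand(
    model: Model,
    kinetics: KineticTable,
    abundances: Optional[AbundanceTable] = None,
    parent_map: Optional[Mapping[str, str]] = None,
) -> ECModel:
    """Expand an irreversible model into an enzyme-constrained model.

    Parameters
    ----------
    model
        Fully irreversible model (every lb >= 0).
    kinetics
        kcat evidence; a protein/reaction pair without evidence leaves the
        affected branch (and, if no branch remains characterised, the whole
        reaction) unconstrained.
    abundances
        Abundance evidence; proteins without a match get an unbounded usage
        reaction.  ``None`` leaves every usage unbounded.
    parent_map
        Mapping from ``model``'s reaction ids to the pre-split base model's
        ids (as returned by :func:`ecgem.model_core.to_irreversible`); used
        as a kcat-lookup fallback so direction-agnostic evidence applies to
        both split copies.

    A reaction is expanded only when *every* distinct GPR branch has complete
    kinetic evidence; partially characterised reactions are recorded in the
    build report and left unmodified, mirroring the policy of removing
    constraints instead of imputing kinetics.
    """
    for r in model.reactions:
        if r.lb < 0:
            raise ModelValidationError(
                f"expand() needs an irreversible model; {r.id} has lb={r.lb}"
            )
    ec_model = model.copy()
    ec_model.id = model.id + "_ec" if not model.id.endswith("_ec") else model.id
    proteins: Dict[str, ProteinEntry] = {}
    arm_mets: List[str] = []
    usage: Dict[str, str] = {}
    # parent_map of the ECModel stays at the irreversible model's level
    # (arm/branch -> replaced reaction); the supplied pre-split parent_map is
    # only a kcat-lookup fallback for direction-agnostic evidence.
    pmap: Dict[str, str] = {r.id: r.id for r in model.reactions}
    presplit = dict(parent_map or {})
    report: List[dict] = []

    def protein_of(gene: str) -> str:
        return model.protein_map.get(gene, gene)

    def entry(protein: str, genes: Sequence[str]) -> ProteinEntry:
        if protein not in proteins:
            proteins[protein] = ProteinEntry(protein, sorted(genes),
                                             mw=kinetics.mw(protein))
        else:
            proteins[protein].genes = sorted(
                set(proteins[protein].genes) | set(genes)
            )
        return proteins[protein]

    new_reactions: List[Reaction] = []
    new_metabolites: List[Metabolite] = list(ec_model.metabolites)

    for rxn in ec_model.reactions:
        base_rid = presplit.get(rxn.id, rxn.id)
        branches = gpr_branches(rxn.gpr)
        if not branches or rxn.kind in (RxnKind.EXCHANGE, RxnKind.USAGE):
            new_reactions.append(rxn)
            continue

        # one (proteins, {protein: kcat}) per branch; None marks a gap
        matched: List[Optional[Tuple[FrozenSet[str], Dict[str, float]]]] = []
        for branch in branches:
            prots = frozenset(protein_of(g) for g in branch)
            kcats: Dict[str, float] = {}
            ok = True
            for p in sorted(prots):
                k = _resolve_kcat(kinetics, p, rxn.id, base_rid)
                if k is None:
                    ok = False
                    break
                kcats[p] = k
            matched.append((prots, kcats) if ok else None)

        n_gaps = sum(m is None for m in matched)
        if n_gaps:
            report.append({
                "reaction": rxn.id, "status": "unconstrained",
                "reason": f"{n_gaps}/{len(branches)} branches lack kcat evidence",
                "proteins": "", "kcats": "",
            })
            new_reactions.append(rxn)
            continue

        # deduplicate branches that resolve to the same protein set
        uniq: List[Tuple[FrozenSet[str], Dict[str, float]]] = []
        seen_prots = set()
        for m in matched:
            if m[0] not in seen_prots:
                seen_prots.add(m[0])
                uniq.append(m)

        gene_by_protein: Dict[str, set] = {}
        for branch in branches:
            for g in branch:
                gene_by_protein.setdefault(protein_of(g), set()).add(g)

        def note(status: str) -> None:
            report.append({
                "reaction": rxn.id, "status": status,
                "reason": "",
                "proteins": ";".join(sorted(p for b, _ in uniq for p in b)),
                "kcats": ";".join(
                    f"{p}={k:g}" for b, ks in uniq for p, k in sorted(ks.items())
                ),
            })

        if len(uniq) == 1:
            prots, kcats = uniq[0]
            stoich = dict(rxn.stoich)
            for p in sorted(prots):
                e = entry(p, gene_by_protein[p])
                e.kcat_by_reaction[rxn.id] = kcats[p]
                emet = ENZYME_MET_PREFIX + p
                stoich[emet] = stoich.get(emet, 0.0) - 1.0 / kcats[p]
            new_reactions.append(
                Reaction(rxn.id, stoich, rxn.lb, rxn.ub, rxn.gpr, rxn.kind)
            )
            note("single")
        else:
            # isozymes: arm reaction + one branch reaction per protein set
            arm_met = ARM_MET_PREFIX + rxn.id
            arm_mets.append(arm_met)
            new_metabolites.append(
                Metabolite(arm_met, arm_met, _arm_compartment(ec_model, rxn),
                           MetKind.ARM)
            )
            substrates = {m: c for m, c in rxn.stoich.items() if c < 0}
            products = {m: c for m, c in rxn.stoich.items() if c > 0}
            arm_stoich = dict(substrates)
            arm_stoich[arm_met] = 1.0
            arm_rid = ARM_RXN_PREFIX + rxn.id
            new_reactions.append(
                Reaction(arm_rid, arm_stoich, 0.0, rxn.ub, rxn.gpr, RxnKind.ARM)
            )
            pmap[arm_rid] = rxn.id
            for i, (prots, kcats) in enumerate(uniq, start=1):
                stoich = dict(products)
                stoich[arm_met] = -1.0
                for p in sorted(prots):
                    e = entry(p, gene_by_protein[p])
                    emet = ENZYME_MET_PREFIX + p
                    stoich[emet] = stoich.get(emet, 0.0) - 1.0 / kcats[p]
                branch_rid = f"{rxn.id}_iso{i}"
                branch_gpr = _branch_gpr(prots, gene_by_protein)
                new_reactions.append(
                    Reaction(branch_rid, stoich, 0.0, rxn.ub, branch_gpr,
                             rxn.kind)
                )
                pmap[branch_rid] = rxn.id
                for p, k in kcats.items():
                    proteins[p].kcat_by_reaction[branch_rid] = k
            del pmap[rxn.id]
            note(f"isozymes({len(uniq)})")

    # enzyme species + usage reactions
    for p in sorted(proteins):
        e = proteins[p]
        emet = ENZYME_MET_PREFIX + p
        new_metabolites.append(Metabolite(emet, p, "c", MetKind.ENZYME))
        if abundances is not None:
            rec = abundances.lookup(p)
            if rec is not None:
                e.abundance_bound = rec.abundance
                e.abundance_source = f"{rec.taxon or 'target'}:{rec.rank}"
            else:
                e.abundance_bound = INF
                e.abundance_source = "unmatched"
        urid = USAGE_RXN_PREFIX + p
        usage[p] = urid
        new_reactions.append(
            Reaction(urid, {emet: 1.0}, 0.0, e.abundance_bound, None,
                     RxnKind.USAGE)
        )

    ec_model.metabolites = new_metabolites
    ec_model.reactions = new_reactions
    ec_model.validate()
    ec = ECModel(ec_model, proteins, arm_mets, usage, pmap, report)
    return ec


def _arm_compartment(model: Model, rxn: Reaction) -> str:
    comps = sorted({model.metabolite(m).compartment for m in rxn.stoich})
    return comps[0] if comps else "c"


def _branch_gpr(
    prots: FrozenSet[str], gene_by_protein: Mapping[str, set]
) -> Optional[GPRNode]:
    genes = sorted(g for p in prots for g in gene_by_protein.get(p, ()))
    if not genes:
        return None
    if len(genes) == 1:
        return GPRNode.leaf(genes[0])
    return GPRNode("AND", tuple(GPRNode.leaf(g) for g in genes))


# ---------------------------------------------------------------------------
# Bound edits
# ---------------------------------------------------------------------------


def set_usage_bound(ecmodel: ECModel, protein: str, bound: float) -> ECModel:
    """Return a copy with one protein's usage upper bound replaced."""
    if protein not in ecmodel.usage_reactions:
        raise KeyError(f"protein {protein!r} has no usage reaction")
    if bound < 0:
        raise ValueError(f"usage bound must be >= 0, got {bound}")
    out = ecmodel.copy()
    out.model.reaction(out.usage_reactions[protein]).ub = bound
    out.proteins[protein].abundance_bound = bound
    return out


def add_protein_pool(
    ecmodel: ECModel, ptot: float, sigma: float = 1.0
) -> ECModel:
    """Couple all enzymes through a shared protein pool.

    Adds a pool species drawn by every usage reaction at MW/1000 g/mmol and
    supplied by one pool exchange bounded at ``sigma * ptot`` g protein/gDW,
    enforcing ``sum_p MW_p * usage_p <= sigma * ptot`` (mass units).
    Proteins with unknown MW are excluded with a warning.  Disabled by
    default in the pipeline: per-protein abundance bounds are the primary
    constraint and the pool is an optional global cap.
    """
    if ptot < 0 or sigma < 0:
        raise ValueError("ptot and sigma must be >= 0")
    out = ecmodel.copy()
    m = out.model
    if any(met.id == POOL_MET for met in m.metabolites):
        raise ValueError("model already has a protein pool")
    m.metabolites.append(Metabolite(POOL_MET, "protein pool", "c", MetKind.ENZYME))
    pooled = 0
    for p, urid in sorted(out.usage_reactions.items()):
        e = out.proteins[p]
        if e.mw is None:
            warnings.warn(f"protein {p} has no MW; excluded from pool",
                          stacklevel=2)
            continue
        rxn = m.reaction(urid)
        rxn.stoich[POOL_MET] = -e.mw / 1000.0  # g pool per mmol enzyme
        pooled += 1
    m.reactions.append(
        Reaction(POOL_RXN, {POOL_MET: 1.0}, 0.0, sigma * ptot, None,
                 RxnKind.USAGE)
    )
    m.validate()
    out.report.append({
        "reaction": POOL_RXN, "status": "pool",
        "reason": f"{pooled} proteins pooled, cap {sigma * ptot:g} g/gDW",
        "proteins": "", "kcats": "",
    })
    return out


# ---------------------------------------------------------------------------
# Archive I/O
# ---------------------------------------------------------------------------


def ecmodel_to_dict(ec: ECModel) -> dict:
    def num(x):
        return "inf" if x == INF else x

    return {
        "model": model_to_dict(ec.model),
        "proteins": [
            {"protein": e.protein, "genes": e.genes, "mw": e.mw,
             "kcat_by_reaction": e.kcat_by_reaction,
             "abundance_bound": num(e.abundance_bound),
             "abundance_source": e.abundance_source}
            for e in (ec.proteins[p] for p in sorted(ec.proteins))
        ],
        "arm_metabolites": list(ec.arm_metabolites),
        "usage_reactions": dict(ec.usage_reactions),
        "parent_map": dict(ec.parent_map),
        "report": list(ec.report),
    }


def ecmodel_from_dict(data: Mapping) -> ECModel:
    def denum(x):
        return INF if x == "inf" else float(x)

    proteins = {
        d["protein"]: ProteinEntry(
            d["protein"], list(d.get("genes", [])), d.get("mw"),
            {k: float(v) for k, v in d.get("kcat_by_reaction", {}).items()},
            denum(d.get("abundance_bound", "inf")),
            d.get("abundance_source", ""),
        )
        for d in data["proteins"]
    }
    return ECModel(
        model=model_from_dict(data["model"]),
        proteins=proteins,
        arm_metabolites=list(data.get("arm_metabolites", [])),
        usage_reactions=dict(data.get("usage_reactions", {})),
        parent_map=dict(data.get("parent_map", {})),
        report=list(data.get("report", [])),
    )


def write_ecmodel(ec: ECModel, path: str) -> None:
    ec.model.validate()
    with open(path, "w") as fh:
        json.dump(ecmodel_to_dict(ec), fh, indent=1)
        fh.write("\n")


def read_ecmodel(path: str) -> ECModel:
    with open(path) as fh:
        ec = ecmodel_from_dict(json.load(fh))
    ec.model.validate()
    return ec
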