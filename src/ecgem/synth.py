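"""Toy metabolic models with analytically known optima.

The generator builds small, stoichiometrically consistent chain models —
substrate exchange, a linear conversion chain, a biomass drain — decorated
with the enzymatic patterns the expansion has to handle: isozyme steps (OR
rules), complex steps (AND rules), reversible steps and a multifunctional
enzyme shared by two steps.  Topology is a deterministic function of the
requested counts; randomness (seeded) is confined to kcat and abundance
draws and to which steps are reversible, so the max-growth optimum stays
hand-derivable:

    mu* = min( uptake bound,
               min over independent steps of their capacity,
               E / (1/kcat_a + 1/kcat_b) for the multifunctional pair )

where a plain step's capacity is ``kcat*E``, an isozyme step's the *sum* of
its branches' ``kcat_i*E_i``, and a complex step's ``min_i kcat_i*E_i`` over
its subunits.  Units match the pipeline throughout: kcat 1/h, abundance
mmol/gDW, fluxes mmol/gDW/h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .expansion import ECModel, expand
from .kinetics import AbundanceRecord, AbundanceTable, KcatRecord, KineticTable
from .model_core import (
    Metabolite,
    Model,
    Reaction,
    RxnKind,
    parse_gpr,
    to_irreversible,
)
from .simulation import ConditionSpec

__all__ = [
    "ToySpec",
    "make_toy",
    "make_overconstrained",
    "make_carbon_switch_toy",
    "build_ec_toy",
]

INF = math.inf


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a toy model (see module docstring for the optimum)."""

    n_linear_steps: int = 4
    isozyme_reactions: int = 1
    complex_reactions: int = 1
    reversible_fraction: float = 0.25
    multifunctional_pair: bool = False
    kcat_range: Tuple[float, float] = (50.0, 200.0)  # 1/h
    abundance_range: Tuple[float, float] = (0.005, 0.05)  # mmol/gDW
    uptake: float = 10.0  # mmol/gDW/h
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_linear_steps < 1:
            raise ValueError("toy needs at least one chain step")
        if self.isozyme_reactions + self.complex_reactions > self.n_linear_steps:
            raise ValueError("more special steps than chain steps")
        if self.multifunctional_pair and (
            self.n_linear_steps - self.isozyme_reactions - self.complex_reactions < 2
        ):
            raise ValueError("multifunctional pair needs two plain steps")
        for rng_ in (self.kcat_range, self.abundance_range):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"invalid positive range {rng_}")
        if not (0.0 <= self.reversible_fraction <= 1.0):
            raise ValueError("reversible_fraction must be in [0, 1]")


def make_toy(spec: ToySpec) -> Tuple[Model, KineticTable, AbundanceTable, dict]:
    """Generate (model, kcat table, abundance table, analytic answers).

    The model is reversible-form (exchange with negative lower bound); run
    :func:`ecgem.model_core.to_irreversible` before expansion.  Analytic
    answers record the max-growth optimum with (``optimum_constrained``) and
    without (``optimum_unconstrained``) enzyme caps, plus each step's
    capacity.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_linear_steps

    mets = [Metabolite(f"M{i}", f"M{i}", "c") for i in range(n + 1)]
    reactions: List[Reaction] = [
        Reaction("EX_S", {"M0": -1.0}, -spec.uptake, 1000.0, None,
                 RxnKind.EXCHANGE)
    ]

    # step roles, deterministic: isozyme steps first, then complexes, then plain
    roles = (["isozyme"] * spec.isozyme_reactions
             + ["complex"] * spec.complex_reactions
             + ["plain"] * (n - spec.isozyme_reactions - spec.complex_reactions))
    plain_idx = [i for i, r in enumerate(roles) if r == "plain"]
    shared_steps = set(plain_idx[-2:]) if spec.multifunctional_pair else set()

    reversible = rng.random(n) < spec.reversible_fraction

    def draw_kcat() -> float:
        return float(rng.uniform(*spec.kcat_range))

    def draw_abundance() -> float:
        return float(rng.uniform(*spec.abundance_range))

    kcat_records: List[KcatRecord] = []
    ab_records: List[AbundanceRecord] = []
    protein_map: Dict[str, str] = {}
    genes: List[str] = []
    capacities: Dict[str, float] = {}
    shared_terms: List[float] = []  # 1/kcat of the multifunctional pair
    shared_abundance: Optional[float] = None
    mw_default = 50000.0  # g/mol, a typical enzyme

    def register(gene: str, protein: str) -> None:
        genes.append(gene)
        protein_map[gene] = protein

    def add_kcat(protein: str, rid: str, step: int) -> float:
        """Record kcat(s); reversible steps get distinct fwd/rev values."""
        k_fwd = draw_kcat()
        if reversible[step]:
            kcat_records.append(KcatRecord(protein, rid + "_fwd", kcat=k_fwd,
                                           mw=mw_default, source="toy"))
            kcat_records.append(KcatRecord(protein, rid + "_rev",
                                           kcat=draw_kcat(), mw=mw_default,
                                           source="toy"))
        else:
            kcat_records.append(KcatRecord(protein, rid, kcat=k_fwd,
                                           mw=mw_default, source="toy"))
        return k_fwd

    for i in range(n):
        rid = f"R{i + 1}"
        stoich = {f"M{i}": -1.0, f"M{i + 1}": 1.0}
        lb = -1000.0 if reversible[i] else 0.0
        role = roles[i]
        if role == "isozyme":
            ga, gb = f"g{i + 1}a", f"g{i + 1}b"
            pa, pb = f"P{i + 1}A", f"P{i + 1}B"
            register(ga, pa)
            register(gb, pb)
            gpr = parse_gpr(f"{ga} or {gb}")
            cap = 0.0
            for prot in (pa, pb):
                k = add_kcat(prot, rid, i)
                e = draw_abundance()
                ab_records.append(AbundanceRecord(prot, e, "target", "species"))
                cap += k * e
            capacities[rid] = cap
        elif role == "complex":
            ga, gb = f"g{i + 1}a", f"g{i + 1}b"
            pa, pb = f"P{i + 1}A", f"P{i + 1}B"
            register(ga, pa)
            register(gb, pb)
            gpr = parse_gpr(f"{ga} and {gb}")
            cap = INF
            for prot in (pa, pb):
                k = add_kcat(prot, rid, i)
                e = draw_abundance()
                ab_records.append(AbundanceRecord(prot, e, "target", "species"))
                cap = min(cap, k * e)
            capacities[rid] = cap
        else:  # plain, possibly sharing the multifunctional protein
            if i in shared_steps:
                gene, prot = "gMF", "PMF"
                if gene not in protein_map:
                    register(gene, prot)
                    shared_abundance = draw_abundance()
                    ab_records.append(
                        AbundanceRecord(prot, shared_abundance, "target",
                                        "species")
                    )
                gpr = parse_gpr(gene)
                k = add_kcat(prot, rid, i)
                shared_terms.append(1.0 / k)
            else:
                gene, prot = f"g{i + 1}", f"P{i + 1}"
                register(gene, prot)
                gpr = parse_gpr(gene)
                k = add_kcat(prot, rid, i)
                e = draw_abundance()
                ab_records.append(AbundanceRecord(prot, e, "target", "species"))
                capacities[rid] = k * e
        reactions.append(Reaction(rid, stoich, lb, 1000.0, gpr))

    reactions.append(Reaction("BIOMASS", {f"M{n}": -1.0}, 0.0, INF))

    model = Model(
        id=f"toy_seed{spec.seed}",
        metabolites=mets,
        reactions=reactions,
        genes=genes,
        objective="BIOMASS",
        protein_map=protein_map,
    )
    model.validate()

    caps = dict(capacities)
    if shared_terms and shared_abundance is not None:
        caps["multifunctional_pair"] = shared_abundance / sum(shared_terms)
    optimum = min([spec.uptake, *caps.values()]) if caps else spec.uptake
    answers = {
        "uptake": spec.uptake,
        "optimum_unconstrained": spec.uptake,
        "optimum_constrained": optimum,
        "capacities": caps,
    }
    return model, KineticTable(kcat_records), AbundanceTable(ab_records), answers


def build_ec_toy(spec: ToySpec) -> Tuple[ECModel, dict]:
    """Convenience: generate, split to irreversible, and expand a toy."""
    model, kinetics, abundances, answers = make_toy(spec)
    irrev, parent = to_irreversible(model)
    ec = expand(irrev, kinetics, abundances, parent)
    return ec, answers


def make_overconstrained(
    spec: ToySpec, shrink: float
) -> Tuple[Model, KineticTable, AbundanceTable, dict]:
    """A toy whose essential-step kcat is scaled down by ``shrink``.

    With ``shrink`` small enough the enzyme-constrained optimum collapses
    towards zero, emulating a model loaded with a database kcat far below
    the in-vivo rate; ``shrink=1`` reproduces :func:`make_toy` exactly.
    The answers dict gains the targeted protein/reaction, the true kcat and
    the degraded optimum.
    """
    if shrink > 1:
        raise ValueError("shrink must be <= 1")
    model, kinetics, abundances, answers = make_toy(spec)
    # target the first plain non-shared step: essential and singly catalysed
    target_rid = None
    for rid in sorted(answers["capacities"], key=_step_order):
        if rid.startswith("R"):
            gpr_rxn = model.reaction(rid)
            branch_genes = gpr_rxn.genes()
            if len(branch_genes) == 1 and branch_genes[0] != "gMF":
                target_rid = rid
                break
    if target_rid is None:
        raise ValueError("spec has no plain single-enzyme step to degrade")
    target_protein = model.protein_map[model.reaction(target_rid).genes()[0]]

    shrunk = KineticTable()
    true_kcat = None
    for (prot, rid), recs in kinetics._groups.items():
        for rec in recs:
            if prot == target_protein:
                if rid in (target_rid, target_rid + "_fwd"):
                    true_kcat = rec.kcat
                shrunk.add(KcatRecord(prot, rid, kcat=rec.kcat * shrink,
                                      sa=rec.sa, mw=rec.mw, source=rec.source))
            else:
                shrunk.add(rec)
    assert true_kcat is not None
    answers = dict(answers)
    answers["target_protein"] = target_protein
    answers["target_reaction"] = target_rid
    answers["true_kcat"] = true_kcat
    answers["shrink"] = shrink
    answers["degraded_capacity"] = answers["capacities"][target_rid] * shrink
    return model, shrunk, abundances, answers


def _step_order(rid: str) -> int:
    try:
        return int(rid.lstrip("R"))
    except ValueError:
        return 10**6


def make_carbon_switch_toy() -> Tuple[
    Model, KineticTable, AbundanceTable, Dict[str, ConditionSpec], Dict[str, int]
]:
    """A toy with dedicated glucose / xylose / maltose entry pathways.

    Each carbon source funnels into a common carbon pool (one pool unit per
    carbon atom: glucose 6, xylose 5, maltose 12) through its own
    enzyme-gated pathway — the xylose route has two steps so an entire
    dedicated branch must be induced when the source switches.  Biomass
    consumes 6 pool units plus one O2, so the iso-carbon uptakes
    (glucose 1.0, xylose 1.2, maltose 0.5 mmol/gDW/h; all 6 C-mmol/gDW/h)
    give the same growth rate.  Returns the model, kinetic and abundance
    fixtures, the three named conditions, and the carbon counts per
    exchange.
    """
    mets = [
        Metabolite("glc", "glucose", "e"),
        Metabolite("xyl", "xylose", "e"),
        Metabolite("malt", "maltose", "e"),
        Metabolite("o2x", "oxygen", "e"),
        Metabolite("xint", "xylulose", "c"),
        Metabolite("cpool", "carbon pool", "c"),
    ]
    reactions = [
        Reaction("EX_glc", {"glc": -1.0}, -1.0, 1000.0, None, RxnKind.EXCHANGE),
        Reaction("EX_xyl", {"xyl": -1.0}, 0.0, 1000.0, None, RxnKind.EXCHANGE),
        Reaction("EX_malt", {"malt": -1.0}, 0.0, 1000.0, None, RxnKind.EXCHANGE),
        Reaction("EX_o2", {"o2x": -1.0}, -1000.0, 1000.0, None, RxnKind.EXCHANGE),
        Reaction("R_glc", {"glc": -1.0, "cpool": 6.0}, 0.0, 1000.0,
                 parse_gpr("gGLC")),
        Reaction("R_xyl1", {"xyl": -1.0, "xint": 1.0}, 0.0, 1000.0,
                 parse_gpr("gXYL1")),
        Reaction("R_xyl2", {"xint": -1.0, "cpool": 5.0}, 0.0, 1000.0,
                 parse_gpr("gXYL2")),
        Reaction("R_malt", {"malt": -1.0, "cpool": 12.0}, 0.0, 1000.0,
                 parse_gpr("gMALT")),
        Reaction("BIOMASS", {"cpool": -6.0, "o2x": -1.0}, 0.0, INF),
    ]
    genes = ["gGLC", "gXYL1", "gXYL2", "gMALT"]
    protein_map = {g: "P" + g[1:] for g in genes}
    model = Model("carbon_switch", mets, reactions, genes, "BIOMASS",
                  protein_map)
    model.validate()

    kcat_records = [
        KcatRecord(protein_map[g], rid, kcat=1000.0, mw=60000.0, source="toy")
        for g, rid in (("gGLC", "R_glc"), ("gXYL1", "R_xyl1"),
                       ("gXYL2", "R_xyl2"), ("gMALT", "R_malt"))
    ]
    ab_records = [
        AbundanceRecord(protein_map[g], 0.1, "target", "species") for g in genes
    ]
    conditions = {
        "glucose": ConditionSpec({"EX_glc": 1.0}, label="glucose"),
        "xylose": ConditionSpec({"EX_xyl": 1.2}, label="xylose"),
        "maltose": ConditionSpec({"EX_malt": 0.5}, label="maltose"),
    }
    carbon_atoms = {"EX_glc": 6, "EX_xyl": 5, "EX_malt": 12}
    return (model, KineticTable(kcat_records), AbundanceTable(ab_records),
            conditions, carbon_atoms)
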