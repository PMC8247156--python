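"""Shared fixtures: hand-built micro-models and a cobra-based LP oracle."""

from __future__ import annotations

import math

import pytest

from ecgem import (
    AbundanceRecord,
    AbundanceTable,
    KcatRecord,
    KineticTable,
    Metabolite,
    Model,
    Reaction,
    RxnKind,
    ToySpec,
    expand,
    parse_gpr,
    to_irreversible,
)

INF = math.inf


def chain_model(
    caps: dict[str, tuple[float, float]] | None = None,
    uptake: float = 10.0,
    gprs: dict[str, str] | None = None,
    n_steps: int = 2,
) -> tuple[Model, KineticTable, AbundanceTable]:
    """A linear chain EX_S -> M0 -> ... -> Mn -> BIOMASS with given enzymes.

    ``caps`` maps protein id -> (kcat, abundance); ``gprs`` maps reaction id
    -> GPR string (genes are protein ids prefixed with ``g``).
    """
    caps = caps or {}
    gprs = gprs or {}
    mets = [Metabolite(f"M{i}", compartment="c") for i in range(n_steps + 1)]
    rxns = [Reaction("EX_S", {"M0": -1.0}, -uptake, 1000.0, None, RxnKind.EXCHANGE)]
    for i in range(n_steps):
        rid = f"R{i + 1}"
        gpr = parse_gpr(gprs[rid]) if rid in gprs else None
        rxns.append(Reaction(rid, {f"M{i}": -1.0, f"M{i + 1}": 1.0}, 0.0, 1000.0, gpr))
    rxns.append(Reaction("BIOMASS", {f"M{n_steps}": -1.0}, 0.0, INF))
    genes = sorted({g for r in rxns for g in r.genes()})
    model = Model("chain", mets, rxns, genes, "BIOMASS",
                  {g: g.lstrip("g") for g in genes})
    model.validate()
    kin = KineticTable()
    ab = AbundanceTable()
    for protein, (kcat, abundance) in caps.items():
        kin.add(KcatRecord(protein, "*", kcat=kcat, mw=50000.0, source="fix"))
        ab.add(AbundanceRecord(protein, abundance, "target", "species"))
    return model, kin, ab


def expand_chain(model, kin, ab):
    irrev, parent = to_irreversible(model)
    return expand(irrev, kin, ab, parent)


@pytest.fixture
def simple_chain():
    """2-step chain, one enzyme capped at vmax = 100/h * 0.01 = 1 mmol/gDW/h."""
    model, kin, ab = chain_model(
        caps={"P1": (100.0, 0.01)}, gprs={"R1": "gP1"}, uptake=10.0
    )
    return model, kin, ab


@pytest.fixture
def isozyme_pair_chain():
    """Symmetric isozymes with caps 1 and 1 against a demand of 2."""
    model, kin, ab = chain_model(
        caps={"PA": (100.0, 0.01), "PB": (100.0, 0.01)},
        gprs={"R1": "gPA or gPB"},
        uptake=2.0,
    )
    return model, kin, ab


def cobra_optimum(model: Model, objective: str | None = None) -> float:
    """Independent FBA optimum via cobra/optlang-glpk (the cross-solver oracle)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment)
            for m in model.metabolites}
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cr.lower_bound = -1e6 if r.lb == -INF else r.lb
        cr.upper_bound = 1e6 if r.ub == INF else r.ub
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r, cr in zip(model.reactions, rxns):
        cr.add_metabolites({mets[mid]: coef for mid, coef in r.stoich.items()})
    cm.objective = objective or model.objective
    sol = cm.optimize()
    if sol.status != "optimal":
        raise RuntimeError(f"cobra oracle: {sol.status}")
    return float(sol.objective_value)
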