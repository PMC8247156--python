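"""FBA, robustness, FVA and reduction, knockouts, differential usage."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ecgem import (
    ConditionSpec,
    differential_usage,
    expand,
    fba,
    fv_reduction,
    fva,
    make_carbon_switch_toy,
    robustness_surface,
    single_gene_knockout,
    to_irreversible,
)

from conftest import chain_model, cobra_optimum, expand_chain

INF = math.inf


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


def test_fba_linear_chain_yields_uptake():
    model, _, _ = chain_model(uptake=10.0)
    assert fba(model).objective_value == pytest.approx(10.0, abs=1e-9)


def test_fba_enzyme_cap_on_middle_step(simple_chain):
    ec = expand_chain(*simple_chain)
    assert fba(ec).objective_value == pytest.approx(1.0, abs=1e-8)


def test_fba_condition_overrides_uptake():
    model, _, _ = chain_model(uptake=10.0)
    sol = fba(model, condition=ConditionSpec({"EX_S": 2.5}))
    assert sol.objective_value == pytest.approx(2.5, abs=1e-9)


def test_fba_fixed_growth_mode_with_alternative_objective():
    """Chemostat-style use: pin biomass, then minimise substrate uptake."""
    model, _, _ = chain_model(uptake=10.0)
    irrev, _ = to_irreversible(model)
    cond = ConditionSpec({}, fixed={"BIOMASS": 4.0})
    sol = fba(irrev, objective="EX_S_rev", condition=cond, sense="min")
    assert sol.optimal
    assert sol.fluxes["BIOMASS"] == pytest.approx(4.0, abs=1e-9)
    assert sol.objective_value == pytest.approx(4.0, abs=1e-9)  # yield 1


def test_fba_infeasible_status():
    model, _, _ = chain_model(uptake=1.0)
    sol = fba(model, condition=ConditionSpec({}, fixed={"BIOMASS": 5.0}))
    assert sol.status == "infeasible" and sol.fluxes == {}


def test_fba_matches_independent_solver_on_toys():
    """Cross-solver oracle: HiGHS optimum equals cobra/GLPK on every toy."""
    from ecgem import ToySpec, build_ec_toy, make_toy

    for seed in range(5):
        spec = ToySpec(n_linear_steps=4, isozyme_reactions=1,
                       complex_reactions=1, reversible_fraction=0.3, seed=seed)
        model, _, _, _ = make_toy(spec)
        assert fba(model).objective_value == pytest.approx(
            cobra_optimum(model), abs=1e-7
        )
        ec, _ = build_ec_toy(spec)
        assert fba(ec).objective_value == pytest.approx(
            cobra_optimum(ec.model), abs=1e-7
        )


def test_pfba_flux_vector_is_parsimonious():
    """pFBA drops futile cycling that plain FBA may leave in place."""
    model, _, _ = chain_model(uptake=3.0)
    model.reaction("R1").lb = -1000.0  # reversible step allows a fwd/rev cycle
    irrev, _ = to_irreversible(model)
    sol = fba(irrev, parsimonious=True)
    assert sol.objective_value == pytest.approx(3.0, abs=1e-8)
    assert sol.fluxes["R1_rev"] == pytest.approx(0.0, abs=1e-6)
    assert sol.fluxes["R1_fwd"] == pytest.approx(3.0, rel=1e-6)


# ---------------------------------------------------------------------------
# Robustness
# ---------------------------------------------------------------------------


def test_robustness_enzyme_capped_surface_plateaus(simple_chain):
    model, kin, ab = simple_chain
    model = model.copy()
    # add an oxygen-like second exchange so two axes exist
    from ecgem.model_core import Metabolite, Reaction, RxnKind

    model.metabolites.append(Metabolite("O2", compartment="c"))
    model.reactions.insert(1, Reaction("EX_O2", {"O2": -1.0}, -1000.0, 1000.0,
                                       None, RxnKind.EXCHANGE))
    model.reaction("BIOMASS").stoich["O2"] = -0.001  # trace requirement
    ec = expand(*(to_irreversible(model)[0], kin, ab))
    surf = robustness_surface(ec, "EX_S", "EX_O2", 5.0, 5.0, steps=6)
    assert surf["max_growth"] == pytest.approx(1.0, abs=1e-8)  # vmax = 1
    assert surf["saturates_a"] and surf["saturates_b"]
    # monotone non-decreasing along each axis
    g = surf["growth"]
    assert (np.diff(g, axis=0) >= -1e-9).all()
    assert (np.diff(g, axis=1) >= -1e-9).all()
    # zero-supply row and column give zero growth
    assert np.allclose(g[0, :], 0.0, atol=1e-9)


def test_robustness_uncapped_growth_keeps_rising():
    model, _, _ = chain_model(uptake=1000.0)
    from ecgem.model_core import Metabolite, Reaction, RxnKind

    model.metabolites.append(Metabolite("O2", compartment="c"))
    model.reactions.insert(1, Reaction("EX_O2", {"O2": -1.0}, -1000.0, 1000.0,
                                       None, RxnKind.EXCHANGE))
    model.reaction("BIOMASS").stoich["O2"] = -0.001
    surf = robustness_surface(model, "EX_S", "EX_O2", 5.0, 5.0, steps=6)
    assert not surf["saturates_a"]  # substrate axis keeps paying off
    g = surf["growth"]
    assert (np.diff(g[:, -1]) > 1e-9).all()


# ---------------------------------------------------------------------------
# FVA and reduction
# ---------------------------------------------------------------------------


def test_fva_single_path_has_zero_variability():
    model, _, _ = chain_model(uptake=10.0)
    irrev, _ = to_irreversible(model)
    recs = fva(irrev, fraction=1.0)
    for rec in recs:
        if rec.reaction in ("R1", "R2", "BIOMASS", "EX_S_rev"):
            assert rec.fv == pytest.approx(0.0, abs=1e-7)


def test_fva_parallel_equivalent_paths_split_the_window():
    """Two identical branches carrying total flux 10: each branch alone can
    span [0, 10] at fraction 1.0 of the optimum."""
    from ecgem.model_core import Metabolite, Model, Reaction, RxnKind

    mets = [Metabolite(m, compartment="c") for m in ("A", "B")]
    rxns = [
        Reaction("EX_A", {"A": -1.0}, -10.0, 1000.0, None, RxnKind.EXCHANGE),
        Reaction("Ra", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        Reaction("Rb", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        Reaction("BIO", {"B": -1.0}, 0.0, INF),
    ]
    model = Model("par", mets, rxns, [], "BIO")
    recs = {r.reaction: r for r in fva(model, fraction=1.0)}
    assert recs["Ra"].fv == pytest.approx(10.0, abs=1e-7)
    assert recs["Rb"].fv == pytest.approx(10.0, abs=1e-7)
    assert recs["BIO"].fv == pytest.approx(0.0, abs=1e-7)


def test_fva_fraction_windows_are_nested(simple_chain):
    ec = expand_chain(*simple_chain)
    tight = {r.reaction: r.fv for r in fva(ec, fraction=1.0)}
    loose = {r.reaction: r.fv for r in fva(ec, fraction=0.999)}
    for rid in tight:
        assert tight[rid] <= loose[rid] + 1e-9


def test_fva_bounds_bracket_fba_flux(simple_chain):
    ec = expand_chain(*simple_chain)
    sol = fba(ec)
    recs = {r.reaction: r for r in fva(ec, fraction=0.999)}
    for rid, v in sol.fluxes.items():
        assert recs[rid].min_flux - 1e-7 <= v <= recs[rid].max_flux + 1e-7


def test_fv_reduction_of_model_against_itself_is_zero():
    model, _, _ = chain_model(uptake=10.0)
    irrev, _ = to_irreversible(model)
    recs = fva(irrev, 0.999)
    red = fv_reduction(recs, recs, {r.reaction: r.reaction for r in recs})
    assert red.model_reduction == 0.0
    assert red.n_reduced == 0
    assert all(v == 0.0 for v in red.per_reaction.values())


def test_fv_reduction_arithmetic_on_halved_variability():
    from ecgem.simulation import FVARecord

    base = [FVARecord("R1", 0.0, 4.0), FVARecord("R2", 0.0, 2.0),
            FVARecord("R3", 1.0, 1.0)]
    ecr = [FVARecord("R1", 0.0, 2.0), FVARecord("R2", 0.0, 2.0),
           FVARecord("R3", 1.0, 1.0)]
    red = fv_reduction(base, ecr, {"R1": "R1", "R2": "R2", "R3": "R3"})
    assert red.per_reaction["R1"] == pytest.approx(50.0)
    assert red.per_reaction["R2"] == pytest.approx(0.0)
    assert red.per_reaction["R3"] == 0.0  # zero-baseline rule
    assert red.model_reduction == pytest.approx(50.0 / 3)
    assert red.total_reduction == pytest.approx((1 - 4.0 / 6.0) * 100)
    assert red.n_reduced == 1 and red.n_reduced_75 == 0


def test_ec_variability_nested_within_base_at_matched_floor(simple_chain):
    """At an identical growth requirement the enzyme-constrained polytope is
    contained in the base polytope, so every paired FV can only shrink."""
    model, kin, ab = simple_chain
    irrev, parent = to_irreversible(model)
    ec = expand(irrev, kin, ab, parent)
    mu_ec = fba(ec).objective_value
    base_recs = fva(irrev, floor=0.999 * mu_ec)
    ec_recs = fva(ec, fraction=0.999)
    red = fv_reduction(base_recs, ec_recs, ec.parent_map)
    base_total = sum(r.fv for r in base_recs)
    paired_ec_total = sum(
        rec.fv for rec in ec_recs
        if rec.reaction in red.per_reaction
        or rec.reaction.startswith("arm_")
    )
    assert all(v >= -1e-7 for v in red.per_reaction.values())
    assert paired_ec_total <= base_total + 1e-7


# ---------------------------------------------------------------------------
# Knockouts
# ---------------------------------------------------------------------------


def test_knockout_gene_outside_gpr_is_neutral(simple_chain):
    model, kin, ab = simple_chain
    model = model.copy()
    model.genes.append("gGhost")
    ec = expand_chain(model, kin, ab)
    (rec,) = single_gene_knockout(ec, ["gGhost"])
    assert rec.gr_ratio == pytest.approx(1.0, abs=1e-9)
    assert rec.klass == "neutral"


def test_knockout_sole_path_gene_is_lethal(simple_chain):
    ec = expand_chain(*simple_chain)
    (rec,) = single_gene_knockout(ec, ["gP1"])
    assert rec.gr_ratio == pytest.approx(0.0, abs=1e-9)
    assert rec.klass == "lethal"


def test_knockout_symmetric_isozyme_gives_half_growth(isozyme_pair_chain):
    """Caps 1 + 1 against demand 2: losing one isozyme halves growth and the
    surviving isozyme carries the flux (limiting, not lethal)."""
    ec = expand_chain(*isozyme_pair_chain)
    assert fba(ec).objective_value == pytest.approx(2.0, abs=1e-8)
    records = {r.gene: r for r in single_gene_knockout(ec)}
    for gene in ("gPA", "gPB"):
        assert records[gene].gr_ratio == pytest.approx(0.5, abs=1e-8)
        assert records[gene].klass == "limiting"


def test_knockout_never_raises_growth(isozyme_pair_chain):
    ec = expand_chain(*isozyme_pair_chain)
    for rec in single_gene_knockout(ec):
        assert rec.gr_ratio <= 1.0 + 1e-6


def test_knockout_unknown_gene_is_an_error(simple_chain):
    ec = expand_chain(*simple_chain)
    with pytest.raises(KeyError, match="gNope"):
        single_gene_knockout(ec, ["gNope"])


def test_knockout_on_plain_model_uses_gpr_evaluation():
    model, _, _ = chain_model(gprs={"R1": "gA or gB", "R2": "gC"})
    irrev, _ = to_irreversible(model)
    recs = {r.gene: r for r in single_gene_knockout(irrev)}
    assert recs["gA"].klass == "neutral"  # isozyme partner covers
    assert recs["gC"].klass == "lethal"


# ---------------------------------------------------------------------------
# Differential usage
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def carbon_switch():
    model, kin, ab, conds, atoms = make_carbon_switch_toy()
    irrev, parent = to_irreversible(model)
    ec = expand(irrev, kin, ab, parent)
    return ec, conds, atoms


def test_differential_usage_upregulates_only_active_pathway(carbon_switch):
    ec, conds, atoms = carbon_switch
    ref, xyl, malt = differential_usage(
        ec, conds["glucose"], [conds["xylose"], conds["maltose"]],
        oxygen_exchange="EX_o2", carbon_atoms=atoms,
    )
    assert ref.usage["PGLC"] > 0 and ref.usage["PXYL1"] == pytest.approx(0, abs=1e-9)
    assert xyl.induced_from_zero == ["PXYL1", "PXYL2"]
    assert malt.induced_from_zero == ["PMALT"]
    assert all(math.isinf(xyl.fold_change[p]) for p in ("PXYL1", "PXYL2"))
    # the glucose enzyme is switched off under xylose
    assert xyl.usage["PGLC"] == pytest.approx(0.0, abs=1e-9)


def test_differential_usage_iso_carbon_conditions_grow_equally(carbon_switch):
    """1.0 glucose, 1.2 xylose and 0.5 maltose all supply 6 C-mmol/gDW/h."""
    ec, conds, atoms = carbon_switch
    profiles = differential_usage(
        ec, conds["glucose"], [conds["xylose"], conds["maltose"]],
        oxygen_exchange="EX_o2", carbon_atoms=atoms,
    )
    assert [p.carbon_flux for p in profiles] == [6.0, 6.0, 6.0]
    for p in profiles:
        assert p.growth == pytest.approx(1.0, abs=1e-8)


def test_differential_usage_identical_conditions_fold_change_one(carbon_switch):
    ec, conds, _ = carbon_switch
    _, again = differential_usage(ec, conds["glucose"], [conds["glucose"]],
                                  oxygen_exchange="EX_o2")
    assert all(fc == pytest.approx(1.0, rel=1e-6) for fc in
               again.fold_change.values())
    assert again.induced_from_zero == []
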