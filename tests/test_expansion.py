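"""Enzyme expansion: stoichiometric rewriting, usage bounds, protein pool."""

from __future__ import annotations

import math

import pytest

from ecgem import (
    fba,
    parse_gpr,
    set_usage_bound,
    to_irreversible,
)
from ecgem.expansion import add_protein_pool, expand, gpr_branches
from ecgem.model_core import ModelValidationError, RxnKind

from conftest import chain_model, expand_chain

INF = math.inf


def test_gpr_branches_flatten_or_of_ands():
    assert gpr_branches(parse_gpr("g1 or g2")) == [
        frozenset({"g1"}), frozenset({"g2"})
    ]
    assert gpr_branches(parse_gpr("(g1 and g2) or g3")) == [
        frozenset({"g1", "g2"}), frozenset({"g3"})
    ]
    # AND over OR distributes into the cross product
    assert gpr_branches(parse_gpr("g1 and (g2 or g3)")) == [
        frozenset({"g1", "g2"}), frozenset({"g1", "g3"})
    ]


def test_isozyme_reaction_rewritten_as_three_reactions():
    """A -> B with two isozymes becomes arm + two enzyme-costed branches."""
    model, kin, ab = chain_model(
        caps={"P1": (100.0, 0.01), "P2": (200.0, 0.01)},
        gprs={"R1": "gP1 or gP2"}, n_steps=1,
    )
    ec = expand_chain(model, kin, ab)
    m = ec.model
    assert ec.arm_metabolites == ["pmet_R1"]
    arm = m.reaction("arm_R1")
    assert arm.kind == RxnKind.ARM
    assert arm.stoich == {"M0": -1.0, "pmet_R1": 1.0}
    b1, b2 = m.reaction("R1_iso1"), m.reaction("R1_iso2")
    assert b1.stoich == {"pmet_R1": -1.0, "M1": 1.0, "prot_P1": -1.0 / 100.0}
    assert b2.stoich == {"pmet_R1": -1.0, "M1": 1.0, "prot_P2": -1.0 / 200.0}
    assert not m.has_reaction("R1")
    # every enzyme species has exactly one producing (usage) reaction
    for p, urid in ec.usage_reactions.items():
        producers = [r.id for r in m.reactions if r.stoich.get("prot_" + p, 0) > 0]
        assert producers == [urid]
    assert ec.parent_map["arm_R1"] == "R1"
    assert ec.parent_map["R1_iso1"] == "R1"


def test_single_enzyme_cap_limits_flux():
    """kcat=100/h and E=0.01 mmol/gDW cap the step at 1 mmol/gDW/h."""
    model, kin, ab = chain_model(caps={"P1": (100.0, 0.01)},
                                 gprs={"R1": "gP1"}, uptake=10.0)
    ec = expand_chain(model, kin, ab)
    assert fba(ec).objective_value == pytest.approx(1.0, abs=1e-8)


def test_complex_requires_every_subunit():
    model, kin, ab = chain_model(
        caps={"PA": (100.0, 0.02), "PB": (100.0, 0.005)},
        gprs={"R1": "gPA and gPB"}, uptake=10.0,
    )
    ec = expand_chain(model, kin, ab)
    rxn = ec.model.reaction("R1")
    assert rxn.stoich["prot_PA"] == pytest.approx(-0.01)
    assert rxn.stoich["prot_PB"] == pytest.approx(-0.01)
    # the scarcer subunit binds: min(100*0.02, 100*0.005) = 0.5
    assert fba(ec).objective_value == pytest.approx(0.5, abs=1e-8)


def test_expansion_neutral_when_bounds_lifted():
    model, kin, ab = chain_model(caps={"P1": (100.0, 0.01)},
                                 gprs={"R1": "gP1"}, uptake=10.0)
    ec = expand_chain(model, kin, ab)
    relaxed = set_usage_bound(ec, "P1", INF)
    assert fba(relaxed).objective_value == pytest.approx(10.0, rel=1e-8)


def test_reaction_without_kinetics_left_unconstrained():
    model, kin, ab = chain_model(caps={"P1": (100.0, 0.01)},
                                 gprs={"R1": "gP1", "R2": "gOrphan"})
    ec = expand_chain(model, kin, ab)
    r2 = ec.model.reaction("R2")
    assert all(not mid.startswith("prot_") for mid in r2.stoich)
    assert any(r["reaction"] == "R2" and r["status"] == "unconstrained"
               for r in ec.report)
    assert "Orphan" not in ec.proteins


def test_partially_matched_isozyme_pair_left_unconstrained():
    """If one isozyme lacks kinetic evidence the reaction keeps no cap at
    all (constraints are removed, not imputed), and no arm is created."""
    model, kin, ab = chain_model(caps={"P1": (100.0, 0.01)},
                                 gprs={"R1": "gP1 or gMissing"}, uptake=10.0)
    ec = expand_chain(model, kin, ab)
    assert ec.arm_metabolites == []
    assert fba(ec).objective_value == pytest.approx(10.0, rel=1e-8)


def test_expand_rejects_reversible_input():
    model, kin, ab = chain_model()
    with pytest.raises(ModelValidationError, match="irreversible"):
        expand(model, kin, ab)


def test_column_and_metabolite_count_arithmetic():
    """n_rxns = base + arms + extra branches + usages; n_mets = base +
    enzymes + arm metabolites."""
    model, kin, ab = chain_model(
        caps={"P1": (100.0, 0.01), "P2": (100.0, 0.01), "P3": (50.0, 0.1)},
        gprs={"R1": "gP1 or gP2", "R2": "gP3"}, n_steps=2,
    )
    irrev, parent = to_irreversible(model)
    ec = expand(irrev, kin, ab, parent)
    n_base_rxns = len(irrev.reactions)
    n_arms = len(ec.arm_metabolites)
    n_usage = len(ec.usage_reactions)
    n_branches = sum(1 for r in ec.model.reactions if "_iso" in r.id)
    # each split reaction is replaced by 1 arm + n branches: net + n_branches
    assert len(ec.model.reactions) == n_base_rxns + n_arms + n_branches - n_arms + n_usage
    assert n_arms == 1 and n_branches == 2 and n_usage == 3
    assert len(ec.model.metabolites) == len(irrev.metabolites) + len(ec.proteins) + n_arms


def test_reversible_enzyme_shares_usage_across_directions():
    """A reversible catalysed step gets two kcats but one usage bound."""
    from ecgem import AbundanceRecord, AbundanceTable, KcatRecord, KineticTable
    model, _, _ = chain_model(gprs={"R1": "gP1"})
    model.reaction("R1").lb = -1000.0  # make the catalysed step reversible
    kin = KineticTable([
        KcatRecord("P1", "R1_fwd", kcat=100.0, mw=5e4),
        KcatRecord("P1", "R1_rev", kcat=40.0, mw=5e4),
    ])
    ab = AbundanceTable([AbundanceRecord("P1", 0.01, "target", "species")])
    irrev, parent = to_irreversible(model)
    ec = expand(irrev, kin, ab, parent)
    assert ec.model.reaction("R1_fwd").stoich["prot_P1"] == pytest.approx(-0.01)
    assert ec.model.reaction("R1_rev").stoich["prot_P1"] == pytest.approx(-0.025)
    assert len([r for r in ec.model.reactions if r.kind == RxnKind.USAGE]) == 1
    # forward capacity binds: 100 * 0.01 = 1
    assert fba(ec).objective_value == pytest.approx(1.0, abs=1e-8)


def test_flux_respects_kcat_times_usage():
    """Any optimal flux satisfies v_j <= kcat_j * usage flux numerically."""
    model, kin, ab = chain_model(
        caps={"P1": (100.0, 0.01), "P2": (200.0, 0.004)},
        gprs={"R1": "gP1", "R2": "gP2"}, n_steps=2,
    )
    ec = expand_chain(model, kin, ab)
    sol = fba(ec)
    for p, entry in ec.proteins.items():
        usage_flux = sol.fluxes[ec.usage_reactions[p]]
        for rid, kcat in entry.kcat_by_reaction.items():
            assert sol.fluxes[rid] <= kcat * usage_flux + 1e-8


# ---------------------------------------------------------------------------
# set_usage_bound
# ---------------------------------------------------------------------------


def test_usage_bound_zero_blocks_reaction(simple_chain):
    ec = expand_chain(*simple_chain)
    blocked = set_usage_bound(ec, "P1", 0.0)
    sol = fba(blocked)
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
    assert abs(sol.fluxes["R1"]) <= 1e-9


def test_usage_bound_halving_halves_optimum(simple_chain):
    ec = expand_chain(*simple_chain)
    mu0 = fba(ec).objective_value
    halved = set_usage_bound(ec, "P1", ec.proteins["P1"].abundance_bound / 2)
    assert fba(halved).objective_value == pytest.approx(mu0 / 2, rel=1e-8)


def test_usage_bound_validation(simple_chain):
    ec = expand_chain(*simple_chain)
    with pytest.raises(KeyError):
        set_usage_bound(ec, "nope", 1.0)
    with pytest.raises(ValueError):
        set_usage_bound(ec, "P1", -0.1)


# ---------------------------------------------------------------------------
# Protein pool
# ---------------------------------------------------------------------------


def test_pool_slack_when_larger_than_individual_bounds(simple_chain):
    ec = expand_chain(*simple_chain)
    mu0 = fba(ec).objective_value
    # individual bound 0.01 mmol * 50 kDa -> 0.5 g/gDW of enzyme mass
    pooled = add_protein_pool(ec, ptot=10.0, sigma=1.0)
    assert fba(pooled).objective_value == pytest.approx(mu0, rel=1e-8)


def test_pool_zero_blocks_growth(simple_chain):
    ec = expand_chain(*simple_chain)
    pooled = add_protein_pool(ec, ptot=0.0)
    assert fba(pooled).objective_value == pytest.approx(0.0, abs=1e-9)


def test_binding_pool_matches_analytic_allocation():
    """Two enzymes competing for one pool: the LP allocates the pool to
    equalise marginal cost, giving mu = ptot / (MW1/kcat1 + MW2/kcat2)
    for a serial chain that needs both steps at flux mu."""
    model, kin, ab = chain_model(
        caps={"P1": (100.0, 10.0), "P2": (50.0, 10.0)},  # slack individual bounds
        gprs={"R1": "gP1", "R2": "gP2"}, n_steps=2, uptake=1000.0,
    )
    ec = expand_chain(model, kin, ab)
    ptot = 0.2  # g/gDW, binding
    pooled = add_protein_pool(ec, ptot=ptot, sigma=1.0)
    mw = 50000.0
    expected = ptot / (mw / 1000.0 / 100.0 + mw / 1000.0 / 50.0)
    assert fba(pooled).objective_value == pytest.approx(expected, rel=1e-8)
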