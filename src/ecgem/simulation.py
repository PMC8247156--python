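"""LP-based phenotype analyses: FBA, robustness, FVA, knockouts, usage.

All analyses solve linear programs over the steady-state polytope
``{v : S v = 0, lb <= v <= ub}`` with the HiGHS solver (via
:func:`scipy.optimize.linprog`).  Conditions are expressed as uptake
magnitudes on exchange reactions: in a reversible model uptake is a negative
exchange flux, and after the irreversible split the ``_rev`` copy of the
exchange carries uptake as a non-negative flux; :func:`apply_condition`
resolves either form.

Because FBA optima are degenerate in general, analyses that consume flux
*vectors* (rather than just the optimum) stabilise them with parsimonious
FBA: the objective is fixed at its optimum and total absolute flux is
minimised, which selects a reproducible representative solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .expansion import ECModel
from .model_core import Model, Reaction, RxnKind, eval_gpr

__all__ = [
    "ConditionSpec",
    "FluxSolution",
    "FVARecord",
    "FVReduction",
    "KnockoutRecord",
    "UsageProfile",
    "apply_condition",
    "fba",
    "robustness_surface",
    "fva",
    "fv_reduction",
    "single_gene_knockout",
    "differential_usage",
]

INF = math.inf

#: LP feasibility/optimality tolerances passed to HiGHS.
LP_TOL = 1e-9
#: grRatio classification tolerance.
GR_EPS = 1e-6
#: Zero floor for fold-change denominators.
USAGE_EPS = 1e-8


@dataclass(frozen=True)
class ConditionSpec:
    """Environmental condition: uptake magnitudes plus fixed fluxes.

    ``uptake_bounds`` maps an exchange reaction id (pre-split id; the
    ``_rev`` copy is resolved automatically) to a non-negative uptake
    magnitude in mmol/gDW/h (``inf`` lifts the limitation).  ``fixed`` pins
    reactions to exact flux values, e.g. biomass to a chemostat dilution
    rate.
    """

    uptake_bounds: Mapping[str, float] = field(default_factory=dict)
    fixed: Mapping[str, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        for rid, v in self.uptake_bounds.items():
            if v < 0:
                raise ValueError(f"uptake magnitude for {rid} must be >= 0")


@dataclass
class FluxSolution:
    objective_value: float
    fluxes: Dict[str, float]
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class FVARecord:
    reaction: str
    min_flux: float
    max_flux: float

    @property
    def fv(self) -> float:
        return self.max_flux - self.min_flux


@dataclass
class FVReduction:
    """Variability-reduction summary of an ec model against its base.

    ``model_reduction`` is the arithmetic mean of per-reaction percentage
    reductions; ``total_reduction`` is the reduction of summed FV (both are
    reported because either reading fits a single headline percentage).
    """

    per_reaction: Dict[str, float]
    model_reduction: float
    total_reduction: float
    n_reduced: int
    n_reduced_75: int
    n_excluded: int


@dataclass(frozen=True)
class KnockoutRecord:
    gene: str
    mu_mutant: float
    gr_ratio: float
    klass: str  # lethal | limiting | neutral


@dataclass
class UsageProfile:
    condition: str
    growth: float
    usage: Dict[str, float]  # protein -> usage flux, mmol/gDW
    fold_change: Dict[str, float]  # vs reference (inf = induced from zero)
    induced_from_zero: List[str]
    carbon_flux: Optional[float] = None  # C-mmol/gDW/h if carbon counts given


ModelLike = Union[Model, ECModel]


def _as_model(m: ModelLike) -> Model:
    return m.model if isinstance(m, ECModel) else m


# ---------------------------------------------------------------------------
# Conditions
# ---------------------------------------------------------------------------


def apply_condition(model: Model, condition: Optional[ConditionSpec]) -> Model:
    """Return a copy of ``model`` with the condition's bounds installed."""
    out = model.copy()
    if condition is None:
        return out
    for rid, mag in condition.uptake_bounds.items():
        rev = rid + "_rev"
        if out.has_reaction(rev):
            out.reaction(rev).ub = mag
        elif out.has_reaction(rid):
            rxn = out.reaction(rid)
            if rxn.lb <= 0:
                rxn.lb = -mag
            else:  # already forward-only: treat as a plain ub
                rxn.ub = mag
        else:
            raise KeyError(f"condition names unknown exchange {rid!r}")
    for rid, value in condition.fixed.items():
        if not out.has_reaction(rid):
            raise KeyError(f"condition fixes unknown reaction {rid!r}")
        rxn = out.reaction(rid)
        rxn.lb = value
        rxn.ub = value
    return out


# ---------------------------------------------------------------------------
# LP core
# ---------------------------------------------------------------------------

_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _solve(
    S: sparse.spmatrix,
    bounds: List[Tuple[float, float]],
    c: np.ndarray,
) -> Tuple[str, Optional[np.ndarray], float]:
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": LP_TOL,
                 "dual_feasibility_tolerance": LP_TOL},
    )
    status = _STATUS.get(res.status, "infeasible")
    if status == "optimal":
        return status, res.x, float(res.fun)
    return status, None, math.nan


def fba(
    target: ModelLike,
    objective: Optional[str] = None,
    condition: Optional[ConditionSpec] = None,
    sense: str = "max",
    parsimonious: bool = False,
) -> FluxSolution:
    """Flux balance analysis.

    Maximises (or minimises) the objective reaction's flux subject to
    ``S v = 0`` and the model's bounds with the condition applied.  With
    ``parsimonious=True`` the objective is then fixed at its optimum and the
    total absolute flux is minimised, yielding a stable flux vector.
    """
    model = apply_condition(_as_model(target), condition)
    obj = objective or model.objective
    if not obj or not model.has_reaction(obj):
        raise KeyError(f"objective reaction {obj!r} not in model")
    S, _, rxn_pos = model.stoichiometric_matrix()
    bounds = [(r.lb, r.ub) for r in model.reactions]
    n = len(model.reactions)
    c = np.zeros(n)
    c[rxn_pos[obj]] = -1.0 if sense == "max" else 1.0
    status, x, fun = _solve(S, bounds, c)
    if status != "optimal":
        return FluxSolution(math.nan, {}, status)
    opt = -fun if sense == "max" else fun

    if parsimonious:
        x = _pfba_vector(S, bounds, rxn_pos[obj], opt, sense)
    fluxes = {r.id: float(x[j]) for r, j in zip(model.reactions, rxn_pos.values())}
    return FluxSolution(opt, fluxes, "optimal")


def _pfba_vector(
    S: sparse.spmatrix,
    bounds: List[Tuple[float, float]],
    obj_col: int,
    opt: float,
    sense: str,
) -> np.ndarray:
    """Minimise total |v| with the objective pinned at its optimum.

    Variables are split ``v = p - q`` with ``p, q >= 0`` so the L1 norm is
    linear; the objective column is pinned with a tiny relative slack to
    stay inside HiGHS feasibility tolerances.
    """
    n = S.shape[1]
    slack = 1e-9 * max(1.0, abs(opt))
    pin = list(bounds)
    if sense == "max":
        pin[obj_col] = (opt - slack, bounds[obj_col][1])
    else:
        pin[obj_col] = (bounds[obj_col][0], opt + slack)
    p_bounds, q_bounds = [], []
    for lb, ub in pin:
        p_bounds.append((max(lb, 0.0), max(ub, 0.0)))
        q_bounds.append((max(-ub, 0.0), max(-lb, 0.0)))
    A = sparse.hstack([S, -S], format="csc")
    c = np.ones(2 * n)
    status, y, _ = _solve(A, p_bounds + q_bounds, c)
    if status != "optimal":  # fall back to the unstabilised vector
        status2, x, _ = _solve(S, pin, np.zeros(n))
        if status2 == "optimal":
            return x
        raise RuntimeError("pFBA restriction unexpectedly infeasible")
    return y[:n] - y[n:]


# ---------------------------------------------------------------------------
# Robustness analysis
# ---------------------------------------------------------------------------


def robustness_surface(
    target: ModelLike,
    rxn_a: str,
    rxn_b: str,
    max_a: float = 5.0,
    max_b: float = 5.0,
    steps: int = 21,
    condition: Optional[ConditionSpec] = None,
) -> dict:
    """Growth optimum over a 2-D grid of uptake bounds.

    Returns axes, the growth matrix (rows follow ``rxn_a``), a matrix of
    infeasible flags (growth recorded as 0 there), and whether growth
    saturates along each axis at full supply of the other (the signature of
    an enzyme-limited model, as opposed to growth that keeps rising with
    supply).
    """
    a_vals = np.linspace(0.0, max_a, steps)
    b_vals = np.linspace(0.0, max_b, steps)
    growth = np.zeros((steps, steps))
    infeasible = np.zeros((steps, steps), dtype=bool)
    base = dict(condition.uptake_bounds) if condition else {}
    fixed = dict(condition.fixed) if condition else {}
    for i, a in enumerate(a_vals):
        for j, b in enumerate(b_vals):
            cond = ConditionSpec({**base, rxn_a: a, rxn_b: b}, fixed,
                                 f"{rxn_a}={a:g},{rxn_b}={b:g}")
            sol = fba(target, condition=cond)
            if sol.status == "optimal":
                growth[i, j] = sol.objective_value
            elif sol.status == "unbounded":
                growth[i, j] = INF
            else:
                infeasible[i, j] = True
    finite = growth[np.isfinite(growth)]
    top = finite.max() if finite.size else 0.0

    def saturates(axis: int) -> bool:
        last, prev = (growth[-1, -1], growth[-2, -1] if axis == 0 else growth[-1, -2])
        if not (np.isfinite(last) and np.isfinite(prev)):
            return False
        return abs(last - prev) <= 1e-9 * max(1.0, abs(last))

    return {
        "axis_a": a_vals,
        "axis_b": b_vals,
        "growth": growth,
        "infeasible": infeasible,
        "max_growth": top,
        "saturates_a": saturates(0),
        "saturates_b": saturates(1),
    }


# ---------------------------------------------------------------------------
# Flux variability analysis
# ---------------------------------------------------------------------------


def fva(
    target: ModelLike,
    fraction: float = 0.999,
    condition: Optional[ConditionSpec] = None,
    reactions: Optional[Sequence[str]] = None,
    floor: Optional[float] = None,
) -> List[FVARecord]:
    """Per-reaction flux ranges at ``biomass >= fraction * mu*``.

    ``fraction`` is the fraction of the FBA optimum the objective is held
    above while each reaction's flux is minimised and maximised.  An
    explicit ``floor`` (absolute growth, 1/h) overrides the fraction — use
    it to compare two models' variability under an identical growth
    requirement.  Unbounded directions are recorded as ``±inf``.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    model = apply_condition(_as_model(target), condition)
    obj = model.objective
    if floor is None:
        sol = fba(model)
        if not sol.optimal:
            raise RuntimeError(f"FVA: base FBA is {sol.status}")
        floor = fraction * sol.objective_value
    S, _, rxn_pos = model.stoichiometric_matrix()
    bounds = [(r.lb, r.ub) for r in model.reactions]
    ocol = rxn_pos[obj]
    lo, hi = bounds[ocol]
    bounds[ocol] = (max(lo, floor - 1e-9 * max(1.0, abs(floor))), hi)
    wanted = list(reactions) if reactions is not None else [r.id for r in model.reactions]
    out = []
    n = len(model.reactions)
    for rid in wanted:
        j = rxn_pos[rid]
        c = np.zeros(n)
        c[j] = 1.0
        st_min, x_min, f_min = _solve(S, bounds, c)
        vmin = f_min if st_min == "optimal" else (-INF if st_min == "unbounded" else math.nan)
        c[j] = -1.0
        st_max, x_max, f_max = _solve(S, bounds, c)
        vmax = -f_max if st_max == "optimal" else (INF if st_max == "unbounded" else math.nan)
        out.append(FVARecord(rid, vmin, vmax))
    return out


def fv_reduction(
    fva_base: Sequence[FVARecord],
    fva_ec: Sequence[FVARecord],
    parent_map: Mapping[str, str],
) -> FVReduction:
    """Per-reaction and model-level flux-variability reduction (percent).

    Base reactions are paired with the expanded model's reaction carrying
    the same total flux: the identically named reaction when it survived
    expansion, or the arm reaction of an isozyme split.  Branch and usage
    reactions are excluded; base reactions whose FV is zero contribute a
    reduction of 0 (the ratio is undefined there); pairs with infinite FV on
    either side are excluded and counted.
    """
    base_fv = {rec.reaction: rec.fv for rec in fva_base}
    ec_fv_by_parent: Dict[str, float] = {}
    for rec in fva_ec:
        parent = parent_map.get(rec.reaction)
        if parent is None:
            continue
        if rec.reaction == parent or rec.reaction == f"arm_{parent}":
            ec_fv_by_parent[parent] = rec.fv
    per: Dict[str, float] = {}
    n_excluded = 0
    for rid, fv0 in base_fv.items():
        if rid not in ec_fv_by_parent:
            n_excluded += 1
            continue
        fv1 = ec_fv_by_parent[rid]
        if not (math.isfinite(fv0) and math.isfinite(fv1)):
            n_excluded += 1
            continue
        if fv0 <= 1e-12:
            per[rid] = 0.0
        else:
            per[rid] = (1.0 - fv1 / fv0) * 100.0
    vals = np.array(list(per.values())) if per else np.zeros(0)
    finite_pairs = [(base_fv[r], ec_fv_by_parent[r]) for r in per]
    sum_base = sum(b for b, _ in finite_pairs)
    sum_ec = sum(e for _, e in finite_pairs)
    total = (1.0 - sum_ec / sum_base) * 100.0 if sum_base > 0 else 0.0
    return FVReduction(
        per_reaction=per,
        model_reduction=float(vals.mean()) if vals.size else 0.0,
        total_reduction=total,
        n_reduced=int((vals > 1e-9).sum()),
        n_reduced_75=int((vals > 75.0).sum()),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Gene knockouts
# ---------------------------------------------------------------------------


def single_gene_knockout(
    target: ModelLike,
    genes: Optional[Sequence[str]] = None,
    condition: Optional[ConditionSpec] = None,
) -> List[KnockoutRecord]:
    """Simulate single-gene deletions and score grRatio = mu_ko / mu_wt.

    In a plain model a reaction is disabled (bounds ``[0, 0]``) when its GPR
    evaluates false without the gene.  In an enzyme-constrained model the
    usage bound of every protein encoded by the gene is additionally set to
    0, so isozyme branches supported by other proteins keep operating —
    matrix shape is preserved and flux reroutes through surviving isozymes.
    """
    model = apply_condition(_as_model(target), condition)
    known = set(model.genes) or {g for r in model.reactions for g in r.genes()}
    todo = list(genes) if genes is not None else sorted(known)
    missing = [g for g in todo if g not in known]
    if missing:
        raise KeyError(f"genes absent from model: {missing}")
    wt = fba(model)
    if not wt.optimal or wt.objective_value <= 0:
        raise RuntimeError("wild-type FBA must be optimal with positive growth")
    mu_wt = wt.objective_value

    ec = target if isinstance(target, ECModel) else None
    records = []
    for gene in todo:
        ko = model.copy()
        for rxn in ko.reactions:
            if rxn.gpr is not None and not eval_gpr(rxn.gpr, {gene}):
                rxn.lb = 0.0
                rxn.ub = 0.0
        if ec is not None:
            for p, entry in ec.proteins.items():
                if gene in entry.genes:
                    urxn = ko.reaction(ec.usage_reactions[p])
                    urxn.lb = 0.0
                    urxn.ub = 0.0
        sol = fba(ko)
        mu = sol.objective_value if sol.optimal else 0.0
        gr = mu / mu_wt
        if gr <= GR_EPS:
            klass = "lethal"
        elif abs(gr - 1.0) <= GR_EPS:
            klass = "neutral"
        else:
            klass = "limiting"
        records.append(KnockoutRecord(gene, mu, gr, klass))
    return records


# ---------------------------------------------------------------------------
# Differential enzyme usage
# ---------------------------------------------------------------------------


def differential_usage(
    ecmodel: ECModel,
    reference: ConditionSpec,
    alternates: Sequence[ConditionSpec],
    oxygen_exchange: Optional[str] = None,
    carbon_atoms: Optional[Mapping[str, int]] = None,
) -> List[UsageProfile]:
    """Enzyme-usage profiles across carbon sources, relative to a reference.

    Each condition names its carbon source's uptake magnitude; all carbon
    exchanges appearing in *any* of the conditions are closed before a
    condition's own uptake is applied, so exactly one source feeds the model
    at a time.  ``oxygen_exchange`` (if given) is unbounded in every
    condition.  Usage is the parsimonious-FBA flux of each enzyme-usage
    reaction at maximal growth; fold changes against the reference use a
    floor of ``1e-8`` on the denominator, with enzymes whose reference usage
    is zero reported as induced-from-zero (fold change ``inf``).

    With ``carbon_atoms`` (exchange -> carbon count) the carbon-mole influx
    of every condition is recorded, letting callers verify iso-carbon
    comparisons (e.g. glucose 1.0 x 6 = xylose 1.2 x 5 = 6 C-mmol/gDW/h).
    """
    all_conditions = [reference, *alternates]
    carbon_sources = sorted(
        {rid for cond in all_conditions for rid in cond.uptake_bounds}
        - ({oxygen_exchange} if oxygen_exchange else set())
    )

    def run(cond: ConditionSpec) -> UsageProfile:
        bounds = {rid: 0.0 for rid in carbon_sources}
        bounds.update(cond.uptake_bounds)
        if oxygen_exchange:
            bounds[oxygen_exchange] = INF
        spec = ConditionSpec(bounds, cond.fixed, cond.label)
        sol = fba(ecmodel, condition=spec, parsimonious=True)
        if not sol.optimal:
            raise RuntimeError(
                f"differential usage: condition {cond.label!r} is {sol.status}"
            )
        usage = {
            p: max(sol.fluxes.get(urid, 0.0), 0.0)
            for p, urid in ecmodel.usage_reactions.items()
        }
        cflux = None
        if carbon_atoms is not None:
            cflux = sum(
                mag * carbon_atoms.get(rid, 0)
                for rid, mag in cond.uptake_bounds.items()
                if math.isfinite(mag)
            )
        return UsageProfile(cond.label, sol.objective_value, usage, {}, [], cflux)

    ref = run(reference)
    ref.fold_change = {p: 1.0 for p in ref.usage}
    profiles = [ref]
    for cond in alternates:
        prof = run(cond)
        for p, u in prof.usage.items():
            u0 = ref.usage.get(p, 0.0)
            if u0 > USAGE_EPS:
                prof.fold_change[p] = u / u0
            elif u > USAGE_EPS:
                prof.fold_change[p] = INF
                prof.induced_from_zero.append(p)
            else:
                prof.fold_change[p] = 1.0
        prof.induced_from_zero.sort()
        profiles.append(prof)
    return profiles
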