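"""Apparent-catalytic-rate (kapp) sweeps and kcat correction.

Database turnover numbers are often far below the in-vivo rates an enzyme
can sustain, and loading them into an enzyme-constrained model can choke
growth entirely (over-constraint).  The remedy implemented here estimates an
*apparent* catalytic rate under each of many environmental conditions,

    kapp_j(C) = v_j(C) / E_j = kcat_j * eta(C),

where ``v_j(C)`` is the simulated flux through reaction *j* under condition
*C* and ``E_j`` the (condition-independent, measured) abundance of its
enzyme.  Some condition drives the enzyme near saturation (eta -> 1), so the
maximum over the grid, ``kapp_max``, is a usable kcat estimate and replaces
the database value.

Fluxes for the sweep come, by default, from the *relaxed* model: the 1/kcat
stoichiometry is kept but usage bounds are lifted, since fluxes clipped by
the very constraints under suspicion could never exceed them (``v <= kcat*E``
forces ``kapp <= kcat``).  The ``constrained`` source is available as a
consistency check, where ``kapp <= kcat`` must hold for every estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .expansion import ECModel
from .simulation import ConditionSpec, fba

__all__ = [
    "KappEstimate",
    "condition_grid",
    "estimate_kapp",
    "correct_kcats",
    "detect_overconstraint",
]

INF = math.inf


@dataclass
class KappEstimate:
    """kapp estimates for one (protein, reaction) pair across a grid."""

    protein: str
    reaction: str
    kapp_by_condition: Dict[str, float]
    kcat_db: float  # the kcat currently in the model, 1/h

    @property
    def kapp_max(self) -> float:
        return max(self.kapp_by_condition.values())

    @property
    def eta_by_condition(self) -> Dict[str, float]:
        """Condition-dependent efficiency kapp/kcat (relative to kcat_db)."""
        return {c: k / self.kcat_db for c, k in self.kapp_by_condition.items()}


def condition_grid(
    glc_exchange: str = "EX_glc",
    o2_exchange: str = "EX_o2",
    glc_range: Tuple[float, float] = (0.25, 5.0),
    o2_range: Tuple[float, float] = (0.25, 5.0),
    steps: Tuple[int, int] = (20, 20),
) -> List[ConditionSpec]:
    """Cartesian substrate x oxygen uptake grid (default 20 x 20 = 400).

    Values are evenly spaced over the closed ranges and the list is sorted
    glucose-major, deterministically.
    """
    if steps[0] < 1 or steps[1] < 1:
        raise ValueError("steps must be >= 1")
    if glc_range[1] <= 0 or o2_range[1] <= 0:
        raise ValueError("ranges must be positive")
    glc_vals = np.linspace(glc_range[0], glc_range[1], steps[0])
    o2_vals = np.linspace(o2_range[0], o2_range[1], steps[1])
    grid = []
    for g in glc_vals:
        for o in o2_vals:
            grid.append(ConditionSpec(
                {glc_exchange: float(g), o2_exchange: float(o)},
                label=f"glc={g:g},o2={o:g}",
            ))
    return grid


def _relaxed(ecmodel: ECModel) -> ECModel:
    out = ecmodel.copy()
    for p, urid in out.usage_reactions.items():
        out.model.reaction(urid).ub = INF
        # registry bounds are kept: kapp uses the measured abundance
    return out


def estimate_kapp(
    ecmodel: ECModel,
    conditions: Sequence[ConditionSpec],
    flux_source: str = "relaxed",
) -> List[KappEstimate]:
    """Sweep conditions and collect kapp = v_j / E_j per enzyme-reaction.

    Only proteins with a finite abundance bound are scored (``E_j`` is the
    fixed measured abundance, not a condition-specific value).  Reactions
    that never carry flux over the grid produce no estimate; infeasible
    conditions are skipped with a warning.  Flux vectors are stabilised with
    parsimonious FBA.
    """
    if flux_source not in ("relaxed", "constrained"):
        raise ValueError(f"unknown flux_source {flux_source!r}")
    sim_model = _relaxed(ecmodel) if flux_source == "relaxed" else ecmodel
    scored = {
        p: e for p, e in ecmodel.proteins.items()
        if math.isfinite(e.abundance_bound) and e.abundance_bound > 0
    }
    acc: Dict[Tuple[str, str], Dict[str, float]] = {}
    for cond in conditions:
        sol = fba(sim_model, condition=cond, parsimonious=True)
        if not sol.optimal:
            warnings.warn(
                f"kapp sweep: condition {cond.label!r} {sol.status}; skipped",
                stacklevel=2,
            )
            continue
        for p, entry in scored.items():
            for rid in entry.kcat_by_reaction:
                v = sol.fluxes.get(rid, 0.0)
                if v > 0:
                    acc.setdefault((p, rid), {})[cond.label] = (
                        v / entry.abundance_bound
                    )
    out = []
    for (p, rid) in sorted(acc):
        out.append(KappEstimate(
            p, rid, acc[(p, rid)], ecmodel.proteins[p].kcat_by_reaction[rid]
        ))
    return out


def correct_kcats(
    ecmodel: ECModel,
    estimates: Sequence[KappEstimate],
    policy: str = "replace_if_larger",
) -> Tuple[ECModel, List[dict]]:
    """Replace model kcats with kapp_max and return (model, change log).

    Under ``replace_if_larger`` (default) a kcat is only ever raised —
    correction relaxes constraints and can never lower the growth optimum;
    ``always_replace`` installs kapp_max unconditionally.  Each change
    rewrites the enzyme's stoichiometric coefficient in the affected
    reaction to ``-1/kcat_new`` and is logged as (protein, reaction, old,
    new, ratio).
    """
    if policy not in ("replace_if_larger", "always_replace"):
        raise ValueError(f"unknown policy {policy!r}")
    out = ecmodel.copy()
    log: List[dict] = []
    for est in estimates:
        entry = out.proteins.get(est.protein)
        if entry is None or est.reaction not in entry.kcat_by_reaction:
            raise KeyError(
                f"estimate for unknown coefficient "
                f"{est.protein}/{est.reaction}"
            )
        old = entry.kcat_by_reaction[est.reaction]
        new = max(old, est.kapp_max) if policy == "replace_if_larger" else est.kapp_max
        if new == old:
            continue
        entry.kcat_by_reaction[est.reaction] = new
        rxn = out.model.reaction(est.reaction)
        emet = "prot_" + est.protein
        if emet not in rxn.stoich:
            raise KeyError(f"{est.reaction} does not consume {emet}")
        rxn.stoich[emet] = -1.0 / new
        log.append({
            "protein": est.protein,
            "reaction": est.reaction,
            "kcat_old": old,
            "kcat_new": new,
            "ratio": new / old,
        })
    return out, log


def detect_overconstraint(
    ecmodel: ECModel,
    conditions: Sequence[ConditionSpec],
    threshold: float = 1e-6,
) -> dict:
    """Flag a model that cannot grow anywhere on the condition grid.

    The model is *flagged* when the maximal growth optimum over every
    condition stays below ``threshold`` (1/h).  The report also lists
    capacity-limited enzymes: proteins whose bound ``kcat * E`` falls short
    of the enzyme demand of the relaxed model's flux distribution at its
    best condition, which are the candidates that choke growth.
    """
    best_label = ""
    best_growth = 0.0
    best_cond: Optional[ConditionSpec] = None
    for cond in conditions:
        sol = fba(ecmodel, condition=cond)
        g = sol.objective_value if sol.optimal else 0.0
        if not math.isnan(g) and g >= best_growth:
            best_growth, best_label, best_cond = g, cond.label, cond
    flagged = best_growth < threshold

    limiting: List[dict] = []
    if best_cond is not None:
        relaxed = _relaxed(ecmodel)
        sol = fba(relaxed, condition=best_cond, parsimonious=True)
        if sol.optimal:
            for p, entry in sorted(ecmodel.proteins.items()):
                if not math.isfinite(entry.abundance_bound):
                    continue
                required = sum(
                    sol.fluxes.get(rid, 0.0) / kc
                    for rid, kc in entry.kcat_by_reaction.items()
                )
                if required > entry.abundance_bound * (1 + 1e-9):
                    limiting.append({
                        "protein": p,
                        "required_mmol_gdw": required,
                        "bound_mmol_gdw": entry.abundance_bound,
                        "shortfall": required / max(entry.abundance_bound, 1e-300),
                    })
    return {
        "flagged": flagged,
        "max_growth": best_growth,
        "best_condition": best_label,
        "threshold": threshold,
        "limiting": limiting,
    }
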