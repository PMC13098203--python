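"""Constraint-based simulation core.

Thin, deterministic layer over the COBRA/GLPK stack: media are expressed as
:class:`SimulationCondition` objects (exchange uptake bounds plus explicit
reaction-bound overrides), solved with plain FBA or parsimonious FBA.  All
flux calls in the package share a single "carries flux" tolerance of
1e-6 mmol gDW^-1 h^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Set, Tuple

import cobra
from cobra import Model, Reaction
from cobra.flux_analysis import pfba as _cobra_pfba

from .model_core import objective_reaction_id

__all__ = [
    "FLUX_TOL",
    "UNCONSTRAINED_BOUND",
    "SimulationCondition",
    "FluxSolution",
    "GrowthCall",
    "growth_call",
    "apply_condition",
    "solve_fba",
    "solve_pfba",
    "max_atp_yield",
    "ensure_atpm",
    "steady_state_residuals",
]

#: fluxes with magnitude at or below this are treated as zero everywhere
FLUX_TOL = 1e-6
#: bound magnitude used for "unconstrained" exchanges (water, protons)
UNCONSTRAINED_BOUND = 1000.0

#: canonical ATP-maintenance stoichiometry (ATP + H2O -> ADP + Pi + H+)
ATPM_ID = "ATPM"
_ATPM_STOICH = {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0}


@dataclass
class SimulationCondition:
    """A medium plus explicit reaction-bound overrides.

    ``medium`` maps exchange ids to maximum uptake magnitudes (the exchange
    lower bound becomes the negated uptake); exchanges in
    ``unconstrained_exchanges`` are opened to the full bound magnitude;
    every other exchange is closed for uptake.  ``reaction_overrides`` are
    applied last and must reference existing reactions.
    """

    medium: Dict[str, float] = field(default_factory=dict)
    unconstrained_exchanges: Set[str] = field(default_factory=set)
    reaction_overrides: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    objective_override: Optional[str] = None

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.medium.items() if v < 0}
        if bad:
            raise ValueError(f"negative uptake magnitudes: {bad}")

    def with_override(self, reaction_id: str, lb: float, ub: float) -> "SimulationCondition":
        overrides = dict(self.reaction_overrides)
        overrides[reaction_id] = (lb, ub)
        return replace(self, reaction_overrides=overrides)

    def with_uptake(self, exchange_id: str, uptake: float) -> "SimulationCondition":
        medium = dict(self.medium)
        medium[exchange_id] = uptake
        return replace(self, medium=medium)

    def without_component(self, exchange_id: str) -> "SimulationCondition":
        medium = {k: v for k, v in self.medium.items() if k != exchange_id}
        return replace(self, medium=medium)

    def with_objective(self, reaction_id: str) -> "SimulationCondition":
        return replace(self, objective_override=reaction_id)


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux(self, reaction_id: str) -> float:
        return self.fluxes.get(reaction_id, 0.0)


@dataclass
class GrowthCall:
    """Growth verdict under the 10 %-of-reference rule."""

    growth_rate: float
    reference_rate: float
    growing: bool


def growth_call(growth_rate: float, reference_rate: float) -> GrowthCall:
    growing = reference_rate > 0 and growth_rate >= 0.10 * reference_rate
    return GrowthCall(growth_rate, reference_rate, growing)


# ---------------------------------------------------------------------------
# condition application
# ---------------------------------------------------------------------------


def apply_condition(model: Model, cond: SimulationCondition,
                    copy: bool = True) -> Tuple[Model, List[str]]:
    """Return a constrained copy of *model* plus the medium ids it lacks.

    Exchanges named in the medium get ``lower_bound = -uptake`` (upper bound
    untouched); the unconstrained set opens fully; every other exchange
    closes for uptake.  Overrides apply last and raise if their reaction is
    absent (a missing medium component is data, a dangling override is a
    bug).
    """
    m = model.copy() if copy else model
    missing: List[str] = []
    exchange_ids = {r.id for r in m.reactions if len(r.metabolites) == 1}

    for rxn_id in exchange_ids:
        rxn = m.reactions.get_by_id(rxn_id)
        if rxn_id in cond.medium:
            rxn.lower_bound = -float(cond.medium[rxn_id])
        elif rxn_id in cond.unconstrained_exchanges:
            rxn.lower_bound = -UNCONSTRAINED_BOUND
        else:
            rxn.lower_bound = 0.0

    for ex_id in cond.medium:
        if ex_id not in exchange_ids:
            missing.append(ex_id)

    for rxn_id, (lb, ub) in cond.reaction_overrides.items():
        if rxn_id not in m.reactions:
            raise KeyError(f"override references absent reaction {rxn_id!r}")
        rxn = m.reactions.get_by_id(rxn_id)
        rxn.lower_bound, rxn.upper_bound = float(lb), float(ub)

    if cond.objective_override is not None:
        if cond.objective_override not in m.reactions:
            raise KeyError(
                f"objective override references absent reaction "
                f"{cond.objective_override!r}"
            )
        m.objective = cond.objective_override

    return m, sorted(missing)


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------


def _solution_from(model: Model, solution) -> FluxSolution:
    status = solution.status
    if status != "optimal":
        return FluxSolution(status="infeasible" if status == "infeasible" else status,
                            objective_value=0.0)
    fluxes = {rid: float(v) for rid, v in solution.fluxes.items()}
    return FluxSolution(status="optimal",
                        objective_value=float(solution.objective_value),
                        fluxes=fluxes)


def solve_fba(model: Model, cond: Optional[SimulationCondition] = None) -> FluxSolution:
    """Maximize the model objective under *cond* (plain FBA)."""
    m = model
    if cond is not None:
        m, _ = apply_condition(model, cond)
    objective_reaction_id(m)
    solution = m.optimize()
    return _solution_from(m, solution)


def solve_pfba(model: Model, cond: Optional[SimulationCondition] = None) -> FluxSolution:
    """Parsimonious FBA: fix the objective at its FBA optimum (relative
    slack 1e-6), minimize total absolute flux, and report the FBA optimum
    as the objective value."""
    m = model
    if cond is not None:
        m, _ = apply_condition(model, cond)
    obj_id = objective_reaction_id(m)
    opt = m.slim_optimize()
    if opt is None or opt != opt:  # NaN -> infeasible
        return FluxSolution(status="infeasible", objective_value=0.0)
    try:
        solution = _cobra_pfba(m, fraction_of_optimum=1.0 - 1e-6)
    except Exception:
        return FluxSolution(status="infeasible", objective_value=0.0)
    fluxes = {rid: float(v) for rid, v in solution.fluxes.items()}
    # report the FBA optimum; the pFBA flux of the objective may sit up to
    # the relative slack below it
    return FluxSolution(status="optimal", objective_value=float(opt), fluxes=fluxes)


def ensure_atpm(model: Model) -> Reaction:
    """Return the model's ATP-maintenance reaction, adding the canonical
    ATP + H2O -> ADP + Pi + H+ hydrolysis if it is missing."""
    if ATPM_ID in model.reactions:
        return model.reactions.get_by_id(ATPM_ID)
    missing = [mid for mid in _ATPM_STOICH if mid not in model.metabolites]
    if missing:
        raise ValueError(f"cannot install ATPM; metabolites missing: {missing}")
    rxn = Reaction(ATPM_ID, name="ATP maintenance", lower_bound=0.0,
                   upper_bound=UNCONSTRAINED_BOUND)
    model.add_reactions([rxn])
    rxn.add_metabolites({model.metabolites.get_by_id(m): c
                         for m, c in _ATPM_STOICH.items()})
    return rxn


def max_atp_yield(model: Model, cond: SimulationCondition,
                  substrate_exchange: str, carbons: int) -> float:
    """Maximum ATP yield on a substrate, in mol ATP per C-mol.

    Switches the objective to the ATP-maintenance reaction (installed if
    absent), maximizes it under *cond*, and divides by carbon actually taken
    up.  Returns 0.0 when the substrate is not consumed or no ATP can be
    made.
    """
    if carbons < 1:
        raise ValueError("carbons must be >= 1")
    if substrate_exchange not in model.reactions:
        raise KeyError(f"substrate exchange {substrate_exchange!r} absent from model")
    m, _ = apply_condition(model, cond)
    ensure_atpm(m)
    m.objective = ATPM_ID
    sol = solve_pfba(m)
    if not sol.optimal or sol.objective_value <= FLUX_TOL:
        return 0.0
    uptake = -sol.flux(substrate_exchange)
    if uptake <= FLUX_TOL:
        return 0.0
    return sol.objective_value / (carbons * uptake)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def steady_state_residuals(model: Model, fluxes: Dict[str, float]) -> Dict[str, float]:
    """Per-metabolite net production under a flux vector (should be ~0)."""
    residuals: Dict[str, float] = {m.id: 0.0 for m in model.metabolites}
    for rxn in model.reactions:
        v = fluxes.get(rxn.id, 0.0)
        if v == 0.0:
            continue
        for met, coeff in rxn.metabolites.items():
            residuals[met.id] += coeff * v
    return residuals
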