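"""Pan-model construction and cohort-level curation discovery.

Rather than curating hundreds of strain models one by one, all strain
reactions are compiled into a single *pan-model* whose union network and
strain x reaction presence matrix drive curation: detection of
energy-generating cycles (currency metabolites producible with every
exchange closed — a thermodynamic impossibility introduced by redundant
transport variants with inconsistent proton stoichiometry) and of the
variant groups themselves.  Which variant of a group to keep is a human
decision delivered as a patch; this module only detects and reports.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from cobra import Model, Reaction

from .lp_engine import FLUX_TOL
from .model_core import classify_reaction
from .universal_curation import _reaction_canon

__all__ = [
    "PanModel",
    "build_pan_model",
    "CurrencySpec",
    "default_currency_specs",
    "read_currency_specs",
    "EGCReport",
    "detect_energy_generating_cycles",
    "find_transport_variants",
]


# ---------------------------------------------------------------------------
# pan-model
# ---------------------------------------------------------------------------


@dataclass
class PanModel:
    """Union network plus strain x reaction boolean presence matrix."""

    union: Model
    presence: pd.DataFrame  # index: strain ids, columns: reaction ids

    @property
    def strain_ids(self) -> List[str]:
        return list(self.presence.index)


def build_pan_model(models: Sequence[Model]) -> PanModel:
    """Compile strain models sharing an id namespace into a pan-model.

    The union keeps one copy per reaction id with direction-union bounds;
    a reaction id carrying different stoichiometries across strains is a
    namespace violation and raises.
    """
    if not models:
        raise ValueError("no models given")
    union = Model("pan_model")
    stoich_seen: Dict[str, tuple] = {}
    conflicts: List[str] = []
    presence_rows: Dict[str, Dict[str, bool]] = {}

    for model in models:
        presence_rows[model.id] = {r.id: True for r in model.reactions}
        for rxn in model.reactions:
            canon = tuple(sorted((m.id, round(c, 9))
                                 for m, c in rxn.metabolites.items()))
            if rxn.id not in stoich_seen:
                stoich_seen[rxn.id] = canon
                union.add_reactions([rxn.copy()])
            else:
                if stoich_seen[rxn.id] != canon:
                    conflicts.append(rxn.id)
                    continue
                kept = union.reactions.get_by_id(rxn.id)
                kept.lower_bound = min(kept.lower_bound, rxn.lower_bound)
                kept.upper_bound = max(kept.upper_bound, rxn.upper_bound)
    if conflicts:
        raise ValueError(
            f"same reaction id with different stoichiometry across strains: "
            f"{sorted(set(conflicts))}"
        )

    columns = sorted(r.id for r in union.reactions)
    presence = pd.DataFrame(
        [[presence_rows[sid].get(rid, False) for rid in columns]
         for sid in presence_rows],
        index=list(presence_rows), columns=columns, dtype=bool,
    )
    return PanModel(union=union, presence=presence)


# ---------------------------------------------------------------------------
# energy-generating cycles
# ---------------------------------------------------------------------------


@dataclass
class CurrencySpec:
    """A currency-dissipation pseudo-reaction (e.g. ATP hydrolysis)."""

    name: str
    stoichiometry: Dict[str, float]


def read_currency_specs(path) -> List[CurrencySpec]:
    df = pd.read_csv(path, sep="\t")
    specs = []
    for _, row in df.iterrows():
        stoich = {}
        for item in str(row["stoichiometry"]).split(";"):
            key, _, val = item.rpartition(":")
            stoich[key] = float(val)
        specs.append(CurrencySpec(str(row["name"]), stoich))
    return specs


def default_currency_specs() -> List[CurrencySpec]:
    """Packaged defaults: ATP, GTP, NADH, NADPH, FADH2 hydrolysis/oxidation
    plus transmembrane proton-gradient dissipation (BiGG namespace)."""
    ref = importlib.resources.files("strainforge").joinpath("data/currencies.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_currency_specs(path)


@dataclass
class EGCReport:
    """Closed-exchange dissipation optimum per currency, with the reactions
    supporting any nonzero cycle."""

    fluxes: Dict[str, float] = field(default_factory=dict)
    support: Dict[str, List[str]] = field(default_factory=dict)

    def positive(self) -> Dict[str, float]:
        return {k: v for k, v in self.fluxes.items() if v > FLUX_TOL}

    @property
    def clean(self) -> bool:
        return not self.positive()


def detect_energy_generating_cycles(
    model: Model, currencies: Optional[Sequence[CurrencySpec]] = None
) -> EGCReport:
    """Probe each currency for production out of nothing.

    All exchange bounds are closed, the currency's dissipation reaction is
    added temporarily and maximized; any optimum above tolerance is an
    energy-generating cycle, reported together with the reactions active in
    a parsimonious solution at that optimum.  Currencies whose metabolites
    the model lacks report zero.
    """
    from cobra.flux_analysis import pfba as _pfba

    if currencies is None:
        currencies = default_currency_specs()
    m = model.copy()
    for rxn in m.reactions:
        if len(rxn.metabolites) == 1:
            rxn.bounds = (0.0, 0.0)

    report = EGCReport()
    for spec in currencies:
        if any(mid not in m.metabolites for mid in spec.stoichiometry):
            report.fluxes[spec.name] = 0.0
            report.support[spec.name] = []
            continue
        diss_id = f"DISS_{spec.name}"
        diss = Reaction(diss_id, name=f"{spec.name} dissipation",
                        lower_bound=0.0, upper_bound=1000.0)
        m.add_reactions([diss])
        diss.add_metabolites({m.metabolites.get_by_id(k): v
                              for k, v in spec.stoichiometry.items()})
        m.objective = diss_id
        opt = m.slim_optimize()
        opt = float(opt) if opt == opt else 0.0  # NaN guard
        report.fluxes[spec.name] = round(max(opt, 0.0), 6)
        support: List[str] = []
        if opt > FLUX_TOL:
            # cap the dissipation so the support LP is bounded and small
            diss.upper_bound = min(opt, 10.0)
            sol = _pfba(m, fraction_of_optimum=1.0 - 1e-6)
            support = sorted(
                rid for rid, v in sol.fluxes.items()
                if abs(v) > FLUX_TOL and rid != diss_id
            )
        report.support[spec.name] = support
        m.remove_reactions([diss])
    return report


# ---------------------------------------------------------------------------
# transport variants
# ---------------------------------------------------------------------------


def _is_proton(met_id: str) -> bool:
    return met_id.split("_")[0] == "h"


def find_transport_variants(model: Model) -> List[List[str]]:
    """Group transport reactions identical up to proton stoichiometry.

    Such variant sets (e.g. a lactate uniporter next to a lactate/2H+
    symporter) are the canonical source of proton-gradient energy loops.
    Singleton groups and groups that vanish entirely after proton deletion
    are dropped.
    """
    buckets: Dict[tuple, List[str]] = {}
    for rxn in model.reactions:
        if classify_reaction(rxn) != "transport":
            continue
        stripped = {m.id: c for m, c in rxn.metabolites.items()
                    if not _is_proton(m.id)}
        if not stripped:
            continue
        buckets.setdefault(_reaction_canon(stripped), []).append(rxn.id)
    return sorted(sorted(ids) for ids in buckets.values() if len(ids) >= 2)
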