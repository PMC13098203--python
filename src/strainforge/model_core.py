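"""Core model handling: SBML I/O, formula parsing, balance auditing, statistics.

Models are held as :class:`cobra.Model` objects throughout the package.  On
top of the plain COBRA representation this module adds

* a small *flag* vocabulary stored in reaction notes (``gap_filled``,
  ``restored_disconnected``, ``biomass``, ``exempt_from_balance``) that
  survives SBML round-trips,
* elemental formula parsing with support for the ``R``/``X`` pseudo-elements
  used by reaction databases for generic acyl/alkyl groups,
* per-reaction mass/charge balance classification, and
* whole-model summary statistics (reaction classes, gene coverage,
  disconnected metabolites).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set

import cobra
from cobra import Metabolite, Model, Reaction

__all__ = [
    "FLAG_NOTE_KEY",
    "KNOWN_FLAGS",
    "get_flags",
    "set_flags",
    "add_flag",
    "remove_flag",
    "has_flag",
    "parse_formula",
    "formula_to_string",
    "metabolite_formula",
    "BalanceEntry",
    "check_reaction_balance",
    "classify_reaction",
    "StatsReport",
    "model_stats",
    "base_metabolite_id",
    "objective_reaction_id",
    "read_sbml",
    "write_sbml",
]

#: Reaction-note key under which curation flags are serialized.
FLAG_NOTE_KEY = "strainforge_flags"

KNOWN_FLAGS = frozenset(
    {"gap_filled", "restored_disconnected", "biomass", "exempt_from_balance"}
)

# ---------------------------------------------------------------------------
# flags
# ---------------------------------------------------------------------------


def get_flags(reaction: Reaction) -> Set[str]:
    """Return the set of curation flags attached to *reaction*."""
    raw = reaction.notes.get(FLAG_NOTE_KEY, "")
    if not raw:
        return set()
    return {tok for tok in str(raw).split(",") if tok}


def set_flags(reaction: Reaction, flags: Iterable[str]) -> None:
    flags = sorted(set(flags))
    unknown = set(flags) - KNOWN_FLAGS
    if unknown:
        raise ValueError(f"unknown flags: {sorted(unknown)}")
    if flags:
        reaction.notes[FLAG_NOTE_KEY] = ",".join(flags)
    else:
        reaction.notes.pop(FLAG_NOTE_KEY, None)


def add_flag(reaction: Reaction, flag: str) -> None:
    set_flags(reaction, get_flags(reaction) | {flag})


def remove_flag(reaction: Reaction, flag: str) -> None:
    set_flags(reaction, get_flags(reaction) - {flag})


def has_flag(reaction: Reaction, flag: str) -> bool:
    return flag in get_flags(reaction)


# ---------------------------------------------------------------------------
# formulas
# ---------------------------------------------------------------------------

# Element = capital + optional lowercase letter; R/X are pseudo-elements used
# by databases for generic residues (fatty-acyl chains, polymer ends, ...).
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: Optional[str]) -> Optional[Dict[str, int]]:
    """Parse an elemental formula string into an element -> count map.

    Returns ``None`` for an empty or unparsable formula (the caller treats
    this as an *unknown formula* rather than an error, so that a balance
    audit never aborts on an exotic database entry).  Repeated element
    tokens are summed; counts default to 1.
    """
    if not text:
        return None
    counts: Dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            return None  # unmatched characters (parentheses, dots, ...)
        element, digits = match.groups()
        n = int(digits) if digits else 1
        if n <= 0:
            return None
        counts[element] = counts.get(element, 0) + n
        pos = match.end()
    if pos != len(text) or not counts:
        return None
    return counts


def formula_to_string(counts: Dict[str, int]) -> str:
    """Render an element map in Hill-like deterministic order (C, H, rest)."""

    def key(el: str):
        order = {"C": 0, "H": 1}
        return (order.get(el, 2), el)

    parts = []
    for el in sorted(counts, key=key):
        n = counts[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def metabolite_formula(met: Metabolite) -> Optional[Dict[str, int]]:
    return parse_formula(met.formula)


# ---------------------------------------------------------------------------
# balance checking
# ---------------------------------------------------------------------------


@dataclass
class BalanceEntry:
    """Mass/charge balance verdict for a single reaction."""

    reaction_id: str
    element_delta: Dict[str, float] = field(default_factory=dict)
    charge_delta: float = 0.0
    classification: str = "balanced"  # balanced | proton_imbalanced |
    # charge_imbalanced | mass_imbalanced | exempt | unknown_formula


def _is_boundary(reaction: Reaction) -> bool:
    return len(reaction.metabolites) == 1


def check_reaction_balance(reaction: Reaction, model: Optional[Model] = None) -> BalanceEntry:
    """Classify the mass/charge balance of a reaction.

    Exchange/sink reactions and reactions flagged ``biomass`` or
    ``exempt_from_balance`` are *exempt*.  A reaction involving a metabolite
    whose formula cannot be parsed (or whose charge is unset) classifies as
    ``unknown_formula``.  Otherwise the summed per-element and charge deltas
    decide between ``balanced``, ``proton_imbalanced`` (only H and charge
    off, by the same amount — a missing/extra proton), ``charge_imbalanced``
    (mass fine, charge off) and ``mass_imbalanced``.
    """
    flags = get_flags(reaction)
    if "exempt_from_balance" in flags or "biomass" in flags or _is_boundary(reaction):
        return BalanceEntry(reaction.id, {}, 0.0, "exempt")

    element_delta: Dict[str, float] = {}
    charge_delta = 0.0
    for met, coeff in reaction.metabolites.items():
        counts = metabolite_formula(met)
        if counts is None or met.charge is None:
            return BalanceEntry(reaction.id, {}, 0.0, "unknown_formula")
        for el, n in counts.items():
            element_delta[el] = element_delta.get(el, 0.0) + coeff * n
        charge_delta += coeff * met.charge

    tol = 1e-9
    element_delta = {el: d for el, d in element_delta.items() if abs(d) > tol}
    if abs(charge_delta) <= tol:
        charge_delta = 0.0

    if not element_delta and charge_delta == 0.0:
        cls = "balanced"
    elif set(element_delta) <= {"H"} and charge_delta != 0.0 and abs(
        element_delta.get("H", 0.0) - charge_delta
    ) <= 1e-9:
        cls = "proton_imbalanced"
    elif not element_delta and charge_delta != 0.0:
        cls = "charge_imbalanced"
    else:
        cls = "mass_imbalanced"
    return BalanceEntry(reaction.id, element_delta, charge_delta, cls)


# ---------------------------------------------------------------------------
# reaction classification and model statistics
# ---------------------------------------------------------------------------


def classify_reaction(reaction: Reaction, model: Optional[Model] = None) -> str:
    """Classify a reaction as exchange / biomass / transport / metabolic.

    Exchange: boundary pseudo-reaction with a single metabolite.  Biomass:
    carries the ``biomass`` flag.  Transport: participants span at least two
    compartments.  Everything else is metabolic.
    """
    if _is_boundary(reaction):
        return "exchange"
    if has_flag(reaction, "biomass"):
        return "biomass"
    compartments = {met.compartment for met in reaction.metabolites}
    if len(compartments) >= 2:
        return "transport"
    return "metabolic"


def base_metabolite_id(met_id: str, compartment: Optional[str] = None) -> str:
    """Strip the trailing ``_<compartment>`` suffix from a metabolite id."""
    if compartment and met_id.endswith("_" + compartment):
        return met_id[: -(len(compartment) + 1)]
    return met_id.rsplit("_", 1)[0] if "_" in met_id else met_id


@dataclass
class StatsReport:
    """Per-model content summary (counts plus percentages)."""

    model_id: str
    n_metabolites: int
    n_unique_metabolites: int
    n_disconnected_metabolites: int
    n_reactions: int
    n_metabolic: int
    n_transport: int
    n_exchange: int
    n_other: int
    pct_metabolic: float
    pct_transport: float
    pct_exchange: float
    n_with_genes: int
    pct_with_genes: float
    n_genes: int
    n_genes_multi_reaction: int
    pct_genes_multi_reaction: float

    def to_dict(self) -> Dict[str, object]:
        return dict(self.__dict__)


def model_stats(model: Model) -> StatsReport:
    """Compute content statistics for a model.

    A *disconnected* metabolite participates in at most one reaction in
    total (the dead-end notion used when pruning exchanges).  *Unique*
    metabolites are counted after stripping the compartment suffix, so a
    species present in both cytosol and medium counts once.
    """
    classes = {"metabolic": 0, "transport": 0, "exchange": 0, "biomass": 0}
    n_with_genes = 0
    for rxn in model.reactions:
        classes[classify_reaction(rxn)] += 1
        if rxn.gene_reaction_rule.strip():
            n_with_genes += 1

    unique = {base_metabolite_id(m.id, m.compartment) for m in model.metabolites}
    disconnected = sum(1 for m in model.metabolites if len(m.reactions) <= 1)
    n_rxn = len(model.reactions)
    n_genes = len(model.genes)
    multi = sum(1 for g in model.genes if len(g.reactions) > 1)

    def pct(x: int, total: int) -> float:
        return round(100.0 * x / total, 2) if total else 0.0

    return StatsReport(
        model_id=model.id or "",
        n_metabolites=len(model.metabolites),
        n_unique_metabolites=len(unique),
        n_disconnected_metabolites=disconnected,
        n_reactions=n_rxn,
        n_metabolic=classes["metabolic"],
        n_transport=classes["transport"],
        n_exchange=classes["exchange"],
        n_other=classes["biomass"],
        pct_metabolic=pct(classes["metabolic"], n_rxn),
        pct_transport=pct(classes["transport"], n_rxn),
        pct_exchange=pct(classes["exchange"], n_rxn),
        n_with_genes=n_with_genes,
        pct_with_genes=pct(n_with_genes, n_rxn),
        n_genes=n_genes,
        n_genes_multi_reaction=multi,
        pct_genes_multi_reaction=pct(multi, n_genes),
    )


# ---------------------------------------------------------------------------
# SBML I/O
# ---------------------------------------------------------------------------


def objective_reaction_id(model: Model) -> str:
    """Id of the (single) reaction carrying a nonzero objective coefficient."""
    ids = [
        rxn.id
        for rxn in model.reactions
        if getattr(rxn, "objective_coefficient", 0.0)
    ]
    if len(ids) != 1:
        candidates = [r.id for r in model.reactions if has_flag(r, "biomass")]
        raise ValueError(
            f"model {model.id!r} must declare exactly one objective reaction "
            f"(found {ids}); biomass-flagged candidates: {candidates}"
        )
    return ids[0]


def read_sbml(path) -> Model:
    """Read an SBML Level 3 / FBC model; bounds, GPRs, formulas, charges,
    annotations and curation flags (notes) are preserved."""
    model = cobra.io.read_sbml_model(str(path))
    objective_reaction_id(model)  # raises if no usable objective
    return model


def write_sbml(model: Model, path) -> None:
    """Write a model as SBML Level 3 Version 1 with the FBC v2 package.

    Curation flags travel in reaction notes and survive a round-trip
    through :func:`read_sbml`.
    """
    objective_reaction_id(model)  # refuse to write an objective-less model
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cobra.io.write_sbml_model(model, str(path))
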