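"""Post-carve refinement of draft strain models.

A homology-based carving step (CarveMe-style) outputs a draft model plus a
reaction-score table.  Refinement (1) installs the organism-specific
biomass reaction as the objective, (2) prunes gap-filled reactions — added
without genomic evidence — that carry no flux under the gap-fill growth
conditions, keeping gene-less transporters whose cargo touches
gene-evidenced reactions and dropping exchanges left dangling, and
(3) restores gene-evidenced reactions the carve omitted for lack of
connectivity (dead ends included: they still matter for presence/absence
comparison).  Order matters: the biomass is installed first so pruning sees
the final objective, and restoration runs last so restored dead ends can
never be pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
from cobra import Model, Reaction

from .lp_engine import FLUX_TOL, SimulationCondition, solve_fba, solve_pfba
from .model_core import (
    add_flag,
    base_metabolite_id,
    classify_reaction,
    get_flags,
    has_flag,
    set_flags,
)

__all__ = [
    "ScoreTable",
    "read_reaction_scores",
    "BiomassSpec",
    "RefinementLog",
    "ingest_carveme_flags",
    "prune_gapfill",
    "restore_scored_reactions",
    "install_biomass",
    "refine",
]

ScoreTable = Dict[str, float]


def read_reaction_scores(path) -> ScoreTable:
    """Read a CarveMe-style ``*_reaction_scores.tsv`` table.

    Requires ``reaction`` and ``score`` columns; duplicated reaction rows
    are ambiguous evidence and raise.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"reaction", "score"} - set(df.columns)
    if missing:
        raise ValueError(
            f"score table lacks columns {sorted(missing)}; expected header "
            "'reaction<TAB>score'"
        )
    if df["reaction"].duplicated().any():
        dups = sorted(df["reaction"][df["reaction"].duplicated()].unique())
        raise ValueError(f"duplicated reaction rows in score table: {dups}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    if scores.isna().any():
        bad = df.loc[scores.isna(), "reaction"].tolist()
        raise ValueError(f"non-numeric scores for reactions: {bad}")
    return dict(zip(df["reaction"].astype(str), scores.astype(float)))


def write_reaction_scores(scores: ScoreTable, path) -> None:
    pd.DataFrame(
        {"reaction": list(scores), "score": [scores[k] for k in scores]}
    ).to_csv(path, sep="\t", index=False)


@dataclass
class BiomassSpec:
    """Stoichiometry of the biomass pseudo-reaction (negative = consumed;
    includes the growth-associated ATP hydrolysis)."""

    id: str
    stoichiometry: Dict[str, float]
    name: str = "Biomass"


@dataclass
class RefinementLog:
    pruned_metabolic: List[str] = field(default_factory=list)
    pruned_transport: List[str] = field(default_factory=list)
    pruned_exchanges: List[str] = field(default_factory=list)
    restored: List[str] = field(default_factory=list)
    biomass_swapped: bool = False

    def merge(self, other: "RefinementLog") -> "RefinementLog":
        return RefinementLog(
            pruned_metabolic=self.pruned_metabolic + other.pruned_metabolic,
            pruned_transport=self.pruned_transport + other.pruned_transport,
            pruned_exchanges=self.pruned_exchanges + other.pruned_exchanges,
            restored=self.restored + other.restored,
            biomass_swapped=self.biomass_swapped or other.biomass_swapped,
        )


def ingest_carveme_flags(model: Model, scores: ScoreTable,
                         spontaneous: Iterable[str] = ()) -> List[str]:
    """Mark gap-filled reactions on a freshly carved model.

    The carve output does not label gap fills in SBML, so they are inferred:
    a non-exchange reaction with an empty gene rule that is absent from the
    score table (or scored <= 0) was added by gap filling.  Known
    spontaneous reactions and the biomass are exempt.  Returns the flagged
    ids.
    """
    spontaneous = set(spontaneous)
    flagged = []
    for rxn in model.reactions:
        if rxn.id in spontaneous or len(rxn.metabolites) == 1:
            continue
        if has_flag(rxn, "biomass"):
            continue
        if rxn.gene_reaction_rule.strip():
            continue
        if scores.get(rxn.id, 0.0) <= 0.0:
            add_flag(rxn, "gap_filled")
            flagged.append(rxn.id)
    return sorted(flagged)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


def _transported_base_ids(rxn: Reaction) -> Set[str]:
    by_base: Dict[str, Set[str]] = {}
    for met in rxn.metabolites:
        by_base.setdefault(base_metabolite_id(met.id, met.compartment), set()).add(
            met.compartment
        )
    return {b for b, comps in by_base.items() if len(comps) >= 2}


def prune_gapfill(
    model: Model, conditions: Sequence[SimulationCondition]
) -> Tuple[Model, RefinementLog]:
    """Remove gap-filled reactions that never carry flux.

    One parsimonious solution per condition decides "carries flux"
    (|v| > 1e-6).  A flux-less gap-filled metabolic reaction is removed; a
    flux-less gap-filled transport reaction survives if any metabolite it
    moves participates in a gene-bearing reaction; exchanges whose
    metabolite is left without any non-exchange reaction are dropped.  The
    growth optimum of every condition is preserved (checked to 1e-6).
    """
    if not conditions:
        raise ValueError("at least one gap-fill condition is required")
    m = model.copy()

    pre_optima = []
    used: Set[str] = set()
    for i, cond in enumerate(conditions):
        sol = solve_pfba(m, cond)
        if not sol.optimal or sol.objective_value <= FLUX_TOL:
            raise ValueError(
                f"gap-fill condition {i} does not support growth pre-pruning "
                f"(status {sol.status}, objective {sol.objective_value:g})"
            )
        pre_optima.append(sol.objective_value)
        used |= {rid for rid, v in sol.fluxes.items() if abs(v) > FLUX_TOL}

    log = RefinementLog()
    gapfilled = [r for r in m.reactions if has_flag(r, "gap_filled")]
    bad_gpr = [r.id for r in gapfilled if r.gene_reaction_rule.strip()]
    if bad_gpr:
        raise ValueError(f"gap-filled reactions carry gene rules: {bad_gpr}")

    gene_bearing_met_ids: Set[str] = set()
    for rxn in m.reactions:
        if rxn.gene_reaction_rule.strip():
            gene_bearing_met_ids.update(met.id for met in rxn.metabolites)

    to_remove: List[Reaction] = []
    for rxn in gapfilled:
        if rxn.id in used:
            continue
        cls = classify_reaction(rxn)
        if cls == "metabolic":
            to_remove.append(rxn)
            log.pruned_metabolic.append(rxn.id)
        elif cls == "transport":
            if not any(met.id in gene_bearing_met_ids for met in rxn.metabolites):
                to_remove.append(rxn)
                log.pruned_transport.append(rxn.id)
        elif cls == "exchange":
            # handled with the dangling-exchange sweep below
            continue
    m.remove_reactions(to_remove, remove_orphans=True)

    for rxn in list(m.reactions):
        if len(rxn.metabolites) != 1:
            continue
        met = next(iter(rxn.metabolites))
        if all(len(r.metabolites) == 1 for r in met.reactions):
            log.pruned_exchanges.append(rxn.id)
            m.remove_reactions([rxn], remove_orphans=True)

    for i, cond in enumerate(conditions):
        post = solve_fba(m, cond)
        if not post.optimal or abs(post.objective_value - pre_optima[i]) > 1e-6:
            raise RuntimeError(
                f"pruning changed the optimum of condition {i}: "
                f"{pre_optima[i]:g} -> {post.objective_value:g}"
            )

    log.pruned_metabolic.sort()
    log.pruned_transport.sort()
    log.pruned_exchanges.sort()
    return m, log


# ---------------------------------------------------------------------------
# restoration
# ---------------------------------------------------------------------------


def restore_scored_reactions(
    model: Model, universal: Model, scores: ScoreTable
) -> Tuple[Model, RefinementLog]:
    """Copy positively scored universal reactions missing from the model.

    Gene evidence was found for these reactions but the carve dropped them
    for lack of network connectivity; they return (with their gene rules and
    any missing metabolites) flagged ``restored_disconnected``.
    """
    absent_from_universal = [rid for rid in scores if rid not in universal.reactions]
    if absent_from_universal:
        raise KeyError(
            f"scored reactions absent from universal model: "
            f"{sorted(absent_from_universal)}"
        )
    m = model.copy()
    log = RefinementLog()
    for rid in sorted(scores):
        if scores[rid] <= 0.0 or rid in m.reactions:
            continue
        rxn = universal.reactions.get_by_id(rid).copy()
        add_flag(rxn, "restored_disconnected")
        m.add_reactions([rxn])
        log.restored.append(rid)
    return m, log


# ---------------------------------------------------------------------------
# biomass installation
# ---------------------------------------------------------------------------


def install_biomass(model: Model, spec: BiomassSpec) -> Model:
    """Replace the current biomass reaction with *spec* and set it as the
    objective.  All precursors must already exist in the model."""
    missing = [mid for mid in spec.stoichiometry if mid not in model.metabolites]
    if missing:
        raise KeyError(f"biomass precursors missing from model: {sorted(missing)}")
    m = model.copy()
    old = [r for r in m.reactions if has_flag(r, "biomass")]
    if old:
        m.remove_reactions(old, remove_orphans=True)
    rxn = Reaction(spec.id, name=spec.name, lower_bound=0.0, upper_bound=1000.0)
    m.add_reactions([rxn])
    rxn.add_metabolites({m.metabolites.get_by_id(k): v
                         for k, v in spec.stoichiometry.items()})
    set_flags(rxn, {"biomass", "exempt_from_balance"})
    m.objective = spec.id
    return m


# ---------------------------------------------------------------------------
# full refinement
# ---------------------------------------------------------------------------


def refine(
    draft: Model,
    universal: Model,
    scores: ScoreTable,
    conditions: Sequence[SimulationCondition],
    biomass: BiomassSpec,
) -> Tuple[Model, RefinementLog]:
    """Full refinement: install biomass, prune gap fills, restore scored
    reactions.  The result grows under every gap-fill condition."""
    m = install_biomass(draft, biomass)
    log = RefinementLog(biomass_swapped=True)
    m, prune_log = prune_gapfill(m, conditions)
    m, restore_log = restore_scored_reactions(m, universal, scores)
    log = log.merge(prune_log).merge(restore_log)
    for i, cond in enumerate(conditions):
        sol = solve_fba(m, cond)
        if not sol.optimal or sol.objective_value <= FLUX_TOL:
            raise RuntimeError(f"refined model fails to grow under condition {i}")
    return m, log
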