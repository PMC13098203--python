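"""Universal-model curation: duplicate detection/merging, balance auditing
and patch application.

A reaction-database ("universal") model accumulates duplicate entries and
mass/charge-imbalanced reactions as it is compiled from many source
reconstructions.  This module finds duplicate metabolites (same compartment,
formula and charge plus a shared database identifier or an equal
canonicalized name) and duplicate reactions (identical stoichiometry up to
orientation), merges them while preserving gene rules and annotations,
audits elemental/charge balance across the model, and applies tabular
curation patches (protonation fixes, bound changes, reaction additions and
deletions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd
from cobra import Metabolite, Model, Reaction

from .model_core import (
    BalanceEntry,
    check_reaction_balance,
    get_flags,
    set_flags,
)

__all__ = [
    "DuplicateGroups",
    "MergeLog",
    "MergeRecord",
    "find_duplicates",
    "merge_duplicates",
    "BalanceReport",
    "audit_balance",
    "Patch",
    "PatchEdit",
    "apply_patch",
    "read_patch_tsv",
    "write_patch_tsv",
]


# ---------------------------------------------------------------------------
# duplicate detection
# ---------------------------------------------------------------------------


@dataclass
class DuplicateGroups:
    metabolite_groups: List[List[str]] = field(default_factory=list)
    reaction_groups: List[List[str]] = field(default_factory=list)
    metabolite_evidence: List[str] = field(default_factory=list)
    reaction_evidence: List[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.metabolite_groups or self.reaction_groups)


def _canonical_name(name: str) -> str:
    return "".join(ch for ch in (name or "").lower() if ch.isalnum())


def _annotation_ids(met: Metabolite) -> Set[Tuple[str, str]]:
    out: Set[Tuple[str, str]] = set()
    for db, vals in met.annotation.items():
        if isinstance(vals, str):
            vals = [vals]
        for v in vals:
            out.add((db, str(v)))
    return out


def _reaction_canon(stoich: Dict[str, float]) -> Tuple[Tuple[str, float], ...]:
    """Orientation-independent canonical form of a stoichiometry map."""
    fwd = tuple(sorted((m, round(c, 9)) for m, c in stoich.items()))
    rev = tuple(sorted((m, round(-c, 9)) for m, c in stoich.items()))
    return min(fwd, rev)


def find_duplicates(model: Model) -> DuplicateGroups:
    """Detect duplicate metabolites and reactions.

    Metabolites pair when they share compartment, formula and charge and
    additionally either a database identifier or a canonicalized name.
    Reactions pair when their stoichiometries are identical after
    normalizing orientation.  Groups are connected components of the pair
    relation.
    """
    groups = DuplicateGroups()

    g = nx.Graph()
    mets = list(model.metabolites)
    by_key: Dict[Tuple, List[Metabolite]] = {}
    for met in mets:
        key = (met.compartment, met.formula or "", met.charge)
        by_key.setdefault(key, []).append(met)
    pair_shared_annotation: Set[Tuple[str, str]] = set()
    for bucket in by_key.values():
        for i, a in enumerate(bucket):
            for b in bucket[i + 1:]:
                ann = bool(_annotation_ids(a) & _annotation_ids(b))
                name = (
                    _canonical_name(a.name) == _canonical_name(b.name)
                    and _canonical_name(a.name) != ""
                )
                if ann or name:
                    g.add_edge(a.id, b.id)
                    if ann:
                        pair_shared_annotation.add((a.id, b.id))
    for comp in nx.connected_components(g):
        group = sorted(comp)
        groups.metabolite_groups.append(group)
        shared = any(
            (x, y) in pair_shared_annotation or (y, x) in pair_shared_annotation
            for i, x in enumerate(group)
            for y in group[i + 1:]
        )
        groups.metabolite_evidence.append(
            "shared_annotation" if shared else "identical_formula_charge_name"
        )

    by_canon: Dict[Tuple, List[Reaction]] = {}
    for rxn in model.reactions:
        if len(rxn.metabolites) == 1:
            continue  # exchange pseudo-reactions never merge
        stoich = {m.id: c for m, c in rxn.metabolites.items()}
        by_canon.setdefault(_reaction_canon(stoich), []).append(rxn)
    for members in by_canon.values():
        if len(members) < 2:
            continue
        ids = sorted(r.id for r in members)
        fwd_forms = {
            tuple(sorted((m.id, round(c, 9)) for m, c in r.metabolites.items()))
            for r in members
        }
        groups.reaction_groups.append(ids)
        groups.reaction_evidence.append(
            "identical_stoichiometry" if len(fwd_forms) == 1
            else "sign_flipped_stoichiometry"
        )

    order = sorted(range(len(groups.metabolite_groups)),
                   key=lambda i: groups.metabolite_groups[i])
    groups.metabolite_groups = [groups.metabolite_groups[i] for i in order]
    groups.metabolite_evidence = [groups.metabolite_evidence[i] for i in order]
    order = sorted(range(len(groups.reaction_groups)),
                   key=lambda i: groups.reaction_groups[i])
    groups.reaction_groups = [groups.reaction_groups[i] for i in order]
    groups.reaction_evidence = [groups.reaction_evidence[i] for i in order]
    return groups


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


@dataclass
class MergeRecord:
    kept_id: str
    removed_ids: List[str]
    kind: str  # "metabolite" | "reaction"
    gpr_union_applied: bool = False
    annotations_merged: bool = False
    bounds_rule: str = ""


@dataclass
class MergeLog:
    records: List[MergeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def _union_annotations(target, sources) -> bool:
    changed = False
    for src in sources:
        for db, vals in src.annotation.items():
            if isinstance(vals, str):
                vals = [vals]
            existing = target.annotation.get(db)
            if existing is None:
                target.annotation[db] = list(vals) if len(vals) > 1 else vals[0]
                changed = True
            else:
                if isinstance(existing, str):
                    existing = [existing]
                merged = list(dict.fromkeys(list(existing) + list(vals)))
                if merged != existing:
                    target.annotation[db] = merged if len(merged) > 1 else merged[0]
                    changed = True
    return changed


def merge_duplicates(model: Model, groups: DuplicateGroups) -> Tuple[Model, MergeLog]:
    """Merge duplicate groups into a new model, keeping the smallest id.

    Metabolite merges rewrite every stoichiometry reference and union
    annotations.  Reaction merges orient all members to the kept member's
    direction, take the union of the feasible flux directions (min lower /
    max upper bound), OR-combine distinct gene rules and union annotations
    and flags.  Scanning the result again finds nothing.
    """
    all_ids = [mid for grp in groups.metabolite_groups for mid in grp]
    if len(all_ids) != len(set(all_ids)):
        raise ValueError("overlapping metabolite groups")
    all_rids = [rid for grp in groups.reaction_groups for rid in grp]
    if len(all_rids) != len(set(all_rids)):
        raise ValueError("overlapping reaction groups")

    m = model.copy()
    log = MergeLog()

    for group in groups.metabolite_groups:
        kept_id, *removed = sorted(group)
        kept = m.metabolites.get_by_id(kept_id)
        removed_mets = [m.metabolites.get_by_id(x) for x in removed]
        ann = _union_annotations(kept, removed_mets)
        for met in removed_mets:
            for rxn in list(met.reactions):
                coeff = rxn.metabolites[met]
                rxn.add_metabolites({met: -coeff, kept: coeff}, combine=True)
            m.remove_metabolites([met])
        log.records.append(MergeRecord(kept_id, removed, "metabolite",
                                       annotations_merged=ann))

    for group in groups.reaction_groups:
        kept_id, *removed = sorted(group)
        kept = m.reactions.get_by_id(kept_id)
        kept_stoich = tuple(sorted((x.id, round(c, 9))
                                   for x, c in kept.metabolites.items()))
        lbs, ubs = [kept.lower_bound], [kept.upper_bound]
        rules = []
        if kept.gene_reaction_rule.strip():
            rules.append(kept.gene_reaction_rule.strip())
        flags = set(get_flags(kept))
        removed_rxns = [m.reactions.get_by_id(x) for x in removed]
        for rxn in removed_rxns:
            stoich = tuple(sorted((x.id, round(c, 9))
                                  for x, c in rxn.metabolites.items()))
            if stoich == kept_stoich:
                lb, ub = rxn.lower_bound, rxn.upper_bound
            else:  # member written in the opposite direction
                lb, ub = -rxn.upper_bound, -rxn.lower_bound
            lbs.append(lb)
            ubs.append(ub)
            rule = rxn.gene_reaction_rule.strip()
            if rule and rule not in rules:
                rules.append(rule)
            flags |= get_flags(rxn)
        ann = _union_annotations(kept, removed_rxns)
        kept.lower_bound, kept.upper_bound = min(lbs), max(ubs)
        gpr_union = len(rules) > 1
        if rules:
            kept.gene_reaction_rule = (
                " or ".join(f"({r})" for r in rules) if gpr_union else rules[0]
            )
        set_flags(kept, flags)
        m.remove_reactions(removed_rxns, remove_orphans=True)
        log.records.append(MergeRecord(kept_id, removed, "reaction",
                                       gpr_union_applied=gpr_union,
                                       annotations_merged=ann,
                                       bounds_rule="direction_union"))
    return m, log


# ---------------------------------------------------------------------------
# balance audit
# ---------------------------------------------------------------------------


@dataclass
class BalanceReport:
    entries: List[BalanceEntry]

    @property
    def n_total(self) -> int:
        return len(self.entries)

    def count(self, classification: str) -> int:
        return sum(1 for e in self.entries if e.classification == classification)

    @property
    def imbalanced_fraction(self) -> float:
        """Imbalanced share among non-exempt, known-formula reactions."""
        considered = [e for e in self.entries
                      if e.classification not in ("exempt", "unknown_formula")]
        if not considered:
            return 0.0
        bad = [e for e in considered if e.classification != "balanced"]
        return len(bad) / len(considered)

    def imbalanced_ids(self) -> List[str]:
        return [e.reaction_id for e in self.entries
                if e.classification in ("proton_imbalanced", "charge_imbalanced",
                                        "mass_imbalanced")]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append({
                "reaction_id": e.reaction_id,
                "classification": e.classification,
                "element_deltas": ";".join(
                    f"{el}:{d:g}" for el, d in sorted(e.element_delta.items())
                ),
                "charge_delta": e.charge_delta,
            })
        return pd.DataFrame(rows, columns=["reaction_id", "classification",
                                           "element_deltas", "charge_delta"])


def audit_balance(model: Model) -> BalanceReport:
    """One balance entry per reaction plus summary fractions."""
    return BalanceReport([check_reaction_balance(rxn, model)
                          for rxn in model.reactions])


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------

_PATCH_OPS = {
    "set_stoichiometry", "set_charge", "set_formula", "set_bounds",
    "delete_reaction", "add_reaction",
}


@dataclass
class PatchEdit:
    """One tabular curation edit.

    ``op`` selects the edit; ``target`` names the reaction or metabolite;
    the free-form fields carry the operands (see :func:`apply_patch`).
    """

    op: str
    target: str
    metabolite: Optional[str] = None
    value: Optional[float] = None
    formula: Optional[str] = None
    lower: Optional[float] = None
    upper: Optional[float] = None
    stoichiometry: Optional[Dict[str, float]] = None
    gpr: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.op not in _PATCH_OPS:
            raise ValueError(f"unknown patch op {self.op!r}")


@dataclass
class Patch:
    edits: List[PatchEdit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edits)

    @staticmethod
    def delete_reactions(ids: Iterable[str]) -> "Patch":
        return Patch([PatchEdit("delete_reaction", rid) for rid in ids])


def apply_patch(model: Model, patch: Patch) -> Model:
    """Apply a curation patch to a copy of *model*.

    Edits apply in order and are idempotent: re-applying the same patch to
    the result changes nothing.  A ``delete_reaction`` of an id that is
    already gone is a no-op (that is what makes deletion idempotent); every
    other dangling reference raises, naming the edit index.
    """
    m = model.copy()
    for i, e in enumerate(patch.edits):
        try:
            _apply_edit(m, e)
        except KeyError as exc:
            raise KeyError(f"patch edit {i} ({e.op} {e.target}): {exc}") from None
    return m


def _apply_edit(m: Model, e: PatchEdit) -> None:
    if e.op == "delete_reaction":
        if e.target in m.reactions:
            m.remove_reactions([m.reactions.get_by_id(e.target)],
                               remove_orphans=True)
        return
    if e.op == "add_reaction":
        if e.stoichiometry is None:
            raise KeyError("add_reaction requires a stoichiometry")
        if e.target in m.reactions:
            m.remove_reactions([m.reactions.get_by_id(e.target)])
        rxn = Reaction(e.target, name=e.name or e.target)
        rxn.lower_bound = e.lower if e.lower is not None else 0.0
        rxn.upper_bound = e.upper if e.upper is not None else 1000.0
        m.add_reactions([rxn])
        missing = [mid for mid in e.stoichiometry if mid not in m.metabolites]
        if missing:
            raise KeyError(f"metabolites missing: {missing}")
        rxn.add_metabolites({m.metabolites.get_by_id(k): v
                             for k, v in e.stoichiometry.items()})
        if e.gpr:
            rxn.gene_reaction_rule = e.gpr
        return
    if e.op == "set_bounds":
        if e.target not in m.reactions:
            raise KeyError(f"reaction {e.target!r} not in model")
        rxn = m.reactions.get_by_id(e.target)
        rxn.lower_bound, rxn.upper_bound = float(e.lower), float(e.upper)
        return
    if e.op == "set_stoichiometry":
        if e.target not in m.reactions:
            raise KeyError(f"reaction {e.target!r} not in model")
        if e.metabolite not in m.metabolites:
            raise KeyError(f"metabolite {e.metabolite!r} not in model")
        rxn = m.reactions.get_by_id(e.target)
        met = m.metabolites.get_by_id(e.metabolite)
        current = rxn.metabolites.get(met, 0.0)
        rxn.add_metabolites({met: float(e.value) - current}, combine=True)
        return
    if e.op == "set_charge":
        if e.target not in m.metabolites:
            raise KeyError(f"metabolite {e.target!r} not in model")
        m.metabolites.get_by_id(e.target).charge = int(e.value)
        return
    if e.op == "set_formula":
        if e.target not in m.metabolites:
            raise KeyError(f"metabolite {e.target!r} not in model")
        m.metabolites.get_by_id(e.target).formula = e.formula or ""
        return
    raise KeyError(f"unhandled op {e.op!r}")


# ---------------------------------------------------------------------------
# patch TSV round-trip
# ---------------------------------------------------------------------------

_PATCH_COLUMNS = ["op", "target", "metabolite", "value", "formula",
                  "lower", "upper", "stoichiometry", "gpr", "name"]


def _stoich_to_str(stoich: Optional[Dict[str, float]]) -> str:
    if not stoich:
        return ""
    return ";".join(f"{k}:{v:g}" for k, v in sorted(stoich.items()))


def _stoich_from_str(text: str) -> Optional[Dict[str, float]]:
    text = (text or "").strip()
    if not text:
        return None
    out: Dict[str, float] = {}
    for item in text.split(";"):
        key, _, val = item.rpartition(":")
        out[key] = float(val)
    return out


def write_patch_tsv(patch: Patch, path) -> None:
    rows = []
    for e in patch.edits:
        rows.append({
            "op": e.op, "target": e.target, "metabolite": e.metabolite or "",
            "value": "" if e.value is None else e.value,
            "formula": e.formula or "",
            "lower": "" if e.lower is None else e.lower,
            "upper": "" if e.upper is None else e.upper,
            "stoichiometry": _stoich_to_str(e.stoichiometry),
            "gpr": e.gpr, "name": e.name,
        })
    pd.DataFrame(rows, columns=_PATCH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_patch_tsv(path) -> Patch:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"op", "target"} - set(df.columns)
    if missing:
        raise ValueError(f"patch file lacks columns: {sorted(missing)}")
    edits = []
    for _, row in df.iterrows():
        edits.append(PatchEdit(
            op=row["op"], target=row["target"],
            metabolite=row.get("metabolite") or None,
            value=float(row["value"]) if row.get("value", "") != "" else None,
            formula=row.get("formula") or None,
            lower=float(row["lower"]) if row.get("lower", "") != "" else None,
            upper=float(row["upper"]) if row.get("upper", "") != "" else None,
            stoichiometry=_stoich_from_str(row.get("stoichiometry", "")),
            gpr=row.get("gpr", ""), name=row.get("name", ""),
        ))
    return Patch(edits)
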