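"""Comparative simulation suite.

The analyses a strain-cohort study runs on refined models: chemically
defined medium (CDM) construction with C-mol-normalized carbon bounds,
fermentation profiling under mixed-acid and homolactate regimes, the
pyruvate-formate-lyase (PFL) bound scan, carbon-source ATP yields,
leave-one-out nutrient essentiality with the 10 % growth rule, growth on a
casein oligopeptide as amino-acid source, catabolic-capacity probes,
transporter restriction experiments, and cross-feeding screens.

Conventions follow the cohort-study setup: every medium component is capped
at 1 mmol gDW^-1 h^-1 except the carbon source (bounded at a C-mol
equivalent of 20 mmol gDW^-1 h^-1 glucose, i.e. 120/carbons), water and
protons are unconstrained, and simulations use parsimonious FBA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from cobra import Metabolite, Model, Reaction

from .lp_engine import (
    FLUX_TOL,
    SimulationCondition,
    apply_condition,
    ensure_atpm,
    max_atp_yield,
    solve_fba,
    solve_pfba,
)
from .model_core import base_metabolite_id, classify_reaction

__all__ = [
    "CDMSpec",
    "build_cdm",
    "homolactate_overrides",
    "FermentationProfile",
    "fermentation_profile",
    "PFLScan",
    "pfl_scan",
    "EssentialityProfile",
    "essentiality_scan",
    "CaseinSpec",
    "CaseinAttachment",
    "attach_casein",
    "detach_casein",
    "casein_condition",
    "catabolic_capacity",
    "restrict_transport",
    "CrossFeedMatrix",
    "crossfeed_screen",
    "MAIN_PRODUCT_EXCHANGES",
    "ESSENTIALITY_THRESHOLD",
]

#: main fermentation products; everything else secreted is a byproduct
MAIN_PRODUCT_EXCHANGES = (
    "EX_lac__D_e", "EX_for_e", "EX_ac_e", "EX_etoh_e", "EX_co2_e",
)
#: relative growth below this marks a left-out component as essential
ESSENTIALITY_THRESHOLD = 0.10
#: exchanges never reported as fermentation products
_NON_PRODUCTS = {"EX_h_e", "EX_h2o_e"}

#: id of the pyruvate-formate-lyase reaction in the packaged namespace
PFL_ID = "PFL"
PDH_ID = "PDH"


# ---------------------------------------------------------------------------
# media
# ---------------------------------------------------------------------------


@dataclass
class CDMSpec:
    """Chemically defined medium template.

    ``components`` lists non-carbon exchange ids with their class (amino
    acid, vitamin, mineral, base, nucleobase); each is bounded at
    ``component_uptake`` (default 1 mmol gDW^-1 h^-1).  The single carbon
    source is bounded at ``carbon_cmol_budget / carbons`` so every substrate
    supplies the same carbon flux (default budget: 120 C-mmol gDW^-1 h^-1,
    the C-mol equivalent of 20 mmol glucose).
    """

    components: List[Tuple[str, str]]
    free: Set[str] = field(default_factory=set)
    carbon_source: str = "EX_glc__D_e"
    carbon_atoms: int = 6
    component_uptake: float = 1.0
    carbon_cmol_budget: float = 120.0

    def amino_acid_exchanges(self) -> List[str]:
        return [ex for ex, cls in self.components if cls == "amino_acid"]

    def component_exchanges(self) -> List[str]:
        return [ex for ex, _ in self.components]


def build_cdm(
    spec: CDMSpec,
    substrate: Optional[str] = None,
    carbons: Optional[int] = None,
) -> SimulationCondition:
    """Build a simulation condition from a CDM template.

    With no arguments the spec's default carbon source is used; passing
    ``substrate``/``carbons`` swaps the carbon source while keeping the
    C-mol budget (glucose -> 20, lactose -> 10, ribose -> 24, ...).
    """
    substrate = substrate or spec.carbon_source
    carbons = carbons if carbons is not None else spec.carbon_atoms
    if carbons < 1:
        raise ValueError("carbons must be >= 1")
    medium = {ex: spec.component_uptake for ex, _ in spec.components
              if ex != substrate}
    medium[substrate] = spec.carbon_cmol_budget / carbons
    return SimulationCondition(medium=medium,
                               unconstrained_exchanges=set(spec.free))


def homolactate_overrides(cond: SimulationCondition,
                          pfl_bound: float = 0.1,
                          close_pdh: bool = True) -> SimulationCondition:
    """Constrain PFL (default 0.1 mmol gDW^-1 h^-1, the homolactate
    regime); optionally close pyruvate dehydrogenase as well."""
    out = cond.with_override(PFL_ID, 0.0, pfl_bound)
    if close_pdh:
        out = out.with_override(PDH_ID, 0.0, 0.0)
    return out


# ---------------------------------------------------------------------------
# fermentation profiling
# ---------------------------------------------------------------------------


@dataclass
class FermentationProfile:
    growth_rate: float
    products: Dict[str, float]  # exchange id -> secretion flux (> tol)
    growing: bool

    def main_products(self) -> Dict[str, float]:
        return {k: v for k, v in self.products.items()
                if k in MAIN_PRODUCT_EXCHANGES}

    def byproducts(self) -> Dict[str, float]:
        return {k: v for k, v in self.products.items()
                if k not in MAIN_PRODUCT_EXCHANGES}


def fermentation_profile(model: Model, cond: SimulationCondition) -> FermentationProfile:
    """Parsimonious growth simulation; secreted products are the positive
    exchange fluxes above tolerance (water/protons excluded)."""
    sol = solve_pfba(model, cond)
    if not sol.optimal:
        return FermentationProfile(0.0, {}, False)
    products = {
        rid: round(v, 6)
        for rid, v in sol.fluxes.items()
        if rid.startswith("EX_") and rid not in _NON_PRODUCTS and v > FLUX_TOL
    }
    return FermentationProfile(round(sol.objective_value, 6), products,
                               sol.objective_value > FLUX_TOL)


# ---------------------------------------------------------------------------
# PFL scan
# ---------------------------------------------------------------------------


@dataclass
class PFLScan:
    bounds: List[float]
    growth: List[float]
    product_fluxes: pd.DataFrame  # index: bound, columns: product exchanges


_PFL_PRODUCTS = ("EX_lac__D_e", "EX_for_e", "EX_ac_e", "EX_etoh_e")


def pfl_scan(model: Model, cond: SimulationCondition,
             grid: Optional[Sequence[float]] = None) -> PFLScan:
    """Growth and product formation across a grid of PFL upper bounds
    (default 25 log-spaced points over 0.1-60 mmol gDW^-1 h^-1)."""
    if PFL_ID not in model.reactions:
        raise KeyError(f"{PFL_ID!r} absent from model {model.id!r}")
    if grid is None:
        grid = np.geomspace(0.1, 60.0, 25)
    bounds = [float(b) for b in grid]
    growth: List[float] = []
    rows = []
    for b in bounds:
        sol = solve_pfba(model, cond.with_override(PFL_ID, 0.0, b))
        growth.append(round(sol.objective_value, 6) if sol.optimal else 0.0)
        rows.append({p: round(max(sol.flux(p), 0.0), 6) if sol.optimal else 0.0
                     for p in _PFL_PRODUCTS})
    return PFLScan(bounds, growth,
                   pd.DataFrame(rows, index=bounds, columns=list(_PFL_PRODUCTS)))


# ---------------------------------------------------------------------------
# essentiality
# ---------------------------------------------------------------------------


@dataclass
class EssentialityProfile:
    reference_growth: float
    relative_growth: Dict[str, float]  # component exchange -> growth ratio

    def essential(self) -> List[str]:
        return sorted(k for k, v in self.relative_growth.items()
                      if v < ESSENTIALITY_THRESHOLD)


def essentiality_scan(model: Model, cond: SimulationCondition,
                      components: Optional[Sequence[str]] = None) -> EssentialityProfile:
    """Leave-one-out essentiality over medium components.

    Each component's exchange is closed in both directions in turn; a
    component whose exchange the model lacks trivially scores relative
    growth 1 (no phantom essentiality).  Essential = relative growth below
    10 % of the reference.
    """
    if components is None:
        components = sorted(cond.medium)
    ref = solve_pfba(model, cond)
    if not ref.optimal or ref.objective_value <= FLUX_TOL:
        raise ValueError("reference condition does not support growth")
    ref_mu = ref.objective_value
    rel: Dict[str, float] = {}
    for ex in components:
        if ex not in model.reactions:
            rel[ex] = 1.0
            continue
        left_out = cond.without_component(ex).with_override(ex, 0.0, 0.0)
        sol = solve_fba(model, left_out)
        mu = sol.objective_value if sol.optimal else 0.0
        rel[ex] = round(max(mu, 0.0) / ref_mu, 6)
    return EssentialityProfile(round(ref_mu, 6), rel)


# ---------------------------------------------------------------------------
# casein growth
# ---------------------------------------------------------------------------


@dataclass
class CaseinSpec:
    """Average casein oligopeptide.

    ``aa_fractions`` maps amino-acid base ids to residue fractions (sum 1;
    cysteine-poor by default).  The peptide is represented at
    ``residue_scale`` residues per molecule so its formula stays integral;
    ``peptide_uptake`` is the molar uptake bound (in residue-mol it equals
    ``peptide_uptake * residue_scale``).
    """

    aa_fractions: Dict[str, float]
    peptide_uptake: float
    residue_scale: int = 1000
    metabolite_base: str = "cspep"

    def __post_init__(self) -> None:
        total = sum(self.aa_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"amino-acid fractions sum to {total!r}, not 1")
        if any(f < 0 for f in self.aa_fractions.values()):
            raise ValueError("negative amino-acid fraction")


@dataclass
class CaseinAttachment:
    exchange_id: str
    transport_id: str
    hydrolysis_id: str
    metabolite_ids: List[str]

    @property
    def reaction_ids(self) -> List[str]:
        return [self.exchange_id, self.transport_id, self.hydrolysis_id]


def attach_casein(model: Model, spec: CaseinSpec) -> Tuple[Model, CaseinAttachment]:
    """Add casein-peptide machinery to a copy of *model*.

    Creates the peptide species (extracellular and cytosolic), an exchange,
    an ATP-driven oligopeptide uptake and an intracellular hydrolysis
    releasing the free amino acids in the spec's proportions.
    """
    from .model_core import formula_to_string, parse_formula

    m = model.copy()
    base = spec.metabolite_base
    scale = spec.residue_scale
    residues = {aa: spec.aa_fractions[aa] * scale for aa in spec.aa_fractions}

    missing = [aa for aa, n in residues.items()
               if n > 0 and f"{aa}_c" not in m.metabolites]
    if missing:
        raise KeyError(f"amino acids missing from model: {sorted(missing)}")

    totals: Dict[str, float] = {}
    charge = 0.0
    for aa, n in residues.items():
        if n <= 0:
            continue
        met = m.metabolites.get_by_id(f"{aa}_c")
        counts = parse_formula(met.formula) or {}
        for el, c in counts.items():
            totals[el] = totals.get(el, 0.0) + n * c
        charge += n * (met.charge or 0)
    totals["H"] = totals.get("H", 0.0) - 2 * (scale - 1)
    totals["O"] = totals.get("O", 0.0) - (scale - 1)
    formula = formula_to_string({k: int(round(v)) for k, v in totals.items()})

    met_ids = []
    for comp in ("e", "c"):
        mid = f"{base}_{comp}"
        if mid in m.metabolites:
            raise ValueError(f"metabolite {mid!r} already present")
        met = Metabolite(mid, name="Casein oligopeptide", compartment=comp,
                         formula=formula, charge=int(round(charge)))
        m.add_metabolites([met])
        met_ids.append(mid)

    ex = Reaction(f"EX_{base}_e", name="Casein peptide exchange",
                  lower_bound=-1000.0, upper_bound=1000.0)
    # uptake carries no energy cost so that the amino-acid composition skew
    # is the only difference between peptide and free-amino-acid supply
    tr = Reaction(f"{base.upper()}t", name="Casein peptide uptake",
                  lower_bound=0.0, upper_bound=1000.0)
    hy = Reaction(f"{base.upper()}hyd", name="Casein peptide hydrolysis",
                  lower_bound=0.0, upper_bound=1000.0)
    m.add_reactions([ex, tr, hy])
    ex.add_metabolites({m.metabolites.get_by_id(f"{base}_e"): -1})
    tr.add_metabolites({m.metabolites.get_by_id(f"{base}_e"): -1.0,
                        m.metabolites.get_by_id(f"{base}_c"): 1.0})
    hy_stoich: Dict[str, float] = {f"{base}_c": -1.0, "h2o_c": -(scale - 1.0)}
    for aa, n in residues.items():
        if n > 0:
            hy_stoich[f"{aa}_c"] = hy_stoich.get(f"{aa}_c", 0.0) + n
    hy.add_metabolites({m.metabolites.get_by_id(k): v for k, v in hy_stoich.items()})

    return m, CaseinAttachment(ex.id, tr.id, hy.id, met_ids)


def detach_casein(model: Model, attachment: CaseinAttachment) -> Model:
    m = model.copy()
    m.remove_reactions([m.reactions.get_by_id(r) for r in attachment.reaction_ids
                        if r in m.reactions])
    m.remove_metabolites([m.metabolites.get_by_id(x)
                          for x in attachment.metabolite_ids
                          if x in m.metabolites])
    return m


def casein_condition(cdm: CDMSpec, spec: CaseinSpec,
                     substrate: str = "EX_lcts_e",
                     carbons: int = 12,
                     exchange_id: Optional[str] = None) -> SimulationCondition:
    """Milk-like condition: free amino acids replaced by the casein peptide,
    lactose as default carbon source."""
    cond = build_cdm(cdm, substrate=substrate, carbons=carbons)
    for ex in cdm.amino_acid_exchanges():
        cond = cond.without_component(ex)
    ex_id = exchange_id or f"EX_{spec.metabolite_base}_e"
    return cond.with_uptake(ex_id, spec.peptide_uptake)


# ---------------------------------------------------------------------------
# catabolic capacity / transport restriction
# ---------------------------------------------------------------------------


def catabolic_capacity(model: Model, nutrient_exchange: str,
                       base_exchanges: Sequence[str] = (),
                       uptake: float = 1.0) -> Tuple[bool, float]:
    """Can the strain extract ATP from a nutrient on a minimal base medium?

    The objective is the ATP-maintenance reaction; capability requires both
    a positive ATP optimum and actual uptake of the nutrient.  A missing
    nutrient exchange is itself incapacity (no transport, no catabolism).
    """
    if nutrient_exchange not in model.reactions:
        return False, 0.0
    m = model.copy()
    ensure_atpm(m)
    medium = {ex: 1.0 for ex in base_exchanges if ex in m.reactions}
    medium[nutrient_exchange] = uptake
    cond = SimulationCondition(
        medium=medium,
        unconstrained_exchanges={"EX_h_e", "EX_h2o_e"},
        objective_override="ATPM",
    )
    sol = solve_pfba(m, cond)
    if not sol.optimal:
        return False, 0.0
    atp = round(sol.objective_value, 6)
    taken = -sol.flux(nutrient_exchange)
    return bool(atp > FLUX_TOL and taken > FLUX_TOL), atp


def restrict_transport(model: Model, metabolite_base: str, keep: str) -> Model:
    """Close every e<->c transport route for a metabolite except *keep*.

    Mirrors the transporter-attribution experiment: force uptake through a
    single named transporter and see whether growth survives.  If *keep* is
    absent from the model every route closes (the strain simply lacks that
    transporter).  *keep* naming a reaction that does not move the
    metabolite is a bug and raises.
    """
    m = model.copy()
    movers = [r for r in m.reactions
              if classify_reaction(r) == "transport"
              and metabolite_base in {
                  base_metabolite_id(met.id, met.compartment)
                  for met in r.metabolites
              }]
    mover_ids = {r.id for r in movers}
    if keep in m.reactions and keep not in mover_ids:
        raise ValueError(
            f"{keep!r} does not transport {metabolite_base!r} "
            f"(transporters: {sorted(mover_ids)})"
        )
    for r in movers:
        if r.id != keep:
            r.bounds = (0.0, 0.0)
    return m


# ---------------------------------------------------------------------------
# cross-feeding
# ---------------------------------------------------------------------------


@dataclass
class CrossFeedMatrix:
    produced: pd.DataFrame   # strain x product booleans
    consumed: pd.DataFrame   # strain x product booleans
    uptake_flux: pd.DataFrame  # strain x product floats

    def consumer_fraction(self, product: str) -> float:
        col = self.consumed[product]
        return float(col.mean()) if len(col) else 0.0


def crossfeed_screen(models: Sequence[Model], cond: SimulationCondition,
                     products: Sequence[str]) -> CrossFeedMatrix:
    """Test which strains produce and which can consume each product.

    Production comes from the baseline fermentation profile.  Consumption
    is probed by allowing uptake of the product at 1 mmol gDW^-1 h^-1 (2 if
    it already is a medium component); a strain consumes the product when
    the probed solution takes it up above tolerance *and* grows faster than
    baseline.
    """
    prod_rows, cons_rows, flux_rows = [], [], []
    ids = []
    for model in models:
        ids.append(model.id)
        baseline = fermentation_profile(model, cond)
        prod_rows.append({p: p in baseline.products for p in products})
        cons, flux = {}, {}
        for p in products:
            if p not in model.reactions:
                cons[p], flux[p] = False, 0.0
                continue
            bound = 2.0 if p in cond.medium else 1.0
            sol = solve_pfba(model, cond.with_uptake(p, bound))
            if not sol.optimal:
                cons[p], flux[p] = False, 0.0
                continue
            taken = -sol.flux(p)
            grew = sol.objective_value > baseline.growth_rate + FLUX_TOL
            cons[p] = bool(taken > FLUX_TOL and grew)
            flux[p] = round(max(taken, 0.0), 6) if cons[p] else 0.0
        cons_rows.append(cons)
        flux_rows.append(flux)
    produced = pd.DataFrame(prod_rows, index=ids, columns=list(products))
    consumed = pd.DataFrame(cons_rows, index=ids, columns=list(products))
    uptake = pd.DataFrame(flux_rows, index=ids, columns=list(products))
    return CrossFeedMatrix(produced, consumed, uptake)
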