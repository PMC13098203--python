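# Methods

## Scope

strainforge implements a high-throughput workflow for building, curating
and comparing strain-specific genome-scale metabolic models (GEMs) of
closely related bacteria, of the kind used to survey hundreds of
*Lactococcus lactis* / *L. cremoris* dairy isolates: curation of a
universal reaction-database model, refinement of homology-carved draft
strain models, pan-model-level discovery of energy-generating cycles, and
a comparative flux-balance simulation suite (fermentation modes,
carbon-source ATP yields, nutrient essentiality, growth on casein,
cross-feeding). Everything is exercisable end to end on a packaged,
fully balanced toy universe.

## Constraint-based core

Simulations are flux balance analysis (FBA) and parsimonious FBA (pFBA)
over cobrapy models with the GLPK backend, single-threaded and
deterministic. pFBA fixes the objective at its FBA optimum with a relative
slack of 1e-6 and minimizes total absolute flux; the reported objective
value is the FBA optimum. The "carries flux" tolerance is 1e-6
mmol gDW⁻¹ h⁻¹ everywhere (pruning, secretion calls, energy-cycle
detection, consumption calls); unconstrained exchanges (water, protons)
open to ±1000. A strain counts as non-growing under a perturbed condition
when its growth rate falls below 10 % of the reference rate. The rate
alone is used for this call: under a fixed substrate bound, rate and yield
are proportional.

Media are `SimulationCondition` objects: per-exchange maximum uptake
magnitudes, an unconstrained set, and explicit reaction-bound overrides
applied last. The chemically defined medium (CDM) convention is 1
mmol gDW⁻¹ h⁻¹ for every component except the single carbon source, which
is bounded at a C-mol equivalent of 20 mmol gDW⁻¹ h⁻¹ glucose
(120/carbons) so that every substrate supplies equal carbon flux. A
missing medium component is reported, not fatal; a dangling bound override
raises, because overrides are deliberate experimental interventions.

## Universal-model curation

Duplicate metabolites group when they share compartment, formula and
charge plus either a database identifier or an equal canonicalized name
(lowercased, non-alphanumerics stripped — the raw name field is too
brittle to compare directly). Duplicate reactions group on identical
stoichiometry after orientation normalization (the lexicographically
smaller of the map and its negation). Merging keeps the lexicographically
smallest id (determinism), rewrites references, unions annotations,
OR-combines distinct gene rules, and takes the union of feasible flux
directions so that merging never removes a capability either duplicate
had. Balance auditing classifies each reaction as balanced,
proton-imbalanced (H and charge off by the same amount), charge-imbalanced,
mass-imbalanced, exempt (boundary/biomass) or unknown-formula. `R` and `X`
are legal pseudo-elements, so generic-group chemistry audits like ordinary
chemistry; formulas with parentheses or other unparsable syntax classify
as unknown rather than aborting the audit. Protonation-state fixes arrive
as tabular patches (idempotent edits), not from live database queries.

## Draft-strain refinement

Draft models stand for the output of a score-based carving step; gap-filled
reactions (added without genomic evidence) carry a flag inferred at ingest
from an empty gene rule plus a non-positive carving score, with a
caller-supplied allowlist for genuinely spontaneous reactions. Refinement
runs biomass installation → gap-fill pruning → score-based restoration:
the biomass first so pruning optimizes the final objective, restoration
last so restored dead ends can never be pruned. Pruning takes one pFBA
solution per gap-fill condition and removes flux-less gap-filled metabolic
reactions; a flux-less gap-filled transporter survives if any metabolite
it moves participates in a gene-bearing reaction; exchanges left without
any non-exchange neighbor are dropped; growth optima are asserted
unchanged to 1e-6. Judging "carries flux" on a single parsimonious
solution is alternate-optima-blind; that caveat is accepted rather than
mitigated with flux-variability analysis, matching the workflow being
modeled. Restoration copies every positively scored universal reaction the
draft lacks, with genes and metabolites, flagged `restored_disconnected` —
such reactions rarely carry flux but are genomic evidence and count in
presence/absence comparisons.

## Pan-model curation

All strain reactions compile into a pan-model (union network plus
strain × reaction presence matrix). Energy-generating cycles are probed by
closing every exchange and maximizing, one at a time, a set of currency
dissipation reactions (ATP, GTP, NADH, NADPH, FADH2 hydrolysis/oxidation
and transmembrane proton-gradient dissipation — shipped as a data table,
not code, for namespace portability; currencies whose species a model
lacks report zero). Any positive optimum is thermodynamically impossible
and is reported with the reactions active in a parsimonious solution.
Transport-variant detection groups transporters that become
stoichiometrically identical after deleting protons — the canonical cause
of such cycles. Which variant to keep is a human decision delivered as a
patch; the tool only detects and reports.

## Simulation suite

Fermentation profiles are the positive exchange fluxes (water and protons
excluded) of a pFBA growth solution; lactate, formate, acetate, ethanol
and CO2 are "main products", everything else a byproduct. The
homolactate regime caps pyruvate-formate lyase at 0.1 mmol gDW⁻¹ h⁻¹ (and
closes pyruvate dehydrogenase); the PFL scan sweeps the upper bound over
25 log-spaced points in 0.1–60 mmol gDW⁻¹ h⁻¹. Leave-one-out essentiality
closes one component exchange at a time; a component the model cannot
exchange scores relative growth 1 (no phantom essentiality). ATP yields
switch the objective to the ATP maintenance reaction
(ATP + H₂O → ADP + Pi + H⁺, installed if absent) on a substrate-only
medium and normalize by carbon actually taken up. Catabolic capacity asks
for positive ATP *and* positive uptake on a minimal base medium.
Cross-feeding allows uptake of a candidate product at 1 mmol gDW⁻¹ h⁻¹
(2 if already in the medium) and calls consumption when uptake exceeds
tolerance and growth strictly increases.

Growth on milk replaces the free amino acids by a single average casein
oligopeptide plus uptake and intracellular hydrolysis reactions. The
peptide is represented at a fixed scale of 1000 residues per molecule so
its polymerized formula stays integral; hydrolysis releases the free amino
acids in the spec's fractions (cysteine 0.003 by default) plus the
condensation water. The default uptake bound gives residue-supply parity
with the summed free-amino-acid bounds of the CDM, and uptake is modeled
without an energy cost, so the composition skew — casein's low cysteine
versus the 5 % cysteine share of the biomass amino acids — is the *only*
difference between the two amino-acid sources. That is what makes the
relief experiment exact: adding free cysteine at the CDM bound restores
the free-amino-acid optimum to numerical precision, and the casein growth
rate of a cysteine auxotroph equals the closed form
f_cys,casein × residue_supply / c_cys,biomass.

## Cohort comparison

Reaction presence/absence feeds Jaccard (default) or Hamming distances via
scipy's pdist/squareform and average-linkage (default) hierarchical
clustering; neither metric nor linkage is canonical for this analysis, so
both are configurable. Strains are processed in id order, making the
dendrogram and its k-cuts invariant under input permutation.

## The toy universe

The fixture generator builds a ~96-reaction universal model whose every
non-boundary reaction is elementally and charge balanced (lumped steps are
sums of balanced textbook reactions, using BiGG-convention formulas and
charges). It encodes the pathway architecture the analyses need:

* PTS glucose uptake; glycolysis lumps with one ATP and one NADH per
  triose phosphate; the pyruvate node (lactate dehydrogenase irreversible
  toward lactate, formate lyase, dehydrogenase) with the acetate (+1 ATP)
  and two-NADH ethanol branches. Mixed-acid fermentation therefore nets
  exactly 3 ATP per glucose and homolactate exactly 2 — the anchors the
  LP tests pin.
* Galactose via PTS + tagatose-6-phosphate split, or permease + a Leloir
  lump that carries one extra ATP-hydrolysis equivalent for UDP-glucose
  turnover — hence a one-ATP yield separation between the routes. Lactose
  routes pair with the galactose routes as in the *lac* operon (PTS +
  phospho-β-galactosidase needs the tagatose pathway; permease +
  β-galactosidase needs Leloir), so lactose capability emerges from the
  profile rather than being set directly.
* Maltose by PTS or ABC import; xylose and ribose through xylulokinase /
  phosphoketolase, with a single non-energy-conserving hydrolysis lump
  standing in for the nucleotide-loop ribose route (growth stays possible
  without phosphoketolase, at strictly lower ATP yield).
* Sulfate assimilation (8-electron reduction lump) feeding
  cysteine-from-serine; methionine from cysteine; toggleable leucine
  synthesis; an arginine-deiminase lump (+1 ATP); citrate lyase with
  oxaloacetate decarboxylation.
* Fermentation acids leave by 1-proton symport; a reversible F1F0-type
  ATPase closes the proton books. The clean network has no
  energy-generating cycle (proved by the closed-exchange probes), but an
  injected transport variant with deviant proton stoichiometry plus the
  ATPase forms a compact, hand-verifiable ATP-from-nothing loop — the
  exact artifact the pan-curation hunts. A side effect of real membrane
  energetics in a toy: the arginine-deiminase ATP optimum on a minimal
  medium is 1.5 rather than the lump's nominal 1.0, because the ATPase
  can import medium protons; the capability call is unaffected.
* A generic biomass (with a trace iron requirement) on the universal
  model, and an organism-specific biomass without it — iron essentiality
  flips on installation. Cysteine is exactly 5 % of the biomass amino
  acids; the growth-associated maintenance is 72 mmol ATP per gDW, which
  puts mixed-acid growth near 0.8 h⁻¹ at the 20 mmol glucose bound.

Strains derive from a 12-flag pathway profile; deleted pathways take their
orphaned genes along. The generator emits a carving-style score table
(positive exactly for kept gene-bearing reactions plus any withheld ones),
can inject gene-less gap-filled reactions drawn from the strain's own
removed metabolic pool (guaranteed flux-less on the glucose medium used
for pruning), and can withhold a two-step gene-evidenced dead-end pathway
to exercise restoration. Cohorts split into a plant-associated class
(pentose-competent, Leloir/permease lactose route) and a dairy-associated
class (tagatose route, no pentose catabolism, partially missing maltose
PTS), which is what makes k=2 clustering on reaction content recover the
class labels exactly.

The toy CDM contains the four amino acids, sulfate, iron, phosphate,
ammonium and glucose. Two deliberate departures from the full-size
organism setup: phosphate appears explicitly because the biomass drains a
phosphorylated precursor, and the leucine bound binds for leucine
auxotrophs (amino acids are otherwise in surplus) so that amino-acid
cross-feeding benefit is expressible in a four-amino-acid world.

## What the fixtures do and do not show

The toy universe makes every contract exactly checkable: known ground
truth for duplicates, gap fills, withheld reactions, cycle variants and
class labels, and hand-derivable ATP accounting. Passing these tests shows
the machinery is correct, deterministic and self-consistent. It does not
show that real CarveMe output obeys the same assumptions: real universal
models carry thousands of unknown-formula metabolites, GPRs of very
different quality, alternate optima that make single-solution flux calls
less stable, and media whose component list dwarfs the toy CDM. Runs on
real deposited cohorts should treat the packaged defaults (medium table,
casein composition, currency list) as templates to be replaced by the
study's own tables.

## Numerical choices

GLPK, single-threaded, default scaling; reported values rounded to six
decimals in outputs. pFBA objective-fixing slack 1e-6 relative; flux
tolerance 1e-6; steady-state residuals of returned solutions bounded by
1e-6. Duplicate and variant normalization round coefficients to nine
decimals. Tie-breaks are lexicographic (kept ids in merges) or id-order
(clustering input), so every pipeline stage is reproducible to the byte:
regenerating a fixture or refining the same draft twice yields identical
SBML files.
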