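# strainforge

Curation, refinement and comparative flux-balance simulation of
strain-specific genome-scale metabolic models (GEMs).

When hundreds of bacterial isolates of one species are reconstructed by
carving strain models out of a universal reaction database with
homology-derived reaction scores, the raw drafts are not simulation-ready:
the universal model carries duplicate entries and mass/charge-imbalanced
reactions, the drafts carry gap-filled reactions without genomic evidence
and miss gene-evidenced reactions dropped for lack of connectivity, and
redundant transport variants with inconsistent proton stoichiometry create
thermodynamically impossible energy-generating cycles. strainforge
implements the workflow that fixes all of this at cohort scale and then
asks the comparative questions such a cohort is built for — which strains
ferment what, which nutrients are essential for whom, who grows on milk
casein, who can cross-feed whom. It was written with dairy
*Lactococcus lactis* / *L. cremoris* cohorts in mind but is
namespace-portable.

## The computations at the core

* **FBA / pFBA** — maximize an objective flux v_obj subject to steady
  state (S·v = 0) and bounds; parsimonious FBA then minimizes Σ|v| with
  v_obj fixed at its optimum (relative slack 1e-6). Media follow the
  cohort-study convention: every component at 1 mmol gDW⁻¹ h⁻¹, the
  carbon source at a C-mol equivalent of 20 mmol gDW⁻¹ h⁻¹ glucose
  (120/carbons), water and protons unconstrained.
* **Balance audit** — per-reaction elemental/charge deltas
  Σⱼ cⱼ·formula(j), with `R`/`X` pseudo-elements for generic groups,
  classifying balanced / proton- / charge- / mass-imbalanced /
  unknown-formula / exempt.
* **Refinement** — install the organism biomass as objective, prune
  gap-filled reactions that carry no flux (|v| ≤ 1e-6) under the gap-fill
  media (keeping gene-less transporters whose cargo touches gene-bearing
  reactions), restore positively scored reactions the carve omitted.
* **Energy-generating-cycle detection** — close all exchanges, maximize
  currency dissipation (ATP, GTP, NADH, NADPH, FADH2, transmembrane
  proton gradient); any positive optimum is an artifact, reported with
  its parsimonious support.
* **Comparative suite** — fermentation profiles, the pyruvate-formate
  lyase (PFL) bound scan that moves strains between mixed-acid and
  homolactate fermentation, carbon-source ATP yields per C-mol,
  leave-one-out nutrient essentiality (essential = growth < 10 % of
  reference), growth on an average casein oligopeptide, cross-feeding
  screens, and Jaccard-distance hierarchical clustering of reaction
  content.

A deterministic fixture universe (`strainforge.toy_universe`) ships with
the package: a fully balanced ~96-reaction model with the relevant pathway
alternatives (PTS vs permease uptake, tagatose-6-P vs Leloir galactose
routes, pentose routes, sulfate assimilation, arginine deiminase, casein
machinery) and seeded strain cohorts with known ground truth.

## Worked example

```python
from strainforge.toy_universe import (build_toy_universal, derive_strain,
                                      toy_biomass_spec, toy_cdm_spec, PROFILE_KEYS)
from strainforge.strain_refinement import refine
from strainforge.sim_suite import build_cdm, fermentation_profile, homolactate_overrides
from strainforge.lp_engine import SimulationCondition, max_atp_yield

universal, manifest = build_toy_universal(seed=0)
profile = {key: True for key in PROFILE_KEYS}
profile["sulfate_assimilation"] = False          # a cysteine auxotroph
draft, scores, _ = derive_strain(universal, profile, seed=42, strain_id="isolate_42",
                                 gapfill_n=3, withhold_deadend=True)

cdm = build_cdm(toy_cdm_spec())                  # glucose CDM, 20 mmol/gDW/h
model, log = refine(draft, universal, scores, [cdm], toy_biomass_spec())
print(f"pruned gap fills : {log.pruned_metabolic}")
print(f"restored         : {log.restored}")

mixed = fermentation_profile(model, cdm)
homo = fermentation_profile(model, homolactate_overrides(cdm))
print(f"growth (mixed-acid) : {mixed.growth_rate:.3f} /h")
print(f"growth (homolactate): {homo.growth_rate:.3f} /h, lactate "
      f"{homo.products['EX_lac__D_e']:.1f} mmol/gDW/h")

atp_medium = SimulationCondition(medium={"EX_glc__D_e": 1.0},
                                 unconstrained_exchanges={"EX_h_e", "EX_h2o_e"},
                                 objective_override="ATPM")
print(f"ATP yield on glucose: {max_atp_yield(model, atp_medium, 'EX_glc__D_e', 6):.3f} per C-mol")
```

Output:

```
pruned gap fills : ['SULFAS']
restored         : ['ALLS6PI', 'ALLS6PP']
growth (mixed-acid) : 0.803 /h
growth (homolactate): 0.545 /h, lactate 39.4 mmol/gDW/h
ATP yield on glucose: 0.500 per C-mol
```

The carve had gap-filled the sulfate-assimilation lump this auxotroph has
no genes for; it carries no flux on the cysteine-containing medium and is
pruned. The two-step gene-evidenced dead-end pathway withheld by the carve
is restored. Mixed-acid fermentation (formate + acetate + ethanol, 3 ATP
per glucose, 0.5 ATP per C-mol) outgrows the homolactate regime (PFL
capped at 0.1 mmol gDW⁻¹ h⁻¹, lactate as dominant product, 2 ATP per
glucose).

The same steps are available from the shell:

```
strainforge fixture --n 40 --seed 7 -o fixtures/
strainforge refine fixtures/models/lactis_000.xml \
    --universal fixtures/toy_universal.xml \
    --scores fixtures/models/lactis_000_reaction_scores.tsv \
    --medium fixtures/cdm.tsv --biomass fixtures/biomass.tsv \
    -o refined.xml --log refine_log.json
strainforge compare fixtures/models/*.xml -o cohort
```

## Documentation

`docs/methods.md` describes the model and procedure assumptions, the
tunable parameters and their defaults, what the fixture universe does and
does not emulate, and the numerical conventions.
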