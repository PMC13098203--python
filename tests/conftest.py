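"""Shared fixtures: the toy universe, derived strains and cohorts.

Everything is generated programmatically and seeded; session scope keeps the
expensive cohort builds to one instance per run.
"""

from __future__ import annotations

import pytest

from strainforge.lp_engine import SimulationCondition
from strainforge.sim_suite import build_cdm, homolactate_overrides
from strainforge.strain_refinement import install_biomass, refine
from strainforge.toy_universe import (
    CohortSpec,
    PROFILE_KEYS,
    build_toy_universal,
    derive_strain,
    generate_cohort,
    toy_biomass_spec,
    toy_casein_spec,
    toy_cdm_spec,
)


def full_profile(**off):
    """All pathways on, except the keys passed with a False value."""
    profile = {k: True for k in PROFILE_KEYS}
    profile.update(off)
    return profile


@pytest.fixture(scope="session")
def universal():
    model, manifest = build_toy_universal()
    return model, manifest


@pytest.fixture(scope="session")
def cdm_spec():
    return toy_cdm_spec()


@pytest.fixture(scope="session")
def cdm(cdm_spec):
    return build_cdm(cdm_spec)


@pytest.fixture(scope="session")
def homolactate_cdm(cdm):
    return homolactate_overrides(cdm)


@pytest.fixture(scope="session")
def biomass_spec():
    return toy_biomass_spec()


@pytest.fixture(scope="session")
def casein_spec():
    return toy_casein_spec()


@pytest.fixture(scope="session")
def atp_condition():
    """Simplified substrate-only medium for ATP-yield runs (no amino acids,
    vitamins or minerals), glucose at 1 mmol gDW^-1 h^-1."""
    return SimulationCondition(
        medium={"EX_glc__D_e": 1.0},
        unconstrained_exchanges={"EX_h_e", "EX_h2o_e"},
        objective_override="ATPM",
    )


@pytest.fixture(scope="session")
def prototroph(universal, biomass_spec):
    """All-pathways strain with the strain-specific biomass installed."""
    model, _, manifest = derive_strain(universal[0], full_profile(),
                                       strain_id="prototroph")
    return install_biomass(model, biomass_spec), manifest


@pytest.fixture(scope="session")
def cys_auxotroph(universal, biomass_spec):
    model, _, manifest = derive_strain(
        universal[0], full_profile(sulfate_assimilation=False),
        strain_id="cys_auxotroph")
    return install_biomass(model, biomass_spec), manifest


@pytest.fixture(scope="session")
def cohort_refine(universal):
    """40 drafts with injected gap fills and withheld scored reactions."""
    return generate_cohort(
        CohortSpec(n=40, seed=7, gapfill_per_strain=3, withhold_deadend=True),
        universal=universal[0],
    )


@pytest.fixture(scope="session")
def cohort_refined(cohort_refine, universal, cdm, biomass_spec):
    """The same cohort after full refinement (used for clustering too)."""
    out = []
    for draft, scores, manifest in cohort_refine:
        refined, log = refine(draft, universal[0], scores, [cdm], biomass_spec)
        out.append((refined, log, manifest))
    return out


@pytest.fixture(scope="session")
def cohort_egc(universal):
    """40 strains with injected proton-stoichiometry transport variants."""
    return generate_cohort(
        CohortSpec(n=40, seed=11, gapfill_per_strain=0, withhold_deadend=False,
                   inject_egc=True),
        universal=universal[0],
    )
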