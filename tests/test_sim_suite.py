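"""Comparative analyses: CDM construction, fermentation modes, the PFL
scan, essentiality, casein growth, catabolic capacity, transporter
restriction and cross-feeding."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import full_profile
from strainforge.lp_engine import FLUX_TOL, solve_pfba
from strainforge.sim_suite import (
    CaseinSpec,
    attach_casein,
    build_cdm,
    casein_condition,
    catabolic_capacity,
    crossfeed_screen,
    detach_casein,
    essentiality_scan,
    fermentation_profile,
    homolactate_overrides,
    pfl_scan,
    restrict_transport,
)
from strainforge.strain_refinement import install_biomass
from strainforge.toy_universe import derive_strain

MINERAL_BASE = ("EX_so4_e", "EX_fe2_e", "EX_pi_e", "EX_nh4_e")


# ---------------------------------------------------------------------------
# CDM construction
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "substrate,carbons,bound",
    [
        ("EX_glc__D_e", 6, 20.0),
        ("EX_lcts_e", 12, 10.0),
        ("EX_rib__D_e", 5, 24.0),
    ],
)
def test_cmol_normalized_carbon_bounds(cdm_spec, substrate, carbons, bound):
    cond = build_cdm(cdm_spec, substrate=substrate, carbons=carbons)
    assert cond.medium[substrate] == pytest.approx(bound)
    for ex, _cls in cdm_spec.components:
        if ex != substrate:
            assert cond.medium[ex] == 1.0
    assert cond.unconstrained_exchanges == {"EX_h_e", "EX_h2o_e"}


def test_cdm_rejects_nonpositive_carbons(cdm_spec):
    with pytest.raises(ValueError):
        build_cdm(cdm_spec, substrate="EX_glc__D_e", carbons=0)


# ---------------------------------------------------------------------------
# fermentation profiles
# ---------------------------------------------------------------------------


def test_mixed_acid_profile(prototroph, cdm):
    prof = fermentation_profile(prototroph[0], cdm)
    assert prof.growing
    main = prof.main_products()
    for ex in ("EX_for_e", "EX_ac_e", "EX_etoh_e"):
        assert main.get(ex, 0.0) > 1.0
    # lactate is marginal under the mixed-acid optimum
    assert main.get("EX_lac__D_e", 0.0) < 0.01 * main["EX_for_e"]
    assert prof.byproducts() == {}


def test_homolactate_profile(prototroph, cdm, homolactate_cdm):
    prof = fermentation_profile(prototroph[0], homolactate_cdm)
    assert prof.growing
    lactate = prof.products.get("EX_lac__D_e", 0.0)
    assert lactate > 0.9 * max(prof.products.values())
    mixed = fermentation_profile(prototroph[0], cdm)
    assert prof.growth_rate < mixed.growth_rate


def test_infeasible_condition_gives_empty_profile(prototroph, cdm):
    starved = cdm.without_component("EX_glc__D_e")
    prof = fermentation_profile(prototroph[0], starved)
    assert not prof.growing and prof.growth_rate <= FLUX_TOL


# ---------------------------------------------------------------------------
# PFL scan
# ---------------------------------------------------------------------------


def test_pfl_scan_monotone_and_saturating(prototroph, cdm):
    scan = pfl_scan(prototroph[0], cdm)
    assert len(scan.bounds) == 25
    assert scan.bounds[0] == pytest.approx(0.1)
    assert scan.bounds[-1] == pytest.approx(60.0)
    growth = np.asarray(scan.growth)
    assert (np.diff(growth) >= -1e-6).all()
    # tight bound: lactate dominates; saturated: equals unconstrained
    assert scan.product_fluxes.iloc[0]["EX_lac__D_e"] > \
        scan.product_fluxes.iloc[0]["EX_ac_e"]
    free = solve_pfba(prototroph[0], cdm).objective_value
    assert scan.growth[-1] == pytest.approx(free, abs=1e-6)


def test_pfl_scan_requires_pfl(universal, cdm, biomass_spec):
    model, _, _ = derive_strain(universal[0], full_profile(), strain_id="nopfl")
    model = install_biomass(model, biomass_spec)
    model.remove_reactions([model.reactions.PFL])
    with pytest.raises(KeyError, match="PFL"):
        pfl_scan(model, cdm)


# ---------------------------------------------------------------------------
# essentiality
# ---------------------------------------------------------------------------


def test_component_without_exchange_scores_one(prototroph, cdm):
    prof = essentiality_scan(prototroph[0], cdm,
                             components=["EX_ghost_e", "EX_cys__L_e"])
    assert prof.relative_growth["EX_ghost_e"] == 1.0


def test_cysteine_sulfate_linkage(prototroph, cys_auxotroph, cdm):
    """Cysteine is essential exactly when sulfate assimilation is absent."""
    proto = essentiality_scan(prototroph[0], cdm)
    assert "EX_cys__L_e" not in proto.essential()
    aux = essentiality_scan(cys_auxotroph[0], cdm)
    assert "EX_cys__L_e" in aux.essential()
    # knocking the sulfate route out of the prototroph flips the call
    knocked = prototroph[0].copy()
    knocked.reactions.SULFAS.bounds = (0.0, 0.0)
    assert "EX_cys__L_e" in essentiality_scan(knocked, cdm).essential()


def test_carbon_source_is_essential(prototroph, cdm):
    prof = essentiality_scan(prototroph[0], cdm)
    assert "EX_glc__D_e" in prof.essential()


# ---------------------------------------------------------------------------
# casein
# ---------------------------------------------------------------------------


def test_casein_spec_validates_fractions():
    with pytest.raises(ValueError, match="sum"):
        CaseinSpec(aa_fractions={"cys__L": 0.5}, peptide_uptake=0.004)


def test_attach_detach_round_trip(prototroph, casein_spec):
    model = prototroph[0]
    withcas, att = attach_casein(model, casein_spec)
    assert set(att.reaction_ids) <= {r.id for r in withcas.reactions}
    back = detach_casein(withcas, att)
    assert {r.id for r in back.reactions} == {r.id for r in model.reactions}
    assert {m.id for m in back.metabolites} == {m.id for m in model.metabolites}


def test_attach_requires_amino_acids(universal, casein_spec):
    model = universal[0].copy()
    model.remove_metabolites([model.metabolites.met__L_c])
    with pytest.raises(KeyError, match="met__L"):
        attach_casein(model, casein_spec)


def test_casein_cysteine_limitation_and_relief(cys_auxotroph, cdm_spec,
                                               casein_spec):
    """The cysteine-poor peptide throttles growth of cysteine auxotrophs to
    the analytic cysteine-limited rate; free cysteine at the CDM fraction
    restores the free-amino-acid optimum exactly."""
    model, _ = cys_auxotroph
    withcas, _ = attach_casein(model, casein_spec)
    milk = casein_condition(cdm_spec, casein_spec)
    free_aa = build_cdm(cdm_spec, substrate="EX_lcts_e", carbons=12)

    mu_ref = solve_pfba(withcas, free_aa).objective_value
    mu_cas = solve_pfba(withcas, milk).objective_value
    assert mu_cas < 0.10 * mu_ref  # non-growing by the 10 % rule

    # independent accounting: growth = cys supply / biomass cys coefficient
    residue_supply = casein_spec.peptide_uptake * casein_spec.residue_scale
    cys_supply = casein_spec.aa_fractions["cys__L"] * residue_supply
    cys_coeff = 3.3 / 19.0
    assert mu_cas == pytest.approx(cys_supply / cys_coeff, abs=1e-6)

    mu_relieved = solve_pfba(withcas,
                             milk.with_uptake("EX_cys__L_e", 1.0)).objective_value
    assert mu_relieved == pytest.approx(mu_ref, abs=1e-6)


def test_prototroph_unaffected_by_casein(prototroph, cdm_spec, casein_spec):
    model, _ = prototroph
    withcas, _ = attach_casein(model, casein_spec)
    milk = casein_condition(cdm_spec, casein_spec)
    free_aa = build_cdm(cdm_spec, substrate="EX_lcts_e", carbons=12)
    mu_milk = solve_pfba(withcas, milk).objective_value
    mu_free = solve_pfba(withcas, free_aa).objective_value
    assert mu_milk >= 0.95 * mu_free


def test_lactose_negative_strain_fails_on_milk(universal, biomass_spec,
                                               cdm_spec, casein_spec):
    model, _, _ = derive_strain(
        universal[0],
        full_profile(lactose_pts=False, lactose_permease=False),
        strain_id="lactoseneg")
    model = install_biomass(model, biomass_spec)
    withcas, _ = attach_casein(model, casein_spec)
    mu = solve_pfba(withcas, casein_condition(cdm_spec, casein_spec)).objective_value
    assert mu <= FLUX_TOL


# ---------------------------------------------------------------------------
# catabolic capacity / transporter restriction
# ---------------------------------------------------------------------------


def test_arginine_catabolism_requires_deiminase(universal, biomass_spec):
    with_adi = install_biomass(
        derive_strain(universal[0], full_profile(), strain_id="adi")[0],
        biomass_spec)
    capable, atp = catabolic_capacity(with_adi, "EX_arg__L_e",
                                      base_exchanges=MINERAL_BASE)
    assert capable and atp > FLUX_TOL
    without, _, _ = derive_strain(universal[0],
                                  full_profile(arginine_deiminase=False),
                                  strain_id="noadi")
    without = install_biomass(without, biomass_spec)
    incapable, atp0 = catabolic_capacity(without, "EX_arg__L_e",
                                         base_exchanges=MINERAL_BASE)
    assert not incapable and atp0 <= FLUX_TOL


def test_water_is_not_a_catabolite(prototroph):
    capable, _ = catabolic_capacity(prototroph[0], "EX_h2o_e",
                                    base_exchanges=MINERAL_BASE)
    assert not capable


def test_missing_exchange_means_incapable(prototroph):
    capable, atp = catabolic_capacity(prototroph[0], "EX_ghost_e")
    assert capable is False and atp == 0.0


def test_maltose_transport_restriction(universal, biomass_spec, cdm_spec):
    malt_cdm = build_cdm(cdm_spec, substrate="EX_malt_e", carbons=12)
    both = install_biomass(
        derive_strain(universal[0], full_profile(), strain_id="both")[0],
        biomass_spec)
    mu_both = solve_pfba(both, malt_cdm).objective_value
    mu_pts = solve_pfba(restrict_transport(both, "malt", "MALTpts"),
                        malt_cdm).objective_value
    assert mu_pts == pytest.approx(mu_both, abs=1e-6)  # PTS is the optimum

    abc_only = install_biomass(
        derive_strain(universal[0], full_profile(maltose_pts=False),
                      strain_id="abconly")[0], biomass_spec)
    assert solve_pfba(abc_only, malt_cdm).objective_value > FLUX_TOL
    restricted = restrict_transport(abc_only, "malt", "MALTpts")
    assert solve_pfba(restricted, malt_cdm).objective_value <= FLUX_TOL


def test_restricting_other_transporters_keeps_glucose_growth(prototroph, cdm):
    restricted = restrict_transport(prototroph[0], "cit", "CITt")
    assert solve_pfba(restricted, cdm).objective_value == pytest.approx(
        solve_pfba(prototroph[0], cdm).objective_value, abs=1e-6)


def test_restrict_rejects_non_transporter_keep(prototroph):
    with pytest.raises(ValueError, match="transport"):
        restrict_transport(prototroph[0], "malt", "LDH_D")


# ---------------------------------------------------------------------------
# cross-feeding
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def crossfeed_trio(universal, biomass_spec):
    proto = install_biomass(
        derive_strain(universal[0], full_profile(), strain_id="proto")[0],
        biomass_spec)
    leu_aux = install_biomass(
        derive_strain(universal[0], full_profile(leucine_synthesis=False),
                      strain_id="leu_aux")[0], biomass_spec)
    no_lyase = install_biomass(
        derive_strain(universal[0], full_profile(citrate_lyase=False),
                      strain_id="no_lyase")[0], biomass_spec)
    return proto, leu_aux, no_lyase


def test_main_products_not_consumed_anaerobically(crossfeed_trio, cdm):
    mat = crossfeed_screen(list(crossfeed_trio), cdm,
                           ["EX_lac__D_e", "EX_for_e", "EX_ac_e", "EX_etoh_e"])
    assert not mat.consumed.values.any()


def test_leucine_consumed_by_auxotroph(crossfeed_trio, cdm):
    _, leu_aux, _ = crossfeed_trio
    mat = crossfeed_screen([leu_aux], cdm, ["EX_leu__L_e"])
    assert bool(mat.consumed.loc["leu_aux", "EX_leu__L_e"]) is True
    # leucine already in the medium: the probe raises its bound to 2
    assert mat.uptake_flux.loc["leu_aux", "EX_leu__L_e"] > 1.0


def test_citrate_consumed_only_with_lyase(crossfeed_trio, cdm):
    proto, _, no_lyase = crossfeed_trio
    mat = crossfeed_screen([proto, no_lyase], cdm, ["EX_cit_e"])
    assert bool(mat.consumed.loc["proto", "EX_cit_e"]) is True
    assert bool(mat.consumed.loc["no_lyase", "EX_cit_e"]) is False


def test_growth_atp_equivalence_per_substrate(universal, biomass_spec, cdm_spec):
    """A strain grows on a substrate exactly when it extracts ATP from it."""
    from strainforge.lp_engine import SimulationCondition, max_atp_yield

    strains = [
        install_biomass(derive_strain(universal[0], full_profile(),
                                      strain_id="full")[0], biomass_spec),
        install_biomass(derive_strain(
            universal[0],
            full_profile(xylulokinase=False, phosphoketolase=False,
                         tag6p=False, lactose_pts=False),
            strain_id="reduced")[0], biomass_spec),
    ]
    substrates = [("EX_glc__D_e", 6), ("EX_gal_e", 6), ("EX_lcts_e", 12),
                  ("EX_xyl__D_e", 5), ("EX_rib__D_e", 5)]
    for strain in strains:
        for ex, carbons in substrates:
            mu = solve_pfba(strain, build_cdm(cdm_spec, substrate=ex,
                                              carbons=carbons)).objective_value
            simple = SimulationCondition(
                medium={ex: 1.0},
                unconstrained_exchanges={"EX_h_e", "EX_h2o_e"},
                objective_override="ATPM")
            y = max_atp_yield(strain, simple, ex, carbons)
            assert (mu > FLUX_TOL) == (y > FLUX_TOL), (strain.id, ex)
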