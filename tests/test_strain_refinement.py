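"""Score ingest, gap-fill pruning, score-based restoration and biomass
installation on manifest-backed fixture strains."""

from __future__ import annotations

import pandas as pd
import pytest
from cobra import Metabolite, Reaction

from conftest import full_profile
from strainforge.lp_engine import FLUX_TOL, solve_fba
from strainforge.model_core import get_flags, has_flag, read_sbml, write_sbml
from strainforge.sim_suite import essentiality_scan
from strainforge.strain_refinement import (
    BiomassSpec,
    ingest_carveme_flags,
    install_biomass,
    prune_gapfill,
    read_reaction_scores,
    refine,
    restore_scored_reactions,
)
from strainforge.toy_universe import derive_strain, toy_biomass_spec


@pytest.fixture(scope="module")
def draft_with_artifacts(universal):
    """Strain lacking the Leloir and lactose-permease routes, with injected
    gap fills and the withheld gene-evidenced dead-end pathway."""
    profile = full_profile(leloir=False, lactose_permease=False,
                           citrate_lyase=False)
    return derive_strain(universal[0], profile, seed=5, strain_id="artifacts",
                         gapfill_n=3, withhold_deadend=True)


# ---------------------------------------------------------------------------
# score table I/O
# ---------------------------------------------------------------------------


def test_read_scores_round_trip(tmp_path):
    path = tmp_path / "scores.tsv"
    pd.DataFrame({"reaction": ["A", "B"], "score": [1.5, -0.5]}).to_csv(
        path, sep="\t", index=False)
    assert read_reaction_scores(path) == {"A": 1.5, "B": -0.5}


def test_read_scores_rejects_bad_tables(tmp_path):
    path = tmp_path / "dup.tsv"
    pd.DataFrame({"reaction": ["A", "A"], "score": [1, 2]}).to_csv(
        path, sep="\t", index=False)
    with pytest.raises(ValueError, match="duplicated"):
        read_reaction_scores(path)
    path2 = tmp_path / "cols.tsv"
    pd.DataFrame({"rxn": ["A"], "score": [1]}).to_csv(path2, sep="\t", index=False)
    with pytest.raises(ValueError, match="reaction"):
        read_reaction_scores(path2)
    path3 = tmp_path / "nan.tsv"
    pd.DataFrame({"reaction": ["A"], "score": ["high"]}).to_csv(
        path3, sep="\t", index=False)
    with pytest.raises(ValueError, match="non-numeric"):
        read_reaction_scores(path3)


def test_generated_scores_positive_exactly_for_kept_gene_reactions(universal):
    model, scores, manifest = derive_strain(
        universal[0], full_profile(), seed=2, strain_id="s",
        withhold_deadend=True)
    gene_bearing = {r.id for r in model.reactions if r.gene_reaction_rule.strip()}
    positive = {rid for rid, s in scores.items() if s > 0}
    assert positive == gene_bearing | set(manifest.withheld_scored)


def test_ingest_marks_exactly_injected_gapfills(draft_with_artifacts):
    model, scores, manifest = draft_with_artifacts
    m = model.copy()
    for rxn in m.reactions:  # start from an unflagged carve output
        if has_flag(rxn, "gap_filled"):
            rxn.notes.clear()
    flagged = ingest_carveme_flags(m, scores, spontaneous=manifest.spontaneous)
    assert flagged == sorted(manifest.injected_gapfill)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


def test_prune_removes_exactly_never_used_gapfills(draft_with_artifacts,
                                                   universal, cdm, biomass_spec):
    draft, _, manifest = draft_with_artifacts
    model = install_biomass(draft, biomass_spec)
    pre = solve_fba(model, cdm).objective_value
    pruned, log = prune_gapfill(model, [cdm])
    assert sorted(log.pruned_metabolic) == sorted(manifest.injected_gapfill)
    assert log.pruned_transport == []
    post = solve_fba(pruned, cdm).objective_value
    assert post == pytest.approx(pre, abs=1e-6)


def test_prune_without_gapfills_is_identity(universal, cdm, biomass_spec):
    draft, _, _ = derive_strain(universal[0], full_profile(), strain_id="plain")
    model = install_biomass(draft, biomass_spec)
    pruned, log = prune_gapfill(model, [cdm])
    assert len(pruned.reactions) == len(model.reactions)
    assert not (log.pruned_metabolic or log.pruned_transport or
                log.pruned_exchanges)


def test_geneless_transporter_kept_when_cargo_touches_gene_reactions(
        universal, cdm, biomass_spec):
    """A flux-less gap-filled transporter survives pruning if the metabolite
    it moves is handled by gene-bearing reactions; with the cargo pathway
    absent, transporter and its exchange both go."""
    for with_pathway in (True, False):
        profile = full_profile() if with_pathway else full_profile()
        draft, _, _ = derive_strain(universal[0], profile, strain_id="t",
                                    withhold_deadend=not with_pathway)
        model = install_biomass(draft, biomass_spec)
        # inject: alls_e species, its exchange, and a gene-less transporter
        alls_e = Metabolite("alls_e", formula="C6H12O6", charge=0, compartment="e")
        model.add_metabolites([alls_e])
        tr = Reaction("ALLSt", lower_bound=-1000, upper_bound=1000)
        ex = Reaction("EX_alls_e", lower_bound=0, upper_bound=1000)
        model.add_reactions([tr, ex])
        tr.add_metabolites({model.metabolites.alls_c: -1, alls_e: 1}
                           if with_pathway else {alls_e: 1})
        if not with_pathway:
            # no cytosolic allose in this strain: make a fresh orphan species
            alls_c = Metabolite("alls_c", formula="C6H12O6", charge=0,
                                compartment="c")
            model.add_metabolites([alls_c])
            tr.add_metabolites({alls_e: -1}, combine=True)  # reset
            tr.add_metabolites({alls_c: -1, alls_e: 1})
        ex.add_metabolites({alls_e: -1})
        from strainforge.model_core import add_flag

        add_flag(tr, "gap_filled")
        pruned, log = prune_gapfill(model, [cdm])
        if with_pathway:
            assert "ALLSt" in pruned.reactions and "EX_alls_e" in pruned.reactions
            assert log.pruned_transport == []
        else:
            assert "ALLSt" not in pruned.reactions
            assert "EX_alls_e" not in pruned.reactions
            assert log.pruned_transport == ["ALLSt"]
            assert "EX_alls_e" in log.pruned_exchanges


def test_prune_rejects_infeasible_condition(draft_with_artifacts, cdm,
                                            biomass_spec):
    draft, _, _ = draft_with_artifacts
    model = install_biomass(draft, biomass_spec)
    dead = cdm.without_component("EX_glc__D_e")
    with pytest.raises(ValueError, match="condition 0"):
        prune_gapfill(model, [dead])


# ---------------------------------------------------------------------------
# restoration
# ---------------------------------------------------------------------------


def test_restore_adds_exactly_withheld_pathway(draft_with_artifacts, universal):
    draft, scores, manifest = draft_with_artifacts
    restored, log = restore_scored_reactions(draft, universal[0], scores)
    assert sorted(log.restored) == sorted(manifest.withheld_scored)
    for rid in manifest.withheld_scored:
        rxn = restored.reactions.get_by_id(rid)
        assert has_flag(rxn, "restored_disconnected")
        assert rxn.gene_reaction_rule.strip()  # genes travel along


def test_restore_noop_when_everything_present(universal):
    model, scores, _ = derive_strain(universal[0], full_profile(),
                                     strain_id="whole")
    restored, log = restore_scored_reactions(model, universal[0], scores)
    assert log.restored == []
    assert len(restored.reactions) == len(model.reactions)


def test_restore_rejects_unknown_scored_id(universal):
    model, scores, _ = derive_strain(universal[0], full_profile(), strain_id="x")
    scores["GHOST"] = 3.0
    with pytest.raises(KeyError, match="GHOST"):
        restore_scored_reactions(model, universal[0], scores)


# ---------------------------------------------------------------------------
# biomass installation
# ---------------------------------------------------------------------------


def test_install_biomass_swaps_objective_and_flags(universal, biomass_spec):
    draft, _, _ = derive_strain(universal[0], full_profile(), strain_id="bm")
    model = install_biomass(draft, biomass_spec)
    assert biomass_spec.id in model.reactions
    assert "BIOMASS_universal" not in model.reactions
    assert has_flag(model.reactions.get_by_id(biomass_spec.id), "biomass")
    again = install_biomass(model, biomass_spec)
    assert len(again.reactions) == len(model.reactions)


def test_biomass_swap_drops_iron_requirement(universal, cdm, biomass_spec):
    """The generic biomass drains Fe2+; the organism-specific one does not,
    so iron stops being an essential medium component."""
    draft, _, _ = derive_strain(universal[0], full_profile(), strain_id="fe")
    generic = essentiality_scan(draft, cdm)
    assert "EX_fe2_e" in generic.essential()
    swapped = install_biomass(draft, biomass_spec)
    specific = essentiality_scan(swapped, cdm)
    assert "EX_fe2_e" not in specific.essential()
    assert specific.relative_growth["EX_fe2_e"] == pytest.approx(1.0, abs=1e-6)


def test_install_biomass_missing_precursor_error(universal):
    draft, _, _ = derive_strain(universal[0], full_profile(), strain_id="mp")
    bad = BiomassSpec(id="BM", stoichiometry={"unobtainium_c": -1.0, "atp_c": -1.0})
    with pytest.raises(KeyError, match="unobtainium_c"):
        install_biomass(draft, bad)


# ---------------------------------------------------------------------------
# full refinement
# ---------------------------------------------------------------------------


def test_refine_full_flow(draft_with_artifacts, universal, cdm, biomass_spec):
    draft, scores, manifest = draft_with_artifacts
    refined, log = refine(draft, universal[0], scores, [cdm], biomass_spec)
    assert log.biomass_swapped
    assert sorted(log.pruned_metabolic) == sorted(manifest.injected_gapfill)
    assert sorted(log.restored) == sorted(manifest.withheld_scored)
    sol = solve_fba(refined, cdm)
    assert sol.objective_value > FLUX_TOL
    # direction properties: fewer gap-filled, at least as many gene-bearing
    n_gf = lambda m: sum(1 for r in m.reactions if has_flag(r, "gap_filled"))
    n_gene = lambda m: sum(1 for r in m.reactions
                           if r.gene_reaction_rule.strip())
    assert n_gf(refined) < n_gf(draft)
    assert n_gene(refined) >= n_gene(draft)
    # refined shares at least as many reactions with an artifact-free
    # reference reconstruction of the same strain as the draft does
    reference, _, _ = derive_strain(
        universal[0], manifest.profile, strain_id="reference")
    ref_ids = {r.id for r in reference.reactions}
    shared = lambda m: len({r.id for r in m.reactions} & ref_ids)
    assert shared(refined) > shared(draft)


def test_refine_is_deterministic_byte_identical(draft_with_artifacts, universal,
                                                cdm, biomass_spec, tmp_path):
    draft, scores, _ = draft_with_artifacts
    paths = []
    for tag in ("a", "b"):
        refined, _ = refine(draft, universal[0], scores, [cdm], biomass_spec)
        path = tmp_path / f"refined_{tag}.xml"
        write_sbml(refined, path)
        paths.append(path)
    assert paths[0].read_bytes() == paths[1].read_bytes()
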