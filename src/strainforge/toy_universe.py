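"""Deterministic desk-scale fixture universe.

Builds a small, fully mass- and charge-balanced "universal" bacterial model
that mirrors the pathway architecture of lactococcal central metabolism:

* PTS glucose uptake feeding lumped glycolysis (1 ATP + 1 NADH per triose),
* the pyruvate node with lactate dehydrogenase, pyruvate-formate lyase and
  pyruvate dehydrogenase, the phosphotransacetylase/acetate-kinase branch
  (+1 ATP) and the 2-NADH ethanol branch — so mixed-acid fermentation nets
  3 ATP per glucose and homolactate fermentation nets 2,
* alternative galactose routes (PTS + tagatose-6-phosphate split versus
  permease + a costed Leloir lump), the matching lactose routes (PTS +
  phospho-beta-galactosidase versus permease + beta-galactosidase),
* maltose via PTS or ABC import, xylose/ribose via xylulokinase and
  phosphoketolase with a deliberately ATP-poor hydrolytic bypass,
* sulfate assimilation to sulfide and cysteine synthesis from serine,
  toggleable leucine synthesis, a methionine-from-cysteine lump,
* the arginine-deiminase lump (+1 ATP per arginine), citrate lyase,
* proton-symport export of the fermentation acids plus a reversible
  F1F0-type ATPase, so that injected transport variants with deviant proton
  stoichiometry create genuine energy-generating cycles,
* casein-peptide uptake/hydrolysis machinery and a biomass reaction whose
  amino-acid composition is 5 % cysteine.

Strain variants are derived by deleting pathway reaction sets according to a
boolean *profile*, emulating what a homology-based carving step would
produce, together with a CarveMe-style reaction-score table, optional
injected gene-less gap-filled reactions and optional withheld (dead-end but
gene-evidenced) reactions.  Everything is recorded in a manifest so tests
can assert exact expectations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from cobra import Metabolite, Model, Reaction

from .model_core import add_flag, set_flags, formula_to_string, parse_formula

__all__ = [
    "ToyManifest",
    "CohortSpec",
    "build_toy_universal",
    "derive_strain",
    "generate_cohort",
    "PATHWAY_REACTIONS",
    "PROFILE_KEYS",
    "CASEIN_REACTIONS",
    "DEADEND_REACTIONS",
    "toy_biomass_spec",
    "toy_cdm_spec",
    "toy_casein_spec",
    "CARBON_ATOMS",
]

# ---------------------------------------------------------------------------
# metabolite table: (base id, name, formula, charge, compartments, annotation)
# ---------------------------------------------------------------------------

_METS: List[Tuple[str, str, str, int, str, str]] = [
    # id, name, formula, charge, compartments ("c", "ce"), chebi id
    ("glc__D", "D-Glucose", "C6H12O6", 0, "ce", "CHEBI:4167"),
    ("gal", "D-Galactose", "C6H12O6", 0, "ce", "CHEBI:4139"),
    ("lcts", "Lactose", "C12H22O11", 0, "ce", "CHEBI:17716"),
    ("malt", "Maltose", "C12H22O11", 0, "ce", "CHEBI:17306"),
    ("xyl__D", "D-Xylose", "C5H10O5", 0, "ce", "CHEBI:53455"),
    ("xylu__D", "D-Xylulose", "C5H10O5", 0, "c", "CHEBI:17140"),
    ("rib__D", "D-Ribose", "C5H10O5", 0, "ce", "CHEBI:47013"),
    ("cit", "Citrate", "C6H5O7", -3, "ce", "CHEBI:16947"),
    ("oaa", "Oxaloacetate", "C4H2O5", -2, "c", "CHEBI:16452"),
    ("akg", "2-Oxoglutarate", "C5H4O5", -2, "c", "CHEBI:16810"),
    ("arg__L", "L-Arginine", "C6H15N4O2", 1, "ce", "CHEBI:32682"),
    ("orn", "Ornithine", "C5H13N2O2", 1, "ce", "CHEBI:46911"),
    ("glu__L", "L-Glutamate", "C5H8NO4", -1, "ce", "CHEBI:29985"),
    ("leu__L", "L-Leucine", "C6H13NO2", 0, "ce", "CHEBI:57427"),
    ("cys__L", "L-Cysteine", "C3H7NO2S", 0, "ce", "CHEBI:35235"),
    ("met__L", "L-Methionine", "C5H11NO2S", 0, "ce", "CHEBI:57844"),
    ("ser__L", "L-Serine", "C3H7NO3", 0, "c", "CHEBI:33384"),
    ("so4", "Sulfate", "O4S", -2, "ce", "CHEBI:16189"),
    ("h2s", "Hydrogen sulfide", "H2S", 0, "c", "CHEBI:16136"),
    ("fe2", "Fe2+", "Fe", 2, "ce", "CHEBI:29033"),
    ("nh4", "Ammonium", "H4N", 1, "ce", "CHEBI:28938"),
    ("g6p", "D-Glucose 6-phosphate", "C6H11O9P", -2, "c", "CHEBI:4170"),
    ("f6p", "D-Fructose 6-phosphate", "C6H11O9P", -2, "c", "CHEBI:16084"),
    ("fdp", "D-Fructose 1,6-bisphosphate", "C6H10O12P2", -4, "c", "CHEBI:37736"),
    ("dhap", "Dihydroxyacetone phosphate", "C3H5O6P", -2, "c", "CHEBI:16108"),
    ("g3p", "Glyceraldehyde 3-phosphate", "C3H5O6P", -2, "c", "CHEBI:17138"),
    ("pep", "Phosphoenolpyruvate", "C3H2O6P", -3, "c", "CHEBI:18021"),
    ("pyr", "Pyruvate", "C3H3O3", -1, "c", "CHEBI:15361"),
    ("gal6p", "D-Galactose 6-phosphate", "C6H11O9P", -2, "c", "CHEBI:91004"),
    ("lcts6p", "Lactose 6-phosphate", "C12H21O14P", -2, "c", "CHEBI:79080"),
    ("malt6p", "Maltose 6-phosphate", "C12H21O14P", -2, "c", "CHEBI:18404"),
    ("xu5p__D", "D-Xylulose 5-phosphate", "C5H9O8P", -2, "c", "CHEBI:57737"),
    ("r5p", "D-Ribose 5-phosphate", "C5H9O8P", -2, "c", "CHEBI:78346"),
    ("alls6p", "D-Allose 6-phosphate", "C6H11O9P", -2, "c", "CHEBI:90605"),
    ("alls", "D-Allose", "C6H12O6", 0, "c", "CHEBI:40656"),
    ("lac__D", "D-Lactate", "C3H5O3", -1, "ce", "CHEBI:16004"),
    ("for", "Formate", "CHO2", -1, "ce", "CHEBI:15740"),
    ("ac", "Acetate", "C2H3O2", -1, "ce", "CHEBI:30089"),
    ("actp", "Acetyl phosphate", "C2H3O5P", -2, "c", "CHEBI:22191"),
    ("acald", "Acetaldehyde", "C2H4O", 0, "c", "CHEBI:15343"),
    ("etoh", "Ethanol", "C2H6O", 0, "ce", "CHEBI:16236"),
    ("co2", "CO2", "CO2", 0, "ce", "CHEBI:16526"),
    ("atp", "ATP", "C10H12N5O13P3", -4, "c", "CHEBI:30616"),
    ("adp", "ADP", "C10H12N5O10P2", -3, "c", "CHEBI:456216"),
    ("pi", "Phosphate", "HO4P", -2, "ce", "CHEBI:43474"),
    ("h", "H+", "H", 1, "ce", "CHEBI:15378"),
    ("h2o", "H2O", "H2O", 0, "ce", "CHEBI:15377"),
    ("nad", "NAD+", "C21H26N7O14P2", -1, "c", "CHEBI:57540"),
    ("nadh", "NADH", "C21H27N7O14P2", -2, "c", "CHEBI:57945"),
    ("coa", "Coenzyme A", "C21H32N7O16P3S", -4, "c", "CHEBI:57287"),
    ("accoa", "Acetyl-CoA", "C23H34N7O17P3S", -4, "c", "CHEBI:57288"),
]

#: casein-peptide amino-acid composition, residues per 1000 (cysteine-poor,
#: remaining mass padded onto glutamate)
CASEIN_RESIDUES = {"cys__L": 3, "met__L": 250, "leu__L": 250, "glu__L": 497}
CASEIN_SCALE = 1000

#: carbon atoms per molecule of each packaged carbon source (exchange ids)
CARBON_ATOMS = {
    "EX_glc__D_e": 6,
    "EX_gal_e": 6,
    "EX_lcts_e": 12,
    "EX_malt_e": 12,
    "EX_xyl__D_e": 5,
    "EX_rib__D_e": 5,
    "EX_cit_e": 6,
}

# reaction table: id -> (stoichiometry over met ids, (lb, ub), gpr, name)
_R = 1000.0

_REACTIONS: Dict[str, Tuple[Dict[str, float], Tuple[float, float], str, str]] = {
    # --- sugar uptake --------------------------------------------------
    "GLCpts": ({"glc__D_e": -1, "pep_c": -1, "g6p_c": 1, "pyr_c": 1}, (0, _R),
               "g_ptsHI and g_ptsG", "Glucose PTS"),
    "GALpts": ({"gal_e": -1, "pep_c": -1, "gal6p_c": 1, "pyr_c": 1}, (0, _R),
               "g_ptsHI and g_lacE", "Galactose PTS"),
    "GALt": ({"gal_e": -1, "gal_c": 1}, (-_R, _R), "g_galP", "Galactose permease"),
    "LCTSpts": ({"lcts_e": -1, "pep_c": -1, "lcts6p_c": 1, "pyr_c": 1}, (0, _R),
                "g_ptsHI and g_lacFE", "Lactose PTS"),
    "LCTSt": ({"lcts_e": -1, "lcts_c": 1}, (0, _R), "g_lacS", "Lactose permease"),
    "MALTpts": ({"malt_e": -1, "pep_c": -1, "malt6p_c": 1, "pyr_c": 1}, (0, _R),
                "g_ptsHI and g_malX", "Maltose PTS"),
    "MALTabc": ({"malt_e": -1, "atp_c": -1, "h2o_c": -1,
                 "malt_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 1}, (0, _R),
                "g_malE and g_malF and g_malG", "Maltose ABC transporter"),
    "XYLt": ({"xyl__D_e": -1, "xyl__D_c": 1}, (-_R, _R), "g_xylT", "Xylose transport"),
    "RIBt": ({"rib__D_e": -1, "rib__D_c": 1}, (-_R, _R), "g_rbsU", "Ribose transport"),
    "CITt": ({"cit_e": -1, "cit_c": 1}, (-_R, _R), "g_citP", "Citrate permease"),
    # --- amino-acid / ion transport ------------------------------------
    "ARGt": ({"arg__L_e": -1, "arg__L_c": 1}, (-_R, _R), "g_arcD", "Arginine transport"),
    "ORNt": ({"orn_e": -1, "orn_c": 1}, (-_R, _R), "g_arcD", "Ornithine transport"),
    "GLUt": ({"glu__L_e": -1, "glu__L_c": 1}, (-_R, _R), "g_gltS", "Glutamate transport"),
    "LEUt": ({"leu__L_e": -1, "leu__L_c": 1}, (-_R, _R), "g_brnQ", "Leucine transport"),
    "CYSt": ({"cys__L_e": -1, "cys__L_c": 1}, (-_R, _R), "g_tcyB", "Cysteine transport"),
    "METt": ({"met__L_e": -1, "met__L_c": 1}, (-_R, _R), "g_metN", "Methionine transport"),
    "SO4t": ({"so4_e": -1, "so4_c": 1}, (-_R, _R), "g_cysP", "Sulfate transport"),
    "FE2t": ({"fe2_e": -1, "fe2_c": 1}, (-_R, _R), "g_feoB", "Iron(II) transport"),
    "NH4t": ({"nh4_e": -1, "nh4_c": 1}, (-_R, _R), "g_amtB", "Ammonium transport"),
    "PIt": ({"pi_e": -1, "pi_c": 1}, (-_R, _R), "g_pstS", "Phosphate transport"),
    # --- product export (acids as proton symport) ----------------------
    "LACt2": ({"lac__D_c": -1, "h_c": -1, "lac__D_e": 1, "h_e": 1}, (-_R, _R),
              "g_lldP", "D-lactate/H+ symport"),
    "FORt2": ({"for_c": -1, "h_c": -1, "for_e": 1, "h_e": 1}, (-_R, _R),
              "g_focA", "Formate/H+ symport"),
    "ACt2": ({"ac_c": -1, "h_c": -1, "ac_e": 1, "h_e": 1}, (-_R, _R),
             "g_actP", "Acetate/H+ symport"),
    "ETOHt": ({"etoh_c": -1, "etoh_e": 1}, (-_R, _R), "", "Ethanol diffusion"),
    "CO2t": ({"co2_c": -1, "co2_e": 1}, (-_R, _R), "", "CO2 diffusion"),
    "H2Ot": ({"h2o_c": -1, "h2o_e": 1}, (-_R, _R), "", "Water diffusion"),
    # reversible F1F0 ATPase; synthesis direction translocates 4 H+ inward
    "ATPS4r": ({"adp_c": -1, "pi_c": -1, "h_e": -4, "atp_c": 1, "h2o_c": 1, "h_c": 3},
               (-_R, _R), "g_atpA and g_atpB and g_atpC", "F1F0 ATP synthase"),
    # --- glycolysis ----------------------------------------------------
    "PGI": ({"g6p_c": -1, "f6p_c": 1}, (-_R, _R), "g_pgi", "Glucose-6-P isomerase"),
    "PFK": ({"f6p_c": -1, "atp_c": -1, "fdp_c": 1, "adp_c": 1, "h_c": 1}, (0, _R),
            "g_pfk", "Phosphofructokinase"),
    "FBA": ({"fdp_c": -1, "dhap_c": 1, "g3p_c": 1}, (-_R, _R), "g_fba",
            "Fructose-bisphosphate aldolase"),
    "FBP": ({"fdp_c": -1, "h2o_c": -1, "f6p_c": 1, "pi_c": 1}, (0, _R),
            "g_fbp", "Fructose-1,6-bisphosphatase"),
    "TPI": ({"dhap_c": -1, "g3p_c": 1}, (-_R, _R), "g_tpi", "Triose-P isomerase"),
    # GAPD+PGK+PGM+ENO lump: one ATP and one NADH per triose phosphate
    "GAPDL": ({"g3p_c": -1, "nad_c": -1, "pi_c": -1, "adp_c": -1,
               "pep_c": 1, "atp_c": 1, "nadh_c": 1, "h_c": 1, "h2o_c": 1}, (0, _R),
              "g_gap and g_pgk", "Lower glycolysis lump (G3P -> PEP)"),
    "PYK": ({"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1, "atp_c": 1}, (0, _R),
            "g_pyk", "Pyruvate kinase"),
    # --- pyruvate node -------------------------------------------------
    "LDH_D": ({"pyr_c": -1, "nadh_c": -1, "h_c": -1, "lac__D_c": 1, "nad_c": 1},
              (0, _R), "g_ldh", "D-lactate dehydrogenase"),
    "PFL": ({"pyr_c": -1, "coa_c": -1, "accoa_c": 1, "for_c": 1}, (0, _R),
            "g_pfl", "Pyruvate formate lyase"),
    "PDH": ({"pyr_c": -1, "coa_c": -1, "nad_c": -1,
             "accoa_c": 1, "co2_c": 1, "nadh_c": 1}, (0, _R),
            "g_pdhA and g_pdhB", "Pyruvate dehydrogenase"),
    "PTA": ({"accoa_c": -1, "pi_c": -1, "actp_c": 1, "coa_c": 1}, (-_R, _R),
            "g_pta", "Phosphotransacetylase"),
    "ACKr": ({"actp_c": -1, "adp_c": -1, "ac_c": 1, "atp_c": 1}, (0, _R),
             "g_ackA", "Acetate kinase"),
    "ACALD": ({"accoa_c": -1, "nadh_c": -1, "h_c": -1,
               "acald_c": 1, "coa_c": 1, "nad_c": 1}, (0, _R),
              "g_adhE", "Acetaldehyde dehydrogenase"),
    "ALCD2x": ({"acald_c": -1, "nadh_c": -1, "h_c": -1, "etoh_c": 1, "nad_c": 1},
               (0, _R), "g_adhE", "Alcohol dehydrogenase"),
    "ATPM": ({"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1}, (0, _R),
             "", "ATP maintenance"),
    # --- galactose / lactose / maltose ---------------------------------
    # Leloir lump (galactokinase + uridylyltransferase + phosphoglucomutase);
    # carries one extra ATP-hydrolysis equivalent for UDP-glucose turnover
    "GALLELOIR": ({"gal_c": -1, "atp_c": -2, "h2o_c": -1,
                   "g6p_c": 1, "adp_c": 2, "pi_c": 1, "h_c": 2}, (0, _R),
                  "g_galK and g_galT", "Leloir pathway lump"),
    # tagatose-6P pathway lump (isomerase + kinase + aldolase)
    "TAG6PSPLIT": ({"gal6p_c": -1, "atp_c": -1,
                    "dhap_c": 1, "g3p_c": 1, "adp_c": 1, "h_c": 1}, (0, _R),
                   "g_lacA and g_lacC and g_lacD", "Tagatose-6-P pathway lump"),
    "LCTS6PH": ({"lcts6p_c": -1, "h2o_c": -1, "glc__D_c": 1, "gal6p_c": 1}, (0, _R),
                "g_lacG", "Phospho-beta-galactosidase"),
    "LCTSH": ({"lcts_c": -1, "h2o_c": -1, "glc__D_c": 1, "gal_c": 1}, (0, _R),
              "g_lacZ", "Beta-galactosidase"),
    "GLK": ({"glc__D_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1}, (0, _R),
            "g_glk", "Glucokinase"),
    "MALT6PH": ({"malt6p_c": -1, "h2o_c": -1, "glc__D_c": 1, "g6p_c": 1}, (0, _R),
                "g_mapP", "Maltose-6-P hydrolase"),
    "MALTH": ({"malt_c": -1, "h2o_c": -1, "glc__D_c": 2}, (0, _R),
              "g_malL", "Maltase"),
    # --- pentoses ------------------------------------------------------
    "XYLI": ({"xyl__D_c": -1, "xylu__D_c": 1}, (-_R, _R), "g_xylA", "Xylose isomerase"),
    "XYLK": ({"xylu__D_c": -1, "atp_c": -1, "xu5p__D_c": 1, "adp_c": 1, "h_c": 1},
             (0, _R), "g_xylB", "Xylulokinase"),
    "RBK": ({"rib__D_c": -1, "atp_c": -1, "r5p_c": 1, "adp_c": 1, "h_c": 1}, (0, _R),
            "g_rbsK", "Ribokinase"),
    "RPEL": ({"r5p_c": -1, "xu5p__D_c": 1}, (-_R, _R), "g_rpe", "Pentose-P epimerase lump"),
    "PKETX": ({"xu5p__D_c": -1, "pi_c": -1, "actp_c": 1, "g3p_c": 1, "h2o_c": 1},
              (0, _R), "g_xpk", "Phosphoketolase"),
    # non-energy-conserving bypass standing in for the nucleotide-loop route:
    # growth stays possible without phosphoketolase, at a lower ATP yield
    "XU5PHL": ({"xu5p__D_c": -1, "ac_c": 1, "g3p_c": 1, "h_c": 1},
               (0, _R), "g_drm and g_deoB", "Xylulose-5-P hydrolysis lump"),
    # --- anaplerosis / amino-acid metabolism ----------------------------
    "PPC": ({"pep_c": -1, "co2_c": -1, "h2o_c": -1, "oaa_c": 1, "pi_c": 1, "h_c": 1},
            (0, _R), "g_ppc", "PEP carboxylase"),
    "CSAKG": ({"accoa_c": -1, "oaa_c": -1, "h2o_c": -1, "nad_c": -1,
               "akg_c": 1, "co2_c": 1, "coa_c": 1, "nadh_c": 1, "h_c": 1}, (0, _R),
              "g_citB and g_icd", "Oxidative TCA branch lump (to 2-oxoglutarate)"),
    "GLUDx": ({"akg_c": -1, "nh4_c": -1, "nadh_c": -1, "h_c": -1,
               "glu__L_c": 1, "h2o_c": 1, "nad_c": 1}, (-_R, _R),
              "g_gdhA", "Glutamate dehydrogenase"),
    "SERSYNL": ({"pep_c": -1, "h2o_c": -2, "nad_c": -1, "glu__L_c": -1,
                 "ser__L_c": 1, "akg_c": 1, "nadh_c": 1, "pi_c": 1, "h_c": 1},
                (0, _R), "g_serA and g_serB", "Serine synthesis lump"),
    "SULFAS": ({"so4_c": -1, "atp_c": -1, "nadh_c": -4, "h_c": -5,
                "h2s_c": 1, "adp_c": 1, "pi_c": 1, "nad_c": 4, "h2o_c": 3}, (0, _R),
               "g_cysD and g_cysIJ", "Sulfate assimilation lump"),
    "CYSSYNL": ({"ser__L_c": -1, "accoa_c": -1, "h2s_c": -1,
                 "cys__L_c": 1, "coa_c": 1, "ac_c": 1, "h_c": 1}, (0, _R),
                "g_cysE and g_cysK", "Cysteine synthesis from serine"),
    "METSYNL": ({"cys__L_c": -1, "pyr_c": -1, "atp_c": -1, "nadh_c": -1, "h_c": -1,
                 "met__L_c": 1, "co2_c": 1, "adp_c": 1, "pi_c": 1, "nad_c": 1},
                (0, _R), "g_metB and g_metE", "Methionine synthesis lump"),
    "LEUSYNL": ({"pyr_c": -2, "accoa_c": -1, "glu__L_c": -1, "h_c": -1,
                 "leu__L_c": 1, "co2_c": 2, "coa_c": 1, "akg_c": 1}, (0, _R),
                "g_leuA and g_leuB and g_leuCD", "Leucine synthesis lump"),
    "ARGDI": ({"arg__L_c": -1, "h2o_c": -1, "adp_c": -1, "pi_c": -1, "h_c": -3,
               "orn_c": 1, "nh4_c": 2, "co2_c": 1, "atp_c": 1}, (0, _R),
              "g_arcA and g_arcB and g_arcC", "Arginine deiminase pathway lump"),
    "CITL": ({"cit_c": -1, "oaa_c": 1, "ac_c": 1}, (0, _R),
             "g_citD and g_citE and g_citF", "Citrate lyase"),
    "OAADC": ({"oaa_c": -1, "h_c": -1, "pyr_c": 1, "co2_c": 1}, (0, _R),
              "g_oad", "Oxaloacetate decarboxylase"),
    # --- gene-evidenced dead-end pathway (withheld from drafts) ---------
    "ALLS6PI": ({"g6p_c": -1, "alls6p_c": 1}, (-_R, _R), "g_alsI",
                "Allose-6-P isomerase"),
    "ALLS6PP": ({"alls6p_c": -1, "h2o_c": -1, "alls_c": 1, "pi_c": 1}, (0, _R),
                "g_alsP", "Allose-6-P phosphatase"),
}

#: reactions toggled by each strain-profile boolean
PATHWAY_REACTIONS: Dict[str, List[str]] = {
    "tag6p": ["GALpts", "TAG6PSPLIT"],
    "leloir": ["GALt", "GALLELOIR"],
    "lactose_pts": ["LCTSpts", "LCTS6PH"],
    "lactose_permease": ["LCTSt", "LCTSH"],
    "xylulokinase": ["XYLK"],
    "phosphoketolase": ["PKETX"],
    "sulfate_assimilation": ["SULFAS"],
    "leucine_synthesis": ["LEUSYNL"],
    "arginine_deiminase": ["ARGDI"],
    "citrate_lyase": ["CITL"],
    "maltose_pts": ["MALTpts", "MALT6PH"],
    "maltose_abc": ["MALTabc", "MALTH"],
}
PROFILE_KEYS = tuple(PATHWAY_REACTIONS)

#: casein machinery lives in the universal model but is stripped from drafts
#: (it is re-attached at simulation time)
CASEIN_REACTIONS = ["CSPEPt", "CSPEPHYD", "EX_cspep_e"]
#: gene-evidenced dead-end pathway used to exercise score-based restoration
DEADEND_REACTIONS = ["ALLS6PI", "ALLS6PP"]
#: reactions without genes that are nevertheless genuine model content
SPONTANEOUS_REACTIONS = ["ETOHt", "CO2t", "H2Ot", "ATPM"]

_EXCHANGE_METS = [
    "glc__D", "gal", "lcts", "malt", "xyl__D", "rib__D", "cit", "arg__L",
    "orn", "glu__L", "leu__L", "cys__L", "met__L", "so4", "fe2", "nh4",
    "pi", "lac__D", "for", "ac", "etoh", "co2", "h", "h2o", "cspep",
]

GENERIC_BIOMASS_ID = "BIOMASS_universal"
STRAIN_BIOMASS_ID = "BIOMASS_lactococcus"

#: amino-acid drains (mmol per gDW); cysteine is exactly 5 % of the total
#: amino-acid requirement (0.05 * total with total = 3.3 * 20/19)
_BIOMASS_AA = {"glu__L_c": 1.0, "leu__L_c": 1.5, "cys__L_c": 3.3 / 19.0,
               "met__L_c": 0.8}
_BIOMASS_GAM = 72.0


def _biomass_stoich(include_fe: bool) -> Dict[str, float]:
    stoich: Dict[str, float] = {m: -c for m, c in _BIOMASS_AA.items()}
    stoich.update({
        "g6p_c": -0.5,
        "accoa_c": -0.05,
        "coa_c": 0.05,
        "atp_c": -_BIOMASS_GAM,
        "h2o_c": -_BIOMASS_GAM,
        "adp_c": _BIOMASS_GAM,
        "pi_c": _BIOMASS_GAM,
        "h_c": _BIOMASS_GAM,
    })
    if include_fe:
        stoich["fe2_c"] = -0.01
    return stoich


def toy_biomass_spec():
    """Strain-specific biomass (drops the generic trace-metal requirement)."""
    from .strain_refinement import BiomassSpec

    return BiomassSpec(id=STRAIN_BIOMASS_ID, stoichiometry=_biomass_stoich(False),
                       name="Lactococcus biomass lump")


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


@dataclass
class ToyManifest:
    """Ground truth for a generated fixture model."""

    seed: int
    model_id: str
    reaction_ids: List[str]
    profile: Dict[str, bool] = field(default_factory=dict)
    species: Optional[str] = None
    removed_reactions: List[str] = field(default_factory=list)
    injected_gapfill: List[str] = field(default_factory=list)
    withheld_scored: List[str] = field(default_factory=list)
    injected_duplicate_reactions: List[List[str]] = field(default_factory=list)
    injected_duplicate_metabolites: List[List[str]] = field(default_factory=list)
    injected_egc_pairs: List[List[str]] = field(default_factory=list)
    spontaneous: List[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class CohortSpec:
    """Parameters of a derived strain cohort.

    Class-specific pathway probabilities emulate the split between a
    plant-associated class (pentose-competent, Leloir galactose route) and a
    dairy-associated class (tagatose-6-P route, no pentose catabolism).
    """

    n: int = 40
    seed: int = 7
    gapfill_per_strain: int = 3
    withhold_deadend: bool = True
    inject_egc: bool = False
    class_probabilities: Optional[Dict[str, Dict[str, float]]] = None

    def probabilities(self) -> Dict[str, Dict[str, float]]:
        if self.class_probabilities is not None:
            return self.class_probabilities
        return {
            "lactis": {
                "tag6p": 0.15, "leloir": 1.0, "lactose_pts": 0.15,
                "lactose_permease": 0.9, "xylulokinase": 1.0,
                "phosphoketolase": 1.0, "sulfate_assimilation": 0.3,
                "leucine_synthesis": 0.6, "arginine_deiminase": 0.95,
                "citrate_lyase": 0.3, "maltose_pts": 1.0, "maltose_abc": 0.5,
            },
            "cremoris": {
                "tag6p": 1.0, "leloir": 0.15, "lactose_pts": 1.0,
                "lactose_permease": 0.1, "xylulokinase": 0.0,
                "phosphoketolase": 0.0, "sulfate_assimilation": 0.1,
                "leucine_synthesis": 0.5, "arginine_deiminase": 0.3,
                "citrate_lyase": 0.15, "maltose_pts": 0.7, "maltose_abc": 0.9,
            },
        }


# ---------------------------------------------------------------------------
# universal model construction
# ---------------------------------------------------------------------------


def _casein_peptide_formula() -> Tuple[str, int]:
    """Formula/charge of the packaged casein oligopeptide.

    The peptide is modelled at a fixed residue scale (1000 residues) so the
    polymerized formula stays integral; hydrolysis releases the free amino
    acids plus the condensation water.
    """
    totals: Dict[str, int] = {}
    charge = 0
    table = {m: (f, c) for m, _, f, c, _, _ in _METS}
    for aa, n in CASEIN_RESIDUES.items():
        f, c = table[aa]
        for el, cnt in parse_formula(f).items():
            totals[el] = totals.get(el, 0) + n * cnt
        charge += n * c
    # remove condensation water for (scale - 1) peptide bonds
    totals["H"] -= 2 * (CASEIN_SCALE - 1)
    totals["O"] -= CASEIN_SCALE - 1
    return formula_to_string(totals), charge


def _add_metabolite(model: Model, base: str, name: str, formula: str,
                    charge: int, comp: str, chebi: str) -> None:
    met = Metabolite(f"{base}_{comp}", formula=formula, name=name, compartment=comp,
                     charge=charge)
    met.annotation["chebi"] = chebi
    model.add_metabolites([met])


def _add_reaction(model: Model, rid: str, stoich: Dict[str, float],
                  bounds: Tuple[float, float], gpr: str, name: str = "") -> Reaction:
    rxn = Reaction(rid, name=name or rid, lower_bound=bounds[0], upper_bound=bounds[1])
    model.add_reactions([rxn])
    rxn.add_metabolites({model.metabolites.get_by_id(m): c for m, c in stoich.items()})
    if gpr:
        rxn.gene_reaction_rule = gpr
    return rxn


def build_toy_universal(
    seed: int = 0,
    inject_duplicates: bool = False,
    inject_egc: bool = False,
) -> Tuple[Model, ToyManifest]:
    """Build the balanced toy universal model.

    ``inject_duplicates`` adds three duplicate reactions (one sign-flipped)
    and two duplicate metabolites for the curation machinery to find;
    ``inject_egc`` adds proton-stoichiometry transport variants of the
    lactate and acetate exporters that create energy-generating cycles.
    All injected artifacts are recorded in the manifest.
    """
    model = Model("toy_universal")
    model.compartments = {"c": "cytosol", "e": "extracellular"}

    for base, name, formula, charge, comps, chebi in _METS:
        for comp in comps:
            _add_metabolite(model, base, name, formula, charge, comp, chebi)
    pep_formula, pep_charge = _casein_peptide_formula()
    for comp in "ce":
        _add_metabolite(model, "cspep", "Casein oligopeptide (1000-residue average)",
                        pep_formula, pep_charge, comp, "CHEBI:60466")

    for base in _EXCHANGE_METS:
        _add_reaction(model, f"EX_{base}_e", {f"{base}_e": -1.0}, (-_R, _R),
                      "", f"{base} exchange")

    for rid, (stoich, bounds, gpr, name) in _REACTIONS.items():
        _add_reaction(model, rid, stoich, bounds, gpr, name)

    # casein machinery (cost-free oligopeptide uptake + peptidase lump)
    _add_reaction(model, "CSPEPt", {"cspep_e": -1, "cspep_c": 1},
                  (0, _R), "g_oppA and g_oppBCDF", "Casein peptide uptake")
    _add_reaction(model, "CSPEPHYD",
                  {"cspep_c": -1.0, "h2o_c": -(CASEIN_SCALE - 1.0),
                   **{f"{aa}_c": float(n) for aa, n in CASEIN_RESIDUES.items()}},
                  (0, _R), "g_pepN", "Casein peptide hydrolysis")

    biomass = _add_reaction(model, GENERIC_BIOMASS_ID, _biomass_stoich(True), (0, _R),
                            "", "Generic biomass")
    set_flags(biomass, {"biomass", "exempt_from_balance"})
    model.objective = GENERIC_BIOMASS_ID

    manifest = ToyManifest(
        seed=seed,
        model_id=model.id,
        reaction_ids=[r.id for r in model.reactions],
        spontaneous=list(SPONTANEOUS_REACTIONS),
    )

    if inject_duplicates:
        dup_r: List[List[str]] = []
        r = _add_reaction(model, "LDH_D_dup",
                          dict(_REACTIONS["LDH_D"][0]), (0, _R), "g_ldhB",
                          "D-lactate dehydrogenase B")
        dup_r.append(["LDH_D", r.id])
        flipped = {m: -c for m, c in _REACTIONS["PGI"][0].items()}
        r = _add_reaction(model, "PGI_rev_dup", flipped, (-_R, _R), "g_pgi2",
                          "Glucose-6-P isomerase (reversed duplicate)")
        dup_r.append(["PGI", r.id])
        r = _add_reaction(model, "ACKr_dup", dict(_REACTIONS["ACKr"][0]), (0, _R),
                          "g_ackB", "Acetate kinase B")
        dup_r.append(["ACKr", r.id])
        manifest.injected_duplicate_reactions = dup_r

        _add_metabolite(model, "lac__D_alt", "D-Lactate (duplicate entry)",
                        "C3H5O3", -1, "c", "CHEBI:16004")
        _add_metabolite(model, "glcdup__D", "D: GLUCOSE!", "C6H12O6", 0, "c",
                        "CHEBI:999999")
        manifest.injected_duplicate_metabolites = [
            ["lac__D_c", "lac__D_alt_c"],   # grouped via shared ChEBI id
            ["glc__D_c", "glcdup__D_c"],    # grouped via canonicalized name
        ]
        manifest.reaction_ids = [x.id for x in model.reactions]

    if inject_egc:
        manifest.injected_egc_pairs = _inject_egc_variants(model)
        manifest.reaction_ids = [x.id for x in model.reactions]

    return model, manifest


def _inject_egc_variants(model: Model) -> List[List[str]]:
    """Add transport variants differing only in proton stoichiometry.

    Paired with the reversible ATPase, each variant pair can pump protons
    outward for free, which closes an ATP-generating cycle even with every
    exchange shut — the classic artifact the pan-model curation hunts.
    """
    pairs = []
    for base, met in (("LACt2", "lac__D"), ("ACt2", "ac")):
        rid = f"{base}_v2"
        _add_reaction(model, rid,
                      {f"{met}_c": -1, "h_c": -2, f"{met}_e": 1, "h_e": 2},
                      (-_R, _R), "", f"{met}/2H+ symport variant")
        pairs.append([base, rid])
    return pairs


# ---------------------------------------------------------------------------
# strain derivation
# ---------------------------------------------------------------------------


def _drop_orphan_genes(model: Model) -> None:
    for gene in [g for g in model.genes if not g.reactions]:
        model.genes.remove(gene)


def derive_strain(
    universal: Model,
    profile: Dict[str, bool],
    seed: int = 0,
    strain_id: str = "strain",
    species: Optional[str] = None,
    gapfill_n: int = 0,
    withhold_deadend: bool = False,
    inject_egc: bool = False,
) -> Tuple[Model, Dict[str, float], ToyManifest]:
    """Derive a draft strain model from the universal model.

    Stands in for a homology-based carving step: pathway reaction sets whose
    profile flag is false are deleted (with their now-orphaned genes), a
    CarveMe-style score table is emitted with positive scores exactly for
    the gene-bearing reactions the strain kept (plus any withheld ones), a
    configurable number of gene-less *gap-filled* reactions is injected from
    the strain's own removed pathway pool, and the gene-evidenced dead-end
    pathway can be withheld to exercise score-based restoration.
    """
    unknown = set(profile) - set(PROFILE_KEYS)
    if unknown:
        raise ValueError(f"unknown profile keys: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    model = universal.copy()
    model.id = strain_id

    removed: List[str] = []
    for key in PROFILE_KEYS:
        if not profile.get(key, True):
            removed.extend(PATHWAY_REACTIONS[key])
    withheld = list(DEADEND_REACTIONS) if withhold_deadend else []
    to_remove = removed + withheld + [
        rid for rid in CASEIN_REACTIONS if rid in model.reactions
    ]
    model.remove_reactions([model.reactions.get_by_id(r) for r in to_remove],
                           remove_orphans=True)
    _drop_orphan_genes(model)

    # CarveMe-style score table: positive scores for gene-evidenced content
    scores: Dict[str, float] = {}
    for rxn in model.reactions:
        if rxn.gene_reaction_rule.strip():
            scores[rxn.id] = round(float(rng.uniform(0.5, 5.0)), 3)
    for rid in withheld:
        scores[rid] = round(float(rng.uniform(0.5, 5.0)), 3)

    # inject gene-less gap-filled reactions from the removed metabolic pool;
    # none of these can carry flux on the glucose medium used for pruning
    gapfill_pool = [
        rid for rid in removed
        if rid in _REACTIONS and rid != "LEUSYNL"
        and len({universal.metabolites.get_by_id(m).compartment
                 for m in _REACTIONS[rid][0]}) == 1
    ]
    injected: List[str] = []
    if gapfill_n and gapfill_pool:
        chosen = rng.choice(gapfill_pool, size=min(gapfill_n, len(gapfill_pool)),
                            replace=False)
        for rid in sorted(str(x) for x in chosen):
            stoich, bounds, _gpr, name = _REACTIONS[rid]
            for mid in stoich:  # species may have left with their pathway
                if mid not in model.metabolites:
                    model.add_metabolites([
                        universal.metabolites.get_by_id(mid).copy()])
            rxn = _add_reaction(model, rid, stoich, bounds, "", name)
            add_flag(rxn, "gap_filled")
            scores[rid] = -0.5
            injected.append(rid)

    egc_pairs: List[List[str]] = []
    if inject_egc:
        egc_pairs = _inject_egc_variants(model)

    manifest = ToyManifest(
        seed=seed,
        model_id=strain_id,
        reaction_ids=[r.id for r in model.reactions],
        profile={k: bool(profile.get(k, True)) for k in PROFILE_KEYS},
        species=species,
        removed_reactions=removed,
        injected_gapfill=injected,
        withheld_scored=withheld,
        injected_egc_pairs=egc_pairs,
        spontaneous=list(SPONTANEOUS_REACTIONS),
    )
    return model, scores, manifest


def generate_cohort(
    spec: CohortSpec, universal: Optional[Model] = None
) -> List[Tuple[Model, Dict[str, float], ToyManifest]]:
    """Generate a reproducible cohort of draft strains with class labels."""
    if spec.n < 2:
        raise ValueError("cohort needs at least two strains")
    if universal is None:
        universal, _ = build_toy_universal(seed=spec.seed)
    rng = np.random.default_rng(spec.seed)
    probs = spec.probabilities()
    out = []
    for i in range(spec.n):
        species = "lactis" if i < (spec.n + 1) // 2 else "cremoris"
        p = probs[species]
        profile = {k: bool(rng.random() < p[k]) for k in PROFILE_KEYS}
        strain_seed = int(rng.integers(0, 2**31 - 1))
        out.append(
            derive_strain(
                universal, profile, seed=strain_seed,
                strain_id=f"{species}_{i:03d}", species=species,
                gapfill_n=spec.gapfill_per_strain,
                withhold_deadend=spec.withhold_deadend,
                inject_egc=spec.inject_egc,
            )
        )
    return out


# ---------------------------------------------------------------------------
# packaged media
# ---------------------------------------------------------------------------


def toy_cdm_spec():
    """Chemically defined medium for the toy universe.

    Glucose as default carbon source at a C-mol bound equivalent to
    20 mmol gDW^-1 h^-1 glucose; every other component capped at
    1 mmol gDW^-1 h^-1; water and protons unconstrained.
    """
    from .sim_suite import CDMSpec

    return CDMSpec(
        components=[
            ("EX_glu__L_e", "amino_acid"),
            ("EX_leu__L_e", "amino_acid"),
            ("EX_cys__L_e", "amino_acid"),
            ("EX_met__L_e", "amino_acid"),
            ("EX_so4_e", "mineral"),
            ("EX_fe2_e", "mineral"),
            ("EX_pi_e", "mineral"),
            ("EX_nh4_e", "base"),
        ],
        free={"EX_h_e", "EX_h2o_e"},
        carbon_source="EX_glc__D_e",
        carbon_atoms=6,
    )


def toy_casein_spec():
    """Casein-peptide composition for the toy universe.

    Cysteine at 0.3 % of residues (versus 5 % of the biomass amino acids);
    the peptide uptake bound gives residue-supply parity with the summed
    free-amino-acid bounds of the CDM, so the composition skew is the only
    difference between the two amino-acid sources.
    """
    from .sim_suite import CaseinSpec

    fractions = {aa: n / CASEIN_SCALE for aa, n in CASEIN_RESIDUES.items()}
    n_aa = len(toy_cdm_spec().amino_acid_exchanges())
    return CaseinSpec(
        aa_fractions=fractions,
        peptide_uptake=n_aa * 1.0 / CASEIN_SCALE,
        residue_scale=CASEIN_SCALE,
    )
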