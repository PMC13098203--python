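"""Independent oracles used by the test suite.

These deliberately avoid the package's own solver path: linear programs are
rebuilt from the raw stoichiometric matrix and solved with scipy's HiGHS
interface (the package uses optlang/GLPK), and the formula parser is checked
against a character-walk reimplementation.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import linprog


# ---------------------------------------------------------------------------
# formula parsing oracle: explicit character walk, no regex
# ---------------------------------------------------------------------------


def charwalk_parse_formula(text: Optional[str]) -> Optional[Dict[str, int]]:
    if not text:
        return None
    counts: Dict[str, int] = {}
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if not ("A" <= ch <= "Z"):
            return None
        element = ch
        i += 1
        if i < n and "a" <= text[i] <= "z":
            element += text[i]
            i += 1
        digits = ""
        while i < n and text[i].isdigit():
            digits += text[i]
            i += 1
        if digits == "":
            count = 1
        else:
            count = int(digits)
            if count <= 0:
                return None
        counts[element] = counts.get(element, 0) + count
    return counts if counts else None


# ---------------------------------------------------------------------------
# LP oracles on the raw stoichiometric matrix (scipy HiGHS)
# ---------------------------------------------------------------------------


def lp_arrays(model) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[str]]:
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rxn_ids = [r.id for r in model.reactions]
    S = np.zeros((len(met_index), len(rxn_ids)))
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    for j, rxn in enumerate(model.reactions):
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for met, coeff in rxn.metabolites.items():
            S[met_index[met.id], j] = coeff
    return S, lb, ub, rxn_ids


def oracle_fba(model, objective_id: str) -> Tuple[str, float, Dict[str, float]]:
    """Maximize one reaction flux subject to Sv=0 and bounds."""
    S, lb, ub, rxn_ids = lp_arrays(model)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_id)] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status == 2:
        return "infeasible", 0.0, {}
    if res.status == 3:
        return "unbounded", 0.0, {}
    fluxes = dict(zip(rxn_ids, res.x))
    return "optimal", -res.fun, fluxes


def oracle_pfba(model, objective_id: str,
                fraction: float = 1.0 - 1e-6
                ) -> Tuple[str, float, float, Dict[str, float]]:
    """Textbook flux-split parsimonious FBA.

    Stage 1 maximizes the objective; stage 2 splits v = p - n (p, n >= 0)
    and minimizes sum(p + n) subject to the objective held at
    ``fraction * optimum``.  Returns (status, fba_optimum, total_abs_flux,
    fluxes).
    """
    status, opt, _ = oracle_fba(model, objective_id)
    if status != "optimal":
        return status, 0.0, 0.0, {}
    S, lb, ub, rxn_ids = lp_arrays(model)
    k = len(rxn_ids)
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])
    obj_row = np.zeros(2 * k)
    j = rxn_ids.index(objective_id)
    obj_row[j] = -1.0
    obj_row[k + j] = 1.0
    A_ub = obj_row.reshape(1, -1)  # -(p_j - n_j) <= -fraction*opt
    b_ub = np.array([-fraction * opt])
    bounds = (
        [(max(l, 0.0), max(u, 0.0)) for l, u in zip(lb, ub)]
        + [(max(-u, 0.0), max(-l, 0.0)) for l, u in zip(lb, ub)]
    )
    c = np.ones(2 * k)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status != 0:
        return "infeasible", opt, 0.0, {}
    p, n = res.x[:k], res.x[k:]
    fluxes = dict(zip(rxn_ids, p - n))
    return "optimal", opt, float(res.fun), fluxes
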