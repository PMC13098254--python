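"""Flux balance analysis and minimal gap-filling.

FBA maximises the biomass objective subject to steady-state mass balance
(S·v = 0) and flux bounds, solved with the HiGHS LP solver.  Growth on a
single carbon source follows the convention used for phenotype simulation:
the chosen carbon exchange is opened to the uptake rate (default
10 mmol/h/gCDW), all other non-medium exchanges are closed to uptake, and
the medium's inorganic exchanges stay open.

Gap-filling finds a minimum-cardinality set of universal-network reactions
whose addition lets the model reach a required growth rate, as a MILP with
one binary indicator per candidate reaction; ties between equally small sets
are broken toward the lexicographically smallest reaction-id set.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, Bounds, linprog, milp

from .errors import GapFillError, ModelError
from .network import Medium, MetabolicNetwork

GROWTH_TOLERANCE = 1e-6  # /h; objective above this counts as growth


@dataclass
class FbaSolution:
    objective: float | None
    fluxes: dict[str, float]
    status: str  # "optimal" | "infeasible" | solver message

    def grows(self, tolerance: float = GROWTH_TOLERANCE) -> bool:
        return self.status == "optimal" and self.objective is not None and self.objective > tolerance


def _environment_bounds(
    network: MetabolicNetwork,
    medium: Medium | None,
    carbon_source: str | None,
    uptake: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-reaction bounds after applying the medium and carbon-source policy."""
    rids = list(network.reactions)
    lb = np.array([network.reactions[r].lower_bound for r in rids], dtype=float)
    ub = np.array([network.reactions[r].upper_bound for r in rids], dtype=float)
    uptakes = medium.uptakes if medium is not None else {}
    if carbon_source is not None and carbon_source not in network.reactions:
        raise ModelError(f"unknown exchange reaction {carbon_source!r}")
    if carbon_source is not None and not network.is_exchange(carbon_source):
        raise ModelError(f"{carbon_source!r} is not an exchange reaction")
    for i, rid in enumerate(rids):
        if not network.is_exchange(rid):
            continue
        if rid == carbon_source:
            lb[i] = -abs(uptake)
        elif rid in uptakes:
            lb[i] = -abs(uptakes[rid])
        else:
            lb[i] = max(lb[i], 0.0)  # uptake closed, secretion still allowed
    return lb, ub


def _stoichiometric_matrix(network: MetabolicNetwork, rids: list[str]) -> sparse.csr_matrix:
    mids = {m: i for i, m in enumerate(network.metabolites)}
    rows, cols, vals = [], [], []
    for j, rid in enumerate(rids):
        for mid, coef in network.reactions[rid].metabolites.items():
            rows.append(mids[mid])
            cols.append(j)
            vals.append(coef)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(len(mids), len(rids)))


def fba(
    network: MetabolicNetwork,
    medium: Medium | None = None,
    carbon_source: str | None = None,
    uptake: float = 10.0,
) -> FbaSolution:
    """Maximise the biomass objective on a single carbon source."""
    rids = list(network.reactions)
    lb, ub = _environment_bounds(network, medium, carbon_source, uptake)
    S = _stoichiometric_matrix(network, rids)
    c = np.zeros(len(rids))
    c[rids.index(network.objective)] = -1.0  # linprog minimises
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=np.column_stack([lb, ub]), method="highs")
    if not res.success:
        status = "infeasible" if res.status == 2 else res.message
        return FbaSolution(None, {}, status)
    return FbaSolution(-res.fun, dict(zip(rids, res.x)), "optimal")


@dataclass
class GapFillResult:
    added: list[str]
    objective_after: float | None
    candidates: int
    already_viable: bool = False
    provenance: dict = field(default_factory=dict)


def _union_network(model: MetabolicNetwork, universal: MetabolicNetwork) -> tuple[MetabolicNetwork, list[str]]:
    missing = universal.reactions.keys() - model.reactions.keys()
    for rid in model.reactions:
        if rid not in universal.reactions:
            raise ModelError(f"model reaction {rid} absent from the universal network; universal must be a superset")
    merged = universal.copy(model.id + "_union")
    return merged, sorted(missing)


def _min_cardinality(
    S: sparse.csr_matrix,
    lb: np.ndarray,
    ub: np.ndarray,
    obj_idx: int,
    cand_idx: list[int],
    min_growth: float,
    forced: list[int],
) -> tuple[int, np.ndarray] | None:
    """Solve the indicator MILP; returns (cardinality, y) or None if infeasible."""
    n, k = S.shape[1], len(cand_idx)
    # variables: v (n fluxes) then y (k binaries)
    c = np.concatenate([np.zeros(n), np.ones(k)])
    cons = [LinearConstraint(sparse.hstack([S, sparse.csr_matrix((S.shape[0], k))]), 0.0, 0.0)]
    growth_row = sparse.csr_matrix(([1.0], ([0], [obj_idx])), shape=(1, n + k))
    cons.append(LinearConstraint(growth_row, min_growth, np.inf))
    # candidate gating: lb_j*y_j <= v_j <= ub_j*y_j
    rows_u, rows_l = [], []
    for pos, j in enumerate(cand_idx):
        ru = sparse.csr_matrix(([1.0, -ub[j]], ([0, 0], [j, n + pos])), shape=(1, n + k))
        rows_u.append(ru)
        rl = sparse.csr_matrix(([1.0, -lb[j]], ([0, 0], [j, n + pos])), shape=(1, n + k))
        rows_l.append(rl)
    if rows_u:
        cons.append(LinearConstraint(sparse.vstack(rows_u), -np.inf, 0.0))
        cons.append(LinearConstraint(sparse.vstack(rows_l), 0.0, np.inf))
    y_lb = np.zeros(k)
    for pos in forced:
        y_lb[pos] = 1.0
    var_bounds = Bounds(np.concatenate([lb, y_lb]), np.concatenate([ub, np.ones(k)]))
    integrality = np.concatenate([np.zeros(n), np.ones(k)])
    res = milp(c, constraints=cons, integrality=integrality, bounds=var_bounds)
    if not res.success:
        return None
    y = np.round(res.x[n:]).astype(int)
    return int(y.sum()), y


def gapfill(
    model: MetabolicNetwork,
    universal: MetabolicNetwork,
    carbon_source: str,
    min_growth: float = GROWTH_TOLERANCE,
    medium: Medium | None = None,
    uptake: float = 10.0,
) -> GapFillResult:
    """Minimum-cardinality reaction additions restoring growth on a substrate.

    Returns the empty set when the model already grows.  When several
    minimum sets exist, the lexicographically smallest sorted tuple of
    reaction ids is returned, enforced by greedily forcing candidates in id
    order and re-solving the cardinality MILP.
    """
    base = fba(model, medium, carbon_source if carbon_source in model.reactions else None, uptake)
    if carbon_source in model.reactions and base.grows(min_growth * 0.999):
        return GapFillResult([], base.objective, 0, already_viable=True)

    merged, candidates = _union_network(model, universal)
    rids = list(merged.reactions)
    lb, ub = _environment_bounds(merged, medium, carbon_source, uptake)
    S = _stoichiometric_matrix(merged, rids)
    obj_idx = rids.index(merged.objective)
    cand_idx = [rids.index(c) for c in candidates]

    # the MILP needs a growth requirement comfortably above the solver's MIP
    # feasibility tolerance; the LP verification below still uses min_growth
    floor = max(min_growth, 1e-3)
    added: list[str] | None = None
    for _ in range(3):
        best = _min_cardinality(S, lb, ub, obj_idx, cand_idx, floor, forced=[])
        if best is None:
            raise GapFillError(
                f"no subset of the {len(candidates)} universal candidate reactions restores "
                f"growth >= {min_growth} on {carbon_source}"
            )
        k, _ = best
        chosen: list[int] = []
        if k > 0:
            for pos, _cid in enumerate(candidates):
                trial = _min_cardinality(S, lb, ub, obj_idx, cand_idx, floor, forced=chosen + [pos])
                if trial is not None and trial[0] == k:
                    chosen.append(pos)
                if len(chosen) == k:
                    break
        trial_added = [candidates[p] for p in chosen]
        check = fba(apply_gapfill(model, universal, trial_added), medium, carbon_source, uptake)
        if check.grows(min_growth * 0.999):
            added = trial_added
            break
        floor *= 100.0  # spurious tolerance-level solution; demand more growth
    if added is None:
        raise GapFillError(
            f"gap-fill candidates on {carbon_source} satisfy the MILP only within solver "
            f"tolerance; no verified solution reaching growth {min_growth}"
        )

    filled = model.copy()
    for rid in added:
        filled.reactions[rid] = universal.reactions[rid].copy()
        for mid in universal.reactions[rid].metabolites:
            if mid not in filled.metabolites:
                m = universal.metabolites[mid]
                filled.metabolites[mid] = type(m)(m.id, m.compartment, m.name)
        filled.genes = sorted(set(filled.genes) | universal.reactions[rid].genes())
    after = fba(filled, medium, carbon_source, uptake)
    return GapFillResult(added, after.objective, len(candidates))


def apply_gapfill(model: MetabolicNetwork, universal: MetabolicNetwork, added: list[str]) -> MetabolicNetwork:
    """Return a copy of ``model`` with the gap-filled reactions inserted."""
    out = model.copy()
    for rid in added:
        r = universal.reactions[rid]
        out.reactions[rid] = r.copy()
        for mid in r.metabolites:
            if mid not in out.metabolites:
                m = universal.metabolites[mid]
                out.metabolites[mid] = type(m)(m.id, m.compartment, m.name)
        out.genes = sorted(set(out.genes) | r.genes())
    out.validate()
    return out
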