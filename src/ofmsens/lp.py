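"""Parametric LP construction and solving for enzyme-constrained FBA.

The ecFBA problem maximizes the objective reaction flux subject to

* steady state            ``S v = 0``
* irreversibility          ``v >= 0`` (models must be reversible-split)
* kcat coupling            ``v_i - kcat_i e_i = 0`` for catalysed reactions
* pool capacities          ``sum_{i in R_k} w_i e_i <= E_k``
* fixed fluxes             ``v_j = c_j`` (encoded as ``lb = ub = c_j``)

:func:`build_lp` assembles the problem together with a record, for every
matrix/vector entry that depends on a named parameter, of the partial
derivative of that entry with respect to the parameter — the raw
material for implicit differentiation.  :func:`solve_lp` obtains a basic
(vertex) optimum with duals via HiGHS dual simplex, and
:func:`fva_at_optimum` measures the variability of each variable at the
optimal objective value (the uniqueness probe used after pruning).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import EcModel, ParamRef, ParameterRegistry, canonical_reaction_order

logger = logging.getLogger(__name__)

__all__ = ["ParamDep", "ParametricLP", "Solution", "build_lp", "solve_lp", "fva_at_optimum"]

#: default solver feasibility tolerance
TOL_FEAS = 1e-9
#: default tolerance for classifying a value as zero/active downstream
TOL_ZERO = 1e-6


@dataclass(frozen=True)
class ParamDep:
    """Linear dependence of one LP entry on a named parameter.

    ``entry = const + coeff * p``; ``kind`` selects the container
    (``"A_eq"``, ``"b_eq"``, ``"A_ub"``, ``"b_ub"``, ``"lb"``, ``"ub"``),
    ``row``/``col`` locate the entry (col is None for right-hand sides,
    row is None for bounds).
    """

    kind: str
    row: int | None
    col: int | None
    param: str
    coeff: float


@dataclass
class ParametricLP:
    variables: list[str]
    var_kind: list[str]  # "flux" | "isozyme_flux" | "enzyme"
    c: np.ndarray  # objective, maximized
    A_eq: np.ndarray
    b_eq: np.ndarray
    eq_row_ids: list[str]
    A_ub: np.ndarray
    b_ub: np.ndarray
    ub_row_ids: list[str]
    lb: np.ndarray
    ub: np.ndarray
    param_deps: list[ParamDep]
    model: EcModel
    params: ParameterRegistry
    #: flux variable index of the objective reaction
    objective_var: int = 0
    var_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.var_index:
            self.var_index = {v: i for i, v in enumerate(self.variables)}

    @property
    def n(self) -> int:
        return len(self.variables)

    def dep_params(self) -> list[str]:
        """Parameter names appearing anywhere in the problem, sorted."""
        return sorted({d.param for d in self.param_deps})


@dataclass
class Solution:
    status: str  # "optimal" | "infeasible" | "unbounded" | "failed"
    variables: list[str]
    x: np.ndarray
    objective_value: float
    duals_eq: np.ndarray
    duals_ub: np.ndarray
    duals_lb: np.ndarray
    duals_ubnd: np.ndarray

    @property
    def primal(self) -> dict[str, float]:
        return dict(zip(self.variables, self.x))

    def __getitem__(self, var: str) -> float:
        return float(self.x[self.variables.index(var)])


def enzyme_var_names(model: EcModel) -> dict[tuple[str, int], str]:
    """Stable names for the enzyme-concentration variables.

    One variable per (reaction, isozyme) pair; reactions with a single
    isozyme get the shorter ``e__<rxn>`` name.
    """
    names = {}
    for r in model.reactions:
        for i, _ in enumerate(r.isozymes):
            names[(r.id, i)] = f"e__{r.id}" if len(r.isozymes) == 1 else f"e__{r.id}__{i}"
    return names


def build_lp(model: EcModel, params: ParameterRegistry | None = None) -> ParametricLP:
    """Assemble the parametric ecFBA linear program.

    The model must be validated and reversible-split (all lower bounds
    nonnegative).  Reactions with several isozymes are expanded into
    parallel isozyme flux variables that sum to the reaction flux, each
    with its own kcat coupling and enzyme variable.  Pool rows weight
    each enzyme by the summed molar mass of its subunits that belong to
    the pool, so capacities are in mg·gDCW⁻¹.
    """
    reg = params if params is not None else model.registry()
    rxn_order = canonical_reaction_order(model)
    rxn = {r.id: r for r in model.reactions}
    enames = enzyme_var_names(model)

    variables: list[str] = list(rxn_order)
    var_kind: list[str] = ["flux"] * len(rxn_order)
    # isozyme flux variables for multi-isozyme reactions
    iso_flux: dict[tuple[str, int], int] = {}
    for rid in rxn_order:
        r = rxn[rid]
        if len(r.isozymes) > 1:
            for i in range(len(r.isozymes)):
                iso_flux[(rid, i)] = len(variables)
                variables.append(f"{rid}#iso{i}")
                var_kind.append("isozyme_flux")
    enzyme_idx: dict[tuple[str, int], int] = {}
    for rid in rxn_order:
        r = rxn[rid]
        for i in range(len(r.isozymes)):
            enzyme_idx[(rid, i)] = len(variables)
            variables.append(enames[(rid, i)])
            var_kind.append("enzyme")
    n = len(variables)
    vidx = {v: i for i, v in enumerate(variables)}

    deps: list[ParamDep] = []
    eq_rows: list[np.ndarray] = []
    b_eq: list[float] = []
    eq_ids: list[str] = []

    def _resolve(value, where):
        try:
            return reg.resolve(value)
        except KeyError:
            raise KeyError(f"{where}: unresolved parameter {value.name!r}") from None

    # steady state, one row per metabolite (canonical metabolite order)
    for m in sorted(model.metabolites, key=lambda m: m.id):
        row = np.zeros(n)
        for rid in rxn_order:
            coef = rxn[rid].stoichiometry.get(m.id)
            if coef:
                row[vidx[rid]] = coef
        eq_rows.append(row)
        b_eq.append(0.0)
        eq_ids.append(f"mb__{m.id}")

    # isozyme expansion: v_rxn - sum_i v_iso = 0
    for rid in rxn_order:
        r = rxn[rid]
        if len(r.isozymes) > 1:
            row = np.zeros(n)
            row[vidx[rid]] = 1.0
            for i in range(len(r.isozymes)):
                row[iso_flux[(rid, i)]] = -1.0
            eq_rows.append(row)
            b_eq.append(0.0)
            eq_ids.append(f"isosum__{rid}")

    # kcat couplings: v - kcat * e = 0 (exactly two nonzeros per row)
    for rid in rxn_order:
        r = rxn[rid]
        for i, iso in enumerate(r.isozymes):
            kc = iso.kcat_forward
            kval = _resolve(kc, f"reaction {rid!r} isozyme {i} kcat")
            row = np.zeros(n)
            fcol = iso_flux.get((rid, i), vidx[rid])
            ecol = enzyme_idx[(rid, i)]
            row[fcol] = 1.0
            row[ecol] = -kval
            ridx = len(eq_rows)
            eq_rows.append(row)
            b_eq.append(0.0)
            eq_ids.append(f"cpl__{rid}" if len(r.isozymes) == 1 else f"cpl__{rid}__{i}")
            if isinstance(kc, ParamRef):
                deps.append(ParamDep("A_eq", ridx, ecol, kc.name, -1.0))

    # pool capacity rows: sum_e w_e * e <= E_k
    masses = {g.id: g.molar_mass for g in model.gene_products}
    ub_rows: list[np.ndarray] = []
    b_ub: list[float] = []
    ub_ids: list[str] = []
    for p in sorted(model.pools, key=lambda p: p.id):
        row = np.zeros(n)
        members = set(p.members)
        for (rid, i), ecol in enzyme_idx.items():
            iso = rxn[rid].isozymes[i]
            w = sum(
                cnt * masses[g] for g, cnt in iso.subunit_counts.items() if g in members
            )
            if w:
                row[ecol] += w
        cap = _resolve(p.capacity, f"pool {p.id!r} capacity")
        ridx = len(ub_rows)
        ub_rows.append(row)
        b_ub.append(cap)
        ub_ids.append(f"pool__{p.id}")
        if isinstance(p.capacity, ParamRef):
            deps.append(ParamDep("b_ub", ridx, None, p.capacity.name, 1.0))

    # variable bounds
    lb = np.zeros(n)
    ub = np.full(n, math.inf)
    for rid in rxn_order:
        r = rxn[rid]
        col = vidx[rid]
        lbv = _resolve(r.lower_bound, f"reaction {rid!r} lower_bound")
        ubv = _resolve(r.upper_bound, f"reaction {rid!r} upper_bound")
        if lbv < 0:
            raise ValueError(
                f"reaction {rid!r} has negative lower bound {lbv}; run split_reversible first"
            )
        lb[col], ub[col] = lbv, ubv
        if isinstance(r.lower_bound, ParamRef):
            deps.append(ParamDep("lb", None, col, r.lower_bound.name, 1.0))
        if isinstance(r.upper_bound, ParamRef):
            deps.append(ParamDep("ub", None, col, r.upper_bound.name, 1.0))
    for f in model.fixed_fluxes:
        col = vidx[f.reaction_id]
        cval = _resolve(f.value, f"fixed flux on {f.reaction_id!r}")
        lb[col] = ub[col] = cval
        if isinstance(f.value, ParamRef):
            deps.append(ParamDep("lb", None, col, f.value.name, 1.0))
            deps.append(ParamDep("ub", None, col, f.value.name, 1.0))

    c = np.zeros(n)
    for rid in rxn_order:
        c[vidx[rid]] = rxn[rid].objective_coefficient
    obj = model.objective_id()
    if c[vidx[obj]] == 0:
        c[vidx[obj]] = 1.0

    return ParametricLP(
        variables=variables,
        var_kind=var_kind,
        c=c,
        A_eq=np.array(eq_rows) if eq_rows else np.zeros((0, n)),
        b_eq=np.array(b_eq),
        eq_row_ids=eq_ids,
        A_ub=np.array(ub_rows) if ub_rows else np.zeros((0, n)),
        b_ub=np.array(b_ub),
        ub_row_ids=ub_ids,
        lb=lb,
        ub=ub,
        param_deps=deps,
        model=model,
        params=reg,
        objective_var=vidx[obj],
    )


_STATUS = {0: "optimal", 1: "failed", 2: "infeasible", 3: "unbounded", 4: "failed"}

_SOLVER_OPTS = {"presolve": True}


def solve_lp(lp: ParametricLP, tol_feas: float = TOL_FEAS) -> Solution:
    """Solve to a basic (vertex) optimum with duals.

    Uses HiGHS dual simplex so the returned solution is a vertex and
    deterministic across repeated calls.  Infeasible/unbounded problems
    are reported through ``Solution.status``, never as exceptions.
    """
    res = linprog(
        -lp.c,
        A_ub=lp.A_ub if lp.A_ub.size else None,
        b_ub=lp.b_ub if lp.A_ub.size else None,
        A_eq=lp.A_eq if lp.A_eq.size else None,
        b_eq=lp.b_eq if lp.A_eq.size else None,
        bounds=list(zip(lp.lb, lp.ub)),
        method="highs-ds",
        options=dict(_SOLVER_OPTS),
    )
    status = _STATUS.get(res.status, "failed")
    n = lp.n
    if status != "optimal":
        z = np.zeros(n)
        return Solution(status, lp.variables, z, math.nan, z[:0], z[:0], z, z)
    # convert HiGHS marginals (for the minimized problem) to the package's
    # convention: maximize c'x, duals of <=-rows and bounds are >= 0 and
    # satisfy c = A_eq'λ + A_ub'μ - ν_lb + ν_ub.
    duals_eq = -np.asarray(res.eqlin.marginals) if lp.A_eq.size else np.zeros(0)
    duals_ub = -np.asarray(res.ineqlin.marginals) if lp.A_ub.size else np.zeros(0)
    duals_lb = np.asarray(res.lower.marginals)
    duals_ubnd = -np.asarray(res.upper.marginals)
    return Solution(
        status="optimal",
        variables=list(lp.variables),
        x=np.asarray(res.x),
        objective_value=float(lp.c @ res.x),
        duals_eq=duals_eq,
        duals_ub=duals_ub,
        duals_lb=duals_lb,
        duals_ubnd=duals_ubnd,
    )


def fva_at_optimum(
    lp: ParametricLP,
    sol: Solution,
    tol_feas: float = TOL_FEAS,
    variables: list[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Flux (and enzyme) variability with the objective fixed at its optimum.

    Adds the constraint ``c'x >= z* - tol`` and minimizes/maximizes each
    requested variable.  Zero-width ranges for every variable certify a
    unique optimum.
    """
    if sol.status != "optimal":
        raise ValueError("fva_at_optimum requires an optimal solution")
    zstar = sol.objective_value
    eps = tol_feas * max(1.0, abs(zstar))
    obj_row = -lp.c.reshape(1, -1)
    A_ub = np.vstack([lp.A_ub, obj_row]) if lp.A_ub.size else obj_row
    b_ub = np.concatenate([lp.b_ub, [-(zstar - eps)]]) if lp.A_ub.size else np.array([-(zstar - eps)])
    bounds = list(zip(lp.lb, lp.ub))
    out: dict[str, tuple[float, float]] = {}
    targets = variables if variables is not None else lp.variables
    for v in targets:
        col = lp.var_index[v]
        w = np.zeros(lp.n)
        w[col] = 1.0
        lohi = []
        for sign in (1.0, -1.0):
            res = linprog(
                sign * w,
                A_ub=A_ub,
                b_ub=b_ub,
                A_eq=lp.A_eq if lp.A_eq.size else None,
                b_eq=lp.b_eq if lp.A_eq.size else None,
                bounds=bounds,
                method="highs",
            )
            if res.status != 0:
                raise RuntimeError(f"FVA subproblem for {v!r} failed: {res.message}")
            lohi.append(sign * res.fun)
        out[v] = (lohi[0], lohi[1])
    return out


def check_kkt(lp: ParametricLP, sol: Solution, tol: float = 1e-6) -> dict[str, float]:
    """Residuals of primal feasibility, stationarity and complementary
    slackness at a solution; used by tests and diagnostics."""
    x = sol.x
    res = {}
    res["eq"] = float(np.max(np.abs(lp.A_eq @ x - lp.b_eq))) if lp.A_eq.size else 0.0
    slack = lp.b_ub - lp.A_ub @ x if lp.A_ub.size else np.zeros(0)
    res["ub"] = float(max(0.0, -slack.min())) if slack.size else 0.0
    res["bounds"] = float(
        max(np.max(np.clip(lp.lb - x, 0, None)), np.max(np.clip(x - lp.ub, 0, None)))
    )
    stat = lp.c.copy()
    if lp.A_eq.size:
        stat -= lp.A_eq.T @ sol.duals_eq
    if lp.A_ub.size:
        stat -= lp.A_ub.T @ sol.duals_ub
    stat += sol.duals_lb - sol.duals_ubnd
    res["stationarity"] = float(np.max(np.abs(stat)))
    res["comp_slack"] = float(np.max(np.abs(slack * sol.duals_ub))) if slack.size else 0.0
    return res
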