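"""Exact parameter sensitivities of a pruned optimum via implicit
differentiation of the KKT conditions.

At a unique vertex optimum the active constraints, collected as
``M(p) x = b(p)``, determine the solution.  Differentiating stationarity
``c - M'y = 0`` and feasibility ``M x = b`` with respect to a parameter
``p`` gives the linear system

    M dx = db/dp - (dM/dp) x
    M' dy = -(dM/dp)' y

so one LU factorization of ``M`` yields the sensitivities of every
variable to every parameter.  kcats enter ``M`` through the coupling
rows; pool capacities, fixed-flux values and simple bounds enter ``b``.
Parameters absent from the active rows have exactly-zero columns.

The scaled form ``(p/x) dx/dp`` (a control coefficient, the log-log
response) and a central-finite-difference oracle for cross-checking are
also provided here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .lp import TOL_ZERO, ParamDep, ParametricLP, Solution, build_lp, solve_lp
from .model import EcModel, ParameterRegistry

logger = logging.getLogger(__name__)

__all__ = [
    "ActiveSet",
    "SensitivityMatrix",
    "detect_active_set",
    "kkt_differentiate",
    "control_coefficients",
    "finite_difference_oracle",
]

#: default activity tolerance for constraint slacks and duals
TOL_ACT = 1e-7


class DegenerateSolutionError(RuntimeError):
    pass


@dataclass
class ActiveSet:
    """The active constraints of a vertex optimum, as a square system."""

    M: np.ndarray  # (n x n) after redundancy elimination
    b: np.ndarray
    row_labels: list[str]
    #: per active row, the ParamDeps that touch it (col None for rhs)
    row_deps: list[list[ParamDep]]
    y: np.ndarray  # duals solving M' y = c
    dropped: list[str] = field(default_factory=list)

    def fingerprint(self) -> str:
        return "|".join(self.row_labels)


@dataclass
class SensitivityMatrix:
    """dx/dp for all variable-parameter pairs, raw and optionally scaled."""

    raw: pd.DataFrame  # rows: variables, columns: parameters
    scaled: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def variables(self) -> list[str]:
        return list(self.raw.index)

    @property
    def parameters(self) -> list[str]:
        return list(self.raw.columns)


def detect_active_set(
    lp: ParametricLP, sol: Solution, tol_act: float = TOL_ACT
) -> ActiveSet:
    """Identify the active constraints at a (unique) vertex optimum.

    All equality rows are active; a ≤-row is active when its slack is
    below ``tol_act`` (a warning is emitted if its dual is also ~0,
    since the derivative is then only one-sided); variable bounds are
    active when attained, with ``lb == ub`` (fixed fluxes) contributing
    a single row.  Redundant rows (e.g. conserved-moiety steady-state
    rows) are dropped by a rank-revealing QR; fewer independent active
    rows than variables raises :class:`DegenerateSolutionError`.
    """
    if sol.status != "optimal":
        raise ValueError("active set requires an optimal solution")
    n = lp.n
    x = sol.x
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    labels: list[str] = []
    keys: list[tuple[str, int]] = []

    for i in range(lp.A_eq.shape[0]):
        rows.append(lp.A_eq[i])
        rhs.append(lp.b_eq[i])
        labels.append(lp.eq_row_ids[i])
        keys.append(("A_eq", i))
    for i in range(lp.A_ub.shape[0]):
        slack = lp.b_ub[i] - lp.A_ub[i] @ x
        if slack <= tol_act * max(1.0, abs(lp.b_ub[i])):
            if sol.duals_ub[i] <= tol_act:
                logger.warning(
                    "active row %s has ~zero dual (strict complementarity fails); "
                    "the reported derivative is one-sided",
                    lp.ub_row_ids[i],
                )
            rows.append(lp.A_ub[i])
            rhs.append(lp.b_ub[i])
            labels.append(lp.ub_row_ids[i])
            keys.append(("A_ub", i))
    for j in range(n):
        lbj, ubj = lp.lb[j], lp.ub[j]
        scale = max(1.0, abs(x[j]))
        unit = np.zeros(n)
        unit[j] = 1.0
        if lbj == ubj:
            rows.append(unit)
            rhs.append(lbj)
            labels.append(f"fix__{lp.variables[j]}")
            keys.append(("fix", j))
        elif x[j] - lbj <= tol_act * scale:
            rows.append(unit)
            rhs.append(lbj)
            labels.append(f"lb__{lp.variables[j]}")
            keys.append(("lb", j))
        elif np.isfinite(ubj) and ubj - x[j] <= tol_act * scale:
            rows.append(unit)
            rhs.append(ubj)
            labels.append(f"ub__{lp.variables[j]}")
            keys.append(("ub", j))

    if len(rows) < n:
        raise DegenerateSolutionError(
            f"non-vertex solution: {len(rows)} active constraints < {n} variables"
        )

    M_full = np.array(rows)
    # rank-revealing QR of M' picks a maximal independent row subset
    _, R, piv = scipy.linalg.qr(M_full.T, pivoting=True, mode="economic")
    diag = np.abs(np.diag(R))
    rank_tol = 1e-9 * (diag[0] if diag.size else 1.0)
    rank = int(np.sum(diag > rank_tol))
    if rank < n:
        raise DegenerateSolutionError(
            f"active constraint matrix has rank {rank} < {n}; "
            "run verify_unique / check for duplicated columns"
        )
    keep = sorted(piv[:rank])
    dropped = [labels[i] for i in range(len(rows)) if i not in set(keep)]
    for d in dropped:
        logger.info("dropping redundant active row %s", d)

    M = M_full[keep]
    b = np.array([rhs[i] for i in keep])
    kept_labels = [labels[i] for i in keep]
    kept_keys = [keys[i] for i in keep]

    # map parameter dependences onto kept rows
    deps_by_key: dict[tuple[str, int], list[ParamDep]] = {}
    for d in lp.param_deps:
        if d.kind in ("A_eq", "b_eq"):
            deps_by_key.setdefault(("A_eq", d.row), []).append(d)
        elif d.kind in ("A_ub", "b_ub"):
            deps_by_key.setdefault(("A_ub", d.row), []).append(d)
        elif d.kind in ("lb", "ub"):
            j = d.col
            if lp.lb[j] == lp.ub[j]:
                # fixed flux: lb and ub deps coincide on the single "fix" row
                deps_by_key.setdefault(("fix", j), []).append(d)
            else:
                deps_by_key.setdefault((d.kind, j), []).append(d)
    row_deps = []
    for key in kept_keys:
        ds = deps_by_key.get(key, [])
        if key[0] == "fix":
            # one rhs dep per parameter, not one per (lb, ub) record
            seen = {}
            for d in ds:
                seen[d.param] = ParamDep("b", None, None, d.param, d.coeff)
            ds = list(seen.values())
        row_deps.append(ds)

    y = scipy.linalg.solve(M.T, lp.c)
    resid = np.max(np.abs(M.T @ y - lp.c))
    if resid > 1e-6 * max(1.0, float(np.max(np.abs(lp.c)))):
        raise DegenerateSolutionError(f"stationarity residual {resid:.3g} at active set")
    return ActiveSet(M=M, b=b, row_labels=kept_labels, row_deps=row_deps, y=y, dropped=dropped)


def kkt_differentiate(
    lp: ParametricLP,
    sol: Solution,
    active: ActiveSet,
    params: list[str] | None = None,
) -> SensitivityMatrix:
    """Solve the differentiated KKT system for each parameter.

    One factorization of the active matrix is reused for every
    parameter, so differentiating parameters singly or in batch gives
    bitwise-identical results.
    """
    names = params if params is not None else lp.dep_params()
    n = lp.n
    M = active.M
    lu = scipy.linalg.lu_factor(M)
    x = sol.x

    # collect the active-row dependences per parameter
    per_param: dict[str, list[tuple[int, ParamDep]]] = {p: [] for p in names}
    for i, ds in enumerate(active.row_deps):
        for d in ds:
            if d.param in per_param:
                per_param[d.param].append((i, d))

    cols = {}
    for p in names:
        touches = per_param[p]
        if not touches:
            cols[p] = np.zeros(n)
            continue
        dM = np.zeros_like(M)
        db = np.zeros(n)
        for i, d in touches:
            if d.kind in ("A_eq", "A_ub") and d.col is not None:
                dM[i, d.col] += d.coeff
            else:  # rhs-type dependence (b_eq, b_ub, bounds, fixed fluxes)
                db[i] += d.coeff
        rhs = db - dM @ x
        cols[p] = scipy.linalg.lu_solve(lu, rhs)

    raw = pd.DataFrame(cols, index=lp.variables, columns=names)
    meta = {
        "active_set": active.fingerprint(),
        "dropped_rows": active.dropped,
        "n_variables": n,
    }
    return SensitivityMatrix(raw=raw, metadata=meta)


def control_coefficients(
    sens: SensitivityMatrix,
    sol: Solution,
    params: ParameterRegistry,
    tol_zero: float = TOL_ZERO,
) -> SensitivityMatrix:
    """Scale raw sensitivities to control coefficients (p/x)·dx/dp.

    Entries for variables with ``|x| <= tol_zero`` are undefined and
    reported as NaN, not zero.
    """
    xs = pd.Series(dict(zip(sol.variables, sol.x))).reindex(sens.raw.index)
    pvals = pd.Series({p: params[p] for p in sens.raw.columns})
    scaled = sens.raw.mul(pvals, axis=1).div(xs, axis=0)
    scaled[np.abs(xs) <= tol_zero] = np.nan
    return SensitivityMatrix(raw=sens.raw, scaled=scaled, metadata=dict(sens.metadata))


def finite_difference_oracle(
    model: EcModel,
    params: ParameterRegistry,
    names: list[str],
    rel_step: float = 1e-3,
) -> SensitivityMatrix:
    """Central finite differences on the (pruned) model, re-solving the LP
    at ``p·(1 ± rel_step)`` for each named parameter.

    This is the slow-but-independent comparator for
    :func:`kkt_differentiate`; no re-pruning is performed.  A perturbed
    problem that fails to solve flags the whole column as missing (NaN)
    with a warning.
    """
    if rel_step <= 0:
        raise ValueError("rel_step must be positive")
    base_lp = build_lp(model, params)
    variables = base_lp.variables
    cols = {}
    for p in names:
        h = rel_step * params[p]
        if h == 0:
            raise ValueError(f"parameter {p!r} is zero; relative step degenerates")
        xs = []
        for sgn in (+1.0, -1.0):
            reg = params.perturbed(p, sgn * h)
            s = solve_lp(build_lp(model, reg))
            if s.status != "optimal":
                logger.warning("perturbed problem (%s %+g) is %s; column flagged missing", p, sgn * h, s.status)
                xs = None
                break
            xs.append(s.x)
        cols[p] = np.full(len(variables), np.nan) if xs is None else (xs[0] - xs[1]) / (2 * h)
    raw = pd.DataFrame(cols, index=variables, columns=names)
    return SensitivityMatrix(raw=raw, metadata={"method": "central-fd", "rel_step": rel_step})
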