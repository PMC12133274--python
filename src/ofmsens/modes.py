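"""Optimal flux modes: homogenization, Double Description enumeration,
decomposition of the optimum, and differentiation of mode usage.

Elementary flux modes (EFMs) are the support-minimal rays of the flux
cone ``{v | Sv = 0, v >= 0}``.  Inhomogeneous constraints — fixed fluxes
such as ATP maintenance, and the objective held at its optimal value —
break the cone structure; appending their aggregated stoichiometric
contribution ``w = S_fixed · v_fixed`` as an extra column with a slack
coordinate ``v̄`` restores it:

    A = [S_free | w],   x = [v_free; v̄],   cone {x | A x = 0, x >= 0}.

At ``v̄ = 1`` the homogenized system reproduces the original problem, so
the extreme rays with ``v̄ > 0``, rescaled to ``v̄ = 1``, are the optimal
flux modes (OFMs): support-minimal pathways that deliver the fixed
fluxes and the optimal objective.  The pruned optimum is a convex
combination of at most K OFMs, K the number of enzyme-pool constraints,
with weights λ summing to one (read off the v̄ coordinate).

Because the optimal objective value enters ``w``, the cone — and hence
each OFM — shifts when a kinetic parameter moves; the usage
sensitivities ∂λ/∂p therefore combine the whole-solution sensitivities
with the induced ray displacement (chain rule), and are cross-checked by
a finite-difference oracle that re-enumerates the OFMs per perturbation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.linalg import null_space
from scipy.optimize import nnls

from .lp import TOL_ZERO, Solution, build_lp, solve_lp
from .model import ParameterRegistry, canonical_reaction_order
from .prune import PrunedModel
from .sensitivity import SensitivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "HomogenizedSystem",
    "FluxMode",
    "OfmDecomposition",
    "homogenize",
    "double_description",
    "brute_force_modes",
    "ofms",
    "decompose",
    "ofm_sensitivity",
    "ofm_usage_fd",
    "DecompositionError",
]


class DecompositionError(RuntimeError):
    pass


class UnsupportedParameterError(ValueError):
    pass


@dataclass
class HomogenizedSystem:
    """The cone matrix ``A = [S_free | w]`` of a pruned model."""

    A: np.ndarray
    metabolite_ids: list[str]
    free_reactions: list[str]
    has_vbar: bool
    #: folded reaction id -> its fixed value (includes the objective when folded)
    fixed_values: dict[str, float] = field(default_factory=dict)
    #: columns of the folded reactions in metabolite space
    fixed_columns: dict[str, np.ndarray] = field(default_factory=dict)
    objective_reaction: str | None = None
    #: parameter names that feed fixed-flux values (unsupported in ofm_sensitivity)
    fixed_param_names: set[str] = field(default_factory=set)

    @property
    def S_free(self) -> np.ndarray:
        return self.A[:, : len(self.free_reactions)] if self.has_vbar else self.A

    @property
    def w(self) -> np.ndarray | None:
        return self.A[:, -1] if self.has_vbar else None


@dataclass
class FluxMode:
    """A nonnegative steady-state mode over the free reactions.

    OFMs carry ``vbar == 1`` (they deliver the fixed fluxes and the
    optimal objective once); purely homogeneous EFMs have ``vbar None``
    and are normalized to unit L1 norm.
    """

    values: np.ndarray
    reaction_ids: list[str]
    vbar: float | None = None
    tol: float = TOL_ZERO

    @property
    def support(self) -> frozenset[str]:
        scale = max(self.values.max(), 1.0 if self.vbar else 0.0)
        return frozenset(
            r for r, v in zip(self.reaction_ids, self.values) if v > self.tol * scale
        )

    def __getitem__(self, rid: str) -> float:
        return float(self.values[self.reaction_ids.index(rid)])


@dataclass
class OfmDecomposition:
    modes: list[FluxMode]
    weights: np.ndarray
    residual: float
    K: int

    @property
    def n_active(self) -> int:
        return int(np.sum(self.weights > TOL_ZERO))


def homogenize(
    pruned: PrunedModel,
    sol: Solution,
    params: ParameterRegistry | None = None,
    fold_objective: bool = True,
    tol_feas: float = 1e-8,
) -> HomogenizedSystem:
    """Build the homogenized cone matrix of a pruned model.

    Active inhomogeneous constraints — every fixed flux, plus the
    objective reaction at its optimal value when ``fold_objective`` is
    set (the default; this is what makes the rays *optimal* flux modes)
    — contribute stoichiometry-times-value to the extra column ``w``.
    With no fixed flux and ``fold_objective=False`` the system
    degenerates to the plain flux cone FC(S) (EFM mode, no ``v̄``).
    """
    model = pruned.model
    reg = params if params is not None else model.registry()
    if sol.status != "optimal":
        raise ValueError("homogenize requires the pruned optimal solution")
    x = dict(zip(sol.variables, sol.x))

    met_ids = sorted(m.id for m in model.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rxn_order = canonical_reaction_order(model)
    obj = model.objective_id()

    fixed_values: dict[str, float] = {}
    fixed_param_names: set[str] = set()
    for f in model.fixed_fluxes:
        fixed_values[f.reaction_id] = reg.resolve(f.value)
        from .model import ParamRef

        if isinstance(f.value, ParamRef):
            fixed_param_names.add(f.value.name)
    if fold_objective and obj not in fixed_values:
        fixed_values[obj] = x[obj]

    free = [r for r in rxn_order if r not in fixed_values]
    rxn = {r.id: r for r in model.reactions}

    def column(rid: str) -> np.ndarray:
        col = np.zeros(len(met_ids))
        for m, c in rxn[rid].stoichiometry.items():
            col[met_index[m]] = c
        return col

    S_free = np.column_stack([column(r) for r in free]) if free else np.zeros((len(met_ids), 0))
    if not fixed_values:
        hs = HomogenizedSystem(
            A=S_free,
            metabolite_ids=met_ids,
            free_reactions=free,
            has_vbar=False,
            objective_reaction=obj,
        )
        logger.info("no inhomogeneous constraint: falling back to the plain flux cone (EFMs)")
        return hs
    fixed_columns = {r: column(r) for r in fixed_values}
    w = np.zeros(len(met_ids))
    for r, v in fixed_values.items():
        w += fixed_columns[r] * v
    A = np.column_stack([S_free, w])
    hs = HomogenizedSystem(
        A=A,
        metabolite_ids=met_ids,
        free_reactions=free,
        has_vbar=True,
        fixed_values=fixed_values,
        fixed_columns=fixed_columns,
        objective_reaction=obj,
        fixed_param_names=fixed_param_names,
    )
    xref = np.array([x[r] for r in free] + [1.0])
    resid = np.max(np.abs(A @ xref)) if A.size else 0.0
    if resid > tol_feas * max(1.0, float(np.max(np.abs(xref)))):
        raise RuntimeError(f"homogenized system violated by reference solution (residual {resid:.3g})")
    return hs


# ----------------------------------------------------------------------
# Double Description
# ----------------------------------------------------------------------

def double_description(A: np.ndarray, tol: float = 1e-9) -> list[np.ndarray]:
    """Enumerate the extreme rays of the pointed cone {x | A x = 0, x >= 0}.

    Works in null-space coordinates: with ``N`` a basis of null(A), the
    cone is the preimage of {z | N z >= 0}.  The algorithm starts from a
    simplicial cone formed by d independent nonnegativity constraints
    and inserts the remaining ones incrementally, combining adjacent
    ray pairs of opposite sign; adjacency uses the algebraic rank test.
    Constraints are inserted by descending nonzero count of the
    corresponding columns of ``A`` (a growth-limiting heuristic), and
    the output is canonically ordered by support, so the enumeration is
    deterministic.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n = A.shape[1]
    N = null_space(A)
    d = N.shape[1]
    if d == 0:
        return []
    B = N  # row i of B is the constraint x_i = B[i] @ z >= 0

    nnz = (np.abs(A) > tol).sum(axis=0)
    order = sorted(range(n), key=lambda i: (-nnz[i], i))

    # initial simplicial cone from d independent constraints
    chosen: list[int] = []
    basis = np.zeros((0, d))
    for i in order:
        if len(chosen) == d:
            break
        cand = np.vstack([basis, B[i]])
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) > basis.shape[0]:
            chosen.append(i)
            basis = cand
    if len(chosen) < d:
        # N has full column rank, so this cannot happen for consistent input
        raise RuntimeError("could not find an independent constraint subset")
    rays = list(np.linalg.inv(basis).T)  # columns of basis^-1
    rays = [r / np.linalg.norm(r) for r in rays]
    processed = list(chosen)

    def zero_set(r: np.ndarray) -> frozenset[int]:
        vals = B[processed] @ r
        scale = max(1.0, float(np.abs(vals).max()))
        return frozenset(i for i, v in zip(processed, vals) if abs(v) <= tol * scale)

    for i in order:
        if i in chosen:
            continue
        vals = {id(r): float(B[i] @ r) for r in rays}
        scale = max(1.0, max((abs(v) for v in vals.values()), default=1.0))
        pos = [r for r in rays if vals[id(r)] > tol * scale]
        neg = [r for r in rays if vals[id(r)] < -tol * scale]
        zer = [r for r in rays if abs(vals[id(r)]) <= tol * scale]
        processed.append(i)
        if not neg:
            rays = pos + zer
            continue
        zsets = {id(r): zero_set(r) for r in rays}
        new_rays = []
        for rp in pos:
            for rn in neg:
                common = zsets[id(rp)] & zsets[id(rn)]
                if len(common) < d - 2:
                    continue
                if d > 2:
                    sub = B[sorted(common)]
                    if np.linalg.matrix_rank(sub, tol=tol * max(1.0, np.abs(sub).max())) < d - 2:
                        continue
                r_new = vals[id(rp)] * rn - vals[id(rn)] * rp
                r_new /= np.linalg.norm(r_new)
                new_rays.append(r_new)
        rays = pos + zer + new_rays

    out = []
    seen = set()
    for r in rays:
        xv = N @ r
        m = np.abs(xv).max()
        if m <= tol:
            continue
        xv[np.abs(xv) <= tol * m] = 0.0
        if xv.min() < -tol * m:
            continue  # numerical stragglers
        xv = np.clip(xv, 0.0, None)
        xv = xv / xv.sum()
        key = tuple(np.round(xv / max(xv.max(), 1e-300), 9))
        if key in seen:
            continue
        seen.add(key)
        out.append(xv)
    out.sort(key=lambda v: tuple(np.flatnonzero(v > tol)))
    return out


def brute_force_modes(
    A: np.ndarray, max_reactions: int = 14, tol: float = 1e-9
) -> list[np.ndarray]:
    """Support-minimal mode enumeration by exhaustive subset search.

    Independent oracle for :func:`double_description`: a column subset T
    is a mode support iff the null space of ``A[:, T]`` is 1-dimensional
    with a strictly positive generator and no proper subset qualifies.
    Only for small instances (≤ ``max_reactions`` columns).
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n = A.shape[1]
    if n > max_reactions:
        raise ValueError(f"{n} columns exceed the brute-force cap of {max_reactions}")
    found_supports: list[frozenset[int]] = []
    modes: list[np.ndarray] = []
    for size in range(1, n + 1):
        for T in itertools.combinations(range(n), size):
            Tset = frozenset(T)
            if any(s <= Tset for s in found_supports):
                continue
            ns = null_space(A[:, T])
            if ns.shape[1] != 1:
                continue
            g = ns[:, 0]
            m = np.abs(g).max()
            if np.all(g >= -tol * m) or np.all(g <= tol * m):
                g = np.abs(g)
                if g.min() <= tol * m:
                    continue  # actual support is smaller; found at lower size
                full = np.zeros(n)
                full[list(T)] = g
                full /= full.sum()
                found_supports.append(Tset)
                modes.append(full)
    modes.sort(key=lambda v: tuple(np.flatnonzero(v > tol)))
    return modes


def ofms(hs: HomogenizedSystem, tol_zero: float = TOL_ZERO) -> list[FluxMode]:
    """Enumerate the optimal flux modes (rays with v̄ > 0, rescaled to v̄ = 1).

    Rays with v̄ = 0 cannot deliver the fixed fluxes and are discarded
    (their count is logged).  For a purely homogeneous system the EFMs
    are returned instead, L1-normalized, with ``vbar`` unset.
    """
    rays = double_description(hs.A)
    if not hs.has_vbar:
        return [
            FluxMode(values=r, reaction_ids=list(hs.free_reactions), vbar=None)
            for r in rays
        ]
    out = []
    discarded = 0
    for r in rays:
        vbar = r[-1]
        if vbar <= tol_zero * max(1.0, r.max()):
            discarded += 1
            continue
        out.append(
            FluxMode(values=r[:-1] / vbar, reaction_ids=list(hs.free_reactions), vbar=1.0)
        )
    if discarded:
        logger.info("%d rays with v̄ = 0 discarded (cannot meet the fixed fluxes)", discarded)
    if not out:
        raise DecompositionError(
            "infeasible homogenization: no ray with v̄ > 0, contradicting pruned feasibility"
        )
    return out


def decompose(
    sol: Solution,
    modes: list[FluxMode],
    K: int,
    tol_zero: float = TOL_ZERO,
    tol_residual: float = 1e-8,
) -> OfmDecomposition:
    """Express the pruned optimum as a nonnegative combination of modes.

    Solves ``min ||R λ - v*||`` with λ ≥ 0 (NNLS), where R stacks the
    mode flux vectors (plus the v̄ row of ones for OFMs, which forces
    Σλ = 1).  Violations of the residual bound, of Σλ = 1, or of the
    at-most-K active-mode bound raise :class:`DecompositionError`.
    """
    if not modes:
        raise ValueError("no modes to decompose into")
    rids = modes[0].reaction_ids
    x = dict(zip(sol.variables, sol.x))
    vstar = np.array([x[r] for r in rids])
    R = np.column_stack([m.values for m in modes])
    target = vstar
    with_vbar = modes[0].vbar is not None
    if with_vbar:
        R = np.vstack([R, np.ones((1, len(modes)))])
        target = np.concatenate([vstar, [1.0]])
    lam, _ = nnls(R, target)
    resid = float(np.max(np.abs(R @ lam - target)))
    scale = max(1.0, float(np.max(np.abs(vstar))))
    if resid > tol_residual * scale:
        raise DecompositionError(
            f"decomposition failure: residual {resid:.3g} exceeds {tol_residual:.1g}·scale "
            "(missed OFM or wrong active set?)"
        )
    if with_vbar and abs(lam.sum() - 1.0) > 1e-8:
        raise DecompositionError(f"mode weights sum to {lam.sum():.12g}, expected 1")
    n_active = int(np.sum(lam > tol_zero))
    if n_active > K:
        raise DecompositionError(
            f"{n_active} modes with positive weight exceed the pool-constraint bound K={K}"
        )
    return OfmDecomposition(modes=list(modes), weights=lam, residual=resid, K=K)


def _ray_jacobian(
    hs: HomogenizedSystem, mode: FluxMode, sens: SensitivityMatrix, names: list[str]
) -> pd.DataFrame:
    """d(mode values)/dp for each parameter, via displacement of w.

    On its support T the v̄=1 ray solves ``S[:, T] r_T = -w``; only the
    objective contribution to w moves with kinetic parameters, so
    ``dr_T/dp = -pinv(S[:, T]) · S_obj · d v_r*/dp``.
    """
    obj = hs.objective_reaction
    sobj = hs.fixed_columns[obj]
    dvr = sens.raw.loc[obj, names].to_numpy()  # 1 x P
    T = [i for i, r in enumerate(mode.reaction_ids) if r in mode.support]
    S_T = hs.S_free[:, T]
    # consistent overdetermined system; lstsq gives the exact solution
    drT = np.linalg.lstsq(S_T, -np.outer(sobj, dvr), rcond=None)[0]
    dr = np.zeros((len(mode.reaction_ids), len(names)))
    dr[T, :] = drT
    return pd.DataFrame(dr, index=mode.reaction_ids, columns=names)


def ofm_sensitivity(
    dec: OfmDecomposition,
    hs: HomogenizedSystem,
    sens: SensitivityMatrix,
    params: list[str],
    registry: ParameterRegistry | None = None,
    tol_zero: float = TOL_ZERO,
    max_condition: float = 1e10,
) -> SensitivityMatrix:
    """Differentiate OFM usage weights λ with respect to parameters.

    Differentiating ``R(p) λ(p) = v*(p)`` (with the v̄ row pinned to 1)
    gives ``R_sub dλ = dv*_sub - Σ_k λ_k dr_k`` on a well-conditioned
    square row subset R_sub chosen greedily; the v̄ row is always
    included, which makes the columns of ∂λ/∂p sum to zero exactly.
    Kinetic (kcat) and capacity parameters are supported; fixed-flux
    parameters change the cone itself and are rejected.
    """
    bad = set(params) & hs.fixed_param_names
    if bad:
        raise UnsupportedParameterError(
            f"fixed-flux parameters {sorted(bad)} alter the homogenized cone; "
            "OFM usage sensitivities are not defined for them here"
        )
    if not hs.has_vbar:
        raise ValueError("ofm_sensitivity requires a homogenized (v̄) system")
    modes = dec.modes
    k = len(modes)
    rids = modes[0].reaction_ids
    R_flux = np.column_stack([m.values for m in modes])  # rows: free reactions

    # greedy selection of k-1 flux rows on top of the forced v̄ row
    rows = [np.ones(k)]
    labels = ["__vbar__"]
    avail = list(range(len(rids)))
    for _ in range(k - 1):
        best, best_sv = None, -1.0
        for i in avail:
            cand = np.vstack(rows + [R_flux[i]])
            sv = np.linalg.svd(cand, compute_uv=False)[-1]
            if sv > best_sv:
                best, best_sv = i, sv
        rows.append(R_flux[best])
        labels.append(rids[best])
        avail.remove(best)
    R_sub = np.vstack(rows)
    cond = np.linalg.cond(R_sub)
    if cond > max_condition:
        raise RuntimeError(
            f"ill-conditioned mode matrix (cond {cond:.3g} > {max_condition:.1g}); "
            "modes may be nearly parallel"
        )

    dR = {m_i: _ray_jacobian(hs, m, sens, params) for m_i, m in enumerate(modes)}
    rhs = np.zeros((k, len(params)))
    for j, label in enumerate(labels):
        if label == "__vbar__":
            continue  # d v̄ / dp = 0
        dv = sens.raw.loc[label, params].to_numpy()
        corr = sum(dec.weights[m_i] * dR[m_i].loc[label].to_numpy() for m_i in range(k))
        rhs[j] = dv - corr
    dlam = scipy.linalg.solve(R_sub, rhs)
    raw = pd.DataFrame(dlam, index=[f"mode_{i}" for i in range(k)], columns=params)
    scaled = None
    if registry is not None:
        pvals = pd.Series({p: registry[p] for p in params})
        lam = pd.Series(dec.weights, index=raw.index)
        scaled = raw.mul(pvals, axis=1).div(lam, axis=0)
        scaled[lam <= tol_zero] = np.nan
    return SensitivityMatrix(
        raw=raw, scaled=scaled, metadata={"rows": labels, "condition": float(cond)}
    )


def ofm_usage_fd(
    pruned: PrunedModel,
    params: ParameterRegistry,
    names: list[str],
    rel_step: float = 1e-3,
) -> pd.DataFrame:
    """Finite-difference oracle for ∂λ/∂p: re-solve, re-homogenize,
    re-enumerate and re-decompose at p·(1 ± rel_step), matching modes
    across perturbations by support."""
    if rel_step <= 0:
        raise ValueError("rel_step must be positive")

    def usages(reg: ParameterRegistry) -> dict[frozenset, float]:
        lp = build_lp(pruned.model, reg)
        sol = solve_lp(lp)
        if sol.status != "optimal":
            raise RuntimeError(f"perturbed pruned problem is {sol.status}")
        hs = homogenize(pruned, sol, reg)
        dec = decompose(sol, ofms(hs), K=max(1, len(pruned.model.pools)))
        return {m.support: w for m, w in zip(dec.modes, dec.weights)}

    base = usages(params)
    supports = sorted(base, key=sorted)
    cols = {}
    for p in names:
        h = rel_step * params[p]
        up = usages(params.perturbed(p, +h))
        dn = usages(params.perturbed(p, -h))
        cols[p] = [
            (up.get(s, 0.0) - dn.get(s, 0.0)) / (2 * h) for s in supports
        ]
    return pd.DataFrame(cols, index=[f"support:{sorted(s)}" for s in supports])
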