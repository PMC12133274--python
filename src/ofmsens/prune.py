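"""Pruning an optimal solution down to a model with a unique optimum.

Reactions carrying (numerically) zero flux and enzymes with zero
concentration in an optimal solution are inactive; removing them leaves
a reduced model whose optimum is provably unique whenever every
metabolic reaction carries an enzyme cost with generic kcats.  A unique
optimum is the precondition for implicit differentiation, so
:func:`verify_unique` (zero-width flux variability at the optimum) gates
every downstream sensitivity computation.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .lp import ParametricLP, Solution, build_lp, fva_at_optimum, solve_lp, TOL_ZERO
from .model import EcModel, EnzymePool, ParameterRegistry

logger = logging.getLogger(__name__)

__all__ = ["PrunedModel", "PruningError", "prune", "verify_unique"]


class PruningError(RuntimeError):
    pass


@dataclass
class PrunedModel:
    """A reduced model plus bookkeeping back to the original."""

    model: EcModel
    #: pruned reaction id -> original reaction id
    index_map: dict[str, str] = field(default_factory=dict)
    #: pruned reaction ids that are reversed (backward) copies of originals
    flipped: set[str] = field(default_factory=set)


def prune(
    model: EcModel,
    sol: Solution,
    tol_zero: float = TOL_ZERO,
    params: ParameterRegistry | None = None,
) -> tuple[PrunedModel, Solution]:
    """Remove inactive reactions and enzymes from an optimal solution.

    A reaction is kept when its flux exceeds ``tol_zero`` times the
    largest flux magnitude; an enzyme (gene product) is kept when some
    kept isozyme using it has concentration above ``tol_zero`` times the
    largest concentration.  Metabolites with all-zero rows, pool members
    that no longer occur, and empty pools are dropped; capacities are
    untouched.  Backward split copies that remain active are recorded in
    ``flipped`` (their fluxes are already forward in the split model).

    Returns the pruned model and its (unique) optimal solution, which
    must match the input objective within 1e-6 relative or a
    :class:`PruningError` ("pruning inconsistency") is raised.
    """
    if sol.status != "optimal":
        raise ValueError("prune requires an optimal solution")
    reg = params if params is not None else model.registry()
    x = dict(zip(sol.variables, sol.x))

    flux_vals = [abs(x[r.id]) for r in model.reactions]
    scale = max(flux_vals) if flux_vals else 0.0
    if scale <= 0:
        raise PruningError("pruning inconsistency: all fluxes are zero")
    keep_rxn = {r.id for r in model.reactions if abs(x[r.id]) > tol_zero * scale}

    obj = model.objective_id()
    if obj not in keep_rxn:
        raise PruningError("pruning inconsistency: objective reaction carries zero flux")

    from .lp import enzyme_var_names

    enames = enzyme_var_names(model)
    evals = [x[n] for n in enames.values() if n in x]
    escale = max(evals) if evals else 0.0

    new_reactions = []
    active_genes: set[str] = set()
    for r in model.reactions:
        if r.id not in keep_rxn:
            continue
        r2 = copy.deepcopy(r)
        if r.isozymes:
            kept_isos = []
            for i, iso in enumerate(r2.isozymes):
                ev = x.get(enames[(r.id, i)], 0.0)
                if ev > tol_zero * escale:
                    kept_isos.append(iso)
                    active_genes.update(iso.subunit_counts)
            if not kept_isos:
                # the reaction is active, so its (cheapest) enzyme must be too;
                # numerical noise aside this should not happen
                raise PruningError(
                    f"pruning inconsistency: active reaction {r.id!r} has no active enzyme"
                )
            r2.isozymes = kept_isos
        new_reactions.append(r2)

    used_mets = set()
    for r in new_reactions:
        used_mets.update(r.stoichiometry)

    new_pools = []
    for p in model.pools:
        members = [g for g in p.members if g in active_genes]
        if members:
            new_pools.append(EnzymePool(p.id, members, p.capacity))

    pruned_model = EcModel(
        metabolites=[copy.deepcopy(m) for m in model.metabolites if m.id in used_mets],
        reactions=new_reactions,
        gene_products=[copy.deepcopy(g) for g in model.gene_products if g.id in active_genes],
        pools=new_pools,
        fixed_fluxes=[copy.deepcopy(f) for f in model.fixed_fluxes if f.reaction_id in keep_rxn],
        objective_reaction=obj,
        parameters=dict(model.parameters),
        provenance={k: v for k, v in model.provenance.items() if k in keep_rxn},
    )

    index_map = {
        rid: model.provenance.get(rid, [rid, "fwd"])[0] for rid in (r.id for r in new_reactions)
    }
    flipped = {
        rid for rid in index_map if model.provenance.get(rid, ["", "fwd"])[1] == "bwd"
    }

    plp = build_lp(pruned_model, reg)
    psol = solve_lp(plp)
    if psol.status != "optimal":
        raise PruningError(f"pruning inconsistency: pruned model is {psol.status}")
    drop = abs(psol.objective_value - sol.objective_value)
    if drop > 1e-6 * max(1.0, abs(sol.objective_value)):
        raise PruningError(
            "pruning inconsistency: objective changed by "
            f"{drop:.3g} (tol_zero too aggressive or non-vertex input solution?)"
        )
    if np.min(psol.x) < -1e-9:
        raise PruningError("pruning inconsistency: negative flux in pruned solution")
    return PrunedModel(pruned_model, index_map, flipped), psol


def verify_unique(
    model: EcModel,
    params: ParameterRegistry | None = None,
    tol: float = 1e-6,
    lp: ParametricLP | None = None,
    sol: Solution | None = None,
) -> bool:
    """True iff every variable's range at the optimum has width <= ``tol``.

    Operational uniqueness gate before differentiation: for a pruned
    model with generic parameters this holds by construction; a False
    return signals degeneracy (e.g. duplicated columns with identical
    costs).
    """
    if lp is None:
        lp = build_lp(model, params)
    if sol is None:
        sol = solve_lp(lp)
    if sol.status != "optimal":
        return False
    ranges = fva_at_optimum(lp, sol)
    width = max(hi - lo for lo, hi in ranges.values())
    return width <= tol
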