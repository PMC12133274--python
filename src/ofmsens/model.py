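"""Data model and JSON I/O for enzyme-constrained metabolic models.

An enzyme-constrained model (ecGSMM) couples each catalysed reaction flux
``v_i`` to the concentration ``e_i`` of its enzyme through the turnover
number, ``v_i = kcat_i * e_i``, and bounds the mass of enzymes drawn from
each pool ``k`` by a capacity, ``sum_{i in R_k} w_i e_i <= E_k`` with
``w_i`` the enzyme molar mass.  This module defines the in-memory types,
reads and writes the native JSON schema (see ``schema.json``), imports
COBRA-style JSON models on a best-effort basis, and manages named
parameters (kcats, pool capacities, fixed-flux values, bounds) through a
:class:`ParameterRegistry`.

Units used throughout: fluxes in mmol·gDCW⁻¹·h⁻¹, kcats in h⁻¹, molar
masses in mg·mmol⁻¹, enzyme concentrations in mmol·gDCW⁻¹ and pool
capacities in mg·gDCW⁻¹.
"""

from __future__ import annotations

import copy
import json
import logging
import math
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Union

logger = logging.getLogger(__name__)

__all__ = [
    "ParamRef",
    "ParameterRegistry",
    "Metabolite",
    "GeneProduct",
    "Isozyme",
    "Reaction",
    "EnzymePool",
    "FixedFlux",
    "EcModel",
    "ValidationReport",
    "ValidationError",
    "load_model",
    "save_model",
    "model_to_dict",
    "model_from_dict",
    "split_reversible",
    "validate",
    "canonical_reaction_order",
]


@dataclass(frozen=True)
class ParamRef:
    """A symbolic reference to a named scalar parameter."""

    name: str


#: A model entry that is either a literal scalar or a named parameter.
Value = Union[float, ParamRef]


class ParameterRegistry(Mapping):
    """Immutable-ish mapping of parameter names to scalar values.

    The registry resolves :class:`ParamRef` entries found in a model.
    ``updated``/``perturbed`` return modified copies, which keeps
    finite-difference perturbations free of shared-state surprises.
    """

    def __init__(self, values: Mapping[str, float] | None = None):
        self._values: dict[str, float] = dict(values or {})

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ParameterRegistry({self._values!r})"

    def resolve(self, value: Value | None) -> float | None:
        """Resolve a scalar-or-parameter entry to a number."""
        if value is None:
            return None
        if isinstance(value, ParamRef):
            try:
                return self._values[value.name]
            except KeyError:
                raise KeyError(f"unresolved parameter {value.name!r}") from None
        return float(value)

    def updated(self, changes: Mapping[str, float]) -> "ParameterRegistry":
        merged = dict(self._values)
        merged.update(changes)
        return ParameterRegistry(merged)

    def perturbed(self, name: str, delta: float) -> "ParameterRegistry":
        """Return a copy with ``name`` shifted by the additive ``delta``."""
        return self.updated({name: self[name] + delta})


@dataclass
class Metabolite:
    id: str
    compartment: str | None = None


@dataclass
class GeneProduct:
    id: str
    molar_mass: float  # mg/mmol


@dataclass
class Isozyme:
    """One enzyme (possibly a complex) able to catalyse a reaction."""

    subunit_counts: dict[str, int]
    kcat_forward: Value | None = None
    kcat_reverse: Value | None = None


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: Value = 0.0
    upper_bound: Value = math.inf
    isozymes: list[Isozyme] = field(default_factory=list)
    objective_coefficient: float = 0.0


@dataclass
class EnzymePool:
    """A capacity constraint over a group of gene products (e.g. a compartment)."""

    id: str
    members: list[str]
    capacity: Value


@dataclass
class FixedFlux:
    """An inhomogeneous constraint pinning a reaction flux to a positive value."""

    reaction_id: str
    value: Value


@dataclass
class EcModel:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    gene_products: list[GeneProduct] = field(default_factory=list)
    pools: list[EnzymePool] = field(default_factory=list)
    fixed_fluxes: list[FixedFlux] = field(default_factory=list)
    objective_reaction: str | None = None
    #: default values for every ParamRef used in the model
    parameters: dict[str, float] = field(default_factory=dict)
    #: maps post-split reaction ids to ``[original_id, direction]``
    provenance: dict[str, list] = field(default_factory=dict)

    # -- lookups -------------------------------------------------------
    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def gene_product(self, gid: str) -> GeneProduct:
        for g in self.gene_products:
            if g.id == gid:
                return g
        raise KeyError(gid)

    def objective_id(self) -> str:
        """The id of the objective reaction (declared, or unique nonzero coefficient)."""
        if self.objective_reaction is not None:
            return self.objective_reaction
        with_coef = [r.id for r in self.reactions if r.objective_coefficient != 0]
        if len(with_coef) != 1:
            raise ValueError(
                f"expected exactly one objective reaction, found {with_coef!r}"
            )
        return with_coef[0]

    def registry(self) -> ParameterRegistry:
        return ParameterRegistry(self.parameters)

    def fixed_flux_for(self, rid: str) -> FixedFlux | None:
        for f in self.fixed_fluxes:
            if f.reaction_id == rid:
                return f
        return None


def canonical_reaction_order(model: EcModel) -> list[str]:
    """Reaction ids sorted lexicographically with the objective reaction last."""
    obj = model.objective_id()
    ids = sorted(r.id for r in model.reactions if r.id != obj)
    return ids + [obj]


# ----------------------------------------------------------------------
# JSON serialization
# ----------------------------------------------------------------------

def _value_to_json(v: Value | None):
    if v is None:
        return None
    if isinstance(v, ParamRef):
        return {"param": v.name}
    v = float(v)
    if math.isinf(v):
        return "inf" if v > 0 else "-inf"
    return v


def _value_from_json(v) -> Value | None:
    if v is None:
        return None
    if isinstance(v, dict):
        return ParamRef(str(v["param"]))
    if v == "inf":
        return math.inf
    if v == "-inf":
        return -math.inf
    return float(v)


def model_to_dict(model: EcModel) -> dict:
    """Canonical (sorted, JSON-ready) dictionary form of a model."""
    return {
        "metabolites": [
            {"id": m.id, "compartment": m.compartment}
            for m in sorted(model.metabolites, key=lambda m: m.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lower_bound": _value_to_json(r.lower_bound),
                "upper_bound": _value_to_json(r.upper_bound),
                "isozymes": [
                    {
                        "subunit_counts": {
                            k: int(iso.subunit_counts[k]) for k in sorted(iso.subunit_counts)
                        },
                        "kcat_forward": _value_to_json(iso.kcat_forward),
                        "kcat_reverse": _value_to_json(iso.kcat_reverse),
                    }
                    for iso in r.isozymes
                ],
                "objective_coefficient": r.objective_coefficient,
            }
            for r in sorted(model.reactions, key=lambda r: r.id)
        ],
        "genes": [
            {"id": g.id, "molar_mass": g.molar_mass}
            for g in sorted(model.gene_products, key=lambda g: g.id)
        ],
        "pools": [
            {"id": p.id, "members": sorted(p.members), "capacity": _value_to_json(p.capacity)}
            for p in sorted(model.pools, key=lambda p: p.id)
        ],
        "fixed_fluxes": [
            {"reaction_id": f.reaction_id, "value": _value_to_json(f.value)}
            for f in sorted(model.fixed_fluxes, key=lambda f: f.reaction_id)
        ],
        "objective": model.objective_reaction,
        "parameters": {k: model.parameters[k] for k in sorted(model.parameters)},
        "provenance": {k: model.provenance[k] for k in sorted(model.provenance)},
    }


def model_from_dict(data: dict) -> EcModel:
    return EcModel(
        metabolites=[
            Metabolite(id=m["id"], compartment=m.get("compartment"))
            for m in data.get("metabolites", [])
        ],
        reactions=[
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r.get("stoichiometry", {}).items()},
                lower_bound=_value_from_json(r.get("lower_bound", 0.0)),
                upper_bound=_value_from_json(r.get("upper_bound", "inf")),
                isozymes=[
                    Isozyme(
                        subunit_counts={k: int(v) for k, v in iso["subunit_counts"].items()},
                        kcat_forward=_value_from_json(iso.get("kcat_forward")),
                        kcat_reverse=_value_from_json(iso.get("kcat_reverse")),
                    )
                    for iso in r.get("isozymes", [])
                ],
                objective_coefficient=float(r.get("objective_coefficient", 0.0)),
            )
            for r in data.get("reactions", [])
        ],
        gene_products=[
            GeneProduct(id=g["id"], molar_mass=float(g["molar_mass"]))
            for g in data.get("genes", [])
        ],
        pools=[
            EnzymePool(
                id=p["id"],
                members=list(p["members"]),
                capacity=_value_from_json(p["capacity"]),
            )
            for p in data.get("pools", [])
        ],
        fixed_fluxes=[
            FixedFlux(reaction_id=f["reaction_id"], value=_value_from_json(f["value"]))
            for f in data.get("fixed_fluxes", [])
        ],
        objective_reaction=data.get("objective"),
        parameters={k: float(v) for k, v in data.get("parameters", {}).items()},
        provenance={k: list(v) for k, v in data.get("provenance", {}).items()},
    )


def model_to_json(model: EcModel) -> str:
    return json.dumps(model_to_dict(model), indent=1, sort_keys=False)


def save_model(model: EcModel, path: str | Path) -> None:
    Path(path).write_text(model_to_json(model) + "\n")


class ValidationError(ValueError):
    """Raised when a model fails schema/consistency validation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("model validation failed:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate(model: EcModel) -> ValidationReport:
    """Check referential integrity and basic invariants of a model.

    Errors are structural problems (dangling references, inverted bounds,
    unresolved parameters).  Warnings flag modelling choices that are
    legal but weaken downstream guarantees — in particular metabolic
    (multi-metabolite) reactions without an enzyme cost, since uniqueness
    of the pruned optimum is only guaranteed when every metabolic
    reaction carries a cost.
    """
    rep = ValidationReport()
    reg = model.registry()

    met_ids = [m.id for m in model.metabolites]
    rxn_ids = [r.id for r in model.reactions]
    gene_ids = [g.id for g in model.gene_products]
    for label, ids in (("metabolite", met_ids), ("reaction", rxn_ids), ("gene", gene_ids)):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                rep.errors.append(f"duplicate {label} id {i!r}")
            seen.add(i)
    mets, genes = set(met_ids), set(gene_ids)

    def _resolve(value, where):
        try:
            return reg.resolve(value)
        except KeyError as e:
            rep.errors.append(f"{where}: {e.args[0]}")
            return None

    for g in model.gene_products:
        if not g.molar_mass > 0:
            rep.errors.append(f"gene {g.id!r}: molar_mass must be > 0")

    for r in model.reactions:
        for m, coef in r.stoichiometry.items():
            if m not in mets:
                rep.errors.append(f"reaction {r.id!r}: unknown metabolite {m!r}")
            if coef == 0:
                rep.errors.append(f"reaction {r.id!r}: zero stoichiometric coefficient for {m!r}")
        lb = _resolve(r.lower_bound, f"reaction {r.id!r} lower_bound")
        ub = _resolve(r.upper_bound, f"reaction {r.id!r} upper_bound")
        if lb is not None and ub is not None and lb > ub:
            rep.errors.append(f"reaction {r.id!r}: lower_bound {lb} > upper_bound {ub}")
        for i, iso in enumerate(r.isozymes):
            if not iso.subunit_counts:
                rep.errors.append(f"reaction {r.id!r} isozyme {i}: empty subunit_counts")
            for g, n in iso.subunit_counts.items():
                if g not in genes:
                    rep.errors.append(f"reaction {r.id!r} isozyme {i}: unknown gene {g!r}")
                if n <= 0:
                    rep.errors.append(f"reaction {r.id!r} isozyme {i}: subunit count for {g!r} must be positive")
            if iso.kcat_forward is None and iso.kcat_reverse is None:
                rep.errors.append(f"reaction {r.id!r} isozyme {i}: no kcat given")
            for tag, kc in (("kcat_forward", iso.kcat_forward), ("kcat_reverse", iso.kcat_reverse)):
                if kc is not None:
                    v = _resolve(kc, f"reaction {r.id!r} isozyme {i} {tag}")
                    if v is not None and v <= 0:
                        rep.errors.append(f"reaction {r.id!r} isozyme {i}: {tag} must be > 0")
        if not r.isozymes and len(r.stoichiometry) > 1:
            rep.warnings.append(
                f"reaction {r.id!r} converts metabolites without an enzyme cost; "
                "pruned-optimum uniqueness is not guaranteed"
            )

    for p in model.pools:
        if not p.members:
            rep.errors.append(f"pool {p.id!r}: empty member set")
        for g in p.members:
            if g not in genes:
                rep.errors.append(f"pool {p.id!r}: unknown gene {g!r}")
        cap = _resolve(p.capacity, f"pool {p.id!r} capacity")
        if cap is not None and cap <= 0:
            rep.errors.append(f"pool {p.id!r}: capacity must be > 0")

    rxns = set(rxn_ids)
    for f in model.fixed_fluxes:
        if f.reaction_id not in rxns:
            rep.errors.append(f"fixed flux references unknown reaction {f.reaction_id!r}")
        v = _resolve(f.value, f"fixed flux on {f.reaction_id!r}")
        if v is not None and v <= 0:
            rep.errors.append(f"fixed flux on {f.reaction_id!r} must be > 0, got {v}")

    try:
        obj = model.objective_id()
        if obj not in rxns:
            rep.errors.append(f"objective reaction {obj!r} does not exist")
    except ValueError as e:
        rep.errors.append(str(e))

    return rep


def load_model(path: str | Path, format: str = "native-json") -> EcModel:
    """Load a model from disk.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"native-json"`` for the package's own schema, ``"cobra-json"``
        for a COBRA-style JSON genome-scale model (best-effort import:
        gene-reaction rules become isozymes, molar masses and kcats that
        the format does not carry become defaults/parameter references).

    Raises
    ------
    ValidationError
        If the loaded model fails :func:`validate` with errors.
    """
    if format == "native-json":
        data = json.loads(Path(path).read_text())
        model = model_from_dict(data)
    elif format == "cobra-json":
        model = _load_cobra_json(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    rep = validate(model)
    if not rep.ok:
        raise ValidationError(rep.errors)
    for w in rep.warnings:
        logger.warning("%s", w)
    return model


def _gpr_isozymes(rule: str, rxn_id: str) -> list[Isozyme]:
    """Translate a gene-reaction rule into isozymes (OR -> alternatives,
    AND -> one complex with unit subunit counts)."""
    import sympy
    from sympy.logic.boolalg import Or, And, to_dnf

    if not rule.strip():
        return []
    expr = rule.replace(" and ", " & ").replace(" or ", " | ")
    expr = expr.replace(" AND ", " & ").replace(" OR ", " | ")
    try:
        sym = to_dnf(sympy.parsing.sympy_parser.parse_expr(expr, evaluate=False))
    except Exception:
        logger.warning("reaction %r: could not parse gene rule %r; skipped", rxn_id, rule)
        return []
    alts = sym.args if isinstance(sym, Or) else (sym,)
    isozymes = []
    for alt in alts:
        genes = alt.args if isinstance(alt, And) else (alt,)
        counts = {str(g): 1 for g in genes}
        isozymes.append(
            Isozyme(subunit_counts=counts, kcat_forward=ParamRef(f"kcat__{rxn_id}"))
        )
    return isozymes


def _load_cobra_json(path: str | Path) -> EcModel:
    # cobra does the parsing; we only map onto our types.
    import cobra.io

    cm = cobra.io.load_json_model(str(path))
    model = EcModel()
    for m in cm.metabolites:
        model.metabolites.append(Metabolite(id=m.id, compartment=m.compartment))
    gene_ids = set()
    for r in cm.reactions:
        isozymes = _gpr_isozymes(r.gene_reaction_rule, r.id)
        for iso in isozymes:
            gene_ids.update(iso.subunit_counts)
        model.reactions.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                isozymes=isozymes,
                objective_coefficient=float(r.objective_coefficient),
            )
        )
        for iso in isozymes:
            name = iso.kcat_forward.name
            model.parameters.setdefault(name, 1.0)
    if any(model.parameters):
        logger.warning(
            "cobra-json import: kcats are not part of the format; parameter "
            "references with placeholder value 1.0 were created"
        )
    for g in sorted(gene_ids):
        model.gene_products.append(GeneProduct(id=g, molar_mass=1.0))
    if gene_ids:
        logger.warning("cobra-json import: molar masses default to 1.0 mg/mmol")
    try:
        model.objective_reaction = model.objective_id()
    except ValueError:
        pass
    return model


def split_reversible(
    model: EcModel, fwd_suffix: str = "_fwd", bwd_suffix: str = "_bwd"
) -> EcModel:
    """Split reversible reactions into irreversible forward/backward copies.

    A reaction with a negative lower bound is replaced by a forward copy
    with bounds ``[0, ub]`` and a backward copy with reversed
    stoichiometry and bounds ``[0, |lb|]``.  ``kcat_forward`` and
    ``kcat_reverse`` move to the respective copies; a reversible reaction
    without ``kcat_reverse`` yields a cost-free backward copy and a
    warning.  Irreversible reactions are passed through unchanged, so the
    operation is idempotent.
    """
    reg = model.registry()
    out = EcModel(
        metabolites=copy.deepcopy(model.metabolites),
        gene_products=copy.deepcopy(model.gene_products),
        pools=copy.deepcopy(model.pools),
        fixed_fluxes=copy.deepcopy(model.fixed_fluxes),
        objective_reaction=model.objective_reaction,
        parameters=dict(model.parameters),
        provenance=dict(model.provenance),
    )
    renamed: dict[str, str] = {}
    for r in model.reactions:
        lb = reg.resolve(r.lower_bound)
        ub = reg.resolve(r.upper_bound)
        if lb >= 0:
            out.reactions.append(copy.deepcopy(r))
            continue
        if isinstance(r.lower_bound, ParamRef) or isinstance(r.upper_bound, ParamRef):
            logger.warning(
                "reaction %r: parametric bounds are frozen to their current values on splitting",
                r.id,
            )
        fwd = Reaction(
            id=r.id + fwd_suffix,
            stoichiometry=dict(r.stoichiometry),
            lower_bound=0.0,
            upper_bound=max(ub, 0.0),
            isozymes=[
                Isozyme(subunit_counts=dict(iso.subunit_counts), kcat_forward=iso.kcat_forward)
                for iso in r.isozymes
                if iso.kcat_forward is not None
            ],
            objective_coefficient=r.objective_coefficient,
        )
        bwd_isozymes = [
            Isozyme(subunit_counts=dict(iso.subunit_counts), kcat_forward=iso.kcat_reverse)
            for iso in r.isozymes
            if iso.kcat_reverse is not None
        ]
        if r.isozymes and not bwd_isozymes:
            logger.warning(
                "reaction %r: no kcat_reverse given; backward copy has no enzyme cost",
                r.id,
            )
        bwd = Reaction(
            id=r.id + bwd_suffix,
            stoichiometry={m: -c for m, c in r.stoichiometry.items()},
            lower_bound=0.0,
            upper_bound=-lb,
            isozymes=bwd_isozymes,
            objective_coefficient=0.0,
        )
        out.reactions.extend([fwd, bwd])
        out.provenance[fwd.id] = [r.id, "fwd"]
        out.provenance[bwd.id] = [r.id, "bwd"]
        renamed[r.id] = fwd.id
    if out.objective_reaction in renamed:
        logger.warning(
            "objective reaction %r was reversible; the forward copy keeps the objective",
            out.objective_reaction,
        )
        out.objective_reaction = renamed[out.objective_reaction]
    for f in out.fixed_fluxes:
        if f.reaction_id in renamed:
            logger.warning(
                "fixed flux on reversible reaction %r attaches to the forward copy",
                f.reaction_id,
            )
            f.reaction_id = renamed[f.reaction_id]
    return out
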