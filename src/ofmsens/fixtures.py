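"""Deterministic generators for small enzyme-constrained test models.

Three hand-built networks cover the qualitatively distinct regimes:

``chain``
    A single linear pathway with one catalysed step.  The optimum has
    the closed form ``v* = kcat * E / w`` (here 2 * 5 / 1 = 10), which
    pins down every sensitivity analytically.

``branch``
    Two parallel routes competing for one enzyme pool; the faster
    enzyme wins outright, so pruning removes exactly one reaction and
    one enzyme, leaving a single mode.

``overflow``
    A desk-scale overflow-metabolism network: a high-yield respiratory
    route whose enzyme sits in a crowded "membrane" pool, a low-yield
    fermentative route drawing on the "cytosol" pool, an ATP-consuming
    biomass objective (cytosolic enzyme), and an ATP maintenance
    reaction with a fixed flux (the inhomogeneous constraint).  The
    constants below were chosen once so that at the optimum both pools
    bind and both routes carry flux; the optimum then superposes exactly
    two optimal flux modes, a respiratory and a fermentative one, with
    usage weights 15/16 and 1/16 (closed forms in the docstring of
    :func:`make_overflow`).

``random_ec_network``
    Seeded random feasible networks with generic kcats for property
    testing; generators reject degenerate optima so that pruning always
    yields a unique optimum.
"""

from __future__ import annotations

import numpy as np

from .model import (
    EcModel,
    EnzymePool,
    FixedFlux,
    GeneProduct,
    Isozyme,
    Metabolite,
    ParamRef,
    Reaction,
)

__all__ = ["make_chain", "make_branch", "make_overflow", "random_ec_network", "make_fixture"]

# overflow network constants: yields of ATP per glucose for the two
# routes, ATP cost of biomass, and the maintenance requirement.
OVERFLOW = dict(
    y_resp=10.0,  # ATP / glucose, respiratory
    y_ferm=2.0,  # ATP / glucose, fermentative
    atp_per_biomass=1.0,
    kcat_resp=1.0,  # h^-1, slow but high-yield
    kcat_ferm=10.0,  # h^-1, fast but low-yield
    kcat_bio=10.0,  # h^-1
    cap_membrane=1.0,  # mg/gDCW
    cap_cytosol=1.0,  # mg/gDCW
    atpm=1.0,  # mmol/gDCW/h fixed maintenance flux
)


def make_chain() -> EcModel:
    """Linear chain: uptake -> A -(enzymatic)-> B -> secretion (objective).

    kcat = 2 h⁻¹, molar mass w = 1 mg/mmol, pool capacity E = 5 mg/gDCW,
    hence the optimum is v* = kcat·E/w = 10 mmol/gDCW/h.
    """
    return EcModel(
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("uptake", {"A": 1.0}),
            Reaction(
                "cat",
                {"A": -1.0, "B": 1.0},
                isozymes=[Isozyme({"g_cat": 1}, kcat_forward=ParamRef("kcat_cat"))],
            ),
            Reaction("secretion", {"B": -1.0}, objective_coefficient=1.0),
        ],
        gene_products=[GeneProduct("g_cat", molar_mass=1.0)],
        pools=[EnzymePool("pool", ["g_cat"], capacity=ParamRef("cap_pool"))],
        objective_reaction="secretion",
        parameters={"kcat_cat": 2.0, "cap_pool": 5.0},
    )


def make_branch() -> EcModel:
    """Two parallel enzymatic routes A -> B sharing one pool.

    kcats 1 vs 2 h⁻¹, equal molar masses, capacity 1: the faster route
    carries everything, objective = 2, and pruning removes the slow
    route and its enzyme.
    """
    return EcModel(
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("uptake", {"A": 1.0}),
            Reaction(
                "r1",
                {"A": -1.0, "B": 1.0},
                isozymes=[Isozyme({"g1": 1}, kcat_forward=ParamRef("kcat_r1"))],
            ),
            Reaction(
                "r2",
                {"A": -1.0, "B": 1.0},
                isozymes=[Isozyme({"g2": 1}, kcat_forward=ParamRef("kcat_r2"))],
            ),
            Reaction("secretion", {"B": -1.0}, objective_coefficient=1.0),
        ],
        gene_products=[GeneProduct("g1", 1.0), GeneProduct("g2", 1.0)],
        pools=[EnzymePool("pool", ["g1", "g2"], capacity=ParamRef("cap_pool"))],
        objective_reaction="secretion",
        parameters={"kcat_r1": 1.0, "kcat_r2": 2.0, "cap_pool": 1.0},
    )


def make_overflow() -> EcModel:
    """Overflow-metabolism toy with two pools and a fixed maintenance flux.

    Closed-form optimum (masses 1, see module constants): the membrane
    pool caps respiration at ``v_resp = kcat_resp·E_mem = 1``; the
    cytosol pool is shared by fermentation and biomass, giving

        v_ferm = (E_cyt·kcat_bio - y_resp·v_resp + atpm) / (kcat_bio/kcat_ferm + y_ferm) = 1/3
        v_bio  = y_resp·v_resp + y_ferm·v_ferm - atpm = 29/3

    Both pools bind and both routes are active, so the optimum is a
    superposition of a respiratory and a fermentative optimal flux mode
    with weights λ = (15/16, 1/16).
    """
    C = OVERFLOW
    return EcModel(
        metabolites=[Metabolite("Glc"), Metabolite("ATP"), Metabolite("Byp")],
        reactions=[
            Reaction("glc_uptake", {"Glc": 1.0}),
            Reaction(
                "resp",
                {"Glc": -1.0, "ATP": C["y_resp"]},
                isozymes=[Isozyme({"g_resp": 1}, kcat_forward=ParamRef("kcat_resp"))],
            ),
            Reaction(
                "ferm",
                {"Glc": -1.0, "ATP": C["y_ferm"], "Byp": 1.0},
                isozymes=[Isozyme({"g_ferm": 1}, kcat_forward=ParamRef("kcat_ferm"))],
            ),
            Reaction("byp_secretion", {"Byp": -1.0}),
            Reaction(
                "biomass",
                {"ATP": -C["atp_per_biomass"]},
                isozymes=[Isozyme({"g_bio": 1}, kcat_forward=ParamRef("kcat_bio"))],
                objective_coefficient=1.0,
            ),
            Reaction("atpm", {"ATP": -1.0}),
        ],
        gene_products=[
            GeneProduct("g_resp", 1.0),
            GeneProduct("g_ferm", 1.0),
            GeneProduct("g_bio", 1.0),
        ],
        pools=[
            EnzymePool("membrane", ["g_resp"], capacity=ParamRef("cap_membrane")),
            EnzymePool("cytosol", ["g_ferm", "g_bio"], capacity=ParamRef("cap_cytosol")),
        ],
        fixed_fluxes=[FixedFlux("atpm", ParamRef("atpm_flux"))],
        objective_reaction="biomass",
        parameters={
            "kcat_resp": C["kcat_resp"],
            "kcat_ferm": C["kcat_ferm"],
            "kcat_bio": C["kcat_bio"],
            "cap_membrane": C["cap_membrane"],
            "cap_cytosol": C["cap_cytosol"],
            "atpm_flux": C["atpm"],
        },
    )


def _random_attempt(
    rng: np.random.Generator, n_mets: int, n_rxns: int, n_pools: int
) -> EcModel:
    """One draw of a connected feasible random network (no rejection here)."""
    mets = [f"M{i}" for i in range(n_mets)]
    reactions = [Reaction("uptake", {mets[0]: 1.0})]
    genes: list[GeneProduct] = []
    params: dict[str, float] = {}

    def add_internal(idx: int, sub: int, prod: int):
        rid = f"r{idx}"
        gid = f"g{idx}"
        a = float(rng.integers(1, 3))
        b = float(rng.integers(1, 3))
        kcat = float(10 ** rng.uniform(-1, 2))  # log-uniform in [0.1, 100] 1/h
        mass = float(rng.uniform(10, 100))
        genes.append(GeneProduct(gid, molar_mass=mass))
        params[f"kcat_{rid}"] = kcat
        reactions.append(
            Reaction(
                rid,
                {mets[sub]: -a, mets[prod]: b},
                isozymes=[Isozyme({gid: 1}, kcat_forward=ParamRef(f"kcat_{rid}"))],
            )
        )

    # backbone chain guarantees a route from uptake to the objective
    idx = 0
    for i in range(n_mets - 1):
        add_internal(idx, i, i + 1)
        idx += 1
    # extra forward edges create alternative routes
    while idx < n_rxns:
        sub = int(rng.integers(0, n_mets - 1))
        prod = int(rng.integers(sub + 1, n_mets))
        add_internal(idx, sub, prod)
        idx += 1
    reactions.append(
        Reaction("secretion", {mets[-1]: -1.0}, objective_coefficient=1.0)
    )

    # randomly partition gene products over pools, each pool nonempty
    gids = [g.id for g in genes]
    assignment = list(rng.integers(0, n_pools, size=len(gids)))
    for k in range(n_pools):
        if k not in assignment:
            assignment[int(rng.integers(0, len(gids)))] = k
    pools = []
    for k in range(n_pools):
        members = [g for g, a in zip(gids, assignment) if a == k]
        if not members:
            continue
        pid = f"pool{k}"
        params[f"cap_{pid}"] = float(rng.uniform(0.5, 5.0))
        pools.append(EnzymePool(pid, members, capacity=ParamRef(f"cap_{pid}")))

    return EcModel(
        metabolites=[Metabolite(m) for m in mets],
        reactions=reactions,
        gene_products=genes,
        pools=pools,
        objective_reaction="secretion",
        parameters=params,
    )


def random_ec_network(
    seed: int, n_mets: int = 6, n_rxns: int = 10, n_pools: int = 2, max_tries: int = 1000
) -> EcModel:
    """Generate a random connected, feasible enzyme-constrained network.

    Structure: cost-free uptake of ``M0``, a backbone chain of catalysed
    conversions ``M0 -> ... -> M{n-1}`` plus random forward shortcut
    reactions (small-integer stoichiometry), and a cost-free secretion
    of the last metabolite as objective.  kcats are log-uniform in
    [0.1, 100] h⁻¹, molar masses uniform in [10, 100] mg/mmol, and gene
    products are partitioned randomly over ``n_pools`` pools.  Draws are
    rejected until the optimum is positive and, after pruning, unique
    (generic kcats make degeneracy measure-zero, so rejection is rare).
    Identical seeds give byte-identical model JSON.
    """
    if n_mets < 2 or n_rxns < n_mets - 1 or n_pools < 1:
        raise ValueError("sizes below minimal viable network")
    from .lp import build_lp, solve_lp
    from .prune import prune, verify_unique

    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        model = _random_attempt(rng, n_mets, n_rxns, n_pools)
        lp = build_lp(model)
        sol = solve_lp(lp)
        if sol.status != "optimal" or sol.objective_value <= 1e-6:
            continue
        try:
            pruned, psol = prune(model, sol)
        except Exception:
            continue
        if verify_unique(pruned.model):
            return model
    raise RuntimeError(f"no generic feasible network found in {max_tries} tries (seed={seed})")


def make_fixture(name: str, seed: int = 0, **size_kwargs) -> EcModel:
    """Dispatch by fixture name: chain, branch, overflow or random."""
    if name == "chain":
        return make_chain()
    if name == "branch":
        return make_branch()
    if name == "overflow":
        return make_overflow()
    if name == "random":
        return random_ec_network(seed, **size_kwargs)
    raise ValueError(f"unknown fixture {name!r}")
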