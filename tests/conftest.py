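"""Shared fixtures: the three named toy models and their solved/pruned
pipeline stages, cached per session to keep the suite fast."""

import pytest

from ofmsens import (
    build_lp,
    detect_active_set,
    homogenize,
    kkt_differentiate,
    make_branch,
    make_chain,
    make_overflow,
    prune,
    solve_lp,
)


@pytest.fixture(scope="session")
def chain():
    return make_chain()


@pytest.fixture(scope="session")
def branch():
    return make_branch()


@pytest.fixture(scope="session")
def overflow():
    return make_overflow()


def run_pipeline(model):
    """solve -> prune -> active set -> raw sensitivities -> homogenize."""
    lp = build_lp(model)
    sol = solve_lp(lp)
    pruned, psol = prune(model, sol)
    plp = build_lp(pruned.model)
    act = detect_active_set(plp, psol)
    sens = kkt_differentiate(plp, psol, act)
    hs = homogenize(pruned, psol)
    return dict(lp=lp, sol=sol, pruned=pruned, psol=psol, plp=plp, act=act, sens=sens, hs=hs)


@pytest.fixture(scope="session")
def chain_run(chain):
    return run_pipeline(chain)


@pytest.fixture(scope="session")
def branch_run(branch):
    return run_pipeline(branch)


@pytest.fixture(scope="session")
def overflow_run(overflow):
    return run_pipeline(overflow)
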