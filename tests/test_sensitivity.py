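"""Implicit KKT differentiation against closed forms and the FD oracle."""

import numpy as np
import pandas as pd
import pytest

from ofmsens import (
    build_lp,
    control_coefficients,
    detect_active_set,
    finite_difference_oracle,
    kkt_differentiate,
    make_branch,
    make_chain,
    prune,
    random_ec_network,
    solve_lp,
)
from ofmsens.sensitivity import DegenerateSolutionError


def fd_deviation(model_run):
    """Sup-norm deviation between KKT and central-FD sensitivities,
    relative to max(1, ||KKT||_inf)."""
    pruned, plp, sens = model_run["pruned"], model_run["plp"], model_run["sens"]
    fd = finite_difference_oracle(pruned.model, pruned.model.registry(), plp.dep_params())
    diff = np.abs(fd.raw.values - sens.raw.values).max()
    return diff / max(1.0, np.abs(sens.raw.values).max())


class TestActiveSet:
    def test_chain_pool_row_active_with_positive_dual(self, chain_run):
        act = chain_run["act"]
        assert "pool__pool" in act.row_labels
        i = act.row_labels.index("pool__pool")
        assert act.y[i] > 0

    def test_slack_pool_row_excluded(self):
        m = make_chain()
        m.reactions[1].upper_bound = 1.0  # flux cap binds long before the pool
        lp = build_lp(m)
        sol = solve_lp(lp)
        act = detect_active_set(lp, sol)
        assert "pool__pool" not in act.row_labels
        assert "ub__cat" in act.row_labels

    def test_non_vertex_solution_raises(self):
        # with duplicated routes the optimal face is an edge; the midpoint of
        # its two vertices is optimal but not basic, so differentiation must refuse
        import dataclasses

        m = make_branch()
        m.parameters["kcat_r1"] = m.parameters["kcat_r2"]
        lp = build_lp(m)
        sol = solve_lp(lp)
        x = sol.x.copy()
        i1, i2 = lp.var_index["r1"], lp.var_index["r2"]
        e1, e2 = lp.var_index["e__r1"], lp.var_index["e__r2"]
        x[i1] = x[i2] = (sol.x[i1] + sol.x[i2]) / 2
        x[e1] = x[e2] = (sol.x[e1] + sol.x[e2]) / 2
        midpoint = dataclasses.replace(sol, x=x)
        with pytest.raises(DegenerateSolutionError, match="non-vertex"):
            detect_active_set(lp, midpoint)


class TestKktDifferentiate:
    def test_chain_closed_form(self, chain_run):
        # v* = kcat*E/w: dv/dkcat = E/w = 5, dv/dE = kcat/w = 2
        raw = chain_run["sens"].raw
        assert raw.loc["secretion", "kcat_cat"] == pytest.approx(5.0, abs=1e-9)
        assert raw.loc["secretion", "cap_pool"] == pytest.approx(2.0, abs=1e-9)
        # the enzyme concentration is capacity-limited: de/dkcat = 0
        assert raw.loc["e__cat", "kcat_cat"] == pytest.approx(0.0, abs=1e-12)

    def test_parameter_in_inactive_row_gives_exact_zero_column(self):
        m = make_chain()
        m.parameters["cap_pool"] = 50.0  # slack pool; cap the flux instead
        m.reactions[1].upper_bound = 1.0
        lp = build_lp(m)
        sol = solve_lp(lp)
        act = detect_active_set(lp, sol)
        sens = kkt_differentiate(lp, sol, act)
        assert np.all(sens.raw["cap_pool"].values == 0.0)

    def test_batch_equals_single_parameter_runs_bitwise(self, overflow_run):
        plp, psol, act = overflow_run["plp"], overflow_run["psol"], overflow_run["act"]
        batch = kkt_differentiate(plp, psol, act)
        for p in plp.dep_params():
            single = kkt_differentiate(plp, psol, act, params=[p])
            assert np.array_equal(single.raw[p].values, batch.raw[p].values)

    @pytest.mark.parametrize("fixture_name", ["chain_run", "branch_run", "overflow_run"])
    def test_matches_fd_oracle_on_fixtures(self, fixture_name, request):
        assert fd_deviation(request.getfixturevalue(fixture_name)) <= 1e-4

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_fd_oracle_on_random_models(self, seed):
        m = random_ec_network(seed, 5, 8, 2)
        sol = solve_lp(build_lp(m))
        pruned, psol = prune(m, sol)
        plp = build_lp(pruned.model)
        act = detect_active_set(plp, psol)
        sens = kkt_differentiate(plp, psol, act)
        fd = finite_difference_oracle(pruned.model, pruned.model.registry(), plp.dep_params())
        dev = np.abs(fd.raw.values - sens.raw.values).max() / max(
            1.0, np.abs(sens.raw.values).max()
        )
        assert dev <= 1e-4


class TestControlCoefficients:
    def test_chain_log_log_slopes_are_one(self, chain_run):
        cc = control_coefficients(chain_run["sens"], chain_run["psol"], make_chain().registry())
        assert cc.scaled.loc["secretion", "kcat_cat"] == pytest.approx(1.0, abs=1e-9)
        assert cc.scaled.loc["secretion", "cap_pool"] == pytest.approx(1.0, abs=1e-9)

    def test_zero_raw_gives_zero_scaled(self, chain_run):
        cc = control_coefficients(chain_run["sens"], chain_run["psol"], make_chain().registry())
        zero_raw = chain_run["sens"].raw == 0.0
        assert (cc.scaled.values[zero_raw.values] == 0.0).all()

    @pytest.mark.parametrize("seed", [0, 4, 11])
    def test_kcat_summation_theorem_on_homogeneous_models(self, seed):
        # scaling all kcats by alpha scales every flux by alpha, so kcat
        # control coefficients of each flux sum to 1
        m = random_ec_network(seed, 5, 8, 2)
        sol = solve_lp(build_lp(m))
        pruned, psol = prune(m, sol)
        plp = build_lp(pruned.model)
        act = detect_active_set(plp, psol)
        sens = kkt_differentiate(plp, psol, act)
        cc = control_coefficients(sens, psol, pruned.model.registry())
        kcat_cols = [c for c in cc.scaled.columns if c.startswith("kcat")]
        flux_rows = [v for v, k in zip(plp.variables, plp.var_kind) if k == "flux"]
        sums = cc.scaled.loc[flux_rows, kcat_cols].sum(axis=1)
        assert np.allclose(sums.values, 1.0, atol=1e-6)


class TestFiniteDifferenceOracle:
    def test_chain_kcat_slope_exact_for_linear_closed_form(self, chain_run):
        pruned = chain_run["pruned"]
        fd = finite_difference_oracle(pruned.model, pruned.model.registry(), ["kcat_cat"])
        assert fd.raw.loc["secretion", "kcat_cat"] == pytest.approx(5.0, abs=1e-6)

    def test_zero_step_rejected(self, chain_run):
        pruned = chain_run["pruned"]
        with pytest.raises(ValueError):
            finite_difference_oracle(pruned.model, pruned.model.registry(), ["kcat_cat"], rel_step=0.0)

    def test_infeasible_perturbation_flags_column_missing(self, overflow_run):
        pruned = overflow_run["pruned"]
        reg = pruned.model.registry()
        # an enormous step on the maintenance flux makes the problem infeasible
        fd = finite_difference_oracle(pruned.model, reg, ["atpm_flux"], rel_step=50.0)
        assert fd.raw["atpm_flux"].isna().all()
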