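"""Flux-mode enumeration, decomposition of the optimum, and usage sensitivity."""

import numpy as np
import pytest

from ofmsens import (
    build_lp,
    brute_force_modes,
    decompose,
    double_description,
    homogenize,
    make_branch,
    ofm_sensitivity,
    ofm_usage_fd,
    ofms,
    prune,
    random_ec_network,
    solve_lp,
)
from ofmsens.model import canonical_reaction_order
from ofmsens.modes import UnsupportedParameterError


def stoichiometric_matrix(model):
    mets = sorted(m.id for m in model.metabolites)
    order = canonical_reaction_order(model)
    return np.array(
        [[model.reaction(r).stoichiometry.get(met, 0.0) for r in order] for met in mets]
    ), order


def normalize_set(rays, tol=1e-9):
    out = set()
    for r in rays:
        r = np.asarray(r, dtype=float)
        r = r / r.sum()
        out.add(tuple(np.round(r, 8)))
    return out


class TestDoubleDescription:
    def test_line_meets_orthant_in_single_ray(self):
        rays = double_description(np.array([[1.0, -1.0]]))
        assert len(rays) == 1
        assert rays[0] == pytest.approx([0.5, 0.5])

    def test_empty_cone(self):
        # x1 = -x2 with x >= 0 admits only 0
        rays = double_description(np.array([[1.0, 1.0]]))
        assert rays == []

    def test_branch_stoichiometry_has_two_efms(self, branch):
        S, _ = stoichiometric_matrix(branch)
        assert len(double_description(S)) == 2
        assert len(brute_force_modes(S)) == 2

    def test_linear_chain_has_one_efm(self, chain):
        S, _ = stoichiometric_matrix(chain)
        assert len(brute_force_modes(S)) == 1
        assert len(double_description(S)) == 1

    @pytest.mark.parametrize("seed", range(30))
    def test_agrees_with_brute_force_on_random_networks(self, seed):
        m = random_ec_network(seed, n_mets=5, n_rxns=np.random.default_rng(seed).integers(6, 10))
        S, _ = stoichiometric_matrix(m)
        assert S.shape[1] <= 12
        dd = normalize_set(double_description(S))
        bf = normalize_set(brute_force_modes(S))
        assert dd == bf

    @pytest.mark.parametrize("seed", [2, 9, 17])
    def test_modes_are_support_minimal(self, seed):
        m = random_ec_network(seed, 5, 8)
        S, _ = stoichiometric_matrix(m)
        rays = double_description(S)
        supports = [frozenset(np.flatnonzero(r > 1e-9)) for r in rays]
        for a in supports:
            for b in supports:
                assert not (a < b), "a mode support strictly contains another's"


class TestHomogenize:
    def test_overflow_w_column_aggregates_fixed_contributions(self, overflow_run):
        hs = overflow_run["hs"]
        assert hs.has_vbar
        # w = S_atpm * 1 + S_biomass * v_b*; only the ATP row is nonzero
        atp = hs.metabolite_ids.index("ATP")
        vb = overflow_run["psol"]["biomass"]
        expect = -1.0 * 1.0 + (-1.0) * vb
        assert hs.w[atp] == pytest.approx(expect, rel=1e-9)
        assert np.count_nonzero(np.abs(hs.w) > 1e-12) == 1

    def test_homogeneous_model_without_objective_fold_passes_through(self, branch_run):
        hs = homogenize(
            branch_run["pruned"], branch_run["psol"], fold_objective=False
        )
        assert not hs.has_vbar
        S = hs.A
        assert S.shape[1] == len(hs.free_reactions)

    def test_reference_solution_lies_in_the_cone(self, overflow_run):
        hs, psol = overflow_run["hs"], overflow_run["psol"]
        x = np.array([psol[r] for r in hs.free_reactions] + [1.0])
        assert np.max(np.abs(hs.A @ x)) <= 1e-8


class TestOfms:
    def test_overflow_has_exactly_two_ofms(self, overflow_run):
        modes = ofms(overflow_run["hs"])
        assert len(modes) == 2
        supports = {tuple(sorted(m.support)) for m in modes}
        assert ("glc_uptake", "resp") in supports  # respiratory
        assert ("byp_secretion", "ferm", "glc_uptake") in supports  # fermentative

    def test_single_route_model_has_one_ofm_equal_to_solution(self, branch_run):
        modes = ofms(branch_run["hs"])
        assert len(modes) == 1
        psol = branch_run["psol"]
        # v_bar = 1 delivers the optimum, so the mode IS the solution
        for r in modes[0].reaction_ids:
            assert modes[0][r] == pytest.approx(psol[r], rel=1e-9)

    def test_each_ofm_is_admissible(self, overflow_run):
        hs = overflow_run["hs"]
        for m in ofms(hs):
            x = np.concatenate([m.values, [1.0]])
            assert np.max(np.abs(hs.A @ x)) <= 1e-8
            assert np.min(m.values) >= 0

    def test_before_pruning_two_efms_after_pruning_one_ofm(self, branch, branch_run):
        S, _ = stoichiometric_matrix(branch)
        assert len(double_description(S)) == 2
        assert len(ofms(branch_run["hs"])) == 1


class TestDecompose:
    def test_single_mode_gives_unit_weight(self, branch_run):
        dec = decompose(branch_run["psol"], ofms(branch_run["hs"]), K=1)
        assert dec.weights == pytest.approx([1.0])

    def test_overflow_weights_match_closed_form(self, overflow_run):
        # lambda_resp = y_R v_r*/(1+v_b*) = 15/16, lambda_ferm = 1/16
        dec = decompose(overflow_run["psol"], ofms(overflow_run["hs"]), K=2)
        w = sorted(dec.weights)
        assert w[0] == pytest.approx(1 / 16, rel=1e-9)
        assert w[1] == pytest.approx(15 / 16, rel=1e-9)
        assert dec.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert dec.n_active <= 2

    @pytest.mark.parametrize("seed", range(15))
    def test_invariants_on_random_models(self, seed):
        m = random_ec_network(seed, 5, 8, 2)
        sol = solve_lp(build_lp(m))
        pruned, psol = prune(m, sol)
        hs = homogenize(pruned, psol)
        dec = decompose(psol, ofms(hs), K=max(1, len(pruned.model.pools)))
        assert np.all(dec.weights >= 0)
        assert dec.weights.sum() == pytest.approx(1.0, abs=1e-8)
        assert dec.residual <= 1e-8 * max(1.0, np.abs(psol.x).max())
        assert dec.n_active <= max(1, len(pruned.model.pools))


@pytest.fixture(scope="module")
def overflow_osens_data(overflow_run):
    hs, psol = overflow_run["hs"], overflow_run["psol"]
    dec = decompose(psol, ofms(hs), K=2)
    names = [p for p in overflow_run["plp"].dep_params() if p != "atpm_flux"]
    osens = ofm_sensitivity(
        dec, hs, overflow_run["sens"], names,
        registry=overflow_run["pruned"].model.registry(),
    )
    return dec, osens


class TestOfmSensitivity:
    @pytest.fixture()
    def overflow_osens(self, overflow_osens_data):
        return overflow_osens_data

    def test_columns_sum_to_zero(self, overflow_osens):
        _, osens = overflow_osens
        assert np.abs(osens.raw.sum(axis=0).values).max() <= 1e-10

    def test_two_mode_antisymmetry(self, overflow_osens):
        _, osens = overflow_osens
        assert np.array_equal(osens.raw.iloc[0].values, -osens.raw.iloc[1].values)

    def test_membrane_crowding_sign_pattern(self, overflow_osens):
        # raising a cytosolic kcat favours the fermentative mode; raising the
        # membrane-bound respiratory kcat favours the respiratory mode
        dec, osens = overflow_osens
        ferm = next(i for i, m in enumerate(dec.modes) if "ferm" in m.support)
        resp = next(i for i, m in enumerate(dec.modes) if "resp" in m.support)
        for cytosolic in ("kcat_ferm", "kcat_bio"):
            assert osens.scaled.iloc[ferm][cytosolic] > 0
            assert osens.scaled.iloc[resp][cytosolic] < 0
        assert osens.scaled.iloc[resp]["kcat_resp"] > 0
        assert osens.scaled.iloc[ferm]["kcat_resp"] < 0

    def test_matches_fd_oracle_on_overflow(self, overflow_run, overflow_osens):
        dec, osens = overflow_osens
        pruned = overflow_run["pruned"]
        fd = ofm_usage_fd(pruned, pruned.model.registry(), list(osens.raw.columns))
        # align by support
        order = [f"support:{sorted(m.support)}" for m in dec.modes]
        fd = fd.loc[order]
        dev = np.abs(fd.values - osens.raw.values).max() / max(1.0, np.abs(osens.raw.values).max())
        assert dev <= 1e-4

    def test_fixed_flux_parameters_rejected(self, overflow_run):
        hs, psol = overflow_run["hs"], overflow_run["psol"]
        dec = decompose(psol, ofms(hs), K=2)
        with pytest.raises(UnsupportedParameterError):
            ofm_sensitivity(dec, hs, overflow_run["sens"], ["atpm_flux"])
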