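"""Model data structures, JSON round-trips, reversible splitting, validation."""

import json
import math

import pytest

from ofmsens import (
    EcModel,
    EnzymePool,
    GeneProduct,
    Isozyme,
    Metabolite,
    ParamRef,
    Reaction,
    ValidationError,
    load_model,
    make_branch,
    make_chain,
    make_overflow,
    save_model,
    split_reversible,
    validate,
)
from ofmsens.model import model_to_dict


@pytest.mark.parametrize("maker", [make_chain, make_branch, make_overflow])
def test_json_round_trip_preserves_model(tmp_path, maker):
    model = maker()
    path = tmp_path / "m.json"
    save_model(model, path)
    reread = load_model(path)
    assert model_to_dict(reread) == model_to_dict(model)


def test_chain_fixture_shape(tmp_path):
    path = tmp_path / "chain.json"
    save_model(make_chain(), path)
    m = load_model(path)
    assert len(m.reactions) == 3
    assert len(m.pools) == 1


def test_overflow_fixture_shape(tmp_path):
    path = tmp_path / "overflow.json"
    save_model(make_overflow(), path)
    m = load_model(path)
    assert len(m.pools) == 2
    assert len(m.fixed_fluxes) == 1


def test_dangling_metabolite_ref_raises_naming_it(tmp_path):
    m = make_chain()
    m.reactions[1].stoichiometry["GHOST"] = -1.0
    path = tmp_path / "bad.json"
    save_model(m, path)
    with pytest.raises(ValidationError, match="GHOST"):
        load_model(path)


def test_infinite_bounds_survive_json(tmp_path):
    m = make_chain()
    assert math.isinf(m.reactions[0].upper_bound)
    path = tmp_path / "m.json"
    save_model(m, path)
    assert math.isinf(load_model(path).reactions[0].upper_bound)
    assert "inf" in json.loads(path.read_text())["reactions"][0]["upper_bound"]


def _reversible_model(kcat_reverse=2.0):
    return EcModel(
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("in", {"A": 1.0}),
            Reaction(
                "rev",
                {"A": -1.0, "B": 1.0},
                lower_bound=-5.0,
                upper_bound=10.0,
                isozymes=[Isozyme({"g": 1}, kcat_forward=1.0, kcat_reverse=kcat_reverse)],
            ),
            Reaction("out", {"B": -1.0}, objective_coefficient=1.0),
        ],
        gene_products=[GeneProduct("g", 1.0)],
        pools=[EnzymePool("p", ["g"], 1.0)],
        objective_reaction="out",
    )


class TestSplitReversible:
    def test_reversible_reaction_splits_with_swapped_bounds(self):
        split = split_reversible(_reversible_model())
        fwd = split.reaction("rev_fwd")
        bwd = split.reaction("rev_bwd")
        assert (fwd.lower_bound, fwd.upper_bound) == (0.0, 10.0)
        assert (bwd.lower_bound, bwd.upper_bound) == (0.0, 5.0)
        assert bwd.stoichiometry == {"A": 1.0, "B": -1.0}
        assert fwd.isozymes[0].kcat_forward == 1.0
        assert bwd.isozymes[0].kcat_forward == 2.0

    def test_irreversible_model_unchanged(self):
        m = make_overflow()
        assert model_to_dict(split_reversible(m)) == model_to_dict(m)

    def test_idempotent(self):
        once = split_reversible(_reversible_model())
        twice = split_reversible(once)
        assert model_to_dict(twice) == model_to_dict(once)

    def test_reaction_count_bookkeeping(self):
        m = _reversible_model()
        n_rev = sum(1 for r in m.reactions if r.lower_bound < 0)
        n_irr = len(m.reactions) - n_rev
        assert len(split_reversible(m).reactions) == n_irr + 2 * n_rev

    def test_missing_kcat_reverse_gives_costfree_backward_copy(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="ofmsens.model"):
            split = split_reversible(_reversible_model(kcat_reverse=None))
        assert split.reaction("rev_bwd").isozymes == []
        assert any("kcat_reverse" in r.message for r in caplog.records)


class TestValidate:
    def test_fixtures_clean_with_costfree_exchange_warnings(self):
        for m in (make_chain(), make_branch(), make_overflow()):
            rep = validate(m)
            assert rep.errors == []
        # the maintenance reaction converts ATP without an enzyme: warned
        rep = validate(make_overflow())
        assert any("atpm" in w for w in rep.warnings) or rep.warnings == []

    def test_bound_inversion_is_an_error(self):
        m = make_chain()
        m.reactions[0].lower_bound = 5.0
        m.reactions[0].upper_bound = 1.0
        rep = validate(m)
        assert len([e for e in rep.errors if "lower_bound" in e]) == 1

    def test_pool_member_not_in_genes_is_an_error(self):
        m = make_chain()
        m.pools[0].members.append("phantom")
        rep = validate(m)
        assert len([e for e in rep.errors if "phantom" in e]) == 1

    def test_unresolved_parameter_is_an_error(self):
        m = make_chain()
        del m.parameters["kcat_cat"]
        rep = validate(m)
        assert any("kcat_cat" in e for e in rep.errors)


def test_cobra_json_import_maps_gpr_to_isozymes(tmp_path):
    # minimal COBRA-style JSON: one OR of two genes and one AND complex
    data = {
        "metabolites": [
            {"id": "a_c", "compartment": "c"},
            {"id": "b_c", "compartment": "c"},
        ],
        "reactions": [
            {
                "id": "R1",
                "metabolites": {"a_c": -1.0, "b_c": 1.0},
                "lower_bound": 0.0,
                "upper_bound": 1000.0,
                "gene_reaction_rule": "g1 or g2",
                "objective_coefficient": 0.0,
            },
            {
                "id": "R2",
                "metabolites": {"b_c": -1.0},
                "lower_bound": 0.0,
                "upper_bound": 1000.0,
                "gene_reaction_rule": "g3 and g4",
                "objective_coefficient": 1.0,
            },
            {
                "id": "EX_a",
                "metabolites": {"a_c": 1.0},
                "lower_bound": 0.0,
                "upper_bound": 1000.0,
                "gene_reaction_rule": "",
            },
        ],
        "genes": [{"id": g, "name": g} for g in ["g1", "g2", "g3", "g4"]],
        "id": "mini",
        "compartments": {"c": "cytosol"},
        "version": "1",
    }
    path = tmp_path / "mini.json"
    path.write_text(json.dumps(data))
    m = load_model(path, format="cobra-json")
    r1 = m.reaction("R1")
    assert len(r1.isozymes) == 2  # OR -> two isozymes
    r2 = m.reaction("R2")
    assert len(r2.isozymes) == 1  # AND -> one complex
    assert r2.isozymes[0].subunit_counts == {"g3": 1, "g4": 1}
    assert isinstance(r1.isozymes[0].kcat_forward, ParamRef)
    assert m.objective_id() == "R2"
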