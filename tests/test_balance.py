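"""Mass/charge balance checking and minimal bookkeeping repair."""

import itertools
from fractions import Fraction

import pytest

from gemrefinery.balance import (
    BALANCED,
    DEFAULT_POOL,
    IMBALANCED,
    UNCHECKABLE,
    BalanceResult,
    apply_repairs,
    check_balance,
    suggest_repair,
)
from gemrefinery.model import Compartment, Model, Reaction, Species, classify_all


def water_model():
    m = Model("w")
    m.add_compartment(Compartment("c"))
    for sid, formula, charge in (("h2_c", {"H": 2}, 0), ("o2_c", {"O": 2}, 0),
                                 ("h2o_c", {"H": 2, "O": 1}, 0),
                                 ("x_c", None, None)):
        m.add_species(Species(id=sid, compartment="c", formula=formula,
                              charge=charge))
    return m


def oracle_search(target, budget=4):
    """Independent exhaustive search over the same pool, written directly
    from the definition: all signed multisets of pool species up to the
    budget, smallest total count first."""
    options = [(b, side) for b in DEFAULT_POOL for side in (-1, 1)]
    for total in range(1, budget + 1):
        hits = []
        for combo in itertools.combinations_with_replacement(options, total):
            remaining = dict(target)
            for b, side in combo:
                for key, count in b.composition().items():
                    remaining[key] = remaining.get(key, 0) + side * count
            if all(v == 0 for v in remaining.values()):
                hits.append(combo)
        if hits:
            return total, hits
    return None, []


class TestCheckBalance:
    def test_water_formation_balanced(self):
        m = water_model()
        r = m.add_reaction(Reaction("comb", stoichiometry={
            "h2_c": -2, "o2_c": -1, "h2o_c": 2}))
        result = check_balance(r, m)
        assert result.status == BALANCED
        assert result.element_delta == {} and result.charge_delta == 0

    def test_missing_oxygen_reported(self):
        m = water_model()
        r = m.add_reaction(Reaction("broken", stoichiometry={
            "h2o_c": -1, "h2_c": 1}))
        result = check_balance(r, m)
        assert result.status == IMBALANCED
        assert result.element_delta == {"O": Fraction(-1)}

    def test_missing_formula_uncheckable(self):
        m = water_model()
        r = m.add_reaction(Reaction("opaque", stoichiometry={
            "h2o_c": -1, "x_c": 1}))
        assert check_balance(r, m).status == UNCHECKABLE

    def test_boundary_reactions_uncheckable(self, fixture):
        assert check_balance(fixture.model.reactions["EX_GLC"],
                             fixture.model).status == UNCHECKABLE

    def test_fixture_background_balanced(self, fixture):
        imbalanced = {
            r.id for r in fixture.model.enabled_reactions()
            if check_balance(r, fixture.model).status == IMBALANCED}
        assert imbalanced == set(fixture.manifest["planted"]["unbalanced"])


class TestSuggestRepair:
    @pytest.mark.parametrize("delta,expected", [
        ({"H": 2, "O": 1}, [("h2o", "reactant", 1)]),
        ({"H": 1, "charge": 1}, [("h", "reactant", 1)]),
        ({"H": -1, "charge": -1}, [("h", "product", 1)]),
        ({"H": -4, "O": -2}, [("h2o", "product", 2)]),
    ])
    def test_examples(self, delta, expected):
        result = BalanceResult(
            "r", IMBALANCED,
            {k: Fraction(v) for k, v in delta.items() if k != "charge"},
            Fraction(delta.get("charge", 0)))
        assert suggest_repair(result) == expected

    def test_carbon_deficit_unreachable_at_budget_one(self):
        result = BalanceResult("r", IMBALANCED, {"C": Fraction(-2)},
                               Fraction(0))
        assert suggest_repair(result, budget=1) is None
        total, hits = oracle_search({"C": -2, "charge": 0}, budget=1)
        assert hits == []

    def test_minimality_against_oracle(self, fixture):
        for rxn in fixture.model.enabled_reactions():
            result = check_balance(rxn, fixture.model)
            if result.status != IMBALANCED:
                continue
            repair = suggest_repair(result)
            assert repair is not None
            target = {k: int(v) for k, v in result.element_delta.items()}
            target["charge"] = int(result.charge_delta)
            oracle_total, _ = oracle_search(target)
            assert sum(n for _s, _side, n in repair) == oracle_total

    def test_requires_imbalanced_status(self):
        with pytest.raises(ValueError):
            suggest_repair(BalanceResult("r", BALANCED))


class TestApplyRepairs:
    def test_planted_omissions_recovered_and_applied(self, fixture):
        m = fixture.model.copy()
        classify_all(m)
        results = [check_balance(r, m) for r in m.enabled_reactions()]
        expected = fixture.manifest["planted"]["unbalanced"]
        out, audit = apply_repairs(m, results, mode="apply")
        by_rxn = {a["reaction"]: a for a in audit}
        for rid, planted_repair in expected.items():
            assert by_rxn[rid]["repair"] == \
                [tuple(x) for x in planted_repair]
        # proton/water-only repairs applied, Pi left for review
        assert by_rxn["UB_H2O"]["applied"] and by_rxn["UB_H"]["applied"]
        assert not by_rxn["UB_PI"]["applied"]
        assert check_balance(out.reactions["UB_H2O"], out).status == BALANCED
        assert check_balance(out.reactions["UB_PI"], out).status == IMBALANCED

    def test_allowlist_enables_pi_repair(self, fixture):
        m = fixture.model.copy()
        classify_all(m)
        results = [check_balance(r, m) for r in m.enabled_reactions()]
        out, audit = apply_repairs(m, results, mode="apply",
                                   allowlist={"UB_PI"})
        assert check_balance(out.reactions["UB_PI"], out).status == BALANCED

    def test_suggest_mode_does_not_touch_model(self, fixture):
        m = fixture.model.copy()
        classify_all(m)
        results = [check_balance(r, m) for r in m.enabled_reactions()]
        out, audit = apply_repairs(m, results, mode="suggest")
        assert check_balance(out.reactions["UB_H2O"], out).status == IMBALANCED

    def test_balanced_model_is_noop(self):
        m = water_model()
        m.add_reaction(Reaction("comb", stoichiometry={
            "h2_c": -2, "o2_c": -1, "h2o_c": 2}))
        classify_all(m)
        results = [check_balance(r, m) for r in m.enabled_reactions()]
        out, audit = apply_repairs(m, results, mode="apply")
        assert audit == []

    def test_repairs_never_touch_existing_coefficients(self, fixture):
        m = fixture.model.copy()
        classify_all(m)
        before = {sid: c for sid, c
                  in m.reactions["UB_H2O"].stoichiometry.items()}
        results = [check_balance(r, m) for r in m.enabled_reactions()]
        out, _ = apply_repairs(m, results, mode="apply")
        after = out.reactions["UB_H2O"].stoichiometry
        for sid, coef in before.items():
            assert after[sid] == coef
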