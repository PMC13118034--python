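"""Directionality rules, closed-boundary loop detection and resolution."""

import pytest

from gemrefinery.dedup import deduplicate
from gemrefinery.model import (
    Compartment,
    Model,
    Reaction,
    Species,
    classify_all,
)
from gemrefinery.synth import random_loop_fixture
from gemrefinery.thermo import (
    RuleConflictError,
    apply_irreversibility_rules,
    detect_loops,
    irreversibility_stats,
    loop_reactions_by_enumeration,
    producible_species,
    resolve_loops,
    verify_loopless,
)


def chain_model():
    """A -> B -> C with exchanges at both ends: no circulation possible."""
    m = Model("chain")
    m.add_compartment(Compartment("c"))
    for sid in ("a_c", "b_c", "c_c"):
        m.add_species(Species(id=sid, compartment="c"))
    m.add_reaction(Reaction("EX_A", stoichiometry={"a_c": -1}))
    m.add_reaction(Reaction("EX_C", stoichiometry={"c_c": -1}))
    m.add_reaction(Reaction("AB", stoichiometry={"a_c": -1, "b_c": 1}))
    m.add_reaction(Reaction("BC", stoichiometry={"b_c": -1, "c_c": 1}))
    classify_all(m)
    return m


@pytest.fixture()
def deduped(fixture):
    out, _ = deduplicate(fixture.model.copy())
    return out


class TestRules:
    def test_atp_ligase_constrained_forward(self, model):
        out, changes = apply_irreversibility_rules(model)
        assert out.reactions["LIG1"].lower_bound == 0.0
        assert any(c["reaction"] == "LIG1" and c["class"] == "ATP_LIGASE"
                   for c in changes)

    def test_decarboxylation_committed_toward_co2(self, model):
        model.reactions["PDC"].lower_bound = -1000.0
        out, changes = apply_irreversibility_rules(model)
        assert out.reactions["PDC"].lower_bound == 0.0
        assert any(c["reaction"] == "PDC" and c["class"] == "DECARBOXYLATION"
                   for c in changes)

    def test_unmatched_reaction_untouched(self, model):
        before = (model.reactions["PGI"].lower_bound,
                  model.reactions["PGI"].upper_bound)
        out, _ = apply_irreversibility_rules(model)
        assert (out.reactions["PGI"].lower_bound,
                out.reactions["PGI"].upper_bound) == before

    def test_conflicting_orientations_raise(self):
        m = Model("conflict")
        m.add_compartment(Compartment("c"))
        for sid, formula, charge in (("atp_c", None, None), ("amp_c", None, None),
                                     ("ppi_c", None, None), ("co2_c", None, None),
                                     ("x_c", None, None)):
            m.add_species(Species(id=sid, compartment="c", formula=formula,
                                  charge=charge))
        # reverse ligase signature (AMP+PPi consumed) but CO2 produced:
        # ligase says reverse-forward, decarboxylation says as-written
        m.add_reaction(Reaction("weird", stoichiometry={
            "amp_c": -1, "ppi_c": -1, "atp_c": 1, "co2_c": 1, "x_c": 1}))
        classify_all(m)
        with pytest.raises(RuleConflictError):
            apply_irreversibility_rules(m)


class TestDetectLoops:
    def test_fig3_triangle_is_one_cycle(self, deduped):
        report = detect_loops(deduped)
        assert report.loop_reactions == {"FIG3_R1", "FIG3_R2", "FIG3_R3"}
        assert [sorted(c) for c in report.cycles] == \
            [["FIG3_R1", "FIG3_R2", "FIG3_R3"]]

    def test_linear_chain_has_no_loops(self):
        assert detect_loops(chain_model()).loop_reactions == set()

    def test_bound_scaling_invariance(self, deduped):
        base = detect_loops(deduped).loop_reactions
        scaled = deduped.copy()
        for rxn in scaled.reactions.values():
            rxn.lower_bound *= 10
            rxn.upper_bound *= 10
        assert detect_loops(scaled, cap=10000.0).loop_reactions == base

    def test_bounds_restored_after_detection(self, deduped):
        before = {rid: (r.lower_bound, r.upper_bound)
                  for rid, r in deduped.reactions.items()}
        detect_loops(deduped)
        after = {rid: (r.lower_bound, r.upper_bound)
                 for rid, r in deduped.reactions.items()}
        assert before == after

    def test_invalid_cap_rejected(self, deduped):
        with pytest.raises(ValueError):
            detect_loops(deduped, cap=0.0)


class TestResolveLoops:
    def test_fig3_single_constraint_breaks_cycle(self, deduped, fixture):
        out, reports = resolve_loops(deduped, fixture.dg_table)
        actions = [a for r in reports for a in r.actions]
        assert ("FIG3_R1", "SET_IRREVERSIBLE", "dg0=-30<-20") in actions
        touched = {a[0] for a in actions}
        assert touched == {"FIG3_R1"}  # R2/R3 untouched
        assert out.reactions["FIG3_R1"].lower_bound == 0.0
        ok, optimum = verify_loopless(out)
        assert ok and optimum <= 1e-6

    def test_loopless_model_unchanged(self):
        m = chain_model()
        out, reports = resolve_loops(m)
        assert all(not r.actions for r in reports)
        for rid, rxn in m.reactions.items():
            assert (out.reactions[rid].lower_bound,
                    out.reactions[rid].upper_bound) == \
                (rxn.lower_bound, rxn.upper_bound)

    def test_only_tightens_bounds(self, deduped, fixture):
        out, _ = resolve_loops(deduped, fixture.dg_table)
        for rid, rxn in deduped.reactions.items():
            assert out.reactions[rid].lower_bound >= rxn.lower_bound
            assert out.reactions[rid].upper_bound <= rxn.upper_bound

    def test_loop_set_monotonically_shrinks(self, fixture):
        from gemrefinery.synth import FixtureSpec, build_fixture
        fx = build_fixture(FixtureSpec(futile_cycles=3))
        classify_all(fx.model)
        deduped, _ = deduplicate(fx.model)
        _, reports = resolve_loops(deduped, fx.dg_table)
        sizes = [len(r.loop_reactions) for r in reports]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == 0

    def test_reachability_preserved(self, deduped, fixture):
        before = producible_species(deduped)
        out, _ = resolve_loops(deduped, fixture.dg_table)
        assert producible_species(out) == before


class TestVerifyLoopless:
    def test_empty_model(self):
        ok, optimum = verify_loopless(Model("empty"))
        assert ok and optimum == 0.0

    def test_pre_resolution_triangle_fails(self, deduped):
        ok, optimum = verify_loopless(deduped)
        assert not ok and optimum > 0


class TestEnumerationOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_networks_agree(self, seed):
        m = random_loop_fixture(seed)
        classify_all(m)
        assert detect_loops(m).loop_reactions == \
            loop_reactions_by_enumeration(m)


class TestStats:
    def test_four_of_five_is_eighty_percent(self):
        m = Model("s")
        m.add_compartment(Compartment("c"))
        for sid in ("a_c", "b_c"):
            m.add_species(Species(id=sid, compartment="c"))
        for i in range(5):
            lb = 0.0 if i < 4 else -1000.0
            m.add_reaction(Reaction(f"ox{i}", stoichiometry={"a_c": -1,
                                                             "b_c": 1},
                                    lower_bound=lb))
        rows = irreversibility_stats(m, {f"ox{i}": "OXPHOS/ETC"
                                         for i in range(5)})
        assert rows == [{"class": "OXPHOS/ETC", "n": 5,
                         "pct_irreversible": 80.0, "pct_blocked": 0.0}]

    def test_matches_bruteforce_on_fixture(self, deduped):
        class_map = {r.id: r.rclass for r in deduped.enabled_reactions()}
        rows = irreversibility_stats(deduped, class_map)
        for row in rows:
            members = [r for r in deduped.enabled_reactions()
                       if r.rclass == row["class"]]
            n_irr = sum(1 for r in members if r.irreversible)
            assert row["n"] == len(members)
            from gemrefinery.reporting import round1
            assert row["pct_irreversible"] == round1(100 * n_irr / len(members))
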