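"""Canonical keys, duplicate detection and consolidation guarantees."""

from fractions import Fraction
from itertools import combinations

import pytest

from gemrefinery.dedup import (
    canonical_key,
    consolidate,
    deduplicate,
    find_duplicates,
)
from gemrefinery.model import (
    Compartment,
    GprTree,
    Model,
    Reaction,
    Species,
)


def proton_model():
    m = Model("p")
    m.add_compartment(Compartment("c"))
    m.add_compartment(Compartment("m"))
    for sid, comp, formula, charge in (
            ("h_c", "c", {"H": 1}, 1), ("h_m", "m", {"H": 1}, 1),
            ("x_c", "c", None, None), ("y_c", "c", None, None),
            ("x_m", "m", None, None), ("y_m", "m", None, None)):
        m.add_species(Species(id=sid, compartment=comp, formula=formula,
                              charge=charge))
    return m


class TestCanonicalKey:
    def test_scaling_invariance(self, model):
        r = model.reactions["PGI"]
        scaled = Reaction("scaled", stoichiometry={
            sid: coef * Fraction(3, 7) for sid, coef in r.stoichiometry.items()})
        model.add_reaction(scaled)
        assert canonical_key(r, model).participants == \
            canonical_key(scaled, model).participants
        assert canonical_key(r, model).orientation == \
            canonical_key(scaled, model).orientation

    def test_reverse_pair_shares_participants_opposite_orientation(self, model):
        r = model.reactions["PGI"]
        rev = Reaction("rev", stoichiometry={
            sid: -coef for sid, coef in r.stoichiometry.items()})
        model.add_reaction(rev)
        k1, k2 = canonical_key(r, model), canonical_key(rev, model)
        assert k1.participants == k2.participants
        assert k1.orientation == -k2.orientation

    def test_proton_only_difference_collapses(self):
        m = proton_model()
        a = m.add_reaction(Reaction("a", stoichiometry={
            "h_c": -1, "x_c": -1, "y_c": 1}))
        b = m.add_reaction(Reaction("b", stoichiometry={"x_c": -1, "y_c": 1}))
        assert canonical_key(a, m, strip_protons=True) == \
            canonical_key(b, m, strip_protons=True)
        assert canonical_key(a, m, strip_protons=False) != \
            canonical_key(b, m, strip_protons=False)

    def test_proton_translocation_keeps_protons(self):
        m = proton_model()
        pump = m.add_reaction(Reaction("pump", stoichiometry={
            "h_c": -1, "h_m": 1, "x_c": -1, "y_c": 1}))
        key = canonical_key(pump, m, strip_protons=True)
        assert any(sid.startswith("h_") for sid, _ in key.participants)

    def test_degenerate_after_stripping_raises(self):
        m = proton_model()
        r = m.add_reaction(Reaction("only_h", stoichiometry={"h_c": -1}))
        with pytest.raises(ValueError, match="degenerate"):
            canonical_key(r, m, strip_protons=True)


class TestFindDuplicates:
    def test_planted_artifacts_recovered_exactly(self, fixture):
        report = find_duplicates(fixture.model)
        planted = fixture.manifest["planted"]
        assert sorted(sorted(g) for g in report.exact_duplicate_groups) == \
            planted["exact_duplicate_groups"]
        assert sorted(sorted(p) for p in report.reverse_pairs) == \
            planted["reverse_pairs"]

    def test_compartment_scoping(self):
        m = proton_model()
        m.add_reaction(Reaction("cyt", stoichiometry={"x_c": -1, "y_c": 1}))
        m.add_reaction(Reaction("mit", stoichiometry={"x_m": -1, "y_m": 1}))
        report = find_duplicates(m)
        assert report.exact_duplicate_groups == []
        assert report.reverse_pairs == []

    def test_grouping_equals_pairwise_bruteforce(self, fixture):
        m = fixture.model
        enabled = [r for r in m.enabled_reactions()]
        keys = {r.id: canonical_key(r, m) for r in enabled}
        expected_pairs = {
            tuple(sorted((a.id, b.id)))
            for a, b in combinations(enabled, 2)
            if keys[a.id] == keys[b.id]
        }
        report = find_duplicates(m)
        got_pairs = {
            tuple(sorted(p))
            for group in report.exact_duplicate_groups
            for p in combinations(group, 2)
        }
        assert got_pairs == expected_pairs


class TestConsolidate:
    def test_gpr_carrier_survives(self, fixture):
        out, report = deduplicate(fixture.model.copy())
        for group in fixture.manifest["planted"]["exact_duplicate_groups"]:
            survivors = [rid for rid in group if rid in out.reactions]
            assert len(survivors) == 1
            assert out.reactions[survivors[0]].gpr is not None

    def test_reverse_pair_becomes_reversible(self, fixture):
        out, report = deduplicate(fixture.model.copy())
        for pair in fixture.manifest["planted"]["reverse_pairs"]:
            survivors = [rid for rid in pair if rid in out.reactions]
            assert len(survivors) == 1
            merged = out.reactions[survivors[0]]
            assert merged.lower_bound < 0 < merged.upper_bound

    def test_gene_product_count_invariance(self, fixture):
        out, report = deduplicate(fixture.model.copy())
        assert set(out.gene_products) == set(fixture.model.gene_products)
        assert report.gpr_preservation_check

    def test_no_gpr_bearing_reaction_lost(self, fixture):
        out, report = deduplicate(fixture.model.copy())
        genes_before = set()
        for r in fixture.model.enabled_reactions():
            if r.gpr:
                genes_before |= r.gpr.genes()
        genes_after = set()
        for r in out.enabled_reactions():
            if r.gpr:
                genes_after |= r.gpr.genes()
        assert genes_after == genes_before

    def test_conflicting_gprs_disable_not_remove(self):
        m = proton_model()
        m.gene_products["g1"] = __import__(
            "gemrefinery.model", fromlist=["GeneProduct"]).GeneProduct("g1")
        m.gene_products["g2"] = m.gene_products["g1"].__class__("g2")
        m.add_reaction(Reaction("a", stoichiometry={"x_c": -1, "y_c": 1},
                                gpr=GprTree.leaf("g1")))
        m.add_reaction(Reaction("b", stoichiometry={"x_c": -1, "y_c": 1},
                                gpr=GprTree.leaf("g2")))
        out, report = deduplicate(m)
        assert report.removed_ids == []
        assert len(report.disabled_ids) == 1
        disabled = out.reactions[report.disabled_ids[0]]
        assert not disabled.enabled and disabled.gpr is not None

    def test_no_duplicates_is_identity(self):
        m = proton_model()
        m.add_reaction(Reaction("solo", stoichiometry={"x_c": -1, "y_c": 1}))
        out, report = deduplicate(m)
        assert set(out.reactions) == {"solo"}
        assert report.removed_ids == [] and report.disabled_ids == []

    def test_stale_report_cannot_drop_sole_gpr_carrier(self):
        m = proton_model()
        from gemrefinery.model import GeneProduct
        m.gene_products["g1"] = GeneProduct("g1")
        m.add_reaction(Reaction("a", stoichiometry={"x_c": -1, "y_c": 1},
                                gpr=GprTree.leaf("g1")))
        m.add_reaction(Reaction("b", stoichiometry={"x_c": -1, "y_c": 1}))
        report = find_duplicates(m)
        # corrupt the group order so the GPR-free copy looks like survivor
        m.reactions["a"].gpr, m.reactions["b"].gpr = None, GprTree.leaf("g1")
        m.reactions["b"].gpr = GprTree.leaf("g1")
        m.reactions["a"].gpr = None
        out, rep = consolidate(m, report)
        assert "b" in out.reactions  # carrier survived anyway


def test_fba_optimum_preserved(fixture, tmp_path):
    """Flux-space preservation cross-checked with cobrapy FBA on a planted
    objective before and after consolidation."""
    cobra = pytest.importorskip("cobra")
    from gemrefinery.sbml_io import write_sbml

    before = fixture.model.copy()
    after, _ = deduplicate(fixture.model.copy())
    optima = []
    for tag, m in (("before", before), ("after", after)):
        path = tmp_path / f"{tag}.xml"
        write_sbml(m, path)
        cm = cobra.io.read_sbml_model(str(path))
        cm.objective = "T_LAC"
        optima.append(cm.optimize().objective_value)
    assert optima[0] == pytest.approx(optima[1], abs=1e-9)
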