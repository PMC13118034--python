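"""Identifier reconciliation: matching stages, ambiguity rules, merging."""

import pytest

from gemrefinery.harmonise import (
    DISAMBIGUATED,
    FLAGGED_UNRESOLVED,
    UNMAPPED,
    VARIANT_PROTONATION,
    VARIANT_STEREO,
    HarmonisePolicy,
    MappingRecord,
    MappingTable,
    harmonise_model,
    match_exact,
    match_structure,
    merge_species,
    resolve_ambiguity,
)
from gemrefinery.model import Compartment, Model, Species


def make_species(xrefs=None, formula=None, charge=None, inchikey=None):
    sp = Species(id="x_c", compartment="c", formula=formula, charge=charge)
    for resource, ident in (xrefs or {}).items():
        sp.add_xref(resource, ident)
    if inchikey:
        sp.add_xref("inchikey", inchikey)
    return sp


class TestMatchExact:
    def test_direct_lookup(self):
        table = MappingTable([MappingRecord("kegg.compound", "C00031", "MNXM41")])
        sp = make_species({"kegg.compound": "C00031"})
        assert [r.canonical_id for r in match_exact(sp, table)] == ["MNXM41"]

    def test_no_xrefs_gives_empty(self):
        table = MappingTable([MappingRecord("kegg.compound", "C00031", "MNXM41")])
        assert match_exact(make_species(), table) == []

    def test_conflicting_hits_ordered_by_curation_rank(self):
        table = MappingTable([
            MappingRecord("kegg.compound", "C1", "MNX_B", curation_rank=2),
            MappingRecord("bigg.metabolite", "g1", "MNX_A", curation_rank=1),
        ])
        sp = make_species({"kegg.compound": "C1", "bigg.metabolite": "g1"})
        assert [r.canonical_id for r in match_exact(sp, table)] == \
            ["MNX_A", "MNX_B"]


class TestMatchStructure:
    def test_inchikey_connectivity_block(self):
        key = "WQZGKKKJIJFFOK-GASJEMHNSA-N"
        table = MappingTable([
            MappingRecord("kegg.compound", "C1", "MNXM41", inchikey=key)])
        sp = make_species(inchikey="WQZGKKKJIJFFOK-DVKNGEFBSA-N")
        assert [r.canonical_id for r in match_structure(sp, table)] == ["MNXM41"]

    def test_formula_fallback_returns_all_matches(self):
        formula = {"C": 6, "H": 12, "O": 6}
        table = MappingTable([
            MappingRecord("kegg.compound", "C1", "MNXM41", formula=formula),
            MappingRecord("kegg.compound", "C2", "MNXM99", formula=formula),
        ])
        sp = make_species(formula=formula)
        assert {r.canonical_id for r in match_structure(sp, table)} == \
            {"MNXM41", "MNXM99"}

    def test_inchikey_hits_ordered_first(self):
        formula = {"C": 3, "H": 6, "O": 3}
        table = MappingTable([
            MappingRecord("kegg.compound", "C1", "MNX_F", formula=formula),
            MappingRecord("kegg.compound", "C2", "MNX_K", formula=formula,
                          inchikey="AAAAAAAAAAAAAA-X-N"),
        ])
        sp = make_species(formula=formula, inchikey="AAAAAAAAAAAAAA-Y-N")
        assert [r.canonical_id for r in match_structure(sp, table)][0] == "MNX_K"

    def test_requires_structure_information(self):
        with pytest.raises(ValueError):
            match_structure(make_species(), MappingTable())


class TestResolveAmbiguity:
    def test_identical_species_merge(self):
        recs = [MappingRecord("kegg.compound", "C1", "MNXM41"),
                MappingRecord("bigg.metabolite", "g1", "MNXM41")]
        out = resolve_ambiguity("x_c", recs)
        assert out.status == DISAMBIGUATED
        assert out.chosen_canonical_id == "MNXM41"
        assert out.rule_applied == "identical-species"

    def test_protonation_group_resolves_to_dominant(self):
        recs = [
            MappingRecord("kegg.compound", "C1", "MNX_A", charge=-1,
                          variant_kind=VARIANT_PROTONATION, variant_group="g",
                          dominant=True),
            MappingRecord("kegg.compound", "C1", "MNX_B", charge=0,
                          variant_kind=VARIANT_PROTONATION, variant_group="g"),
        ]
        out = resolve_ambiguity("x_c", recs)
        assert out.chosen_canonical_id == "MNX_A"
        assert out.rule_applied == "dominant-protonation"

    def test_policy_override_beats_table_marker(self):
        recs = [
            MappingRecord("kegg.compound", "C1", "MNX_A", charge=-1,
                          variant_kind=VARIANT_PROTONATION, variant_group="g",
                          dominant=True),
            MappingRecord("kegg.compound", "C1", "MNX_B", charge=0,
                          variant_kind=VARIANT_PROTONATION, variant_group="g"),
        ]
        policy = HarmonisePolicy(dominant_protonation={"g": "MNX_B"})
        assert resolve_ambiguity("x_c", recs, policy).chosen_canonical_id == \
            "MNX_B"

    def test_stereo_group_prefers_curated_chebi_entry(self):
        recs = [
            MappingRecord("kegg.compound", "C1", "MNX_S1",
                          variant_kind=VARIANT_STEREO, variant_group="s",
                          chebi_id="CHEBI:200", curation_rank=2),
            MappingRecord("kegg.compound", "C1", "MNX_S2",
                          variant_kind=VARIANT_STEREO, variant_group="s",
                          chebi_id="CHEBI:100", curation_rank=1),
        ]
        assert resolve_ambiguity("x_c", recs).chosen_canonical_id == "MNX_S2"

    def test_unrelated_candidates_flagged(self):
        recs = [MappingRecord("kegg.compound", "C1", "MNX_A"),
                MappingRecord("kegg.compound", "C1", "MNX_B")]
        out = resolve_ambiguity("x_c", recs)
        assert out.status == FLAGGED_UNRESOLVED
        assert out.chosen_canonical_id is None

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            resolve_ambiguity("x_c", [])


class TestMergeOnFixture:
    def test_planted_protonation_pair_collapses(self, fixture):
        merged, outcomes, audit = harmonise_model(
            fixture.model.copy(), fixture.chem_xref)
        expected = fixture.manifest["planted"]["protonation_merges"]
        merge_events = [list(a) for a in audit if a[1] != "cancelled"]
        assert sorted(merge_events) == \
            sorted([[b, a] for a, b in expected])  # survivor is smallest id
        for survivor, _gone in ((a, b) for a, b in expected):
            assert survivor in merged.species

    def test_flagged_species_exactly_as_planted(self, fixture):
        _, outcomes, _ = harmonise_model(fixture.model.copy(),
                                         fixture.chem_xref)
        flagged = sorted(o.species_id for o in outcomes
                         if o.status == FLAGGED_UNRESOLVED)
        assert flagged == fixture.manifest["planted"]["ambiguous_species"]

    def test_merge_preserves_reaction_count_gpr_and_bounds(self, fixture):
        original = fixture.model
        merged, _, _ = harmonise_model(original.copy(), fixture.chem_xref)
        assert set(merged.reactions) == set(original.reactions)
        for rid, rxn in original.reactions.items():
            out = merged.reactions[rid]
            assert out.gpr == rxn.gpr
            assert (out.lower_bound, out.upper_bound) == \
                (rxn.lower_bound, rxn.upper_bound)

    def test_idempotence(self, fixture):
        once, outcomes1, _ = harmonise_model(fixture.model.copy(),
                                             fixture.chem_xref)
        twice, outcomes2, audit2 = harmonise_model(once, fixture.chem_xref)
        assert audit2 == []
        assert set(twice.species) == set(once.species)
        # every surviving species keeps the canonical id it was given
        chosen1 = {o.species_id: o.chosen_canonical_id for o in outcomes1
                   if o.species_id in twice.species and o.chosen_canonical_id}
        chosen2 = {o.species_id: o.chosen_canonical_id for o in outcomes2
                   if o.chosen_canonical_id}
        for sid, canon in chosen1.items():
            assert chosen2.get(sid) == canon

    def test_different_compartments_never_merge(self):
        m = Model("t")
        m.add_compartment(Compartment("c"))
        m.add_compartment(Compartment("m"))
        for sid, comp in (("atp_c", "c"), ("atp_m", "m")):
            sp = Species(id=sid, compartment=comp)
            sp.add_xref("kegg.compound", "C00002")
            m.species[sid] = sp
        table = MappingTable([MappingRecord("kegg.compound", "C00002", "MNXM3")])
        merged, outcomes, audit = harmonise_model(m, table)
        assert audit == []
        assert set(merged.species) == {"atp_c", "atp_m"}
        assert all(o.chosen_canonical_id == "MNXM3" for o in outcomes)

    def test_exact_cancellation_is_audited(self):
        m = Model("t")
        m.add_compartment(Compartment("c"))
        for sid in ("a1_c", "a2_c", "z_c"):
            m.add_species(Species(id=sid, compartment="c"))
        m.species["a1_c"].add_xref("kegg.compound", "C1")
        m.species["a2_c"].add_xref("kegg.compound", "C2")
        from gemrefinery.model import Reaction
        m.add_reaction(Reaction("iso", stoichiometry={"a1_c": -1, "a2_c": 1}))
        m.add_reaction(Reaction("use", stoichiometry={"a1_c": -1, "z_c": 1}))
        table = MappingTable([MappingRecord("kegg.compound", "C1", "MNX_X"),
                              MappingRecord("kegg.compound", "C2", "MNX_X")])
        merged, audit = merge_species(m, [
            resolve_ambiguity("a1_c", match_exact(m.species["a1_c"], table)),
            resolve_ambiguity("a2_c", match_exact(m.species["a2_c"], table)),
        ])
        assert ("a2_c", "a1_c") in audit
        assert ("iso:a1_c", "cancelled") in audit
        assert merged.reactions["iso"].stoichiometry == {}
        assert merged.reactions["use"].stoichiometry == {"a1_c": -1, "z_c": 1}


def test_unmapped_species_reported(fixture):
    _, outcomes, _ = harmonise_model(fixture.model.copy(), fixture.chem_xref)
    unmapped = {o.species_id for o in outcomes if o.status == UNMAPPED}
    assert "leg1_c" in unmapped  # legacy species carry no usable xrefs
    assert all(o.status == UNMAPPED
               for o in outcomes if o.species_id.startswith("fx"))
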