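"""Metabolite identifier reconciliation against an MNXref-style mapping table.

Four stages: exact cross-reference matching, structure-supported matching
(InChIKey connectivity block, then formula+charge), a stoichiometric
consistency filter (a candidate whose formula would unbalance a previously
balanced reaction is rejected), and rule-based ambiguity resolution
(protonation variants collapse to the dominant form at physiological pH,
stereo/tautomer variants prefer the best-curated ChEBI-linked record,
anything else is retained and flagged).  Species that end up sharing a
canonical id within one compartment are merged; the same id in different
compartments never merges (cytosolic and mitochondrial pools stay distinct).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional

from .model import Model, Species

__all__ = [
    "MappingRecord", "MappingTable", "HarmonisationOutcome",
    "match_exact", "match_structure", "resolve_ambiguity",
    "merge_species", "harmonise_model", "HarmonisePolicy",
]

VARIANT_NONE = "NONE"
VARIANT_PROTONATION = "PROTONATION"
VARIANT_STEREO = "STEREO_TAUTOMER"

EXACT = "EXACT"
STRUCTURE = "STRUCTURE"
DISAMBIGUATED = "DISAMBIGUATED"
FLAGGED_UNRESOLVED = "FLAGGED_UNRESOLVED"
UNMAPPED = "UNMAPPED"


@dataclass
class MappingRecord:
    source_resource: str
    source_id: str
    canonical_id: str
    formula: Optional[dict[str, int]] = None
    charge: Optional[int] = None
    inchikey: Optional[str] = None
    chebi_id: Optional[str] = None
    variant_kind: str = VARIANT_NONE
    variant_group: Optional[str] = None
    dominant: bool = False
    curation_rank: int = 0

    def __post_init__(self) -> None:
        if not self.canonical_id:
            raise ValueError("mapping record requires a canonical id")
        if self.variant_kind != VARIANT_NONE and not self.variant_group:
            raise ValueError(
                f"{self.source_resource}:{self.source_id}: variant_kind "
                f"{self.variant_kind} requires a variant_group")


class MappingTable:
    """Cross-reference table in the style of the MNXref ``chem_xref`` TSV.

    Core columns are ``source`` (``resource:id``), ``ID`` (canonical MNX-style
    id), ``evidence`` and ``description``; the fixture dialect appends
    formula, charge, inchikey, chebi, variant kind/group, a dominant-form
    marker and a curation rank.  Real chem_xref files parse by leaving the
    extra columns absent.
    """

    def __init__(self, records: Optional[list[MappingRecord]] = None):
        self.records: list[MappingRecord] = list(records or [])
        self._by_source: dict[tuple[str, str], list[MappingRecord]] = {}
        self._by_inchikey14: dict[str, list[MappingRecord]] = {}
        for rec in self.records:
            self._index(rec)

    def _index(self, rec: MappingRecord) -> None:
        self._by_source.setdefault(
            (rec.source_resource.lower(), rec.source_id), []).append(rec)
        if rec.inchikey:
            self._by_inchikey14.setdefault(rec.inchikey[:14], []).append(rec)

    def add(self, rec: MappingRecord) -> None:
        self.records.append(rec)
        self._index(rec)

    def lookup_source(self, resource: str, identifier: str) -> list[MappingRecord]:
        return list(self._by_source.get((resource.lower(), identifier), []))

    def lookup_inchikey(self, inchikey: str) -> list[MappingRecord]:
        return list(self._by_inchikey14.get(inchikey[:14], []))

    def by_canonical(self, canonical_id: str) -> list[MappingRecord]:
        return [r for r in self.records if r.canonical_id == canonical_id]

    @classmethod
    def read_tsv(cls, path: str) -> "MappingTable":
        from .model import parse_formula
        table = cls()
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                source = row[0]
                if ":" in source:
                    resource, sid = source.split(":", 1)
                else:
                    resource, sid = "legacy", source
                def col(i: int) -> str:
                    return row[i].strip() if len(row) > i else ""
                formula = None
                if col(4):
                    try:
                        formula = parse_formula(col(4))
                    except ValueError:
                        formula = None
                table.add(MappingRecord(
                    source_resource=resource.lower(), source_id=sid,
                    canonical_id=col(1),
                    formula=formula,
                    charge=int(col(5)) if col(5) not in ("", "None") else None,
                    inchikey=col(6) or None,
                    chebi_id=col(7) or None,
                    variant_kind=col(8) or VARIANT_NONE,
                    variant_group=col(9) or None,
                    dominant=col(10).lower() in ("1", "true", "yes", "dominant"),
                    curation_rank=int(col(11)) if col(11) else 0,
                ))
        return table


@dataclass
class HarmonisationOutcome:
    species_id: str
    status: str
    chosen_canonical_id: Optional[str] = None
    candidates: list[MappingRecord] = field(default_factory=list)
    rule_applied: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status in (EXACT, STRUCTURE, DISAMBIGUATED) and \
                not self.chosen_canonical_id:
            raise ValueError(f"{self.species_id}: status {self.status} "
                             "requires a chosen canonical id")
        if self.status == FLAGGED_UNRESOLVED and len(self.candidates) < 2:
            raise ValueError(f"{self.species_id}: FLAGGED_UNRESOLVED "
                             "requires >=2 candidates")


@dataclass
class HarmonisePolicy:
    """Tunables for ambiguity resolution.  ``ph`` documents the reference pH
    at which dominant protonation forms were marked in the table; it is not
    used to compute pKa (dominant forms must be flagged as table input)."""

    ph: float = 7.3
    #: per variant-group override of the dominant member's canonical id
    dominant_protonation: dict[str, str] = field(default_factory=dict)


def match_exact(species: Species, table: MappingTable) -> list[MappingRecord]:
    """Records whose (resource, id) equals any xref of the species, ordered
    by curation rank (best first).  Empty when nothing matches."""
    hits: list[MappingRecord] = []
    seen: set[int] = set()
    for resource, ids in species.xrefs.items():
        if resource == "inchikey":
            continue
        for identifier in ids:
            for rec in table.lookup_source(resource, identifier):
                if id(rec) not in seen:
                    seen.add(id(rec))
                    hits.append(rec)
    hits.sort(key=lambda r: (r.curation_rank, r.canonical_id))
    return hits


def match_structure(species: Species, table: MappingTable) -> list[MappingRecord]:
    """Structure-supported matching: InChIKey connectivity block (first 14
    characters) preferred, formula+charge as fallback; InChIKey hits are
    ordered first."""
    inchikey = species.xref("inchikey")
    if inchikey is None and species.formula is None:
        raise ValueError(
            f"species {species.id}: structure matching requires an InChIKey "
            "or a formula")
    hits: list[MappingRecord] = []
    seen: set[int] = set()
    if inchikey:
        for rec in table.lookup_inchikey(inchikey):
            if id(rec) not in seen:
                seen.add(id(rec))
                hits.append(rec)
    if species.formula is not None:
        formula_hits = [
            rec for rec in table.records
            if rec.formula == species.formula
            and (rec.charge is None or species.charge is None
                 or rec.charge == species.charge)
        ]
        formula_hits.sort(key=lambda r: (r.curation_rank, r.canonical_id))
        for rec in formula_hits:
            if id(rec) not in seen:
                seen.add(id(rec))
                hits.append(rec)
    return hits


def resolve_ambiguity(species_id: str, candidates: list[MappingRecord],
                      policy: Optional[HarmonisePolicy] = None,
                      provenance: str = EXACT) -> HarmonisationOutcome:
    """Apply the conflict-resolution rules to a non-empty candidate list.

    Identical chemical species (one distinct canonical id) merge; a pure
    protonation variant group resolves to its dominant-at-physiological-pH
    member; stereo/tautomer groups resolve to the best-curated ChEBI-linked
    record; anything else is flagged and the original id retained.
    """
    if not candidates:
        raise ValueError("resolve_ambiguity requires >=1 candidate")
    policy = policy or HarmonisePolicy()

    distinct = sorted({rec.canonical_id for rec in candidates})
    if len(distinct) == 1:
        rule = None if len(candidates) == 1 else "identical-species"
        status = provenance if len(candidates) == 1 else DISAMBIGUATED
        return HarmonisationOutcome(species_id, status, distinct[0],
                                    candidates, rule)

    groups = {rec.variant_group for rec in candidates}
    kinds = {rec.variant_kind for rec in candidates}

    if kinds == {VARIANT_PROTONATION} and len(groups) == 1:
        group = next(iter(groups))
        override = policy.dominant_protonation.get(group)
        if override is not None:
            chosen = next((r for r in candidates if r.canonical_id == override),
                          None)
        else:
            chosen = next((r for r in candidates if r.dominant), None)
        if chosen is not None:
            return HarmonisationOutcome(
                species_id, DISAMBIGUATED, chosen.canonical_id, candidates,
                "dominant-protonation")
    elif kinds == {VARIANT_STEREO} and len(groups) == 1:
        linked = [r for r in candidates if r.chebi_id]
        if linked:
            linked.sort(key=lambda r: (r.curation_rank, r.chebi_id))
            return HarmonisationOutcome(
                species_id, DISAMBIGUATED, linked[0].canonical_id, candidates,
                "curated-stereo")

    return HarmonisationOutcome(species_id, FLAGGED_UNRESOLVED, None,
                                candidates, "retain-and-flag")


def _consistency_filter(model: Model, species: Species,
                        candidates: list[MappingRecord],
                        balanced_cache: dict[str, bool]) -> list[MappingRecord]:
    """Stage-3 stoichiometric consistency: drop a candidate if adopting its
    formula would unbalance a reaction that balances with the current
    species formula."""
    from .balance import check_balance, BALANCED

    if species.formula is None:
        return candidates
    kept: list[MappingRecord] = []
    for rec in candidates:
        if rec.formula is None or rec.formula == species.formula:
            kept.append(rec)
            continue
        ok = True
        for rxn in model.enabled_reactions():
            if species.id not in rxn.stoichiometry:
                continue
            if rxn.id not in balanced_cache:
                balanced_cache[rxn.id] = \
                    check_balance(rxn, model).status == BALANCED
            if not balanced_cache[rxn.id]:
                continue
            original = species.formula, species.charge
            species.formula = rec.formula
            if rec.charge is not None:
                species.charge = rec.charge
            try:
                still = check_balance(rxn, model).status == BALANCED
            finally:
                species.formula, species.charge = original
            if not still:
                ok = False
                break
        if ok:
            kept.append(rec)
    return kept or candidates


def harmonise_species(model: Model, table: MappingTable,
                      policy: Optional[HarmonisePolicy] = None
                      ) -> list[HarmonisationOutcome]:
    """Run the four matching stages for every species in the model."""
    policy = policy or HarmonisePolicy()
    outcomes: list[HarmonisationOutcome] = []
    balanced_cache: dict[str, bool] = {}
    for sp in model.species.values():
        candidates = match_exact(sp, table)
        provenance = EXACT
        if not candidates and (sp.xref("inchikey") or sp.formula is not None):
            candidates = match_structure(sp, table)
            provenance = STRUCTURE
        if not candidates:
            outcomes.append(HarmonisationOutcome(sp.id, UNMAPPED))
            continue
        candidates = _consistency_filter(model, sp, candidates, balanced_cache)
        outcomes.append(resolve_ambiguity(sp.id, candidates, policy, provenance))
    return outcomes


def merge_species(model: Model, outcomes: list[HarmonisationOutcome]
                  ) -> tuple[Model, list[tuple[str, str]]]:
    """Merge species that share a chosen canonical id within one compartment.

    The lexicographically smallest id survives; reactions are rewritten by
    id substitution only (coefficients untouched).  When substitution puts a
    species on both sides of one reaction the coefficients are summed; an
    exact cancellation drops the participant and is audited as
    ``(removed, survivor)`` like every merge.  Canonical ids are recorded
    as ``metanetx.chemical`` xrefs on every resolved species.
    """
    chosen = {o.species_id: o.chosen_canonical_id
              for o in outcomes if o.chosen_canonical_id}

    merged = model.copy()
    for sid, canon in chosen.items():
        if sid in merged.species:
            merged.species[sid].add_xref("metanetx.chemical", canon)

    groups: dict[tuple[str, str], list[str]] = {}
    for sid, canon in chosen.items():
        sp = merged.species[sid]
        groups.setdefault((canon, sp.compartment), []).append(sid)

    audit: list[tuple[str, str]] = []
    replacement: dict[str, str] = {}
    for (_canon, _comp), members in sorted(groups.items()):
        if len(members) < 2:
            continue
        members.sort()
        survivor = members[0]
        for gone in members[1:]:
            replacement[gone] = survivor
            audit.append((gone, survivor))
            for resource, ids in merged.species[gone].xrefs.items():
                for identifier in ids:
                    merged.species[survivor].add_xref(resource, identifier)

    if not replacement:
        return merged, audit

    for rxn in merged.reactions.values():
        if not any(sid in replacement for sid in rxn.stoichiometry):
            continue
        new_stoich: dict = {}
        for sid, coef in rxn.stoichiometry.items():
            target = replacement.get(sid, sid)
            new_stoich[target] = new_stoich.get(target, 0) + coef
        for sid in [s for s, c in new_stoich.items() if c == 0]:
            del new_stoich[sid]
            audit.append((f"{rxn.id}:{sid}", "cancelled"))
        rxn.stoichiometry = new_stoich

    for gone in replacement:
        del merged.species[gone]
    return merged, audit


def harmonise_model(model: Model, table: MappingTable,
                    policy: Optional[HarmonisePolicy] = None
                    ) -> tuple[Model, list[HarmonisationOutcome],
                               list[tuple[str, str]]]:
    """Full harmonisation pass: match, resolve, merge.

    Returns the harmonised model, the per-species outcomes, and the merge
    audit.  Coverage = species with a chosen canonical id / all species.
    """
    outcomes = harmonise_species(model, table, policy)
    merged, audit = merge_species(model, outcomes)
    return merged, outcomes, audit


def coverage(outcomes: list[HarmonisationOutcome]) -> float:
    """Fraction of species with a chosen canonical id."""
    if not outcomes:
        return 0.0
    return sum(1 for o in outcomes if o.chosen_canonical_id) / len(outcomes)
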