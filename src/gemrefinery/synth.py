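"""Deterministic miniature fixtures exercising every pipeline stage.

The generator emits a small, boundary-fed, mass-balanced central-carbon
network (glucose uptake, a lumped glycolysis, lactate fermentation,
pyruvate decarboxylation, optional electron transport chain) and then
plants known curation artefacts on top of it: an ATP-handling futile
triangle in the style of a Type-III loop, extra all-reversible triangles,
scaled exact-duplicate and reverse-duplicate reactions, reactions with a
bookkeeping species (H₂O, H⁺, Pi) deliberately omitted, ambiguous and
protonation-variant identifier mappings, and a small pathway hierarchy.
Every planted artefact is recorded in a ground-truth manifest so pipeline
stages can be scored for exact recovery.  Same seed → byte-identical
outputs.

Reverse/exact duplicate copies of reversible reactions necessarily create
artificial closed-system loops (that is precisely why deduplication runs
before thermodynamic refinement); the manifest's cycle list therefore
describes the post-deduplication model.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

from .harmonise import (
    VARIANT_NONE,
    VARIANT_PROTONATION,
    MappingRecord,
    MappingTable,
)
from .gpr import CURRENT, MERGED, OBSOLETE, GeneIdMap, GeneIdRecord
from .model import Compartment, GeneProduct, GprTree, Model, Reaction, Species
from . import sbml_io

__all__ = ["FixtureSpec", "Fixture", "build_fixture", "generate",
           "random_loop_fixture", "GenerationError"]

BOUND = 1000.0

SPECIES_FORMULAS: dict[str, tuple[dict[str, int], int]] = {
    "glc": ({"C": 6, "H": 12, "O": 6}, 0),
    "g6p": ({"C": 6, "H": 11, "O": 9, "P": 1}, -2),
    "f6p": ({"C": 6, "H": 11, "O": 9, "P": 1}, -2),
    "pyr": ({"C": 3, "H": 3, "O": 3}, -1),
    "lac": ({"C": 3, "H": 5, "O": 3}, -1),
    "acald": ({"C": 2, "H": 4, "O": 1}, 0),
    "atp": ({"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}, -4),
    "adp": ({"C": 10, "H": 12, "N": 5, "O": 10, "P": 2}, -3),
    "pi": ({"H": 1, "O": 4, "P": 1}, -2),
    "h": ({"H": 1}, 1),
    "h2o": ({"H": 2, "O": 1}, 0),
    "co2": ({"C": 1, "O": 2}, 0),
    "hco3": ({"C": 1, "H": 1, "O": 3}, -1),
    "nad": ({"C": 21, "H": 26, "N": 7, "O": 14, "P": 2}, -1),
    "nadh": ({"C": 21, "H": 27, "N": 7, "O": 14, "P": 2}, -2),
    "amp": ({"C": 10, "H": 12, "N": 5, "O": 7, "P": 1}, -2),
    "ppi": ({"H": 1, "O": 7, "P": 2}, -3),
}

#: kegg-style xrefs and canonical ids for the mapped background species
SPECIES_XREFS: dict[str, tuple[str, str]] = {
    "glc": ("C00031", "MNXM41"),
    "g6p": ("C00092", "MNXM160"),
    "f6p": ("C00085", "MNXM89621"),
    "pyr": ("C00022", "MNXM23"),
    "lac": ("C00186", "MNXM285"),
    "atp": ("C00002", "MNXM3"),
    "adp": ("C00008", "MNXM7"),
    "pi": ("C00009", "MNXM9"),
    "h": ("C00080", "MNXM1"),
    "h2o": ("C00001", "MNXM2"),
    "co2": ("C00011", "MNXM13"),
    "nad": ("C00003", "MNXM8"),
    "nadh": ("C00004", "MNXM10"),
}

_DUP_TARGETS = ("PGI", "LDH", "HEX1")
_REV_TARGETS = ("GLYC", "PDC", "T_PYR")
_MAX_CYCLES = 5
_MAX_PLANTED = 5

ROOT_PATHWAY = "R-HSA-1430728"
OXPHOS_LEAF = "R-HSA-163200"


class GenerationError(ValueError):
    """The requested planted counts are not realisable at fixture scale."""


@dataclass
class FixtureSpec:
    seed: int = 1
    futile_cycles: int = 1
    exact_duplicates: int = 1
    reverse_pairs: int = 1
    unbalanced_missing: tuple[str, ...] = ("h2o", "h", "pi")
    ambiguous_mappings: int = 1
    protonation_pairs: int = 1
    include_etc: bool = True
    hierarchy_depth: int = 3
    genes_per_reaction: tuple[int, int] = (1, 2)

    def validate(self) -> None:
        if self.seed < 0:
            raise GenerationError("seed must be non-negative")
        if self.futile_cycles > _MAX_CYCLES:
            raise GenerationError(f"at most {_MAX_CYCLES} futile cycles")
        if self.exact_duplicates > len(_DUP_TARGETS):
            raise GenerationError(
                f"at most {len(_DUP_TARGETS)} exact duplicates")
        if self.reverse_pairs > len(_REV_TARGETS):
            raise GenerationError(f"at most {len(_REV_TARGETS)} reverse pairs")
        if self.ambiguous_mappings > _MAX_PLANTED or \
                self.protonation_pairs > _MAX_PLANTED:
            raise GenerationError(f"at most {_MAX_PLANTED} mapping artefacts")
        bad = set(self.unbalanced_missing) - {"h2o", "h", "pi"}
        if bad:
            raise GenerationError(f"unknown unbalanced types: {sorted(bad)}")
        if self.hierarchy_depth < 2:
            raise GenerationError("hierarchy depth must be >=2")


@dataclass
class Fixture:
    model: Model
    chem_xref: MappingTable
    gene_idmap: GeneIdMap
    gene2path_rows: list[list[str]]
    relation_rows: list[list[str]]
    dg_table: dict[str, float]
    manifest: dict = field(default_factory=dict)


def _sp(model: Model, base: str, comp: str, artificial: bool = False) -> str:
    sid = f"{base}_{comp}"
    if sid in model.species:
        return sid
    formula, charge = SPECIES_FORMULAS.get(base, (None, None))
    sp = Species(id=sid, name=base, compartment=comp,
                 formula=dict(formula) if formula else None,
                 charge=charge, artificial=artificial)
    if base in SPECIES_XREFS:
        sp.add_xref("kegg.compound", SPECIES_XREFS[base][0])
    model.species[sid] = sp
    return sid


def _rxn(model: Model, rid: str, stoich: dict[str, int | Fraction],
         lb: float = -BOUND, ub: float = BOUND, gpr: GprTree | None = None,
         subsystem: str | None = None) -> Reaction:
    rxn = Reaction(id=rid, stoichiometry={k: Fraction(v) for k, v in stoich.items()},
                   lower_bound=lb, upper_bound=ub, gpr=gpr, subsystem=subsystem)
    model.add_reaction(rxn)
    return rxn


def _ensg(rng: random.Random) -> str:
    return f"ENSG{rng.randrange(10**10, 10**11)}"


def build_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Construct the fixture in memory (model, tables, manifest)."""
    spec = spec or FixtureSpec()
    spec.validate()
    rng = random.Random(spec.seed)

    model = Model("fixture", name="synthetic curation fixture")
    for cid, cname in (("c", "cytosol"), ("m", "mitochondrion"),
                       ("e", "extracellular")):
        model.add_compartment(Compartment(cid, cname))
    if spec.include_etc:
        model.add_compartment(Compartment("i", "intermembrane space"))

    genes = {}
    for gid in ("G_HK1", "G_GPI1", "G_GPI2", "G_LDHA", "G_LDHB", "G_PFK1",
                "G_PDC1", "G_LIG1", "G_OLDX", "G_ND1", "G_CYB", "G_COX1",
                "G_ATP5", "G_SLC25"):
        genes[gid] = model.add_gene_product(GeneProduct(gid))

    c, m, e = "c", "m", "e"
    for base in ("glc", "g6p", "f6p", "pyr", "lac", "atp", "adp", "pi",
                 "h", "h2o", "co2", "nad", "nadh"):
        _sp(model, base, c)
    for base in ("pyr", "h", "co2", "acald"):
        _sp(model, base, m)
    for base in ("glc", "lac", "co2"):
        _sp(model, base, e)

    leaf = GprTree.leaf
    # boundary-fed backbone (balanced wherever formulas exist)
    _rxn(model, "EX_GLC", {"glc_e": -1})
    _rxn(model, "EX_LAC", {"lac_e": -1})
    _rxn(model, "EX_CO2", {"co2_e": -1})
    _rxn(model, "T_GLC", {"glc_e": -1, "glc_c": 1}, lb=0)
    _rxn(model, "T_LAC", {"lac_c": -1, "lac_e": 1}, lb=0)
    _rxn(model, "T_PYR", {"pyr_c": -1, "pyr_m": 1})
    _rxn(model, "T_CO2", {"co2_m": -1, "co2_e": 1}, lb=0)
    _rxn(model, "HEX1",
         {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1},
         lb=0, gpr=leaf("G_HK1"))
    _rxn(model, "PGI", {"g6p_c": -1, "f6p_c": 1},
         gpr=GprTree.make(GprTree.OR, [leaf("G_GPI1"), leaf("G_GPI2")]))
    _rxn(model, "GLYC",
         {"glc_c": -1, "nad_c": -2, "adp_c": -2, "pi_c": -2,
          "pyr_c": 2, "nadh_c": 2, "h_c": 2, "atp_c": 2, "h2o_c": 2},
         lb=0, gpr=leaf("G_PFK1"))
    _rxn(model, "LDH",
         {"pyr_c": -1, "nadh_c": -1, "h_c": -1, "lac_c": 1, "nad_c": 1},
         gpr=GprTree.make(GprTree.OR, [leaf("G_LDHA"), leaf("G_LDHB")]))
    _rxn(model, "PDC", {"pyr_m": -1, "h_m": -1, "acald_m": 1, "co2_m": 1},
         lb=0, gpr=leaf("G_PDC1"))
    _rxn(model, "DM_ACALD", {"acald_m": -1}, lb=0)
    # ATP-dependent ligase (AMP + PPi signature); written reversible so the
    # irreversibility rule pass has something to constrain
    for base in ("amp", "ppi"):
        _sp(model, base, c)
    _sp(model, "sub1", c)
    _sp(model, "sub2", c)
    _rxn(model, "LIG1",
         {"atp_c": -1, "sub1_c": -1, "amp_c": 1, "ppi_c": 1, "sub2_c": 1},
         gpr=leaf("G_LIG1"))
    _rxn(model, "EX_SUB1", {"sub1_c": -1})
    _rxn(model, "DM_SUB2", {"sub2_c": -1}, lb=0)
    for rid, rhea in (("HEX1", "17825"), ("PGI", "11816"), ("LDH", "23444")):
        model.reactions[rid].add_xref("rhea", rhea)
        model.reactions[rid].add_xref("kegg.reaction", f"R{rhea}")
    # legacy KEGG-lineage reaction with an obsolete gene symbol
    _sp(model, "leg1", c)
    _sp(model, "leg2", c)
    _rxn(model, "R00001", {"leg1_c": -1, "leg2_c": 1}, lb=0,
         gpr=leaf("G_OLDX"))
    _rxn(model, "EX_LEG1", {"leg1_c": -1})
    _rxn(model, "DM_LEG2", {"leg2_c": -1}, lb=0)

    manifest: dict = {"seed": spec.seed, "planted": {}}

    # ---- futile cycles --------------------------------------------------
    cycles: list[list[str]] = []
    dg_table: dict[str, float] = {}
    if spec.futile_cycles >= 1:
        for base in ("fx", "fxp", "fy"):
            _sp(model, base, c)
        _sp(model, "fx", e)
        _rxn(model, "EX_FX", {"fx_e": -1})
        _rxn(model, "T_FX", {"fx_e": -1, "fx_c": 1}, lb=0)
        # the only feasible circulation runs FIG3_R1 backwards; constraining
        # it forward (ΔrG′° = −30) breaks the loop
        _rxn(model, "FIG3_R1",
             {"fx_c": -1, "atp_c": -1, "fxp_c": 1, "adp_c": 1})
        _rxn(model, "FIG3_R2", {"fy_c": -1, "fxp_c": 1}, lb=0)
        _rxn(model, "FIG3_R3",
             {"fx_c": -1, "atp_c": -1, "fy_c": 1, "adp_c": 1}, lb=0)
        cycles.append(["FIG3_R1", "FIG3_R2", "FIG3_R3"])
        dg_table["FIG3_R1"] = -30.0
    for k in range(2, spec.futile_cycles + 1):
        names = [f"u{k}{x}" for x in "abc"]
        for base in names:
            _sp(model, base, c)
        rids = [f"CYC{k}_{i}" for i in (1, 2, 3)]
        _rxn(model, rids[0], {f"{names[0]}_c": -1, f"{names[1]}_c": 1})
        _rxn(model, rids[1], {f"{names[1]}_c": -1, f"{names[2]}_c": 1})
        _rxn(model, rids[2], {f"{names[2]}_c": -1, f"{names[0]}_c": 1})
        cycles.append(rids)
        dg_table[rids[0]] = -25.0
    manifest["planted"]["futile_cycles"] = cycles

    # ---- exact duplicates (scaled copies, no GPR -> removable) ----------
    dup_groups: list[list[str]] = []
    for k in range(spec.exact_duplicates):
        target = model.reactions[_DUP_TARGETS[k]]
        dup_id = f"DUP{k + 1}"
        _rxn(model, dup_id,
             {sid: coef * 2 for sid, coef in target.stoichiometry.items()},
             lb=target.lower_bound, ub=target.upper_bound)
        dup_groups.append(sorted([target.id, dup_id]))
    manifest["planted"]["exact_duplicate_groups"] = sorted(dup_groups)

    # ---- reverse pairs --------------------------------------------------
    rev_pairs: list[list[str]] = []
    for k in range(spec.reverse_pairs):
        target = model.reactions[_REV_TARGETS[k]]
        rev_id = f"REV{k + 1}"
        _rxn(model, rev_id,
             {sid: -coef for sid, coef in target.stoichiometry.items()}, lb=0)
        rev_pairs.append(sorted([target.id, rev_id]))
    manifest["planted"]["reverse_pairs"] = sorted(rev_pairs)

    # ---- unbalanced reactions (bookkeeping species omitted) -------------
    unbalanced: dict[str, list[list]] = {}
    if "h2o" in spec.unbalanced_missing:
        # ATP hydrolysis with the water reactant left out
        _rxn(model, "UB_H2O",
             {"atp_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1}, lb=0)
        unbalanced["UB_H2O"] = [["h2o", "reactant", 1]]
    if "h" in spec.unbalanced_missing:
        _sp(model, "hco3", c)
        _rxn(model, "UB_H", {"co2_c": -1, "h2o_c": -1, "hco3_c": 1})
        _rxn(model, "T_CO2C", {"co2_m": -1, "co2_c": 1}, lb=0)
        unbalanced["UB_H"] = [["h", "product", 1]]
    if "pi" in spec.unbalanced_missing:
        _rxn(model, "UB_PI",
             {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "h_c": 1}, lb=0)
        unbalanced["UB_PI"] = [["pi", "product", 1]]
    manifest["planted"]["unbalanced"] = unbalanced

    # ---- mapping table --------------------------------------------------
    table = MappingTable()
    for base, (kegg, mnx) in SPECIES_XREFS.items():
        table.add(MappingRecord("kegg.compound", kegg, mnx))
        table.add(MappingRecord("metanetx.chemical", mnx, mnx))

    ambiguous: list[str] = []
    for k in range(1, spec.ambiguous_mappings + 1):
        sid = _sp(model, f"amb{k}", c)
        model.species[sid].add_xref("kegg.compound", f"CAMB{k:03d}")
        table.add(MappingRecord("kegg.compound", f"CAMB{k:03d}", f"MNXA{k}1"))
        table.add(MappingRecord("kegg.compound", f"CAMB{k:03d}", f"MNXA{k}2"))
        _rxn(model, f"DM_AMB{k}", {sid: -1}, lb=0)
        ambiguous.append(sid)
    manifest["planted"]["ambiguous_species"] = ambiguous

    proton_merges: list[list[str]] = []
    for k in range(1, spec.protonation_pairs + 1):
        a = _sp(model, f"pr{k}a", c)
        b = _sp(model, f"pr{k}b", c)
        w = _sp(model, f"wst{k}", c)
        model.species[a].charge = -1
        model.species[b].charge = 0
        model.species[a].add_xref("kegg.compound", f"CPRA{k:03d}")
        model.species[b].add_xref("kegg.compound", f"CPRB{k:03d}")
        group = f"pgrp{k}"
        # both source ids cross-reference both protomer entries; the charged
        # form is marked dominant at physiological pH
        for kegg in (f"CPRA{k:03d}", f"CPRB{k:03d}"):
            table.add(MappingRecord("kegg.compound", kegg, f"MNXP{k}A",
                                    charge=-1, variant_kind=VARIANT_PROTONATION,
                                    variant_group=group, dominant=True))
            table.add(MappingRecord("kegg.compound", kegg, f"MNXP{k}B",
                                    charge=0, variant_kind=VARIANT_PROTONATION,
                                    variant_group=group, dominant=False))
        for mnx, charge, dom in ((f"MNXP{k}A", -1, True),
                                 (f"MNXP{k}B", 0, False)):
            table.add(MappingRecord("metanetx.chemical", mnx, f"MNXP{k}A",
                                    charge=charge,
                                    variant_kind=VARIANT_PROTONATION,
                                    variant_group=group, dominant=dom))
        _rxn(model, f"PR{k}", {a: -1, b: -1, w: 1}, lb=0)
        _rxn(model, f"DM_WST{k}", {w: -1}, lb=0)
        proton_merges.append([min(a, b), max(a, b)])
    manifest["planted"]["protonation_merges"] = proton_merges

    # ---- electron transport chain --------------------------------------
    etc_ids = None
    if spec.include_etc:
        for base in ("nadh", "nad", "h", "h2o", "adp", "atp", "pi"):
            _sp(model, base, m)
        _sp(model, "h", "i")
        _sp(model, "pi", "i")
        for base in ("q", "qh2", "cytc_ox", "cytc_red", "o2"):
            _sp(model, base, m)
        _rxn(model, "ETC_CI",
             {"nadh_m": -1, "q_m": -1, "h_m": -5,
              "nad_m": 1, "qh2_m": 1, "h_i": 4},
             lb=0, gpr=leaf("G_ND1"), subsystem="oxphos")
        _rxn(model, "ETC_CIII",
             {"qh2_m": -1, "cytc_ox_m": -2, "h_m": -2,
              "q_m": 1, "cytc_red_m": 2, "h_i": 4},
             lb=0, gpr=leaf("G_CYB"), subsystem="oxphos")
        _rxn(model, "ETC_CIV",
             {"cytc_red_m": -2, "o2_m": Fraction(-1, 2), "h_m": -4,
              "cytc_ox_m": 2, "h2o_m": 1, "h_i": 2},
             lb=0, gpr=leaf("G_COX1"), subsystem="oxphos")
        # 3 H+ enter from the intermembrane space per ATP; one is consumed
        # by the condensation chemistry, two re-enter the matrix pool
        _rxn(model, "ETC_SYN",
             {"adp_m": -1, "pi_m": -1, "h_i": -3,
              "atp_m": 1, "h2o_m": 1, "h_m": 2},
             lb=0, gpr=leaf("G_ATP5"), subsystem="oxphos")
        _rxn(model, "ETC_PIT",
             {"pi_i": -1, "h_i": -1, "pi_m": 1, "h_m": 1},
             lb=0, gpr=leaf("G_SLC25"), subsystem="oxphos")
        etc_ids = {"complex_i": "ETC_CI", "complex_iii": "ETC_CIII",
                   "complex_iv": "ETC_CIV", "atp_synthase": "ETC_SYN",
                   "pi_transport": "ETC_PIT"}
    manifest["planted"]["etc_reactions"] = etc_ids

    # ---- gene id map and pathway tables ---------------------------------
    idmap = GeneIdMap()
    ensg_of: dict[str, str] = {}
    for gid in sorted(genes):
        if gid == "G_OLDX":
            idmap.records[gid] = GeneIdRecord(gid, hgnc=None, ensg=None,
                                              status=OBSOLETE)
            continue
        if gid == "G_GPI2":
            continue  # merged, handled below
        ensg = _ensg(rng)
        ensg_of[gid] = ensg
        idmap.records[gid] = GeneIdRecord(gid, hgnc=gid[2:], ensg=ensg,
                                          status=CURRENT)
    idmap.records["G_GPI2"] = GeneIdRecord(
        "G_GPI2", hgnc="GPI", ensg=None, status=MERGED,
        merged_into=ensg_of["G_GPI1"])
    manifest["planted"]["obsolete_genes"] = ["G_OLDX"]
    manifest["planted"]["merged_genes"] = {"G_GPI2": ensg_of["G_GPI1"]}

    chain = [ROOT_PATHWAY] + \
        [f"R-HSA-70{300 + i}" for i in range(1, spec.hierarchy_depth)]
    glyco_leaf = chain[-1]
    relation_rows = [[chain[i], chain[i + 1]] for i in range(len(chain) - 1)]
    relation_rows.append([ROOT_PATHWAY, OXPHOS_LEAF])
    # cross-species relation row: must not delete human leaves
    relation_rows.append(["R-MMU-999001", "R-MMU-999002"])

    gene2path_rows: list[list[str]] = []

    def gene_rows(gid: str, pathways: list[str]) -> None:
        for p in pathways:
            gene2path_rows.append([
                ensg_of[gid], p, f"https://reactome.org/content/detail/{p}",
                f"pathway {p}", "TAS", "Homo sapiens"])

    for gid in ("G_HK1", "G_GPI1", "G_PFK1", "G_LDHA", "G_PDC1"):
        gene_rows(gid, chain)  # all hierarchy levels, Reactome-style
    for gid in ("G_ND1", "G_CYB", "G_COX1", "G_ATP5"):
        if gid in ensg_of:
            gene_rows(gid, [ROOT_PATHWAY, OXPHOS_LEAF])
    # G_LDHB, G_SLC25, G_HK1's duplicates etc. stay unmapped; plus one
    # non-human row that the species filter must drop
    gene2path_rows.append(["ENSMUSG00000000001", "R-MMU-999002",
                           "https://reactome.org", "mouse pathway", "TAS",
                           "Mus musculus"])
    manifest["planted"]["true_leaves"] = sorted({glyco_leaf, OXPHOS_LEAF})
    manifest["planted"]["hierarchy_chain"] = chain
    manifest["planted"]["rule_reactions"] = {
        "ATP_LIGASE": ["LIG1"],
        "DECARBOXYLATION": ["PDC"],
        "OXPHOS_ETC": sorted(etc_ids.values()) if etc_ids else [],
    }

    model.check_integrity()
    return Fixture(model=model, chem_xref=table, gene_idmap=idmap,
                   gene2path_rows=gene2path_rows, relation_rows=relation_rows,
                   dg_table=dg_table, manifest=manifest)


# ---------------------------------------------------------------------------
# file output

def _write_chem_xref(table: MappingTable, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("#source\tID\tevidence\tdescription\tformula\tcharge"
                 "\tinchikey\tchebi\tvariant_kind\tvariant_group"
                 "\tdominant\tcuration_rank\n")
        for rec in table.records:
            from .model import format_formula
            fh.write("\t".join([
                f"{rec.source_resource}:{rec.source_id}", rec.canonical_id,
                "identity", "",
                format_formula(rec.formula) if rec.formula else "",
                "" if rec.charge is None else str(rec.charge),
                rec.inchikey or "", rec.chebi_id or "",
                rec.variant_kind if rec.variant_kind != VARIANT_NONE else "",
                rec.variant_group or "",
                "1" if rec.dominant else "",
                str(rec.curation_rank) if rec.curation_rank else "",
            ]) + "\n")


def generate(spec: FixtureSpec | None = None, outdir: str | Path = ".") -> dict:
    """Write the fixture files to ``outdir`` and return the manifest.

    Files: ``model.xml`` (SBML L3V2+FBC2), ``chem_xref.tsv``,
    ``gene_idmap.tsv``, ``gene2path.tsv``, ``relations.tsv``, ``dg.tsv``,
    ``manifest.json``.
    """
    fixture = build_fixture(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sbml_io.write_sbml(fixture.model, outdir / "model.xml")
    _write_chem_xref(fixture.chem_xref, outdir / "chem_xref.tsv")
    with open(outdir / "gene_idmap.tsv", "w") as fh:
        fh.write("#source_id\thgnc\tensg\tstatus\tmerged_into\n")
        for rec in sorted(fixture.gene_idmap.records.values(),
                          key=lambda r: r.source_id):
            fh.write("\t".join([rec.source_id, rec.hgnc or "", rec.ensg or "",
                                rec.status, rec.merged_into or ""]) + "\n")
    with open(outdir / "gene2path.tsv", "w") as fh:
        for row in fixture.gene2path_rows:
            fh.write("\t".join(row) + "\n")
    with open(outdir / "relations.tsv", "w") as fh:
        for row in fixture.relation_rows:
            fh.write("\t".join(row) + "\n")
    with open(outdir / "dg.tsv", "w") as fh:
        fh.write("#reaction_id\tdg0_kj_per_mol\n")
        for rid in sorted(fixture.dg_table):
            fh.write(f"{rid}\t{fixture.dg_table[rid]:g}\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(fixture.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return fixture.manifest


# ---------------------------------------------------------------------------
# random small networks for the loop-detection oracle

def random_loop_fixture(seed: int, n_species: int = 6,
                        n_reactions: int = 8) -> Model:
    """A random small internal network with mixed reversibilities and two
    boundary exchanges; used to cross-check loop detection against direct
    circulation enumeration."""
    if n_reactions > 10:
        raise GenerationError("oracle fixtures are capped at 10 reactions")
    rng = random.Random(seed)
    model = Model(f"random_{seed}")
    model.add_compartment(Compartment("c", "cytosol"))
    sids = [f"s{i}_c" for i in range(n_species)]
    for sid in sids:
        model.species[sid] = Species(id=sid, name=sid, compartment="c")

    model.add_reaction(Reaction("EX_IN", stoichiometry={sids[0]: Fraction(-1)},
                                lower_bound=-BOUND, upper_bound=BOUND))
    model.add_reaction(Reaction("EX_OUT", stoichiometry={sids[-1]: Fraction(-1)},
                                lower_bound=-BOUND, upper_bound=BOUND))
    for j in range(n_reactions - 2):
        n_sub = rng.choice((1, 2))
        n_prod = rng.choice((1, 2))
        participants = rng.sample(sids, min(n_sub + n_prod, n_species))
        stoich: dict[str, Fraction] = {}
        for idx, sid in enumerate(participants):
            coef = Fraction(rng.choice((1, 2)))
            stoich[sid] = -coef if idx < n_sub else coef
        if all(c < 0 for c in stoich.values()) or all(c > 0 for c in stoich.values()):
            first = participants[0]
            stoich[first] = -stoich[first]
        lb = -BOUND if rng.random() < 0.6 else 0.0
        model.add_reaction(Reaction(f"R{j}", stoichiometry=stoich,
                                    lower_bound=lb, upper_bound=BOUND))
    return model
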