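"""SBML Level 3 + FBC v2 reading, writing and structural validation.

Reading accepts Level 3 Version 1 or 2 documents (with or without the FBC
package); writing always emits Level 3 Version 2 with FBC v2, explicit flux
bound parameters for every reaction, and MIRIAM-style identifiers.org CV
terms for all cross-references.  Disabled reactions are retained with
lb = ub = 0 plus a traceability note rather than being deleted.

The structural validation report covers the four checks a curated release
must pass — structural validity, correct FBC syntax, unique identifiers,
no orphan references — plus the presence of finite flux bounds on every
reaction.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction

import libsbml

from .model import (
    Compartment,
    GeneProduct,
    GprTree,
    Model,
    Reaction,
    Species,
    format_formula,
    parse_formula,
)

__all__ = ["read_sbml", "write_sbml", "validate", "ValidationReport",
           "SbmlFormatError", "DEFAULT_BOUND"]

#: Finite stand-in for an unbounded flux (standard COBRA convention).
DEFAULT_BOUND = 1000.0

_SID_OK = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_URI_PATTERN = re.compile(r"identifiers\.org/([^/]+)/(.+)$")


class SbmlFormatError(ValueError):
    """Raised when a file cannot be parsed as SBML Level 3."""


def sanitize_sid(raw: str) -> str:
    """Replace non-SId characters with ``_`` (mapping tables contain ``:``
    and ``-``); prefix with ``_`` if the first character is a digit."""
    out = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not out or out[0].isdigit():
        out = "_" + out
    return out


# ---------------------------------------------------------------------------
# notes: small key/value store in the XHTML notes body (cobra-style "key: value")

def _write_notes(sbase: libsbml.SBase, notes: dict[str, str]) -> None:
    if not notes:
        return
    paragraphs = "".join(f"<p>{k}: {v}</p>" for k, v in notes.items())
    body = (f'<body xmlns="http://www.w3.org/1999/xhtml">{paragraphs}</body>')
    sbase.setNotes(body, True)


def _read_notes(sbase: libsbml.SBase) -> dict[str, str]:
    out: dict[str, str] = {}
    if not sbase.isSetNotes():
        return out
    text = sbase.getNotesString()
    for m in re.finditer(r"<p>([^<:]+):\s*([^<]*)</p>", text):
        out[m.group(1).strip()] = m.group(2).strip()
    return out


# ---------------------------------------------------------------------------
# CV terms

def _write_xrefs(sbase: libsbml.SBase, xrefs: dict[str, list[str]]) -> None:
    if not xrefs:
        return
    if not sbase.isSetMetaId():
        sbase.setMetaId("meta_" + sbase.getId())
    cv = libsbml.CVTerm()
    cv.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
    cv.setBiologicalQualifierType(libsbml.BQB_IS)
    for resource, ids in sorted(xrefs.items()):
        for identifier in ids:
            cv.addResource(f"https://identifiers.org/{resource}/{identifier}")
    sbase.addCVTerm(cv)


def _read_xrefs(sbase: libsbml.SBase) -> dict[str, list[str]]:
    xrefs: dict[str, list[str]] = {}
    for i in range(sbase.getNumCVTerms()):
        cv = sbase.getCVTerm(i)
        for j in range(cv.getNumResources()):
            uri = cv.getResourceURI(j)
            m = _URI_PATTERN.search(uri)
            if not m:
                continue
            resource, identifier = m.group(1), m.group(2)
            # collection-prefixed form: identifiers.org/CHEBI:1234
            if "/" not in identifier and ":" in resource:
                resource, identifier = resource.split(":", 1)[0].lower(), resource
            vals = xrefs.setdefault(resource, [])
            if identifier not in vals:
                vals.append(identifier)
    return xrefs


# ---------------------------------------------------------------------------
# GPR <-> fbc association

def _gpr_to_association(gpr: GprTree, parent) -> None:
    if gpr.kind == GprTree.GENE:
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(gpr.gene)
        return
    node = parent.createAnd() if gpr.kind == GprTree.AND else parent.createOr()
    for child in gpr.children:
        _association_child(node, child)


def _association_child(node, gpr: GprTree) -> None:
    if gpr.kind == GprTree.GENE:
        ref = node.createGeneProductRef()
        ref.setGeneProduct(gpr.gene)
    elif gpr.kind == GprTree.AND:
        sub = node.createAnd()
        for child in gpr.children:
            _association_child(sub, child)
    else:
        sub = node.createOr()
        for child in gpr.children:
            _association_child(sub, child)


def _association_to_gpr(assoc) -> GprTree:
    code = assoc.getTypeCode()
    if code == libsbml.SBML_FBC_GENEPRODUCTREF:
        return GprTree.leaf(assoc.getGeneProduct())
    kind = GprTree.AND if code == libsbml.SBML_FBC_AND else GprTree.OR
    children = [_association_to_gpr(assoc.getAssociation(i))
                for i in range(assoc.getNumAssociations())]
    return GprTree.make(kind, children)


# ---------------------------------------------------------------------------
# read

def read_sbml(path: str) -> Model:
    """Parse an SBML L3 (v1 or v2) file into a :class:`Model`.

    FBC gene products become :class:`GeneProduct` entries, the
    geneProductAssociation becomes a :class:`GprTree`, flux bound parameters
    become reaction bounds, and CV-term URIs become xrefs keyed by resource.
    Models without the FBC package get default bounds (−M, +M), or (0, +M)
    where ``reversible="false"``.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [doc.getError(i).getMessage()
                for i in range(doc.getNumErrors())
                if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR]
        raise SbmlFormatError(f"SBML parse failure for {path}: " + " | ".join(msgs))
    smodel = doc.getModel()
    if smodel is None or doc.getLevel() < 3:
        raise SbmlFormatError(f"{path} is not an SBML Level 3 document")

    model = Model(smodel.getId() or "model", name=smodel.getName() or "")

    for i in range(smodel.getNumCompartments()):
        c = smodel.getCompartment(i)
        model.add_compartment(Compartment(c.getId(), c.getName() or ""))

    for i in range(smodel.getNumSpecies()):
        s = smodel.getSpecies(i)
        notes = _read_notes(s)
        formula = None
        charge = None
        fbc_sp = s.getPlugin("fbc")
        if fbc_sp is not None:
            if fbc_sp.isSetChemicalFormula():
                try:
                    formula = parse_formula(fbc_sp.getChemicalFormula())
                except ValueError:
                    formula = None
            if fbc_sp.isSetCharge():
                charge = fbc_sp.getCharge()
        sp = Species(
            id=s.getId(), name=s.getName() or "", compartment=s.getCompartment(),
            formula=formula, charge=charge,
            artificial=notes.get("artificial", "").lower() == "true",
        )
        sp.xrefs = _read_xrefs(s)
        model.add_species(sp)

    fbc_model = smodel.getPlugin("fbc")
    if fbc_model is not None:
        for i in range(fbc_model.getNumGeneProducts()):
            gp = fbc_model.getGeneProduct(i)
            notes = _read_notes(gp)
            model.add_gene_product(GeneProduct(
                id=gp.getId(),
                hgnc=notes.get("hgnc") or (gp.getName() or None),
                ensg=gp.getLabel() or None,
            ))

    params = {smodel.getParameter(i).getId(): smodel.getParameter(i).getValue()
              for i in range(smodel.getNumParameters())}

    for i in range(smodel.getNumReactions()):
        r = smodel.getReaction(i)
        stoich: dict[str, Fraction] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            if ref.getSpecies() not in model.species:
                raise SbmlFormatError(
                    f"reaction {r.getId()}: orphan species reference "
                    f"{ref.getSpecies()!r}")
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) \
                - Fraction(repr(ref.getStoichiometry()))
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            if ref.getSpecies() not in model.species:
                raise SbmlFormatError(
                    f"reaction {r.getId()}: orphan species reference "
                    f"{ref.getSpecies()!r}")
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) \
                + Fraction(repr(ref.getStoichiometry()))

        fbc_r = r.getPlugin("fbc")
        lb = ub = None
        gpr = None
        if fbc_r is not None:
            if fbc_r.isSetLowerFluxBound():
                pid = fbc_r.getLowerFluxBound()
                if pid not in params:
                    raise SbmlFormatError(
                        f"reaction {r.getId()}: unresolvable bound parameter {pid!r}")
                lb = params[pid]
            if fbc_r.isSetUpperFluxBound():
                pid = fbc_r.getUpperFluxBound()
                if pid not in params:
                    raise SbmlFormatError(
                        f"reaction {r.getId()}: unresolvable bound parameter {pid!r}")
                ub = params[pid]
            if fbc_r.isSetGeneProductAssociation():
                gpr = _association_to_gpr(
                    fbc_r.getGeneProductAssociation().getAssociation())
        if lb is None:
            lb = -DEFAULT_BOUND if r.getReversible() else 0.0
        if ub is None:
            ub = DEFAULT_BOUND

        notes = _read_notes(r)
        rxn = Reaction(
            id=r.getId(), name=r.getName() or "", stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, gpr=gpr,
            enabled=notes.get("disabled", "").lower() != "true",
            dg0=float(notes["dg0"]) if "dg0" in notes else None,
            subsystem=notes.get("subsystem") or None,
        )
        rxn.xrefs = _read_xrefs(r)
        model.add_reaction(rxn)

    return model


# ---------------------------------------------------------------------------
# write

def write_sbml(model: Model, path: str) -> None:
    """Serialise to SBML L3V2 + FBC v2.

    Every reaction gets explicit lower/upper flux bound parameters; disabled
    reactions are written with lb = ub = 0 and a ``disabled: true`` note so
    deduplication remains traceable in the released file.  Refuses to write
    a model that fails the integrity check.
    """
    model.check_integrity()

    ns = libsbml.SBMLNamespaces(3, 2, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    smodel = doc.createModel()
    smodel.setId(sanitize_sid(model.id))
    if model.metadata.get("name"):
        smodel.setName(model.metadata["name"])
    fbc_model = smodel.getPlugin("fbc")
    fbc_model.setStrict(True)

    for comp in model.compartments.values():
        c = smodel.createCompartment()
        c.setId(sanitize_sid(comp.id))
        if comp.name:
            c.setName(comp.name)
        c.setConstant(True)
        c.setSize(1.0)

    for sp in model.species.values():
        s = smodel.createSpecies()
        s.setId(sanitize_sid(sp.id))
        s.setName(sp.name or sp.id)
        s.setCompartment(sanitize_sid(sp.compartment))
        s.setConstant(False)
        s.setBoundaryCondition(False)
        s.setHasOnlySubstanceUnits(False)
        fbc_sp = s.getPlugin("fbc")
        if sp.formula is not None:
            fbc_sp.setChemicalFormula(format_formula(sp.formula))
        if sp.charge is not None:
            fbc_sp.setCharge(sp.charge)
        notes = {}
        if sp.artificial:
            notes["artificial"] = "true"
        _write_notes(s, notes)
        _write_xrefs(s, sp.xrefs)

    for gp in model.gene_products.values():
        g = fbc_model.createGeneProduct()
        g.setId(sanitize_sid(gp.id))
        if gp.ensg:
            g.setLabel(gp.ensg)
        else:
            g.setLabel(gp.id)
        notes = {}
        if gp.hgnc:
            g.setName(gp.hgnc)
            notes["hgnc"] = gp.hgnc
        _write_notes(g, notes)

    # shared constant parameters per distinct bound value
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = smodel.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        r = smodel.createReaction()
        r.setId(sanitize_sid(rxn.id))
        if rxn.name:
            r.setName(rxn.name)
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if not rxn.enabled:
            lb = ub = 0.0
        r.setReversible(lb < 0)
        for sid in sorted(rxn.stoichiometry):
            coef = rxn.stoichiometry[sid]
            if coef < 0:
                ref = r.createReactant()
                ref.setStoichiometry(float(-coef))
            elif coef > 0:
                ref = r.createProduct()
                ref.setStoichiometry(float(coef))
            else:
                continue
            ref.setSpecies(sanitize_sid(sid))
            ref.setConstant(True)
        fbc_r = r.getPlugin("fbc")
        fbc_r.setLowerFluxBound(bound_param(lb))
        fbc_r.setUpperFluxBound(bound_param(ub))
        if rxn.gpr is not None:
            assoc = fbc_r.createGeneProductAssociation()
            _gpr_to_association(rxn.gpr, assoc)
        notes = {}
        if not rxn.enabled:
            notes["disabled"] = "true"
        if rxn.dg0 is not None:
            notes["dg0"] = repr(rxn.dg0)
        if rxn.subsystem:
            notes["subsystem"] = rxn.subsystem
        _write_notes(r, notes)
        _write_xrefs(r, rxn.xrefs)

    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# validation

@dataclass
class ValidationReport:
    """Outcome of the structural check set.

    ``structural_valid`` requires unique identifiers and no orphan
    references; ``fbc_valid`` requires well-formed GPRs referencing declared
    gene products and finite, ordered flux bounds on every reaction.
    """

    structural_valid: bool = True
    fbc_valid: bool = True
    duplicate_ids: list = field(default_factory=list)
    orphan_references: list = field(default_factory=list)
    reactions_without_bounds: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return self.structural_valid and self.fbc_valid and \
            not self.reactions_without_bounds

    def to_dict(self) -> dict:
        return {
            "structural_valid": self.structural_valid,
            "fbc_valid": self.fbc_valid,
            "duplicate_ids": list(self.duplicate_ids),
            "orphan_references": [list(t) for t in self.orphan_references],
            "reactions_without_bounds": list(self.reactions_without_bounds),
            "summary": dict(self.summary),
        }


def validate(model: Model) -> ValidationReport:
    """Run the release check set: unique identifiers across all SId
    namespaces, no orphan references, FBC syntax, and bound presence.
    Violations are report content, never exceptions."""
    report = ValidationReport()

    seen: dict[str, str] = {}
    for kind, collection in (("compartment", model.compartments),
                             ("species", model.species),
                             ("reaction", model.reactions),
                             ("gene_product", model.gene_products)):
        for sid in collection:
            if sid in seen:
                report.duplicate_ids.append(sid)
            else:
                seen[sid] = kind

    for sp in model.species.values():
        if sp.compartment not in model.compartments:
            report.orphan_references.append(("compartment", sp.compartment))
    for rxn in model.reactions.values():
        for sid in rxn.stoichiometry:
            if sid not in model.species:
                report.orphan_references.append(("species", sid))
        if rxn.gpr is not None:
            for gene in rxn.gpr.genes():
                if gene not in model.gene_products:
                    report.orphan_references.append(("gene", gene))
        bad_bounds = (
            rxn.lower_bound is None or rxn.upper_bound is None
            or not math.isfinite(rxn.lower_bound)
            or not math.isfinite(rxn.upper_bound)
            or rxn.lower_bound > rxn.upper_bound
        )
        if bad_bounds:
            report.reactions_without_bounds.append(rxn.id)

    report.structural_valid = not report.duplicate_ids and \
        not report.orphan_references
    gpr_orphans = [t for t in report.orphan_references if t[0] == "gene"]
    report.fbc_valid = not gpr_orphans and not report.reactions_without_bounds
    report.summary = {
        "compartments": len(model.compartments),
        "species": len(model.species),
        "reactions": len(model.reactions),
        "gene_products": len(model.gene_products),
        "duplicate_ids": len(report.duplicate_ids),
        "orphan_references": len(report.orphan_references),
        "reactions_without_bounds": len(report.reactions_without_bounds),
    }
    return report
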