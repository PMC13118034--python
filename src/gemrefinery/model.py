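"""In-memory representation of a constraint-based metabolic model.

The model is the hub every pipeline stage operates on.  It mirrors the SBML
Level 3 view of a reconstruction: a *species* is one metabolite-compartment
pair (cytosolic and mitochondrial ATP are two species), reactions carry a
signed stoichiometry map, flux bounds, an optional Boolean gene-protein-
reaction (GPR) tree, and cross-references into external databases.

Stoichiometric coefficients are stored as exact :class:`fractions.Fraction`
values so that canonicalisation (GCD reduction during duplicate detection)
is exact; conversion to floating point happens only at SBML write time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Optional

__all__ = [
    "EXCHANGE",
    "SINK_DEMAND",
    "TRANSPORT",
    "LEGACY",
    "ENZYMATIC",
    "REACTION_CLASSES",
    "Compartment",
    "Species",
    "GeneProduct",
    "GprTree",
    "Reaction",
    "Model",
    "ClassifierConfig",
    "classify_reaction",
    "classify_all",
    "stoichiometric_nonzeros",
    "parse_formula",
    "format_formula",
]

# Reaction classes, in detection precedence order.  The annotation-density
# denominators subtract classes in exactly this order (all reactions, minus
# exchange+sink, minus transport, minus legacy, enzymatic core).
EXCHANGE = "EXCHANGE"
SINK_DEMAND = "SINK_DEMAND"
TRANSPORT = "TRANSPORT"
LEGACY = "LEGACY"
ENZYMATIC = "ENZYMATIC"
REACTION_CLASSES = (EXCHANGE, SINK_DEMAND, TRANSPORT, LEGACY, ENZYMATIC)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style chemical formula ("C6H12O6") into element counts.

    Raises ``ValueError`` on anything that is not a plain element/count
    sequence; formulas with R-groups or ``*`` are deliberately rejected
    (they are uncheckable for balance purposes).
    """
    if not text:
        raise ValueError("empty formula")
    if "*" in text or re.search(r"R(?![a-z])", text):
        raise ValueError(f"formula {text!r} contains an R-group/wildcard")
    pos = 0
    counts: dict[str, int] = {}
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise ValueError(f"unparseable formula {text!r} at position {pos}")
        element = m.group(1)
        n = int(m.group(2)) if m.group(2) else 1
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Render element counts in Hill order (C, H, then alphabetical)."""
    order = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in order if counts[e])


@dataclass
class Compartment:
    id: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compartment id must be non-empty")


@dataclass
class Species:
    """One metabolite-compartment pair.

    ``xrefs`` maps a resource key (``metanetx.chemical``, ``chebi``,
    ``kegg.compound``, ``inchikey`` ...) to a list of identifiers.
    ``artificial`` marks sink/source pseudo-metabolites that are not real
    chemical entities.
    """

    id: str
    name: str = ""
    compartment: str = ""
    formula: Optional[dict[str, int]] = None
    charge: Optional[int] = None
    xrefs: dict[str, list[str]] = field(default_factory=dict)
    artificial: bool = False

    def xref(self, resource: str) -> Optional[str]:
        vals = self.xrefs.get(resource)
        return vals[0] if vals else None

    @property
    def canonical_id(self) -> Optional[str]:
        """The MNX-style canonical metabolite id, when mapped."""
        return self.xref("metanetx.chemical")

    def add_xref(self, resource: str, identifier: str) -> None:
        vals = self.xrefs.setdefault(resource, [])
        if identifier not in vals:
            vals.append(identifier)

    def is_proton(self) -> bool:
        return self.formula == {"H": 1} and (self.charge in (1, None))

    def is_water(self) -> bool:
        return self.formula == {"H": 2, "O": 1} and (self.charge in (0, None))


@dataclass
class GeneProduct:
    id: str
    hgnc: Optional[str] = None
    ensg: Optional[str] = None


class GprTree:
    """Boolean gene association: GENE leaf, or flat n-ary AND / OR node.

    AND nodes model multi-subunit complexes, OR nodes isozymes.  Non-leaf
    nodes always have at least two children; single-child nodes collapse to
    the child at construction.
    """

    GENE = "GENE"
    AND = "AND"
    OR = "OR"

    __slots__ = ("kind", "gene", "children")

    def __init__(self, kind: str, gene: Optional[str] = None,
                 children: Optional[Iterable["GprTree"]] = None):
        self.kind = kind
        self.gene = gene
        self.children: tuple[GprTree, ...] = tuple(children or ())
        if kind == self.GENE:
            if not gene:
                raise ValueError("GENE leaf requires a gene id")
        elif kind in (self.AND, self.OR):
            if len(self.children) < 2:
                raise ValueError(f"{kind} node requires >=2 children")
        else:
            raise ValueError(f"unknown GPR node kind {kind!r}")

    @classmethod
    def leaf(cls, gene: str) -> "GprTree":
        return cls(cls.GENE, gene=gene)

    @classmethod
    def make(cls, kind: str, children: list["GprTree"]) -> "GprTree":
        """Build an AND/OR node, flattening same-kind children and collapsing
        duplicate leaves; a single distinct child is returned as-is."""
        flat: list[GprTree] = []
        for child in children:
            if child.kind == kind:
                flat.extend(child.children)
            else:
                flat.append(child)
        seen: set[str] = set()
        unique: list[GprTree] = []
        for child in flat:
            key = child.render()
            if key not in seen:
                seen.add(key)
                unique.append(child)
        if len(unique) == 1:
            return unique[0]
        return cls(kind, children=unique)

    def genes(self) -> set[str]:
        if self.kind == self.GENE:
            return {self.gene}  # type: ignore[arg-type]
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def map_genes(self, mapping) -> "GprTree":
        """Rewrite every leaf through ``mapping(gene_id) -> gene_id``."""
        if self.kind == self.GENE:
            return GprTree.leaf(mapping(self.gene))
        return GprTree.make(self.kind, [c.map_genes(mapping) for c in self.children])

    def render(self) -> str:
        if self.kind == self.GENE:
            return self.gene  # type: ignore[return-value]
        op = " and " if self.kind == self.AND else " or "
        parts = []
        for child in self.children:
            text = child.render()
            if child.kind != self.GENE:
                text = f"({text})"
            parts.append(text)
        return op.join(parts)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GprTree):
            return NotImplemented
        if self.kind != other.kind or self.gene != other.gene:
            return False
        # children order-insensitive: AND/OR are commutative
        return sorted(c.render() for c in self.children) == \
            sorted(c.render() for c in other.children)

    def __hash__(self) -> int:
        if self.kind == self.GENE:
            return hash((self.kind, self.gene))
        return hash((self.kind, tuple(sorted(c.render() for c in self.children))))

    def __repr__(self) -> str:
        return f"GprTree({self.render()!r})"


@dataclass
class Reaction:
    """A reaction: signed rational stoichiometry (negative = consumed),
    flux bounds, optional GPR, cross-references and a class tag."""

    id: str
    name: str = ""
    stoichiometry: dict[str, Fraction] = field(default_factory=dict)
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: Optional[GprTree] = None
    xrefs: dict[str, list[str]] = field(default_factory=dict)
    rclass: Optional[str] = None
    enabled: bool = True
    dg0: Optional[float] = None
    subsystem: Optional[str] = None

    def __post_init__(self) -> None:
        self.stoichiometry = {
            sid: coef if isinstance(coef, Fraction) else Fraction(coef)
            for sid, coef in self.stoichiometry.items()
        }

    def add_xref(self, resource: str, identifier: str) -> None:
        vals = self.xrefs.setdefault(resource, [])
        if identifier not in vals:
            vals.append(identifier)

    @property
    def reactants(self) -> dict[str, Fraction]:
        return {s: -c for s, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {s: c for s, c in self.stoichiometry.items() if c > 0}

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def blocked(self) -> bool:
        return self.lower_bound == 0 and self.upper_bound == 0

    @property
    def irreversible(self) -> bool:
        """Flux confined to one sign (but not blocked)."""
        return (self.lower_bound >= 0 and self.upper_bound > 0) or \
            (self.upper_bound <= 0 and self.lower_bound < 0)

    def disable(self) -> None:
        self.enabled = False
        self.lower_bound = 0.0
        self.upper_bound = 0.0

    def copy(self) -> "Reaction":
        r = Reaction(
            id=self.id, name=self.name,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound, upper_bound=self.upper_bound,
            gpr=self.gpr, rclass=self.rclass, enabled=self.enabled,
            dg0=self.dg0, subsystem=self.subsystem,
        )
        r.xrefs = {k: list(v) for k, v in self.xrefs.items()}
        return r


class Model:
    """A metabolic reconstruction: compartments, species, reactions and
    gene products, with unique ids per collection and resolvable
    cross-references."""

    def __init__(self, id: str = "model", name: str = "", version: str = "",
                 notes: str = ""):
        self.id = id
        self.metadata = {"name": name, "version": version, "notes": notes}
        self.compartments: dict[str, Compartment] = {}
        self.species: dict[str, Species] = {}
        self.reactions: dict[str, Reaction] = {}
        self.gene_products: dict[str, GeneProduct] = {}

    # -- construction -----------------------------------------------------
    def add_compartment(self, comp: Compartment) -> Compartment:
        if comp.id in self.compartments:
            raise ValueError(f"duplicate compartment id {comp.id!r}")
        self.compartments[comp.id] = comp
        return comp

    def add_species(self, sp: Species) -> Species:
        if sp.id in self.species:
            raise ValueError(f"duplicate species id {sp.id!r}")
        if sp.compartment not in self.compartments:
            raise ValueError(
                f"species {sp.id!r} references unknown compartment {sp.compartment!r}")
        self.species[sp.id] = sp
        return sp

    def add_gene_product(self, gp: GeneProduct) -> GeneProduct:
        if gp.id in self.gene_products:
            raise ValueError(f"duplicate gene product id {gp.id!r}")
        self.gene_products[gp.id] = gp
        return gp

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        for sid in rxn.stoichiometry:
            if sid not in self.species:
                raise ValueError(
                    f"reaction {rxn.id!r} references unknown species {sid!r}")
        self.reactions[rxn.id] = rxn
        return rxn

    # -- views ------------------------------------------------------------
    def enabled_reactions(self) -> Iterator[Reaction]:
        return (r for r in self.reactions.values() if r.enabled)

    def species_compartments(self, rxn: Reaction) -> set[str]:
        return {self.species[sid].compartment for sid in rxn.stoichiometry}

    # -- integrity --------------------------------------------------------
    def integrity_errors(self) -> list[str]:
        """Dangling references and structural defects; empty when sound."""
        problems: list[str] = []
        for sp in self.species.values():
            if sp.compartment not in self.compartments:
                problems.append(f"species {sp.id}: unknown compartment {sp.compartment}")
            if sp.formula is not None and any(v < 0 for v in sp.formula.values()):
                problems.append(f"species {sp.id}: negative element count")
        for rxn in self.reactions.values():
            for sid in rxn.stoichiometry:
                if sid not in self.species:
                    problems.append(f"reaction {rxn.id}: unknown species {sid}")
            if rxn.lower_bound > rxn.upper_bound:
                problems.append(f"reaction {rxn.id}: lower bound above upper bound")
            if rxn.enabled and not rxn.stoichiometry:
                problems.append(f"reaction {rxn.id}: enabled with empty stoichiometry")
            if rxn.gpr is not None:
                for gene in rxn.gpr.genes():
                    if gene not in self.gene_products:
                        problems.append(
                            f"reaction {rxn.id}: GPR references unknown gene {gene}")
        return problems

    def check_integrity(self) -> None:
        problems = self.integrity_errors()
        if problems:
            raise ValueError("model integrity violated: " + "; ".join(problems))

    def copy(self) -> "Model":
        m = Model(self.id)
        m.metadata = dict(self.metadata)
        for comp in self.compartments.values():
            m.add_compartment(Compartment(comp.id, comp.name))
        for sp in self.species.values():
            clone = Species(
                id=sp.id, name=sp.name, compartment=sp.compartment,
                formula=dict(sp.formula) if sp.formula is not None else None,
                charge=sp.charge, artificial=sp.artificial,
            )
            clone.xrefs = {k: list(v) for k, v in sp.xrefs.items()}
            m.species[clone.id] = clone
        for gp in self.gene_products.values():
            m.gene_products[gp.id] = GeneProduct(gp.id, gp.hgnc, gp.ensg)
        for rxn in self.reactions.values():
            m.reactions[rxn.id] = rxn.copy()
        return m


@dataclass
class ClassifierConfig:
    """Prefix conventions used as fallbacks by the reaction classifier.

    Exchange reactions are detected structurally first (single participant);
    prefixes only catch conventionally named reactions whose structure is
    unusual.  Legacy ids default to the KEGG-lineage R*/RE* convention.
    """

    exchange_prefixes: tuple[str, ...] = ("EX_",)
    sink_prefixes: tuple[str, ...] = ("SK_", "DM_", "sink_", "demand_")
    legacy_pattern: str = r"^(R|RE)\d+"


def _canonical_entity(model: Model, sid: str) -> str:
    """Chemical identity of a species independent of compartment: the MNX
    canonical id when mapped, else the species id with a trailing
    ``_<compartment>`` suffix stripped."""
    sp = model.species[sid]
    canon = sp.canonical_id
    if canon:
        return canon
    suffix = "_" + sp.compartment
    if sp.id.endswith(suffix):
        return sp.id[: -len(suffix)]
    return sp.id


def classify_reaction(rxn: Reaction, model: Model,
                      config: Optional[ClassifierConfig] = None) -> str:
    """Assign one of the five reaction classes.

    Precedence: EXCHANGE > SINK_DEMAND > TRANSPORT > LEGACY > ENZYMATIC.
    A single-participant reaction is a boundary flux; it is SINK_DEMAND when
    named by a sink/demand prefix or when it is an irreversible drain
    (consumption-only), otherwise EXCHANGE.  TRANSPORT requires the same
    chemical entity on both sides in different compartments with no covalent
    transformation of any entity.
    """
    if rxn.id not in model.reactions:
        raise KeyError(f"reaction {rxn.id!r} not in model")
    cfg = config or ClassifierConfig()

    if any(rxn.id.startswith(p) for p in cfg.exchange_prefixes):
        return EXCHANGE
    sinkish_name = any(rxn.id.startswith(p) for p in cfg.sink_prefixes)
    if len(rxn.stoichiometry) == 1:
        (coef,) = rxn.stoichiometry.values()
        irreversible_drain = coef < 0 and rxn.lower_bound >= 0
        if sinkish_name or irreversible_drain:
            return SINK_DEMAND
        return EXCHANGE
    if sinkish_name:
        return SINK_DEMAND

    # transport: entity multiset conserved, >=1 entity changes compartment
    consumed: dict[str, Fraction] = {}
    produced: dict[str, Fraction] = {}
    moves_compartment = False
    for sid, coef in rxn.stoichiometry.items():
        entity = _canonical_entity(model, sid)
        side = consumed if coef < 0 else produced
        side[entity] = side.get(entity, Fraction(0)) + abs(coef)
    if consumed and consumed == produced:
        comps_in = {model.species[s].compartment
                    for s, c in rxn.stoichiometry.items() if c < 0}
        comps_out = {model.species[s].compartment
                     for s, c in rxn.stoichiometry.items() if c > 0}
        moves_compartment = comps_in != comps_out or len(comps_in | comps_out) > 1
        if moves_compartment:
            return TRANSPORT

    if re.match(cfg.legacy_pattern, rxn.id):
        return LEGACY
    return ENZYMATIC


def classify_all(model: Model, config: Optional[ClassifierConfig] = None) -> None:
    """Tag every enabled reaction with its class (in place)."""
    for rxn in model.enabled_reactions():
        rxn.rclass = classify_reaction(rxn, model, config)


def stoichiometric_nonzeros(model: Model) -> int:
    """Number of (species, enabled reaction) pairs with nonzero coefficient
    — the non-zero count of the stoichiometric matrix."""
    return sum(
        sum(1 for c in rxn.stoichiometry.values() if c != 0)
        for rxn in model.enabled_reactions()
    )
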