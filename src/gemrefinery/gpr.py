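"""Gene-protein-reaction rule parsing, standardisation and coverage.

The rule grammar is the usual Boolean GPR convention: ``and`` binds tighter
than ``or``, parentheses nest, operators are case-insensitive, and parsing
produces flat n-ary trees (AND = complex subunits, OR = isozymes).  Gene
identifiers are standardised to current Ensembl gene ids through a mapping
table that also resolves merged and obsolete symbols.  Coverage is reported
under the alternative denominators used to compare reconstructions: all
reactions, then successively excluding boundary, transport and legacy
classes down to the curated enzymatic core.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Optional

from .model import (
    EXCHANGE,
    LEGACY,
    SINK_DEMAND,
    TRANSPORT,
    GeneProduct,
    GprTree,
    Model,
)

__all__ = [
    "GprParseError", "parse_gpr", "GeneIdMap", "GeneIdRecord",
    "standardise_genes", "conservative_or_fallback",
    "coverage_denominators", "CoverageTable", "unique_ensg_count",
]

CURRENT = "CURRENT"
OBSOLETE = "OBSOLETE"
MERGED = "MERGED"


class GprParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: str) -> GprTree:
    """Parse ``expr := term (OR term)*; term := factor (AND factor)*;
    factor := GENE | '(' expr ')'``."""
    if not text or not text.strip():
        raise GprParseError("empty GPR rule", 0)
    tokens = _tokenize(text)
    index = 0

    def peek() -> Optional[str]:
        return tokens[index][0] if index < len(tokens) else None

    def expr() -> GprTree:
        nonlocal index
        terms = [term()]
        while peek() is not None and peek().lower() == "or":
            index += 1
            terms.append(term())
        return GprTree.make(GprTree.OR, terms) if len(terms) > 1 else terms[0]

    def term() -> GprTree:
        nonlocal index
        factors = [factor()]
        while peek() is not None and peek().lower() == "and":
            index += 1
            factors.append(factor())
        return GprTree.make(GprTree.AND, factors) if len(factors) > 1 else factors[0]

    def factor() -> GprTree:
        nonlocal index
        tok = peek()
        if tok is None:
            raise GprParseError("dangling operator", len(text))
        pos = tokens[index][1]
        if tok == "(":
            index += 1
            inner = expr()
            if peek() != ")":
                raise GprParseError("unbalanced parentheses", pos)
            index += 1
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {tok!r}", pos)
        index += 1
        return GprTree.leaf(tok)

    tree = expr()
    if index < len(tokens):
        raise GprParseError(f"unexpected token {tokens[index][0]!r}",
                            tokens[index][1])
    return tree


# ---------------------------------------------------------------------------
# gene identifier standardisation

@dataclass
class GeneIdRecord:
    source_id: str
    hgnc: Optional[str] = None
    ensg: Optional[str] = None
    status: str = CURRENT
    merged_into: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status == CURRENT and not (self.hgnc and self.ensg):
            raise ValueError(
                f"{self.source_id}: CURRENT records require hgnc and ensg")


class GeneIdMap:
    """source id → (HGNC symbol, ENSG id, status) lookup.

    TSV dialect: ``source_id<TAB>hgnc<TAB>ensg<TAB>status<TAB>merged_into``.
    """

    def __init__(self, records: Optional[list[GeneIdRecord]] = None):
        self.records: dict[str, GeneIdRecord] = {}
        for rec in records or []:
            self.records[rec.source_id] = rec

    @classmethod
    def read_tsv(cls, path: str) -> "GeneIdMap":
        idmap = cls()
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                def col(i: int) -> Optional[str]:
                    return row[i].strip() or None if len(row) > i else None
                idmap.records[row[0]] = GeneIdRecord(
                    source_id=row[0], hgnc=col(1), ensg=col(2),
                    status=col(3) or CURRENT, merged_into=col(4))
        return idmap

    def resolve(self, source_id: str) -> Optional[GeneIdRecord]:
        """Follow MERGED chains to the successor record."""
        rec = self.records.get(source_id)
        seen = {source_id}
        while rec is not None and rec.status == MERGED and rec.merged_into:
            successor = self.records.get(rec.merged_into)
            if successor is None:
                return GeneIdRecord(rec.merged_into, hgnc=rec.hgnc,
                                    ensg=rec.merged_into, status=CURRENT)
            if successor.source_id in seen:
                break
            seen.add(successor.source_id)
            rec = successor
        return rec


def standardise_genes(model: Model, idmap: GeneIdMap
                      ) -> tuple[Model, list[str]]:
    """Rewrite every GPR leaf to its current ENSG id.

    MERGED ids follow their successor; OBSOLETE ids without a successor keep
    their leaf and are reported as unmapped.  Gene products gain hgnc/ensg
    fields; duplicate leaves within one AND/OR collapse (handled by tree
    construction).  Tree shape is otherwise preserved.
    """
    out = model.copy()
    unmapped: set[str] = set()
    rename: dict[str, str] = {}

    for gid in list(out.gene_products):
        rec = idmap.resolve(gid)
        if rec is None or not rec.ensg:
            unmapped.add(gid)
            continue
        rename[gid] = rec.ensg
        gp = out.gene_products.pop(gid)
        if rec.ensg in out.gene_products:
            existing = out.gene_products[rec.ensg]
            existing.hgnc = existing.hgnc or rec.hgnc
        else:
            out.gene_products[rec.ensg] = GeneProduct(
                rec.ensg, hgnc=rec.hgnc, ensg=rec.ensg)

    for rxn in out.reactions.values():
        if rxn.gpr is not None:
            rxn.gpr = rxn.gpr.map_genes(lambda g: rename.get(g, g))
    return out, sorted(unmapped)


def conservative_or_fallback(genes: list[str]) -> GprTree:
    """OR-only association over unique genes — used where complex structure
    cannot be reconstructed without over-specifying subunit composition."""
    if not genes:
        raise ValueError("conservative fallback requires >=1 gene")
    unique = sorted(set(genes))
    if len(unique) == 1:
        return GprTree.leaf(unique[0])
    return GprTree.make(GprTree.OR, [GprTree.leaf(g) for g in unique])


# ---------------------------------------------------------------------------
# coverage

@dataclass
class CoverageTable:
    rows: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"rows": [dict(r) for r in self.rows]}


def coverage_denominators(model: Model) -> CoverageTable:
    """GPR coverage under the five standard denominators: all reactions,
    minus exchange+sink/demand, further minus transport, further minus
    legacy, and the enzymatic core only.  Only enabled reactions count, and
    a reaction is annotated when it carries a non-empty GPR."""
    from .reporting import round1

    enabled = [r for r in model.enabled_reactions()]
    for rxn in enabled:
        if rxn.rclass is None:
            raise ValueError(f"reaction {rxn.id} is unclassified; "
                             "run classify_all first")

    def row(label: str, classes_excluded: set[str]) -> dict:
        pool = [r for r in enabled if r.rclass not in classes_excluded]
        annotated = sum(1 for r in pool if r.gpr is not None)
        total = len(pool)
        pct = round1(100.0 * annotated / total) if total else 0.0
        return {"denominator": label, "annotated": annotated,
                "total": total, "percentage": pct}

    table = CoverageTable()
    table.rows.append(row("all reactions", set()))
    table.rows.append(row("excl. exchange + sink/demand",
                          {EXCHANGE, SINK_DEMAND}))
    table.rows.append(row("excl. exchange + sink + transport",
                          {EXCHANGE, SINK_DEMAND, TRANSPORT}))
    table.rows.append(row("excl. exchange + sink + transport + legacy",
                          {EXCHANGE, SINK_DEMAND, TRANSPORT, LEGACY}))
    enzymatic_only = {c for c in (EXCHANGE, SINK_DEMAND, TRANSPORT, LEGACY)}
    table.rows.append(row("enzymatic core only", enzymatic_only))
    # the last two rows coincide under an exclusive partition; both are kept
    # because released models may tag a curated core narrower than ENZYMATIC
    return table


def unique_ensg_count(model: Model) -> int:
    """Distinct ENSG-style leaves across all enabled reactions' GPRs."""
    genes: set[str] = set()
    for rxn in model.enabled_reactions():
        if rxn.gpr is not None:
            genes |= rxn.gpr.genes()
    return len(genes)
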