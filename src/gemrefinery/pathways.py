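"""Gene-level pathway annotation with hierarchical and leaf-only layers.

Genes are mapped to pathways through a Reactome-style all-levels export
(gene → every pathway containing it, at every hierarchy level) and a
parent → child relation table.  A *leaf* pathway is one that never occurs
as a parent; aggregating reactions over leaf events only avoids the
hierarchical double counting that the all-levels layer deliberately keeps.
Reactions inherit the union of their GPR genes' pathways; reactions without
a GPR stay unannotated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .model import ENZYMATIC, Model

__all__ = ["PathwayHierarchy", "PathwayAnnotation", "build_hierarchy",
           "annotate_reactions", "pathway_coverage"]


@dataclass
class PathwayHierarchy:
    gene_pathways: dict[str, set[str]] = field(default_factory=dict)
    pathway_names: dict[str, str] = field(default_factory=dict)
    relations: list[tuple[str, str]] = field(default_factory=list)
    leaves: set[str] = field(default_factory=set)
    skipped_rows: int = 0

    def pathways_of(self, gene: str) -> set[str]:
        return set(self.gene_pathways.get(gene, ()))


def build_hierarchy(gene_table: str, relation_table: str,
                    species_filter: str = "Homo sapiens") -> PathwayHierarchy:
    """Load the gene→pathway export and the parent→child relation.

    Gene-table dialect (Reactome all-levels layout): columns are gene id,
    pathway id, url, pathway name, evidence, species — only 1, 2, 4 and 6
    are consumed.  Relation rows are bare ``parent<TAB>child``.  Leaves are
    computed against parents that occur in the filtered species' records,
    so cross-species relation rows cannot delete leaves.  Malformed rows
    are skipped and counted.
    """
    h = PathwayHierarchy()
    with open(gene_table, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                h.skipped_rows += 1
                continue
            species = row[5].strip() if len(row) > 5 else species_filter
            if species != species_filter:
                continue
            gene, pathway = row[0].strip(), row[1].strip()
            h.gene_pathways.setdefault(gene, set()).add(pathway)
            if len(row) > 3 and row[3].strip():
                h.pathway_names[pathway] = row[3].strip()
    with open(relation_table, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                h.skipped_rows += 1
                continue
            h.relations.append((row[0].strip(), row[1].strip()))

    species_pathways = {p for paths in h.gene_pathways.values() for p in paths}
    parents = {parent for parent, _child in h.relations}
    h.leaves = species_pathways - (parents & species_pathways)
    return h


@dataclass
class PathwayAnnotation:
    reaction_id: str
    all_levels: set[str] = field(default_factory=set)
    leaf_only: set[str] = field(default_factory=set)


def annotate_reactions(model: Model, hierarchy: PathwayHierarchy
                       ) -> tuple[list[PathwayAnnotation], dict]:
    """Aggregate pathway ids from GPR genes onto reactions.

    ``all_levels`` is the union over all participating genes; ``leaf_only``
    keeps terminal events only.  Also reports gene mapping statistics:
    unique gene ids seen in GPRs, how many map to at least one pathway, and
    the mapping rate as a one-decimal percentage.
    """
    from .reporting import round1

    annotations: list[PathwayAnnotation] = []
    genes_seen: set[str] = set()
    genes_mapped: set[str] = set()
    for rxn in model.enabled_reactions():
        ann = PathwayAnnotation(rxn.id)
        if rxn.gpr is not None:
            for gene in rxn.gpr.genes():
                genes_seen.add(gene)
                paths = hierarchy.pathways_of(gene)
                if paths:
                    genes_mapped.add(gene)
                ann.all_levels |= paths
            ann.leaf_only = ann.all_levels & hierarchy.leaves
        annotations.append(ann)
    stats = {
        "unique_genes_in_gprs": len(genes_seen),
        "genes_mapped": len(genes_mapped),
        "mapping_rate_pct": round1(100.0 * len(genes_mapped) / len(genes_seen))
        if genes_seen else 0.0,
    }
    return annotations, stats


def pathway_coverage(model: Model, annotations: list[PathwayAnnotation]) -> dict:
    """Model-level pathway coverage summary.

    Percentages are of enabled reactions; GPR-relative coverage uses the
    GPR-bearing subset as denominator; the enzymatic-core line restricts to
    ENZYMATIC-class reactions.  Pathway-ID counts and reaction counts are
    reported as separate fields.
    """
    from .reporting import round1

    enabled = {r.id: r for r in model.enabled_reactions()}
    total = len(enabled)
    with_gpr = [rid for rid, r in enabled.items() if r.gpr is not None]
    by_id = {a.reaction_id: a for a in annotations}

    any_all = [rid for rid in enabled if by_id.get(rid) and by_id[rid].all_levels]
    any_leaf = [rid for rid in enabled if by_id.get(rid) and by_id[rid].leaf_only]
    leaf_of_gpr = [rid for rid in with_gpr
                   if by_id.get(rid) and by_id[rid].leaf_only]
    enzymatic = [rid for rid, r in enabled.items() if r.rclass == ENZYMATIC]
    enzymatic_annotated = [rid for rid in enzymatic
                           if by_id.get(rid) and by_id[rid].all_levels]

    def pct(n: int, d: int) -> float:
        return round1(100.0 * n / d) if d else 0.0

    return {
        "reactions_total": total,
        "reactions_with_any_pathway": len(any_all),
        "pct_with_any_pathway": pct(len(any_all), total),
        "reactions_with_leaf_pathway": len(any_leaf),
        "pct_with_leaf_pathway": pct(len(any_leaf), total),
        "pct_gpr_reactions_with_leaf": pct(len(leaf_of_gpr), len(with_gpr)),
        "unique_pathways_all_levels": len(
            set().union(*(a.all_levels for a in annotations)) if annotations else set()),
        "unique_pathways_leaf": len(
            set().union(*(a.leaf_only for a in annotations)) if annotations else set()),
        "pct_enzymatic_core_annotated": pct(len(enzymatic_annotated),
                                            len(enzymatic)),
    }
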