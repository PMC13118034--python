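"""End-to-end refinement pipeline.

Fixed stage order: harmonise → dedup → irreversibility rules → cycle
resolution → gene standardisation → pathway annotation → balance →
validation → density report.  The order is part of the contract: rule-based
directionality is applied before loop-driven tightening, and deduplication
precedes loop detection because redundant reverse pairs are themselves
artificial loops.  Each stage's audit is embedded in one consolidated
report; hard errors (GPR loss, unresolved cycles) abort the run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from . import balance as balance_mod
from . import dedup as dedup_mod
from . import gpr as gpr_mod
from . import harmonise as harm_mod
from . import pathways as path_mod
from . import reporting
from . import thermo as thermo_mod
from .model import Model, classify_all
from .sbml_io import validate

__all__ = ["PipelineConfig", "PipelineError", "refine", "read_dg_table"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Tunables for the full pipeline; every constant has the convention
    default (flux tolerance 1e-6, cap 1000, ΔrG′° irreversibility threshold
    −20 kJ/mol, harmonisation pH 7.3, thermodynamic context pH 7.4 / 310 K)."""

    chem_xref: Optional[str] = None
    gene_idmap: Optional[str] = None
    gene2path: Optional[str] = None
    relations: Optional[str] = None
    dg_table: Optional[str] = None
    balance_allowlist: tuple[str, ...] = ()
    balance_mode: str = "apply"
    species_filter: str = "Homo sapiens"
    strip_protons: bool = True
    flux_tol: float = thermo_mod.FLUX_TOL
    flux_cap: float = thermo_mod.FLUX_CAP
    max_iter: int = 50
    harmonise_ph: float = 7.3
    thermo_ph: float = thermo_mod.THERMO_PH
    thermo_temperature_k: float = thermo_mod.THERMO_TEMPERATURE_K
    seed: int = 0
    stages: tuple[str, ...] = ("harmonise", "dedup", "thermo", "gpr",
                               "pathways", "balance", "validate", "report")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown keys: {sorted(unknown)}")
        for key in ("balance_allowlist", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        for key in ("chem_xref", "gene_idmap", "gene2path", "relations",
                    "dg_table"):
            value = getattr(cfg, key)
            if value is not None and not Path(value).exists():
                raise PipelineError("config", f"{key} file not found: {value}")
        return cfg


def read_dg_table(path: str) -> dict[str, float]:
    """TSV ``reaction_id<TAB>dg0_kj_per_mol``."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rid, value = line.split("\t")[:2]
            table[rid] = float(value)
    return table


def refine(model: Model, config: PipelineConfig) -> tuple[Model, dict]:
    """Run the pipeline on an in-memory model; returns the refined model and
    the consolidated stage report."""
    report: dict = {"stages": {}}
    current = model

    classify_all(current)

    if "harmonise" in config.stages and config.chem_xref:
        table = harm_mod.MappingTable.read_tsv(config.chem_xref)
        policy = harm_mod.HarmonisePolicy(ph=config.harmonise_ph)
        current, outcomes, audit = harm_mod.harmonise_model(
            current, table, policy)
        classify_all(current)
        report["stages"]["harmonise"] = {
            "coverage": harm_mod.coverage(outcomes),
            "statuses": {
                status: sum(1 for o in outcomes if o.status == status)
                for status in sorted({o.status for o in outcomes})},
            "merges": [list(a) for a in audit],
        }

    if "dedup" in config.stages:
        try:
            current, dreport = dedup_mod.deduplicate(
                current, strip_protons=config.strip_protons)
        except dedup_mod.GprLossError as exc:
            raise PipelineError("dedup", str(exc)) from exc
        report["stages"]["dedup"] = dreport.to_dict()

    if "thermo" in config.stages:
        current, rule_changes = thermo_mod.apply_irreversibility_rules(current)
        dg = read_dg_table(config.dg_table) if config.dg_table else None
        try:
            current, cycle_reports = thermo_mod.resolve_loops(
                current, dg_table=dg, max_iter=config.max_iter,
                cap=config.flux_cap, tol=config.flux_tol)
        except thermo_mod.UnresolvedCyclesError as exc:
            raise PipelineError("thermo", str(exc)) from exc
        loopless, optimum = thermo_mod.verify_loopless(
            current, config.flux_cap, config.flux_tol)
        if not loopless:
            raise PipelineError("thermo", "loopless verification failed")
        report["stages"]["thermo"] = {
            "rule_changes": rule_changes,
            "iterations": [r.to_dict() for r in cycle_reports],
            "loopless": loopless,
            "final_lp_optimum": optimum,
        }

    if "gpr" in config.stages and config.gene_idmap:
        idmap = gpr_mod.GeneIdMap.read_tsv(config.gene_idmap)
        current, unmapped = gpr_mod.standardise_genes(current, idmap)
        report["stages"]["gpr"] = {
            "unmapped_genes": unmapped,
            "unique_gene_ids": gpr_mod.unique_ensg_count(current),
            "coverage": gpr_mod.coverage_denominators(current).to_dict(),
        }

    annotations = None
    if "pathways" in config.stages and config.gene2path and config.relations:
        hierarchy = path_mod.build_hierarchy(
            config.gene2path, config.relations, config.species_filter)
        annotations, stats = path_mod.annotate_reactions(current, hierarchy)
        report["stages"]["pathways"] = {
            "gene_mapping": stats,
            "coverage": path_mod.pathway_coverage(current, annotations),
        }

    if "balance" in config.stages:
        results = [balance_mod.check_balance(r, current)
                   for r in current.enabled_reactions()]
        current, audit = balance_mod.apply_repairs(
            current, results, mode=config.balance_mode,
            allowlist=set(config.balance_allowlist))
        report["stages"]["balance"] = {
            "statuses": {
                status: sum(1 for r in results if r.status == status)
                for status in sorted({r.status for r in results})},
            "repairs": audit,
        }

    if "thermo" in config.stages and "balance" in config.stages and \
            config.balance_mode == "apply":
        # bookkeeping repairs change stoichiometry and can, in principle,
        # re-open a circulation; the loopless certificate must hold on the
        # final model, so re-verify and re-resolve if needed
        loopless, _ = thermo_mod.verify_loopless(
            current, config.flux_cap, config.flux_tol)
        if not loopless:
            dg = read_dg_table(config.dg_table) if config.dg_table else None
            current, extra_reports = thermo_mod.resolve_loops(
                current, dg_table=dg, max_iter=config.max_iter,
                cap=config.flux_cap, tol=config.flux_tol)
            report["stages"]["thermo"]["iterations"].extend(
                r.to_dict() for r in extra_reports)

    if "validate" in config.stages:
        vreport = validate(current)
        report["stages"]["validate"] = vreport.to_dict()
        if not vreport.valid:
            raise PipelineError("validate", "final model failed validation")

    if "report" in config.stages:
        report["stages"]["report"] = reporting.density_report(
            current, annotations)

    current.check_integrity()
    return current, report
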