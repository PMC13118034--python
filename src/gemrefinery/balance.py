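"""Mass and charge balance validation with bookkeeping-species repair.

Every reaction's element and charge deltas (products − reactants) are
computed in exact integer/rational arithmetic.  Imbalances are searched for
a minimal combination of bookkeeping species — protons, water, phosphate,
pyrophosphate, CO₂, bicarbonate, ammonium — that zeroes all deltas; the
commonest curation error in legacy reconstructions is the omission of
exactly these species.  Proton/water repairs are safe to auto-apply;
anything that changes carbon, nitrogen or phosphorus bookkeeping is applied
only for explicitly allowlisted reactions, since mechanism preservation is
a judgement call.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

from .model import (
    EXCHANGE,
    SINK_DEMAND,
    Model,
    Reaction,
    Species,
    classify_reaction,
)

__all__ = [
    "BALANCED", "IMBALANCED", "UNCHECKABLE",
    "BookkeepingSpecies", "DEFAULT_POOL", "BalanceResult",
    "check_balance", "suggest_repair", "apply_repairs",
]

BALANCED = "BALANCED"
IMBALANCED = "IMBALANCED"
UNCHECKABLE = "UNCHECKABLE"

CHARGE_KEY = "charge"


@dataclass(frozen=True)
class BookkeepingSpecies:
    name: str
    formula: tuple[tuple[str, int], ...]
    charge: int
    auto_apply: bool  # proton/water corrections are mechanism-neutral

    def composition(self) -> dict[str, int]:
        comp = dict(self.formula)
        comp[CHARGE_KEY] = self.charge
        return comp


#: Default pool, in tie-break order.  Pi is modelled as HPO4²⁻ and PPi as
#: HP2O7³⁻ (dominant cytosolic microspecies at physiological pH).
DEFAULT_POOL: tuple[BookkeepingSpecies, ...] = (
    BookkeepingSpecies("h", (("H", 1),), 1, True),
    BookkeepingSpecies("h2o", (("H", 2), ("O", 1)), 0, True),
    BookkeepingSpecies("pi", (("H", 1), ("O", 4), ("P", 1)), -2, False),
    BookkeepingSpecies("ppi", (("H", 1), ("O", 7), ("P", 2)), -3, False),
    BookkeepingSpecies("co2", (("C", 1), ("O", 2)), 0, False),
    BookkeepingSpecies("hco3", (("C", 1), ("H", 1), ("O", 3)), -1, False),
    BookkeepingSpecies("nh4", (("H", 4), ("N", 1)), 1, False),
)


@dataclass
class BalanceResult:
    reaction_id: str
    status: str
    element_delta: dict[str, Fraction] = field(default_factory=dict)
    charge_delta: Fraction = Fraction(0)
    repair: Optional[list[tuple[str, str, int]]] = None  # (species, side, count)

    def to_dict(self) -> dict:
        return {
            "reaction_id": self.reaction_id,
            "status": self.status,
            "element_delta": {k: float(v) for k, v in self.element_delta.items()},
            "charge_delta": float(self.charge_delta),
            "repair": [list(r) for r in self.repair] if self.repair else None,
        }


def check_balance(rxn: Reaction, model: Model) -> BalanceResult:
    """Net element and charge deltas (products − reactants).

    Boundary reactions (single-sided by construction) and reactions with a
    formula-less participant are UNCHECKABLE; a missing charge alone leaves
    elements checkable but makes the charge row uncheckable, which is
    treated conservatively as UNCHECKABLE too.
    """
    rclass = rxn.rclass or classify_reaction(rxn, model)
    if rclass in (EXCHANGE, SINK_DEMAND) or len(rxn.stoichiometry) < 2:
        return BalanceResult(rxn.id, UNCHECKABLE)

    deltas: dict[str, Fraction] = {}
    charge = Fraction(0)
    for sid, coef in rxn.stoichiometry.items():
        sp = model.species[sid]
        if sp.formula is None or sp.charge is None:
            return BalanceResult(rxn.id, UNCHECKABLE)
        for element, count in sp.formula.items():
            deltas[element] = deltas.get(element, Fraction(0)) + coef * count
        charge += coef * sp.charge
    deltas = {e: d for e, d in deltas.items() if d != 0}
    status = BALANCED if not deltas and charge == 0 else IMBALANCED
    return BalanceResult(rxn.id, status, deltas, charge)


def _delta_vector(result: BalanceResult) -> dict[str, Fraction]:
    vec = dict(result.element_delta)
    vec[CHARGE_KEY] = result.charge_delta
    return {k: v for k, v in vec.items() if v != 0}


def suggest_repair(result: BalanceResult,
                   pool: tuple[BookkeepingSpecies, ...] = DEFAULT_POOL,
                   budget: int = 4) -> Optional[list[tuple[str, str, int]]]:
    """Smallest pool combination that zeroes every delta.

    Exhaustive search over signed pool counts with total added stoichiometry
    ≤ ``budget``; "reactant" additions subtract their composition from the
    delta, "product" additions add it.  Minimal total count wins, ties break
    by pool order.  ``None`` when no combination balances the reaction.
    """
    if result.status != IMBALANCED:
        raise ValueError(f"{result.reaction_id}: repair requires IMBALANCED")
    target = _delta_vector(result)
    if any(v.denominator != 1 for v in target.values()):
        return None  # fractional imbalance cannot be fixed by integer additions

    # option k-th pool species on reactant (-1) or product (+1) side
    options = [(i, side) for i in range(len(pool)) for side in (-1, +1)]
    for total in range(1, budget + 1):
        for combo in itertools.combinations_with_replacement(options, total):
            remaining = {k: int(v) for k, v in target.items()}
            for i, side in combo:
                for key, count in pool[i].composition().items():
                    remaining[key] = remaining.get(key, 0) + side * count
            if all(v == 0 for v in remaining.values()):
                counts: dict[tuple[int, int], int] = {}
                for i, side in combo:
                    counts[(i, side)] = counts.get((i, side), 0) + 1
                return [
                    (pool[i].name, "product" if side > 0 else "reactant", n)
                    for (i, side), n in sorted(counts.items())
                ]
    return None


def _pool_species_id(model: Model, name: str, compartment: str,
                     pool: tuple[BookkeepingSpecies, ...]) -> str:
    """Locate (or create) the pool species instance in a compartment."""
    candidate = f"{name}_{compartment}"
    if candidate in model.species:
        return candidate
    spec = next(b for b in pool if b.name == name)
    model.add_species(Species(
        id=candidate, name=name, compartment=compartment,
        formula=dict(spec.formula), charge=spec.charge))
    return candidate


def _majority_compartment(model: Model, rxn: Reaction) -> str:
    counts: dict[str, int] = {}
    for sid in rxn.stoichiometry:
        comp = model.species[sid].compartment
        counts[comp] = counts.get(comp, 0) + 1
    best = max(counts.values())
    return sorted(c for c, n in counts.items() if n == best)[0]


def apply_repairs(model: Model, results: list[BalanceResult],
                  mode: str = "suggest",
                  allowlist: Optional[set[str]] = None,
                  pool: tuple[BookkeepingSpecies, ...] = DEFAULT_POOL,
                  budget: int = 4) -> tuple[Model, list[dict]]:
    """Compute repairs for imbalanced reactions; in ``apply`` mode, install
    the safe ones.

    Proton/water-only repairs are auto-applied; repairs touching other pool
    species need the reaction on the allowlist (mechanism preservation is a
    human judgement).  The added instance lives in the majority compartment
    of the reaction's participants (ties: lexicographically smallest).
    Every applied repair is re-checked; a post-repair imbalance is an
    internal error.
    """
    if mode not in ("suggest", "apply"):
        raise ValueError(f"unknown mode {mode!r}")
    allowlist = allowlist or set()
    out = model.copy() if mode == "apply" else model
    audit: list[dict] = []
    auto_names = {b.name for b in pool if b.auto_apply}

    for result in results:
        if result.status != IMBALANCED:
            continue
        repair = suggest_repair(result, pool, budget)
        result.repair = repair
        entry = {"reaction": result.reaction_id, "repair": repair,
                 "applied": False, "note": None}
        if repair is None:
            entry["note"] = "no pool combination balances this reaction"
            audit.append(entry)
            continue
        needs_review = any(name not in auto_names for name, _s, _n in repair)
        if mode != "apply":
            entry["note"] = "suggest mode"
            audit.append(entry)
            continue
        if needs_review and result.reaction_id not in allowlist:
            entry["note"] = "needs manual review (non-proton/water species)"
            audit.append(entry)
            continue

        rxn = out.reactions[result.reaction_id]
        comp = _majority_compartment(out, rxn)
        for name, side, count in repair:
            sid = _pool_species_id(out, name, comp, pool)
            sign = 1 if side == "product" else -1
            rxn.stoichiometry[sid] = rxn.stoichiometry.get(sid, Fraction(0)) \
                + sign * count
            if rxn.stoichiometry[sid] == 0:
                del rxn.stoichiometry[sid]
        recheck = check_balance(rxn, out)
        if recheck.status != BALANCED:
            raise RuntimeError(
                f"{rxn.id}: still {recheck.status} after applying repair")
        entry["applied"] = True
        audit.append(entry)
    return out, audit
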