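"""Duplicate and reverse-duplicate reaction detection and consolidation.

Reactions are keyed by a canonical stoichiometric signature: participants
sorted lexicographically, coefficients reduced to the smallest coprime
integer vector, and an orientation sign normalised so the smallest
participant is consumed.  Scaled copies collapse to one key; a reaction and
its exact reverse share participants but carry opposite orientation.
Detection is compartment-scoped by construction (species ids are
compartment-specific), so the same transformation in two compartments never
groups.  Proton-only differences are ignored when requested, except for
proton-translocating reactions where the proton gradient is the chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd

from .model import Model, Reaction

__all__ = ["CanonicalKey", "DedupReport", "canonical_key",
           "find_duplicates", "consolidate", "GprLossError"]


class GprLossError(RuntimeError):
    """Consolidation would silently drop the sole carrier of a GPR tree."""


@dataclass(frozen=True)
class CanonicalKey:
    """Direction-signed normalised stoichiometric signature.

    ``participants`` is orientation-normalised: the lexicographically
    smallest participant always carries a negative (consumed) integer
    coefficient.  ``orientation`` is +1 when the reaction as written already
    had that form and −1 when the signs were flipped, so an exact reverse
    pair shares ``participants`` with opposite ``orientation``.
    """

    participants: tuple[tuple[str, int], ...]
    orientation: int
    compartment_signature: tuple[str, ...]

    @property
    def group_key(self) -> tuple:
        return self.participants


def _normalised_integers(stoich: dict[str, Fraction]) -> dict[str, int]:
    denom_lcm = 1
    for coef in stoich.values():
        denom_lcm = denom_lcm * coef.denominator // gcd(denom_lcm, coef.denominator)
    ints = {sid: int(coef * denom_lcm) for sid, coef in stoich.items()}
    g = 0
    for v in ints.values():
        g = gcd(g, abs(v))
    if g > 1:
        ints = {sid: v // g for sid, v in ints.items()}
    return ints


def canonical_key(rxn: Reaction, model: Model,
                  strip_protons: bool = True) -> CanonicalKey:
    """Canonical signature of a reaction.

    Protons are removed before keying when ``strip_protons`` unless the
    reaction moves protons across compartments (proton pumps keep them:
    the translocation is biologically compartment-specific).  A reaction
    whose stoichiometry is empty after stripping is degenerate.
    """
    if not rxn.stoichiometry:
        raise ValueError(f"reaction {rxn.id}: empty stoichiometry")

    stoich = {sid: coef for sid, coef in rxn.stoichiometry.items() if coef != 0}
    if strip_protons:
        protons = [sid for sid in stoich if model.species[sid].is_proton()]
        proton_comps = {model.species[sid].compartment for sid in protons}
        if protons and len(proton_comps) <= 1:
            for sid in protons:
                del stoich[sid]
    if not stoich:
        raise ValueError(
            f"reaction {rxn.id}: degenerate (all-zero) stoichiometry after "
            "proton stripping")

    ints = _normalised_integers(stoich)
    smallest = min(ints)
    orientation = 1
    if ints[smallest] > 0:
        ints = {sid: -v for sid, v in ints.items()}
        orientation = -1
    participants = tuple(sorted(ints.items()))
    comps = tuple(sorted(model.species[sid].compartment for sid in ints))
    return CanonicalKey(participants, orientation, comps)


@dataclass
class DedupReport:
    exact_duplicate_groups: list[list[str]] = field(default_factory=list)
    reverse_pairs: list[tuple[str, str]] = field(default_factory=list)
    removed_ids: list[str] = field(default_factory=list)
    disabled_ids: list[str] = field(default_factory=list)
    gpr_preservation_check: bool = True

    def to_dict(self) -> dict:
        return {
            "exact_duplicate_groups": [list(g) for g in self.exact_duplicate_groups],
            "reverse_pairs": [list(p) for p in self.reverse_pairs],
            "removed_ids": list(self.removed_ids),
            "disabled_ids": list(self.disabled_ids),
            "gpr_preservation_check": self.gpr_preservation_check,
        }


def find_duplicates(model: Model, strip_protons: bool = True) -> DedupReport:
    """Group enabled reactions by canonical key (detection only).

    Same key and orientation → exact duplicates; same participants with
    opposite orientation → reverse pair (one representative per side).
    """
    report = DedupReport()
    by_participants: dict[tuple, dict[int, list[str]]] = {}
    for rxn in model.enabled_reactions():
        key = canonical_key(rxn, model, strip_protons)
        by_participants.setdefault(key.group_key, {}) \
            .setdefault(key.orientation, []).append(rxn.id)

    for sides in by_participants.values():
        for orientation in sorted(sides):
            ids = sorted(sides[orientation])
            if len(ids) > 1:
                report.exact_duplicate_groups.append(ids)
        if len(sides) == 2:
            fwd = sorted(sides[1])[0]
            rev = sorted(sides[-1])[0]
            report.reverse_pairs.append(tuple(sorted((fwd, rev))))
    report.exact_duplicate_groups.sort()
    report.reverse_pairs.sort()
    return report


def _pick_survivor(ids: list[str], model: Model) -> str:
    """GPR-bearing reactions win; ties break lexicographically."""
    with_gpr = sorted(i for i in ids if model.reactions[i].gpr is not None)
    return with_gpr[0] if with_gpr else sorted(ids)[0]


def consolidate(model: Model, report: DedupReport) -> tuple[Model, DedupReport]:
    """Apply a detection report: remove or disable redundant copies and fold
    reverse pairs into single reversible reactions.

    Within an exact-duplicate group, the GPR-carrying (else smallest-id)
    reaction survives; the others are removed when their GPR is identical or
    absent, otherwise disabled for traceability.  A reverse pair with
    compatible GPRs becomes one reversible reaction with unioned bounds
    (lb = min(lb1, −ub2), ub = max(ub1, −lb2)); with conflicting GPRs the
    non-surviving member is disabled instead.  The gene-product collection
    is never touched.
    """
    out = model.copy()
    result = DedupReport(
        exact_duplicate_groups=[list(g) for g in report.exact_duplicate_groups],
        reverse_pairs=[tuple(p) for p in report.reverse_pairs],
    )
    genes_before = set(out.gene_products)

    survivor_of: dict[str, str] = {}
    for group in report.exact_duplicate_groups:
        survivor = _pick_survivor(list(group), out)
        keeper = out.reactions[survivor]
        for rid in group:
            if rid == survivor:
                continue
            survivor_of[rid] = survivor
            doomed = out.reactions[rid]
            if doomed.gpr is None or doomed.gpr == keeper.gpr:
                if doomed.gpr is not None and keeper.gpr is None:
                    raise GprLossError(
                        f"would remove sole GPR carrier {rid}")
                # widen survivor bounds to cover the removed copy
                keeper.lower_bound = min(keeper.lower_bound, doomed.lower_bound)
                keeper.upper_bound = max(keeper.upper_bound, doomed.upper_bound)
                del out.reactions[rid]
                result.removed_ids.append(rid)
            else:
                doomed.disable()
                result.disabled_ids.append(rid)

    for pair in report.reverse_pairs:
        a_id, b_id = pair
        a_id = survivor_of.get(a_id, a_id)
        b_id = survivor_of.get(b_id, b_id)
        if a_id not in out.reactions or b_id not in out.reactions:
            continue
        keep_id = _pick_survivor([a_id, b_id], out)
        drop_id = b_id if keep_id == a_id else a_id
        keep, drop = out.reactions[keep_id], out.reactions[drop_id]
        compatible = drop.gpr is None or keep.gpr is None or drop.gpr == keep.gpr
        if compatible:
            if drop.gpr is not None and keep.gpr is None:
                keep.gpr = drop.gpr
            keep.lower_bound = min(keep.lower_bound, -drop.upper_bound)
            keep.upper_bound = max(keep.upper_bound, -drop.lower_bound)
            for resource, ids in drop.xrefs.items():
                for identifier in ids:
                    keep.add_xref(resource, identifier)
            del out.reactions[drop_id]
            result.removed_ids.append(drop_id)
        else:
            drop.disable()
            result.disabled_ids.append(drop_id)

    result.gpr_preservation_check = set(out.gene_products) == genes_before
    if not result.gpr_preservation_check:
        raise GprLossError("gene product set changed during consolidation")
    result.removed_ids.sort()
    result.disabled_ids.sort()
    return out, result


def deduplicate(model: Model, strip_protons: bool = True
                ) -> tuple[Model, DedupReport]:
    """Detection plus consolidation in one call."""
    report = find_duplicates(model, strip_protons)
    return consolidate(model, report)
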