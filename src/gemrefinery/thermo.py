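"""Thermodynamic directionality refinement.

Two phases.  Phase 1 applies biochemical irreversibility rules to five
well-characterised reaction classes (ATP-dependent ligases, decarboxylations,
large-ΔE° NAD(P)H reductions, OXPHOS/ETC, fatty-acid β-oxidation), each with
a default ΔrG′° far from equilibrium.  Phase 2 detects Type-III futile
cycles — internal loops able to carry flux with every boundary reaction
closed — by maximising the L1 norm of the internal flux vector under
S·v = 0 (HiGHS via scipy.linprog), confirms each candidate by per-reaction
FVA under the same closure, and iteratively tightens bounds (ΔrG′° < −20
kJ/mol → forward-irreversible; ΔrG′° > 0 or no gene evidence → blocked)
until no loop remains.  Resolution only ever tightens bounds; it never
reverses a reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from .model import (
    EXCHANGE,
    SINK_DEMAND,
    Model,
    Reaction,
    classify_reaction,
)

__all__ = [
    "DirectionalityRule", "CycleReport", "DEFAULT_RULES",
    "apply_irreversibility_rules", "detect_loops", "resolve_loops",
    "verify_loopless", "irreversibility_stats",
    "loop_reactions_by_enumeration", "producible_species",
    "UnresolvedCyclesError", "RuleConflictError",
    "FLUX_TOL", "FLUX_CAP", "DG_IRREVERSIBLE_THRESHOLD",
]

#: numerical tolerance on flux magnitudes (flux units)
FLUX_TOL = 1e-6
#: finite cap applied to all bounds inside the closed-boundary LP
FLUX_CAP = 1000.0
#: ΔrG′° below which a loop reaction is made forward-irreversible (kJ/mol)
DG_IRREVERSIBLE_THRESHOLD = -20.0
#: thermodynamic reference context for any ΔG bookkeeping (not computed here)
THERMO_TEMPERATURE_K = 310.0
THERMO_PH = 7.4


class UnresolvedCyclesError(RuntimeError):
    def __init__(self, message: str, report: "CycleReport"):
        super().__init__(message)
        self.report = report


class RuleConflictError(ValueError):
    """A reaction matched two rule classes with conflicting orientations."""


# ---------------------------------------------------------------------------
# Phase 1: rule classes

def _base_name(model: Model, sid: str) -> str:
    sp = model.species[sid]
    base = sp.id
    suffix = "_" + sp.compartment
    if base.endswith(suffix):
        base = base[: -len(suffix)]
    return base.lower()


def _names(model: Model, rxn: Reaction, consumed: bool) -> set[str]:
    return {
        _base_name(model, sid)
        for sid, coef in rxn.stoichiometry.items()
        if (coef < 0) == consumed
    }


def _atp_ligase(rxn: Reaction, model: Model) -> Optional[int]:
    eaten, made = _names(model, rxn, True), _names(model, rxn, False)
    if "atp" in eaten and "amp" in made and "ppi" in made:
        return +1
    if "atp" in made and "amp" in eaten and "ppi" in eaten:
        return -1
    return None


def _decarboxylation(rxn: Reaction, model: Model) -> Optional[int]:
    # only the CO2-releasing direction is committed; CO2 consumption alone
    # does not make a reaction a reverse decarboxylation (carboxylases and
    # hydration equilibria are not in this class)
    eaten, made = _names(model, rxn, True), _names(model, rxn, False)
    if "co2" in made and "co2" not in eaten:
        return +1
    return None


def _tagged(tags: tuple[str, ...]) -> Callable[[Reaction, Model], Optional[int]]:
    def predicate(rxn: Reaction, model: Model) -> Optional[int]:
        sub = (rxn.subsystem or "").lower()
        return +1 if sub in tags else None
    return predicate


@dataclass(frozen=True)
class DirectionalityRule:
    """One irreversibility rule class.

    ``predicate(rxn, model)`` returns the biochemically forward orientation
    (+1 = as written, −1 = reverse) or ``None`` when the reaction does not
    belong to the class.  ``default_dg0`` (kJ/mol, < 0) stands in for
    reactions without a measured ΔrG′°.
    """

    class_name: str
    default_dg0: float
    predicate: Callable[[Reaction, Model], Optional[int]]

    def __post_init__(self) -> None:
        if self.default_dg0 >= 0:
            raise ValueError(f"{self.class_name}: default ΔrG′° must be negative")


DEFAULT_RULES: tuple[DirectionalityRule, ...] = (
    DirectionalityRule("ATP_LIGASE", -30.5, _atp_ligase),
    DirectionalityRule("DECARBOXYLATION", -30.0, _decarboxylation),
    DirectionalityRule("REDOX_HIGH_DE", -30.0, _tagged(("redox_high_de",))),
    DirectionalityRule("OXPHOS_ETC", -30.0, _tagged(("oxphos", "etc", "oxphos_etc"))),
    # net ΔG per β-oxidation cycle
    DirectionalityRule("BETA_OXIDATION", -69.0, _tagged(("beta_oxidation",))),
)


def match_rules(rxn: Reaction, model: Model,
                rules: tuple[DirectionalityRule, ...] = DEFAULT_RULES
                ) -> Optional[tuple[DirectionalityRule, int]]:
    """The rule class a reaction belongs to, with its forward orientation;
    conflicting multi-class matches raise."""
    hits = [(rule, o) for rule in rules
            if (o := rule.predicate(rxn, model)) is not None]
    if not hits:
        return None
    orientations = {o for _, o in hits}
    if len(orientations) > 1:
        names = ", ".join(r.class_name for r, _ in hits)
        raise RuleConflictError(
            f"reaction {rxn.id} matches conflicting classes: {names}")
    return hits[0]


def apply_irreversibility_rules(
    model: Model,
    rules: tuple[DirectionalityRule, ...] = DEFAULT_RULES,
) -> tuple[Model, list[dict]]:
    """Phase 1: constrain matching reactions to their biochemically forward
    orientation (lb clipped to 0 in that orientation).  Non-matching
    reactions are untouched.  Returns the adjusted model and a change list
    recording reaction, class and prior bounds."""
    out = model.copy()
    changes: list[dict] = []
    for rxn in out.enabled_reactions():
        if _is_boundary(rxn, out):
            continue  # boundary fluxes are direction-free by design
        hit = match_rules(rxn, out, rules)
        if hit is None:
            continue
        rule, orientation = hit
        prior = (rxn.lower_bound, rxn.upper_bound)
        if orientation > 0:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
        else:
            rxn.upper_bound = min(rxn.upper_bound, 0.0)
        if (rxn.lower_bound, rxn.upper_bound) != prior:
            changes.append({
                "reaction": rxn.id, "class": rule.class_name,
                "prior_bounds": prior,
                "new_bounds": (rxn.lower_bound, rxn.upper_bound),
            })
        if rxn.dg0 is None:
            rxn.dg0 = rule.default_dg0 * orientation
    return out, changes


# ---------------------------------------------------------------------------
# Phase 2: closed-boundary LP loop detection

def _is_boundary(rxn: Reaction, model: Model) -> bool:
    rclass = rxn.rclass or classify_reaction(rxn, model)
    return rclass in (EXCHANGE, SINK_DEMAND)


def _network_arrays(model: Model, cap: float
                    ) -> tuple[list[Reaction], list[str], np.ndarray,
                               np.ndarray, np.ndarray]:
    """Stoichiometric matrix and closed-system bounds over enabled reactions.

    Boundary reactions are fixed to [0, 0]; internal bounds are clipped to
    ±cap so the L1 maximisation is bounded.
    """
    reactions = [r for r in model.enabled_reactions()]
    species = sorted({sid for r in reactions for sid in r.stoichiometry})
    sp_index = {sid: i for i, sid in enumerate(species)}
    S = np.zeros((len(species), len(reactions)))
    lb = np.zeros(len(reactions))
    ub = np.zeros(len(reactions))
    for j, rxn in enumerate(reactions):
        for sid, coef in rxn.stoichiometry.items():
            S[sp_index[sid], j] = float(coef)
        if _is_boundary(rxn, model):
            lb[j] = ub[j] = 0.0
        else:
            lb[j] = max(rxn.lower_bound, -cap)
            ub[j] = min(rxn.upper_bound, cap)
    return reactions, species, S, lb, ub


@dataclass
class CycleReport:
    """Outcome of one loop-detection pass (and any actions taken on it)."""

    iteration: int = 0
    loop_reactions: set[str] = field(default_factory=set)
    cycles: list[set[str]] = field(default_factory=list)
    actions: list[tuple[str, str, str]] = field(default_factory=list)
    lp_optimum: float = 0.0

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "loop_reactions": sorted(self.loop_reactions),
            "cycles": [sorted(c) for c in self.cycles],
            "actions": [list(a) for a in self.actions],
            "lp_optimum": self.lp_optimum,
        }


def _fva_range(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
               j: int) -> tuple[float, float]:
    """(min, max) of v_j under S·v = 0 and the closed bounds."""
    n = S.shape[1]
    bounds = list(zip(lb, ub))
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(n)
        c[j] = sign
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                      method="highs")
        out.append(float(res.x[j]) if res.status == 0 else 0.0)
    return out[0], out[1]


def _fva_confirm(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                 candidates: list[int], tol: float) -> set[int]:
    """Per-reaction flux variability under closure: a candidate is a loop
    reaction iff max |v_i| exceeds tolerance."""
    confirmed: set[int] = set()
    for j in candidates:
        vmin, vmax = _fva_range(S, lb, ub, j)
        if max(abs(vmin), abs(vmax)) > tol:
            confirmed.add(j)
    return confirmed


def detect_loops(model: Model, cap: float = FLUX_CAP,
                 tol: float = FLUX_TOL, iteration: int = 0) -> CycleReport:
    """Find reactions able to carry flux with all boundaries closed.

    Solves one LP maximising Σ(v⁺ + v⁻) subject to S·v = 0 with boundary
    reactions fixed to zero as a global screen (a zero optimum certifies
    looplessness outright; a positive optimum is inconclusive because the
    v⁺/v⁻ split admits cancelling pairs on any reversible reaction), then
    decides per reaction by FVA under the same closure.  The reported
    optimum is the total confirmed circulation magnitude Σ max |v_i| over
    loop reactions — 0 within tolerance iff the model is loopless.  Cycles
    are connected components of the metabolite-sharing graph over the loop
    set (currency metabolites — protons, water — do not connect parallel
    loops).  Original bounds are untouched (work happens on arrays).
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    report = CycleReport(iteration=iteration)
    reactions, species, S, lb, ub = _network_arrays(model, cap)
    if not reactions:
        return report

    n = len(reactions)
    # split v = v+ - v-, maximise the L1 norm of internal flux (screen)
    A_eq = np.hstack([S, -S])
    c = -np.ones(2 * n)
    bounds = [(0.0, max(u, 0.0)) for u in ub] + [(0.0, max(-l, 0.0)) for l in lb]
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs")
    if res.status != 0:
        raise RuntimeError(f"closed-boundary LP failed: {res.message}")
    if -res.fun <= tol:
        return report  # no internal flux possible at all
    candidates = [j for j in range(n) if ub[j] > tol or lb[j] < -tol]
    confirmed = _fva_confirm(S, lb, ub, candidates, tol)
    report.loop_reactions = {reactions[j].id for j in confirmed}
    report.lp_optimum = float(sum(
        max(abs(v) for v in _fva_range(S, lb, ub, j)) for j in confirmed))

    if report.loop_reactions:
        graph = nx.Graph()
        graph.add_nodes_from(report.loop_reactions)
        currency = {
            sid for sid in model.species
            if model.species[sid].is_proton() or model.species[sid].is_water()
        }
        by_species: dict[str, list[str]] = {}
        for j in confirmed:
            for sid in reactions[j].stoichiometry:
                if sid not in currency:
                    by_species.setdefault(sid, []).append(reactions[j].id)
        for members in by_species.values():
            for other in members[1:]:
                graph.add_edge(members[0], other)
        report.cycles = [set(comp) for comp in nx.connected_components(graph)]
        report.cycles.sort(key=lambda s: sorted(s))
    return report


def verify_loopless(model: Model, cap: float = FLUX_CAP,
                    tol: float = FLUX_TOL) -> tuple[bool, float]:
    """True iff the closed-boundary loop set is empty; also reports the LP
    optimum (0 within tolerance when loopless)."""
    report = detect_loops(model, cap, tol)
    return not report.loop_reactions, report.lp_optimum


def _reaction_dg0(rxn: Reaction, model: Model,
                  dg_table: Optional[dict[str, float]],
                  rules: tuple[DirectionalityRule, ...]) -> Optional[float]:
    if dg_table is not None and rxn.id in dg_table:
        return dg_table[rxn.id]
    if rxn.dg0 is not None:
        return rxn.dg0
    hit = match_rules(rxn, model, rules)
    if hit is not None:
        rule, orientation = hit
        return rule.default_dg0 * orientation
    return None


def resolve_loops(model: Model, dg_table: Optional[dict[str, float]] = None,
                  max_iter: int = 50, cap: float = FLUX_CAP,
                  tol: float = FLUX_TOL,
                  rules: tuple[DirectionalityRule, ...] = DEFAULT_RULES,
                  ) -> tuple[Model, list[CycleReport]]:
    """Iteratively eliminate futile cycles by tightening bounds.

    Per iteration, for every loop reaction: ΔrG′° < −20 kJ/mol → irreversible
    in the negative-ΔG orientation; ΔrG′° > 0, or unknown without a GPR →
    blocked.  Reactions with unknown ΔrG′° but gene evidence are spared
    until the end and blocked only if they alone sustain a residual cycle.
    Raises :class:`UnresolvedCyclesError` at ``max_iter``; the returned
    model otherwise passes :func:`verify_loopless`.
    """
    out = model.copy()
    reports: list[CycleReport] = []
    for iteration in range(max_iter):
        report = detect_loops(out, cap, tol, iteration=iteration)
        if not report.loop_reactions:
            reports.append(report)
            return out, reports
        # evidence-driven irreversibility first; blocking only when no ΔG
        # action makes progress (a single well-placed constraint often
        # breaks the cycle and leaves the other members untouched)
        changed = False
        for rid in sorted(report.loop_reactions):
            rxn = out.reactions[rid]
            dg0 = _reaction_dg0(rxn, out, dg_table, rules)
            prior = (rxn.lower_bound, rxn.upper_bound)
            if dg0 is not None and dg0 < DG_IRREVERSIBLE_THRESHOLD:
                # forward in the negative-ΔG orientation
                rxn.lower_bound = max(rxn.lower_bound, 0.0)
                if (rxn.lower_bound, rxn.upper_bound) != prior:
                    changed = True
                    report.actions.append((
                        rid, "SET_IRREVERSIBLE",
                        f"dg0={dg0:g}<{DG_IRREVERSIBLE_THRESHOLD:g}"))
        if not changed:
            for rid in sorted(report.loop_reactions):
                rxn = out.reactions[rid]
                dg0 = _reaction_dg0(rxn, out, dg_table, rules)
                prior = (rxn.lower_bound, rxn.upper_bound)
                if (dg0 is not None and dg0 > 0) or \
                        (dg0 is None and rxn.gpr is None):
                    rxn.lower_bound = 0.0
                    rxn.upper_bound = 0.0
                    if (rxn.lower_bound, rxn.upper_bound) != prior:
                        changed = True
                        report.actions.append((
                            rid, "BLOCKED",
                            "dg0>0" if dg0 is not None
                            else "no_gene_assignment"))
        if not changed:
            # residual cycles sustained only by deferred reactions
            for rid in sorted(report.loop_reactions):
                rxn = out.reactions[rid]
                if (rxn.lower_bound, rxn.upper_bound) != (0.0, 0.0):
                    rxn.lower_bound = 0.0
                    rxn.upper_bound = 0.0
                    report.actions.append((rid, "BLOCKED", "residual_cycle"))
        reports.append(report)
    final = detect_loops(out, cap, tol, iteration=max_iter)
    if final.loop_reactions:
        raise UnresolvedCyclesError(
            f"{len(final.loop_reactions)} loop reactions remain after "
            f"{max_iter} iterations", final)
    reports.append(final)
    return out, reports


# ---------------------------------------------------------------------------
# statistics and reference checks

def irreversibility_stats(model: Model, class_map: dict[str, str]) -> list[dict]:
    """Per-pathway-class irreversibility table: (class, n, % irreversible,
    % blocked), percentages rounded half-away-from-zero to one decimal."""
    from .reporting import round1

    classes: dict[str, list[Reaction]] = {}
    for rxn in model.enabled_reactions():
        if rxn.id not in class_map:
            raise KeyError(f"class_map missing enabled reaction {rxn.id}")
        classes.setdefault(class_map[rxn.id], []).append(rxn)
    rows = []
    for name in sorted(classes):
        members = classes[name]
        n = len(members)
        n_irr = sum(1 for r in members if r.irreversible)
        n_blocked = sum(1 for r in members if r.blocked)
        rows.append({
            "class": name, "n": n,
            "pct_irreversible": round1(100.0 * n_irr / n) if n else 0.0,
            "pct_blocked": round1(100.0 * n_blocked / n) if n else 0.0,
        })
    return rows


def loop_reactions_by_enumeration(model: Model, cap: float = FLUX_CAP,
                                  tol: float = FLUX_TOL) -> set[str]:
    """Reference loop set by direct circulation feasibility.

    A reaction is loop-capable iff some circulation passes through it:
    for each reaction and allowed direction, test feasibility of
    {S·v = 0, closed bounds, v_i = ±1}.  This is a literal transcription of
    the definition, independent of the L1-maximisation + FVA path, and is
    used as the cross-check oracle on small networks.
    """
    reactions, species, S, lb, ub = _network_arrays(model, cap)
    loops: set[str] = set()
    for j, rxn in enumerate(reactions):
        for direction in (1.0, -1.0):
            if direction > 0 and ub[j] < tol:
                continue
            if direction < 0 and lb[j] > -tol:
                continue
            bounds = list(zip(lb, ub))
            probe = min(1.0, ub[j]) if direction > 0 else max(-1.0, lb[j])
            bounds[j] = (probe, probe)
            res = linprog(np.zeros(S.shape[1]), A_eq=S,
                          b_eq=np.zeros(S.shape[0]), bounds=bounds,
                          method="highs")
            if res.status == 0:
                loops.add(rxn.id)
                break
    return loops


def producible_species(model: Model, cap: float = FLUX_CAP,
                       tol: float = FLUX_TOL) -> set[str]:
    """Species producible from the boundary: for each species, maximise the
    flux of a temporary drain with all reaction bounds as-is.  Used to
    assert that refinement preserves network reachability."""
    reactions = [r for r in model.enabled_reactions()]
    species = sorted({sid for r in reactions for sid in r.stoichiometry})
    sp_index = {sid: i for i, sid in enumerate(species)}
    S = np.zeros((len(species), len(reactions) + 1))
    bounds = []
    for j, rxn in enumerate(reactions):
        for sid, coef in rxn.stoichiometry.items():
            S[sp_index[sid], j] = float(coef)
        bounds.append((max(rxn.lower_bound, -cap), min(rxn.upper_bound, cap)))
    bounds.append((0.0, cap))
    out: set[str] = set()
    demand_col = len(reactions)
    c = np.zeros(len(reactions) + 1)
    c[demand_col] = -1.0
    for sid in species:
        S[:, demand_col] = 0.0
        S[sp_index[sid], demand_col] = -1.0
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                      method="highs")
        if res.status == 0 and -res.fun > tol:
            out.add(sid)
    return out
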