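"""Annotation-density metrics and the analytic ETC bioenergetics calculator.

One rounding convention is used for every reported percentage: one decimal,
half away from zero.  The bioenergetics calculator derives the effective
H⁺/ATP ratio, P/O ratios and the theoretical aerobic ATP yield per glucose
analytically from the proton stoichiometry of the electron transport chain
reactions (proton-pumping coefficients of Complexes I/III/IV against the
proton cost of ATP synthase plus phosphate import), rather than from an
FBA objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .model import Model, Reaction

__all__ = [
    "round1", "density_report", "EtcStoichiometry",
    "extract_etc_stoichiometry", "po_ratios", "atp_yield_glucose",
    "AEROBIC_GLUCOSE_NADH", "AEROBIC_GLUCOSE_FADH2",
    "AEROBIC_GLUCOSE_SUBSTRATE_ATP",
]

#: default aerobic glucose-oxidation scenario (per mmol glucose)
AEROBIC_GLUCOSE_NADH = 10
AEROBIC_GLUCOSE_FADH2 = 2
AEROBIC_GLUCOSE_SUBSTRATE_ATP = 4


def round1(value: float) -> float:
    """Round to one decimal, half away from zero."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"),
                                               rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# annotation density

def density_report(model: Model,
                   annotations: Optional[list] = None) -> dict:
    """Metabolite- and reaction-level annotation density.

    Counts entities carrying at least one xref per resource; reaction-level
    pathway rows use the optional pathway annotation list (all-levels and
    leaf layers).  Percentages: one decimal, half away from zero.
    """
    species = list(model.species.values())
    reactions = [r for r in model.enabled_reactions()]
    n_sp, n_rx = len(species), len(reactions)

    def pct(n: int, d: int) -> float:
        return round1(100.0 * n / d) if d else 0.0

    mnx = sum(1 for s in species if s.xrefs.get("metanetx.chemical"))
    chebi = sum(1 for s in species if s.xrefs.get("chebi"))
    report = {
        "species_total": n_sp,
        "species_mnx_mapped": mnx,
        "pct_species_mnx_mapped": pct(mnx, n_sp),
        "species_chebi_mapped": chebi,
        "pct_species_chebi_mapped": pct(chebi, n_sp),
        "species_chebi_unmapped": n_sp - chebi,
        "pct_species_chebi_unmapped": pct(n_sp - chebi, n_sp),
        "reactions_total": n_rx,
    }
    gpr = sum(1 for r in reactions if r.gpr is not None)
    rhea = sum(1 for r in reactions if r.xrefs.get("rhea"))
    report.update({
        "reactions_with_gpr": gpr, "pct_reactions_with_gpr": pct(gpr, n_rx),
        "reactions_with_rhea": rhea, "pct_reactions_with_rhea": pct(rhea, n_rx),
    })
    if annotations is not None:
        by_id = {a.reaction_id: a for a in annotations}
        all_levels = sum(1 for r in reactions
                         if by_id.get(r.id) and by_id[r.id].all_levels)
        leaf = sum(1 for r in reactions
                   if by_id.get(r.id) and by_id[r.id].leaf_only)
        report.update({
            "reactions_with_pathway_all_levels": all_levels,
            "pct_reactions_with_pathway_all_levels": pct(all_levels, n_rx),
            "reactions_with_pathway_leaf": leaf,
            "pct_reactions_with_pathway_leaf": pct(leaf, n_rx),
        })
    return report


# ---------------------------------------------------------------------------
# bioenergetics

@dataclass
class EtcStoichiometry:
    """Proton stoichiometry of the electron transport chain.

    Pumping coefficients are protons moved to the intermembrane space per
    electron-pair donor (NADH for Complex I, UQH₂ for Complex III, per
    electron pair for Complex IV); consumption coefficients are
    intermembrane protons used per ATP synthesised and per phosphate
    imported.
    """

    h_pumped_complex_i: float
    h_pumped_complex_iii: float
    h_pumped_complex_iv: float
    h_per_atp_synthase: float
    h_per_pi_transport: float

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative")


#: role -> reference species base id used to normalise proton coefficients
ETC_REFERENCE_SPECIES = {
    "complex_i": "nadh",       # per NADH oxidised
    "complex_iii": "qh2",      # per ubiquinol oxidised
    "complex_iv": "h2o",       # one water per electron pair
    "atp_synthase": "atp",     # per ATP made
    "pi_transport": "pi",      # per phosphate imported
}


def _base(model: Model, sid: str) -> str:
    sp = model.species[sid]
    suffix = "_" + sp.compartment
    base = sp.id[: -len(suffix)] if sp.id.endswith(suffix) else sp.id
    return base.lower()


def _proton_coefficient(model: Model, rxn: Reaction,
                        intermembrane: str) -> float:
    """Net signed proton coefficient in the intermembrane compartment."""
    total = 0.0
    found = False
    comps = set()
    for sid, coef in rxn.stoichiometry.items():
        sp = model.species[sid]
        if sp.is_proton():
            found = True
            comps.add(sp.compartment)
            if sp.compartment == intermembrane:
                total += float(coef)
    if not found or len(comps) < 2:
        raise ValueError(
            f"reaction {rxn.id}: no cross-compartment proton movement")
    return total


def extract_etc_stoichiometry(model: Model, etc_reaction_ids: dict[str, str],
                              intermembrane: str = "i") -> EtcStoichiometry:
    """Read proton-pumping/consuming coefficients from named ETC reactions.

    ``etc_reaction_ids`` maps the roles ``complex_i``, ``complex_iii``,
    ``complex_iv``, ``atp_synthase`` and ``pi_transport`` to reaction ids.
    Each reaction must move protons between the matrix and the
    ``intermembrane`` compartment; coefficients are normalised by the
    role's reference species (NADH, UQH₂, H₂O per electron pair, ATP, Pi).
    """
    values: dict[str, float] = {}
    for role in ("complex_i", "complex_iii", "complex_iv",
                 "atp_synthase", "pi_transport"):
        rid = etc_reaction_ids[role]
        if rid not in model.reactions:
            raise KeyError(f"ETC reaction {rid!r} not in model")
        rxn = model.reactions[rid]
        proton = _proton_coefficient(model, rxn, intermembrane)
        ref_base = ETC_REFERENCE_SPECIES[role]
        ref_coef = next(
            (abs(float(c)) for sid, c in rxn.stoichiometry.items()
             if _base(model, sid) == ref_base), None)
        if not ref_coef:
            raise ValueError(
                f"reaction {rid}: reference species {ref_base!r} absent")
        values[role] = abs(proton) / ref_coef
    return EtcStoichiometry(
        h_pumped_complex_i=values["complex_i"],
        h_pumped_complex_iii=values["complex_iii"],
        h_pumped_complex_iv=values["complex_iv"],
        h_per_atp_synthase=values["atp_synthase"],
        h_per_pi_transport=values["pi_transport"],
    )


def po_ratios(s: EtcStoichiometry) -> tuple[float, float, float]:
    """(P/O for NADH, P/O for FADH₂, effective H⁺/ATP).

    The effective proton cost of one cytosolic ATP is synthase consumption
    plus phosphate import; NADH electrons traverse Complexes I+III+IV,
    FADH₂ electrons enter at Complex III.
    """
    h_eff = s.h_per_atp_synthase + s.h_per_pi_transport
    if h_eff <= 0:
        raise ZeroDivisionError("effective H+/ATP is zero")
    po_nadh = (s.h_pumped_complex_i + s.h_pumped_complex_iii
               + s.h_pumped_complex_iv) / h_eff
    po_fadh2 = (s.h_pumped_complex_iii + s.h_pumped_complex_iv) / h_eff
    return po_nadh, po_fadh2, h_eff


def atp_yield_glucose(po_nadh: float, po_fadh2: float,
                      nadh_count: float = AEROBIC_GLUCOSE_NADH,
                      fadh2_count: float = AEROBIC_GLUCOSE_FADH2,
                      substrate_level_atp: float = AEROBIC_GLUCOSE_SUBSTRATE_ATP,
                      ) -> float:
    """Theoretical ATP yield per glucose: linear in each reducing-equivalent
    count plus substrate-level phosphorylation."""
    if nadh_count < 0 or fadh2_count < 0 or substrate_level_atp < 0:
        raise ValueError("counts must be non-negative")
    return nadh_count * po_nadh + fadh2_count * po_fadh2 + substrate_level_atp
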