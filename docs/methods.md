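# Methods

This note documents the models, conventions and numerical choices behind
gem-refinery, and what the synthetic fixtures do and do not demonstrate.

## Model representation

A model is the SBML Level 3 view of a reconstruction: compartments,
species (one metabolite–compartment pair each — cytosolic and
mitochondrial ATP are distinct species), reactions with a signed
stoichiometry map, flux bounds, an optional Boolean GPR tree, and
cross-references keyed by resource (`metanetx.chemical`, `chebi`,
`kegg.compound`, `rhea`, `reactome`, ...). Stoichiometric coefficients are
exact `fractions.Fraction` values internally so that GCD/LCM
canonicalisation during duplicate detection is exact; floats appear only
at SBML write time. Unbounded fluxes are encoded as ±1000 flux units, the
usual COBRA convention; the value is configurable and nothing downstream
depends on it beyond being comfortably larger than any meaningful flux.

Reaction classes partition the enabled reaction set with precedence
EXCHANGE > SINK_DEMAND > TRANSPORT > LEGACY > ENZYMATIC, matching the
order in which coverage denominators subtract classes. One precedence
case is genuinely ambiguous: a single-participant reaction is both
"boundary flux" (exchange) and potentially a "drain" (sink/demand). The
tie-break here: a single-species reaction is SINK_DEMAND when named by a
sink/demand prefix or when it is an irreversible consumption-only drain,
otherwise EXCHANGE. Exchange detection is structural first; prefixes
(`EX_`, `SK_`, `DM_`) are fallbacks only, because identifier conventions
vary across reconstruction lineages while structure does not. Legacy ids
default to the KEGG-lineage `R*`/`RE*` digit pattern.

## Identifier harmonisation

Four stages per species: (1) exact (resource, id) lookup in the mapping
table; (2) structure-supported matching — InChIKey connectivity block
(first 14 characters) preferred, formula+charge fallback; (3) a
stoichiometric consistency filter: a candidate whose formula would
unbalance a reaction that currently balances is rejected (the mechanism
chosen here for the stated goal of consistency within reaction
stoichiometry); (4) rule-based ambiguity resolution. Protonation variant
groups resolve to the member marked dominant at physiological pH
(reference pH 7.3, a config constant; dominance is *table input*, not a
pKa computation — predicting microspecies distributions is out of scope).
Stereo/tautomer groups resolve to the best-curated ChEBI-linked record,
ties broken by smallest ChEBI id for determinism. Anything else is
retained and flagged.

Merging is id-substitution only: species sharing a canonical id within
one compartment collapse to the lexicographically smallest id; reaction
coefficients are never altered except when substitution places one
species on both sides, where coefficients are summed and an exact
cancellation drops the participant with an audit entry. Cross-compartment
merging never happens. Harmonisation is idempotent because chosen
canonical ids are recorded as `metanetx.chemical` xrefs and the table
carries self-referencing rows with the same variant metadata.

## Deduplication

The canonical key is (sorted participants, reduced coprime integer
coefficients, orientation sign). Proton stripping before keying treats
"proton-only differences" as duplicates *unless* the protons span more
than one compartment — a proton pump's gradient is the chemistry, so
translocated protons are never stripped. Detection is compartment-scoped
automatically because species ids are compartment-specific.

Survivor selection is deterministic: GPR-bearing first, then smallest id.
Copies with a conflicting GPR are disabled (lb = ub = 0, retained in SBML
with a traceability note), never removed. Reverse pairs with compatible
GPRs merge into one reversible reaction with unioned bounds
(lb = min(lb₁, −ub₂), ub = max(ub₁, −lb₂)), which preserves the flux
space; the FBA optimum on a planted objective is checked to be unchanged
in the tests (cross-checked with cobrapy). The gene-product collection is
never modified, and a consolidation that would change it is a hard error.

## Thermodynamic refinement

**Rule classes (phase 1).** Five classes with defaults far from
equilibrium: ATP ligases −30.5 kJ/mol (matched structurally: ATP consumed,
AMP + PPi produced), decarboxylations −30 kJ/mol (midpoint of the −20 to
−40 range; only the CO₂-releasing direction is committed — CO₂
consumption alone does not mark a reverse decarboxylation, since
carboxylases and hydration equilibria are real), high-ΔE° NAD(P)H
reductions −30 kJ/mol, OXPHOS/ETC −30 kJ/mol, and β-oxidation −69 kJ/mol
per cycle. The redox/OXPHOS/β-oxidation classes match on subsystem tags
because membership is not derivable from stoichiometry alone. Boundary
reactions are never rule-constrained. A reaction matching two classes
with conflicting orientations raises rather than guessing. Reference
thermodynamic context is fixed at 310 K, pH 7.4 as config constants; no
ΔG′° estimation is performed — full component-contribution
parameterisation is explicitly out of scope.

**Loop detection (phase 2).** Boundary reactions are fixed to [0, 0],
internal bounds clipped to ±1000 (`cap`), and an LP maximises
Σ(v⁺ + v⁻) subject to S·v = 0. A zero optimum certifies looplessness
outright. A positive optimum is deliberately treated as inconclusive: the
v⁺/v⁻ split admits cancelling pairs (v⁺ = v⁻ > 0, net flux zero) on any
reversible reaction, so the L1 optimum is positive even for loopless
networks. Per-reaction FVA under the same closure is therefore the
decider, and the reported "maximum internal flux" is the total confirmed
circulation magnitude Σ max |vᵢ| over loop reactions — zero within
tolerance iff loopless. Flux tolerance is 1e−6 flux units throughout.
Cycle delimitation is connected components over shared metabolites,
excluding protons and water so that parallel loops sharing only currency
metabolites count separately.

**Resolution.** Per iteration, evidence-driven actions first: loop
reactions with ΔrG′° < −20 kJ/mol (from the supplied table, the
reaction's own annotation, or the rule-class default) are made
irreversible in the negative-ΔG orientation. Only when no ΔG action makes
progress are loop members with ΔrG′° > 0 or no gene evidence blocked;
reactions with unknown ΔG but a GPR are spared until they alone sustain a
residual cycle. This ordering means a single well-placed constraint
(e.g., the −30 kJ/mol member of a triangle) eliminates a cycle while
leaving the other members untouched. Resolution only ever tightens
bounds; the iteration count is capped (default 50) and hitting the cap
with loops remaining is an error carrying the residual report. Because
later stages (balance repair) can alter stoichiometry, the pipeline
re-verifies the loopless certificate after repairs and re-resolves if
necessary — the certificate holds on the *final* model.

## GPR handling

The rule grammar is `expr := term (OR term)*; term := factor (AND
factor)*; factor := GENE | '(' expr ')'` with case-insensitive operators,
AND binding tighter than OR, and flat n-ary trees. AND/OR nodes are
order-insensitive for equality; duplicate leaves collapse at
construction, which is what makes merged-gene rewriting (`OR(g, g) → g`)
automatic. Gene standardisation follows MERGED chains to the successor
ENSG; OBSOLETE ids without a successor keep their leaf and are reported
as unmapped rather than silently dropped. The conservative fallback for
unreconstructable associations is a flat OR (isozyme reading) — never an
AND — to avoid over-specifying complex composition.

Coverage is reported under five denominators (all reactions; minus
exchange+sink/demand; further minus transport; further minus legacy;
enzymatic core). Under this package's exclusive class partition the last
two rows coincide; both are kept because released models may tag a
curated core narrower than the structural ENZYMATIC class. Disabled
reactions are excluded from numerator and denominator — they are
bookkeeping, not biology.

## Pathways

Gene→pathway records are species-filtered (default "Homo sapiens"); a
leaf is a pathway that never occurs as a parent, computed against parents
occurring in the filtered species' records so cross-species relation rows
cannot delete leaves. Reactions inherit the union of their genes'
pathways (all-levels layer); the leaf-only layer intersects with the leaf
set and is the right input for enrichment-style analyses, since the
hierarchical layer double-counts by construction. Reactions without a
GPR stay unannotated. Pathway-ID counts and reaction counts are reported
as separate fields because the two are easy to conflate.

## Balance checking and repair

Element and charge deltas (products − reactants) are computed exactly;
charge is one more row of the balance system. Boundary (single-sided)
reactions and reactions with any formula-less or charge-less participant
are UNCHECKABLE, as are R-group/wildcard formulas, which the formula
parser rejects. Repair searches signed combinations of a fixed
bookkeeping pool — H⁺, H₂O, Pi (HPO₄²⁻), PPi (HP₂O₇³⁻), CO₂, HCO₃⁻,
NH₄⁺, the dominant cytosolic microspecies at physiological pH — up to a
total added stoichiometry of 4, returning the smallest combination, ties
broken by pool order. Proton/water repairs are mechanism-neutral and
auto-applied; anything touching C, N or P bookkeeping needs the reaction
on an explicit allowlist, because mechanism preservation is a judgement
the algorithm should not make. The added instance lives in the majority
compartment of the reaction's participants (ties: smallest compartment
id). Every applied repair is re-checked; a post-repair imbalance is an
internal error, not a warning.

## Bioenergetics

The ETC calculator is analytic, not FBA-based: proton-pumping
coefficients are read off the named reactions and normalised per
electron-pair donor (NADH for Complex I, ubiquinol for Complex III, one
H₂O per electron pair for Complex IV, ATP for the synthase, Pi for the
phosphate transporter). Effective H⁺/ATP = synthase + Pi-transport cost;
P/O(NADH) = (I + III + IV)/H⁺-per-ATP; P/O(FADH₂) skips Complex I. The
aerobic glucose scenario defaults (10 NADH, 2 FADH₂, 4 substrate-level
ATP per glucose) are config values. All reported percentages use one
convention: one decimal, half away from zero — verified in the tests to
reproduce all sixteen printed fraction/percentage pairs of the coverage
tables (half-even would too; half-away is simpler to state).

## Synthetic fixtures

The generator emits a small boundary-fed central-carbon network (glucose
uptake, lumped glycolysis, lactate fermentation, pyruvate
decarboxylation, an ATP ligase, legacy KEGG-style reactions, optional
ETC with the textbook 4/4/2‑pumped and 3+1‑consumed proton coefficients)
whose background is clean by construction: mass-balanced wherever
formulas exist, loopless, duplicate-free. Artefacts are planted on top
and recorded in a ground-truth manifest: a futile triangle whose only
feasible circulation runs its reversible member backwards (so one
−30 kJ/mol irreversibility constraint breaks it), all-reversible extra
triangles, scaled exact duplicates, forward-only reverse copies,
reactions with H₂O/H⁺/Pi omitted, ambiguous two-target mappings,
protonation variant pairs, a merged and an obsolete gene id, and a small
pathway hierarchy with a cross-species decoy row. One deliberate
consequence: duplicate and reverse copies of reversible reactions *are*
closed-system loops, which is exactly why deduplication precedes
thermodynamic refinement in the pipeline; the manifest's cycle list
therefore describes the post-deduplication model. Fixture sizes are a
few dozen reactions — large enough to exercise every code path and small
enough that the whole suite runs in seconds. Same seed, byte-identical
output; unrealisable planted counts fail before any file is written.

What passing on fixtures shows: exact recovery of every planted artefact
class with no false positives, and the conservation guarantees (gene
products, GPRs, reachability, bound monotonicity) under those
operations. What it does not show: behaviour on organism-scale networks
(solver conditioning, runtime), on the messier identifier landscapes of
real MNXref/ChEBI dumps, or on GPRs with transcript-level structure.

## Verification strategy

Independent oracles back the main algorithms: loop detection is compared
against direct circulation enumeration (per reaction and direction, a
feasibility LP with that flux pinned — a transcription of the definition,
not a second run of the same algorithm) on random ≤10-reaction networks;
repair minimality is checked against an exhaustive search written
separately in the tests; duplicate grouping is compared with O(n²)
pairwise key comparison; FBA optima across consolidation and SBML
round-trips are cross-checked with cobrapy, which is never used in the
implementation path.

## Known limitations

Directionality uses discrete bounds, not continuous thermodynamic
potentials: near-equilibrium reactions whose direction depends on
metabolite concentrations are left reversible. The redox/OXPHOS/
β-oxidation rule classes require subsystem tags. The balance repair pool
is fixed and small by design; imbalances outside its span are flagged,
not fixed. SBML round-tripping preserves the constraint-based substance
(ids, stoichiometry, bounds, GPRs, xrefs, notes-backed flags) but not
arbitrary foreign annotation blocks. Blocked-but-retained reactions make
reaction counts depend on whether disabled entries are included; reports
state which set they count.
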