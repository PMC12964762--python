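# Methods

## The problem and the model

Genome-scale metabolic models (GEMs) are too large and too heterogeneously
annotated to compare directly across organisms. `gemreduce` reduces each
GEM to three functionally defined modules, following the classical
partition of microbial metabolism into fueling, biosynthesis, and exchange,
and compares organisms module by module with the Jaccard index
J(A, B) = |A ∩ B| / |A ∪ B|.

1. **Fueling (core extraction).** A curated, compartment-free metabolite
   list defines each central subsystem (glycolysis/gluconeogenesis, pentose
   phosphate pathway, TCA cycle, pyruvate metabolism); oxidative
   phosphorylation is defined as every reaction touching an electron
   carrier (quinones/quinols, cytochromes). A reaction joins a subsystem
   when *all* of its reactants and products — after removing inorganic
   compounds and cofactor pairs that turn over across the reaction — are in
   the list. The union of assigned reactions, enriched with every further
   reaction whose non-excluded participants all lie inside the union of the
   lists, is the degree-0 (D0) core. A directed graph search over the
   bipartite metabolite–reaction digraph then adds, for every unordered
   subsystem pair and every length d ≤ D, all directed paths of exactly d
   reactions from a metabolite of one subsystem to a metabolite of the
   other, giving nested cores D1 ⊆ D2 ⊆ … .
2. **Biosynthesis (subnetwork enumeration and lumping).** For each biomass
   building block (BBB; a species consumed by the biomass reaction) a MILP
   finds the smallest sets of non-core reactions that sustain steady-state
   production of one unit of the target, with the core's metabolites acting
   as free boundary species (the core supplies precursors and energy/redox
   carriers and absorbs byproducts). Each subnetwork is lumped into one net
   reaction between core/medium species, normalized to +1 of the target;
   the moles of the twelve canonical precursor metabolites and the net
   ATP/NADH/NADPH turnover per mole of target give the biosynthetic cost,
   averaged over the unique lumped reactions.
3. **Exchange (substrate connection and fates).** The same MILP machinery,
   with the forcing replaced by a fixed unit uptake of an extracellular
   substrate (secretion of the substrate blocked), finds the minimal
   balanced routes that integrate the substrate into the core; the
   co-substrates taken up and byproducts secreted across all alternative
   routes summarize the substrate's metabolic fate independently of the
   enzymes used.

## Algorithmic choices

**Graph search.** Reversible reactions contribute both directions; a path
never reuses a reaction or revisits a metabolite; recording stops at the
first target metabolite (continuing through it would make an endpoint
subsystem member an intermediate, which is disallowed). Inorganics and
cofactor-pair members are removed from the digraph entirely so that e.g.
ATP cannot act as a universal two-step bridge; metabolites of a third
subsystem *are* usable as intermediates, since pairs are searched
independently. Path endpoints are the compartmented instances of subsystem
members that appear in the D0 core, so an extracellular copy the core never
touches is not an endpoint. A reversible one-reaction link traversed in
both orientations is collapsed to one canonical connection record. Degrees
are cumulative ("all paths of exactly d reactions for every d ≤ D"), which
makes the cores nested by construction; all alternative paths of qualifying
length are kept, with no tie-breaking.

**Subsystem rule details.** A cofactor pair is excluded only when its two
members appear on *opposite* sides of a reaction (donor/acceptor turnover);
a lone member — ATP as a substrate of a synthetase, say — is an ordinary
metabolite, so biosynthetic reactions do not leak into the central
subsystems. A reaction whose effective member set is empty after the
exclusions (a pure cofactor/inorganic interconversion such as an ATP
synthase or adenylate kinase) is assigned to no subsystem and is not
enriched into D0: the vacuous reading of "all members in the list" would
put such reactions in every subsystem at once. Source-model subsystem
annotations are kept as metadata only; when an annotated reaction fails the
rule, the event is logged and the rule wins.

**MILP enumeration.** Each non-core, non-exchange reaction carries a binary
use-indicator z coupled to its flux by big-M bounds (M = the reaction's
largest bound magnitude, 1000 when unbounded); exchanges are governed by
the medium and carry no indicator, and the biomass reaction is blocked
during enumeration. The objective minimizes Σz. Alternative optima are
enumerated with integer cuts placed on the *flux support* of each solution
(Σ_{r∈support} z_r ≤ |support| − 1), which excludes every superset of a
found support; because solutions arrive in nondecreasing objective order,
the enumeration yields exactly the support-minimal active sets up to size
S_min + k_relax. `k_relax` defaults to 0 (strictly minimal subnetworks) and
the alternative cap defaults to 5000 per target, with truncation always
surfaced. A target available in the medium yields a transport-only
subnetwork; a target that is itself a core metabolite yields one empty
subnetwork (drawn directly from the core). GLPK (via optlang) solves all
LPs and MILPs; integrality tolerance 1e-6. The target drain is a temporary
sink at 1 mmol·gDW⁻¹·h⁻¹, removed from reported stoichiometries.

**Lumping and costs.** The lump is the flux-weighted sum of the active
reactions' stoichiometries; internally balanced species cancel, core
species remain, coefficients below 1e-9 are dropped after normalization to
+1 of the target. Uniqueness of lumps means identical metabolite support
with coefficients equal within 1e-6. ATP cost counts net ADP production
plus twice net AMP production; NADH/NADPH are net and signed (negative =
produced). Consumed species that are neither precursors nor carriers nor
inorganics land in the `other` component of the cost vector — this is how
an auxotroph's dependence on environmental metabolites shows up. Two
degenerate lump shapes get explicit cost conventions: a core-supplied
target costs one mole of itself, and a transport-only lump (whose
compartment-stripped stoichiometry cancels) costs one mole of the medium
species, recorded under `other`.

**Minimal media.** Binary indicators gate the uptake of each candidate
exchange; the MILP minimizes the number of open uptakes subject to biomass
flux ≥ `growth_fraction` × the maximum with all candidates open, and
integer cuts enumerate all alternative minima of the same cardinality.
`growth_fraction` defaults to 0.1 and is recorded in every report header;
non-candidate exchanges are closed for uptake during the analysis.

**Fates and capabilities.** Fates are read exclusively from non-zero
exchange fluxes, so they are invariant to internal route relabeling. Water
and protons are suppressed on both sides; the medium's inorganic background
is additionally suppressed from co-substrates, so CO₂ secretion remains
visible as a byproduct. Aerobic versus anaerobic analysis is purely a
property of the oxygen bound in the medium, not a separate switch. The
capability matrix calls a substrate "uptake" when at least one balanced
connecting subnetwork exists and "secrete" when its exchange can carry
positive flux under the shared medium (union of the organisms' media, with
per-exchange maxima).

**Jaccard conventions.** Empty-vs-empty is defined as 1 with a logged
warning; empty-vs-nonempty is 0. Cross-organism reaction identity for
subnetwork comparison goes through an optional harmonization lookup table
(models reconstructed in one namespace compare directly). A BBB missing in
one organism is flagged missing (NaN) rather than scored 0, and excluded
from category averages with the exclusion count reported.

## The fixture generator

Real GEMs are too large for exhaustive verification, so the package ships a
generator of small GEMs whose every ground truth is known by construction:
isomerization chains of elementally identical species form the subsystems
(with ATP-activation and NAD-reduction side branches pulling the carriers
into the core); planted bridges of chosen length and multiplicity are the
only inter-subsystem connections; planted biosynthesis routes (steps drawn
from isomerize / aminate / ATP-activate / NAD-reduce) fix the minimal
subnetworks, lumps, and cost vectors; an exchange layer with transporters,
an optional alternative carbon source, an optional medium-supplied building
block, and an optional substrate with a unique three-reaction catabolic
route cover the media and exchange analyses; dead-end distractor chains
enlarge the search space without touching the truth. All internal reactions
are elementally balanced and the build refuses a spec that would plant an
unbalanced one.

What the toys deliberately do not emulate: realistic network density and
redundancy, thermodynamic or regulatory constraints, gene–protein–reaction
logic, charge states, and the namespace noise of real reconstructions.
Passing the fixture batteries therefore certifies the *algorithms* (graph
search against exhaustive depth-bounded enumeration, MILP enumeration
against exhaustive subset search with LP feasibility checks, lump balance
against elemental bookkeeping), not the biological realism of any
particular curated list. The brute-force oracles are guarded to small
problems (path depth ≤ 4, ≤ 60 reactions; ≤ 25 non-core reactions) and are
test-only code paths.

## Problem sizes and numerical settings

Property batteries run on 10–25 seeded toy models per check (2–3
subsystems, 3–4 metabolites each, ≤ ~45 reactions), chosen so the
exhaustive oracles stay exact companions to the implementation. Flux
tolerance 1e-6 throughout; lump coefficient drop 1e-9; lump uniqueness
1e-6; MILP integrality 1e-6. GLPK is deterministic for a fixed model
construction order, and every generator decision flows from a single
integer seed, so full pipeline runs reproduce byte-identical outputs — this
is itself a tested property.

## Known limitations

* The MILP uses big-M coupling; pathological bound magnitudes (≫ 1000 on
  unbounded reactions) could admit indicator leakage. The enumeration reads
  active sets from flux supports, which mitigates but does not formally
  eliminate this on badly scaled models.
* Alternative-optimum enumeration is complete only up to the configured cap
  and k_relax; truncation is flagged, never silent.
* Thermodynamic feasibility of subnetworks is out of scope: a minimal
  balanced subnetwork may be thermodynamically blocked in vivo.
* Compartment stripping relies on the declared compartment attribute and
  common id conventions (`_c`, `[c]`); exotic identifier schemes pass
  through unchanged rather than being guessed.
* Cross-database identifier reconciliation is a lookup-table operation
  supplied by the user; the package does not attempt automated matching.
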