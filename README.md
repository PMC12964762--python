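# gemreduce

Reduce genome-scale metabolic models (GEMs) to comparable functional
modules, and compare organisms module by module.

Raw GEMs — hundreds to thousands of reactions, inconsistent subsystem
annotations, organism-specific compartments — resist direct comparison.
`gemreduce` follows the classical partition of microbial metabolism into
**fueling**, **biosynthesis**, and **exchange**, and makes each level
quantitatively comparable:

1. **Core networks.** Curated metabolite lists define the central
   subsystems; a reaction belongs to a subsystem when all of its reactants
   and products (excluding inorganics and turning-over cofactor pairs) are
   in the list. The resulting D₀ core is expanded by a directed graph
   search that adds all inter-subsystem connecting paths of up to D
   reactions, giving nested D₁ ⊆ D₂ ⊆ … cores.
2. **Biosynthetic subnetworks.** For each biomass building block (BBB), a
   mixed-integer program enumerates all minimal balanced sets of non-core
   reactions that sustain unit production of the target from the core, with
   core metabolites as free boundary species. Each subnetwork is lumped
   into one net reaction, from which the biosynthetic cost — moles of the
   twelve canonical precursor metabolites plus net ATP/NADH/NADPH per mole
   of target — is read off.
3. **Exchange subnetworks.** The same machinery connects extracellular
   substrates to the core at forced unit uptake, and summarizes each
   substrate's fate by the co-substrates consumed and byproducts secreted.

At every level, organisms are compared with the Jaccard index
J(A, B) = |A ∩ B| / |A ∪ B| on reaction or metabolite sets, with or without
compartment tags.

Intended for microbial physiologists and microbiome modelers who want
mechanistic, network-level comparisons (conserved pathways, auxotrophies,
cross-feeding potential) rather than gene-content profiles.

## Worked example

The package ships a generator of small, elementally balanced toy GEMs with
fully known ground truth (`gemreduce.fixtures`), which also powers the test
suite. The same calls work on any cobra-readable model.

```python
import gemreduce as gr

toy = gr.make_toy_gem(gr.ToyGemSpec(seed=7, substrate_route=True,
    planted_bbb_routes=(gr.Route("bbb0", kinds=("aminate", "phos"),
                                 n_alternatives=2),)))
g = toy.model

d0 = gr.build_d0(g, toy.subsystem_defs, toy.exclusions)
print(f"D0 core: {len(d0.reactions)} reactions, {len(d0.metabolites)} metabolites")
for d in gr.pairwise_distances(g, d0, toy.exclusions, d_max=3):
    label = d.min_distance if d.connected else "unconnected"
    print(f"  {'-'.join(sorted(d.subsystem_pair))}: distance {label} "
          f"({d.n_min_paths} minimal path(s))")

result = gr.enumerate_min_subnetworks(g, d0, "bbb0_c", toy.medium)
uniq = gr.unique_lumps([gr.lump(sn, g) for sn in result])
print(f"bbb0_c: {len(result)} minimal subnetwork(s), {len(uniq)} unique lump(s)")
print(f"  lump: {uniq[0].equation()}")
cost = gr.biosynthetic_cost(uniq, precursors=("m0_1",),
                            inorganics=toy.exclusions.inorganics)
print(f"  cost: {cost.precursor_moles['m0_1']:g} mol precursor, "
      f"{cost.atp:g} ATP, {cost.nadh:g} NADH")
```

prints

```
D0 core: 12 reactions, 18 metabolites
  SS0-SS1: distance 2 (1 minimal path(s))
  SS0-SS2: distance unconnected (0 minimal path(s))
  SS1-SS2: distance unconnected (0 minimal path(s))
bbb0_c: 2 minimal subnetwork(s), 1 unique lump(s)
  lump: 1 atp_c + 1 m0_1_c + 1 nh3_e --> 1 adp_c + 1 bbb0_c
  cost: 1 mol precursor, 1 ATP, 0 NADH
```

Reading this: the three planted subsystems connect only through the one
planted two-reaction bridge; the building block `bbb0` has two alternative
minimal routes (the step order differs) that lump to the same net
reaction — one mole of the core precursor `m0_1`, one ammonia, and one ATP
per mole of product — so its biosynthetic cost is 1 precursor + 1 ATP.

## Command line

A thin CLI drives the workflow from a YAML configuration (model paths,
subsystem/exclusion configs, media, D, k_relax, caps):

```sh
gemreduce fixtures --seed 7 --out fixtures/        # toy GEM + ground truth
gemreduce core    --config run.yaml                # D0/D cores, distances, similarity
gemreduce lump    --config run.yaml                # BBB subnetworks, lumps, costs
gemreduce connect --config run.yaml                # substrate fates, capability matrix
gemreduce compare --config run.yaml                # per-BBB cross-organism Jaccard
gemreduce all     --config run.yaml
```

Outputs are TSV/JSON with a provenance header (solver, every tunable
parameter), and reruns with the same configuration are byte-identical.
Curated BiGG-namespace subsystem lists, exclusion lists, and the precursor
set ship in `src/gemreduce/data/` and are plain YAML, meant to be edited.

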