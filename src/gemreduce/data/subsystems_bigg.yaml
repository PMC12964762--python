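# Curated metabolite lists (BiGG base identifiers, no compartment tags) for
# the five central-carbon subsystems. Lists are derived from the KEGG module
# definitions named under `modules` and mapped to BiGG by hand; edit freely.
# Oxidative phosphorylation is carrier-defined (see exclusions_bigg.yaml).
glycolysis_gluconeogenesis:
  modules: [M00001, M00002, M00003]
  metabolites:
    - glc__D
    - g6p
    - f6p
    - fdp
    - dhap
    - g3p
    - 13dpg
    - 3pg
    - 2pg
    - pep
    - pyr
pentose_phosphate_pathway:
  modules: [M00004, M00005, M00008, M00166, M00167]
  metabolites:
    - g6p
    - 6pgl
    - 6pgc
    - ru5p__D
    - r5p
    - xu5p__D
    - s7p
    - e4p
    - g3p
    - f6p
    - 2ddg6p
tca_cycle:
  modules: [M00009]
  metabolites:
    - cit
    - acon_C
    - icit
    - akg
    - succoa
    - succ
    - fum
    - mal__L
    - oaa
    - accoa
pyruvate_metabolism:
  modules: [M00307, M00579, M00172]
  metabolites:
    - pyr
    - accoa
    - actp
    - ac
    - acald
    - etoh
    - lac__D
    - lac__L
    - for
    - oaa
    - mal__L
oxidative_phosphorylation:
  mode: electron_carriers
  modules: []
  metabolites: []
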