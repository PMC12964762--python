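# The twelve canonical biosynthetic precursor metabolites (BiGG base ids)
# from which all biomass building blocks are costed: glucose-6-P,
# fructose-6-P, ribose-5-P, erythrose-4-P, triose-P, 3-phosphoglycerate,
# phosphoenolpyruvate, pyruvate, acetyl-CoA, oxaloacetate, 2-oxoglutarate,
# succinyl-CoA.
precursors:
  - g6p
  - f6p
  - r5p
  - e4p
  - g3p
  - 3pg
  - pep
  - pyr
  - accoa
  - oaa
  - akg
  - succoa
# Carrier accounting: ATP cost counts net ADP production plus twice net AMP
# production; NADH/NADPH are net and signed (negative = produced).
carriers:
  atp:
    adp: 1.0
    amp: 2.0
  nadh:
    nadh: -1.0
  nadph:
    nadph: -1.0
# The ten extracellular carbon compounds of the default substrate pool,
# plus citrate for community studies.
substrate_pool:
  - glc__D
  - ac
  - lac__D
  - pyr
  - succ
  - fum
  - etoh
  - mal__L
  - for
  - akg
substrate_pool_community_extra:
  - cit
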