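# Global exclusion lists (BiGG base identifiers).
# inorganics: never counted when deciding subsystem membership, and unusable
#   as graph-search intermediates.
# cofactor_pairs: removed from a reaction's member set only when both
#   members appear on opposite sides (donor/acceptor turnover); members are
#   unusable as graph-search intermediates.
# electron_carriers: define oxidative phosphorylation (quinone/quinol and
#   cytochrome oxidized/reduced forms, BiGG conventions).
inorganics:
  - h
  - h2o
  - co2
  - o2
  - nh4
  - pi
  - ppi
  - hco3
  - h2s
  - so4
  - so3
  - no2
  - no3
  - n2
  - h2
  - fe2
  - fe3
  - k
  - na1
  - mg2
  - ca2
  - cl
  - zn2
  - cu2
  - mn2
  - cobalt2
  - mobd
cofactor_pairs:
  - [atp, adp]
  - [adp, amp]
  - [gtp, gdp]
  - [ctp, cdp]
  - [utp, udp]
  - [itp, idp]
  - [nad, nadh]
  - [nadp, nadph]
  - [fad, fadh2]
  - [fmn, fmnh2]
  - [gthox, gthrd]
  - [thf, mlthf]
  - [amet, ahcys]
electron_carriers:
  - q8
  - q8h2
  - q6
  - q6h2
  - mql8
  - mqn8
  - 2dmmql8
  - 2dmmq8
  - dmmql8
  - dmmq8
  - focytb
  - ficytb
  - focytb5
  - ficytb5
  - focytb561
  - ficytb561
  - focytc
  - ficytc
  - focytc553
  - ficytc553
  - focytcc553
  - ficytcc553
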