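# Default trophic-group marker scheme for pond seston and zooplankton
# lipid fractions.  Rules are evaluated in order; the first match wins, so
# a fatty acid is assigned to at most one group.
#
# - fungi:     16:1ω5 (any cis/trans annotation)
# - bacteria:  straight-chain 15:0, all iso-/anteiso-branched FA, hydroxy
#              FA, cyclopropyl FA, and 18:1ω8 (type II methanotrophs)
# - autotrophs: C16 and C18 polyunsaturated FA
#
# Straight-chain odd FAs other than 15:0 are deliberately NOT bacterial
# markers: the enumeration is exhaustive.
rules:
  - group: fungi
    fa: "16:1ω5"
  - group: bacteria
    fa: "15:0"
  - group: bacteria
    tag: iso_anteiso
  - group: bacteria
    tag: hydroxy
  - group: bacteria
    tag: cyclopropyl
  - group: bacteria
    fa: "18:1ω8"
  - group: autotrophs
    tag: C16_PUFA
  - group: autotrophs
    tag: C18_PUFA
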