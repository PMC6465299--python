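# Sorting-signal definitions used by the motif scanner.
#
# regex classes use Python regular-expression syntax over upper-case one-letter
# amino-acid codes; all overlapping matches are reported. The KFERQ-related
# (chaperone-mediated autophagy) class is compositional rather than positional
# and is defined by the rule block below: a pentapeptide containing a glutamine
# whose remaining four residues comprise 1-2 basic, 1-2 hydrophobic and at most
# one acidic residue.

regex:
  tyrosine_YXXphi: "Y..[LIMFV]"
  dileucine: "[DE]...L[LI]"
  caveolin_binding: "[FWY].[FWY]....[FWY]|[FWY]....[FWY]..[FWY]"
  ALIX_YPXnL: "YP.{1,3}L"

kferq_rule:
  length: 5
  anchor: "Q"
  basic: "KR"
  basic_count: [1, 2]
  hydrophobic: "FILV"
  hydrophobic_count: [1, 2]
  acidic: "DE"
  acidic_max: 1
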