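# Functional categories of the 35 maize mitochondrial protein-coding genes,
# used to group per-site classifications into complex-level summary rows.
# Categories appear in reporting order. Editable: supply your own map for a
# different genome or nomenclature.
categories:
  complex I: [nad1, nad2, nad3, nad4, nad4L, nad5, nad6, nad7, nad9]
  cob-complex III: [cob]
  complex IV: [cox1, cox2, cox3]
  complex V: [atp1, atp4, atp6, atp8, atp9]
  cytochrome c biogenesis: [ccmB, ccmC, ccmFc, ccmFn]
  ribosomal protein: [rpl2, rpl5, rpl16, rps1, rps2A, rps2B, rps3, rps4, rps7, rps12, rps13]
  matR: [matR]
  mttB: [mttB]
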