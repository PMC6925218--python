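# Canonical murine cell-cycle phase gene lists (editable).
# Four phase sets expressed sequentially over the cycle; scoring z-scores
# each list across cells and assigns the argmax phase.
G1:
  - Ccnd1
  - Ccnd2
  - Ccne1
  - Cdk4
  - Cdk6
  - Cdc25a
  - E2f1
  - Mybl2
  - Cdt1
  - Slbp
  - Gins2
  - Mcm2
S:
  - Pcna
  - Mcm5
  - Mcm6
  - Rrm1
  - Rrm2
  - Fen1
  - Gmnn
  - Tyms
  - Dhfr
  - Chaf1b
  - Uhrf1
  - Hells
G2:
  - Ccna2
  - Cdk1
  - Top2a
  - Ndc80
  - Nusap1
  - Tpx2
  - Aurkb
  - Birc5
  - Kif11
  - Cks2
  - Smc4
  - Ect2
M:
  - Ccnb1
  - Ccnb2
  - Cdc20
  - Plk1
  - Aurka
  - Bub1
  - Cenpa
  - Cenpe
  - Anln
  - Ube2c
  - Hmmr
  - Mki67
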