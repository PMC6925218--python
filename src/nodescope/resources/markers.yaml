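# Default marker configuration for cluster-level cell-type labeling.
# A cell is marker-positive when its log-normalized expression exceeds the
# threshold; a cluster takes the cell type with the highest mean positive
# fraction across its markers (if above min_fraction).
min_fraction: 0.5
cell_types:
  astrocyte:
    Gfap: 1.0
    Aqp4: 1.0
    Slc1a3: 1.0
  oligodendrocyte:
    Sox10: 1.0
    Olig1: 1.0
    Mbp: 1.0
  microglia:
    Cx3cr1: 1.0
    Aif1: 1.0
    Csf1r: 1.0
  endothelial:
    Pecam1: 1.0
    Cldn5: 1.0
    Flt1: 1.0
  fibroblast:
    Col1a1: 1.0
    Dcn: 1.0
    Lum: 1.0
  pericyte:
    Pdgfrb: 1.0
    Rgs5: 1.0
    Kcnj8: 1.0
  cgnp_tumor:
    Atoh1: 0.5
    Gli1: 0.5
    Sfrp1: 0.5
    Rbfox3: 0.5
    Cntn2: 0.5
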