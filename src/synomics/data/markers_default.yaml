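# Surrogate transcriptomic marker lists for bulk deconvolution scoring.
# These are small literature-derived defaults for the cell populations the
# analyses stratify on; they are NOT the published deconvolution tool's
# proprietary lists.  Edit freely or supply your own file.
B:
  - MS4A1
  - CD79A
  - CD79B
  - CD19
  - TNFRSF13B
T_CD8:
  - CD8A
  - CD8B
  - CD3D
  - CD3E
  - GZMK
NK:
  - NKG7
  - KLRD1
  - GNLY
  - NCR1
monocyte_macrophage:
  - CD68
  - CD163
  - CSF1R
  - MSR1
  - MRC1
mDC:
  - FCER1A
  - CD1C
  - CLEC10A
  - ITGAX
neutrophil:
  - FCGR3B
  - CSF3R
  - S100A8
  - FPR1
endothelial:
  - PECAM1
  - VWF
  - CDH5
  - CLDN5
fibroblast:
  - COL1A1
  - COL3A1
  - PDGFRB
  - THY1
  - FAP
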