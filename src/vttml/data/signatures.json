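{
  "javelin_angio": {
    "description": "Javelin Renal 101 Angio signature",
    "genes": ["NRARP", "RAMP2", "ARHGEF15", "VIP", "NRXN3", "KDR", "SMAD6", "KCNAB1", "CALCRL", "NOTCH4", "AQP1", "RAMP3", "TEK", "FLT1", "GATA2", "CACNB2", "ECSCR", "GJA5", "ENPP2", "CASQ2", "PTPRB", "TBX2", "ATP1A2", "CD34", "HEY2", "EDNRB"]
  },
  "javelin_immuno": {
    "description": "Javelin Renal 101 Immuno signature",
    "genes": ["CD3G", "CD3E", "CD8B", "THEMIS", "TRAT1", "GRAP2", "CD247", "CD2", "CD96", "PRF1", "CD6", "IL7R", "ITK", "GPR18", "EOMES", "SIT1", "NLRC3", "CD244", "KLRD1", "SH2D1A", "CCL5", "XCL2", "CST7", "GFI1", "KCNA3", "PSTPIP1"]
  },
  "immotion_angio": {
    "description": "IMmotion151 Angio (clusters C1/C2) signature",
    "genes": ["VEGF-A", "KDR", "ESM1", "PECAM1", "ANGPTL4", "CD34", "FAP", "FN1", "COL5A1", "COL5A2", "POSTN", "COL1A1", "COL1A2", "MMP2"]
  },
  "immotion_immuno": {
    "description": "IMmotion151 Immuno (clusters C4/C5) signature",
    "genes": ["CD8A", "EOMES", "PRF1", "IFNG", "CD274", "CDK2", "CDK4", "CDK6", "BUB1B", "CCNE1", "POLQ", "AURKA", "MKI67", "CCNB2"]
  },
  "naxiva_angio": {
    "description": "NAXIVA Angio signature (genes encoding the angiogenic response markers)",
    "genes": ["PGF", "TEK", "PECAM1", "CD34", "VEGF-A"]
  },
  "naxiva_immuno": {
    "description": "NAXIVA Immuno signature (genes encoding the immune non-response markers)",
    "genes": ["CCL17", "IL12A", "IL12B", "IL-7"]
  },
  "nax_pseudo_response": {
    "description": "Pseudo-signature: genes encoding the baseline-model response features (CD31, CD34)",
    "genes": ["PECAM1", "CD34"]
  },
  "nax_pseudo_nonresponse": {
    "description": "Pseudo-signature: genes encoding the baseline-model non-response features (CCL17/CCR4 axis, IL-12p70 subunits)",
    "genes": ["CCL17", "CCR4", "IL12A", "IL12B"]
  }
}
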