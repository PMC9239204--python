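# Default domain vocabulary: role token -> accepted domain accessions/names.
#
# Role tokens are what the classification rules consume; the lists translate
# between Pfam accessions, Pfam names, and SMART-style names so that domain
# tables from different annotation dialects can be used unchanged.  Matching
# is case-insensitive and accession versions (PF00512.31) are ignored.
# No accession/name may appear under two role tokens.
roles:
  HisKA: [PF00512, HisKA, PF07568, HisKA_2, PF07730, HisKA_3]
  HATPase: [PF02518, HATPase_c, PF13581, HATPase_c_2]
  REC: [PF00072, Response_reg, REC]
  Hpt: [PF01627, Hpt, HPT]
  GGDEF: [PF00990, GGDEF]
  EAL: [PF00563, EAL]
  HD_GYP: [PF13487, HD-GYP, HD_GYP]
  # DNA-binding helix-turn-helix output domains of response regulators.
  # A config list, not code: extend freely for other HTH families.
  HTH: [PF00196, GerE, PF00486, Trans_reg_C, PF02954, HTH_8, PF12833,
        HTH_24, PF00165, HTH_AraC, PF01978, TrmB]
  sigma70_r2: [PF04542, Sigma70_r2]
  sigma70_r4_2: [PF08281, Sigma70_r4_2]
  AC: [PF01295, Adenylate_cycl, PF00211, Guanylate_cyc]
  CHASE2: [PF05226, CHASE2]
  cAMP_PDE: [PF00233, PDEase_I, cAMP_PDE, Icc]
  FecR: [PF04773, FecR]
  TonB_receptor: [PF00593, TonB_dep_Rec, PF07715, Plug]
  TPR: [PF00515, TPR_1, PF07719, TPR_2, TPR]
  Pkinase: [PF00069, Pkinase]
  PP2C: [PF00481, PP2Cc, PF07228, SpoIIE]
  STAS: [PF01740, STAS]
  CRP: [PF00027, cNMP_binding, Crp]
  CheW: [PF01584, CheW]
  MCPsignal: [PF00015, MCPsignal, MA]
  CheB_methylest: [PF01339, CheB_methylest]
  CheR: [PF01739, CheR, PF03705, CheR_N]
  CheC: [PF04509, CheC]
  CheX: [CheX]
  CheD: [PF03975, CheD]
  CheZ: [PF04344, CheZ]
  # optional transmembrane/signal annotations (from e.g. TMHMM export rows)
  TM: [TMhelix, TM, transmembrane]
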