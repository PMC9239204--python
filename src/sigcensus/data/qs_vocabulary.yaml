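# Quorum-sensing screen vocabulary: pathway -> diagnostic domains of the
# signal synthase and of the receptor's ligand-binding module.
#
# Best-effort defaults compiled from experimentally studied model organisms
# in other phyla; fully user-overridable.  A pathway is called present only
# when BOTH a synthase-domain hit and a receptor-domain hit exist in the
# genome; a synthase without its receptor (or vice versa) is reported as
# "partial".
pathways:
  AHL:
    synthase: [PF00765, Autoind_synth, HdtS]
    receptor: [PF03472, Autoind_bind]
  AI-2:
    synthase: [PF02664, LuxS]
    receptor: [LuxP, LuxQ_periplasm]
  CAI-1:
    synthase: [CqsA]
    receptor: [CqsS_6TM]
  DSF:
    synthase: [RpfF]
    receptor: [RpfC_sensor]
  PQS:
    synthase: [PqsA, PqsBC]
    receptor: [PqsR_LBD]
  AIP:
    synthase: [AgrB, AgrD]
    receptor: [AgrC_sensor]
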