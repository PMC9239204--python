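# Chemosensory class signatures: configurable gene-order patterns.
#
# Token alphabet (one token = one gene): A cheA, B cheB, C cheC, D cheD,
# K a histidine-kinase gene, M chemoreceptor, R cheR, S a single-STAS-domain
# gene, V cheV, W cheW, X cheX, Y cheY, Z cheZ, "." one hypothetical /
# unrelated gene.
#
# F3 is transcribed from the text definition: core cheVAW operon, CheA
# carrying an extra REC domain, and an auxiliary CheB lacking REC anywhere
# in the genome.  The F7/F8/F9/F14 gene orders are figure-derived,
# best-effort defaults: they exist only graphically in the source figure and
# should be overridden by users with access to the original scheme.  The F9
# order is anchored on the textual half-F9 component list (chemoreceptor,
# CheW, CheB, CheR, lacking its own kinase and response regulator).
#
# required_components must be a subset of the components named by gene_order
# tokens; auxiliary_rules are searched genome-wide.
signatures:
  - class_name: F3
    priority: 0
    gene_order: [V, A, W]
    required_components: [CheV, CheA, CheW]
    auxiliary_rules: [CheA_has_REC, CheB_lacks_REC]
    max_insertions: 2
  - class_name: F7
    priority: 1
    gene_order: [A, W, Y, M, B, R]   # figure-derived, best effort
    required_components: [CheA, CheW, CheY, MCP, CheB, CheR]
    auxiliary_rules: []
    max_insertions: 2
  - class_name: F8
    priority: 2
    gene_order: [Y, A, W, M, B, R]   # figure-derived, best effort
    required_components: [CheY, CheA, CheW, MCP, CheB, CheR]
    auxiliary_rules: []
    max_insertions: 2
  - class_name: F9
    priority: 3
    gene_order: [M, W, B, R, A, Y]   # anchored on the half-F9 component list
    required_components: [MCP, CheW, CheB, CheR, CheA, CheY]
    auxiliary_rules: []
    max_insertions: 2
  - class_name: F14
    priority: 4
    gene_order: [K, S, M, W, A, B, R]  # figure-derived, best effort
    required_components: [HK, STAS, MCP, CheW, CheA, CheB, CheR]
    auxiliary_rules: []
    max_insertions: 2
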