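# Default gene-class cull rules, applied in order (first match wins).
# A gene is culled when its class label is listed or its symbol matches
# the regex.  Covers classes untestable with germline RNAi lines plus
# ribosomal structural proteins (ubiquitously expressed).
rules:
  - name: mitochondrial
    classes: [mitochondrial]
    symbol_regex: '^mt:'
  - name: CR_pseudogene
    classes: [pseudogene]
    symbol_regex: '^CR\d+'
  - name: asRNA
    classes: [asRNA]
    symbol_regex: '^asRNA:'
  - name: hpRNA
    classes: [hpRNA]
    symbol_regex: '^hpRNA:'
  - name: snRNA
    classes: [snRNA]
    symbol_regex: '^snRNA:'
  - name: snRNP
    classes: [snRNP]
    symbol_regex: '^snRNP:'
  - name: snmRNA
    classes: [snmRNA]
    symbol_regex: '^snmRNA:'
  - name: snoRNA
    classes: [snoRNA]
    symbol_regex: '^snoRNA:'
  - name: lncRNA
    classes: [lncRNA]
    symbol_regex: '^lncRNA:'
  - name: sisRNA
    classes: [sisRNA]
    symbol_regex: '^sisRNA:'
  - name: pre_rRNA
    classes: [pre_rRNA, rRNA]
    symbol_regex: '^pre-rRNA'
  - name: ribosomal_structural
    classes: [ribosomal_protein]
    symbol_regex: '^m?Rp[LS](\d|P)'
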