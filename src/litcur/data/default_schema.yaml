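# Default variant-curation project schema.
# Concept groups: Gene, Disease, Variation (SNV / InDel / Rearrangement),
# and clinical attributes of a variant.  Normalization sources: HGNC for
# genes, OMIM for diseases, dbSNP for SNVs, UMLS CUIs for clinical
# attributes.  InDel and Rearrangement are not normalized.
concept_types:
  - name: Gene
    normalization_source: HGNC
    color: "#1f77b4"
  - name: Disease
    normalization_source: OMIM
    color: "#d62728"
  - name: SNV
    normalization_source: dbSNP
    color: "#2ca02c"
  - name: InDel
    color: "#98df8a"
  - name: Rearrangement
    color: "#17becf"
  - name: Mode of inheritance
    normalization_source: UMLS
    color: "#9467bd"
  - name: Penetrance
    normalization_source: UMLS
    color: "#8c564b"
  - name: Zygosity
    normalization_source: UMLS
    color: "#e377c2"
  - name: Age of patient
    normalization_source: UMLS
    color: "#7f7f7f"
  - name: Age of onset
    normalization_source: UMLS
    color: "#bcbd22"
relation_types:
  - name: associated
    arguments:
      - {arg1: SNV, arg2: Disease}
      - {arg1: SNV, arg2: Gene}
      - {arg1: SNV, arg2: Mode of inheritance}
      - {arg1: SNV, arg2: Penetrance}
      - {arg1: SNV, arg2: Zygosity}
      - {arg1: SNV, arg2: Age of patient}
      - {arg1: SNV, arg2: Age of onset}
      - {arg1: InDel, arg2: Disease}
      - {arg1: InDel, arg2: Gene}
      - {arg1: InDel, arg2: Mode of inheritance}
      - {arg1: InDel, arg2: Penetrance}
      - {arg1: InDel, arg2: Zygosity}
      - {arg1: Rearrangement, arg2: Disease}
      - {arg1: Rearrangement, arg2: Gene}
      - {arg1: Gene, arg2: Disease}
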