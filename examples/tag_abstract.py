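"""Automatically annotate an abstract-like text.

Dictionary matching finds clinical-attribute values (with their UMLS CUIs),
rule patterns find HGVS-style variant mentions and rs numbers, and age
phrases are picked up by cue-word patterns.  A tiny file-backed variant
index then resolves the SNV mention to its dbSNP-style identifier.
"""

from litcur import (TextDocument, VariantIndexRecord, annotate_document,
                    bundled_clinical_lexicon, compile_lexicon,
                    normalize_variant)

text = ("The proband, aged 34 years, was heterozygous for the c.1521_1523delCTT "
        "variant and also carried rs113993960; the family showed autosomal "
        "recessive inheritance with reduced penetrance and onset at age 5.")
doc = TextDocument("example1", text)

lexicon = compile_lexicon(bundled_clinical_lexicon())
annotations = annotate_document(doc, lexicon=lexicon)

index = [VariantIndexRecord("rs113993960", ["c.1521_1523delCTT"], ["CFTR"])]
for ann in annotations:
    line = f"{ann.ann_id:3s} {ann.concept_type:20s} {ann.surface!r}"
    if ann.normalization:
        line += f"  -> {ann.normalization[0]}:{ann.normalization[1]}"
    elif ann.concept_type == "SNV":
        vid = normalize_variant(ann.surface, "CFTR", index)
        line += f"  -> dbSNP:{vid}" if vid else "  (unnormalized)"
    print(line)
# Each line is one automatic annotation: its type, the exact text span, and
# the identifier it was grounded to (UMLS CUI for attributes, dbSNP id for
# SNVs; insertion-deletions are recognized but not normalized).
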