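"""Round-trip an annotated document through A1 standoff and BioC XML.

A1 keeps text and annotations in separate files; BioC nests everything in
one XML collection and, unlike A1, also carries normalization identifiers.
"""

from litcur import read_a1, read_bioc, write_a1, write_bioc

text = "FGFR3 mutation causes achondroplasia"
a1 = ("T1\tGene 0 5\tFGFR3\n"
      "T2\tDisease 22 36\tachondroplasia\n"
      "R1\tassociated Arg1:T1 Arg2:T2\n")

collection = read_a1(text, a1, doc_id="pmid1")
print("parsed:", len(collection.concepts), "concepts,",
      len(collection.relations), "relation")

xml = write_bioc(collection)
print("--- BioC ---")
print(xml)

back = read_bioc(xml)
(doc_id, (text_out, a1_out)), = write_a1(back).items()
print("--- A1 after BioC round trip ---")
print(a1_out, end="")
print("round trip preserves content:", collection.content_equal(back))
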