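"""Split a 100-document corpus among three curators with 33% overlap.

The shared block is what inter-annotator agreement is later computed on;
the rest is split evenly, remainder documents going to the first curators.
"""

from litcur import partition_corpus

doc_ids = [f"pmid{i:05d}" for i in range(100)]
assignment = partition_corpus(doc_ids, ["alice", "bob", "carol"], overlap_percent=33)

print(f"shared block: {len(assignment.shared)} documents")
for curator, docs in assignment.individual.items():
    print(f"{curator}: {len(docs)} individual documents "
          f"({len(assignment.documents_for(curator))} total)")
print("violations:", assignment.validate(doc_ids) or "none")
# 33 shared + 23/22/22 individual: each curator sees 33% of the corpus in
# common plus roughly 22% alone, and every document is assigned exactly once.
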