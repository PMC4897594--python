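"""Inter-annotator agreement between simulated curators.

A synthetic gold corpus is perturbed into three curator views with known
error rates; the IAA is the mean pairwise F-score over shared documents.
Dialing the error rates up lowers the agreement in a controlled way.
"""

from litcur import CorpusSpec, CuratorProfile, generate_corpus, iaa, simulate_curator

gold = generate_corpus(CorpusSpec(n_docs=50, seed=42))
print(f"gold corpus: {len(gold.documents)} documents, "
      f"{len(gold.concepts)} annotations")

profiles = {
    "careful": CuratorProfile(miss_rate=0.05, spurious_rate=0.2, seed=1),
    "average": CuratorProfile(miss_rate=0.15, spurious_rate=0.5, seed=2),
    "hasty": CuratorProfile(miss_rate=0.30, spurious_rate=1.0,
                            boundary_jitter_rate=0.1, seed=3),
}
views = [simulate_curator(gold, p, curator_id=name)
         for name, p in profiles.items()]

report = iaa(views)
for pair in report.pairwise:
    print(f"{pair.curator_a} vs {pair.curator_b}: "
          f"F = {pair.f1:.3f}  (matches {pair.matches}, "
          f"sizes {pair.size_a}/{pair.size_b})")
print(f"overall IAA: {report.overall:.3f}")
# The overall IAA is the unweighted mean of the three pairwise F-scores;
# pairs involving the hasty curator agree least.
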