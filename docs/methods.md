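# Methods

This note documents the models and procedures implemented in `litcur`, the
parameter choices that matter, and what the synthetic-data validation does
and does not establish.

## Annotation model and offsets

All offsets are 0-based, half-open, counted in Unicode code points of the
immutable document text; a discontinuous mention is an ordered list of
non-overlapping fragments and its recorded surface is the text slices
joined by a single space. Surfaces are cross-checked against the text on
every parse and validation pass, so a collection that validates cleanly is
internally consistent by construction. Annotations are grounded as a
`(source, identifier)` pair — OMIM for diseases, HGNC for genes, dbSNP for
SNVs, UMLS CUIs for clinical attributes — declared per concept type in the
project schema (YAML).

## Formats

**A1 standoff.** T-lines carry id, type, offsets (fragments joined by
`;`) and surface; R-lines carry binary relations. Two dialect decisions:
concept types may contain spaces (e.g. `Mode of inheritance`), which is
unambiguous because the trailing offset groups are all digits and parsed
right-anchored; and A1 has no normalization field (attribute/N-line syntax
is out of scope), so normalization survives BioC round-trips but not A1 —
content-comparison helpers take an `include_normalization` flag for this
reason.

**BioC.** Collection → document → passage XML; annotation offsets are
document-global (the passage `offset` places the passage text when a
document is reconstructed from several passages, gaps filled with spaces).
Infon keys: `type`, `source`, `identifier`, and `provenance` for non-default
provenance. Writers emit one whole-text passage per document.

Both writers renumber ids (T1..Tn in ascending offset, then R1..Rm), which
guarantees valid output for merged collections; round-trips preserve
annotation content exactly, and ids too whenever input ids were already
canonical.

## Tagging

Dictionary matching is leftmost-longest at token boundaries (boundaries are
transitions to/from letter-digit runs). Terms longer than 4 characters
match case-insensitively; terms of ≤ 4 characters match exactly, a guard
against short gene-symbol false positives. Compilation rejects a surface
form mapped to two concept types. The scanner tries, at each token start,
the candidate surfaces sharing that first token from longest to shortest —
equivalent to enumerating all occurrences and resolving leftmost-longest
greedily (property-tested against that brute-force oracle). Case folding
assumes folding preserves string length, which holds for the ASCII lexicons
shipped; whitespace inside a mention must match the lexicon surface
literally.

Variant mentions are recognized by a shipped rule set, one rule class per
variation type: HGVS-like DNA/protein substitutions and rs numbers → SNV
(rs mentions carry themselves as a dbSNP normalization candidate);
del/ins/dup/delins forms → InDel; karyotype-style `t(p;q)` / `inv(n)` and
translocation/inversion/fusion phrases → Rearrangement, with an optional
trailing cue word absorbed so `t(9;22) translocation` is one mention. These
rules are a transparent, deterministic recognizer; no accuracy parity with
trained sequence models is claimed. On overlap, variant matches beat
dictionary and age matches (the more specific recognizer wins); ages are
recognized by cue-word patterns (`aged 34 years`, `12-year-old` → patient
age C0001779; `onset at age 5`, `presented at 7` → onset age C0206132),
since the attribute inventory assigns CUIs but no recognition procedure for
ages.

SNV normalization looks a case-folded, whitespace-stripped mention up among
each index record's HGVS names; a gene context restricts multi-record hits
by gene symbol and remaining ambiguity yields abstention (`None`), never an
error. Insertion-deletions and rearrangements are deliberately not
normalized. When normalizing tagged documents, the gene context heuristic
is the nearest preceding gene annotation — a heuristic, flagged as such.

## Corpus partitioning

`floor(overlap/100 × N)` documents form the shared block; the remainder is
split as `floor((N−S)/n)` per curator with the `r` leftover documents
appended one each to the first `r` curators in input order. Floor is the
only rounding consistent with the canonical worked example (100 documents,
3 curators, 33% → 33 shared + 23/22/22). Assignment follows corpus input
order with no shuffling, so partitions are reproducible; callers wanting
random partitions shuffle first. Manual partitions are supported as direct
`Assignment` construction plus invariant validation (disjoint blocks
covering the corpus, individual sizes within 1).

## Agreement

The default match criterion is strict — identical fragments and identical
type; normalization is ignored — because it is the strictest reproducible
choice; an any-overlap mode is available. Under exact matching, match keys
are equivalence classes, so counting `min` of multiset multiplicities is a
maximum one-to-one matching (tested against maximum bipartite matching).
Pair scores micro-average counts over shared documents; the overall IAA is
the unweighted mean F over pairs sharing ≥ 1 document. A pair with both
sets empty over its shared documents scores a vacuous 1.0 and is flagged,
avoiding 0/0 while letting users exclude such pairs. Relations are excluded
from IAA by default.

## Evaluation and the paired t-test

Automatic output is scored per concept type with each curator as reference
and the results macro-averaged across curators (micro available).
Condition summaries compute per-curator totals and ratios (ratios with a
zero denominator are reported absent), then pool by unweighted mean across
curators with data in the condition. The one-tailed paired t-test uses one
pair per curator, `t = mean(d)/(sd(d)/√n)`, df = n−1, with the tail chosen
by the caller (faster-when-assisted is `direction="greater"` for
non-assisted minus assisted times); zero-variance differences are a
degenerate-input error.

## Synthetic data

The generator emulates a variant-curation study at desk scale: 100
template documents of 3–8 sentences with 2–6 planted mentions each (drawn
from the bundled attribute lexicon and a set of HGVS-style variant forms),
decoy filler words filtered so they can never assemble into a lexicon
term. Planted mentions are recorded as gold annotations with exact offsets
and normalizations. Simulated curators drop gold annotations
independently (miss rate), jitter boundaries by 1–3 characters, swap
types, and add Poisson-distributed spurious annotations on unoccupied
tokens. Curation logs model per-document time as
`12 s × max(concepts, 1) × curator speed factor (lognormal σ=0.2) ×
lognormal noise (σ=0.35)`, floored at 30 s, divided by the assisted
speed-up (default 1.5) in the assisted condition; 12 s/concept matches the
magnitude of per-concept curation times reported for comparable workflows.
Each curator receives an independent seeded half/half assisted split —
with a split shared across curators, any concept-count imbalance between
halves would bias every curator identically and the paired t-test would be
anticonservative under the null; independent splits keep the null p-value
uniform (verified by KS test over 200 replicates). A master seed is split
into per-document and per-curator streams, so adding a curator never
changes existing ones.

What passing the synthetic validation shows: the statistics recover
planted parameters (a 20% miss rate appears as ≈ 0.8 recall within
binomial bounds; a 1.5× speed-up is detected with high power; no speed-up
yields uniform p), and all generated artifacts satisfy the model
invariants and survive both formats. What it does not show: performance on
natural language — the templates have no syntax, no ambiguous mentions, no
coordination, no abbreviations — so tagger accuracy numbers on synthetic
text do not transfer to real abstracts.

## Problem sizes and numerics

Validation runs use 100–220 document corpora (≥ 500 gold annotations where
binomial bounds are asserted), 500 fuzzed collections for round-trip
checks, 100 replicates for power and 200 for null calibration; these sizes
make all statistical assertions sharp at desk scale. Tolerances: t-test
agreement with the closed form / reference implementation at 1e-9–1e-6;
binomial 99% bounds for recall recovery; KS p > 0.001 plus the 99% CI of
the mean for null uniformity. Ties in emission order are broken by
(fragments, type, id); degenerate inputs (empty corpora, zero-concept
documents, zero-variance differences) raise informative errors or, where
absence is meaningful (normalization misses, zero-denominator ratios), are
values.

## Known limitations

No chance-corrected agreement coefficients (F-score only, by design); no
ML-based variant recognition; no live terminology services — lexicons and
variant indexes are file-backed snapshots; A1 drops normalization; BioC is
read/written at passage granularity only; age recognition is pattern-based
and English-specific.
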