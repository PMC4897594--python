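"""Synthetic curation-study data.

Real curation studies hinge on curator behaviour that is rarely
distributed: who annotated what, where they disagreed, how long each
document took.  This module generates that substrate with known ground
truth so every other module can be exercised end to end:

* corpora of template documents with planted gold annotations (dictionary
  terms with their normalization ids, and variant surface forms),
* simulated curators who perturb the gold standard with controlled miss /
  spurious / boundary-jitter / type-confusion rates,
* synthetic curation logs contrasting assisted and unassisted conditions
  with a configurable speed-up.

Texts are template-based (decoy filler tokens around planted surface
forms), not natural language; every consumer downstream operates on
offsets and surface forms, for which this is sufficient.  A master seed is
split deterministically into per-document and per-curator streams, so
adding a curator never perturbs previously generated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .agreement import AnnotationSetView
from .evaluation import CurationLogEntry
from .formats import AnnotatedCollection
from .model import (ConceptAnnotation, RelationAnnotation, TextDocument,
                    surface_from_text)
from .tagger import LexiconEntry, bundled_clinical_lexicon

__all__ = [
    "CorpusSpec",
    "CuratorProfile",
    "DEFAULT_VARIANT_FORMS",
    "DEFAULT_DECOYS",
    "generate_corpus",
    "simulate_curator",
    "generate_curation_log",
    "random_collection",
]

#: Variant surface forms planted by default, with their expected class.
DEFAULT_VARIANT_FORMS: tuple[tuple[str, str], ...] = (
    ("c.76A>T", "SNV"),
    ("c.118C>T", "SNV"),
    ("g.31224G>A", "SNV"),
    ("p.Gly12Asp", "SNV"),
    ("p.R117H", "SNV"),
    ("rs113993960", "SNV"),
    ("rs334", "SNV"),
    ("c.35delG", "InDel"),
    ("c.1521_1523delCTT", "InDel"),
    ("p.Phe508del", "InDel"),
    ("c.3067dupA", "InDel"),
    ("t(9;22) translocation", "Rearrangement"),
    ("inv(16)", "Rearrangement"),
)

#: Filler vocabulary; none of these words occurs inside any bundled lexicon
#: surface form, so decoys can never assemble into a dictionary term.
DEFAULT_DECOYS: tuple[str, ...] = (
    "patients", "study", "analysis", "observed", "clinical", "report",
    "family", "affected", "individuals", "mutation", "screening", "cohort",
    "results", "findings", "exon", "sequencing", "identified", "novel",
    "phenotype", "expression", "probands", "segregation", "carriers",
    "missense", "pathogenic", "likely", "detected", "present", "absent",
    "gene", "region", "chromosome", "syndrome", "disorder", "condition",
)


@dataclass
class CorpusSpec:
    """Parameters of a synthetic corpus with planted gold annotations.

    Defaults emulate a curation corpus of abstracts: 100 documents of 3-8
    sentences with 2-6 planted mentions each, drawn from the bundled
    clinical-attribute lexicon and the default variant forms.
    """

    n_docs: int = 100
    sentences_per_doc: tuple[int, int] = (3, 8)
    planted_terms_per_doc: tuple[int, int] = (2, 6)
    lexicon: list[LexiconEntry] = field(default_factory=bundled_clinical_lexicon)
    variant_forms: tuple[tuple[str, str], ...] = DEFAULT_VARIANT_FORMS
    decoy_vocabulary: tuple[str, ...] = DEFAULT_DECOYS
    relation_probability: float = 0.3  # chance of a co-occurrence relation per doc
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        for lo, hi in (self.sentences_per_doc, self.planted_terms_per_doc):
            if not (1 <= lo <= hi):
                raise ValueError("ranges must be non-empty with lo >= 1")
        if not self.lexicon and not self.variant_forms:
            raise ValueError("need a lexicon and/or variant forms to plant")


@dataclass
class CuratorProfile:
    """Error profile of a simulated curator.

    ``miss_rate``: probability a gold annotation is dropped.
    ``spurious_rate``: expected extra (wrong) annotations per document.
    ``boundary_jitter_rate``: probability a kept annotation's span is
    shifted by 1-3 characters.  ``type_confusion_rate``: probability a kept
    annotation's concept type is swapped for another.
    """

    miss_rate: float = 0.0
    spurious_rate: float = 0.0
    boundary_jitter_rate: float = 0.0
    type_confusion_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("miss_rate", "boundary_jitter_rate", "type_confusion_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be >= 0")


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _clean_decoys(spec: CorpusSpec) -> list[str]:
    """Drop decoys whose words occur inside any plantable surface form."""
    lexicon_words = set()
    for entry in spec.lexicon:
        for surface in entry.surfaces():
            lexicon_words.update(w.casefold() for w in surface.split())
    for surface, _ in spec.variant_forms:
        lexicon_words.update(w.casefold() for w in surface.split())
    decoys = [d for d in spec.decoy_vocabulary if d.casefold() not in lexicon_words]
    if not decoys:
        raise ValueError("decoy vocabulary entirely collides with plantable terms")
    return decoys


def generate_corpus(spec: CorpusSpec) -> AnnotatedCollection:
    """Generate documents with gold annotations at recorded offsets.

    Deterministic given ``spec.seed``.  Every planted mention becomes a
    gold :class:`ConceptAnnotation` whose surface equals its text slice;
    dictionary terms carry their ``(source, concept_id)`` normalization,
    rs-number variant forms their dbSNP id.  With probability
    ``relation_probability`` a document with two or more gold annotations
    also gets one co-occurrence 'associated' relation.
    """
    decoys = _clean_decoys(spec)
    plantables: list[tuple[str, str, Optional[tuple[str, str]]]] = []
    for entry in spec.lexicon:
        for surface in entry.surfaces():
            plantables.append((surface, entry.concept_type,
                               (entry.source, entry.concept_id)))
    for surface, ctype in spec.variant_forms:
        token = surface.split()[0]
        norm = ("dbSNP", token) if token.startswith("rs") and token[2:].isdigit() else None
        plantables.append((surface, ctype, norm))

    documents: list[TextDocument] = []
    concepts: list[ConceptAnnotation] = []
    relations: list[RelationAnnotation] = []
    for doc_index in range(spec.n_docs):
        rng = _rng(spec.seed, 1, doc_index)
        doc_id = f"doc{doc_index + 1:04d}"
        n_sent = int(rng.integers(spec.sentences_per_doc[0],
                                  spec.sentences_per_doc[1] + 1))
        sentences: list[list[str]] = [
            [decoys[int(i)] for i in rng.integers(0, len(decoys), size=int(rng.integers(4, 11)))]
            for _ in range(n_sent)]
        n_plant = int(rng.integers(spec.planted_terms_per_doc[0],
                                   spec.planted_terms_per_doc[1] + 1))
        planted: list[tuple[int, int, tuple[str, str, Optional[tuple[str, str]]]]] = []
        for _ in range(n_plant):
            item = plantables[int(rng.integers(0, len(plantables)))]
            s = int(rng.integers(0, n_sent))
            pos = int(rng.integers(0, len(sentences[s]) + 1))
            sentences[s].insert(pos, item[0])
            planted.append((s, pos, item))
        # positions shift as later insertions land before earlier ones in
        # the same sentence; recover each planted token by identity below.
        text_parts: list[str] = []
        offset = 0
        token_offsets: dict[tuple[int, int], int] = {}
        for s, tokens in enumerate(sentences):
            for t, token in enumerate(tokens):
                token_offsets[(s, t)] = offset
                text_parts.append(token)
                offset += len(token)
                if t < len(tokens) - 1:
                    text_parts.append(" ")
                    offset += 1
            text_parts.append(". " if s < len(sentences) - 1 else ".")
            offset += 2 if s < len(sentences) - 1 else 1
        text = "".join(text_parts)
        documents.append(TextDocument(doc_id=doc_id, text=text))

        # locate each planted surface by scanning its sentence's tokens
        doc_concepts: list[ConceptAnnotation] = []
        used_slots: set[tuple[int, int]] = set()
        for s, _, (surface, ctype, norm) in planted:
            slot = next((s, t) for t, tok in enumerate(sentences[s])
                        if tok == surface and (s, t) not in used_slots)
            used_slots.add(slot)
            start = token_offsets[slot]
            fragments = ((start, start + len(surface)),)
            doc_concepts.append(ConceptAnnotation(
                ann_id="", doc_id=doc_id, concept_type=ctype,
                fragments=fragments, surface=surface_from_text(text, fragments),
                normalization=norm, provenance="automatic"))
        doc_concepts.sort(key=lambda a: a.fragments)
        doc_concepts = [a.with_id(f"T{i}") for i, a in enumerate(doc_concepts, 1)]
        concepts.extend(doc_concepts)
        if len(doc_concepts) >= 2 and rng.random() < spec.relation_probability:
            i, j = rng.choice(len(doc_concepts), size=2, replace=False)
            relations.append(RelationAnnotation(
                rel_id="R1", doc_id=doc_id, relation_type="associated",
                arg1=doc_concepts[int(i)].ann_id, arg2=doc_concepts[int(j)].ann_id))
    return AnnotatedCollection(documents=documents, concepts=concepts,
                               relations=relations)


# ---------------------------------------------------------------------------
# simulated curators
# ---------------------------------------------------------------------------

def _jitter_fragment(rng: np.random.Generator, start: int, end: int,
                     text_len: int) -> tuple[int, int]:
    for _ in range(10):
        shift = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
        if rng.random() < 0.5:
            new = (max(0, min(start + shift, end - 1)), end)
        else:
            new = (start, max(start + 1, min(end + shift, text_len)))
        if new != (start, end):
            return new
    return (start, end)


def simulate_curator(gold: AnnotatedCollection, profile: CuratorProfile,
                     curator_id: str = "curator") -> AnnotationSetView:
    """Perturb a gold collection into one curator's annotation view.

    Each gold annotation is independently dropped with ``miss_rate``;
    survivors get a 1-3 character boundary shift with
    ``boundary_jitter_rate`` and a concept-type swap with
    ``type_confusion_rate``; ``Poisson(spurious_rate)`` extra annotations
    per document are placed on token spans not overlapping any other
    annotation.  Deterministic given ``profile.seed``.
    """
    import re
    token_re = re.compile(r"[^\W_]+")
    all_types = sorted({a.concept_type for a in gold.concepts}) or ["Concept"]
    docs = gold.document_map()
    view: dict[str, list[ConceptAnnotation]] = {d: [] for d in docs}
    by_doc = gold.concepts_by_doc()
    for doc_index, (doc_id, anns) in enumerate(sorted(by_doc.items())):
        rng = _rng(profile.seed, 2, doc_index)
        text = docs[doc_id].text
        kept: list[ConceptAnnotation] = []
        for ann in anns:
            if rng.random() < profile.miss_rate:
                continue
            fragments = ann.fragments
            if rng.random() < profile.boundary_jitter_rate:
                start, end = fragments[0]
                limit = fragments[1][0] if len(fragments) > 1 else len(text)
                fragments = (_jitter_fragment(rng, start, end, limit),
                             *fragments[1:])
            ctype = ann.concept_type
            if rng.random() < profile.type_confusion_rate and len(all_types) > 1:
                others = [t for t in all_types if t != ctype]
                ctype = others[int(rng.integers(0, len(others)))]
            kept.append(ConceptAnnotation(
                ann_id="", doc_id=doc_id, concept_type=ctype,
                fragments=fragments,
                surface=surface_from_text(text, fragments),
                normalization=ann.normalization,
                provenance=f"curator:{curator_id}"))
        n_spurious = int(rng.poisson(profile.spurious_rate))
        tokens = [m.span() for m in token_re.finditer(text)]
        occupied = [f for a in kept for f in a.fragments] + \
                   [f for a in anns for f in a.fragments]
        for _ in range(n_spurious):
            for _attempt in range(20):
                if not tokens:
                    break
                s, e = tokens[int(rng.integers(0, len(tokens)))]
                if not any(s < oe and os_ < e for os_, oe in occupied):
                    ctype = all_types[int(rng.integers(0, len(all_types)))]
                    kept.append(ConceptAnnotation(
                        ann_id="", doc_id=doc_id, concept_type=ctype,
                        fragments=((s, e),), surface=text[s:e],
                        provenance=f"curator:{curator_id}"))
                    occupied.append((s, e))
                    break
        kept.sort(key=lambda a: a.fragments)
        view[doc_id] = [a.with_id(f"T{i}") for i, a in enumerate(kept, 1)]
    return AnnotationSetView(curator_id=curator_id, annotations=view)


# ---------------------------------------------------------------------------
# curation logs
# ---------------------------------------------------------------------------

def generate_curation_log(collection: AnnotatedCollection,
                          profiles: dict[str, CuratorProfile],
                          assisted_speedup: float = 1.5,
                          base_seconds_per_concept: float = 12.0,
                          seed: int = 0,
                          noise_sigma: float = 0.35,
                          curator_sigma: float = 0.2,
                          floor_seconds: float = 30.0) -> list[CurationLogEntry]:
    """Simulate per-document curation times under two conditions.

    Each curator receives an independent random half/half split of the
    corpus into assisted and non-assisted documents (an independent split
    per curator keeps the paired t-test exchangeable under the null).  The
    time for a document is ``base_seconds_per_concept x concepts x
    curator speed factor x lognormal noise``, divided by
    ``assisted_speedup`` in the assisted condition and floored at
    ``floor_seconds`` (documents without concepts still cost reading
    time).  The recorded concept count is the curator's own (gold count
    thinned by the miss rate plus spurious additions).  Deterministic
    given ``seed``.
    """
    if assisted_speedup <= 0 or base_seconds_per_concept <= 0:
        raise ValueError("assisted_speedup and base_seconds_per_concept must be > 0")
    doc_ids = [d.doc_id for d in collection.documents]
    concepts_by_doc = {d: len(anns) for d, anns in collection.concepts_by_doc().items()}
    relations_by_doc = {d: len(rels) for d, rels in collection.relations_by_doc().items()}
    log: list[CurationLogEntry] = []
    for cur_index, (curator_id, profile) in enumerate(sorted(profiles.items())):
        rng = _rng(seed, 3, cur_index)
        speed = float(rng.lognormal(0.0, curator_sigma))
        order = list(doc_ids)
        rng.shuffle(order)
        half = len(order) // 2
        assisted_docs = set(order[:half])
        for doc_id in doc_ids:
            gold_n = concepts_by_doc.get(doc_id, 0)
            n_concepts = (int(rng.binomial(gold_n, 1.0 - profile.miss_rate))
                          + int(rng.poisson(profile.spurious_rate)))
            condition = "assisted" if doc_id in assisted_docs else "non_assisted"
            noise = float(rng.lognormal(0.0, noise_sigma))
            t = base_seconds_per_concept * max(n_concepts, 1) * speed * noise
            if condition == "assisted":
                t /= assisted_speedup
            t = max(t, floor_seconds)
            log.append(CurationLogEntry(
                curator_id=curator_id, doc_id=doc_id, condition=condition,
                elapsed_seconds=t, concept_count=n_concepts,
                relation_count=relations_by_doc.get(doc_id, 0)))
    return log


# ---------------------------------------------------------------------------
# format fuzzing
# ---------------------------------------------------------------------------

def random_collection(seed: int, n_docs: int = 2, max_annotations: int = 20,
                      discontinuous: bool = True,
                      with_normalization: bool = True) -> AnnotatedCollection:
    """A random valid collection for format round-trip fuzzing.

    Random alphanumeric texts carry random non-overlapping (optionally
    discontinuous) annotations with random types and normalizations, plus
    relations between random annotation pairs; ids are canonical
    (T1..Tn in offset order) so round-trips preserve them.
    """
    rng = _rng(seed, 4)
    alphabet = list("abcdefghij XYZ0123456789")
    types = ["Gene", "Disease", "SNV", "InDel", "Zygosity", "Penetrance"]
    sources = [None, ("UMLS", "C0019425"), ("dbSNP", "rs12345"),
               ("OMIM", "143100"), ("HGNC", "3689")]
    if not with_normalization:
        sources = [None]
    documents, concepts, relations = [], [], []
    for d in range(n_docs):
        doc_id = f"fz{seed}_{d}"
        length = int(rng.integers(40, 200))
        text = "".join(alphabet[int(i)] for i in rng.integers(0, len(alphabet),
                                                              size=length))
        text = text.replace("  ", " x")
        documents.append(TextDocument(doc_id=doc_id, text=text))
        n_ann = int(rng.integers(0, max_annotations + 1))
        cuts = sorted(set(int(i) for i in rng.integers(0, len(text) + 1,
                                                       size=2 * n_ann + 2)))
        spans = [(cuts[i], cuts[i + 1]) for i in range(0, len(cuts) - 1, 2)
                 if cuts[i] < cuts[i + 1]]
        doc_concepts = []
        i = 0
        while i < len(spans) and len(doc_concepts) < n_ann:
            if discontinuous and i + 1 < len(spans) and rng.random() < 0.2:
                fragments = (spans[i], spans[i + 1])
                i += 2
            else:
                fragments = (spans[i],)
                i += 1
            norm = sources[int(rng.integers(0, len(sources)))]
            doc_concepts.append(ConceptAnnotation(
                ann_id="", doc_id=doc_id,
                concept_type=types[int(rng.integers(0, len(types)))],
                fragments=fragments,
                surface=surface_from_text(text, fragments),
                normalization=norm))
        doc_concepts.sort(key=lambda a: (a.fragments, a.concept_type))
        doc_concepts = [a.with_id(f"T{k}") for k, a in enumerate(doc_concepts, 1)]
        concepts.extend(doc_concepts)
        if len(doc_concepts) >= 2 and rng.random() < 0.5:
            i, j = rng.choice(len(doc_concepts), size=2, replace=False)
            relations.append(RelationAnnotation(
                rel_id="R1", doc_id=doc_id, relation_type="associated",
                arg1=doc_concepts[int(i)].ann_id, arg2=doc_concepts[int(j)].ann_id))
    return AnnotatedCollection(documents=documents, concepts=concepts,
                               relations=relations)
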