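"""Core domain model for annotation projects.

Documents, span annotations, relations, project schemas and the corpus
partitioning scheme used to assign documents to curators.

Conventions
-----------
All character offsets are 0-based, half-open ``[start, end)`` and counted in
Unicode code points of the document text, which is the sole offset reference
frame: annotations never modify text.  Discontinuous mentions are represented
as an ordered list of non-overlapping fragments; the recorded surface string
is the corresponding text slices joined by a single space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml

__all__ = [
    "TextDocument",
    "ConceptAnnotation",
    "RelationAnnotation",
    "ConceptType",
    "RelationType",
    "ProjectSchema",
    "Assignment",
    "surface_from_text",
    "validate_schema",
    "default_schema",
    "partition_corpus",
]


# ---------------------------------------------------------------------------
# documents and annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TextDocument:
    """An immutable document: the offset reference frame for annotations."""

    doc_id: str
    text: str
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


def surface_from_text(text: str, fragments: Sequence[tuple[int, int]]) -> str:
    """Surface string of a (possibly discontinuous) mention: slices joined by ' '."""
    return " ".join(text[s:e] for s, e in fragments)


def _check_fragments(fragments: Sequence[tuple[int, int]]) -> None:
    if not fragments:
        raise ValueError("annotation needs at least one fragment")
    prev_end = -1
    for start, end in fragments:
        if not (0 <= start < end):
            raise ValueError(f"invalid fragment ({start}, {end})")
        if start < prev_end:
            raise ValueError("fragments must be sorted and non-overlapping")
        prev_end = end


@dataclass
class ConceptAnnotation:
    """A typed, optionally normalized text span (or set of spans).

    ``normalization`` is a ``(source, concept_id)`` pair, e.g.
    ``("UMLS", "C0019425")`` or ``("dbSNP", "rs113993960")``.
    ``provenance`` is ``"automatic"`` for tagger output or ``"curator:<id>"``.
    """

    ann_id: str
    doc_id: str
    concept_type: str
    fragments: tuple[tuple[int, int], ...]
    surface: str
    normalization: Optional[tuple[str, str]] = None
    provenance: str = "automatic"

    def __post_init__(self) -> None:
        self.fragments = tuple((int(s), int(e)) for s, e in self.fragments)
        _check_fragments(self.fragments)
        if self.normalization is not None:
            self.normalization = (str(self.normalization[0]), str(self.normalization[1]))

    @property
    def start(self) -> int:
        return self.fragments[0][0]

    @property
    def end(self) -> int:
        return self.fragments[-1][1]

    def match_key(self) -> tuple:
        """Identity under exact agreement matching: fragments + type."""
        return (self.fragments, self.concept_type)

    def content_key(self) -> tuple:
        """Identity up to annotation-id renumbering."""
        return (self.doc_id, self.fragments, self.concept_type, self.surface,
                self.normalization)

    def validate_against(self, text: str) -> list[str]:
        """Return human-readable invariant violations against a document text."""
        problems: list[str] = []
        if self.end > len(text):
            problems.append(
                f"annotation {self.ann_id}: fragment end {self.end} exceeds "
                f"text length {len(text)}")
            return problems
        expected = surface_from_text(text, self.fragments)
        if self.surface != expected:
            problems.append(
                f"annotation {self.ann_id}: surface {self.surface!r} does not "
                f"match text slice {expected!r}")
        return problems

    def with_id(self, ann_id: str) -> "ConceptAnnotation":
        return replace(self, ann_id=ann_id)


@dataclass
class RelationAnnotation:
    """A typed, directed link between two concept annotations of one document."""

    rel_id: str
    doc_id: str
    relation_type: str
    arg1: str
    arg2: str


# ---------------------------------------------------------------------------
# project schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConceptType:
    name: str
    normalization_source: Optional[str] = None
    color: Optional[str] = None


@dataclass(frozen=True)
class RelationType:
    name: str
    argument_pairs: tuple[tuple[str, str], ...]


@dataclass
class ProjectSchema:
    """Declared concept types, relation types and normalization sources.

    The schema is the contract every annotation collection is checked
    against: concept types must be declared, relation arguments must use
    declared types, and each concept type names the terminology (OMIM, HGNC,
    dbSNP, UMLS, ...) its annotations are normalized to, if any.
    """

    concept_types: list[ConceptType]
    relation_types: list[RelationType] = field(default_factory=list)

    def concept_type_names(self) -> list[str]:
        return [ct.name for ct in self.concept_types]

    def normalization_source(self, concept_type: str) -> Optional[str]:
        for ct in self.concept_types:
            if ct.name == concept_type:
                return ct.normalization_source
        return None

    def allows_relation(self, relation_type: str, type1: str, type2: str) -> bool:
        for rt in self.relation_types:
            if rt.name == relation_type and (type1, type2) in rt.argument_pairs:
                return True
        return False

    # -- config file I/O ----------------------------------------------------

    @classmethod
    def from_yaml(cls, text: str) -> "ProjectSchema":
        raw = yaml.safe_load(text)
        cts = [ConceptType(name=c["name"],
                           normalization_source=c.get("normalization_source"),
                           color=c.get("color"))
               for c in raw.get("concept_types", [])]
        rts = [RelationType(name=r["name"],
                            argument_pairs=tuple((a["arg1"], a["arg2"])
                                                 for a in r.get("arguments", [])))
               for r in raw.get("relation_types", [])]
        return cls(concept_types=cts, relation_types=rts)

    def to_yaml(self) -> str:
        raw = {
            "concept_types": [
                {k: v for k, v in
                 (("name", ct.name),
                  ("normalization_source", ct.normalization_source),
                  ("color", ct.color)) if v is not None}
                for ct in self.concept_types],
            "relation_types": [
                {"name": rt.name,
                 "arguments": [{"arg1": a, "arg2": b} for a, b in rt.argument_pairs]}
                for rt in self.relation_types],
        }
        return yaml.safe_dump(raw, sort_keys=False)


def validate_schema(schema: ProjectSchema) -> list[str]:
    """Check schema invariants; violations are returned as data, not raised."""
    problems: list[str] = []
    seen: set[str] = set()
    for ct in schema.concept_types:
        if not ct.name:
            problems.append("concept type with empty name")
        elif ct.name in seen:
            problems.append(f"duplicate concept type {ct.name!r}")
        seen.add(ct.name)
    rel_seen: set[str] = set()
    for rt in schema.relation_types:
        if rt.name in rel_seen:
            problems.append(f"duplicate relation type {rt.name!r}")
        rel_seen.add(rt.name)
        for a, b in rt.argument_pairs:
            for t in (a, b):
                if t not in seen:
                    problems.append(
                        f"relation {rt.name!r} references undeclared concept "
                        f"type {t!r}")
    return problems


def default_schema() -> ProjectSchema:
    """The shipped variant-curation schema.

    Concept groups: Gene (HGNC), Disease (OMIM), variation classes SNV
    (dbSNP) / InDel / Rearrangement, and the clinical attributes Mode of
    inheritance, Penetrance, Zygosity, Age of patient and Age of onset
    (UMLS CUIs), with an 'associated' relation between variants and
    genes/diseases/attributes.
    """
    text = resources.files("litcur.data").joinpath("default_schema.yaml").read_text()
    return ProjectSchema.from_yaml(text)


# ---------------------------------------------------------------------------
# corpus partitioning
# ---------------------------------------------------------------------------

@dataclass
class Assignment:
    """A corpus partition: one shared block plus one block per curator.

    The shared block is annotated by every curator (it is what agreement is
    later computed on); individual blocks are disjoint from it and from each
    other, and their sizes differ by at most one document.
    """

    shared: list[str]
    individual: dict[str, list[str]]
    overlap_percent: float

    def documents_for(self, curator_id: str) -> list[str]:
        return list(self.shared) + list(self.individual[curator_id])

    def validate(self, corpus: Optional[Sequence[str]] = None) -> list[str]:
        problems: list[str] = []
        blocks = [("shared", self.shared)] + [
            (cid, docs) for cid, docs in self.individual.items()]
        seen: dict[str, str] = {}
        for label, docs in blocks:
            for d in docs:
                if d in seen:
                    problems.append(
                        f"document {d!r} appears in both {seen[d]!r} and {label!r}")
                seen[d] = label
        if corpus is not None and set(seen) != set(corpus):
            missing = sorted(set(corpus) - set(seen))
            extra = sorted(set(seen) - set(corpus))
            if missing:
                problems.append(f"documents not assigned: {missing}")
            if extra:
                problems.append(f"assigned documents not in corpus: {extra}")
        sizes = [len(v) for v in self.individual.values()]
        if sizes and max(sizes) - min(sizes) > 1:
            problems.append(f"individual partition sizes {sizes} differ by more than 1")
        if not (0 <= self.overlap_percent <= 100):
            problems.append(f"overlap_percent {self.overlap_percent} outside [0, 100]")
        return problems

    # manifest: doc_id <TAB> partition label (shared | curator id)
    def to_manifest(self) -> str:
        lines = [f"{d}\tshared" for d in self.shared]
        for cid, docs in self.individual.items():
            lines.extend(f"{d}\t{cid}" for d in docs)
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_manifest(cls, text: str, overlap_percent: float = float("nan")) -> "Assignment":
        shared: list[str] = []
        individual: dict[str, list[str]] = {}
        for line in text.splitlines():
            if not line.strip():
                continue
            doc_id, label = line.split("\t")
            if label == "shared":
                shared.append(doc_id)
            else:
                individual.setdefault(label, []).append(doc_id)
        return cls(shared=shared, individual=individual, overlap_percent=overlap_percent)


def partition_corpus(doc_ids: Sequence[str], curator_ids: Sequence[str],
                     overlap_percent: float) -> Assignment:
    """Partition a corpus into a shared block plus per-curator blocks.

    The shared block holds ``floor(overlap_percent/100 * N)`` documents; the
    remaining documents are split evenly (``floor``), and the ``r`` leftover
    documents are appended one each to the first ``r`` curators in input
    order.  Documents are assigned in corpus input order (no shuffling):
    shared first, then consecutive blocks.  Callers wanting a random
    partition shuffle ``doc_ids`` beforehand.

    With 100 documents, 3 curators and 33% overlap this yields a 33-document
    shared block and individual blocks of 23/22/22.
    """
    doc_ids = list(doc_ids)
    curator_ids = list(curator_ids)
    if not doc_ids:
        raise ValueError("corpus must be non-empty")
    if len(set(doc_ids)) != len(doc_ids):
        raise ValueError("doc_ids must be unique")
    if not curator_ids:
        raise ValueError("at least one curator required")
    if len(set(curator_ids)) != len(curator_ids):
        raise ValueError("curator_ids must be unique")
    if not (0 <= overlap_percent <= 100):
        raise ValueError(f"overlap_percent must be in [0, 100], got {overlap_percent}")

    n_docs = len(doc_ids)
    n_cur = len(curator_ids)
    n_shared = math.floor(overlap_percent / 100.0 * n_docs)
    shared = doc_ids[:n_shared]
    rest = doc_ids[n_shared:]
    base = len(rest) // n_cur
    remainder = len(rest) - base * n_cur

    individual: dict[str, list[str]] = {}
    pos = 0
    for cid in curator_ids:
        individual[cid] = rest[pos:pos + base]
        pos += base
    for i in range(remainder):
        individual[curator_ids[i]].append(rest[pos])
        pos += 1
    return Assignment(shared=shared, individual=individual,
                      overlap_percent=float(overlap_percent))
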