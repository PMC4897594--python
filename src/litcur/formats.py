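"""Annotation collection container and A1 / BioC interchange.

A1 standoff keeps text and annotations in separate files: each T-line
carries an annotation id, a concept type, character offsets (discontinuous
spans joined by ';') and the surface string; R-lines link two T ids with a
relation type.  BioC is an XML interchange format organized as collection ->
document -> passage with offset-bearing annotation and relation nodes;
annotation offsets are document-global (the passage ``offset`` element
places the passage text inside the document).

Both writers renumber annotation ids (T1..Tn in ascending first-fragment
offset, R1..Rm after all T-lines) so that merged collections always
serialize to valid output; round-trips therefore preserve annotation
*content* exactly and ids whenever the input ids were already canonical.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from lxml import etree

from .model import (ConceptAnnotation, RelationAnnotation, TextDocument,
                    surface_from_text)

__all__ = [
    "AnnotatedCollection",
    "FormatError",
    "A1ParseError",
    "BioCParseError",
    "read_a1",
    "write_a1",
    "read_bioc",
    "write_bioc",
]


class FormatError(ValueError):
    """Base error for annotation I/O problems."""


class A1ParseError(FormatError):
    pass


class BioCParseError(FormatError):
    pass


@dataclass
class AnnotatedCollection:
    """Documents plus their concept and relation annotations."""

    documents: list[TextDocument] = field(default_factory=list)
    concepts: list[ConceptAnnotation] = field(default_factory=list)
    relations: list[RelationAnnotation] = field(default_factory=list)

    def document_map(self) -> dict[str, TextDocument]:
        return {d.doc_id: d for d in self.documents}

    def concepts_by_doc(self) -> dict[str, list[ConceptAnnotation]]:
        out: dict[str, list[ConceptAnnotation]] = {d.doc_id: [] for d in self.documents}
        for ann in self.concepts:
            out.setdefault(ann.doc_id, []).append(ann)
        return out

    def relations_by_doc(self) -> dict[str, list[RelationAnnotation]]:
        out: dict[str, list[RelationAnnotation]] = {d.doc_id: [] for d in self.documents}
        for rel in self.relations:
            out.setdefault(rel.doc_id, []).append(rel)
        return out

    def validate(self) -> list[str]:
        """All invariant violations: unresolved doc ids, bad offsets/surfaces."""
        problems: list[str] = []
        docs = self.document_map()
        ann_ids = {(a.doc_id, a.ann_id) for a in self.concepts}
        for ann in self.concepts:
            doc = docs.get(ann.doc_id)
            if doc is None:
                problems.append(
                    f"annotation {ann.ann_id} references unknown document "
                    f"{ann.doc_id!r}")
                continue
            problems.extend(ann.validate_against(doc.text))
        for rel in self.relations:
            if rel.doc_id not in docs:
                problems.append(
                    f"relation {rel.rel_id} references unknown document "
                    f"{rel.doc_id!r}")
            for arg in (rel.arg1, rel.arg2):
                if (rel.doc_id, arg) not in ann_ids:
                    problems.append(
                        f"relation {rel.rel_id} references unknown annotation "
                        f"{arg!r} in document {rel.doc_id!r}")
        return problems

    def content_key(self, include_normalization: bool = True) -> tuple[Counter, Counter]:
        """Annotation content as multisets, invariant to id renumbering.

        A1 standoff has no field for normalization (that is BioC-only
        here), so A1 round-trip comparisons pass
        ``include_normalization=False``.
        """
        def ckey(a: ConceptAnnotation) -> tuple:
            key = a.content_key()
            return key if include_normalization else key[:4]
        concept_keys = Counter(ckey(a) for a in self.concepts)
        by_id = {(a.doc_id, a.ann_id): a for a in self.concepts}
        relation_keys = Counter(
            (r.doc_id, r.relation_type,
             ckey(by_id[(r.doc_id, r.arg1)]),
             ckey(by_id[(r.doc_id, r.arg2)]))
            for r in self.relations)
        return concept_keys, relation_keys

    def content_equal(self, other: "AnnotatedCollection",
                      include_normalization: bool = True) -> bool:
        return (self.content_key(include_normalization)
                == other.content_key(include_normalization))


# ---------------------------------------------------------------------------
# A1 standoff
# ---------------------------------------------------------------------------

def _parse_a1_offsets(spec: str, line_no: int) -> tuple[tuple[int, int], ...]:
    fragments = []
    for part in spec.split(";"):
        pieces = part.split()
        if len(pieces) != 2 or not all(p.isdigit() for p in pieces):
            raise A1ParseError(f"line {line_no}: malformed offsets {spec!r}")
        fragments.append((int(pieces[0]), int(pieces[1])))
    return tuple(fragments)


def read_a1(text_content: str, a1_content: str, doc_id: str) -> AnnotatedCollection:
    """Parse one document's A1 standoff annotations against its text.

    Offsets are validated against the text and each T-line surface is
    cross-checked against the corresponding slice; any mismatch raises
    :class:`A1ParseError` naming the offending line.
    """
    doc = TextDocument(doc_id=doc_id, text=text_content)
    concepts: list[ConceptAnnotation] = []
    relations: list[RelationAnnotation] = []
    known: set[str] = set()
    for line_no, line in enumerate(a1_content.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if line.startswith("T"):
            if len(fields) != 3:
                raise A1ParseError(f"line {line_no}: expected 3 tab fields, got "
                                   f"{len(fields)}: {line!r}")
            ann_id, type_and_offsets, surface = fields
            # the concept type may contain spaces (e.g. "Mode of inheritance");
            # offsets are the trailing all-digit groups
            m = re.fullmatch(r"(.+?) (\d+ \d+(?:;\d+ \d+)*)", type_and_offsets)
            if m is None:
                raise A1ParseError(f"line {line_no}: malformed type/offsets "
                                   f"field: {type_and_offsets!r}")
            ctype, offset_spec = m.group(1), m.group(2)
            fragments = _parse_a1_offsets(offset_spec, line_no)
            for start, end in fragments:
                if not (0 <= start < end <= len(text_content)):
                    raise A1ParseError(
                        f"line {line_no}: fragment ({start}, {end}) out of range "
                        f"for text of length {len(text_content)}")
            expected = surface_from_text(text_content, fragments)
            if surface != expected:
                raise A1ParseError(
                    f"line {line_no}: surface {surface!r} does not match text "
                    f"slice {expected!r}")
            concepts.append(ConceptAnnotation(
                ann_id=ann_id, doc_id=doc_id, concept_type=ctype,
                fragments=fragments, surface=surface))
            known.add(ann_id)
        elif line.startswith("R"):
            if len(fields) != 2:
                raise A1ParseError(f"line {line_no}: expected 2 tab fields: {line!r}")
            rel_id, body = fields
            parts = body.split()
            if (len(parts) != 3 or not parts[1].startswith("Arg1:")
                    or not parts[2].startswith("Arg2:")):
                raise A1ParseError(f"line {line_no}: malformed relation: {line!r}")
            arg1 = parts[1][len("Arg1:"):]
            arg2 = parts[2][len("Arg2:"):]
            for arg in (arg1, arg2):
                if arg not in known:
                    raise A1ParseError(
                        f"line {line_no}: relation references unknown "
                        f"annotation {arg!r}")
            relations.append(RelationAnnotation(
                rel_id=rel_id, doc_id=doc_id, relation_type=parts[0],
                arg1=arg1, arg2=arg2))
        else:
            raise A1ParseError(f"line {line_no}: unsupported line kind: {line!r}")
    return AnnotatedCollection(documents=[doc], concepts=concepts,
                               relations=relations)


def _emission_order(concepts: Iterable[ConceptAnnotation]) -> list[ConceptAnnotation]:
    return sorted(concepts, key=lambda a: (a.fragments, a.concept_type, a.ann_id))


def write_a1(collection: AnnotatedCollection) -> dict[str, tuple[str, str]]:
    """Serialize a collection to per-document ``(text, a1)`` string pairs."""
    problems = collection.validate()
    if problems:
        raise FormatError("cannot serialize invalid collection: " + "; ".join(problems))
    out: dict[str, tuple[str, str]] = {}
    rels_by_doc = collection.relations_by_doc()
    for doc_id, anns in collection.concepts_by_doc().items():
        doc = collection.document_map()[doc_id]
        lines: list[str] = []
        id_map: dict[str, str] = {}
        for i, ann in enumerate(_emission_order(anns), start=1):
            new_id = f"T{i}"
            id_map[ann.ann_id] = new_id
            offsets = ";".join(f"{s} {e}" for s, e in ann.fragments)
            lines.append(f"{new_id}\t{ann.concept_type} {offsets}\t{ann.surface}")
        for j, rel in enumerate(rels_by_doc.get(doc_id, []), start=1):
            lines.append(f"R{j}\t{rel.relation_type} "
                         f"Arg1:{id_map[rel.arg1]} Arg2:{id_map[rel.arg2]}")
        out[doc_id] = (doc.text, "\n".join(lines) + ("\n" if lines else ""))
    return out


# ---------------------------------------------------------------------------
# BioC XML
# ---------------------------------------------------------------------------

# infon keys used for annotation attributes (common practice; the format
# itself leaves them open)
INFON_TYPE = "type"
INFON_IDENTIFIER = "identifier"
INFON_SOURCE = "source"
INFON_PROVENANCE = "provenance"


def _infons(node: etree._Element) -> dict[str, str]:
    return {el.get("key"): (el.text or "") for el in node.findall("infon")}


def read_bioc(xml_content: str | bytes) -> AnnotatedCollection:
    """Parse a BioC collection into documents, concepts and relations."""
    if isinstance(xml_content, str):
        xml_content = xml_content.encode("utf-8")
    try:
        root = etree.fromstring(xml_content)
    except etree.XMLSyntaxError as exc:
        raise BioCParseError(f"malformed BioC XML: {exc}") from exc
    if root.tag != "collection":
        raise BioCParseError(f"expected <collection> root, got <{root.tag}>")

    documents: list[TextDocument] = []
    concepts: list[ConceptAnnotation] = []
    relations: list[RelationAnnotation] = []
    for doc_node in root.findall("document"):
        doc_id = (doc_node.findtext("id") or "").strip()
        if not doc_id:
            raise BioCParseError("document without <id>")
        # reconstruct document text from passages placed at their offsets
        pieces: list[tuple[int, str]] = []
        for passage in doc_node.findall("passage"):
            offset = int(passage.findtext("offset") or 0)
            text = passage.findtext("text") or ""
            pieces.append((offset, text))
        length = max((off + len(t) for off, t in pieces), default=0)
        chars = [" "] * length
        for off, t in pieces:
            chars[off:off + len(t)] = list(t)
        doc_text = "".join(chars)
        documents.append(TextDocument(doc_id=doc_id, text=doc_text))

        for passage in doc_node.findall("passage"):
            for ann_node in passage.findall("annotation"):
                infons = _infons(ann_node)
                ctype = infons.get(INFON_TYPE)
                if ctype is None:
                    raise BioCParseError(
                        f"document {doc_id}: annotation without '{INFON_TYPE}' infon")
                locations = ann_node.findall("location")
                if not locations:
                    raise BioCParseError(
                        f"document {doc_id}: annotation "
                        f"{ann_node.get('id')!r} lacks a location")
                fragments = tuple(
                    (int(loc.get("offset")), int(loc.get("offset")) + int(loc.get("length")))
                    for loc in locations)
                surface = ann_node.findtext("text")
                if surface is None:
                    surface = surface_from_text(doc_text, fragments)
                normalization = None
                if INFON_IDENTIFIER in infons:
                    normalization = (infons.get(INFON_SOURCE, ""),
                                     infons[INFON_IDENTIFIER])
                concepts.append(ConceptAnnotation(
                    ann_id=ann_node.get("id") or f"T{len(concepts) + 1}",
                    doc_id=doc_id, concept_type=ctype, fragments=fragments,
                    surface=surface, normalization=normalization,
                    provenance=infons.get(INFON_PROVENANCE, "automatic")))
            for rel_node in passage.findall("relation"):
                infons = _infons(rel_node)
                nodes = rel_node.findall("node")
                if len(nodes) != 2:
                    raise BioCParseError(
                        f"document {doc_id}: relation "
                        f"{rel_node.get('id')!r} must have exactly 2 nodes")
                by_role = {n.get("role"): n.get("refid") for n in nodes}
                if set(by_role) == {"arg1", "arg2"}:
                    arg1, arg2 = by_role["arg1"], by_role["arg2"]
                else:
                    arg1, arg2 = nodes[0].get("refid"), nodes[1].get("refid")
                relations.append(RelationAnnotation(
                    rel_id=rel_node.get("id") or f"R{len(relations) + 1}",
                    doc_id=doc_id,
                    relation_type=infons.get(INFON_TYPE, "associated"),
                    arg1=arg1, arg2=arg2))
    collection = AnnotatedCollection(documents=documents, concepts=concepts,
                                     relations=relations)
    problems = collection.validate()
    if problems:
        raise BioCParseError("; ".join(problems))
    return collection


def write_bioc(collection: AnnotatedCollection, source: str = "litcur") -> str:
    """Serialize a collection to BioC XML (one whole-text passage per document)."""
    problems = collection.validate()
    if problems:
        raise FormatError("cannot serialize invalid collection: " + "; ".join(problems))
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = source
    etree.SubElement(root, "date").text = ""
    etree.SubElement(root, "key").text = ""
    rels_by_doc = collection.relations_by_doc()
    for doc_id, anns in collection.concepts_by_doc().items():
        doc = collection.document_map()[doc_id]
        doc_node = etree.SubElement(root, "document")
        etree.SubElement(doc_node, "id").text = doc_id
        passage = etree.SubElement(doc_node, "passage")
        etree.SubElement(passage, "offset").text = "0"
        etree.SubElement(passage, "text").text = doc.text
        id_map: dict[str, str] = {}
        for i, ann in enumerate(_emission_order(anns), start=1):
            new_id = f"T{i}"
            id_map[ann.ann_id] = new_id
            ann_node = etree.SubElement(passage, "annotation", id=new_id)
            infon = etree.SubElement(ann_node, "infon", key=INFON_TYPE)
            infon.text = ann.concept_type
            if ann.normalization is not None:
                src, cid = ann.normalization
                etree.SubElement(ann_node, "infon", key=INFON_SOURCE).text = src
                etree.SubElement(ann_node, "infon", key=INFON_IDENTIFIER).text = cid
            if ann.provenance != "automatic":
                etree.SubElement(ann_node, "infon",
                                 key=INFON_PROVENANCE).text = ann.provenance
            for start, end in ann.fragments:
                etree.SubElement(ann_node, "location",
                                 offset=str(start), length=str(end - start))
            etree.SubElement(ann_node, "text").text = ann.surface
        for j, rel in enumerate(rels_by_doc.get(doc_id, []), start=1):
            rel_node = etree.SubElement(passage, "relation", id=f"R{j}")
            etree.SubElement(rel_node, "infon", key=INFON_TYPE).text = rel.relation_type
            etree.SubElement(rel_node, "node", refid=id_map[rel.arg1], role="arg1")
            etree.SubElement(rel_node, "node", refid=id_map[rel.arg2], role="arg2")
    return etree.tostring(root, pretty_print=True, encoding="unicode")
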