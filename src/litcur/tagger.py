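"""Automatic concept annotation.

Three recognizers produce :class:`~litcur.model.ConceptAnnotation` lists
with ``provenance="automatic"``:

* dictionary longest-match tagging of diseases and clinical attributes
  against a compiled lexicon (the bundled lexicon maps the categorical
  clinical-attribute values — zygosity, penetrance, inheritance mode, ages —
  to their UMLS CUIs);
* rule-based recognition of variant mentions written in HGVS-like
  nomenclature or as dbSNP rs numbers, classified into SNV / InDel /
  Rearrangement;
* pattern-based recognition of patient-age and age-of-onset phrases.

Normalization of SNV mentions to variant identifiers goes through a
file-backed index mapping each identifier to its HGVS names and gene
symbols (a stand-in for a live dbSNP lookup); insertion-deletions and
rearrangements are not normalized.

Matching policy: matches must start and end at token boundaries
(transitions to/from letter-digit runs); terms longer than 4 characters are
matched case-insensitively, terms of up to 4 characters exactly (a guard
against short gene-symbol false positives).  Overlaps are resolved
leftmost-longest; where a dictionary match overlaps a variant-pattern
match, the variant wins (it is the more specific recognizer).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Optional, Sequence

from .model import ConceptAnnotation, TextDocument

__all__ = [
    "LexiconEntry",
    "MatchingPolicy",
    "CompiledLexicon",
    "VariantIndexRecord",
    "LexiconError",
    "compile_lexicon",
    "tag_dictionary",
    "tag_variants",
    "tag_ages",
    "annotate_document",
    "normalize_variant",
    "load_lexicon",
    "dump_lexicon",
    "bundled_clinical_lexicon",
    "load_variant_index",
    "dump_variant_index",
    "VARIANT_RULES",
]


class LexiconError(ValueError):
    pass


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------

@dataclass
class LexiconEntry:
    """A dictionary term with synonyms, concept type and normalization id."""

    term: str
    synonyms: list[str]
    concept_type: str
    source: str
    concept_id: str

    def __post_init__(self) -> None:
        self.term = " ".join(self.term.split())
        self.synonyms = [" ".join(s.split()) for s in self.synonyms if s.strip()]
        if not self.term:
            raise LexiconError("lexicon entry with empty term")

    def surfaces(self) -> list[str]:
        return [self.term, *self.synonyms]


@dataclass(frozen=True)
class MatchingPolicy:
    """Case folding and boundary rules for dictionary matching."""

    case_sensitive_max_length: int = 4  # terms this short match case-sensitively
    require_token_boundaries: bool = True


@dataclass
class CompiledLexicon:
    """A lexicon compiled for longest-match scanning.

    ``surface_map`` keys are case-folded surface forms; each value records
    the original surface, whether matching is case-sensitive, and the
    ``(concept_type, source, concept_id)`` triple.
    """

    surface_map: dict[str, tuple[str, bool, str, str, str]]
    policy: MatchingPolicy
    # candidate surfaces grouped by case-folded first token, longest first
    _by_first_token: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.surface_map)

    def lookup(self, surface: str) -> Optional[tuple[str, str, str]]:
        """(concept_type, source, concept_id) for a known surface form."""
        info = self.surface_map.get(surface.casefold())
        return None if info is None else info[2:]


_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)  # letter-digit runs


def _first_token(surface: str) -> str:
    m = _TOKEN_RE.search(surface)
    return m.group(0).casefold() if m else surface.casefold()


def compile_lexicon(entries: Sequence[LexiconEntry],
                    policy: MatchingPolicy | None = None) -> CompiledLexicon:
    """Compile entries into a matcher; idempotent for a given entry list.

    The same surface form mapped to two different concept types is a
    compile-time error listing every collision.
    """
    policy = policy or MatchingPolicy()
    surface_map: dict[str, tuple[str, bool, str, str, str]] = {}
    collisions: list[str] = []
    for entry in entries:
        for surface in entry.surfaces():
            key = surface.casefold()
            case_sensitive = len(surface) <= policy.case_sensitive_max_length
            value = (surface, case_sensitive, entry.concept_type,
                     entry.source, entry.concept_id)
            existing = surface_map.get(key)
            if existing is not None and existing[2:] != value[2:]:
                collisions.append(
                    f"surface {surface!r} maps to both "
                    f"{existing[2]}/{existing[4]} and "
                    f"{entry.concept_type}/{entry.concept_id}")
            surface_map.setdefault(key, value)
    if collisions:
        raise LexiconError("lexicon collisions: " + "; ".join(sorted(set(collisions))))
    by_first: dict[str, list[str]] = {}
    for key in surface_map:
        by_first.setdefault(_first_token(key), []).append(key)
    for group in by_first.values():
        group.sort(key=len, reverse=True)
    return CompiledLexicon(surface_map=surface_map, policy=policy,
                           _by_first_token=by_first)


def _boundary_ok(text: str, start: int, end: int) -> bool:
    before = start == 0 or not text[start - 1].isalnum()
    after = end == len(text) or not text[end].isalnum()
    return before and after


def tag_dictionary(doc: TextDocument, lexicon: CompiledLexicon,
                   id_prefix: str = "D") -> list[ConceptAnnotation]:
    """Leftmost-longest non-overlapping dictionary matches at token boundaries."""
    text = doc.text
    folded = text.casefold()
    annotations: list[ConceptAnnotation] = []
    pos = 0
    counter = 0
    for token in _TOKEN_RE.finditer(text):
        start = token.start()
        if start < pos:
            continue
        candidates = lexicon._by_first_token.get(token.group(0).casefold(), [])
        for key in candidates:  # longest first
            end = start + len(key)
            if end > len(text) or folded[start:end] != key:
                continue
            if not _boundary_ok(text, start, end):
                continue
            surface_orig, case_sensitive, ctype, source, cid = lexicon.surface_map[key]
            if case_sensitive and text[start:end] != surface_orig:
                continue
            counter += 1
            annotations.append(ConceptAnnotation(
                ann_id=f"{id_prefix}{counter}", doc_id=doc.doc_id,
                concept_type=ctype, fragments=((start, end),),
                surface=text[start:end],
                normalization=(source, cid) if cid else None,
                provenance="automatic"))
            pos = end
            break
    return annotations


# ---------------------------------------------------------------------------
# variant mention rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRule:
    name: str
    pattern: re.Pattern
    concept_type: str
    normalizer: Optional[Callable[[str], tuple[str, str]]] = None


_AA3 = ("(?:Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|"
        "Thr|Trp|Tyr|Val|Ter|Sec|Xaa)")
_B = r"(?<![A-Za-z0-9])"   # token-boundary lookarounds
_A = r"(?![A-Za-z0-9])"


def _rule(name: str, body: str, concept_type: str, flags: int = 0,
          normalizer=None) -> VariantRule:
    return VariantRule(name=name,
                       pattern=re.compile(_B + body + _A, flags),
                       concept_type=concept_type, normalizer=normalizer)


#: Shipped rule set for variant mention recognition, by variation class.
VARIANT_RULES: tuple[VariantRule, ...] = (
    # SNV: HGVS DNA substitutions (c.76A>T, g.123456G>A, c.88+1G>T)
    _rule("dna_substitution",
          r"[cgmnr]\.\d+(?:[+-]\d+)?[ACGTUacgtu]>[ACGTUacgtu]", "SNV"),
    # SNV: HGVS protein substitutions, three- or one-letter (p.Phe508Ser, p.F508S)
    _rule("protein_substitution",
          rf"p\.(?:\(?{_AA3}\d+{_AA3}\)?|[A-Z]\d+[A-Z])", "SNV"),
    # SNV: dbSNP rs numbers carry their own normalization candidate
    _rule("rsid", r"rs\d+", "SNV",
          normalizer=lambda mention: ("dbSNP", mention)),
    # InDel: HGVS DNA deletion/insertion/duplication (c.35delG, c.1521_1523delCTT)
    _rule("dna_indel",
          r"[cgmnr]\.\d+(?:[+-]\d+)?(?:_\d+(?:[+-]\d+)?)?"
          r"(?:delins|del|ins|dup)[ACGTUacgtu]*", "InDel"),
    # InDel: HGVS protein deletion/duplication/insertion (p.Phe508del)
    _rule("protein_indel",
          rf"p\.\(?{_AA3}\d+(?:_{_AA3}\d+)?(?:delins{_AA3}*|del|dup|ins{_AA3}+)\)?",
          "InDel"),
    # Rearrangement: karyotype-style translocations/inversions, with an
    # optional trailing cue word absorbed into the mention
    _rule("karyotype",
          r"(?:t\(\d+;\d+\)|inv\(\d+\))(?:\([pq0-9.;]+\))?"
          r"(?:\s+(?:translocation|inversion))?", "Rearrangement"),
    # Rearrangement: bare phrases
    _rule("rearrangement_phrase",
          r"(?:(?:chromosomal|balanced|reciprocal)\s+)?(?:translocation|inversion)s?"
          r"|(?:gene\s+fusion|fusion\s+gene)s?", "Rearrangement", re.IGNORECASE),
)


def _resolve_leftmost_longest(candidates: list[tuple[int, int, object]]
                              ) -> list[tuple[int, int, object]]:
    """Greedy selection: earliest start wins, ties broken by longer match."""
    chosen: list[tuple[int, int, object]] = []
    last_end = 0
    for start, end, payload in sorted(candidates, key=lambda c: (c[0], -c[1])):
        if start >= last_end:
            chosen.append((start, end, payload))
            last_end = end
    return chosen


def tag_variants(doc: TextDocument,
                 pattern_set: Sequence[VariantRule] = VARIANT_RULES,
                 id_prefix: str = "V") -> list[ConceptAnnotation]:
    """Non-overlapping variant mentions typed SNV / InDel / Rearrangement."""
    text = doc.text
    candidates: list[tuple[int, int, VariantRule]] = []
    for rule in pattern_set:
        for m in rule.pattern.finditer(text):
            candidates.append((m.start(), m.end(), rule))
    annotations: list[ConceptAnnotation] = []
    for i, (start, end, rule) in enumerate(
            _resolve_leftmost_longest(candidates), start=1):
        mention = text[start:end]
        normalization = rule.normalizer(mention) if rule.normalizer else None
        annotations.append(ConceptAnnotation(
            ann_id=f"{id_prefix}{i}", doc_id=doc.doc_id,
            concept_type=rule.concept_type, fragments=((start, end),),
            surface=mention, normalization=normalization,
            provenance="automatic"))
    return annotations


# ---------------------------------------------------------------------------
# age phrases
# ---------------------------------------------------------------------------

_AGE_ONSET_RE = re.compile(
    r"(?:onset\s+(?:at|of|by)\s+(?:age\s+)?\d+(?:\s+(?:years|months))?"
    r"|presented\s+at\s+(?:age\s+)?\d+(?:\s+(?:years|months))?"
    r"|age\s+(?:at|of)\s+onset\s+(?:of|was|:)?\s*\d+(?:\s+(?:years|months))?)",
    re.IGNORECASE)
_AGE_PATIENT_RE = re.compile(
    r"(?:aged?\s+\d+(?:\s+years)?(?:\s+old)?"
    r"|\d+(?:\s+|-)years?(?:\s+|-)old"
    r"|\d+\s+years\s+of\s+age)",
    re.IGNORECASE)


def tag_ages(doc: TextDocument, id_prefix: str = "G") -> list[ConceptAnnotation]:
    """Patient-age and age-of-onset phrases, normalized to their UMLS CUIs.

    Onset cues take precedence over plain age phrases on overlap.
    """
    text = doc.text
    candidates: list[tuple[int, int, tuple[str, str]]] = []
    for m in _AGE_ONSET_RE.finditer(text):
        if _boundary_ok(text, m.start(), m.end()):
            candidates.append((m.start(), m.end(), ("Age of onset", "C0206132")))
    for m in _AGE_PATIENT_RE.finditer(text):
        if _boundary_ok(text, m.start(), m.end()):
            candidates.append((m.start(), m.end(), ("Age of patient", "C0001779")))
    annotations = []
    for i, (start, end, (ctype, cui)) in enumerate(
            _resolve_leftmost_longest(candidates), start=1):
        annotations.append(ConceptAnnotation(
            ann_id=f"{id_prefix}{i}", doc_id=doc.doc_id, concept_type=ctype,
            fragments=((start, end),), surface=text[start:end],
            normalization=("UMLS", cui), provenance="automatic"))
    return annotations


def annotate_document(doc: TextDocument,
                      lexicon: Optional[CompiledLexicon] = None,
                      pattern_set: Sequence[VariantRule] = VARIANT_RULES,
                      ages: bool = True) -> list[ConceptAnnotation]:
    """Run all recognizers on one document and merge their output.

    Variant-pattern matches take precedence over dictionary and age matches
    on overlap; the merged result is non-overlapping, sorted by offset, with
    ids renumbered T1..Tn.
    """
    merged: list[ConceptAnnotation] = list(tag_variants(doc, pattern_set))
    taken = [(a.start, a.end) for a in merged]

    def overlaps(a: ConceptAnnotation) -> bool:
        return any(a.start < e and s < a.end for s, e in taken)

    extra: list[ConceptAnnotation] = []
    if lexicon is not None:
        extra.extend(a for a in tag_dictionary(doc, lexicon) if not overlaps(a))
    if ages:
        taken2 = taken + [(a.start, a.end) for a in extra]
        extra.extend(a for a in tag_ages(doc)
                     if not any(a.start < e and s < a.end for s, e in taken2))
    merged.extend(extra)
    merged.sort(key=lambda a: a.fragments)
    return [a.with_id(f"T{i}") for i, a in enumerate(merged, start=1)]


# ---------------------------------------------------------------------------
# variant normalization index
# ---------------------------------------------------------------------------

@dataclass
class VariantIndexRecord:
    """One indexed variant: identifier, HGVS names, gene symbols."""

    variant_id: str
    hgvs_names: list[str]
    gene_symbols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValueError("variant_id must be non-empty")
        if not self.hgvs_names:
            raise ValueError(f"variant {self.variant_id}: needs at least one HGVS name")


def normalize_variant(mention: str, gene_context: Optional[str],
                      index: Sequence[VariantIndexRecord]) -> Optional[str]:
    """Resolve an SNV mention to a variant identifier, or ``None``.

    The mention is case-folded and whitespace-stripped, then looked up among
    each record's HGVS names.  When several records share the name, a gene
    context restricts the candidates by gene symbol; if the mention is still
    ambiguous the lookup abstains.  rs-number mentions resolve to themselves
    when present in the index.  Absence is a value, never an error.
    """
    key = "".join(mention.split()).casefold()
    if re.fullmatch(r"rs\d+", key):
        for record in index:
            if record.variant_id.casefold() == key:
                return record.variant_id
        return None
    matches = [r for r in index
               if any("".join(h.split()).casefold() == key for h in r.hgvs_names)]
    if len(matches) > 1 and gene_context:
        gene_key = gene_context.casefold()
        matches = [r for r in matches
                   if any(g.casefold() == gene_key for g in r.gene_symbols)]
    if len(matches) == 1:
        return matches[0].variant_id
    return None


# ---------------------------------------------------------------------------
# lexicon / index file I/O (tab-separated, '|'-joined lists)
# ---------------------------------------------------------------------------

def load_lexicon(text: str) -> list[LexiconEntry]:
    """Parse a lexicon TSV: term, synonyms (|-joined), type, source, id."""
    entries = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 5:
            raise LexiconError(f"lexicon line {line_no}: expected 5 fields, "
                               f"got {len(fields)}")
        term, synonyms, ctype, source, cid = fields
        entries.append(LexiconEntry(
            term=term, synonyms=[s for s in synonyms.split("|") if s],
            concept_type=ctype, source=source, concept_id=cid))
    return entries


def dump_lexicon(entries: Sequence[LexiconEntry]) -> str:
    lines = ["\t".join([e.term, "|".join(e.synonyms), e.concept_type,
                        e.source, e.concept_id]) for e in entries]
    return "\n".join(lines) + ("\n" if lines else "")


def bundled_clinical_lexicon() -> list[LexiconEntry]:
    """The shipped clinical-attribute lexicon (12 term -> UMLS CUI entries)."""
    text = resources.files("litcur.data").joinpath("clinical_attributes.tsv").read_text()
    return load_lexicon(text)


def load_variant_index(text: str) -> list[VariantIndexRecord]:
    """Parse a variant index TSV: variant_id, hgvs (|-joined), genes (|-joined)."""
    records = []
    seen: set[str] = set()
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 3:
            raise LexiconError(f"variant index line {line_no}: expected 3 fields")
        vid, hgvs, genes = fields
        if vid in seen:
            raise LexiconError(f"variant index line {line_no}: duplicate id {vid!r}")
        seen.add(vid)
        records.append(VariantIndexRecord(
            variant_id=vid, hgvs_names=[h for h in hgvs.split("|") if h],
            gene_symbols=[g for g in genes.split("|") if g]))
    return records


def dump_variant_index(records: Sequence[VariantIndexRecord]) -> str:
    lines = ["\t".join([r.variant_id, "|".join(r.hgvs_names),
                        "|".join(r.gene_symbols)]) for r in records]
    return "\n".join(lines) + ("\n" if lines else "")
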