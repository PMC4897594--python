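"""Inter-annotator agreement (IAA) via pairwise F-scores.

Two curators' annotation sets over the documents they share are matched
one-to-one; with matching counts ``m`` and set sizes ``|A|``, ``|B|`` the
pairwise F-score is ``2m / (|A| + |B|)``, i.e. the harmonic mean of
precision ``m/|B|`` and recall ``m/|A|``.  The overall IAA is the
unweighted arithmetic mean of pairwise F-scores over curator pairs that
share at least one document.

The default match criterion is strict: identical fragments and identical
concept type (normalization ids are ignored).  Under this criterion match
keys form equivalence classes, so the greedy one-to-one pairing is a
maximum matching.  An ``overlap`` mode (any character overlap plus equal
type) is provided as the lenient alternative.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import ConceptAnnotation

__all__ = [
    "AnnotationSetView",
    "PairwiseScore",
    "IAAReport",
    "match_annotations",
    "pairwise_f",
    "summarize_pairwise",
    "iaa",
]


@dataclass
class AnnotationSetView:
    """One curator's annotations, indexed by document."""

    curator_id: str
    annotations: dict[str, list[ConceptAnnotation]] = field(default_factory=dict)

    def doc_ids(self) -> set[str]:
        return set(self.annotations)

    def for_doc(self, doc_id: str) -> list[ConceptAnnotation]:
        return self.annotations.get(doc_id, [])


@dataclass
class PairwiseScore:
    """Match counts and precision/recall/F for one curator pair."""

    curator_a: str
    curator_b: str
    shared_docs: int
    matches: int
    size_a: int
    size_b: int
    precision: float
    recall: float
    f1: float
    vacuous: bool = False  # both sides empty over the shared documents


@dataclass
class IAAReport:
    pairwise: list[PairwiseScore]
    overall: float
    type_filter: Optional[frozenset] = None
    curator_filter: Optional[frozenset] = None


def _check_same_doc(*sets: Sequence[ConceptAnnotation]) -> None:
    doc_ids = {a.doc_id for anns in sets for a in anns}
    if len(doc_ids) > 1:
        raise ValueError(f"annotation sets span multiple documents: {sorted(doc_ids)}")


def match_annotations(set_a: Sequence[ConceptAnnotation],
                      set_b: Sequence[ConceptAnnotation],
                      mode: str = "exact") -> int:
    """One-to-one match count between two same-document annotation sets.

    ``exact``: fragments and concept type identical.  ``overlap``: equal
    type plus any character overlap, paired greedily in offset order.
    """
    _check_same_doc(set_a, set_b)
    if mode == "exact":
        keys_a = Counter(a.match_key() for a in set_a)
        keys_b = Counter(b.match_key() for b in set_b)
        return sum(min(keys_a[k], keys_b[k]) for k in keys_a.keys() & keys_b.keys())
    if mode == "overlap":
        used = [False] * len(set_b)
        order_b = sorted(range(len(set_b)), key=lambda i: set_b[i].fragments)
        matches = 0
        for a in sorted(set_a, key=lambda x: x.fragments):
            for i in order_b:
                b = set_b[i]
                if used[i] or b.concept_type != a.concept_type:
                    continue
                if any(fa[0] < fb[1] and fb[0] < fa[1]
                       for fa in a.fragments for fb in b.fragments):
                    used[i] = True
                    matches += 1
                    break
        return matches
    raise ValueError(f"unknown mode {mode!r}")


def _filtered(view: AnnotationSetView, doc_id: str,
              type_filter: Optional[Iterable[str]]) -> list[ConceptAnnotation]:
    anns = view.for_doc(doc_id)
    if type_filter is None:
        return anns
    allowed = set(type_filter)
    return [a for a in anns if a.concept_type in allowed]


def pairwise_f(view_a: AnnotationSetView, view_b: AnnotationSetView,
               type_filter: Optional[Iterable[str]] = None,
               mode: str = "exact") -> PairwiseScore:
    """Micro-averaged pairwise score over the documents both curators hold.

    Counts are summed across shared documents before computing precision,
    recall and F.  A pair with no shared documents gets ``shared_docs=0``
    and NaN scores (excluded from the overall IAA); a pair whose filtered
    sets are both empty over shared documents scores a vacuous 1.0,
    flagged so callers can exclude it.
    """
    shared = sorted(view_a.doc_ids() & view_b.doc_ids())
    matches = size_a = size_b = 0
    for doc_id in shared:
        a = _filtered(view_a, doc_id, type_filter)
        b = _filtered(view_b, doc_id, type_filter)
        matches += match_annotations(a, b, mode=mode)
        size_a += len(a)
        size_b += len(b)
    vacuous = False
    if not shared:
        precision = recall = f1 = float("nan")
    elif size_a == 0 and size_b == 0:
        precision = recall = f1 = 1.0
        vacuous = True
    else:
        precision = matches / size_b if size_b else 0.0
        recall = matches / size_a if size_a else 0.0
        f1 = 2 * matches / (size_a + size_b)
    return PairwiseScore(curator_a=view_a.curator_id, curator_b=view_b.curator_id,
                         shared_docs=len(shared), matches=matches,
                         size_a=size_a, size_b=size_b,
                         precision=precision, recall=recall, f1=f1,
                         vacuous=vacuous)


def summarize_pairwise(pairwise: Sequence[PairwiseScore],
                       type_filter: Optional[Iterable[str]] = None,
                       curator_filter: Optional[Iterable[str]] = None) -> IAAReport:
    """Aggregate pairwise scores into an IAA report.

    The overall IAA is the unweighted mean F over pairs sharing at least
    one document; pairs without shared documents are excluded.
    """
    scored = [p for p in pairwise if p.shared_docs >= 1]
    if not scored:
        raise ValueError("no curator pair shares a document; IAA undefined")
    overall = sum(p.f1 for p in scored) / len(scored)
    return IAAReport(pairwise=list(pairwise), overall=overall,
                     type_filter=frozenset(type_filter) if type_filter else None,
                     curator_filter=frozenset(curator_filter) if curator_filter else None)


def iaa(views: Sequence[AnnotationSetView],
        type_filter: Optional[Iterable[str]] = None,
        curator_filter: Optional[Iterable[str]] = None,
        mode: str = "exact") -> IAAReport:
    """IAA over all unordered curator pairs (after optional filtering)."""
    if curator_filter is not None:
        allowed = set(curator_filter)
        views = [v for v in views if v.curator_id in allowed]
    if len(views) < 2:
        raise ValueError("IAA requires at least two curators")
    pairwise = [pairwise_f(a, b, type_filter=type_filter, mode=mode)
                for a, b in itertools.combinations(views, 2)]
    return summarize_pairwise(pairwise, type_filter=type_filter,
                              curator_filter=curator_filter)
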