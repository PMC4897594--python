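"""Evaluation of automatic annotation and of curation conditions.

Two study questions are supported: how good are the automatic annotations
when each curator in turn is taken as the reference (per-type precision,
recall and F, macro-averaged across curators), and does tool-assisted
curation differ from unassisted curation in annotation counts and per
document/concept/relation times (condition summaries plus a one-tailed
paired t-test with one pair per curator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import AnnotationSetView, match_annotations

__all__ = [
    "CurationLogEntry",
    "ConditionSummary",
    "TTestResult",
    "evaluate_auto",
    "summarize_conditions",
    "paired_t_one_tailed",
    "load_curation_log",
    "dump_curation_log",
]

Condition = Literal["assisted", "non_assisted"]
CONDITIONS: tuple[Condition, Condition] = ("assisted", "non_assisted")


@dataclass(frozen=True)
class CurationLogEntry:
    """One curator-document curation record."""

    curator_id: str
    doc_id: str
    condition: Condition
    elapsed_seconds: float
    concept_count: int
    relation_count: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not math.isfinite(self.elapsed_seconds) or self.elapsed_seconds < 0:
            raise ValueError(f"elapsed_seconds must be finite and >= 0, got "
                             f"{self.elapsed_seconds}")
        if self.concept_count < 0 or self.relation_count < 0:
            raise ValueError("counts must be >= 0")


# ---------------------------------------------------------------------------
# automatic-annotation evaluation
# ---------------------------------------------------------------------------

def _prf(matches: int, n_pred: int, n_ref: int) -> tuple[float, float, float]:
    precision = matches / n_pred if n_pred else float("nan")
    recall = matches / n_ref if n_ref else float("nan")
    if n_pred + n_ref == 0:
        return float("nan"), float("nan"), float("nan")
    return precision, recall, 2 * matches / (n_pred + n_ref)


def evaluate_auto(auto: AnnotationSetView,
                  curators: Sequence[AnnotationSetView],
                  type_filter: Optional[Iterable[str]] = None,
                  average: str = "macro") -> pd.DataFrame:
    """Score automatic annotations against each curator, then average.

    For each curator the automatic view is the prediction and the curator
    the reference, restricted to the documents both hold; exact matching
    (identical fragments and type) is counted per concept type.  With
    ``average="macro"`` per-curator metrics are averaged arithmetically
    across curators (NaN entries, e.g. a type absent for one curator, are
    skipped); ``average="micro"`` sums counts across curators first.

    Returns a DataFrame indexed by concept type with columns
    ``precision``, ``recall``, ``f1``.
    """
    if average not in ("macro", "micro"):
        raise ValueError(f"unknown average {average!r}")
    allowed = set(type_filter) if type_filter is not None else None
    rows: list[dict] = []
    any_shared = False
    for curator in curators:
        shared = sorted(auto.doc_ids() & curator.doc_ids())
        if not shared:
            continue
        any_shared = True
        types: set[str] = set()
        for doc_id in shared:
            for a in auto.for_doc(doc_id) + curator.for_doc(doc_id):
                if allowed is None or a.concept_type in allowed:
                    types.add(a.concept_type)
        for ctype in types:
            matches = n_pred = n_ref = 0
            for doc_id in shared:
                pred = [a for a in auto.for_doc(doc_id) if a.concept_type == ctype]
                ref = [a for a in curator.for_doc(doc_id) if a.concept_type == ctype]
                matches += match_annotations(pred, ref, mode="exact")
                n_pred += len(pred)
                n_ref += len(ref)
            rows.append({"curator": curator.curator_id, "type": ctype,
                         "matches": matches, "n_pred": n_pred, "n_ref": n_ref})
    if not any_shared:
        raise ValueError("automatic view shares no documents with any curator")
    detail = pd.DataFrame(rows)
    if average == "micro":
        grouped = detail.groupby("type")[["matches", "n_pred", "n_ref"]].sum()
        out = grouped.apply(lambda r: pd.Series(
            _prf(r["matches"], r["n_pred"], r["n_ref"]),
            index=["precision", "recall", "f1"]), axis=1)
    else:
        detail[["precision", "recall", "f1"]] = detail.apply(
            lambda r: pd.Series(_prf(r["matches"], r["n_pred"], r["n_ref"])),
            axis=1)
        out = detail.groupby("type")[["precision", "recall", "f1"]].mean()
    return out.sort_index()


# ---------------------------------------------------------------------------
# assisted vs non-assisted condition summaries
# ---------------------------------------------------------------------------

@dataclass
class ConditionSummary:
    """Per-curator and pooled curation statistics for one condition.

    ``per_curator`` is indexed by curator with columns: articles, concepts,
    relations, concepts_per_article, relations_per_article,
    time_per_article, time_per_concept, time_per_relation.  Ratios with a
    zero denominator are NaN ("absent").  ``pooled`` is the unweighted mean
    across curators with at least one article in the condition; curators
    without articles are listed in ``excluded_curators``.
    """

    condition: Condition
    per_curator: pd.DataFrame
    pooled: pd.Series
    excluded_curators: list[str] = field(default_factory=list)


_RATIO_COLUMNS = ["concepts_per_article", "relations_per_article",
                  "time_per_article", "time_per_concept", "time_per_relation"]


def summarize_conditions(log: Sequence[CurationLogEntry]
                         ) -> tuple[ConditionSummary, ConditionSummary]:
    """Summarize a curation log into (assisted, non_assisted) summaries."""
    if not log:
        raise ValueError("curation log is empty")
    seen: set[tuple[str, str]] = set()
    for entry in log:
        key = (entry.curator_id, entry.doc_id)
        if key in seen:
            raise ValueError(f"duplicate log entry for curator/document {key}")
        seen.add(key)
    frame = pd.DataFrame([vars(e) for e in log])
    curators = sorted(frame["curator_id"].unique())
    summaries = []
    for condition in CONDITIONS:
        sub = frame[frame["condition"] == condition]
        rows = {}
        excluded = []
        for curator in curators:
            mine = sub[sub["curator_id"] == curator]
            if mine.empty:
                excluded.append(curator)
                continue
            articles = len(mine)
            concepts = int(mine["concept_count"].sum())
            relations = int(mine["relation_count"].sum())
            time_total = float(mine["elapsed_seconds"].sum())
            rows[curator] = {
                "articles": articles,
                "concepts": concepts,
                "relations": relations,
                "concepts_per_article": concepts / articles,
                "relations_per_article": relations / articles,
                "time_per_article": time_total / articles,
                "time_per_concept": time_total / concepts if concepts else float("nan"),
                "time_per_relation": time_total / relations if relations else float("nan"),
            }
        per_curator = pd.DataFrame.from_dict(rows, orient="index")
        if per_curator.empty:
            per_curator = pd.DataFrame(
                columns=["articles", "concepts", "relations"] + _RATIO_COLUMNS)
        pooled = per_curator.mean()
        summaries.append(ConditionSummary(condition=condition,
                                          per_curator=per_curator,
                                          pooled=pooled,
                                          excluded_curators=excluded))
    return summaries[0], summaries[1]


# ---------------------------------------------------------------------------
# one-tailed paired t-test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def paired_t_one_tailed(x: Sequence[float], y: Sequence[float],
                        direction: str = "greater") -> TTestResult:
    """One-tailed paired t-test on positionally paired samples.

    With differences ``d = x - y``, the statistic is
    ``t = mean(d) / (sd(d) / sqrt(n))`` on ``n - 1`` degrees of freedom
    (sd is the n-1 sample standard deviation).  ``direction="greater"``
    tests mean(x) > mean(y) (upper tail), ``"less"`` the lower tail.  The
    direction must be stated by the caller; it is never inferred from the
    data.
    """
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and equally long")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("all paired differences are identical; t undefined")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    if direction == "greater":
        p = float(stats.t.sf(t, df))
    else:
        p = float(stats.t.cdf(t, df))
    return TTestResult(t=float(t), df=df, p=p)


# ---------------------------------------------------------------------------
# curation-log file I/O (tab-separated)
# ---------------------------------------------------------------------------

_LOG_COLUMNS = ["curator_id", "doc_id", "condition", "elapsed_seconds",
                "concept_count", "relation_count"]


def load_curation_log(text: str) -> list[CurationLogEntry]:
    entries = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 6:
            raise ValueError(f"curation log line {line_no}: expected 6 fields, "
                             f"got {len(fields)}")
        entries.append(CurationLogEntry(
            curator_id=fields[0], doc_id=fields[1], condition=fields[2],
            elapsed_seconds=float(fields[3]), concept_count=int(fields[4]),
            relation_count=int(fields[5])))
    return entries


def dump_curation_log(log: Sequence[CurationLogEntry]) -> str:
    lines = ["\t".join([e.curator_id, e.doc_id, e.condition,
                        f"{e.elapsed_seconds:.3f}", str(e.concept_count),
                        str(e.relation_count)]) for e in log]
    return "\n".join(lines) + ("\n" if lines else "")
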