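"""Evaluation protocol: strict-span mention scoring, document-level concept
scoring, inter-annotator agreement, and pre-annotation accuracy.

Mention-level scoring uses strict boundaries: a prediction is a true positive
only when both its start and end characters equal a gold mention's.
Concept-level scoring compares, per document, the *set* of identifiers
annotated anywhere in the document against the set predicted as present
(composite identifier assignments are split into their member ids; mentions
left unresolved contribute nothing).

Inter-annotator agreement uses a deliberately strict unit scheme: a pair of
annotations with identical spans and identical identifier sets is one exact
unit; identical spans with different identifiers is one identifier-mismatch
unit; every other annotation on either side — including partially
overlapping pairs — counts as a single-annotation unit on its own.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Tuple

from .bioc import CHEMICAL, Document

__all__ = [
    "EvalResult",
    "AgreementReport",
    "strict_span_eval",
    "doc_concept_eval",
    "pairwise_agreement",
    "preannotation_accuracy",
]


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> Dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }


def _align(gold: Iterable[Document], pred: Iterable[Document]):
    gold_by_id = {d.doc_id: d for d in gold}
    pred_by_id = {d.doc_id: d for d in pred}
    extra = sorted(set(pred_by_id) - set(gold_by_id))
    if extra:
        raise ValueError(f"predicted documents absent from gold: {extra}")
    return [(g, pred_by_id.get(doc_id)) for doc_id, g in gold_by_id.items()]


def _chem_span_counts(doc: Document) -> Counter:
    return Counter(
        (m.start, m.end) for m in doc.mentions if m.entity_type == CHEMICAL
    )


def strict_span_eval(
    gold: Iterable[Document], pred: Iterable[Document]
) -> EvalResult:
    """Mention-level P/R/F with strict boundaries.

    Each gold mention matches at most one prediction (identical spans pair
    one-to-one); unmatched predictions are false positives, unmatched gold
    mentions false negatives.
    """
    tp = fp = fn = 0
    for g, p in _align(gold, pred):
        gc = _chem_span_counts(g)
        pc = _chem_span_counts(p) if p is not None else Counter()
        matched = sum((gc & pc).values())
        tp += matched
        fp += sum(pc.values()) - matched
        fn += sum(gc.values()) - matched
    return EvalResult(tp, fp, fn)


def _doc_concept_set(doc: Document) -> FrozenSet[str]:
    ids = set()
    for m in doc.mentions:
        if m.entity_type == CHEMICAL:
            ids |= m.identifiers  # composites are already sets; "-" never stored
    return frozenset(ids)


def doc_concept_eval(
    gold: Iterable[Document], pred: Iterable[Document]
) -> EvalResult:
    """Document-level concept-set P/R/F accumulated over documents."""
    tp = fp = fn = 0
    for g, p in _align(gold, pred):
        gs = _doc_concept_set(g)
        ps = _doc_concept_set(p) if p is not None else frozenset()
        tp += len(gs & ps)
        fp += len(ps - gs)
        fn += len(gs - ps)
    return EvalResult(tp, fp, fn)


@dataclass(frozen=True)
class AgreementReport:
    exact_pairs: int
    mismatch_id_pairs: int
    single_annotations: int

    @property
    def total_units(self) -> int:
        return self.exact_pairs + self.mismatch_id_pairs + self.single_annotations

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.total_units if self.total_units else 0.0

    @property
    def exact_pct(self) -> float:
        return self._pct(self.exact_pairs)

    @property
    def mismatch_pct(self) -> float:
        return self._pct(self.mismatch_id_pairs)

    @property
    def single_pct(self) -> float:
        return self._pct(self.single_annotations)

    def as_dict(self, ndigits: int = 1) -> Dict[str, float]:
        return {
            "exact_pairs": self.exact_pairs,
            "mismatch_id_pairs": self.mismatch_id_pairs,
            "single_annotations": self.single_annotations,
            "exact_pct": round(self.exact_pct, ndigits),
            "mismatch_pct": round(self.mismatch_pct, ndigits),
            "single_pct": round(self.single_pct, ndigits),
        }

    def __add__(self, other: "AgreementReport") -> "AgreementReport":
        return AgreementReport(
            self.exact_pairs + other.exact_pairs,
            self.mismatch_id_pairs + other.mismatch_id_pairs,
            self.single_annotations + other.single_annotations,
        )


def _span_id_map(doc: Document) -> Dict[Tuple[int, int], List[FrozenSet[str]]]:
    out: Dict[Tuple[int, int], List[FrozenSet[str]]] = {}
    for m in doc.mentions:
        out.setdefault((m.start, m.end), []).append(frozenset(m.identifiers))
    return out


def pairwise_agreement(doc_a: Document, doc_b: Document) -> AgreementReport:
    """Agreement units between two annotated versions of the same text.

    Identical spans with equal identifier sets are exact pairs; identical
    spans with different identifier sets are identifier mismatches; anything
    else (missed or partially overlapping annotations) is counted as single
    annotations, one per side.
    """
    if doc_a.doc_id != doc_b.doc_id:
        raise ValueError(f"document ids differ: {doc_a.doc_id!r} vs {doc_b.doc_id!r}")
    if [p.text for p in doc_a.passages] != [p.text for p in doc_b.passages]:
        raise ValueError(f"document texts differ for {doc_a.doc_id!r}")
    a_map = _span_id_map(doc_a)
    b_map = _span_id_map(doc_b)
    exact = mismatch = single = 0
    for span in set(a_map) | set(b_map):
        a_ids = list(a_map.get(span, []))
        b_ids = list(b_map.get(span, []))
        # pair duplicates of the identical span greedily: equal id-sets first
        for ids in list(a_ids):
            if ids in b_ids:
                exact += 1
                a_ids.remove(ids)
                b_ids.remove(ids)
        n_mismatch = min(len(a_ids), len(b_ids))
        mismatch += n_mismatch
        single += len(a_ids) + len(b_ids) - 2 * n_mismatch
    return AgreementReport(exact, mismatch, single)


def preannotation_accuracy(
    final: Iterable[Document], pre: Iterable[Document]
) -> Tuple[EvalResult, EvalResult]:
    """Accuracy of automatic pre-annotations against the final gold standard:
    (mention-level strict-span result, document-level concept-set result)."""
    final = list(final)
    pre = list(pre)
    return strict_span_eval(final, pre), doc_concept_eval(final, pre)
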