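"""Corpus-construction machinery: document-selection scoring and
train/dev/test splitting with distribution diagnostics.

Document selection models the procedure used to build a chemical-rich,
diverse annotation corpus: hard eligibility filters (abstract present, at
least one reference, not a retraction/correction/editorial), removal of
abnormally long articles (passage count more than three standard deviations
above the mean), then soft per-article weights — presence of other
biomedical entities, disagreement between several chemical taggers, TF-IDF
dissimilarity from the articles already selected, and a random component for
diversity — combined linearly into a ranking score.

Splitting samples proportionally from each annotation batch and, over many
seeded restarts, keeps the split whose partition word distributions are
closest (Jensen–Shannon divergence) to the full corpus; Welch t-tests
compare per-article annotation counts in each partition against the corpus.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats
from scipy.spatial.distance import jensenshannon

from .bioc import CHEMICAL, Document

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionScore",
    "SplitPlan",
    "EXCLUDED_PUBLICATION_TYPES",
    "eligibility_filter",
    "passage_length_filter",
    "TfidfSpace",
    "dissimilarity_weight",
    "model_disagreement_weight",
    "combined_score",
    "make_split",
]

EXCLUDED_PUBLICATION_TYPES = {"retracted", "retraction", "correction", "editorial"}

WEIGHT_NAMES = ("entity_presence", "model_disagreement", "dissimilarity", "random")


@dataclass
class SelectionScore:
    doc_id: str
    eligibility: bool
    weights: Dict[str, float] = field(default_factory=dict)
    combined: Optional[float] = None


@dataclass
class SplitPlan:
    assignment: Dict[str, str]  # doc_id -> partition name
    sizes: Tuple[int, ...]
    divergence: float
    t_test_p: Dict[str, float]


# ---------------------------------------------------------------------------
# filters

def _truthy(value: str) -> bool:
    return str(value).strip().lower() in ("1", "true", "yes", "y")


def eligibility_filter(doc: Document) -> bool:
    """Hard filters on article metadata.

    Requires ``has_abstract`` truthy, ``reference_count`` >= 1, and no
    publication type among the excluded set (comma-separated
    ``publication_types``).  A missing metadata field fails the filter.
    """
    meta = doc.metadata
    for key in ("has_abstract", "reference_count", "publication_types"):
        if key not in meta:
            logger.warning("%s: missing metadata %r; treated as ineligible",
                           doc.doc_id, key)
            return False
    if not _truthy(meta["has_abstract"]):
        return False
    try:
        if int(meta["reference_count"]) < 1:
            return False
    except ValueError:
        logger.warning("%s: unparseable reference_count", doc.doc_id)
        return False
    types = {t.strip().lower() for t in meta["publication_types"].split(",") if t.strip()}
    return not (types & EXCLUDED_PUBLICATION_TYPES)


def passage_length_filter(
    docs: Sequence[Document], n_sigma: float = 3.0
) -> Tuple[List[Document], float]:
    """Remove abnormally long articles by passage count.

    The threshold is mean + ``n_sigma``·(sample standard deviation) of the
    passage counts; documents strictly above it are removed.
    """
    if len(docs) < 2:
        raise ValueError("passage_length_filter requires at least 2 documents")
    counts = np.array([len(d.passages) for d in docs], dtype=float)
    threshold = float(counts.mean() + n_sigma * counts.std(ddof=1))
    kept = [d for d, c in zip(docs, counts) if c <= threshold]
    return kept, threshold


# ---------------------------------------------------------------------------
# selection weights

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


def tokenize(text: str) -> List[str]:
    return [t.lower() for t in _TOKEN_RE.findall(text)]


def doc_term_counts(doc: Document) -> Counter:
    counts: Counter = Counter()
    for p in doc.passages:
        counts.update(tokenize(p.text))
    return counts


class TfidfSpace:
    """TF-IDF vectors over a fixed background: idf(t) = log(N / df(t)).

    The background document frequencies stand in for a large reference corpus
    (in production, all of the literature); terms unseen in the background
    get df = 1.
    """

    def __init__(self, background_doc_freqs: Mapping[str, int], n_background: int):
        if n_background < 1:
            raise ValueError("n_background must be positive")
        self.df = dict(background_doc_freqs)
        self.n = n_background

    def vector(self, term_counts: Mapping[str, int]) -> Dict[str, float]:
        return {
            t: c * math.log(self.n / self.df.get(t, 1))
            for t, c in term_counts.items()
            if c
        }

    @staticmethod
    def centroid(vectors: Sequence[Mapping[str, float]]) -> Dict[str, float]:
        acc: Dict[str, float] = {}
        for v in vectors:
            for t, x in v.items():
                acc[t] = acc.get(t, 0.0) + x
        return {t: x / len(vectors) for t, x in acc.items()}

    @staticmethod
    def cosine(a: Mapping[str, float], b: Mapping[str, float]) -> float:
        dot = sum(x * b.get(t, 0.0) for t, x in a.items())
        na = math.sqrt(sum(x * x for x in a.values()))
        nb = math.sqrt(sum(x * x for x in b.values()))
        if na == 0.0 or nb == 0.0:
            return 0.0
        return dot / (na * nb)


def dissimilarity_weight(
    doc_term_counts_: Mapping[str, int],
    selected_term_counts: Sequence[Mapping[str, int]],
    background_doc_freqs: Mapping[str, int],
    n_background: int,
) -> float:
    """1 − cosine(TF-IDF(doc), centroid of already-selected articles).

    With nothing selected yet every candidate gets weight 1; a zero vector
    (no indexable terms) also gets weight 1, logged.
    """
    space = TfidfSpace(background_doc_freqs, n_background)
    if not selected_term_counts:
        return 1.0
    vec = space.vector(doc_term_counts_)
    if not vec:
        logger.warning("document has an all-zero TF-IDF vector; weight 1")
        return 1.0
    centroid = space.centroid([space.vector(tc) for tc in selected_term_counts])
    return 1.0 - space.cosine(vec, centroid)


def model_disagreement_weight(
    prediction_sets: Sequence[Iterable[Tuple[int, int]]],
) -> float:
    """1 − mean pairwise Jaccard similarity of the models' span sets.

    Spans are compared exactly; two models that emit identical sets have
    Jaccard 1 (two empty sets count as identical).
    """
    sets: List[Set[Tuple[int, int]]] = [set(s) for s in prediction_sets]
    if len(sets) < 2:
        raise ValueError("need predictions from at least 2 models")
    sims = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            union = sets[i] | sets[j]
            sims.append(len(sets[i] & sets[j]) / len(union) if union else 1.0)
    return 1.0 - float(np.mean(sims))


def combined_score(
    weights: Mapping[str, float],
    coefficients: Mapping[str, float],
    rng: np.random.Generator,
) -> float:
    """Linear combination of the selection weights, the random component
    drawn uniform[0,1) from ``rng``.  Coefficients must be non-negative and
    sum to 1."""
    coeffs = {name: float(coefficients.get(name, 0.0)) for name in WEIGHT_NAMES}
    if any(c < 0 for c in coeffs.values()):
        raise ValueError("coefficients must be non-negative")
    if not math.isclose(sum(coeffs.values()), 1.0, abs_tol=1e-9):
        raise ValueError(f"coefficients must sum to 1, got {sum(coeffs.values())}")
    score = 0.0
    for name in WEIGHT_NAMES:
        if name == "random":
            w = float(rng.uniform()) if coeffs[name] > 0 else 0.0
        else:
            w = float(weights.get(name, 0.0))
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight {name}={w} outside [0,1]")
        score += coeffs[name] * w
    return score


# ---------------------------------------------------------------------------
# splitting

def _largest_remainder_matrix(
    batch_sizes: Dict[str, int], sizes: Sequence[int]
) -> Dict[str, List[int]]:
    """Per-batch partition counts: proportional allocation by largest
    remainder, reconciled so both batch totals and partition totals hold."""
    total = sum(batch_sizes.values())
    if sum(sizes) != total:
        raise ValueError(f"partition sizes {sizes} do not sum to corpus size {total}")
    batches = sorted(batch_sizes)
    floors = {b: [0] * len(sizes) for b in batches}
    fracs = []
    for b in batches:
        for p, s in enumerate(sizes):
            quota = s * batch_sizes[b] / total
            floors[b][p] = int(math.floor(quota))
            fracs.append((quota - floors[b][p], b, p))
    row_resid = {b: batch_sizes[b] - sum(floors[b]) for b in batches}
    col_resid = [sizes[p] - sum(floors[b][p] for b in batches) for p in range(len(sizes))]
    # round up the largest fractional cells first, respecting both residuals
    for frac, b, p in sorted(fracs, key=lambda x: (-x[0], x[1], x[2])):
        if row_resid[b] > 0 and col_resid[p] > 0 and frac > 0:
            floors[b][p] += 1
            row_resid[b] -= 1
            col_resid[p] -= 1
    # fallback for degenerate residuals (possible only with zero fractions)
    for b in batches:
        while row_resid[b] > 0:
            p = next(i for i, r in enumerate(col_resid) if r > 0)
            floors[b][p] += 1
            row_resid[b] -= 1
            col_resid[p] -= 1
    return floors


def _token_distribution(docs: Sequence[Document], vocab: List[str]) -> np.ndarray:
    counts: Counter = Counter()
    for d in docs:
        counts.update(doc_term_counts(d))
    vec = np.array([counts.get(t, 0) for t in vocab], dtype=float)
    total = vec.sum()
    return vec / total if total else vec


def _chem_counts(docs: Sequence[Document]) -> np.ndarray:
    return np.array(
        [sum(1 for m in d.mentions if m.entity_type == CHEMICAL) for d in docs],
        dtype=float,
    )


PARTITION_NAMES = ("train", "dev", "test")


def make_split(
    docs: Sequence[Document],
    batch_labels: Mapping[str, str],
    sizes: Tuple[int, int, int],
    n_restarts: int = 100,
    seed: int = 0,
) -> SplitPlan:
    """Proportional-by-batch split minimizing word-distribution divergence.

    Over ``n_restarts`` seeded random proportional allocations, keeps the one
    with the smallest total Jensen–Shannon divergence between each non-empty
    partition's token distribution and the full corpus's.  The returned plan
    carries two-sided Welch t-test p-values comparing each partition's
    per-article Chemical annotation counts with the full corpus.
    """
    docs = list(docs)
    by_batch: Dict[str, List[Document]] = {}
    for d in docs:
        if d.doc_id not in batch_labels:
            raise ValueError(f"no batch label for document {d.doc_id!r}")
        by_batch.setdefault(batch_labels[d.doc_id], []).append(d)
    matrix = _largest_remainder_matrix(
        {b: len(ds) for b, ds in by_batch.items()}, sizes
    )
    vocab = sorted({t for d in docs for t in doc_term_counts(d)})
    corpus_dist = _token_distribution(docs, vocab)
    rng = np.random.default_rng(seed)
    best: Optional[Tuple[float, Dict[str, str]]] = None
    for _ in range(max(1, n_restarts)):
        assignment: Dict[str, str] = {}
        for b in sorted(by_batch):
            ds = list(by_batch[b])
            order = rng.permutation(len(ds))
            k = 0
            for p, name in enumerate(PARTITION_NAMES):
                for _i in range(matrix[b][p]):
                    assignment[ds[order[k]].doc_id] = name
                    k += 1
        divergence = 0.0
        for name in PARTITION_NAMES:
            part = [d for d in docs if assignment[d.doc_id] == name]
            if not part:
                continue
            part_dist = _token_distribution(part, vocab)
            divergence += float(jensenshannon(part_dist, corpus_dist, base=2) ** 2)
        if best is None or divergence < best[0]:
            best = (divergence, assignment)
    divergence, assignment = best
    all_counts = _chem_counts(docs)
    t_test_p: Dict[str, float] = {}
    for name in PARTITION_NAMES:
        part = [d for d in docs if assignment[d.doc_id] == name]
        if not part:
            continue
        part_counts = _chem_counts(part)
        if len(part) == len(docs):
            t_test_p[name] = 1.0  # partition is the corpus itself
        elif len(part) < 2:
            t_test_p[name] = float("nan")
        else:
            t_test_p[name] = float(
                stats.ttest_ind(part_counts, all_counts, equal_var=False).pvalue
            )
    return SplitPlan(
        assignment=assignment, sizes=tuple(sizes),
        divergence=divergence, t_test_p=t_test_p,
    )
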