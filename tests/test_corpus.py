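"""Document-selection scoring and corpus splitting."""

import itertools
import math

import numpy as np
import pytest

from chemnorm.bioc import Document, Mention, Passage, Span
from chemnorm.corpus import (
    TfidfSpace,
    combined_score,
    dissimilarity_weight,
    doc_term_counts,
    eligibility_filter,
    make_split,
    model_disagreement_weight,
    passage_length_filter,
)


def doc_with_meta(doc_id="d", has_abstract="true", refs="12",
                  types="research-article", n_passages=1):
    return Document(
        doc_id=doc_id,
        passages=[Passage(i * 10, "word " * 3) for i in range(n_passages)],
        metadata={
            "has_abstract": has_abstract,
            "reference_count": refs,
            "publication_types": types,
        },
    )


@pytest.mark.parametrize(
    ("kwargs", "expected"),
    [
        ({}, True),
        ({"types": "correction"}, False),
        ({"types": "research-article,editorial"}, False),
        ({"types": "Retracted"}, False),
        ({"refs": "0"}, False),
        ({"has_abstract": "false"}, False),
    ],
)
def test_eligibility(kwargs, expected):
    assert eligibility_filter(doc_with_meta(**kwargs)) is expected


def test_eligibility_missing_metadata_fails():
    doc = doc_with_meta()
    del doc.metadata["reference_count"]
    assert eligibility_filter(doc) is False


def test_passage_length_filter_arithmetic():
    docs = [doc_with_meta(doc_id=f"d{i}", n_passages=n) for i, n in
            enumerate([8, 10, 12, 17])]
    # threshold computed over all four: mean 11.75, sd 3.86 -> 23.3; none cut
    kept, thr = passage_length_filter(docs)
    assert len(kept) == 4
    # with the three-document base {8,10,12}: mean 10, sd 2 -> threshold 16
    kept3, thr3 = passage_length_filter(docs[:3])
    assert thr3 == pytest.approx(16.0)
    over = docs[:3] + [doc_with_meta(doc_id="big", n_passages=17)]
    counts = np.array([8.0, 10, 12, 17])
    expected_thr = counts.mean() + 3 * counts.std(ddof=1)
    kept4, thr4 = passage_length_filter(over)
    assert thr4 == pytest.approx(float(expected_thr))


def test_passage_filter_degenerate_equal_counts():
    docs = [doc_with_meta(doc_id=f"d{i}", n_passages=5) for i in range(4)]
    kept, thr = passage_length_filter(docs)
    assert thr == 5.0
    assert len(kept) == 4  # filter is strictly greater-than


def test_passage_filter_requires_two_docs():
    with pytest.raises(ValueError):
        passage_length_filter([doc_with_meta()])


def test_dissimilarity_weight_extremes():
    background = {"alpha": 2, "beta": 2, "gamma": 1}
    doc_tc = {"alpha": 3, "beta": 1}
    # identical to the single selected article -> cosine 1 -> weight 0
    assert dissimilarity_weight(doc_tc, [dict(doc_tc)], background, 10) == (
        pytest.approx(0.0)
    )
    # orthogonal vocabulary -> cosine 0 -> weight 1
    assert dissimilarity_weight({"gamma": 5}, [{"alpha": 1}], background, 10) == 1.0
    # nothing selected yet -> weight 1
    assert dissimilarity_weight(doc_tc, [], background, 10) == 1.0


def test_dissimilarity_weight_hand_computed():
    # two-term toy corpus, idf = log(N/df)
    background = {"a": 2, "b": 1}
    n = 4
    doc = {"a": 1, "b": 1}
    sel = {"a": 2, "b": 0}
    idf_a, idf_b = math.log(4 / 2), math.log(4 / 1)
    va = (1 * idf_a, 1 * idf_b)
    vc = (2 * idf_a, 0.0)
    cos = (va[0] * vc[0]) / (
        math.hypot(*va) * math.hypot(*vc)
    )
    got = dissimilarity_weight(doc, [sel], background, n)
    assert got == pytest.approx(1 - cos)


def test_model_disagreement():
    a = {(0, 5), (10, 15), (20, 25)}
    assert model_disagreement_weight([a, set(a)]) == 0.0
    assert model_disagreement_weight([{(0, 5)}, {(10, 15)}]) == 1.0
    # two models sharing 1 of 3 distinct spans: 1 - 1/3
    assert model_disagreement_weight(
        [{(0, 5), (10, 15)}, {(0, 5), (20, 25)}]
    ) == pytest.approx(2 / 3)
    assert model_disagreement_weight([set(), set()]) == 0.0
    with pytest.raises(ValueError):
        model_disagreement_weight([a])


def test_combined_score_arithmetic():
    class FixedRng:
        def uniform(self):
            return 0.5

    weights = {"entity_presence": 1.0, "model_disagreement": 1.0,
               "dissimilarity": 1.0}
    coeffs = {"entity_presence": 0.3, "model_disagreement": 0.3,
              "dissimilarity": 0.3, "random": 0.1}
    assert combined_score(weights, coeffs, FixedRng()) == pytest.approx(0.95)


def test_combined_score_seed_and_validation():
    weights = {"entity_presence": 0.5, "model_disagreement": 0.2,
               "dissimilarity": 0.1}
    coeffs = {"entity_presence": 0.25, "model_disagreement": 0.25,
              "dissimilarity": 0.25, "random": 0.25}
    s1 = combined_score(weights, coeffs, np.random.default_rng(9))
    s2 = combined_score(weights, coeffs, np.random.default_rng(9))
    assert s1 == s2
    no_random = {**coeffs, "random": 0.0, "entity_presence": 0.5}
    a = combined_score(weights, no_random, np.random.default_rng(1))
    b = combined_score(weights, no_random, np.random.default_rng(2))
    assert a == b  # zero coefficient on random: seed-independent
    with pytest.raises(ValueError, match="sum to 1"):
        combined_score(weights, {"entity_presence": 0.9}, np.random.default_rng(0))


def corpus_docs(n, words_per_doc=30, seed=0):
    rng = np.random.default_rng(seed)
    vocab = ["alpha", "beta", "gamma", "delta", "epsilon"]
    docs = []
    for i in range(n):
        words = [vocab[int(rng.integers(0, len(vocab)))] for _ in range(words_per_doc)]
        text = " ".join(words)
        n_chem = int(rng.integers(0, 6))
        mentions = [
            Mention(spans=[Span(0, 5)], text=text[:5], identifiers=set())
            for _ in range(n_chem)
        ]
        docs.append(
            Document(doc_id=f"d{i:03d}", passages=[Passage(0, text)],
                     mentions=mentions)
        )
    return docs


def test_split_self_partition_is_trivial():
    docs = corpus_docs(8)
    labels = {d.doc_id: "batch1" for d in docs}
    plan = make_split(docs, labels, (8, 0, 0), n_restarts=3, seed=1)
    assert plan.divergence == pytest.approx(0.0, abs=1e-12)
    assert plan.t_test_p["train"] == 1.0
    assert set(plan.assignment.values()) == {"train"}


def test_split_proportionality_largest_remainder():
    docs = corpus_docs(6)
    labels = {d.doc_id: ("batch1" if i < 4 else "batch2")
              for i, d in enumerate(docs)}
    plan = make_split(docs, labels, (4, 1, 1), n_restarts=5, seed=2)
    sizes = {p: sum(1 for v in plan.assignment.values() if v == p)
             for p in ("train", "dev", "test")}
    assert sizes == {"train": 4, "dev": 1, "test": 1}
    # per batch, each partition's count is within 1 of exact proportionality
    for batch, members in (("batch1", 4), ("batch2", 2)):
        for part, size in sizes.items():
            got = sum(
                1 for d in docs
                if labels[d.doc_id] == batch and plan.assignment[d.doc_id] == part
            )
            assert abs(got - size * members / 6) < 1.0


def test_split_deterministic_and_exhaustive():
    docs = corpus_docs(12, seed=5)
    labels = {d.doc_id: f"batch{i % 2 + 1}" for i, d in enumerate(docs)}
    p1 = make_split(docs, labels, (6, 3, 3), n_restarts=20, seed=7)
    p2 = make_split(docs, labels, (6, 3, 3), n_restarts=20, seed=7)
    assert p1 == p2
    assert sorted(p1.assignment) == sorted(d.doc_id for d in docs)
    assert sum(1 for v in p1.assignment.values() if v == "train") == 6


def test_split_p_values_rise_for_matched_partitions():
    # partitions drawn from the same distribution should rarely look different
    docs = corpus_docs(30, seed=8)
    labels = {d.doc_id: "batch1" for d in docs}
    plan = make_split(docs, labels, (20, 5, 5), n_restarts=50, seed=3)
    assert all(0.0 <= p <= 1.0 for p in plan.t_test_p.values())
    assert plan.t_test_p["train"] > 0.05


def test_split_size_mismatch_is_an_error():
    docs = corpus_docs(5)
    labels = {d.doc_id: "batch1" for d in docs}
    with pytest.raises(ValueError, match="sum"):
        make_split(docs, labels, (4, 2, 2), n_restarts=1, seed=0)


def test_tfidf_cosine_is_length_invariant():
    space = TfidfSpace({"a": 1, "b": 2}, 5)
    v1 = space.vector({"a": 1, "b": 2})
    v2 = space.vector({"a": 10, "b": 20})
    assert TfidfSpace.cosine(v1, v2) == pytest.approx(1.0)


def test_doc_term_counts_tokenization():
    doc = Document(doc_id="t", passages=[Passage(0, "Alpha, beta ALPHA 42.")])
    counts = doc_term_counts(doc)
    assert counts == {"alpha": 2, "beta": 1, "42": 1}
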