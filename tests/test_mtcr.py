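"""The candidate-resolution pipeline: cascade order, disambiguation,
hierarchy filter, dictionary tagging, end-to-end normalization."""

import pytest

from chemnorm.bioc import Document, Mention, Passage, Span
from chemnorm.lexicon import Concept, TreePolicy, build_name_index, xref_to_mesh
from chemnorm.mtcr import (
    CASCADE_ORDER,
    CandidateSet,
    LexiconBundle,
    PipelineConfig,
    Stage,
    Status,
    candidate_cascade,
    dictionary_tag,
    disambiguate_document,
    filter_chemical_ids,
    normalize_collection,
)
from chemnorm.textnorm import NormalizationLevel, normalize


@pytest.fixture
def small_bundle() -> LexiconBundle:
    mesh = [
        Concept("MESH:D1", "MESH", ["triphenyl phosphate"],
                xrefs={"CAS": "115-86-6"}, tree_numbers=["D02.705"]),
        Concept("MESH:D2", "MESH", ["fatty acids"], tree_numbers=["D10.251"]),
        Concept("MESH:D3", "MESH", ["mitotane"], tree_numbers=["D02.200"]),
        Concept("MESH:D9", "MESH", ["renal carcinoma"], tree_numbers=["C04.557"]),
    ]
    aux = [
        Concept("UNII:U1", "UNII", ["TPHP"], xrefs={"CAS": "115-86-6"}),
        Concept("CHEBI:C1", "CHEBI", ["orphan name"]),  # no xref: maps nowhere
    ]
    return LexiconBundle(mesh, aux)


def brute_force_stages(text: str, bundle: LexiconBundle):
    """All-stage oracle: evaluate every stage independently, first hit wins."""
    if not any(c.isalpha() for c in text):
        return set(), Stage.NONE
    per_stage = {}
    for stage, level, multi in [
        (Stage.EXACT_MESH, NormalizationLevel.EXACT, False),
        (Stage.RELAXED_MESH, NormalizationLevel.RELAXED, False),
        (Stage.RELAXED_PLURAL_MESH, NormalizationLevel.RELAXED_PLURAL, False),
        (Stage.RELAXED_MULTI, NormalizationLevel.RELAXED, True),
        (Stage.RELAXED_PLURAL_MULTI, NormalizationLevel.RELAXED_PLURAL, True),
    ]:
        if multi:
            hits = set()
            for c in bundle.aux_concepts:
                index = build_name_index([c], level)
                if index.lookup(text):
                    hits |= xref_to_mesh(c, bundle.mesh_concepts)
        else:
            hits = build_name_index(bundle.mesh_concepts, level).lookup(text)
        per_stage[stage] = hits
    for stage in CASCADE_ORDER:
        if per_stage[stage]:
            return per_stage[stage], stage
    return set(), Stage.NONE


@pytest.mark.parametrize(
    ("text", "ids", "stage"),
    [
        ("triphenyl phosphate", {"MESH:D1"}, Stage.EXACT_MESH),
        ("Triphenyl Phosphate", {"MESH:D1"}, Stage.RELAXED_MESH),
        ("Fatty Acid", {"MESH:D2"}, Stage.RELAXED_PLURAL_MESH),
        ("TPHP", {"MESH:D1"}, Stage.RELAXED_MULTI),
        ("TPHPs", {"MESH:D1"}, Stage.RELAXED_PLURAL_MULTI),
        ("115-86-6", set(), Stage.NONE),     # no alphabetic character
        ("unknowndrugname", set(), Stage.NONE),
        ("orphan name", set(), Stage.NONE),  # aux hit with no MeSH mapping
    ],
)
def test_cascade_stages(small_bundle, text, ids, stage):
    cs = candidate_cascade(text, small_bundle)
    assert (cs.candidates, cs.stage) == (ids, stage)
    assert cs.status == (
        Status.UNKNOWN if not ids
        else Status.RESOLVED if len(ids) == 1
        else Status.AMBIGUOUS
    )
    assert brute_force_stages(text, small_bundle) == (ids, stage)


def test_cascade_first_hit_matches_oracle_on_fixture(fixture_bundle, fixture_collection):
    _, gold = fixture_collection
    surfaces = {m.text for d in gold for m in d.mentions}
    surfaces |= {s.upper() for s in list(surfaces)[:20]}
    for text in sorted(surfaces):
        cs = candidate_cascade(text, fixture_bundle)
        assert brute_force_stages(text, fixture_bundle) == (cs.candidates, cs.stage)


def test_disambiguation_by_unambiguous_co_mention():
    candsets = [
        CandidateSet(("d", (0, 3)), {"MESH:Ddye", "MESH:Dtime"},
                     Stage.RELAXED_MESH, Status.AMBIGUOUS),
        CandidateSet(("d", (10, 40)), {"MESH:Ddye"},
                     Stage.EXACT_MESH, Status.RESOLVED),
    ]
    out = disambiguate_document(candsets)
    assert out[0].candidates == {"MESH:Ddye"}
    assert out[0].status == Status.RESOLVED
    assert out[1].candidates == {"MESH:Ddye"}


def test_disambiguation_leaves_empty_intersection_alone():
    candsets = [
        CandidateSet(("d", (0, 3)), {"MESH:DA", "MESH:DB"},
                     Stage.RELAXED_MESH, Status.AMBIGUOUS),
        CandidateSet(("d", (10, 14)), {"MESH:DC"},
                     Stage.EXACT_MESH, Status.RESOLVED),
    ]
    out = disambiguate_document(candsets)
    assert out[0].candidates == {"MESH:DA", "MESH:DB"}
    assert out[0].status == Status.AMBIGUOUS


def test_disambiguation_identity_without_ambiguity():
    candsets = [
        CandidateSet(("d", (0, 3)), {"MESH:DA"}, Stage.EXACT_MESH, Status.RESOLVED),
        CandidateSet(("d", (5, 9)), set(), Stage.NONE, Status.UNKNOWN),
    ]
    assert disambiguate_document(candsets) == candsets


def test_disambiguation_never_increases_counts(fixture_bundle, fixture_collection):
    _, gold = fixture_collection
    for doc in gold:
        before = [
            candidate_cascade(m.text, fixture_bundle, (doc.doc_id, (m.start, m.end)))
            for m in doc.mentions
        ]
        after = disambiguate_document(before)
        for b, a in zip(before, after):
            assert len(a.candidates) <= len(b.candidates)
            if len(b.candidates) <= 1:
                assert a == b


def test_hierarchy_filter(small_bundle):
    cs = CandidateSet(("d", (0, 1)), {"MESH:D1", "MESH:D9"},
                      Stage.RELAXED_MESH, Status.AMBIGUOUS)
    out = filter_chemical_ids(cs, small_bundle.mesh_by_id)
    assert out.candidates == {"MESH:D1"}
    assert out.status == Status.RESOLVED
    all_gone = filter_chemical_ids(
        CandidateSet(("d", (0, 1)), {"MESH:D9"}, Stage.EXACT_MESH, Status.RESOLVED),
        small_bundle.mesh_by_id,
    )
    assert all_gone.candidates == set()
    assert all_gone.status == Status.UNKNOWN
    unknown_id = filter_chemical_ids(
        CandidateSet(("d", (0, 1)), {"MESH:D404"}, Stage.EXACT_MESH, Status.RESOLVED),
        small_bundle.mesh_by_id,
    )
    assert unknown_id.candidates == set()


def test_dictionary_tag_longest_leftmost(small_bundle):
    doc = Document(
        doc_id="t",
        passages=[Passage(0, "triphenyl phosphate inhibits fatty acids here")],
    )
    index = small_bundle.mesh_index[NormalizationLevel.RELAXED]
    tagged = dictionary_tag(doc, index)
    spans = [(m.start, m.end, m.text) for m in tagged.mentions]
    assert spans == [
        (0, 19, "triphenyl phosphate"),
        (29, 40, "fatty acids"),
    ]
    assert all(m.identifiers == set() for m in tagged.mentions)


def test_dictionary_tag_prefers_longer_over_nested():
    mesh = [
        Concept("MESH:D2", "MESH", ["fatty acid"], tree_numbers=["D10"]),
        Concept("MESH:D5", "MESH", ["acid"], tree_numbers=["D01"]),
    ]
    bundle = LexiconBundle(mesh, [])
    doc = Document(doc_id="t", passages=[Passage(0, "some fatty acid level")])
    tagged = dictionary_tag(doc, bundle.mesh_index[NormalizationLevel.RELAXED])
    assert [(m.text,) for m in tagged.mentions] == [("fatty acid",)]


def test_dictionary_tag_empty_lexicon():
    bundle = LexiconBundle(
        [Concept("MESH:D1", "MESH", ["zzz"], tree_numbers=["D02"])], []
    )
    doc = Document(doc_id="t", passages=[Passage(0, "nothing to find")])
    tagged = dictionary_tag(doc, bundle.mesh_index[NormalizationLevel.RELAXED])
    assert tagged.mentions == []


def test_normalize_collection_end_to_end(small_bundle):
    text = ("we dissolved triphenyl phosphate (TPP) in buffer and later "
            "TPP was measured with renal carcinoma biopsies and 115-86-6")
    def at(surface: str, occurrence: int = 0) -> Mention:
        start = -1
        for _ in range(occurrence + 1):
            start = text.index(surface, start + 1)
        return Mention(spans=[Span(start, len(surface))], text=surface)

    doc = Document(
        doc_id="e2e",
        passages=[Passage(0, text)],
        mentions=[
            at("triphenyl phosphate"),
            at("TPP", 0),
            at("TPP", 1),
            at("renal carcinoma"),
            at("115-86-6"),
        ],
    )
    (out,) = normalize_collection([doc], small_bundle)
    ids = [m.identifiers for m in out.mentions]
    assert ids[0] == {"MESH:D1"}          # direct name
    assert ids[1] == ids[2] == {"MESH:D1"}  # abbreviation expanded
    assert ids[3] == set()                # hierarchy filter removes disease
    assert ids[4] == set()                # no alphabetic character
    # inputs are not modified
    assert all(m.identifiers == set() for m in doc.mentions)


def test_normalize_overwrites_preassigned_identifiers(small_bundle):
    doc = Document(
        doc_id="ow",
        passages=[Passage(0, "triphenyl phosphate here")],
        mentions=[
            Mention(spans=[Span(0, 19)], text="triphenyl phosphate",
                    identifiers={"MESH:WRONG"})
        ],
    )
    (out,) = normalize_collection([doc], small_bundle)
    assert out.mentions[0].identifiers == {"MESH:D1"}


def test_pipeline_deterministic(fixture_bundle, fixture_collection):
    inputs, _ = fixture_collection
    a = normalize_collection(inputs, fixture_bundle)
    b = normalize_collection(inputs, fixture_bundle)
    assert a == b


def test_filter_disabled_keeps_non_chemicals(small_bundle):
    doc = Document(
        doc_id="f",
        passages=[Passage(0, "renal carcinoma tissue")],
        mentions=[Mention(spans=[Span(0, 15)], text="renal carcinoma")],
    )
    (out,) = normalize_collection(
        [doc], small_bundle, PipelineConfig(apply_hierarchy_filter=False)
    )
    assert out.mentions[0].identifiers == {"MESH:D9"}
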