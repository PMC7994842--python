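"""Multi-terminology candidate resolution: mapping chemical mentions to MeSH.

The normalizer assigns MeSH identifiers to text spans already recognized as
chemical mentions.  Per document it:

1. skips mentions with no alphabetic character (bare registry numbers and
   formula fragments are not resolvable by name),
2. expands abbreviations in the mention text using definitions detected in
   the full article text (conflicts resolved by frequency),
3. runs a precision-ordered cascade of string matchers — exact match to MeSH,
   relaxed match to MeSH, relaxed-plural match to MeSH, then the relaxed and
   relaxed-plural matches against auxiliary terminologies whose hits are
   carried over to MeSH by cross-reference — stopping at the first stage that
   yields at least one MeSH concept,
4. disambiguates multi-candidate mentions against the identifiers that occur
   unambiguously elsewhere in the same document, and
5. removes identifiers that do not sit in a chemical branch of the MeSH
   hierarchy.

A greedy dictionary tagger is included so the pipeline runs end-to-end on
plain text without an external named-entity recognizer.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from . import abbrev as _abbrev
from .bioc import CHEMICAL, Document, Mention, Span
from .lexicon import (
    Concept,
    NameIndex,
    TreePolicy,
    DEFAULT_TREE_POLICY,
    build_mesh_xref_index,
    build_name_index,
    is_chemical_mesh,
    xref_to_mesh,
)
from .textnorm import NormalizationLevel

logger = logging.getLogger(__name__)

__all__ = [
    "Stage",
    "Status",
    "CandidateSet",
    "LexiconBundle",
    "PipelineConfig",
    "candidate_cascade",
    "disambiguate_document",
    "filter_chemical_ids",
    "dictionary_tag",
    "normalize_collection",
]


class Stage(str, enum.Enum):
    EXACT_MESH = "exact_mesh"
    RELAXED_MESH = "relaxed_mesh"
    RELAXED_PLURAL_MESH = "relaxed_plural_mesh"
    RELAXED_MULTI = "relaxed_multi"
    RELAXED_PLURAL_MULTI = "relaxed_plural_multi"
    NONE = "none"


CASCADE_ORDER: Tuple[Stage, ...] = (
    Stage.EXACT_MESH,
    Stage.RELAXED_MESH,
    Stage.RELAXED_PLURAL_MESH,
    Stage.RELAXED_MULTI,
    Stage.RELAXED_PLURAL_MULTI,
)


class Status(str, enum.Enum):
    RESOLVED = "resolved"
    AMBIGUOUS = "ambiguous"
    UNKNOWN = "unknown"


@dataclass
class CandidateSet:
    """Candidate MeSH ids for one mention plus the stage that produced them."""

    mention_ref: Tuple[str, Tuple[int, int]]  # (doc_id, (start, end))
    candidates: Set[str] = field(default_factory=set)
    stage: Stage = Stage.NONE
    status: Status = Status.UNKNOWN

    @staticmethod
    def _status_for(candidates: Set[str]) -> Status:
        if not candidates:
            return Status.UNKNOWN
        return Status.RESOLVED if len(candidates) == 1 else Status.AMBIGUOUS

    def with_candidates(self, candidates: Set[str]) -> "CandidateSet":
        return replace(
            self, candidates=set(candidates), status=self._status_for(candidates)
        )


class LexiconBundle:
    """A MeSH terminology plus auxiliary terminologies with all match indexes
    prebuilt (per normalization level, per terminology)."""

    def __init__(
        self,
        mesh_concepts: Sequence[Concept],
        aux_concepts: Sequence[Concept] = (),
    ) -> None:
        self.mesh_concepts = list(mesh_concepts)
        self.aux_concepts = list(aux_concepts)
        self.mesh_by_id: Dict[str, Concept] = {
            c.concept_id: c for c in self.mesh_concepts
        }
        aux_by_source: Dict[str, List[Concept]] = {}
        for c in self.aux_concepts:
            aux_by_source.setdefault(c.source, []).append(c)
        self.aux_by_source = aux_by_source
        self.aux_by_id: Dict[str, Concept] = {
            c.concept_id: c for c in self.aux_concepts
        }
        self.mesh_index: Dict[NormalizationLevel, NameIndex] = {
            level: build_name_index(self.mesh_concepts, level)
            for level in NormalizationLevel
        }
        self.aux_index: Dict[str, Dict[NormalizationLevel, NameIndex]] = {
            src: {
                level: build_name_index(concepts, level)
                for level in (
                    NormalizationLevel.RELAXED,
                    NormalizationLevel.RELAXED_PLURAL,
                )
            }
            for src, concepts in aux_by_source.items()
        }
        self._mesh_xref_index = build_mesh_xref_index(self.mesh_concepts)

    def aux_lookup_mesh(self, text: str, level: NormalizationLevel) -> Set[str]:
        """Union over auxiliary terminologies of hits mapped through to MeSH."""
        out: Set[str] = set()
        for src, levels in self.aux_index.items():
            for cid in levels[level].lookup(text):
                out |= xref_to_mesh(
                    self.aux_by_id[cid], mesh_xref_index=self._mesh_xref_index
                )
        return out


def _has_alpha(text: str) -> bool:
    return any(c.isalpha() for c in text)


def candidate_cascade(
    mention_text: str,
    bundle: LexiconBundle,
    mention_ref: Tuple[str, Tuple[int, int]] = ("", (0, 0)),
) -> CandidateSet:
    """Run the matching cascade on (already abbreviation-expanded) text.

    Stages run in fixed precision order; the first stage producing a
    non-empty MeSH id set wins.  For the multi-terminology stages an
    auxiliary hit only stops the cascade if it actually maps to MeSH.
    Text without a single alphabetic character is unknown without any lookup.
    """
    empty = CandidateSet(mention_ref=mention_ref)
    if not _has_alpha(mention_text):
        return empty
    for stage in CASCADE_ORDER:
        if stage is Stage.EXACT_MESH:
            hits = bundle.mesh_index[NormalizationLevel.EXACT].lookup(mention_text)
        elif stage is Stage.RELAXED_MESH:
            hits = bundle.mesh_index[NormalizationLevel.RELAXED].lookup(mention_text)
        elif stage is Stage.RELAXED_PLURAL_MESH:
            hits = bundle.mesh_index[NormalizationLevel.RELAXED_PLURAL].lookup(
                mention_text
            )
        elif stage is Stage.RELAXED_MULTI:
            hits = bundle.aux_lookup_mesh(mention_text, NormalizationLevel.RELAXED)
        else:
            hits = bundle.aux_lookup_mesh(
                mention_text, NormalizationLevel.RELAXED_PLURAL
            )
        if hits:
            return replace(
                empty,
                candidates=hits,
                stage=stage,
                status=CandidateSet._status_for(hits),
            )
    return empty


def disambiguate_document(candsets: List[CandidateSet]) -> List[CandidateSet]:
    """Intersect ambiguous candidate sets with the document's unambiguous ids.

    Let U be the union of candidates over mentions that have exactly one
    candidate.  A mention with two or more candidates whose intersection with
    U is non-empty is narrowed to that intersection; otherwise it is left
    untouched.  Never increases a candidate count.
    """
    unambiguous: Set[str] = set()
    for cs in candsets:
        if len(cs.candidates) == 1:
            unambiguous |= cs.candidates
    out = []
    for cs in candsets:
        if len(cs.candidates) >= 2:
            inter = cs.candidates & unambiguous
            if inter:
                cs = cs.with_candidates(inter)
        out.append(cs)
    return out


def filter_chemical_ids(
    candset: CandidateSet,
    mesh_lexicon: Dict[str, Concept],
    tree_policy: TreePolicy = DEFAULT_TREE_POLICY,
) -> CandidateSet:
    """Drop candidate ids outside the chemical branches of the hierarchy.

    Ids absent from the lexicon are dropped (and logged).  A set emptied by
    the filter becomes unknown.
    """
    kept = set()
    for cid in candset.candidates:
        concept = mesh_lexicon.get(cid)
        if concept is None:
            logger.warning("%s: candidate id not in MeSH lexicon; removed", cid)
            continue
        if is_chemical_mesh(concept, tree_policy):
            kept.add(cid)
    return candset.with_candidates(kept)


# ---------------------------------------------------------------------------
# dictionary tagger

def _word_boundaries(text: str) -> Tuple[List[int], List[int]]:
    starts, ends = [], []
    for i, c in enumerate(text):
        alnum = c.isalnum()
        if alnum and (i == 0 or not text[i - 1].isalnum()):
            starts.append(i)
        if alnum and (i == len(text) - 1 or not text[i + 1].isalnum()):
            ends.append(i + 1)
    return starts, ends


def dictionary_tag(
    doc: Document,
    index: NameIndex,
    min_len: int = 3,
    max_tokens: int = 8,
) -> Document:
    """Tag chemical mentions by greedy longest-leftmost dictionary matching.

    Candidate substrings run from a word start to a word end (at most
    ``max_tokens`` words, at least ``min_len`` characters) and hit when their
    normal form at the index level is a lexicon key.  Emitted mentions carry
    type Chemical and no identifiers — normalization is a separate step.
    """
    tagged = doc.copy()
    tagged.mentions = []
    for passage in tagged.passages:
        starts, ends = _word_boundaries(passage.text)
        si = 0
        while si < len(starts):
            start = starts[si]
            # word-end positions usable from this start, longest first
            usable = [e for e in ends if e > start][:max_tokens]
            hit_end = None
            for e in reversed(usable):
                surface = passage.text[start:e]
                if len(surface) >= min_len and index.lookup(surface):
                    hit_end = e
                    break
            if hit_end is None:
                si += 1
                continue
            span = Span(passage.offset + start, hit_end - start)
            tagged.mentions.append(
                Mention(spans=[span], text=passage.text[start:hit_end])
            )
            while si < len(starts) and starts[si] < hit_end:
                si += 1
    return tagged


# ---------------------------------------------------------------------------
# end-to-end pipeline

@dataclass(frozen=True)
class PipelineConfig:
    tree_policy: TreePolicy = DEFAULT_TREE_POLICY
    apply_hierarchy_filter: bool = True
    abbrev_scope: str = "document"  # or "collection"
    tag_with_dictionary: bool = False
    dictionary_min_len: int = 3


def normalize_collection(
    docs: Iterable[Document],
    bundle: LexiconBundle,
    config: PipelineConfig = PipelineConfig(),
) -> List[Document]:
    """Assign MeSH identifiers to every Chemical mention of every document.

    Input identifier payloads are overwritten by the pipeline's assignment
    (this is the assignment step, not a merge); mentions the cascade cannot
    resolve end with an empty identifier set, which serializes as "-".
    Returns new documents; inputs are not modified.
    """
    docs = [d.copy() for d in docs]
    if config.tag_with_dictionary:
        docs = [
            dictionary_tag(
                d,
                bundle.mesh_index[NormalizationLevel.RELAXED],
                min_len=config.dictionary_min_len,
            )
            for d in docs
        ]
    collection_map: Optional[_abbrev.AbbreviationMap] = None
    if config.abbrev_scope == "collection":
        all_defs = [d for doc in docs for d in _abbrev.detect_definitions(doc)]
        collection_map = _abbrev.resolve_conflicts(all_defs, scope="collection")
    stage_counts: Dict[Stage, int] = {s: 0 for s in Stage}
    for doc in docs:
        if collection_map is not None:
            amap = collection_map
        else:
            amap = _abbrev.resolve_conflicts(
                _abbrev.detect_definitions(doc), scope="document"
            )
        candsets: List[CandidateSet] = []
        chem_mentions = [m for m in doc.mentions if m.entity_type == CHEMICAL]
        for m in chem_mentions:
            ref = (doc.doc_id, (m.start, m.end))
            # precondition runs on the original mention text (step order)
            if not _has_alpha(m.text):
                candsets.append(CandidateSet(mention_ref=ref))
                continue
            expanded = _abbrev.expand_text(m.text, amap)
            candsets.append(candidate_cascade(expanded, bundle, mention_ref=ref))
        candsets = disambiguate_document(candsets)
        if config.apply_hierarchy_filter:
            candsets = [
                filter_chemical_ids(cs, bundle.mesh_by_id, config.tree_policy)
                for cs in candsets
            ]
        for m, cs in zip(chem_mentions, candsets):
            m.identifiers = set(cs.candidates)
            stage_counts[cs.stage] += 1
    for stage in Stage:
        logger.info("cascade stage %s: %d mentions", stage.value, stage_counts[stage])
    return docs
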