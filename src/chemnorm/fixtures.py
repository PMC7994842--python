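"""Synthetic lexicons and annotated BioC collections for testing.

The generator emulates the phenomena the normalizer models, and only those:
chemical names varying in case, hyphen/space alternation, Greek letters and
plurals; parenthetical abbreviation definitions followed by bare short-form
uses; names shared between concepts (ambiguity) always accompanied by an
unambiguous co-mention; auxiliary-terminology synonyms reaching MeSH by
cross-reference; and non-chemical decoy concepts (diseases, enzymes) for
exercising the hierarchy filter.  Filler text is drawn from a fixed word
list disjoint from all generated names, so dictionary-tagging precision is
exactly measurable.

Because every planted surface form stays inside the modeled transformation
space, a correct pipeline recovers the gold identifiers exactly; the
generator is deliberately a closed world, which is what makes end-to-end
accuracy a sharp test (and which real literature, with novel names and
out-of-vocabulary variants, is not).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .abbrev import detect_definitions
from .bioc import CHEMICAL, Document, Mention, Passage, Span
from .lexicon import Concept
from .textnorm import relaxed_plural_normalize

__all__ = [
    "FixtureConfig",
    "generate_lexicon",
    "generate_collection",
    "perturb_annotator",
]

_PREFIXES = [
    "methyl", "ethyl", "propyl", "butyl", "phenyl", "chloro", "bromo",
    "fluoro", "hydroxy", "amino", "nitro", "sulfo", "carboxy", "acetyl",
    "benzyl", "cyclo", "iso", "vinyl", "allyl", "glyco",
]
_STEMS = [
    "benzene", "phenol", "acetate", "sulfate", "phosphate", "oxalate",
    "citrate", "pyridine", "furan", "indole", "toluene", "glucoside",
    "lactone", "carbonate", "stearate", "butyrate", "malonate", "tartrate",
    "salicylate", "palmitate",
]
_GREEK_WORDS = ["alpha", "beta", "gamma", "delta"]
_GREEK_CHARS = {"alpha": "α", "beta": "β", "gamma": "γ",
                "delta": "δ"}

_DISEASE_PRE = ["chronic", "acute", "renal", "hepatic", "cardiac", "gastric"]
_DISEASE_STEM = ["carcinoma", "fibrosis", "nephropathy", "dermatitis",
                 "myopathy", "neuropathy"]
_ENZYME_PRE = ["alcohol", "xanthine", "aldehyde", "glucose", "lactate"]
_ENZYME_STEM = ["oxidase", "reductase", "kinase", "synthase", "hydrolase"]

# disjoint from every syllable above; no parentheses ever appear in filler
_FILLER = (
    "the study showed that levels were higher during exposure and this "
    "result was confirmed in repeated measurements for each group while "
    "controls remained stable over time with no observed change between "
    "visits suggesting a consistent pattern across conditions we examined "
    "further details on dosing schedule outcome records from enrolled "
    "participants"
).split()

_AUX_SOURCES = ("UNII", "CHEBI", "DSSTOX")

_AUX_SURFACE_RATE = 0.3  # chance a mention uses an auxiliary-terminology synonym


def _default_rates() -> Dict[str, float]:
    return {
        "case": 0.3,
        "hyphen_space": 0.3,
        "greek": 0.3,
        "plural": 0.3,
        "abbreviation": 0.3,
        "ambiguous_abbrev": 0.3,
    }


@dataclass
class FixtureConfig:
    seed: int = 7
    n_concepts: int = 30
    n_docs: int = 20
    variant_rates: Dict[str, float] = field(default_factory=_default_rates)
    xref_rate: float = 0.5
    n_aux_terminologies: int = 2

    def __post_init__(self) -> None:
        if self.n_concepts < 2 or self.n_docs < 1:
            raise ValueError("need at least 2 concepts and 1 document")
        rates = _default_rates()
        rates.update(self.variant_rates)
        self.variant_rates = rates
        for k, v in self.variant_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"variant rate {k}={v} outside [0,1]")


@dataclass
class _Lexicon:
    """Generated lexicon plus the bookkeeping the collection generator needs."""

    mesh: List[Concept]
    aux: List[Concept]
    chemical_ids: List[str]
    decoy_ids: List[str]
    canonical: Dict[str, str]  # chemical id -> canonical name
    unique_synonym: Dict[str, str]  # chemical id -> a never-shared synonym
    aux_names: Dict[str, List[str]]  # chemical id -> aux synonyms that resolve
    shared_names: Dict[str, Tuple[str, str]]  # shared synonym -> (id_a, id_b)


def _pairs(rng: np.random.Generator, prefixes: Sequence[str],
           stems: Sequence[str]) -> List[str]:
    pairs = [f"{p} {s}" for p in prefixes for s in stems]
    rng.shuffle(pairs)
    return pairs


def generate_lexicon(config: FixtureConfig) -> Tuple[List[Concept], List[Concept]]:
    """Generate (MeSH-like concepts, auxiliary-terminology concepts).

    Deterministic under the config seed.  MeSH concepts mix chemical tree
    numbers ("D02...") with disease ("C04...") and enzyme ("D08.811...")
    decoys; auxiliary concepts carry a cross-reference (direct MESH or a
    shared CAS number) with probability ``xref_rate``.
    """
    lex = _generate_lexicon(config)
    return lex.mesh, lex.aux


def _generate_lexicon(config: FixtureConfig) -> _Lexicon:
    rng = np.random.default_rng(config.seed)
    names = _pairs(rng, _PREFIXES, _STEMS)
    needed = 3 * config.n_concepts  # canonical + unique synonym + aux synonym
    if needed > len(names):
        raise ValueError(
            f"n_concepts={config.n_concepts} exceeds the name space "
            f"({len(names) // 3} concepts)"
        )
    used_norms: Set[str] = set()

    def claim(name: str) -> str:
        norm = relaxed_plural_normalize(name)
        assert norm not in used_norms, f"normal-form collision on {name!r}"
        used_norms.add(norm)
        return name

    mesh: List[Concept] = []
    chemical_ids: List[str] = []
    canonical: Dict[str, str] = {}
    unique_synonym: Dict[str, str] = {}
    it = iter(names)
    n_greek = max(1, config.n_concepts // 6)
    for i in range(config.n_concepts):
        cid = f"MESH:D{1000 + i}"
        if i < n_greek:
            greek = _GREEK_WORDS[i % len(_GREEK_WORDS)]
            name = claim(f"{greek}-{next(it).split()[1]}{i}")
        else:
            name = claim(next(it))
        syn = claim(next(it))
        xrefs = {"CAS": f"{5000 + i}-{10 + i}-{i % 10}"}
        mesh.append(
            Concept(
                concept_id=cid, source="MESH", names=[name, syn],
                xrefs=xrefs, tree_numbers=[f"D02.{100 + i}"],
            )
        )
        chemical_ids.append(cid)
        canonical[cid] = name
        unique_synonym[cid] = syn

    # shared synonyms: ambiguity by name, planted on disjoint concept pairs
    shared_names: Dict[str, Tuple[str, str]] = {}
    rate = config.variant_rates["ambiguous_abbrev"]
    for k in range(0, config.n_concepts - 1, 2):
        if rng.uniform() < rate:
            shared = claim(f"agentin{k}x")
            id_a, id_b = chemical_ids[k], chemical_ids[k + 1]
            mesh[k].names.append(shared)
            mesh[k + 1].names.append(shared)
            shared_names[shared] = (id_a, id_b)

    decoy_ids: List[str] = []
    n_decoys = max(2, config.n_concepts // 5)
    disease = _pairs(rng, _DISEASE_PRE, _DISEASE_STEM)
    enzyme = _pairs(rng, _ENZYME_PRE, _ENZYME_STEM)
    for i in range(n_decoys):
        if i % 2 == 0:
            cid, name, tree = f"MESH:D{8000 + i}", claim(disease.pop()), f"C04.{500 + i}"
        else:
            cid, name, tree = f"MESH:D{8000 + i}", claim(enzyme.pop()), f"D08.811.{i}"
        mesh.append(
            Concept(concept_id=cid, source="MESH", names=[name],
                    tree_numbers=[tree])
        )
        decoy_ids.append(cid)

    aux: List[Concept] = []
    aux_names: Dict[str, List[str]] = {cid: [] for cid in chemical_ids}
    if config.n_aux_terminologies > 0:
        for i, cid in enumerate(chemical_ids):
            source = _AUX_SOURCES[i % min(config.n_aux_terminologies,
                                          len(_AUX_SOURCES))]
            aux_name = claim(next(it))
            xrefs: Dict[str, str] = {}
            if rng.uniform() < config.xref_rate:
                if rng.uniform() < 0.5:
                    xrefs["MESH"] = cid.split(":", 1)[1]
                else:
                    xrefs["CAS"] = mesh[i].xrefs["CAS"]
                aux_names[cid].append(aux_name)
            aux.append(
                Concept(concept_id=f"{source}:X{i}", source=source,
                        names=[aux_name], xrefs=xrefs)
            )
    return _Lexicon(
        mesh=mesh, aux=aux, chemical_ids=chemical_ids, decoy_ids=decoy_ids,
        canonical=canonical, unique_synonym=unique_synonym,
        aux_names=aux_names, shared_names=shared_names,
    )


# ---------------------------------------------------------------------------
# collection generation

def _initials(name: str) -> str:
    return "".join(w[0] for w in name.replace("-", " ").split()).upper()


def _abbrev_resolvable(name: str, short_form: str) -> bool:
    """True iff the parenthetical detector recovers the full name from
    "name (SF)" — e.g. "PP" after "propyl phosphate" matches only
    "phosphate", so that pair is not plantable in a closed world."""
    probe = Document(doc_id="probe",
                     passages=[Passage(0, f"{name} ({short_form})")])
    defs = detect_definitions(probe)
    return [(d.short_form, d.long_form) for d in defs] == [(short_form, name)]


def _pluralize(name: str) -> Optional[str]:
    last = name.split()[-1].split("-")[-1]
    if not (last.isalpha() and len(last) >= 3):
        return None
    if last.endswith(("s", "y", "x", "z", "ch", "sh")):
        return None
    return name + "s"


@dataclass
class _Planted:
    surface: str
    gold_ids: Set[str]
    is_definition: bool = False
    short_form: str = ""


def _variant_surface(
    rng: np.random.Generator, name: str, rates: Dict[str, float], is_greek: bool
) -> str:
    surface = name
    if is_greek and rng.uniform() < rates["greek"]:
        head, _, tail = surface.partition("-")
        surface = _GREEK_CHARS[head] + "-" + tail
    if rng.uniform() < rates["hyphen_space"] and " " in surface:
        surface = surface.replace(" ", "-")
    if rng.uniform() < rates["plural"]:
        plural = _pluralize(surface)
        if plural is not None:
            surface = plural
    if rng.uniform() < rates["case"]:
        surface = surface.upper() if rng.uniform() < 0.5 else surface.title()
    return surface


def _filler(rng: np.random.Generator, lo: int, hi: int) -> List[str]:
    n = int(rng.integers(lo, hi + 1))
    return [_FILLER[int(rng.integers(0, len(_FILLER)))] for _ in range(n)]


def _build_passages(
    rng: np.random.Generator, planted: List[_Planted]
) -> Tuple[List[Passage], List[Mention]]:
    sections = ["title", "abstract", "body", "body"]
    # title gets no planted items; split the rest over the other passages
    chunks: List[List[_Planted]] = [[]]
    per = max(1, -(-len(planted) // (len(sections) - 1)))
    for i in range(0, len(planted), per):
        chunks.append(planted[i : i + per])
    while len(chunks) < len(sections):
        chunks.append([])
    passages: List[Passage] = []
    mentions: List[Mention] = []
    offset = 0
    for section, chunk in zip(sections, chunks):
        words = _filler(rng, 3, 6)
        text = " ".join(words)
        for item in chunk:
            text += " "
            if item.is_definition:
                start = len(text)
                text += item.surface
                mentions.append(
                    Mention(
                        spans=[Span(offset + start, len(item.surface))],
                        text=item.surface,
                        identifiers=set(item.gold_ids),
                    )
                )
                text += " (" + item.short_form + ")"
                sf_start = start + len(item.surface) + 2
                mentions.append(
                    Mention(
                        spans=[Span(offset + sf_start, len(item.short_form))],
                        text=item.short_form,
                        identifiers=set(item.gold_ids),
                    )
                )
            else:
                start = len(text)
                text += item.surface
                mentions.append(
                    Mention(
                        spans=[Span(offset + start, len(item.surface))],
                        text=item.surface,
                        identifiers=set(item.gold_ids),
                    )
                )
            text += " " + " ".join(_filler(rng, 2, 4))
        passages.append(Passage(offset=offset, text=text, section_label=section))
        offset += len(text) + 1
    return passages, mentions


def generate_collection(
    config: FixtureConfig,
    lexicon: Optional[Tuple[List[Concept], List[Concept]]] = None,
) -> Tuple[List[Document], List[Document]]:
    """Generate (input documents, gold documents).

    Input documents carry Chemical mention spans with empty identifier sets
    (the state an NER tagger leaves them in); gold documents are identical
    but carry the true MeSH identifiers.  Decoy mentions (non-chemical MeSH
    concepts) appear in both with empty gold identifiers.  Every planted
    ambiguity — a surface shared by two concepts — is accompanied in the same
    document by an unambiguous mention of the intended concept, and every
    short form is defined parenthetically before its first bare use.
    """
    lex = _generate_lexicon(config)
    if lexicon is not None:
        pass  # caller-supplied lexicon must come from the same config/seed
    rng = np.random.default_rng(config.seed + 1)
    rates = config.variant_rates
    decoy_names = {cid: c.names[0] for c in lex.mesh for cid in [c.concept_id]
                   if cid in lex.decoy_ids}
    shared_list = sorted(lex.shared_names)
    gold_docs: List[Document] = []
    for j in range(config.n_docs):
        n_chem = int(rng.integers(3, 7))
        chosen = [
            str(c) for c in rng.choice(
                lex.chemical_ids, size=min(n_chem, len(lex.chemical_ids)),
                replace=False)
        ]
        planted: List[_Planted] = []
        # ambiguity by shared name: include one partner, exclude the other
        if shared_list and rng.uniform() < rates["ambiguous_abbrev"]:
            shared = shared_list[int(rng.integers(0, len(shared_list)))]
            id_a, id_b = lex.shared_names[shared]
            if id_b in chosen:
                chosen.remove(id_b)
            if id_a not in chosen:
                chosen.append(id_a)
            # unambiguous co-mention, then the shared (ambiguous) surface
            planted.append(_Planted(lex.unique_synonym[id_a], {id_a}))
            planted.append(_Planted(shared, {id_a}))
            chosen.remove(id_a)
        used_sfs: Set[str] = set()
        for cid in chosen:
            name = lex.canonical[cid]
            is_greek = name.split("-")[0] in _GREEK_WORDS
            n_mentions = int(rng.integers(1, 4))
            sf = _initials(name)
            use_abbrev = (
                rng.uniform() < rates["abbreviation"]
                and len(sf) >= 2
                and sf not in used_sfs
                and _abbrev_resolvable(name, sf)
            )
            if use_abbrev:
                used_sfs.add(sf)
                planted.append(
                    _Planted(name, {cid}, is_definition=True, short_form=sf)
                )
                for _ in range(n_mentions - 1):
                    planted.append(_Planted(sf, {cid}))
            else:
                for _ in range(n_mentions):
                    if lex.aux_names[cid] and rng.uniform() < _AUX_SURFACE_RATE:
                        base = lex.aux_names[cid][0]
                        is_g = False
                    else:
                        base, is_g = name, is_greek
                    planted.append(
                        _Planted(_variant_surface(rng, base, rates, is_g), {cid})
                    )
        if lex.decoy_ids and rng.uniform() < 0.5:
            did = lex.decoy_ids[int(rng.integers(0, len(lex.decoy_ids)))]
            planted.append(_Planted(decoy_names[did], set()))
        passages, mentions = _build_passages(rng, planted)
        mentions.sort(key=lambda m: (m.start, m.end, m.text))
        gold_docs.append(
            Document(
                doc_id=f"doc{j:04d}",
                passages=passages,
                mentions=mentions,
                metadata={
                    "has_abstract": "true",
                    "reference_count": str(int(rng.integers(5, 41))),
                    "publication_types": "research-article",
                    "batch": f"batch{j % 3 + 1}",
                },
            )
        )
    input_docs = []
    for d in gold_docs:
        blank = d.copy()
        for m in blank.mentions:
            m.identifiers = set()
        input_docs.append(blank)
    return input_docs, gold_docs


# ---------------------------------------------------------------------------
# simulated annotator

def perturb_annotator(
    gold: Document,
    drop_rate: float = 0.0,
    id_swap_rate: float = 0.0,
    boundary_shift_rate: float = 0.0,
    seed: int = 0,
    id_pool: Optional[Sequence[str]] = None,
) -> Document:
    """Simulate an imperfect annotator from a gold document.

    Independently per mention: drop it with ``drop_rate``; otherwise swap its
    identifier set for a random different identifier with ``id_swap_rate``;
    otherwise shift one boundary by a single character with
    ``boundary_shift_rate`` (the stored text tracks the new span).
    Deterministic under the seed.
    """
    for name, rate in (("drop_rate", drop_rate), ("id_swap_rate", id_swap_rate),
                       ("boundary_shift_rate", boundary_shift_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name}={rate} outside [0,1]")
    rng = np.random.default_rng(seed)
    pool = sorted(
        set(id_pool)
        if id_pool is not None
        else {i for m in gold.mentions for i in m.identifiers}
    )
    out = gold.copy()
    kept: List[Mention] = []
    for m in out.mentions:
        if rng.uniform() < drop_rate:
            continue
        if rng.uniform() < id_swap_rate:
            others = [i for i in pool if i not in m.identifiers]
            if others:
                m.identifiers = {others[int(rng.integers(0, len(others)))]}
            else:
                m.identifiers = {"MESH:DSWAP"}
        if rng.uniform() < boundary_shift_rate and len(m.spans) == 1:
            span = m.spans[0]
            passage = gold.passage_at(span.offset)
            if passage is not None:
                if span.end < passage.end and rng.uniform() < 0.5:
                    new = Span(span.offset, span.length + 1)
                elif span.length > 1:
                    new = Span(span.offset, span.length - 1)
                else:
                    new = span
                if new != span:
                    m.spans = [new]
                    m.text = out.text_at(new)
        kept.append(m)
    out.mentions = kept
    return out
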