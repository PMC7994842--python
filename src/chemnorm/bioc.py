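"""BioC corpus data model and XML/JSON I/O.

BioC is a shallow interchange format for biomedical text and stand-off
annotations: a collection holds documents, documents hold passages, and
annotations point into the text with (offset, length) locations.  All offsets
here are document-level and counted in Unicode code points — never bytes and
never UTF-16 units — matching how annotation tools that handle Greek letters
and other non-ASCII chemistry notation record positions.

Entity type and concept identifier ride in per-annotation infon key/value
pairs; the key names vary between producers, so they are configurable via
:class:`InfonKeys`.  A mention normalized to several MeSH descriptors
serializes its identifiers as a comma-joined, lexicographically sorted list;
a mention with no identifier serializes as ``"-"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Union

from lxml import etree

__all__ = [
    "Span",
    "Mention",
    "Passage",
    "Document",
    "InfonKeys",
    "Violation",
    "BioCFormatError",
    "UNKNOWN_IDENTIFIER",
    "format_identifiers",
    "parse_identifiers",
    "read_collection",
    "write_collection",
    "validate_document",
    "validate_collection",
]

UNKNOWN_IDENTIFIER = "-"

CHEMICAL = "Chemical"
OTHER = "OTHER"


class BioCFormatError(ValueError):
    """Raised when a file does not parse or validate as BioC."""


@dataclass(frozen=True)
class Span:
    """Half-open character range [offset, offset + length) in document space."""

    offset: int
    length: int

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class Mention:
    """An annotated entity mention; possibly discontinuous (several spans)."""

    spans: List[Span]
    text: str
    entity_type: str = CHEMICAL
    identifiers: Set[str] = field(default_factory=set)
    annotator_tag: Optional[str] = None

    @property
    def start(self) -> int:
        return self.spans[0].offset

    @property
    def end(self) -> int:
        return self.spans[-1].end

    def copy(self) -> "Mention":
        return replace(self, spans=list(self.spans), identifiers=set(self.identifiers))


@dataclass
class Passage:
    offset: int
    text: str
    section_label: Optional[str] = None

    @property
    def end(self) -> int:
        return self.offset + len(self.text)


@dataclass
class Document:
    doc_id: str
    passages: List[Passage] = field(default_factory=list)
    mentions: List[Mention] = field(default_factory=list)
    metadata: Dict[str, str] = field(default_factory=dict)

    def passage_at(self, offset: int) -> Optional[Passage]:
        for p in self.passages:
            if p.offset <= offset <= p.end:
                return p
        return None

    def text_at(self, span: Span) -> str:
        """Text under one span; raises if the span leaves every passage."""
        for p in self.passages:
            if p.offset <= span.offset and span.end <= p.end:
                return p.text[span.offset - p.offset : span.end - p.offset]
        raise IndexError(
            f"span ({span.offset},{span.length}) outside passages of {self.doc_id!r}"
        )

    def mention_text(self, mention: Mention) -> str:
        return "".join(self.text_at(s) for s in mention.spans)

    def copy(self) -> "Document":
        return Document(
            doc_id=self.doc_id,
            passages=[replace(p) for p in self.passages],
            mentions=[m.copy() for m in self.mentions],
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class InfonKeys:
    """Infon key names used for annotation payloads (producer-dependent)."""

    entity_type: str = "type"
    identifier: str = "identifier"
    section: str = "section"
    annotator: str = "annotator"


DEFAULT_KEYS = InfonKeys()


def format_identifiers(identifiers: Iterable[str]) -> str:
    ids = sorted(set(identifiers))
    return ",".join(ids) if ids else UNKNOWN_IDENTIFIER


def parse_identifiers(payload: Optional[str]) -> Set[str]:
    if payload is None or payload.strip() in ("", UNKNOWN_IDENTIFIER):
        return set()
    return {p.strip() for p in payload.split(",") if p.strip()}


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class Violation:
    kind: str
    doc_id: str
    location: str
    message: str


def validate_document(doc: Document) -> List[Violation]:
    """Check the structural invariants; violations are returned, not raised."""
    out: List[Violation] = []
    if not doc.doc_id:
        out.append(Violation("empty-doc-id", doc.doc_id, "document", "doc_id is empty"))
    for i, p in enumerate(doc.passages):
        if i and p.offset < doc.passages[i - 1].end:
            out.append(
                Violation(
                    "passage-overlap",
                    doc.doc_id,
                    f"passage[{i}]@{p.offset}",
                    "passages overlap or are unsorted",
                )
            )
    for j, m in enumerate(doc.mentions):
        loc = f"mention[{j}]@{m.spans[0].offset if m.spans else '?'}"
        if not m.spans:
            out.append(Violation("no-spans", doc.doc_id, loc, "mention has no spans"))
            continue
        for k, s in enumerate(m.spans):
            if s.length <= 0 or s.offset < 0:
                out.append(
                    Violation("bad-span", doc.doc_id, loc, f"degenerate span {s}")
                )
            if k and s.offset < m.spans[k - 1].end:
                out.append(
                    Violation("span-overlap", doc.doc_id, loc, "spans overlap/unsorted")
                )
        try:
            covered = doc.mention_text(m)
        except IndexError:
            out.append(
                Violation(
                    "span-out-of-bounds",
                    doc.doc_id,
                    loc,
                    f"span outside passage extents (offset {m.spans[0].offset})",
                )
            )
            continue
        if covered != m.text:
            out.append(
                Violation(
                    "text-mismatch",
                    doc.doc_id,
                    loc,
                    f"stored text {m.text!r} != passage text {covered!r}",
                )
            )
    return out


def validate_collection(docs: Iterable[Document]) -> List[Violation]:
    out: List[Violation] = []
    for d in docs:
        out.extend(validate_document(d))
    return out


# ---------------------------------------------------------------------------
# XML dialect

def _mention_sort_key(m: Mention):
    return (m.start, m.end, m.text)


def _doc_to_xml(doc: Document, keys: InfonKeys) -> etree._Element:
    el = etree.Element("document")
    etree.SubElement(el, "id").text = doc.doc_id
    for k, v in doc.metadata.items():
        infon = etree.SubElement(el, "infon", key=k)
        infon.text = str(v)
    ann_id = 0
    mentions = sorted(doc.mentions, key=_mention_sort_key)
    for p in doc.passages:
        pel = etree.SubElement(el, "passage")
        if p.section_label is not None:
            infon = etree.SubElement(pel, "infon", key=keys.section)
            infon.text = p.section_label
        etree.SubElement(pel, "offset").text = str(p.offset)
        etree.SubElement(pel, "text").text = p.text
        for m in mentions:
            if not (p.offset <= m.start and m.start < p.end or (p.offset <= m.start <= p.end and not p.text)):
                continue
            ann_id += 1
            ael = etree.SubElement(pel, "annotation", id=str(ann_id))
            tinfon = etree.SubElement(ael, "infon", key=keys.entity_type)
            tinfon.text = m.entity_type
            iinfon = etree.SubElement(ael, "infon", key=keys.identifier)
            iinfon.text = format_identifiers(m.identifiers)
            if m.annotator_tag is not None:
                ainfon = etree.SubElement(ael, "infon", key=keys.annotator)
                ainfon.text = m.annotator_tag
            for s in m.spans:
                etree.SubElement(
                    ael, "location", offset=str(s.offset), length=str(s.length)
                )
            etree.SubElement(ael, "text").text = m.text
    return el


def _ann_from_parts(
    infons: Dict[str, str], locations: List[Span], text: str, keys: InfonKeys
) -> Mention:
    return Mention(
        spans=locations,
        text=text,
        entity_type=infons.get(keys.entity_type, CHEMICAL),
        identifiers=parse_identifiers(infons.get(keys.identifier)),
        annotator_tag=infons.get(keys.annotator),
    )


def _doc_from_xml(el: etree._Element, keys: InfonKeys) -> Document:
    doc_id = el.findtext("id") or ""
    metadata = {i.get("key"): i.text or "" for i in el.findall("infon")}
    passages: List[Passage] = []
    mentions: List[Mention] = []
    for pel in el.findall("passage"):
        infons = {i.get("key"): i.text or "" for i in pel.findall("infon")}
        offset_text = pel.findtext("offset")
        if offset_text is None:
            raise BioCFormatError(
                f"passage without <offset> in document {doc_id!r} "
                f"(line {pel.sourceline})"
            )
        passages.append(
            Passage(
                offset=int(offset_text),
                text=pel.findtext("text") or "",
                section_label=infons.get(keys.section),
            )
        )
        for ael in pel.findall("annotation"):
            ainfons = {i.get("key"): i.text or "" for i in ael.findall("infon")}
            spans = [
                Span(int(loc.get("offset")), int(loc.get("length")))
                for loc in ael.findall("location")
            ]
            if not spans:
                raise BioCFormatError(
                    f"annotation without <location> in document {doc_id!r} "
                    f"(line {ael.sourceline})"
                )
            mentions.append(
                _ann_from_parts(ainfons, spans, ael.findtext("text") or "", keys)
            )
    mentions.sort(key=_mention_sort_key)
    return Document(doc_id=doc_id, passages=passages, mentions=mentions, metadata=metadata)


# ---------------------------------------------------------------------------
# JSON dialect

def _doc_to_json(doc: Document, keys: InfonKeys) -> dict:
    out = {"id": doc.doc_id, "infons": dict(doc.metadata), "passages": []}
    ann_id = 0
    mentions = sorted(doc.mentions, key=_mention_sort_key)
    for p in doc.passages:
        pj = {
            "offset": p.offset,
            "infons": ({keys.section: p.section_label} if p.section_label else {}),
            "text": p.text,
            "annotations": [],
        }
        for m in mentions:
            if not (p.offset <= m.start < p.end or (p.offset <= m.start <= p.end and not p.text)):
                continue
            ann_id += 1
            infons = {
                keys.entity_type: m.entity_type,
                keys.identifier: format_identifiers(m.identifiers),
            }
            if m.annotator_tag is not None:
                infons[keys.annotator] = m.annotator_tag
            pj["annotations"].append(
                {
                    "id": str(ann_id),
                    "infons": infons,
                    "locations": [
                        {"offset": s.offset, "length": s.length} for s in m.spans
                    ],
                    "text": m.text,
                }
            )
        out["passages"].append(pj)
    return out


def _doc_from_json(dj: dict, keys: InfonKeys) -> Document:
    passages: List[Passage] = []
    mentions: List[Mention] = []
    doc_id = str(dj.get("id", ""))
    for pj in dj.get("passages", []):
        infons = pj.get("infons", {}) or {}
        if "offset" not in pj:
            raise BioCFormatError(f"passage without offset in document {doc_id!r}")
        passages.append(
            Passage(
                offset=int(pj["offset"]),
                text=pj.get("text", "") or "",
                section_label=infons.get(keys.section),
            )
        )
        for aj in pj.get("annotations", []):
            spans = [
                Span(int(loc["offset"]), int(loc["length"]))
                for loc in aj.get("locations", [])
            ]
            if not spans:
                raise BioCFormatError(
                    f"annotation without locations in document {doc_id!r}"
                )
            mentions.append(
                _ann_from_parts(
                    aj.get("infons", {}) or {}, spans, aj.get("text", "") or "", keys
                )
            )
    mentions.sort(key=_mention_sort_key)
    return Document(
        doc_id=doc_id,
        passages=passages,
        mentions=mentions,
        metadata={str(k): str(v) for k, v in (dj.get("infons", {}) or {}).items()},
    )


# ---------------------------------------------------------------------------
# public I/O

PathLike = Union[str, Path]


def read_collection(
    path: PathLike,
    dialect: str = "xml",
    keys: InfonKeys = DEFAULT_KEYS,
    validate: bool = True,
) -> List[Document]:
    """Read a BioC collection; offsets are Unicode code points.

    With ``validate=True`` (default) structural violations — e.g. an
    annotation whose span leaves its document — raise :class:`BioCFormatError`
    naming the document and offset.
    """
    path = Path(path)
    if dialect == "xml":
        try:
            tree = etree.parse(str(path))
        except etree.XMLSyntaxError as exc:
            raise BioCFormatError(f"{path}: XML parse failure: {exc}") from exc
        root = tree.getroot()
        if root.tag != "collection":
            raise BioCFormatError(f"{path}: root element is <{root.tag}>, not <collection>")
        docs = [_doc_from_xml(el, keys) for el in root.findall("document")]
    elif dialect == "json":
        try:
            data = json.loads(path.read_text("utf-8"))
        except json.JSONDecodeError as exc:
            raise BioCFormatError(f"{path}: JSON parse failure: {exc}") from exc
        docs = [_doc_from_json(dj, keys) for dj in data.get("documents", [])]
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'xml' or 'json'")
    if validate:
        violations = validate_collection(docs)
        if violations:
            head = "; ".join(
                f"{v.doc_id}:{v.location}:{v.kind}" for v in violations[:5]
            )
            raise BioCFormatError(f"{path}: invalid collection ({head})")
    return docs


def write_collection(
    docs: Iterable[Document],
    path: PathLike,
    dialect: str = "xml",
    keys: InfonKeys = DEFAULT_KEYS,
    source: str = "chemnorm",
) -> Path:
    """Write a BioC collection so that :func:`read_collection` round-trips it.

    Mentions are emitted in canonical (start, end, text) order and attached to
    the passage containing their first span.
    """
    path = Path(path)
    docs = list(docs)
    if dialect == "xml":
        root = etree.Element("collection")
        etree.SubElement(root, "source").text = source
        etree.SubElement(root, "date").text = ""
        etree.SubElement(root, "key").text = ""
        for d in docs:
            root.append(_doc_to_xml(d, keys))
        path.write_bytes(
            etree.tostring(
                root, xml_declaration=True, encoding="UTF-8", pretty_print=True
            )
        )
    elif dialect == "json":
        payload = {
            "source": source,
            "date": "",
            "key": "",
            "infons": {},
            "documents": [_doc_to_json(d, keys) for d in docs],
        }
        path.write_text(json.dumps(payload, ensure_ascii=False, indent=1), "utf-8")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'xml' or 'json'")
    return path
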