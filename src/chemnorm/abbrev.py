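"""Abbreviation definition detection, conflict resolution and expansion.

Full-text articles routinely define an abbreviation in parentheses —
"triphenyl phosphate (TPP)" — and then use the short form alone.  Because
short forms are a dominant source of ambiguity in chemical text (a short form
like "MTT" has hundreds of expansions in the literature), mention text is
expanded to the locally defined long form before dictionary matching.

The detector implements the classic parenthetical long-form/short-form
algorithm: the short form's characters are matched right-to-left against the
text preceding the parenthesis, and the first character of the short form
must begin a word of the long form.  A TSV import path is provided so output
from an external abbreviation detector (e.g. Ab3P) can be used instead.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Tuple

import pandas as pd

from .bioc import Document

__all__ = [
    "AbbreviationDefinition",
    "AbbreviationMap",
    "detect_definitions",
    "resolve_conflicts",
    "expand_text",
    "read_definitions_tsv",
    "write_definitions_tsv",
]

# short-form rejects: function words and list markers that appear in parens
_SF_STOPWORDS = {
    "and", "or", "not", "the", "of", "in", "on", "for", "with", "eg", "e.g.",
    "ie", "i.e.", "etc", "see", "vs",
}

_PAREN_RE = re.compile(r"\(([^()]{1,12})\)")
_MAX_LF_WORDS_PAD = 5


@dataclass(frozen=True)
class AbbreviationDefinition:
    short_form: str
    long_form: str
    doc_id: str
    count: int = 1


@dataclass
class AbbreviationMap:
    """Conflict-resolved mapping: one long form per short form."""

    entries: Dict[str, str] = field(default_factory=dict)
    provenance: Dict[str, int] = field(default_factory=dict)


def _find_long_form(short: str, before: str) -> str | None:
    """Right-to-left character match of ``short`` against ``before``.

    Each short-form character (case-insensitive; non-alphanumerics skipped)
    must appear in order; the first character must start a word of the long
    form.  Returns the matched long form, or None.
    """
    sf = [c for c in short.lower() if c.isalnum()]
    if not sf:
        return None
    i = len(sf) - 1
    j = len(before) - 1
    while i >= 0:
        c = sf[i]
        while j >= 0:
            ok = before[j].lower() == c
            if ok and i == 0 and j > 0 and before[j - 1].isalnum():
                ok = False  # first SF char must start a word
            if ok:
                break
            j -= 1
        if j < 0:
            return None
        i -= 1
        j -= 1
    long_form = before[j + 1 :].strip()
    n_words = len(long_form.split())
    if n_words > min(len(sf) + _MAX_LF_WORDS_PAD, 2 * max(len(sf), 1)):
        return None
    if len(long_form) <= len(short.strip()):
        return None
    return long_form


def _candidate_short_form(sf: str) -> bool:
    sf = sf.strip()
    return (
        bool(sf)
        and any(c.isalpha() for c in sf)
        and sf.lower() not in _SF_STOPWORDS
        and not sf.lower().startswith(("see ", "e.g", "i.e"))
    )


def detect_definitions(doc: Document) -> List[AbbreviationDefinition]:
    """Detect "long form (SF)" definitions in every passage of a document.

    Repeated identical definitions aggregate their counts.
    """
    counts: Counter[Tuple[str, str]] = Counter()
    for passage in doc.passages:
        for m in _PAREN_RE.finditer(passage.text):
            sf = m.group(1).strip()
            if not _candidate_short_form(sf):
                continue
            window = passage.text[: m.start()].rstrip()
            # cap the search window at a handful of words before the paren
            words = window.split()
            max_words = min(len(sf) + _MAX_LF_WORDS_PAD, 2 * max(len(sf), 1))
            window = " ".join(words[-max_words:]) if words else ""
            long_form = _find_long_form(sf, window)
            if long_form and sf not in long_form.split():
                counts[(sf, long_form)] += 1
    return [
        AbbreviationDefinition(short_form=sf, long_form=lf, doc_id=doc.doc_id, count=n)
        for (sf, lf), n in sorted(counts.items())
    ]


def resolve_conflicts(
    defs: Iterable[AbbreviationDefinition], scope: str = "collection"
) -> AbbreviationMap:
    """Pick one long form per short form by aggregated frequency.

    ``scope`` names the aggregation the caller performed ("document" when
    ``defs`` comes from one document, "collection" when pooled); resolution
    itself is the same.  Ties break to the longer long form, then
    lexicographically smallest — deterministic regardless of input order.
    """
    if scope not in ("document", "collection"):
        raise ValueError(f"unknown scope {scope!r}")
    totals: Counter[Tuple[str, str]] = Counter()
    for d in defs:
        totals[(d.short_form, d.long_form)] += d.count
    amap = AbbreviationMap()
    by_sf: Dict[str, List[Tuple[str, int]]] = {}
    for (sf, lf), n in totals.items():
        by_sf.setdefault(sf, []).append((lf, n))
    for sf, options in by_sf.items():
        lf, n = min(options, key=lambda o: (-o[1], -len(o[0]), o[0]))
        amap.entries[sf] = lf
        amap.provenance[sf] = n
    return amap


_TOKEN_BOUNDARY = r"(?<![A-Za-z0-9]){}(?![A-Za-z0-9])"


def expand_text(mention_text: str, amap: AbbreviationMap) -> str:
    """Replace every maximal token equal to a known short form by its long
    form.  Single pass: text introduced by a replacement is never re-expanded.
    """
    if not amap.entries:
        return mention_text
    pattern = re.compile(
        _TOKEN_BOUNDARY.format(
            "(" + "|".join(re.escape(sf) for sf in sorted(amap.entries, key=len, reverse=True)) + ")"
        )
    )
    return pattern.sub(lambda m: amap.entries[m.group(1)], mention_text)


def read_definitions_tsv(path) -> List[AbbreviationDefinition]:
    """Import external detector output: columns doc_id, short_form, long_form, count."""
    df = pd.read_csv(path, sep="\t", dtype={"count": int}, keep_default_na=False)
    return [
        AbbreviationDefinition(
            short_form=r.short_form, long_form=r.long_form, doc_id=str(r.doc_id),
            count=int(r.count),
        )
        for r in df.itertuples(index=False)
    ]


def write_definitions_tsv(defs: Iterable[AbbreviationDefinition], path) -> Path:
    pd.DataFrame(
        [
            {"doc_id": d.doc_id, "short_form": d.short_form,
             "long_form": d.long_form, "count": d.count}
            for d in defs
        ],
        columns=["doc_id", "short_form", "long_form", "count"],
    ).to_csv(path, sep="\t", index=False)
    return Path(path)
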