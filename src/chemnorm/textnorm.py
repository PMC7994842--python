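"""String normalization operators for dictionary matching of chemical names.

Chemical name variants in the literature differ mainly in case, punctuation
(hyphens, commas, brackets), Greek letters, and pluralization.  The matchers
therefore operate at three increasingly permissive normalization levels:

``exact``
    No transformation beyond trimming surrounding whitespace; comparison is
    case-sensitive.
``relaxed``
    Lowercase, fold non-ASCII characters to approximate ASCII equivalents,
    convert non-alphanumeric characters to spaces, then remove all spaces
    except those flanked by digits on both sides (so locants such as "5,6-"
    keep their separation: "5,6-EET" -> "5 6eet").
``relaxed_plural``
    The relaxed mapping plus a conservative plural stemmer applied to each
    token (token boundaries taken before space removal).

Greek letters are transliterated through a TSV table shipped as package data
(``data/greek.tsv``) so deployments can override it.
"""

from __future__ import annotations

import enum
import unicodedata
from functools import lru_cache
from importlib import resources
from typing import Dict

__all__ = [
    "NormalizationLevel",
    "load_greek_table",
    "relaxed_normalize",
    "plural_stem_token",
    "relaxed_plural_normalize",
    "normalize",
]


class NormalizationLevel(str, enum.Enum):
    """Matching permissiveness, totally ordered: exact < relaxed < relaxed_plural."""

    EXACT = "exact"
    RELAXED = "relaxed"
    RELAXED_PLURAL = "relaxed_plural"

    @property
    def rank(self) -> int:
        return _LEVEL_ORDER[self]


_LEVEL_ORDER = {
    NormalizationLevel.EXACT: 0,
    NormalizationLevel.RELAXED: 1,
    NormalizationLevel.RELAXED_PLURAL: 2,
}


@lru_cache(maxsize=1)
def load_greek_table() -> Dict[str, str]:
    """Greek-letter (and micro sign) transliterations, char -> ASCII name."""
    table: Dict[str, str] = {}
    text = resources.files("chemnorm").joinpath("data/greek.tsv").read_text("utf-8")
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        codepoint, _char, replacement = line.split("\t")
        table[chr(int(codepoint, 16))] = replacement
    return table


def _ascii_fold(text: str, greek: Dict[str, str]) -> str:
    # NFKD first so presentation forms (e.g. the micro sign) decompose, then
    # the Greek table, then combining-mark removal; unmapped non-ASCII drops.
    out = []
    for ch in unicodedata.normalize("NFKD", text):
        if ch in greek:
            out.append(greek[ch])
        elif ord(ch) < 128:
            out.append(ch)
        elif unicodedata.combining(ch):
            continue
        # else: no approximate equivalent; dropped
    return "".join(out)


def _relaxed_tokens(text: str) -> list[str]:
    """Lowercase, ASCII-fold, punctuation-to-space; return the space-separated
    tokens that exist *before* the conditional space removal."""
    greek = load_greek_table()
    # casefold rather than lower: full case folding maps e.g. ß -> ss, so
    # normalization is invariant under upper/lower-casing of the input
    folded = _ascii_fold(text.casefold(), greek)
    spaced = "".join(c if c.isalnum() and c.isascii() else " " for c in folded)
    return spaced.split()


def _join_digit_flanked(tokens: list[str]) -> str:
    """Join tokens, keeping a space only between a trailing and a leading digit."""
    if not tokens:
        return ""
    parts = [tokens[0]]
    for tok in tokens[1:]:
        if parts[-1][-1].isdigit() and tok[0].isdigit():
            parts.append(" ")
        parts.append(tok)
    return "".join(parts)


def relaxed_normalize(text: str) -> str:
    """Apply the relaxed mapping: lowercase -> ASCII fold -> punctuation to
    spaces -> remove spaces not flanked by digits.

    >>> relaxed_normalize("Triphenyl Phosphate")
    'triphenylphosphate'
    >>> relaxed_normalize("5,6-EET")
    '5 6eet'
    """
    return _join_digit_flanked(_relaxed_tokens(text))


_STEM_ES_SUFFIXES = ("xes", "ses", "zes", "ches", "shes")
_KEEP_S_SUFFIXES = ("ss", "us", "is")


def plural_stem_token(token: str) -> str:
    """Conservative plural stemmer for a single token.

    Tokens shorter than 4 characters or containing a digit are returned
    unchanged.  Rules, first match wins: "-ies" -> "-y"; "-xes"/"-ses"/
    "-zes"/"-ches"/"-shes" drop "es"; otherwise a final "-s" is dropped
    unless the token ends in "-ss", "-us" or "-is".  Never lengthens a token.
    """
    if len(token) < 4 or any(c.isdigit() for c in token):
        return token
    if token.endswith("ies"):
        return token[:-3] + "y"
    if token.endswith(_STEM_ES_SUFFIXES):
        return token[:-2]
    if token.endswith("s") and not token.endswith(_KEEP_S_SUFFIXES):
        return token[:-1]
    return token


def relaxed_plural_normalize(text: str) -> str:
    """Relaxed mapping with each letter-only token plural-stemmed.

    >>> relaxed_plural_normalize("Fatty Acids")
    'fattyacid'
    """
    tokens = [
        plural_stem_token(tok) if tok.isalpha() else tok
        for tok in _relaxed_tokens(text)
    ]
    return _join_digit_flanked(tokens)


def normalize(text: str, level: NormalizationLevel) -> str:
    """Normalize ``text`` at the given level (exact = whitespace trim only)."""
    level = NormalizationLevel(level)
    if level is NormalizationLevel.EXACT:
        return text.strip()
    if level is NormalizationLevel.RELAXED:
        return relaxed_normalize(text)
    return relaxed_plural_normalize(text)
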