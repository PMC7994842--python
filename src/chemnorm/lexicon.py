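"""Terminology loading, name indexing, cross-referencing and hierarchy tests.

A lexicon bundles one primary MeSH-like terminology (descriptors with tree
numbers) with any number of auxiliary chemical terminologies (UNII, ChEBI,
DSSTox, UMLS, ...).  Auxiliary concepts reach MeSH either through a direct
MESH cross-reference or indirectly by sharing a CAS, INCHI, INCHIKEY, UNII,
SMILES or EINECS identifier with a MeSH concept.

Terminologies are loaded from TSV tables with columns::

    concept_id  name  [MESH] [CAS] [INCHI] [INCHIKEY] [UNII] [SMILES] [EINECS] [tree_numbers]

one row per name; per-concept columns (xrefs, tree numbers) are taken from
the first row carrying a value; tree_numbers is |-separated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set

import pandas as pd

from .textnorm import NormalizationLevel, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "Concept",
    "NameIndex",
    "TreePolicy",
    "XREF_SCHEMES",
    "load_terminology",
    "write_terminology",
    "build_name_index",
    "xref_to_mesh",
    "build_mesh_xref_index",
    "is_chemical_mesh",
]

XREF_SCHEMES = ("CAS", "INCHI", "INCHIKEY", "UNII", "SMILES", "EINECS")
SOURCES = ("MESH", "UNII", "CHEBI", "DSSTOX", "UMLS", "OTHER")


@dataclass
class Concept:
    """One terminology entry: an identifier with its names and join keys."""

    concept_id: str
    source: str
    names: List[str]
    xrefs: Dict[str, str] = field(default_factory=dict)
    tree_numbers: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError(f"{self.concept_id}: concept requires at least one name")
        if self.tree_numbers and self.source != "MESH":
            raise ValueError(
                f"{self.concept_id}: tree numbers only apply to MESH concepts"
            )


@dataclass
class NameIndex:
    """Map from a normal form (at one level) to the concept ids bearing it."""

    level: NormalizationLevel
    entries: Dict[str, Set[str]] = field(default_factory=dict)

    def lookup(self, text: str) -> Set[str]:
        """Normalize ``text`` at the index level and look it up."""
        return set(self.entries.get(normalize(text, self.level), ()))


def load_terminology(path, source: str) -> List[Concept]:
    """Load a TSV terminology table into grouped, de-duplicated concepts."""
    if source not in SOURCES:
        raise ValueError(f"unknown source {source!r}; expected one of {SOURCES}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        logger.warning("%s: terminology table is empty", path)
        return []
    for col in ("concept_id", "name"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    if df.empty:
        logger.warning("%s: terminology table is empty", path)
        return []
    concepts: Dict[str, Concept] = {}
    for row in df.itertuples(index=False):
        cid = row.concept_id.strip()
        name = row.name.strip()
        if cid not in concepts:
            concepts[cid] = Concept(concept_id=cid, source=source, names=[name])
        elif name not in concepts[cid].names:
            concepts[cid].names.append(name)
        c = concepts[cid]
        for scheme in ("MESH",) + XREF_SCHEMES:
            if scheme in df.columns and scheme not in c.xrefs:
                val = getattr(row, scheme).strip()
                if val:
                    c.xrefs[scheme] = val
        if source == "MESH" and "tree_numbers" in df.columns and not c.tree_numbers:
            trees = getattr(row, "tree_numbers").strip()
            if trees:
                c.tree_numbers = trees.split("|")
    return list(concepts.values())


def write_terminology(concepts: Sequence[Concept], path) -> Path:
    """Inverse of :func:`load_terminology` (one row per concept name)."""
    rows = []
    for c in concepts:
        for name in c.names:
            row = {"concept_id": c.concept_id, "name": name}
            for scheme in ("MESH",) + XREF_SCHEMES:
                row[scheme] = c.xrefs.get(scheme, "")
            row["tree_numbers"] = "|".join(c.tree_numbers)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def build_name_index(
    concepts: Iterable[Concept], level: NormalizationLevel
) -> NameIndex:
    """Index every concept name by its normal form at ``level``.

    Names whose normal form is empty (e.g. pure punctuation under the relaxed
    mapping) are not indexed.
    """
    level = NormalizationLevel(level)
    entries: Dict[str, Set[str]] = {}
    for c in concepts:
        for name in c.names:
            key = normalize(name, level)
            if key:
                entries.setdefault(key, set()).add(c.concept_id)
    return NameIndex(level=level, entries=entries)


def _mesh_id(value: str) -> str:
    return value if value.startswith("MESH:") else f"MESH:{value}"


def build_mesh_xref_index(
    mesh_concepts: Iterable[Concept],
) -> Dict[str, Dict[str, Set[str]]]:
    """scheme -> xref value -> MeSH concept ids, for fast indirect joins."""
    index: Dict[str, Dict[str, Set[str]]] = {s: {} for s in XREF_SCHEMES}
    for c in mesh_concepts:
        for scheme in XREF_SCHEMES:
            val = c.xrefs.get(scheme, "").strip()
            if val:
                index[scheme].setdefault(val, set()).add(c.concept_id)
    return index


def xref_to_mesh(
    concept: Concept,
    mesh_concepts: Optional[Iterable[Concept]] = None,
    mesh_xref_index: Optional[Dict[str, Dict[str, Set[str]]]] = None,
) -> Set[str]:
    """MeSH ids reachable from an auxiliary concept by cross-reference.

    A direct MESH xref short-circuits; otherwise any shared value under the
    CAS/INCHI/INCHIKEY/UNII/SMILES/EINECS schemes joins the two (values are
    compared as trimmed opaque strings).  Returns the empty set when
    unreachable.
    """
    direct = concept.xrefs.get("MESH", "").strip()
    if direct:
        return {_mesh_id(direct)}
    if mesh_xref_index is None:
        if mesh_concepts is None:
            raise ValueError("need mesh_concepts or mesh_xref_index")
        mesh_xref_index = build_mesh_xref_index(mesh_concepts)
    out: Set[str] = set()
    for scheme in XREF_SCHEMES:
        val = concept.xrefs.get(scheme, "").strip()
        if val:
            out |= mesh_xref_index[scheme].get(val, set())
    return out


@dataclass(frozen=True)
class TreePolicy:
    """Prefix allow/deny lists over MeSH tree numbers; longest match wins.

    The default admits the chemical descriptor branch ("D") while excluding
    the enzyme (D08.811) and protein (D12.776) subtrees, which annotation
    practice treats as macromolecules rather than chemicals.  Both lists are
    configuration; the policy here is a pragmatic default, not a standard.
    """

    allow: tuple = ("D",)
    deny: tuple = ("D08.811", "D12.776")

    def tree_is_chemical(self, tree: str) -> bool:
        best_len, best_allowed = -1, False
        for prefix in self.allow:
            if tree.startswith(prefix) and len(prefix) > best_len:
                best_len, best_allowed = len(prefix), True
        for prefix in self.deny:
            if tree.startswith(prefix) and len(prefix) > best_len:
                best_len, best_allowed = len(prefix), False
        return best_len >= 0 and best_allowed


DEFAULT_TREE_POLICY = TreePolicy()


def is_chemical_mesh(concept: Concept, tree_policy: TreePolicy = DEFAULT_TREE_POLICY) -> bool:
    """True iff some tree number of a MeSH concept falls in a chemical branch."""
    if concept.source != "MESH":
        raise ValueError(f"{concept.concept_id}: hierarchy test requires a MESH concept")
    return any(tree_policy.tree_is_chemical(t) for t in concept.tree_numbers)
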