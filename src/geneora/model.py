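"""Core in-memory model: gene identifiers, gene sets, databases and gene lists.

All gene-set dialects (GMT, GAF+OBO, KEGG REST flat files, cancer-gene TSV)
are parsed into a single :class:`GeneSetDatabase`, so the statistical core
never needs to know where a database came from.

Identifiers are carried as normalized plain strings; the identifier kind
(official symbol vs. Entrez GeneID) is tracked once per container rather than
per gene. Symbols are upper-cased, GeneIDs must be decimal digits.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping


class IdKind(str, enum.Enum):
    """Gene identifier dialect: official symbols (``sym``) or Entrez GeneIDs (``gid``)."""

    SYM = "sym"
    GID = "gid"


class DbName(str, enum.Enum):
    """Supported reference database families."""

    KEGG = "KEGG"
    GO_BP = "GO_BP"
    GO_MF = "GO_MF"
    GO_CC = "GO_CC"
    REACTOME = "REACTOME"
    NCG = "NCG"


#: GO aspect letter (GAF column 9) -> database name.
GO_ASPECTS: Mapping[str, DbName] = {
    "P": DbName.GO_BP,
    "F": DbName.GO_MF,
    "C": DbName.GO_CC,
}

#: GO aspect letter -> OBO namespace tag.
GO_NAMESPACES: Mapping[str, str] = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}


class IdentifierError(ValueError):
    """An input token is not a valid gene identifier of the requested kind."""


def normalize_gene(token: str, id_kind: IdKind) -> str:
    """Normalize one gene identifier token.

    Symbols are whitespace-stripped and upper-cased; GeneIDs must consist of
    decimal digits only. Raises :class:`IdentifierError` for empty tokens,
    embedded tabs/newlines, or non-digit GeneIDs.
    """
    if "\t" in token or "\n" in token:
        raise IdentifierError(f"identifier contains tab/newline: {token!r}")
    token = token.strip()
    if not token:
        raise IdentifierError("empty gene identifier")
    if id_kind is IdKind.GID:
        if not token.isdigit():
            raise IdentifierError(f"Entrez GeneID must be digits only: {token!r}")
        return token
    return token.upper()


@dataclass(frozen=True)
class GeneSet:
    """One functional term: a GO term, KEGG/Reactome pathway or cancer type.

    ``members`` is the set of annotated genes; its size is the ``k`` of the
    enrichment contingency table.
    """

    term_id: str
    term_name: str
    members: frozenset[str]

    @property
    def k(self) -> int:
        """Number of genes annotated to this term."""
        return len(self.members)


@dataclass
class GeneSetDatabase:
    """A named collection of gene sets with a derived gene universe.

    The universe (union of all member sets) supplies the default background
    size ``N`` for the enrichment test.
    """

    db_name: DbName
    organism: str
    sets: tuple[GeneSet, ...]
    id_kind: IdKind
    retrieved_at: str = "bundled"
    skipped_rows: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.sets:
            if s.term_id in seen:
                raise ValueError(f"duplicate term_id in database: {s.term_id}")
            seen.add(s.term_id)

    @cached_property
    def universe(self) -> frozenset[str]:
        """Union of all member genes across sets."""
        out: set[str] = set()
        for s in self.sets:
            out |= s.members
        return frozenset(out)

    @cached_property
    def by_id(self) -> Mapping[str, GeneSet]:
        return {s.term_id: s for s in self.sets}

    def content_key(self):
        """Hashable summary used to compare databases for logical equality."""
        return (self.db_name, self.organism, frozenset(self.sets))

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class OboTermTable:
    """GO accession -> (name, namespace) lookup parsed from an OBO file.

    Obsolete terms are excluded; alternative accessions (``alt_id``) map to
    the canonical term's name and namespace.
    """

    entries: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def name_of(self, accession: str, default: str | None = None) -> str:
        entry = self.entries.get(accession)
        if entry is None:
            return accession if default is None else default
        return entry[0]

    def namespace_of(self, accession: str) -> str | None:
        entry = self.entries.get(accession)
        return None if entry is None else entry[1]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries


@dataclass(frozen=True)
class GeneList:
    """The user's deduplicated input gene list (the ``d`` of the test)."""

    ids: tuple[str, ...]
    id_kind: IdKind

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("GeneList ids must be unique")
        if not self.ids:
            raise ValueError("GeneList must contain at least one identifier")

    @property
    def d(self) -> int:
        """Number of unique input genes."""
        return len(self.ids)

    @classmethod
    def from_tokens(cls, tokens: Iterable[str], id_kind: IdKind) -> "GeneList":
        """Build a list from raw tokens: normalize, deduplicate keeping first occurrence."""
        seen: dict[str, None] = {}
        for tok in tokens:
            seen.setdefault(normalize_gene(tok, id_kind), None)
        return cls(ids=tuple(seen), id_kind=id_kind)
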