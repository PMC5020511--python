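"""Parsers and serializers for every gene-set database dialect the tool reads.

Supported dialects:

* GMT (Gene Matrix Transposed) — one set per line: name, id/description, genes…
* OBO 1.2 flat files — GO term accessions, names, namespaces (via ``obonet``)
* GAF 2.x — GO gene-association files (15+ tab-separated columns)
* KEGG REST flat files — ``list/pathway`` and ``link`` two-column dialects
* bundled cancer-gene TSV — ``gene_symbol<TAB>cancer_type``
* the local cache dialect — GMT plus a ``key=value`` metadata sidecar

Every parser produces a :class:`~geneora.model.GeneSetDatabase`; none of them
raises on blank or comment lines, and skipped-row counts are kept on the
resulting database (``skipped_rows``) as well as logged.
"""

from __future__ import annotations

import io
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import obonet

from .model import (
    GO_ASPECTS,
    GO_NAMESPACES,
    DbName,
    GeneSet,
    GeneSetDatabase,
    IdentifierError,
    IdKind,
    OboTermTable,
    normalize_gene,
)

logger = logging.getLogger(__name__)

GO_ACCESSION_RE = re.compile(r"^GO:\d{7}$")


class ParseError(ValueError):
    """A structurally malformed line that cannot be skipped safely."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class CacheMissingError(FileNotFoundError):
    """A prepared database cache is absent or incomplete."""


def _as_lines(stream: Iterable[str] | str) -> Iterable[str]:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def _normalize_members(tokens: Iterable[str], id_kind: IdKind) -> tuple[frozenset[str], int]:
    """Normalize member tokens, dropping invalid ones. Returns (members, n_dropped)."""
    members: set[str] = set()
    dropped = 0
    for tok in tokens:
        try:
            members.add(normalize_gene(tok, id_kind))
        except IdentifierError:
            dropped += 1
    return frozenset(members), dropped


def parse_gmt(
    stream: Iterable[str] | str,
    *,
    db_name: DbName = DbName.REACTOME,
    organism: str = "hsa",
    id_kind: IdKind = IdKind.SYM,
    retrieved_at: str = "bundled",
) -> GeneSetDatabase:
    """Parse GMT lines (``name<TAB>id<TAB>gene1…geneN``) into a database.

    The second GMT field, when non-empty, is used as the term id (Reactome
    stable id convention); otherwise the name doubles as the id. Duplicate
    genes within a line collapse; lines with no genes are skipped with a
    warning; lines with fewer than two fields raise :class:`ParseError`.
    Repeated term ids merge their member sets.
    """
    sets: dict[str, GeneSet] = {}
    skipped = 0
    for line_no, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError("GMT line has fewer than 2 tab-separated fields", line_no)
        name, ident = fields[0].strip(), fields[1].strip()
        term_id = ident or name
        members, dropped = _normalize_members(fields[2:], id_kind)
        skipped += dropped
        if not members:
            logger.warning("GMT line %d (%s): no genes, skipped", line_no, term_id)
            skipped += 1
            continue
        if term_id in sets:
            logger.warning("GMT line %d: duplicate term %s merged", line_no, term_id)
            prev = sets[term_id]
            members = prev.members | members
            name = prev.term_name
        sets[term_id] = GeneSet(term_id=term_id, term_name=name or term_id, members=members)
    return GeneSetDatabase(
        db_name=db_name,
        organism=organism,
        sets=tuple(sets.values()),
        id_kind=id_kind,
        retrieved_at=retrieved_at,
        skipped_rows=skipped,
    )


def parse_obo(stream: Iterable[str] | str | TextIO) -> OboTermTable:
    """Parse an OBO 1.2 flat file into an accession -> (name, namespace) table.

    Obsolete terms are excluded. ``alt_id`` accessions map to the canonical
    term's name and namespace. Terms missing a name or namespace, or with
    accessions not matching the ``GO:<7 digits>`` pattern, are skipped with a
    warning.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    graph = obonet.read_obo(stream, ignore_obsolete=True)
    entries: dict[str, tuple[str, str]] = {}
    valid_namespaces = set(GO_NAMESPACES.values())
    for accession, data in graph.nodes(data=True):
        name = data.get("name")
        namespace = data.get("namespace")
        if not name or namespace not in valid_namespaces:
            logger.warning("OBO term %s missing name/namespace, skipped", accession)
            continue
        if not GO_ACCESSION_RE.match(accession):
            logger.warning("OBO term %s is not a GO accession, skipped", accession)
            continue
        entries[accession] = (name, namespace)
        for alt in data.get("alt_id", []):
            if GO_ACCESSION_RE.match(alt):
                entries.setdefault(alt, (name, namespace))
    return OboTermTable(entries=entries)


def parse_gaf(
    stream: Iterable[str] | str,
    aspect: str,
    terms: OboTermTable | None = None,
    id_kind: IdKind = IdKind.SYM,
    *,
    organism: str = "hsa",
    retrieved_at: str = "bundled",
) -> GeneSetDatabase:
    """Parse GAF 2.x annotation rows into one GO-aspect database.

    ``aspect`` is one of ``P``/``F``/``C`` (biological process, molecular
    function, cellular component). Rows whose qualifier (column 4) contains
    ``NOT`` are excluded, as are rows for other aspects. Term names are
    filled from ``terms`` when available, falling back to the accession.
    Rows with fewer than 15 columns are skipped with a warning; ``!`` comment
    lines are ignored.
    """
    if aspect not in GO_ASPECTS:
        raise ValueError(f"aspect must be one of P/F/C, got {aspect!r}")
    terms = terms or OboTermTable()
    members: dict[str, set[str]] = {}
    skipped = 0
    for line_no, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            logger.warning("GAF line %d: %d columns (<15), skipped", line_no, len(cols))
            skipped += 1
            continue
        qualifier, go_id, row_aspect = cols[3], cols[4], cols[8]
        if "NOT" in qualifier.split("|"):
            continue
        if row_aspect != aspect:
            continue
        token = cols[2] if id_kind is IdKind.SYM else cols[1]
        try:
            gene = normalize_gene(token, id_kind)
        except IdentifierError:
            logger.warning("GAF line %d: invalid %s identifier %r, skipped",
                           line_no, id_kind.value, token)
            skipped += 1
            continue
        members.setdefault(go_id, set()).add(gene)
    sets = tuple(
        GeneSet(term_id=go_id, term_name=terms.name_of(go_id), members=frozenset(genes))
        for go_id, genes in members.items()
    )
    return GeneSetDatabase(
        db_name=GO_ASPECTS[aspect],
        organism=organism,
        sets=sets,
        id_kind=id_kind,
        retrieved_at=retrieved_at,
        skipped_rows=skipped,
    )


def parse_kegg_pathway_list(stream: Iterable[str] | str, organism: str) -> dict[str, str]:
    """Parse KEGG REST ``list/pathway/<org>`` lines into pathway id -> name.

    Accepts ids with or without the ``path:`` prefix; the trailing
    `` - <organism descriptor>`` suffix is stripped from names when present.
    A non-blank line without a tab raises :class:`ParseError`.
    """
    names: dict[str, str] = {}
    for line_no, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        if "\t" not in line:
            raise ParseError("KEGG pathway list line has no tab", line_no)
        ident, name = line.split("\t", 1)
        ident = ident.strip()
        if ident.startswith("path:"):
            ident = ident[len("path:"):]
        if " - " in name:
            name = name.rsplit(" - ", 1)[0]
        names[ident] = name.strip()
    return names


_KEGG_PATHWAY_RE = re.compile(r"^(?:path:)?([a-z]{2,4}\d{5})$")


def parse_kegg_links(
    stream: Iterable[str] | str,
    names: Mapping[str, str],
    id_kind: IdKind = IdKind.GID,
    *,
    organism: str = "hsa",
    retrieved_at: str = "bundled",
) -> GeneSetDatabase:
    """Parse KEGG REST gene<->pathway link lines into a pathway database.

    Each line pairs an ``<org>:<gene>`` token with a ``path:<pathway>`` token,
    in either column order. Gene tokens are stripped of the organism prefix;
    in ``gid`` mode the residue must be digits (rows violating this are
    skipped with a warning). Pathways absent from ``names`` keep their id as
    name, with a warning.
    """
    members: dict[str, set[str]] = {}
    skipped = 0
    for line_no, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            logger.warning("KEGG link line %d: no tab, skipped", line_no)
            skipped += 1
            continue
        a, b = cols[0].strip(), cols[1].strip()
        m_a, m_b = _KEGG_PATHWAY_RE.match(a), _KEGG_PATHWAY_RE.match(b)
        if m_a and not m_b:
            pathway, gene_tok = m_a.group(1), b
        elif m_b and not m_a:
            pathway, gene_tok = m_b.group(1), a
        else:
            logger.warning("KEGG link line %d: cannot identify pathway column, skipped", line_no)
            skipped += 1
            continue
        if ":" in gene_tok:
            gene_tok = gene_tok.split(":", 1)[1]
        try:
            gene = normalize_gene(gene_tok, id_kind)
        except IdentifierError:
            logger.warning("KEGG link line %d: invalid %s gene token %r, skipped",
                           line_no, id_kind.value, gene_tok)
            skipped += 1
            continue
        members.setdefault(pathway, set()).add(gene)
    sets = []
    for pathway, genes in members.items():
        name = names.get(pathway)
        if name is None:
            logger.warning("KEGG pathway %s has no name in pathway list; using id", pathway)
            name = pathway
        sets.append(GeneSet(term_id=pathway, term_name=name, members=frozenset(genes)))
    return GeneSetDatabase(
        db_name=DbName.KEGG,
        organism=organism,
        sets=tuple(sets),
        id_kind=id_kind,
        retrieved_at=retrieved_at,
        skipped_rows=skipped,
    )


def parse_kegg_gene_symbols(stream: Iterable[str] | str) -> dict[str, str]:
    """Parse KEGG REST ``list/<org>`` gene lines into GeneID -> primary symbol.

    Lines look like ``hsa:7157<TAB>...<TAB>TP53, P53; tumor protein p53``;
    the first comma-separated token before the ``;`` description is the
    primary symbol. Lines without a symbol field are skipped.
    """
    mapping: dict[str, str] = {}
    for raw in _as_lines(stream):
        line = raw.rstrip("\n")
        if not line.strip() or "\t" not in line:
            continue
        ident, rest = line.split("\t", 1)
        gid = ident.split(":", 1)[-1].strip()
        sym_field = rest.split("\t")[-1].split(";", 1)[0]
        symbol = sym_field.split(",")[0].strip()
        if gid.isdigit() and symbol:
            mapping[gid] = symbol.upper()
    return mapping


def parse_ncg_tsv(
    stream: Iterable[str] | str,
    *,
    retrieved_at: str = "bundled",
) -> GeneSetDatabase:
    """Parse a two-column ``gene_symbol<TAB>cancer_type`` TSV into a database.

    One gene set per cancer type (human-only); the cancer-type label serves
    as both term id and name.
    """
    members: dict[str, set[str]] = {}
    skipped = 0
    for line_no, raw in enumerate(_as_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2 or not cols[0].strip() or not cols[1].strip():
            logger.warning("cancer-gene TSV line %d malformed, skipped", line_no)
            skipped += 1
            continue
        gene = normalize_gene(cols[0], IdKind.SYM)
        members.setdefault(cols[1].strip(), set()).add(gene)
    sets = tuple(
        GeneSet(term_id=label, term_name=label, members=frozenset(genes))
        for label, genes in members.items()
    )
    return GeneSetDatabase(
        db_name=DbName.NCG,
        organism="hsa",
        sets=sets,
        id_kind=IdKind.SYM,
        retrieved_at=retrieved_at,
        skipped_rows=skipped,
    )


# ---------------------------------------------------------------------------
# Local cache: GMT + key=value metadata sidecar
# ---------------------------------------------------------------------------

_SIDE_KEYS = ("db_name", "organism", "id_kind", "retrieved_at")


def _sidecar_path(gmt_path: Path) -> Path:
    return gmt_path.with_suffix(gmt_path.suffix + ".meta")


def write_cached_database(db: GeneSetDatabase, path: str | Path) -> Path:
    """Serialize a database to ``<path>`` (GMT) plus ``<path>.meta`` sidecar.

    Sets are written sorted by term id with sorted member columns, so two
    writes of the same database are byte-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for s in sorted(db.sets, key=lambda s: s.term_id):
        lines.append("\t".join([s.term_name, s.term_id, *sorted(s.members)]))
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
    meta = {
        "db_name": db.db_name.value,
        "organism": db.organism,
        "id_kind": db.id_kind.value,
        "retrieved_at": db.retrieved_at,
    }
    _sidecar_path(path).write_text(
        "".join(f"{k}={meta[k]}\n" for k in _SIDE_KEYS), encoding="utf-8"
    )
    return path


def read_cached_database(path: str | Path) -> GeneSetDatabase:
    """Read a database previously written by :func:`write_cached_database`.

    Raises :class:`CacheMissingError` (telling the user to run
    ``prepare_database``) when the GMT file or its metadata sidecar is absent.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists() or not sidecar.exists():
        raise CacheMissingError(
            f"database not prepared: {path} (run 'prepare_database -db=... -org=...' "
            "or geneora --mode=update first)"
        )
    meta: dict[str, str] = {}
    for line in sidecar.read_text(encoding="utf-8").splitlines():
        if "=" in line:
            key, value = line.split("=", 1)
            meta[key.strip()] = value.strip()
    missing = [k for k in _SIDE_KEYS if k not in meta]
    if missing:
        raise CacheMissingError(
            f"cache sidecar {sidecar} is missing keys {missing}; re-run update mode"
        )
    with path.open(encoding="utf-8") as handle:
        return parse_gmt(
            handle,
            db_name=DbName(meta["db_name"]),
            organism=meta["organism"],
            id_kind=IdKind(meta["id_kind"]),
            retrieved_at=meta["retrieved_at"],
        )
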