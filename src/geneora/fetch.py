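"""Update mode: retrieve reference databases from their source endpoints.

Every endpoint is a *locator* — either an HTTP(S) URL or a local file path —
so tests and offline runs substitute fixture files for the live services.
Gzip and zip payloads are decompressed transparently based on the locator
suffix. Prepared databases are written to the local cache in the GMT+sidecar
dialect via :mod:`geneora.formats`.
"""

from __future__ import annotations

import gzip
import io
import logging
import time
import urllib.error
import urllib.request
import zipfile
from dataclasses import dataclass, replace
from datetime import datetime, timezone
from pathlib import Path

from . import formats
from .model import DbName, GeneSet, GeneSetDatabase, IdKind

logger = logging.getLogger(__name__)

ORG_PLACEHOLDER = "ORGANISM_CODE"


class FetchError(RuntimeError):
    """A locator could not be retrieved (after retries, for HTTP)."""

    def __init__(self, locator: str, message: str):
        self.locator = locator
        super().__init__(f"{message} [{locator}]")


@dataclass(frozen=True)
class EndpointSet:
    """Locator templates for the five remote resources (plus an optional
    KEGG gene-list endpoint used to resolve symbols).

    Each template contains at most one ``ORGANISM_CODE`` placeholder. The
    defaults point at the public KEGG REST API, the GO OBO/GAF mirrors and
    the current Reactome GMT archive.
    """

    kegg_list: str = "http://rest.kegg.jp/list/pathway/ORGANISM_CODE"
    kegg_link: str = "http://rest.kegg.jp/link/genes/ORGANISM_CODE"
    go_obo: str = "http://purl.obolibrary.org/obo/go.obo"
    go_gaf: str = "http://geneontology.org/gene-associations/gene_association.ORGANISM_CODE.gz"
    reactome_gmt: str = "http://www.reactome.org/download/current/ReactomePathways.gmt.zip"
    kegg_genes: str | None = None  # e.g. http://rest.kegg.jp/list/ORGANISM_CODE

    def resolve(self, template: str, organism: str) -> str:
        if template.count(ORG_PLACEHOLDER) > 1:
            raise ValueError(f"template has more than one placeholder: {template}")
        return template.replace(ORG_PLACEHOLDER, organism)

    def with_overrides(self, **overrides: str) -> "EndpointSet":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})


def _decompress(name: str, payload: bytes) -> str:
    if name.endswith(".gz"):
        return gzip.decompress(payload).decode("utf-8")
    if name.endswith(".zip"):
        with zipfile.ZipFile(io.BytesIO(payload)) as zf:
            inner = zf.namelist()
            if not inner:
                raise FetchError(name, "zip archive is empty")
            return zf.read(inner[0]).decode("utf-8")
    return payload.decode("utf-8")


def fetch_text(locator: str, *, retries: int = 3, backoff: float = 1.0,
               sleep=time.sleep, timeout: float = 60.0) -> str:
    """Fetch a locator as decoded text.

    Local paths are read directly. HTTP(S) URLs are retried up to
    ``retries`` times with doubling backoff starting at ``backoff`` seconds.
    ``.gz``/``.zip`` payloads are decompressed. Raises :class:`FetchError`
    on a missing path or exhausted retries.
    """
    if locator.startswith(("http://", "https://")):
        delay = backoff
        last: Exception | None = None
        for attempt in range(1, retries + 1):
            try:
                with urllib.request.urlopen(locator, timeout=timeout) as resp:
                    payload = resp.read()
                logger.info("fetched %d bytes from %s", len(payload), locator)
                return _decompress(locator, payload)
            except (urllib.error.URLError, OSError) as exc:
                last = exc
                logger.warning("fetch attempt %d/%d failed for %s: %s",
                               attempt, retries, locator, exc)
                if attempt < retries:
                    sleep(delay)
                    delay *= 2
        raise FetchError(locator, f"exhausted {retries} attempts: {last}")
    path = Path(locator)
    if not path.exists():
        raise FetchError(locator, "no such file")
    payload = path.read_bytes()
    logger.info("read %d bytes from %s", len(payload), locator)
    return _decompress(path.name, payload)


def cache_path(cache_dir: str | Path, db_name: DbName, organism: str,
               id_kind: IdKind) -> Path:
    """Canonical cache location for one (database, organism, id kind)."""
    return Path(cache_dir) / f"{db_name.value}_{organism}.{id_kind.value}.gmt"


def _write_cache(db: GeneSetDatabase, cache_dir: Path) -> Path:
    """Atomically cache a database (write to a temp name, then rename)."""
    final = cache_path(cache_dir, db.db_name, db.organism, db.id_kind)
    tmp = final.with_name(final.name + ".tmp")
    formats.write_cached_database(db, tmp)
    tmp_meta = tmp.with_suffix(tmp.suffix + ".meta")
    tmp.replace(final)
    tmp_meta.replace(final.with_suffix(final.suffix + ".meta"))
    return final


def _now_iso() -> str:
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def prepare_database(
    db: str,
    organism: str,
    cache_dir: str | Path,
    endpoints: EndpointSet | None = None,
    *,
    id_kind: IdKind | None = None,
    now: str | None = None,
    retries: int = 3,
    backoff: float = 1.0,
) -> list[Path]:
    """Fetch and cache one database family; returns the cache paths written.

    ``db`` is ``GO`` (produces the three aspect databases GO_BP/GO_MF/GO_CC),
    ``KEGG`` (pathway list joined with the gene-pathway link table) or
    ``REACTOME`` (GMT archive; human only). GO defaults to symbol
    identifiers, KEGG to Entrez GeneIDs unless a KEGG gene-list endpoint is
    available to resolve symbols. ``now`` overrides the retrieval timestamp
    (for reproducible caches).
    """
    endpoints = endpoints or EndpointSet()
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    retrieved_at = now or _now_iso()
    db = db.upper()
    fetch = lambda loc: fetch_text(loc, retries=retries, backoff=backoff)  # noqa: E731

    if db == "GO":
        kind = id_kind or IdKind.SYM
        obo_text = fetch(endpoints.resolve(endpoints.go_obo, organism))
        terms = formats.parse_obo(obo_text)
        gaf_text = fetch(endpoints.resolve(endpoints.go_gaf, organism))
        paths = []
        for aspect in ("P", "F", "C"):
            parsed = formats.parse_gaf(gaf_text, aspect, terms, kind,
                                       organism=organism, retrieved_at=retrieved_at)
            if not parsed.sets:
                logger.warning("GO aspect %s for organism %s produced no sets",
                               aspect, organism)
            paths.append(_write_cache(parsed, cache_dir))
        return paths

    if db == "KEGG":
        names = formats.parse_kegg_pathway_list(
            fetch(endpoints.resolve(endpoints.kegg_list, organism)), organism)
        if not names:
            raise FetchError(endpoints.resolve(endpoints.kegg_list, organism),
                             f"empty pathway list for organism {organism!r}")
        links = fetch(endpoints.resolve(endpoints.kegg_link, organism))
        kind = id_kind or IdKind.GID
        gid_db = formats.parse_kegg_links(links, names, kind,
                                          organism=organism, retrieved_at=retrieved_at)
        if not gid_db.sets:
            raise FetchError(endpoints.resolve(endpoints.kegg_link, organism),
                             f"no usable {kind.value} gene-pathway links for {organism!r}")
        paths = [_write_cache(gid_db, cache_dir)]
        if endpoints.kegg_genes:
            symbols = formats.parse_kegg_gene_symbols(
                fetch(endpoints.resolve(endpoints.kegg_genes, organism)))
            sym_sets = []
            for s in gid_db.sets:
                mapped = frozenset(symbols[g] for g in s.members if g in symbols)
                if mapped:
                    sym_sets.append(GeneSet(s.term_id, s.term_name, mapped))
            sym_db = GeneSetDatabase(DbName.KEGG, organism, tuple(sym_sets),
                                     IdKind.SYM, retrieved_at=retrieved_at)
            paths.append(_write_cache(sym_db, cache_dir))
        return paths

    if db == "REACTOME":
        if organism != "hsa":
            raise ValueError(
                "the Reactome database supports only Homo sapiens (-org=hsa)")
        gmt_text = fetch(endpoints.resolve(endpoints.reactome_gmt, organism))
        parsed = formats.parse_gmt(gmt_text, db_name=DbName.REACTOME,
                                   organism="hsa", id_kind=id_kind or IdKind.SYM,
                                   retrieved_at=retrieved_at)
        if not parsed.sets:
            raise FetchError(endpoints.reactome_gmt, "empty Reactome payload")
        return [_write_cache(parsed, cache_dir)]

    raise ValueError(f"unknown database {db!r}; expected GO, KEGG or REACTOME")
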