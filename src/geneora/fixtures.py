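"""Deterministic miniature databases and gene lists with a planted enriched term.

This module emulates, at desk scale, the situation the tool is built for: a
reference database of overlapping gene sets and an input gene list in which
one chosen term is genuinely over-represented. The same logical database is
serialized in all three native dialects the parsers read (GMT, GAF+OBO, and
KEGG list/link flat files), so every pipeline stage is testable with no
download.

Generation is a pure function of the :class:`FixtureSpec`: the NumPy
``default_rng`` (PCG64) is seeded from ``spec.seed``, with separate streams
for database and gene-list sampling. Term memberships are sampled
independently from the gene pool, so terms overlap — as real GO/KEGG terms
do — which exercises the correction family under dependence. The planted
term is assigned the top of the term-size range so that the default signal
(``ceil(signal_fraction * list_size)`` genes) always fits inside it.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .model import DbName, GeneList, GeneSet, GeneSetDatabase, IdKind

_ORG = "hsa"
_DESCRIPTOR = "Synthetic organism (test)"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic benchmark instance.

    Defaults describe the standard study condition: 200 overlapping terms of
    10-50 genes over a 5000-gene pool, and a 100-gene input list of which
    40 % is drawn from the planted term.
    """

    n_terms: int = 200
    term_size_range: tuple[int, int] = (10, 50)
    universe_size: int = 5000
    planted_term_index: int = 0
    signal_fraction: float = 0.4
    list_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid term_size_range {self.term_size_range}")
        if hi > self.universe_size:
            raise ValueError("term size exceeds universe size")
        if self.list_size > self.universe_size:
            raise ValueError("list_size exceeds universe_size")
        if self.list_size < 1:
            raise ValueError("list_size must be >= 1")
        if not (0.0 <= self.signal_fraction <= 1.0):
            raise ValueError("signal_fraction must lie in [0, 1]")
        if self.n_terms < 0:
            raise ValueError("n_terms must be >= 0")
        if self.n_terms and not (0 <= self.planted_term_index < self.n_terms):
            raise ValueError("planted_term_index out of range")

    @property
    def gene_pool(self) -> list[str]:
        return [f"G{i:06d}" for i in range(1, self.universe_size + 1)]


def _term_sizes(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.term_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_terms)
    if spec.n_terms:
        sizes[spec.planted_term_index] = hi  # signal must fit inside the planted term
    return sizes


def make_database(spec: FixtureSpec, db_name: DbName = DbName.GO_BP) -> GeneSetDatabase:
    """Generate the logical fixture database (symbol identifiers).

    Term ids follow the GO accession pattern (``GO:0000001`` …); term names
    are ``Synthetic term NNN``. Memberships are sampled without replacement
    from the gene pool, independently per term.
    """
    rng = np.random.default_rng([spec.seed, 0])
    pool = np.array(spec.gene_pool)
    sizes = _term_sizes(spec, rng)
    sets = []
    for i in range(spec.n_terms):
        members = frozenset(rng.choice(pool, size=int(sizes[i]), replace=False))
        sets.append(GeneSet(term_id=f"GO:{i + 1:07d}",
                            term_name=f"Synthetic term {i + 1:03d}",
                            members=members))
    return GeneSetDatabase(db_name=db_name, organism=_ORG, sets=tuple(sets),
                           id_kind=IdKind.SYM, retrieved_at=f"fixture-seed-{spec.seed}")


def make_gene_list(spec: FixtureSpec, db: GeneSetDatabase) -> GeneList:
    """Generate the input gene list with the planted signal.

    ``ceil(signal_fraction * list_size)`` genes are sampled without
    replacement from the planted term; the remainder is drawn uniformly from
    the rest of the gene pool (excluding already-selected genes, so planted
    genes can still enter by chance through the noise draw only when not
    already chosen). Raises when the planted term cannot supply the signal.
    """
    rng = np.random.default_rng([spec.seed, 1])
    if not db.sets:
        raise ValueError("cannot build a gene list from an empty database")
    planted = db.sets[spec.planted_term_index]
    n_signal = math.ceil(spec.signal_fraction * spec.list_size)
    if n_signal > planted.k:
        raise ValueError(
            f"planted term holds {planted.k} genes but {n_signal} signal genes "
            "are required; enlarge the term or lower signal_fraction")
    signal = list(rng.choice(sorted(planted.members), size=n_signal, replace=False))
    remaining = [g for g in spec.gene_pool if g not in set(signal)]
    noise = list(rng.choice(remaining, size=spec.list_size - n_signal, replace=False))
    ids = signal + noise
    rng.shuffle(ids)
    return GeneList(ids=tuple(ids), id_kind=IdKind.SYM)


# ---------------------------------------------------------------------------
# Dialect serialization
# ---------------------------------------------------------------------------


def _kegg_id(index: int) -> str:
    return f"{_ORG}{index + 1:05d}"


def write_dialect_files(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Serialize the fixture database in GMT, GAF+OBO and KEGG dialects.

    The same logical sets are written to each dialect; GO-style accessions
    are used in GMT/GAF/OBO and KEGG pathway ids (``hsa00001`` …) in the
    KEGG files, with identical term names throughout. A JSON manifest
    records the generating spec (including the seed). Returns the map of
    dialect name -> written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    db = make_database(spec)

    gmt_lines = []
    for s in db.sets:
        gmt_lines.append("\t".join([s.term_name, s.term_id, *sorted(s.members)]))
    gmt = out_dir / "fixture.gmt"
    gmt.write_text("".join(line + "\n" for line in gmt_lines), encoding="utf-8")

    obo_parts = [
        "format-version: 1.2",
        "ontology: go-fixture",
        f"remark: synthetic fixture, seed={spec.seed}",
        "",
    ]
    for s in db.sets:
        obo_parts += [
            "[Term]",
            f"id: {s.term_id}",
            f"name: {s.term_name}",
            "namespace: biological_process",
            "",
        ]
    obo = out_dir / "fixture.obo"
    obo.write_text("\n".join(obo_parts), encoding="utf-8")

    gaf_lines = ["!gaf-version: 2.1", f"!generated-by: geneora fixture, seed={spec.seed}"]
    for i, s in enumerate(db.sets):
        for gene in sorted(s.members):
            gaf_lines.append("\t".join([
                "FIX", gene.lstrip("G").lstrip("0") or "0", gene, "", s.term_id,
                "FIX:0001", "IEA", "", "P", s.term_name, "", "protein",
                f"taxon:9606", "20160101", "FIX",
            ]))
    gaf = out_dir / "fixture.gaf"
    gaf.write_text("".join(line + "\n" for line in gaf_lines), encoding="utf-8")

    kegg_list_lines = [
        f"path:{_kegg_id(i)}\t{s.term_name} - {_DESCRIPTOR}"
        for i, s in enumerate(db.sets)
    ]
    kegg_list = out_dir / "fixture_kegg_list.tsv"
    kegg_list.write_text("".join(line + "\n" for line in kegg_list_lines),
                         encoding="utf-8")

    kegg_link_lines = []
    for i, s in enumerate(db.sets):
        for gene in sorted(s.members):
            kegg_link_lines.append(f"{_ORG}:{gene}\tpath:{_kegg_id(i)}")
    kegg_link = out_dir / "fixture_kegg_link.tsv"
    kegg_link.write_text("".join(line + "\n" for line in kegg_link_lines),
                         encoding="utf-8")

    manifest = out_dir / "fixture_manifest.json"
    manifest.write_text(json.dumps(asdict(spec), indent=2) + "\n", encoding="utf-8")

    return {"gmt": gmt, "obo": obo, "gaf": gaf, "kegg_list": kegg_list,
            "kegg_link": kegg_link, "manifest": manifest}


def write_gene_list(spec: FixtureSpec, db: GeneSetDatabase,
                    path: str | Path) -> Path:
    """Write the planted gene list one identifier per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gene_list = make_gene_list(spec, db)
    path.write_text("".join(g + "\n" for g in gene_list.ids), encoding="utf-8")
    return path
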