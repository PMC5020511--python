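# Methods

## Model

Over-representation analysis treats the input gene list as a draw of `d`
genes and asks, for each term of size `k` in a background of `N` genes,
whether the observed overlap `x` is larger than chance. Under the null of
no association the overlap is hypergeometric, and the reported p-value is
the right (enrichment) tail

    P(X >= x) = sum_{j=x}^{min(d,k)} C(k,j) C(N-k, d-j) / C(N, d).

The test is one-tailed by construction: the tool ranks *enriched* functions
and never tests depletion. The per-term diagnostic table mirrors the
classic presentation — cells `x`, `d−x`, `k`, and `N−(k+d)` — and the
fourth reported cell can go negative when `N < k + d`; the test itself
always uses the standard non-negative cell `N−k−d+x` and a warning is
logged when the two diverge.

Conventions that shape the numbers:

* **`d` counts every unique input gene**, including genes absent from the
  database universe. The list is the analyst's claim about the experiment;
  filtering it to annotated genes would silently change the question.
* **`N` defaults to the annotated universe** (the union of all member sets
  of the chosen database), the only background that is self-consistent
  with the database in hand. `--background` overrides it, e.g. with a
  genome-wide gene count.
* **Terms with `x = 0` are omitted** from the output and from the
  correction family; the family size `m` is the number of terms with at
  least one hit. Zero-hit rows carry no evidence and would only dilute the
  step-up corrections.
* **Ranking is by raw p-value ascending**, ties broken by overlap
  descending and then term id, so output order is total and deterministic.
  `--sort=hits` gives the overlap-count ranking as a documented
  alternative.

## Multiple-testing corrections

Five adjusted p-values are computed per run: Benjamini–Hochberg and
Benjamini–Yekutieli (FDR; BY multiplies BH by the harmonic sum
`Σ 1/i`, valid under arbitrary dependence), and Bonferroni, Hochberg and
Hommel (FWER). The step-up methods are suffix running minima over the
sorted p-values; Hommel follows the standard closed-testing algorithm,
vectorised so a 500-term family adjusts in milliseconds. All outputs are
clipped to `[p, 1]`, and the implementation is cross-validated elementwise
against an independent reference implementation in the test suite, along
with the dominance chain raw ≤ Hommel ≤ Hochberg ≤ Bonferroni and
BH ≤ BY.

## Numerics

The tail sum is evaluated in log-space (`gammaln` for log-binomials,
`logsumexp` for the sum) and clipped to 1, which keeps every table the tool
can meet well inside 1e-12 of the exact rational value (the test suite
checks all ~86,000 tables with `N ≤ 30` against `Fraction` arithmetic, and
spot-checks large-`N` tables against an independent survival-function
route). `x` at or below the lower support bound returns exactly 1.0. In
the bubble plot, a zero p-value is clamped to a tenth of the smallest
positive p-value in the table so the log axis stays finite.

## Databases and parsing

All dialects converge on one in-memory model (term id, name, member set;
database = named collection plus derived universe):

* **GMT**: field 1 name, field 2 id (Reactome convention), remaining
  fields genes; in-line duplicates collapse; repeated ids merge with a
  warning.
* **OBO**: parsed with `obonet`; obsolete terms excluded, `alt_id`
  accessions aliased to the canonical entry, terms without a name or GO
  namespace skipped.
* **GAF 2.x**: rows whose qualifier contains `NOT` are excluded; rows are
  restricted to the requested aspect; all evidence codes (including IEA)
  are accepted, since no evidence filter is part of the method; symbols
  come from column 3, Entrez ids from column 2.
* **KEGG REST flat files**: the pathway list supplies id → name (organism
  descriptor suffix stripped); the link table supplies gene ↔ pathway
  pairs in either column order. KEGG gene tokens are Entrez ids; symbol
  mode requires the optional organism gene-list endpoint to build an
  id → symbol map, otherwise the tool instructs use of `--gtype=gid`.
* **Cancer-gene catalogue**: a bundled two-column TSV
  (`gene_symbol<TAB>cancer_type`), one set per cancer type, human only.
  The shipped file is a *synthetic stand-in* generated deterministically;
  replace it with a real catalogue export for production use.

GO annotations are used directly as they appear in the GAF, without
propagation to ancestor terms through the ontology graph; term sets are
exactly the annotation sets, and no DAG reasoning is performed.

Symbols are upper-cased on input (HGNC convention), Entrez ids must be all
digits; this normalisation is applied identically to gene lists and
databases so matches never fail on case.

The cache dialect is GMT plus a `key=value` sidecar (`db_name`, `organism`,
`id_kind`, `retrieved_at`); writes are sorted and byte-deterministic, and
update mode writes to a temporary name and renames, so an interrupted fetch
never leaves a half-written cache. Endpoints are locator templates
(URL-or-path with an `ORGANISM_CODE` placeholder), so the entire update
path is exercised offline against fixture files; KEGG links are fetched as
one organism-wide table rather than per-pathway requests, which is kinder
to the service and reproducible. HTTP fetches retry 3 times with doubling
backoff from 1 s. Organism codes are validated by the service itself: an
unknown code yields an empty pathway list and a clear abort, rather than
maintaining a version-frozen code list in the package.

## Synthetic benchmark

`FixtureSpec` defines the study conditions; the defaults are 200 terms of
10–50 genes sampled independently (so terms overlap, as real GO/KEGG terms
do — this exercises the corrections under dependence) from a 5000-gene
pool, and a 100-gene input list with `signal_fraction = 0.4`: 40 genes
drawn from the planted term, the rest uniformly from the remaining pool.
Two choices are deliberate:

* the planted term is assigned the top of the size range (50 genes), so
  the default signal always fits inside it — `make_gene_list` refuses a
  planted term smaller than the required signal rather than silently
  shrinking the signal;
* noise genes are drawn from the pool *excluding already-selected genes*
  but not excluding the planted term, so under `signal_fraction = 0` the
  planted term's overlap has its natural chance expectation `d·k/U`.

Generation is a pure function of the `FixtureSpec` (NumPy PCG64; separate streams
for database and list, derived from the recorded seed), and the same
logical database is serialized to GMT, GAF+OBO and KEGG dialects with
identical term names, which is what the cross-dialect fidelity tests
compare.

What the benchmark does not emulate: real term-size distributions and DAG
structure, annotation bias toward well-studied genes, identifier aliasing
and withdrawal, or inter-database disagreement. Passing the planted-signal
tests therefore shows the pipeline is statistically and mechanically
correct, not that any particular biological database is well curated.

## Problem sizes

The shipped test suite and the acceptance script run the default
conditions end to end: exhaustive tail validation at `N ≤ 30`, 1000 random
p-vectors of length up to 500 for the corrections, 100 seeded replicates
each for signal recovery and null calibration, and 500 random lists for
the family-wise null check — a few minutes in total on one CPU.

## Limitations

* Over-representation only: no rank-based (GSEA-style) statistics, no
  permutation nulls, no gene-length or coverage bias correction.
* KEGG symbol mode depends on the optional gene-list endpoint.
* The bundled cancer catalogue is a synthetic placeholder.
* Update mode trusts the source formats; a service that changes its flat
  dialect will surface as parse warnings/errors, not silent misreads.
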