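"""Statistical core: overlap clustering, Fisher's exact test, p-value corrections.

Each gene set (term) is scored against the input gene list with the 2x2
contingency table

    ===============================  ==========================
    in list & in term                x
    in list, not in term             d - x
    all genes in term                k
    rest of the background           N - (k + d)   (as reported)
    ===============================  ==========================

where ``d`` is the number of unique input genes, ``k`` the term size and
``N`` the background (gene universe) size. The reported fourth cell follows
the tool's diagnostic convention ``N - (k + d)``; the test itself uses the
standard hypergeometric parameterisation, under which the number of list
genes falling in the term is distributed as ``Hypergeom(N, k, d)``. The
enrichment p-value is the right tail

    P(X >= x) = sum_{j=x}^{min(d,k)} C(k,j) C(N-k, d-j) / C(N,d),

computed in log-space to avoid overflow. Five multiple-testing corrections
(Benjamini-Hochberg, Bonferroni, Hochberg, Hommel, Benjamini-Yekutieli) are
applied across the family of terms with at least one hit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .model import GeneList, GeneSet, GeneSetDatabase

logger = logging.getLogger(__name__)

CORRECTION_METHODS = ("BH", "Bonferroni", "Hochberg", "Hommel", "BY")


@dataclass(frozen=True)
class ContingencyInputs:
    """Validated inputs of the per-term 2x2 table.

    Attributes
    ----------
    x : overlap between gene list and term
    d : unique input genes (including genes outside the universe)
    k : term size
    N : background size
    """

    x: int
    d: int
    k: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.d, self.k)):
            raise ValueError(f"x={self.x} outside [0, min(d={self.d}, k={self.k})]")
        if self.d < 1 or self.k < 1 or self.N < 1:
            raise ValueError("d, k and N must be positive")
        if self.d > self.N or self.k > self.N:
            raise ValueError(f"d={self.d} and k={self.k} must not exceed N={self.N}")

    # Reported cells of the table (diagnostic convention).
    @property
    def n11(self) -> int:
        return self.x

    @property
    def n21(self) -> int:
        return self.d - self.x

    @property
    def n12(self) -> int:
        return self.k

    @property
    def n22_reported(self) -> int:
        """Fourth cell as reported in diagnostics: N - (k + d); may be negative."""
        return self.N - (self.k + self.d)

    @property
    def n22(self) -> int:
        """Standard non-negative fourth Fisher cell, N - k - d + x."""
        return self.N - self.k - self.d + self.x


def _log_comb(n: int, r) -> np.ndarray | float:
    r = np.asarray(r, dtype=float)
    return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)


def hypergeom_pmf(j: int, inputs: ContingencyInputs) -> float:
    """Point probability C(k,j) C(N-k, d-j) / C(N,d); 0 outside the support."""
    N, k, d = inputs.N, inputs.k, inputs.d
    if j < max(0, k + d - N) or j > min(d, k):
        return 0.0
    log_p = _log_comb(k, j) + _log_comb(N - k, d - j) - _log_comb(N, d)
    return float(math.exp(log_p))


def fisher_right_tail(inputs: ContingencyInputs) -> float:
    """Enrichment (right-tail) Fisher p-value: P(overlap >= x).

    Summed in log-space over the upper tail of the hypergeometric support.
    Returns exactly 1.0 when x is at or below the lower support bound.
    """
    N, k, d, x = inputs.N, inputs.k, inputs.d, inputs.x
    lo, hi = max(0, k + d - N), min(d, k)
    if x <= lo:
        return 1.0
    js = np.arange(x, hi + 1)
    log_terms = _log_comb(k, js) + _log_comb(N - k, d - js) - _log_comb(N, d)
    return float(min(1.0, math.exp(logsumexp(log_terms))))


# ---------------------------------------------------------------------------
# Multiple-testing corrections
# ---------------------------------------------------------------------------


def _step_up(p_sorted: np.ndarray, factors: np.ndarray) -> np.ndarray:
    """min over j >= i of factors[j]*p_(j), clipped to 1 (suffix running min)."""
    return np.minimum(1.0, np.minimum.accumulate((factors * p_sorted)[::-1])[::-1])


def _hommel_sorted(p: np.ndarray) -> np.ndarray:
    """Hommel closed-testing adjusted p-values for ascending-sorted ``p``.

    Port of the standard algorithm (as used by R's ``p.adjust``): iterate the
    intersection-hypothesis sizes m = n-1 .. 2, maintaining the running
    maximum of the per-size Simes bounds.
    """
    n = len(p)
    i = np.arange(1, n + 1)
    pa = np.full(n, np.min(n * p / i))
    q = pa.copy()
    for m in range(n - 1, 1, -1):
        # indices split: i1 = 0 .. n-m, i2 = n-m+1 .. n-1
        i2 = np.arange(n - m + 1, n)
        q1 = np.min(m * p[i2] / np.arange(2, m + 1)) if len(i2) else np.inf
        q[: n - m + 1] = np.minimum(m * p[: n - m + 1], q1)
        q[n - m + 1:] = q[n - m]
        pa = np.maximum(pa, q)
    return np.maximum(pa, p)


def adjust_pvalues(pvals: Sequence[float], method: str) -> np.ndarray:
    """Adjusted p-values for one correction method, in the input order.

    ``method`` is one of ``BH`` (Benjamini-Hochberg step-up FDR),
    ``Bonferroni`` (single-step FWER), ``Hochberg`` (step-up FWER),
    ``Hommel`` (closed-testing FWER) or ``BY`` (Benjamini-Yekutieli FDR
    under arbitrary dependence). All outputs lie in [p, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "Bonferroni":
        return np.minimum(1.0, m * p)
    order = np.argsort(p, kind="stable")
    inverse = np.empty(m, dtype=int)
    inverse[order] = np.arange(m)
    ps = p[order]
    ranks = np.arange(1, m + 1, dtype=float)
    if method == "BH":
        adj = _step_up(ps, m / ranks)
    elif method == "BY":
        c_m = np.sum(1.0 / ranks)
        adj = _step_up(ps, c_m * m / ranks)
    elif method == "Hochberg":
        adj = _step_up(ps, m - ranks + 1.0)
    elif method == "Hommel":
        adj = _hommel_sorted(ps)
    else:
        raise ValueError(f"unknown correction method {method!r}; "
                         f"expected one of {CORRECTION_METHODS}")
    return adj[inverse]


def adjust_all(pvals: Sequence[float]) -> dict[str, np.ndarray]:
    """All five corrections at once: method name -> adjusted vector."""
    return {method: adjust_pvalues(pvals, method) for method in CORRECTION_METHODS}


# ---------------------------------------------------------------------------
# Per-term scoring and the full enrichment run
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    """One scored term: overlap, coverage, raw and adjusted p-values, rank."""

    term_id: str
    term_name: str
    hit_genes: frozenset[str]
    x: int
    k: int
    percentage: float
    p_value: float
    adjusted: Mapping[str, float]
    rank: int


def overlap(gene_list: GeneList, gene_set: GeneSet) -> tuple[int, frozenset[str]]:
    """Overlap between the input list and one term: (x, hit genes)."""
    hits = frozenset(gene_list.ids) & gene_set.members
    return len(hits), hits


def run_enrichment(
    gene_list: GeneList,
    db: GeneSetDatabase,
    background: int | None = None,
    *,
    sort_by: Literal["pvalue", "hits"] = "pvalue",
) -> list[EnrichmentResult]:
    """Score every term of ``db`` against ``gene_list`` and rank the hits.

    Terms with no overlapping gene are omitted from the output and from the
    correction family, so the family size ``m`` is the number of terms with
    at least one hit. ``background`` overrides the default universe-size
    ``N``; it must be at least ``max(d, max k)``. Results are sorted by raw
    p-value ascending (ties: overlap descending, then term id), or by
    overlap first with ``sort_by="hits"``; 1-based ranks are assigned after
    sorting.
    """
    if gene_list.id_kind is not db.id_kind:
        raise ValueError(
            f"gene list uses {gene_list.id_kind.value} identifiers but database "
            f"{db.db_name.value} uses {db.id_kind.value}; pass the matching --gtype"
        )
    d = gene_list.d
    if not db.sets:
        logger.warning("database %s holds no gene sets; nothing to test",
                       db.db_name.value)
        return []
    N = len(db.universe) if background is None else int(background)
    max_k = max(s.k for s in db.sets)
    if N < max(d, max_k):
        raise ValueError(
            f"background N={N} is smaller than max(d={d}, largest term k={max_k}); "
            "supply a larger --background"
        )

    scored: list[tuple[GeneSet, int, frozenset[str], ContingencyInputs]] = []
    for s in db.sets:
        x, hits = overlap(gene_list, s)
        if x == 0:
            continue
        inputs = ContingencyInputs(x=x, d=d, k=s.k, N=N)
        if inputs.n22_reported < 0:
            logger.warning(
                "term %s: reported cell N-(k+d) = %d is negative; the test uses the "
                "standard cell N-k-d+x = %d", s.term_id, inputs.n22_reported, inputs.n22,
            )
        scored.append((s, x, hits, inputs))

    if not scored:
        logger.warning(
            "no gene from the input list (d=%d) matched any of the %d sets in %s; "
            "check --gtype and the identifier dialect", d, len(db.sets), db.db_name.value,
        )
        return []

    raw = [fisher_right_tail(inputs) for (_, _, _, inputs) in scored]
    adjusted = adjust_all(raw)

    rows = list(range(len(scored)))
    if sort_by == "hits":
        rows.sort(key=lambda i: (-scored[i][1], raw[i], scored[i][0].term_id))
    else:
        rows.sort(key=lambda i: (raw[i], -scored[i][1], scored[i][0].term_id))

    results = []
    for rank, i in enumerate(rows, start=1):
        s, x, hits, _ = scored[i]
        results.append(
            EnrichmentResult(
                term_id=s.term_id,
                term_name=s.term_name,
                hit_genes=hits,
                x=x,
                k=s.k,
                percentage=100.0 * x / s.k,
                p_value=raw[i],
                adjusted={m: float(adjusted[m][i]) for m in CORRECTION_METHODS},
                rank=rank,
            )
        )
    return results
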