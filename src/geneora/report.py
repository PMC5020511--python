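"""Result serialization: the ranked TSV table and the top-20 bubble plot."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering; the tool never opens a window
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .enrich import CORRECTION_METHODS, EnrichmentResult

logger = logging.getLogger(__name__)

#: Fixed column order of the output TSV.
TSV_COLUMNS = (
    "term_id",
    "term_name",
    "genes",
    "num_of_hits",
    "term_size",
    "percentage",
    "p_value",
    "fdr_BH",
    "fdr_Bonferroni",
    "fdr_Hochberg",
    "fdr_Hommel",
    "fdr_BY",
)

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class ResultTable:
    """Ranked enrichment results plus run metadata, ready for serialization."""

    results: Sequence[EnrichmentResult]
    database: str = ""
    organism: str = ""
    N: int = 0
    d: int = 0
    mode: str = "normal"
    timestamp: str = "unset"
    extra_metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ranks = [r.rank for r in self.results]
        if ranks != sorted(ranks):
            raise ValueError("results must be supplied in rank order")


def _fmt_p(p: float) -> str:
    """Scientific notation with 6 significant digits."""
    return f"{p:.5e}"


def write_tsv(table: ResultTable, path: str | Path) -> Path:
    """Write the ranked table as UTF-8 TSV with ``#`` metadata comment lines.

    Percentages print with 2 decimals, p-values in scientific notation with
    6 significant digits; hit genes are comma-joined and sorted. Output is
    byte-deterministic given the same table (including its timestamp).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"# database={table.database}",
        f"# organism={table.organism}",
        f"# N={table.N}",
        f"# d={table.d}",
        f"# mode={table.mode}",
        f"# timestamp={table.timestamp}",
    ]
    lines += [f"# {k}={v}" for k, v in sorted(table.extra_metadata.items())]
    lines.append("\t".join(TSV_COLUMNS))
    for r in table.results:
        row = [
            r.term_id,
            r.term_name,
            ",".join(sorted(r.hit_genes)),
            str(r.x),
            str(r.k),
            f"{r.percentage:.2f}",
            _fmt_p(r.p_value),
            *(_fmt_p(r.adjusted[m]) for m in CORRECTION_METHODS),
        ]
        lines.append("\t".join(row))
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read back a written TSV (metadata comments skipped) as a DataFrame."""
    return pd.read_csv(path, sep="\t", comment="#", header=0)


def build_bubble_figure(table: ResultTable, top: int = 20):
    """Build the enrichment bubble figure; returns (figure, axes).

    X is the term rank, Y the -log10 p-value, bubble area is proportional
    to the percentage of the term's genes covered by the input list, and a
    horizontal reference line marks p = 0.05. At most ``top`` terms are
    drawn. Zero p-values are clamped to a tenth of the smallest positive
    p-value so the log axis stays finite.
    """
    rows = list(table.results)[:top]
    if not rows:
        raise ValueError("cannot plot an empty result table")
    pvals = np.array([r.p_value for r in rows], dtype=float)
    positive = pvals[pvals > 0]
    floor = (positive.min() / 10.0) if positive.size else 1e-300
    y = -np.log10(np.maximum(pvals, floor))
    x = np.array([r.rank for r in rows], dtype=float)
    sizes = 20.0 * np.array([r.percentage for r in rows])  # area ~ percent covered

    fig, ax = plt.subplots(figsize=(9, 6))
    ax.scatter(x, y, s=sizes, alpha=0.6, edgecolors="black", linewidths=0.5, zorder=3)
    ax.axhline(-np.log10(SIGNIFICANCE_LEVEL), color="red", linestyle="--",
               linewidth=1.0, label=f"p = {SIGNIFICANCE_LEVEL}")
    for r, xi, yi in zip(rows, x, y):
        ax.annotate(r.term_name, (xi, yi), textcoords="offset points",
                    xytext=(4, 4), fontsize=7, rotation=30)
    ax.set_xlabel("Rank")
    ax.set_ylabel("-log10(P-value)")
    title = f"Top {len(rows)} enriched terms"
    if table.database:
        title += f" ({table.database})"
    ax.set_title(title)
    ax.set_xticks(x)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    return fig, ax


def bubble_plot(table: ResultTable, path: str | Path, *, top: int = 20,
                dpi: int = 300) -> Path | None:
    """Render the bubble plot to ``path`` (format from the suffix, PNG default).

    Returns the written path, or ``None`` (with a warning) when the table is
    empty.
    """
    if not table.results:
        logger.warning("no enriched terms to plot; skipping %s", path)
        return None
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, _ = build_bubble_figure(table, top=top)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    return path
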