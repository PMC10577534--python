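"""Hypergeometric over-representation of gene sets among top-ranked DE aptamers.

The query is the gene-level collapse of the top-k (default 500) aptamers of a
DE table, ranked by (fdr, p, -|log2FC|, aptamer_id); the background universe
is the set of genes targeted by the filtered assay panel, not the genome.
Compound symbols ("A|B") are split so each component counts as a gene. For
each set with at least ``min_set`` background genes, the upper-tail
hypergeometric probability P(X >= k) of the observed overlap is computed and
BH-adjusted across tested sets; sets below ``fdr_keep`` (default 0.1) are
flagged as reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .panel_io import AptamerPanel, GeneSetCollection

ENRICHMENT_COLUMNS = [
    "set_name", "N", "K", "n", "k", "fold_enrichment", "p_value", "fdr", "reported",
]


def _split_symbols(symbols) -> set[str]:
    out: set[str] = set()
    for sym in symbols:
        if sym:
            out.update(part for part in str(sym).split("|") if part)
    return out


def select_top_k(de_table: pd.DataFrame, k: int = 500) -> set[str]:
    """Gene symbols of the top-k ranked aptamers (compound symbols split).

    Ranking is ascending on (fdr, p, -|log2FC|, aptamer_id); the aptamer_id
    key makes the order total and reproducible.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    tbl = de_table.copy()
    tbl["_negabs"] = -tbl["log2FC"].abs()
    ranked = tbl.sort_values(
        ["fdr", "p", "_negabs", "aptamer_id"], kind="stable"
    ).head(k)
    return _split_symbols(ranked["gene_symbol"])


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed stably.

    N = background size, K = marked genes in background, n = query size,
    k = observed overlap.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if K > N or n > N or k > min(n, K):
        raise ValueError(f"invalid bounds: N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    # sum the log-pmf tail to avoid underflow for extreme overlaps
    support = np.arange(k, min(n, K) + 1)
    logpmf = stats.hypergeom.logpmf(support, N, K, n)
    m = logpmf.max()
    return float(min(1.0, np.exp(m) * np.exp(logpmf - m).sum()))


def run_enrichment(
    de_table: pd.DataFrame,
    gene_sets: GeneSetCollection,
    panel: AptamerPanel,
    k: int = 500,
    fdr_keep: float = 0.1,
    min_set: int = 5,
) -> pd.DataFrame:
    """Over-representation of each gene set among the top-k DE genes."""
    background = panel.gene_symbols(split_compound=True)
    if not background:
        raise ValueError("empty background universe")
    query = select_top_k(de_table, k=k) & background
    N, n = len(background), len(query)

    records = []
    for name, members in gene_sets.sets.items():
        in_bg = members & background
        K = len(in_bg)
        if K < min_set:
            continue
        overlap = len(in_bg & query)
        fold = (overlap / n) / (K / N) if n > 0 else 0.0
        records.append(
            {
                "set_name": name,
                "N": N,
                "K": K,
                "n": n,
                "k": overlap,
                "fold_enrichment": fold,
                "p_value": hypergeom_upper_tail(N, K, n, overlap),
            }
        )
    table = pd.DataFrame(records, columns=ENRICHMENT_COLUMNS[:-2])
    if len(table):
        table["fdr"] = bh_adjust(table["p_value"].to_numpy())
        table["reported"] = table["fdr"] < fdr_keep
        table = table.sort_values(["fdr", "p_value", "set_name"], kind="stable").reset_index(drop=True)
    else:
        table["fdr"] = []
        table["reported"] = []
    return table


def write_enrichment_table(path, table: pd.DataFrame) -> None:
    table[ENRICHMENT_COLUMNS].to_csv(path, sep="\t", index=False)
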