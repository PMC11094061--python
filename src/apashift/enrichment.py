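"""Gene-set overrepresentation (overlap) testing.

One-sided exact hypergeometric test of the overlap between a query gene
set (e.g. genes with 3'UTR shortening) and an annotation set (e.g.
TIS11B-bound mRNAs) against a background universe.  The recommended
background is the set of genes assessable for APA (a clean PDUI fit),
not the whole genome.  Fold enrichment follows the usual
overrepresentation convention:

    fold = (overlap / query) / (set / background)

and the standard filter is p < 0.05 with fold > 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coverage import ValidationError


@dataclass(frozen=True)
class EnrichmentResult:
    query_n: int
    set_n: int
    overlap_n: int
    background_n: int
    fold_enrichment: float
    p_value: float
    odds_ratio: float
    passes_filter: bool


def read_gene_list(path: str | Path) -> set[str]:
    """One gene id per line; ``#`` comments and blank lines ignored."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def overlap_enrichment(
    query_genes: set[str],
    set_genes: set[str],
    background_genes: set[str],
    alpha: float = 0.05,
    fold_threshold: float = 2.0,
) -> EnrichmentResult:
    """Hypergeometric upper-tail overlap test of query vs annotation set.

    The query must be a subset of the background; the annotation set is
    intersected with the background before testing.  The p-value is the
    probability of an overlap at least as large as observed
    (upper tail including the observed count), identical to a one-sided
    Fisher exact test on the 2x2 membership table.
    """
    query = set(query_genes)
    bg = set(background_genes)
    outside = query - bg
    if outside:
        shown = ", ".join(sorted(outside)[:10])
        raise ValidationError(
            f"query contains {len(outside)} gene(s) outside the background: "
            f"{shown}")
    gset = set(set_genes) & bg
    k = len(query & gset)
    M, n, N = len(bg), len(gset), len(query)

    p = float(stats.hypergeom.sf(k - 1, M, n, N)) if min(n, N) > 0 else 1.0
    fold = (k / N) / (n / M) if N > 0 and n > 0 else 0.0

    a, b = k, N - k
    c, d = n - k, M - n - N + k
    odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    return EnrichmentResult(
        query_n=N, set_n=n, overlap_n=k, background_n=M,
        fold_enrichment=fold, p_value=min(p, 1.0), odds_ratio=float(odds),
        passes_filter=bool(p < alpha and fold > fold_threshold))


def batch_enrichment(
    query_sets: dict[str, set[str]],
    annotation_sets: dict[str, set[str]],
    background_genes: set[str],
    alpha: float = 0.05,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """All (query, set) pairs with BH adjustment within each query."""
    rows = []
    for qname, query in query_sets.items():
        batch = []
        for sname, gset in annotation_sets.items():
            res = overlap_enrichment(query, gset, background_genes,
                                     alpha=alpha, fold_threshold=fold_threshold)
            batch.append((sname, res))
        pvals = [res.p_value for _, res in batch]
        padj = multipletests(pvals, method="fdr_bh")[1] if batch else []
        for (sname, res), pa in zip(batch, padj):
            rows.append({
                "query": qname, "set": sname,
                "query_n": res.query_n, "set_n": res.set_n,
                "overlap_n": res.overlap_n, "background_n": res.background_n,
                "fold_enrichment": res.fold_enrichment,
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value, "p_adj": float(pa),
                "passes_filter": res.passes_filter,
            })
    return pd.DataFrame(rows, columns=["query", "set", "query_n", "set_n",
                                       "overlap_n", "background_n",
                                       "fold_enrichment", "odds_ratio",
                                       "p_value", "p_adj", "passes_filter"])
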