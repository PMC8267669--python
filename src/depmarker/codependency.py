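"""Co-dependency: Pearson correlation of knockout-effect profiles.

Genes acting in one complex or pathway tend to have correlated
dependency-score profiles across cell lines (if losing either kills the
same lines, the profiles move together). The top correlated partners of
a query gene are therefore candidates for shared complex membership.

Missing scores are handled by pairwise-complete deletion; the effective
sample size is always reported. A correlation over fewer than 3 pairs,
or against a zero-variance profile, is undefined and flagged rather than
silently set to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneEffectMatrix, gene_lookup_message

MIN_PAIRS = 3


@dataclass
class CoDependencyResult:
    query_gene: str
    partner_gene: str
    pearson_r: float  # NaN when undefined
    n_pairs: int
    defined: bool
    rank: int | None = None


def _pairwise_pearson(x: pd.Series, y: pd.Series) -> tuple[float, int, bool]:
    both = x.notna() & y.notna()
    n = int(both.sum())
    if n < MIN_PAIRS:
        return float("nan"), n, False
    xv = x[both].to_numpy(dtype=float)
    yv = y[both].to_numpy(dtype=float)
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        return float("nan"), n, False
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r, n, True


def profile_correlation(
    matrix: GeneEffectMatrix, gene_a: str, gene_b: str
) -> CoDependencyResult:
    """Pearson r between two genes' dependency profiles (pairwise complete)."""
    for gene in (gene_a, gene_b):
        if gene not in matrix.scores.columns:
            raise KeyError(gene_lookup_message(gene, matrix.gene_symbols))
    r, n, defined = _pairwise_pearson(matrix.scores[gene_a], matrix.scores[gene_b])
    return CoDependencyResult(gene_a, gene_b, r, n, defined)


def top_codependencies(matrix: GeneEffectMatrix, query_gene: str, k: int) -> pd.DataFrame:
    """The k partners most correlated with the query profile.

    Sorted by descending r (the query itself excluded), ties broken by
    symbol; undefined correlations are dropped from the ranking.
    """
    if query_gene not in matrix.scores.columns:
        raise KeyError(gene_lookup_message(query_gene, matrix.gene_symbols))
    columns = ["rank", "query_gene", "partner_gene", "pearson_r", "n_pairs"]
    if k <= 0:
        return pd.DataFrame(columns=columns)

    scores = matrix.scores
    query = scores[query_gene]
    others = scores.drop(columns=[query_gene])
    # pandas corrwith is pairwise-complete; enforce the min-pairs and
    # zero-variance rules on the pairwise-complete subsets ourselves
    r = others.corrwith(query)
    present = others.notna().mul(query.notna(), axis=0)
    n_pairs = present.sum()
    r[n_pairs < MIN_PAIRS] = np.nan

    frame = pd.DataFrame(
        {"partner_gene": r.index, "pearson_r": r.to_numpy(), "n_pairs": n_pairs.to_numpy()}
    ).dropna(subset=["pearson_r"])
    frame = frame.sort_values(
        ["pearson_r", "partner_gene"], ascending=[False, True], kind="mergesort"
    ).head(k)
    frame.insert(0, "rank", range(1, len(frame) + 1))
    frame.insert(1, "query_gene", query_gene)
    return frame.reset_index(drop=True)[columns]
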