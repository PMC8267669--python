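"""Mutation markers of knockout sensitivity in a CRISPR dependency screen.

The screen asks, for every gene with at least one documented non-silent
mutation in the analysis universe: are cell lines carrying a mutation in
that gene enriched among the lines sensitive to knockout of a chosen
target? Sensitivity is a strict threshold on the gene-effect score
(score < -0.5 by convention: depletion of most cells). The default test
is the one-sided Fisher exact test on the 2x2 table

                sensitive   not sensitive
    mutated         a            b
    wild-type       c            d

with the alternative that sensitivity is enriched among mutated lines.
A two-sided Fisher variant and a Wilcoxon rank-sum test on the raw
scores are selectable for sensitivity analysis.

Markers mutated in fewer lines than ``min_mutated`` (default 10) are
flagged, never dropped: all obtained values are kept so that possibly
promising genes with few observed mutations remain visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import (
    AnalysisUniverse,
    GeneEffectMatrix,
    MutationTable,
    SampleInfo,
    ValidationError,
    gene_lookup_message,
)

logger = logging.getLogger(__name__)

TEST_VARIANTS = ("fisher_one_sided_enrichment", "fisher_two_sided", "rank_sum_on_scores")


@dataclass(frozen=True)
class ScreenConfig:
    """All thresholds of the screening procedure.

    sensitivity_threshold : gene-effect score below which (strictly) a
        line is called sensitive; -0.5 marks depletion of most cells.
    alpha : significance level for flagging (raw p, no correction by
        default; BH q-values are always emitted alongside).
    min_mutated : minimum mutated-line count for a marker to be treated
        as statistically relevant.
    """

    sensitivity_threshold: float = -0.5
    alpha: float = 0.05
    min_mutated: int = 10
    test_variant: str = "fisher_one_sided_enrichment"
    target_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sensitivity_threshold < 0:
            raise ValueError("sensitivity_threshold must be negative")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_mutated < 1:
            raise ValueError("min_mutated must be >= 1")
        if self.test_variant not in TEST_VARIANTS:
            raise ValueError(f"test_variant must be one of {TEST_VARIANTS}")


@dataclass
class SensitivityCalls:
    """Per-line sensitivity calls for one knockout target.

    ``scores`` covers the analysis universe; lines with a missing score
    are excluded from every count (never treated as insensitive).
    """

    target_gene: str
    scores: pd.Series  # index = universe lines, NaN = missing
    threshold: float

    @property
    def sensitive(self) -> frozenset[str]:
        s = self.scores
        return frozenset(s.index[s < self.threshold])

    @property
    def insensitive(self) -> frozenset[str]:
        s = self.scores
        return frozenset(s.index[s.notna() & ~(s < self.threshold)])

    @property
    def missing(self) -> frozenset[str]:
        s = self.scores
        return frozenset(s.index[s.isna()])

    @property
    def n_evaluable(self) -> int:
        return int(self.scores.notna().sum())

    @property
    def n_sensitive(self) -> int:
        return int((self.scores < self.threshold).sum())


@dataclass
class AssociationResult:
    """One marker gene tested against one knockout target."""

    marker_gene: str
    target_gene: str
    a: int  # mutated & sensitive
    b: int  # mutated & not sensitive
    c: int  # wild-type & sensitive
    d: int  # wild-type & not sensitive
    p_value: float
    odds_direction: str  # '>', '<' or '=' relative to odds ratio 1
    below_min_mutated: bool
    significant_at_alpha: bool
    degenerate: bool

    @property
    def n_mutated(self) -> int:
        return self.a + self.b

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class ScreenReport:
    """Ordered association results for one target plus run context.

    ``results`` is sorted by ascending p-value with a deterministic
    tie-break (descending mutated count, then symbol) and always carries
    a Benjamini-Hochberg q-value column.
    """

    target_gene: str
    config: ScreenConfig
    results: pd.DataFrame
    n_sensitive: int
    n_evaluable: int
    universe_size: int
    provenance: dict = field(default_factory=dict)

    def top(self, k: int) -> pd.DataFrame:
        return self.results.head(max(k, 0))


def filter_nonsilent(mutations: MutationTable) -> MutationTable:
    """Drop records whose variant classification is exactly ``Silent``.

    Matching is case-sensitive on the DepMap token; a case-insensitive
    near-miss (e.g. ``silent``) is retained but logged as a warning so a
    mislabeled file cannot silently pass the filter.
    """
    cls = mutations.records["variant_classification"].astype(str)
    is_silent = cls == "Silent"
    near_miss = (cls.str.lower() == "silent") & ~is_silent
    if near_miss.any():
        tokens = sorted(cls[near_miss].unique())
        logger.warning(
            "retained %d records with near-miss silent classification %s "
            "(exact token 'Silent' required to filter)",
            int(near_miss.sum()), tokens,
        )
    kept = mutations.records.loc[~is_silent].reset_index(drop=True)
    return MutationTable(kept, nonsilent_filtered=True)


def mutation_calls(
    mutations: MutationTable, universe: AnalysisUniverse | Iterable[str]
) -> dict[str, frozenset[str]]:
    """Collapse records to per-gene sets of mutated universe lines.

    A line is mutated in a gene iff at least one retained record exists
    for the pair; duplicates collapse. Records for lines outside the
    universe are ignored (tallied to the log); genes left with zero
    mutated universe lines are dropped.
    """
    if not mutations.nonsilent_filtered:
        raise ValidationError(
            "mutation_calls requires a table that passed filter_nonsilent"
        )
    ids = universe.id_set if isinstance(universe, AnalysisUniverse) else frozenset(universe)
    records = mutations.records
    in_universe = records["cell_line_id"].isin(ids)
    n_dropped = int((~in_universe).sum())
    if n_dropped:
        logger.info("%d mutation records outside the analysis universe ignored", n_dropped)
    kept = records.loc[in_universe, ["gene_symbol", "cell_line_id"]].drop_duplicates()
    return {
        gene: frozenset(group)
        for gene, group in kept.groupby("gene_symbol", sort=True)["cell_line_id"]
    }


def call_sensitivity(
    matrix: GeneEffectMatrix,
    target: str,
    config: ScreenConfig = ScreenConfig(),
    universe: AnalysisUniverse | Iterable[str] | None = None,
) -> SensitivityCalls:
    """Binarize the target's dependency profile at the strict threshold."""
    if target not in matrix.scores.columns:
        raise KeyError(gene_lookup_message(target, matrix.gene_symbols))
    profile = matrix.scores[target]
    if universe is not None:
        ids = (
            universe.cell_line_ids
            if isinstance(universe, AnalysisUniverse)
            else sorted(universe)
        )
        profile = profile.reindex(ids)
    return SensitivityCalls(target, profile, config.sensitivity_threshold)


def _one_sided_enrichment_p(a: int, b: int, c: int, d: int) -> float:
    # P(A >= a) under the hypergeometric null with the observed margins
    n = a + b + c + d
    return float(stats.hypergeom.sf(a - 1, n, a + b, a + c))


def association_test(
    marker_lines: Iterable[str],
    calls: SensitivityCalls,
    config: ScreenConfig = ScreenConfig(),
    marker_gene: str = "",
) -> AssociationResult:
    """Test dependence between marker mutation and knockout sensitivity.

    The 2x2 table is built over evaluable lines only (missing target
    scores are excluded entirely). Degenerate margins -- no mutated line,
    every line mutated, no sensitive line or no insensitive line -- carry
    no contrast and return p = 1.0 with the degenerate flag set.
    """
    marker = frozenset(marker_lines)
    sensitive = calls.sensitive
    insensitive = calls.insensitive
    a = len(marker & sensitive)
    b = len(marker & insensitive)
    c = len(sensitive) - a
    d = len(insensitive) - b

    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if degenerate:
        p = 1.0
    elif config.test_variant == "fisher_one_sided_enrichment":
        p = _one_sided_enrichment_p(a, b, c, d)
    elif config.test_variant == "fisher_two_sided":
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    else:  # rank_sum_on_scores: are mutated lines' scores shifted downward?
        scores = calls.scores.dropna()
        in_marker = scores.index.isin(marker)
        p = float(
            stats.mannwhitneyu(
                scores[in_marker], scores[~in_marker], alternative="less"
            ).pvalue
        )

    if b == 0 or c == 0:
        direction = ">" if a * d > 0 else "="
    else:
        ad, bc = a * d, b * c
        direction = ">" if ad > bc else ("<" if ad < bc else "=")
    return AssociationResult(
        marker_gene=marker_gene,
        target_gene=calls.target_gene,
        a=a, b=b, c=c, d=d,
        p_value=float(p),
        odds_direction=direction,
        below_min_mutated=(a + b) < config.min_mutated,
        significant_at_alpha=p < config.alpha,
        degenerate=degenerate,
    )


_RESULT_COLUMNS = [
    "marker_gene", "target_gene", "a", "b", "c", "d", "n_mutated",
    "p_value", "q_value", "odds_direction",
    "below_min_mutated", "significant_at_alpha", "degenerate",
]


def run_screen(
    matrix: GeneEffectMatrix,
    mutations: MutationTable,
    info: SampleInfo | None,
    target: str,
    config: ScreenConfig = ScreenConfig(),
    universe: AnalysisUniverse | None = None,
) -> ScreenReport:
    """Screen every non-silently mutated gene against one knockout target.

    Orchestrates harmonization, the silent filter, sensitivity calling
    and per-marker association tests; results are sorted by ascending
    p-value (ties: descending mutated count, then symbol) with BH
    q-values computed over all emitted tests.
    """
    from .io import harmonize

    if universe is None:
        universe = harmonize(matrix, mutations, info)
    if len(universe) == 0:
        raise ValidationError("empty analysis universe")
    nonsilent = mutations if mutations.nonsilent_filtered else filter_nonsilent(mutations)
    markers = mutation_calls(nonsilent, universe)
    calls = call_sensitivity(matrix, target, config, universe=universe)

    rows = []
    for gene in sorted(markers):
        result = association_test(markers[gene], calls, config, marker_gene=gene)
        rows.append(
            {
                "marker_gene": result.marker_gene,
                "target_gene": result.target_gene,
                "a": result.a, "b": result.b, "c": result.c, "d": result.d,
                "n_mutated": result.n_mutated,
                "p_value": result.p_value,
                "odds_direction": result.odds_direction,
                "below_min_mutated": result.below_min_mutated,
                "significant_at_alpha": result.significant_at_alpha,
                "degenerate": result.degenerate,
            }
        )
    frame = pd.DataFrame(rows, columns=[c for c in _RESULT_COLUMNS if c != "q_value"])
    if len(frame):
        frame["q_value"] = multipletests(frame["p_value"], method="fdr_bh")[1]
        frame = frame.sort_values(
            ["p_value", "n_mutated", "marker_gene"],
            ascending=[True, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    else:
        frame["q_value"] = pd.Series(dtype=float)
    frame = frame.reindex(columns=_RESULT_COLUMNS)
    return ScreenReport(
        target_gene=target,
        config=config,
        results=frame,
        n_sensitive=calls.n_sensitive,
        n_evaluable=calls.n_evaluable,
        universe_size=len(universe),
    )


def intersect_markers(reports: Sequence[ScreenReport]) -> pd.DataFrame:
    """Markers significant (and not below min-mutated) for every target.

    Returns one row per shared marker with the per-target p-values, e.g.
    the genes whose alteration correlates with sensitivity to knockout of
    any of the three PRC2 subunits.
    """
    if len(reports) < 2:
        raise ValidationError("intersection needs at least two screen reports")
    sizes = {r.universe_size for r in reports}
    if len(sizes) > 1:
        raise ValidationError(f"screen reports cover different universes: sizes {sorted(sizes)}")
    targets = [r.target_gene for r in reports]
    if len(set(targets)) != len(targets):
        raise ValidationError("duplicate target genes among reports")

    selected: list[set[str]] = []
    for report in reports:
        frame = report.results
        keep = frame["significant_at_alpha"] & ~frame["below_min_mutated"]
        selected.append(set(frame.loc[keep, "marker_gene"]))
    shared = sorted(set.intersection(*selected))

    rows = []
    for gene in shared:
        row: dict[str, object] = {"marker_gene": gene}
        for report in reports:
            sub = report.results.set_index("marker_gene")
            row[f"p_{report.target_gene}"] = float(sub.at[gene, "p_value"])
            row[f"n_mutated_{report.target_gene}"] = int(sub.at[gene, "n_mutated"])
        rows.append(row)
    columns = ["marker_gene"] + [
        f"{prefix}_{t}" for t in targets for prefix in ("p", "n_mutated")
    ]
    return pd.DataFrame(rows, columns=columns)


def top_sensitive_lines(
    matrix: GeneEffectMatrix,
    target: str,
    k: int,
    info: SampleInfo | None = None,
) -> pd.DataFrame:
    """The k lines most depleted by the target knockout, most negative first.

    Missing scores are excluded; annotated with cell-line name and primary
    disease when sample info is given.
    """
    if target not in matrix.scores.columns:
        raise KeyError(gene_lookup_message(target, matrix.gene_symbols))
    if k <= 0:
        return pd.DataFrame(columns=["cell_line_id", "cell_line_name", "primary_disease", "score"])
    profile = matrix.scores[target].dropna().sort_values(kind="mergesort")
    top = profile.head(k)
    out = pd.DataFrame({"cell_line_id": top.index, "score": top.to_numpy()})
    for column in ("cell_line_name", "primary_disease"):
        if info is not None and column in info.table.columns:
            out[column] = info.annotate(out["cell_line_id"], column).to_numpy()
        else:
            out[column] = pd.NA
    return out[["cell_line_id", "cell_line_name", "primary_disease", "score"]].reset_index(
        drop=True
    )
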