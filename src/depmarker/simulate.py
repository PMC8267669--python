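"""Synthetic gene-effect matrices, mutation tables and survival cohorts.

Every generator plants known structure and emits it as a truth table so
each downstream stage can be tested against ground truth:

* selective genes draw scores from a two-component normal mixture -- a
  latent per-line sensitivity state selects between a background component
  (mean 0) and a sensitive component (mean -0.8, well below the -0.5
  sensitivity threshold);
* designated gene groups share one latent state with a concordance
  parameter, producing both correlated dependency profiles and concordant
  binarized sensitivity calls;
* marker genes mutate at different rates in sensitive vs insensitive
  lines, planting a chosen odds ratio into the mutation table;
* survival cohorts follow an exponential proportional-hazards model in a
  continuous expression covariate, with independent exponential censoring.

All generators are deterministic given their spec's seed; no analysis
stage reads the truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneEffectMatrix, GeneLabel, MutationTable

#: Non-silent variant classes assigned (uniformly) to non-synonymous records.
NONSILENT_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
)


@dataclass(frozen=True)
class CodependentGroup:
    """Genes sharing one latent sensitivity state with concordance rho.

    Each member adopts the group's latent call with probability ``rho``
    and redraws independently otherwise; ``rho = 1`` makes the members'
    sensitivity calls identical, ``rho = 0`` makes them independent.
    """

    genes: tuple[str, ...]
    rho: float = 1.0


@dataclass
class EffectSimSpec:
    """Study conditions for a simulated dependency screen.

    ``selective_genes`` maps each strongly selective gene to its sensitive
    fraction pi (the probability a line depends on it). Background genes,
    and selective genes in insensitive lines, draw scores from
    N(background_mean, background_sd); sensitive lines draw from
    N(sensitive_mean, sensitive_sd). Units are gene-effect scores.
    """

    n_lines: int
    selective_genes: dict[str, float] = field(default_factory=dict)
    codependent_groups: Sequence[CodependentGroup] = ()
    n_background_genes: int = 0
    background_mean: float = 0.0
    background_sd: float = 0.15
    sensitive_mean: float = -0.8
    sensitive_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.background_sd <= 0 or self.sensitive_sd <= 0:
            raise ValueError("component standard deviations must be > 0")
        for gene, pi in self.selective_genes.items():
            if not 0.0 <= pi <= 1.0:
                raise ValueError(f"sensitive fraction for {gene} outside [0, 1]")
        for group in self.codependent_groups:
            if not 0.0 <= group.rho <= 1.0:
                raise ValueError("concordance rho outside [0, 1]")
            unknown = [g for g in group.genes if g not in self.selective_genes]
            if unknown:
                raise ValueError(f"codependent genes {unknown} not listed as selective")
            fracs = {self.selective_genes[g] for g in group.genes}
            if len(fracs) > 1:
                raise ValueError("codependent group members must share one sensitive fraction")


@dataclass
class MarkerSimSpec:
    """Planted marker-sensitivity dependence for one knockout target.

    ``q1``/``q0`` are the marker-gene mutation probabilities given that a
    line is / is not sensitive to ``target_gene`` knockout, planting an
    odds ratio (q1/(1-q1))/(q0/(1-q0)). Background genes mutate at
    ``background_rate`` independently of sensitivity. Each record is
    labeled Silent with probability ``silent_fraction``.
    """

    marker_gene: str
    target_gene: str
    q1: float = 0.5
    q0: float = 0.05
    background_rate: float = 0.05
    n_background_genes: int = 200
    silent_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("q1", "q0", "background_rate", "silent_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")


@dataclass
class SurvivalSimSpec:
    """Exponential proportional-hazards cohort with planted effect size.

    Event times are exponential with rate h0 * exp(beta * expression);
    censoring is an independent exponential (rate ``censoring_rate``, 0 for
    none), optionally truncated at an administrative cutoff time.
    """

    n_subjects: int
    expression_mean: float = 0.0
    expression_sd: float = 1.0
    log_hazard: float = 0.0  # beta per unit expression
    baseline_hazard: float = 0.1  # events per time unit
    censoring_rate: float = 0.0
    admin_time: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.expression_sd <= 0:
            raise ValueError("expression_sd must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")


def simulate_gene_effect(spec: EffectSimSpec) -> tuple[GeneEffectMatrix, pd.DataFrame]:
    """Draw a gene-effect matrix with planted selective genes.

    Returns the matrix and a truth table (lines x selective genes, bool):
    True where the line's latent state is sensitive, i.e. its score was
    drawn from the sensitive mixture component.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lines = [f"ACH-{i:06d}" for i in range(spec.n_lines)]

    grouped = {g for group in spec.codependent_groups for g in group.genes}
    states: dict[str, np.ndarray] = {}
    for group in spec.codependent_groups:
        pi = spec.selective_genes[group.genes[0]]
        latent = rng.random(spec.n_lines) < pi
        for gene in group.genes:
            adopt = rng.random(spec.n_lines) < group.rho
            redraw = rng.random(spec.n_lines) < pi
            states[gene] = np.where(adopt, latent, redraw)
    for gene, pi in spec.selective_genes.items():
        if gene not in grouped:
            states[gene] = rng.random(spec.n_lines) < pi

    columns: dict[str, np.ndarray] = {}
    for gene in spec.selective_genes:  # insertion order keeps output deterministic
        sensitive = states[gene]
        background = rng.normal(spec.background_mean, spec.background_sd, spec.n_lines)
        depleted = rng.normal(spec.sensitive_mean, spec.sensitive_sd, spec.n_lines)
        columns[gene] = np.where(sensitive, depleted, background)
    for j in range(spec.n_background_genes):
        columns[f"BG{j:04d}"] = rng.normal(
            spec.background_mean, spec.background_sd, spec.n_lines
        )

    scores = pd.DataFrame(columns, index=pd.Index(lines, name="DepMap_ID"))
    labels = [GeneLabel(sym, 100000 + k) for k, sym in enumerate(scores.columns)]
    truth = pd.DataFrame(
        {gene: states[gene] for gene in spec.selective_genes},
        index=scores.index,
    )
    return GeneEffectMatrix(scores, labels), truth


def simulate_mutations(spec: MarkerSimSpec, truth: pd.DataFrame) -> MutationTable:
    """Draw a mutation table with the marker gene enriched in sensitive lines.

    ``truth`` is the sensitivity truth table from :func:`simulate_gene_effect`
    and must contain a column for ``spec.target_gene``.
    """
    spec.validate()
    if spec.target_gene not in truth.columns:
        raise ValueError(f"truth table has no column for target {spec.target_gene!r}")
    rng = np.random.default_rng(spec.seed)
    lines = np.asarray(truth.index, dtype=object)
    sensitive = truth[spec.target_gene].to_numpy(dtype=bool)

    rows_line: list[str] = []
    rows_gene: list[str] = []

    p_marker = np.where(sensitive, spec.q1, spec.q0)
    hit = rng.random(len(lines)) < p_marker
    rows_line.extend(lines[hit])
    rows_gene.extend([spec.marker_gene] * int(hit.sum()))

    for j in range(spec.n_background_genes):
        hit = rng.random(len(lines)) < spec.background_rate
        rows_line.extend(lines[hit])
        rows_gene.extend([f"MBG{j:04d}"] * int(hit.sum()))

    n = len(rows_line)
    silent = rng.random(n) < spec.silent_fraction
    classes = np.array(NONSILENT_CLASSES, dtype=object)[
        rng.integers(0, len(NONSILENT_CLASSES), n)
    ]
    classes[silent] = "Silent"
    records = pd.DataFrame(
        {
            "cell_line_id": rows_line,
            "gene_symbol": rows_gene,
            "variant_classification": classes,
            "entrez_id": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )
    return MutationTable(records)


def simulate_survival(spec: SurvivalSimSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a right-censored survival cohort under proportional hazards.

    Returns the cohort (subject_id, time, event, expression) and a truth
    record with the planted log-hazard and the realized censoring fraction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    expression = rng.normal(spec.expression_mean, spec.expression_sd, spec.n_subjects)
    rate = spec.baseline_hazard * np.exp(spec.log_hazard * expression)
    event_time = rng.exponential(1.0 / rate)
    if spec.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / spec.censoring_rate, spec.n_subjects)
    else:
        censor_time = np.full(spec.n_subjects, np.inf)
    if spec.admin_time is not None:
        censor_time = np.minimum(censor_time, spec.admin_time)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    # strictly positive follow-up even under extreme censoring rates
    observed = np.maximum(observed, np.finfo(float).tiny)
    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(spec.n_subjects)],
            "time": observed,
            "event": event,
            "expression": expression,
        }
    )
    truth = {
        "log_hazard": spec.log_hazard,
        "baseline_hazard": spec.baseline_hazard,
        "censoring_fraction": float(1.0 - event.mean()),
    }
    return cohort, truth
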