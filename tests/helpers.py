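"""Independent oracles and data builders shared across the test suite.

The oracles are deliberately naive (integer enumeration, two-pass sums,
hand tabulation) and share no code with the implementation paths they
check.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd

from depmarker.simulate import SurvivalSimSpec, simulate_survival


def enumeration_enrichment_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided enrichment p by exhaustive hypergeometric enumeration.

    Sums exact integer binomial terms for every table with the observed
    margins and at least ``a`` mutated-and-sensitive lines; the only
    floating-point step is the final division.
    """
    n = a + b + c + d
    row = a + b  # mutated lines
    col = a + c  # sensitive lines
    numerator = 0
    for a2 in range(a, min(row, col) + 1):
        if row - a2 > n - col:
            continue
        numerator += comb(col, a2) * comb(n - col, row - a2)
    return numerator / comb(n, row)


def tabulation_logrank_chi2(time_a, event_a, time_b, event_b) -> float:
    """Log-rank chi-square by explicit per-event-time observed/expected sums."""
    ta, ea = list(map(float, time_a)), list(map(int, event_a))
    tb, eb = list(map(float, time_b)), list(map(int, event_b))
    event_times = sorted({t for t, e in zip(ta + tb, ea + eb) if e == 1})
    observed = expected = variance = 0.0
    for t in event_times:
        n1 = sum(1 for x in ta if x >= t)
        n2 = sum(1 for x in tb if x >= t)
        d1 = sum(1 for x, e in zip(ta, ea) if x == t and e == 1)
        d2 = sum(1 for x, e in zip(tb, eb) if x == t and e == 1)
        n, d = n1 + n2, d1 + d2
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (observed - expected) ** 2 / variance


def two_pass_pearson(x, y) -> float:
    """Pairwise-complete Pearson r via explicit two-pass mean/covariance sums."""
    pairs = [(a, b) for a, b in zip(x, y) if not (np.isnan(a) or np.isnan(b))]
    n = len(pairs)
    mx = sum(a for a, _ in pairs) / n
    my = sum(b for _, b in pairs) / n
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    sxx = sum((a - mx) ** 2 for a, _ in pairs)
    syy = sum((b - my) ** 2 for _, b in pairs)
    return sxy / (sxx * syy) ** 0.5


def two_population_cohort(
    n: int = 400, hr: float = 3.0, seed: int = 0,
    low_mode: float = 0.0, high_mode: float = 3.0, sd: float = 0.5,
    baseline_hazard: float = 0.1, censoring_rate: float = 0.02,
) -> pd.DataFrame:
    """Cohort of two expression populations with a hazard ratio planted
    between them: the true dichotomization cutoff lies between the modes."""
    half = n // 2
    low, _ = simulate_survival(SurvivalSimSpec(
        n_subjects=half, expression_mean=low_mode, expression_sd=sd,
        log_hazard=0.0, baseline_hazard=baseline_hazard,
        censoring_rate=censoring_rate, seed=seed,
    ))
    high, _ = simulate_survival(SurvivalSimSpec(
        n_subjects=n - half, expression_mean=high_mode, expression_sd=sd,
        log_hazard=0.0, baseline_hazard=baseline_hazard * hr,
        censoring_rate=censoring_rate, seed=seed + 1,
    ))
    high = high.assign(subject_id=lambda f: "H" + f["subject_id"])
    return pd.concat([low, high], ignore_index=True)
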