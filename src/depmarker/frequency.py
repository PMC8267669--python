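"""Cohort alteration-frequency tabulation.

Summarizes clinical alteration tables (sample, cohort/group, gene,
alteration type) into per-cohort percentages, applying minimum cohort
sizes so that small cohorts never produce unstable percentages: by
default a tissue-level group needs at least 500 tested samples and a
subtype at least 50. Excluded groups are kept in the output with the
exclusion reason so nothing disappears silently.
"""

from __future__ import annotations

import pandas as pd

from .io import ValidationError

ALTERATION_TYPES = ("amplification", "deep_deletion", "mutation", "fusion", "multiple")

#: Default minimum tested-sample counts per aggregation level.
DEFAULT_MIN_GROUP = {"group": 500, "subtype": 50}


def alteration_frequency(
    records: pd.DataFrame,
    group_sizes: pd.Series | dict,
    level: str = "group",
    min_group: int | None = None,
) -> pd.DataFrame:
    """Per-(group, gene, alteration type) percentages over tested samples.

    ``records`` columns: sample_id, group, gene, alteration_type, and a
    ``subtype`` column when ``level="subtype"``. ``group_sizes`` gives
    the number of tested samples per group (the denominator; it cannot
    be derived from the altered records alone). A sample altered in
    several queried genes counts once per gene; samples altered in two
    or more queried genes within a group are tallied separately in the
    ``n_coaltered_samples`` column.

    Percentages are reported to 2 decimals. Groups below ``min_group``
    are flagged ``excluded`` with reason ``below_min_group``.
    """
    if level not in DEFAULT_MIN_GROUP:
        raise ValueError(f"level must be one of {tuple(DEFAULT_MIN_GROUP)}")
    if min_group is None:
        min_group = DEFAULT_MIN_GROUP[level]
    required = {"sample_id", "group", "gene", "alteration_type"}
    if level == "subtype":
        required.add("subtype")
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"alteration records missing columns {sorted(missing)}")
    if (records["sample_id"].astype(str).str.len() == 0).any():
        raise ValidationError("empty sample_id in alteration records")
    unknown = set(records["alteration_type"]) - set(ALTERATION_TYPES)
    if unknown:
        raise ValidationError(
            f"unknown alteration types {sorted(unknown)}; expected {ALTERATION_TYPES}"
        )

    sizes = pd.Series(group_sizes, dtype=float)
    key = "group" if level == "group" else "subtype"

    rows = []
    for (grp, gene, alt), sub in records.groupby([key, "gene", "alteration_type"], sort=True):
        if grp not in sizes.index:
            raise ValidationError(f"no tested-sample count supplied for group {grp!r}")
        n_samples = int(sizes[grp])
        n_altered = int(sub["sample_id"].nunique())
        excluded = n_samples < min_group
        rows.append(
            {
                key: grp,
                "gene": gene,
                "alteration_type": alt,
                "n_samples": n_samples,
                "n_altered": n_altered,
                "percent": round(100.0 * n_altered / n_samples, 2),
                "excluded": excluded,
                "exclusion_reason": "below_min_group" if excluded else "",
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[key, "gene", "alteration_type", "n_samples", "n_altered",
                 "percent", "excluded", "exclusion_reason"],
    )

    # co-occurrence: samples altered in >= 2 distinct queried genes per group
    co = (
        records.groupby([key, "sample_id"])["gene"].nunique().reset_index(name="n_genes")
    )
    co_counts = co[co["n_genes"] >= 2].groupby(key)["sample_id"].count()
    table["n_coaltered_samples"] = (
        table[key].map(co_counts).fillna(0).astype(int) if len(table) else pd.Series(dtype=int)
    )
    return table
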