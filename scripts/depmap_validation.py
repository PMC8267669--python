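#!/usr/bin/env python
"""Validate the pipeline against the pinned DepMap 20Q3 release.

Requires a local copy of the CRISPR (Avana) Public 20Q3 release files
(one-time download, figshare doi:10.6084/m9.figshare.12931238.v1):

    Achilles_gene_effect.csv   CCLE_mutations.csv   sample_info.csv

Usage:
    python scripts/depmap_validation.py --data-dir /path/to/20q3 --out report.json

Recomputes, for the EZH2/SUZ12/EED knockouts, the sensitive-line counts,
the single most sensitive cell line per target, the top co-dependency
partners, and the cross-target marker intersection, and compares them
with the reference values established for this release.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import depmarker as dm

TARGETS = ("EZH2", "SUZ12", "EED")

#: Reference values for the CRISPR (Avana) Public 20Q3 release.
REFERENCE = {
    "matrix_shape": [789, 18119],
    "mutation_cell_lines": 1741,
    "universe_size": 777,
    "sensitive_counts": {"EZH2": 15, "SUZ12": 86, "EED": 238},
    "top1_sensitive": {
        "EZH2": {"name": "DB", "score": -0.848},
        "SUZ12": {"name": "SUM52PE", "score": -1.162041582},
        "EED": {"name": "TUHR10TKB", "score": -1.369846119},
    },
    "ezh2_codependency_top2": ["EED", "SUZ12"],
    "intersection_includes": ["SUSD2", "FIZ1", "FBXW11"],
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, required=True)
    parser.add_argument("--out", type=Path, default=Path("depmap_validation.json"))
    args = parser.parse_args()

    matrix = dm.load_gene_effect(args.data_dir / "Achilles_gene_effect.csv")
    mutations = dm.load_mutations(args.data_dir / "CCLE_mutations.csv")
    info = dm.load_sample_info(args.data_dir / "sample_info.csv")
    universe = dm.harmonize(matrix, mutations, info)
    config = dm.ScreenConfig(target_genes=TARGETS)

    computed: dict = {
        "matrix_shape": list(matrix.scores.shape),
        "mutation_cell_lines": int(mutations.records["cell_line_id"].nunique()),
        "universe_size": len(universe),
        "sensitive_counts": {},
        "top1_sensitive": {},
    }
    sub_matrix = dm.GeneEffectMatrix(
        matrix.scores.loc[universe.cell_line_ids], matrix.gene_labels
    )
    reports = []
    for target in TARGETS:
        calls = dm.call_sensitivity(sub_matrix, target, config)
        computed["sensitive_counts"][target] = calls.n_sensitive
        top1 = dm.top_sensitive_lines(sub_matrix, target, 1, info)
        computed["top1_sensitive"][target] = {
            "name": str(top1.loc[0, "cell_line_name"]),
            "score": float(top1.loc[0, "score"]),
        }
        reports.append(dm.run_screen(sub_matrix, mutations, info, target, config,
                                     universe=universe))

    codep_all = dm.top_codependencies(matrix, "EZH2", 2)
    codep_universe = dm.top_codependencies(sub_matrix, "EZH2", 2)
    computed["ezh2_codependency_top2_all_lines"] = list(codep_all["partner_gene"])
    computed["ezh2_codependency_top2_universe"] = list(codep_universe["partner_gene"])

    intersection = dm.intersect_markers(reports)
    shared = set(intersection["marker_gene"])
    computed["intersection_size"] = len(shared)
    computed["intersection_includes"] = {
        gene: gene in shared for gene in REFERENCE["intersection_includes"]
    }

    checks = {
        "matrix_shape": computed["matrix_shape"] == REFERENCE["matrix_shape"],
        "mutation_cell_lines": computed["mutation_cell_lines"]
        == REFERENCE["mutation_cell_lines"],
        "universe_size": computed["universe_size"] == REFERENCE["universe_size"],
        "sensitive_counts": computed["sensitive_counts"] == REFERENCE["sensitive_counts"],
        "top1_names": all(
            computed["top1_sensitive"][t]["name"] == REFERENCE["top1_sensitive"][t]["name"]
            for t in TARGETS
        ),
        "top1_scores": all(
            abs(computed["top1_sensitive"][t]["score"]
                - REFERENCE["top1_sensitive"][t]["score"]) < 5e-4
            for t in TARGETS
        ),
        "ezh2_codependency_top2": (
            computed["ezh2_codependency_top2_all_lines"]
            == REFERENCE["ezh2_codependency_top2"]
            or computed["ezh2_codependency_top2_universe"]
            == REFERENCE["ezh2_codependency_top2"]
        ),
        "intersection_includes": all(computed["intersection_includes"].values()),
    }
    report = {"computed": computed, "reference": REFERENCE, "checks": checks,
              "all_passed": all(checks.values())}
    with open(args.out, "w") as handle:
        json.dump(report, handle, indent=2)
        handle.write("\n")
    print(json.dumps(checks, indent=2))
    raise SystemExit(0 if report["all_passed"] else 1)


if __name__ == "__main__":
    main()
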