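import logging

import numpy as np
import pandas as pd
import pytest

import depmarker as dm
from depmarker.io import ValidationError
from depmarker.screen import _one_sided_enrichment_p

from helpers import enumeration_enrichment_p


class TestFilterNonsilent:
    def test_all_silent_table_empties(self):
        records = pd.DataFrame(
            {
                "cell_line_id": ["A", "B"],
                "gene_symbol": ["G", "G"],
                "variant_classification": ["Silent", "Silent"],
            }
        )
        filtered = dm.filter_nonsilent(dm.MutationTable(records))
        assert len(filtered) == 0
        assert filtered.nonsilent_filtered

    def test_exactly_silent_records_removed(self, mutation_records):
        filtered = dm.filter_nonsilent(mutation_records)
        assert len(filtered) == 4
        assert "Silent" not in set(filtered.records["variant_classification"])

    def test_lowercase_near_miss_retained_with_warning(self, caplog):
        records = pd.DataFrame(
            {
                "cell_line_id": ["A", "B"],
                "gene_symbol": ["G", "G"],
                "variant_classification": ["silent", "Missense_Mutation"],
            }
        )
        with caplog.at_level(logging.WARNING, logger="depmarker.screen"):
            filtered = dm.filter_nonsilent(dm.MutationTable(records))
        assert len(filtered) == 2
        assert any("silent" in record.message for record in caplog.records)


class TestMutationCalls:
    def test_requires_filtered_input(self, mutation_records):
        with pytest.raises(ValidationError):
            dm.mutation_calls(mutation_records, {"ACH-000000"})

    def test_duplicates_collapse_to_one_call(self, mutation_records):
        universe = {f"ACH-{i:06d}" for i in range(5)}
        calls = dm.mutation_calls(dm.filter_nonsilent(mutation_records), universe)
        # two non-silent MARK records for ACH-000000 collapse to one call
        assert calls["MARK"] == frozenset({"ACH-000000"})
        assert calls["QUIET"] == frozenset({"ACH-000003"})

    def test_lines_outside_universe_ignored_and_empty_genes_dropped(self, mutation_records):
        calls = dm.mutation_calls(dm.filter_nonsilent(mutation_records), {"ACH-000003"})
        assert "MARK" not in calls  # its only universe record fell outside
        assert calls == {"QUIET": frozenset({"ACH-000003"})}


class TestCallSensitivity:
    def test_strict_inequality_at_the_threshold(self, toy_matrix):
        calls = dm.call_sensitivity(toy_matrix, "TGT")
        # scores -0.6, -0.5, -0.4, -0.9, missing: only the strict < -0.5 pass
        assert calls.sensitive == {"ACH-000000", "ACH-000003"}
        assert "ACH-000001" in calls.insensitive

    def test_missing_scores_excluded_from_counts(self, toy_matrix):
        calls = dm.call_sensitivity(toy_matrix, "TGT")
        assert calls.missing == {"ACH-000004"}
        assert calls.n_evaluable == 4

    def test_absent_target_names_near_symbols(self, toy_matrix):
        with pytest.raises(KeyError, match="TGT"):
            dm.call_sensitivity(toy_matrix, "TGTT")


def _calls_from_counts(a, b, c, d):
    """Build SensitivityCalls and a marker set realizing a given 2x2 table."""
    lines = [f"L{i}" for i in range(a + b + c + d)]
    scores = pd.Series(
        [-1.0] * a + [0.0] * b + [-1.0] * c + [0.0] * d, index=lines, dtype=float
    )
    calls = dm.SensitivityCalls("TGT", scores, threshold=-0.5)
    marker = set(lines[: a + b])
    return marker, calls


class TestAssociationTest:
    def test_matches_enumeration_oracle_on_worked_example(self):
        marker, calls = _calls_from_counts(5, 1, 10, 50)
        result = dm.association_test(marker, calls, marker_gene="M")
        assert result.p_value == pytest.approx(enumeration_enrichment_p(5, 1, 10, 50), abs=1e-12)
        assert (result.a, result.b, result.c, result.d) == (5, 1, 10, 50)
        assert result.odds_direction == ">"

    @pytest.mark.parametrize("table", [(0, 0, 3, 5), (3, 5, 0, 0), (0, 3, 0, 5), (3, 0, 5, 0)])
    def test_degenerate_margins_return_p_one(self, table):
        marker, calls = _calls_from_counts(*table)
        result = dm.association_test(marker, calls)
        assert result.p_value == 1.0
        assert result.degenerate
        assert not result.significant_at_alpha

    def test_exhaustive_small_tables_through_the_set_interface(self):
        for n in range(1, 13):
            for row in range(n + 1):
                for col in range(n + 1):
                    lo, hi = max(0, row + col - n), min(row, col)
                    for a in range(lo, hi + 1):
                        b, c = row - a, col - a
                        d = n - row - col + a
                        marker, calls = _calls_from_counts(a, b, c, d)
                        result = dm.association_test(marker, calls)
                        if result.degenerate:
                            continue
                        expected = enumeration_enrichment_p(a, b, c, d)
                        assert result.p_value == pytest.approx(expected, abs=1e-12)

    def test_enrichment_p_monotone_in_a_at_fixed_margins(self):
        n, row, col = 40, 12, 15
        previous = 1.1
        for a in range(max(0, row + col - n), min(row, col) + 1):
            p = _one_sided_enrichment_p(a, row - a, col - a, n - row - col + a)
            assert p <= previous + 1e-12
            previous = p

    def test_rank_sum_variant_detects_downward_score_shift(self):
        rng = np.random.default_rng(0)
        lines = [f"L{i}" for i in range(60)]
        scores = pd.Series(rng.normal(0, 0.1, 60), index=lines)
        scores.iloc[:15] -= 1.0  # mutated lines strongly depleted
        calls = dm.SensitivityCalls("TGT", scores, threshold=-0.5)
        config = dm.ScreenConfig(test_variant="rank_sum_on_scores")
        result = dm.association_test(set(lines[:15]), calls, config)
        assert result.p_value < 1e-6


class TestRunScreen:
    def test_no_nonsilent_mutations_gives_empty_results(self, toy_matrix):
        records = pd.DataFrame(
            {
                "cell_line_id": ["ACH-000000"],
                "gene_symbol": ["MARK"],
                "variant_classification": ["Silent"],
            }
        )
        report = dm.run_screen(
            toy_matrix, dm.MutationTable(records), None, "TGT",
            universe=dm.AnalysisUniverse(["ACH-000000"], 0, 0),
        )
        assert report.results.empty

    def test_sparse_marker_kept_with_below_min_flag(self, planted_screen):
        matrix, _, mutations = planted_screen
        config = dm.ScreenConfig(min_mutated=10_000)  # everything is sparse
        report = dm.run_screen(matrix, mutations, None, "TGT", config)
        assert len(report.results) > 0
        assert report.results["below_min_mutated"].all()

    def test_results_sorted_by_p_with_deterministic_tie_break(self, planted_screen):
        matrix, _, mutations = planted_screen
        report = dm.run_screen(matrix, mutations, None, "TGT")
        p = report.results["p_value"].to_numpy()
        assert (np.diff(p) >= 0).all()
        ties = report.results.groupby("p_value")
        for _, group in ties:
            n_mut = group["n_mutated"].to_numpy()
            assert (np.diff(n_mut) <= 0).all()

    def test_planted_marker_ranks_first_and_is_significant(self, planted_screen):
        matrix, _, mutations = planted_screen
        report = dm.run_screen(matrix, mutations, None, "TGT")
        top = report.results.iloc[0]
        assert top["marker_gene"] == "MARK"
        assert top["significant_at_alpha"]
        assert not top["below_min_mutated"]
        assert "q_value" in report.results.columns

    def test_input_row_order_never_changes_statistics(self, planted_screen):
        matrix, _, mutations = planted_screen
        shuffled_records = mutations.records.sample(frac=1.0, random_state=9)
        shuffled_matrix = dm.GeneEffectMatrix(
            matrix.scores.sample(frac=1.0, random_state=9), matrix.gene_labels
        )
        baseline = dm.run_screen(matrix, mutations, None, "TGT")
        shuffled = dm.run_screen(
            shuffled_matrix,
            dm.MutationTable(shuffled_records.reset_index(drop=True)),
            None, "TGT",
        )
        pd.testing.assert_frame_equal(baseline.results, shuffled.results)


class TestIntersectMarkers:
    def _report(self, target, significant_genes, universe_size=100):
        rows = [
            {
                "marker_gene": g, "target_gene": target,
                "a": 5, "b": 5, "c": 10, "d": 80, "n_mutated": 10,
                "p_value": 0.01, "q_value": 0.05, "odds_direction": ">",
                "below_min_mutated": False, "significant_at_alpha": True,
                "degenerate": False,
            }
            for g in significant_genes
        ]
        return dm.ScreenReport(
            target_gene=target, config=dm.ScreenConfig(),
            results=pd.DataFrame(
                rows,
                columns=["marker_gene", "target_gene", "a", "b", "c", "d",
                         "n_mutated", "p_value", "q_value", "odds_direction",
                         "below_min_mutated", "significant_at_alpha", "degenerate"],
            ),
            n_sensitive=20, n_evaluable=100, universe_size=universe_size,
        )

    def test_disjoint_significant_sets_intersect_empty(self):
        out = dm.intersect_markers([self._report("T1", ["A"]), self._report("T2", ["B"])])
        assert out.empty

    def test_shared_marker_reported_with_per_target_p(self):
        out = dm.intersect_markers(
            [self._report("T1", ["A", "B"]), self._report("T2", ["B", "C"])]
        )
        assert list(out["marker_gene"]) == ["B"]
        assert {"p_T1", "p_T2"} <= set(out.columns)

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValidationError):
            dm.intersect_markers(
                [self._report("T1", ["A"]), self._report("T2", ["A"], universe_size=99)]
            )

    def test_marker_planted_against_three_targets_appears(self):
        spec = dm.EffectSimSpec(
            n_lines=777, selective_genes={"T1": 0.3, "T2": 0.3, "T3": 0.3},
            codependent_groups=[dm.CodependentGroup(("T1", "T2", "T3"), rho=1.0)],
            seed=21,
        )
        matrix, truth = dm.simulate_gene_effect(spec)
        mutations = dm.simulate_mutations(
            dm.MarkerSimSpec("MARK", "T1", q1=0.5, q0=0.05, n_background_genes=50, seed=22),
            truth,
        )
        reports = [dm.run_screen(matrix, mutations, None, t) for t in ("T1", "T2", "T3")]
        out = dm.intersect_markers(reports)
        assert "MARK" in set(out["marker_gene"])


class TestTopSensitiveLines:
    def test_nonpositive_k_gives_empty_list(self, toy_matrix):
        assert dm.top_sensitive_lines(toy_matrix, "TGT", 0).empty
        assert dm.top_sensitive_lines(toy_matrix, "TGT", -3).empty

    def test_ascending_score_order_with_missing_excluded(self):
        scores = pd.DataFrame(
            {"TGT": [-0.2, -0.9, -0.5, np.nan]}, index=["X", "Y", "Z", "W"]
        )
        matrix = dm.GeneEffectMatrix(scores, [dm.GeneLabel("TGT")])
        top = dm.top_sensitive_lines(matrix, "TGT", 2)
        assert list(top["cell_line_id"]) == ["Y", "Z"]
        assert list(top["score"]) == [-0.9, -0.5]

    def test_disease_annotation_joined_from_sample_info(self, toy_matrix):
        info = dm.SampleInfo(
            pd.DataFrame(
                {"cell_line_name": ["DB"], "primary_disease": ["Lymphoma"]},
                index=["ACH-000003"],
            )
        )
        top = dm.top_sensitive_lines(toy_matrix, "TGT", 1, info)
        assert top.loc[0, "cell_line_id"] == "ACH-000003"
        assert top.loc[0, "primary_disease"] == "Lymphoma"
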