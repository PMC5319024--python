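import numpy as np
import pandas as pd
import pytest

import tilscore as ts


def _log2_matrix(df):
    return ts.ExpressionMatrix(df, ts.Scale.log2)


def _simple_markers():
    return ts.MarkerSet(
        [
            ts.CellTypeMarkers("T-cells", ["CD3D", "CD3E"]),
            ts.CellTypeMarkers("CD8 T cells", ["CD8A", "CD8B"]),
            ts.CellTypeMarkers("B-cells", ["CD19", "MS4A1"]),
        ],
        [ts.DerivedScore("CD4 cells", "T-cells", "CD8 T cells")],
    )


class TestCellScores:
    def test_score_is_mean_of_marker_log2(self):
        df = pd.DataFrame({"s1": [4.0, 6.0], "s2": [1.0, 3.0]},
                          index=["CD3D", "CD3E"])
        ms = ts.MarkerSet([ts.CellTypeMarkers("T-cells", ["CD3D", "CD3E"])])
        table = ts.cell_scores(_log2_matrix(df), ms)
        assert table.scores.loc["s1", "T-cells"] == pytest.approx(5.0)
        assert table.scores.loc["s2", "T-cells"] == pytest.approx(2.0)

    def test_derived_cd4_is_tcell_minus_cd8(self):
        df = pd.DataFrame(
            {"s1": [7.0, 7.0, 5.0, 5.0]},
            index=["CD3D", "CD3E", "CD8A", "CD8B"],
        )
        ms = _simple_markers().subset(["CD3D", "CD3E", "CD8A", "CD8B"])
        table = ts.cell_scores(_log2_matrix(df), ms)
        assert table.scores.loc["s1", "CD4 cells"] == pytest.approx(2.0)

    def test_missing_markers_use_available_subset_with_provenance(self):
        df = pd.DataFrame({"s1": [4.0, 8.0]}, index=["CD3D", "CD3E"])
        ms = ts.MarkerSet(
            [ts.CellTypeMarkers("T-cells", ["CD3D", "CD3E", "TRAT1", "CD3G"])]
        )
        with pytest.warns(UserWarning, match="2/4"):
            table = ts.cell_scores(_log2_matrix(df), ms)
        assert table.scores.loc["s1", "T-cells"] == pytest.approx(6.0)
        assert table.provenance["T-cells"] == ["CD3D", "CD3E"]

    def test_allow_missing_false_errors(self):
        df = pd.DataFrame({"s1": [4.0]}, index=["CD3D"])
        ms = ts.MarkerSet([ts.CellTypeMarkers("T-cells", ["CD3D", "CD3E"])])
        with pytest.raises(ValueError, match="CD3E"):
            ts.cell_scores(_log2_matrix(df), ms, allow_missing=False)

    def test_cell_type_without_any_marker_skipped_with_warning(self):
        df = pd.DataFrame({"s1": [4.0], "s2": [5.0]}, index=["CD3D"])
        ms = ts.MarkerSet(
            [
                ts.CellTypeMarkers("T-cells", ["CD3D"]),
                ts.CellTypeMarkers("B-cells", ["CD19"]),
            ]
        )
        with pytest.warns(UserWarning, match="B-cells"):
            table = ts.cell_scores(_log2_matrix(df), ms)
        assert table.cell_types == ["T-cells"]

    def test_duplicate_marker_listing_deduplicated(self):
        df = pd.DataFrame({"s1": [4.0, 6.0]}, index=["CD3D", "CD3E"])
        a = ts.cell_scores(
            _log2_matrix(df),
            ts.MarkerSet([ts.CellTypeMarkers("T", ["CD3D", "CD3E"])]),
        )
        df2 = pd.DataFrame({"s1": [4.0, 6.0]}, index=["CD3D", "CD3E"])
        b = ts.cell_scores(
            _log2_matrix(df2),
            ts.MarkerSet([ts.CellTypeMarkers("T", ["CD3E", "CD3D"])]),
        )
        assert a.scores.loc["s1", "T"] == b.scores.loc["s1", "T"]


class TestTotalTils:
    def test_affine_functions_of_cd45_all_included(self, rng):
        cd45 = pd.Series(rng.normal(8, 1, 50), index=[f"s{i}" for i in range(50)])
        scores = pd.DataFrame(
            {"A": 2 * cd45 + 1, "B": 0.5 * cd45 - 3}, index=cd45.index
        )
        table = ts.total_tils(ts.CellScoreTable(scores), cd45)
        assert table.tils_included == ["A", "B"]
        np.testing.assert_allclose(
            table.total_tils, scores.mean(axis=1), rtol=1e-12
        )

    def test_independent_score_excluded(self, rng):
        n = 500
        cd45 = pd.Series(rng.normal(8, 1, n), index=[f"s{i}" for i in range(n)])
        scores = pd.DataFrame(
            {
                "Tracks": cd45 + rng.normal(0, 0.2, n),
                "Indep": pd.Series(rng.normal(5, 1, n), index=cd45.index),
            }
        )
        table = ts.total_tils(ts.CellScoreTable(scores), cd45)
        assert table.tils_included == ["Tracks"]
        assert table.tils_excluded == ["Indep"]

    def test_designed_correlations_split_at_threshold(self, rng):
        # noise SDs calibrated so population correlations are 0.9, 0.7, 0.3
        n = 500
        cd45 = pd.Series(rng.normal(0, 1, n), index=[f"s{i}" for i in range(n)])
        scores = {}
        for name, rho in [("Hi", 0.9), ("Mid", 0.7), ("Lo", 0.3)]:
            sd = np.sqrt(1 / rho**2 - 1)
            scores[name] = cd45 + rng.normal(0, sd, n)
        table = ts.total_tils(ts.CellScoreTable(pd.DataFrame(scores)), cd45, 0.6)
        assert table.tils_included == ["Hi", "Mid"]
        assert table.tils_excluded == ["Lo"]

    def test_no_passing_score_raises_with_hint(self, rng):
        n = 100
        cd45 = pd.Series(rng.normal(0, 1, n), index=[f"s{i}" for i in range(n)])
        scores = pd.DataFrame({"X": pd.Series(rng.normal(0, 1, n), index=cd45.index)})
        with pytest.raises(ValueError, match="threshold"):
            ts.total_tils(ts.CellScoreTable(scores), cd45)


class TestEnrichment:
    def _table(self, scores, tils):
        t = ts.CellScoreTable(pd.DataFrame(scores))
        t.total_tils = pd.Series(tils, index=t.scores.index, name="Total TILs")
        return t

    def test_score_identical_to_tils_gives_zero_residuals(self):
        tils = [1.0, 2.0, 3.0, 4.0]
        table = ts.enrichment_scores(self._table({"A": tils}, tils))
        np.testing.assert_allclose(table.enrichment["A"], 0.0, atol=1e-12)

    def test_orthogonal_offsets_recovered_as_residuals(self):
        # tils mean-centered and orthogonal to the offsets by construction
        tils = np.array([1.0, 1.0, -1.0, -1.0])
        offsets = np.array([1.0, -1.0, 0.0, 0.0])
        table = ts.enrichment_scores(self._table({"A": tils + offsets}, tils))
        np.testing.assert_allclose(table.enrichment["A"], offsets, atol=1e-12)

    def test_residuals_sum_to_zero(self, rng):
        tils = rng.normal(0, 1, 30)
        scores = {c: 0.8 * tils + rng.normal(0, 0.5, 30) for c in "ABC"}
        table = ts.enrichment_scores(self._table(scores, tils))
        for c in "ABC":
            sd = table.enrichment[c].std(ddof=1)
            assert abs(table.enrichment[c].mean()) < 1e-8 * max(sd, 1.0)

    def test_requires_total_tils_and_variance(self):
        t = ts.CellScoreTable(pd.DataFrame({"A": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValueError, match="total_tils"):
            ts.enrichment_scores(t)
        flat = self._table({"A": [1.0, 2.0, 3.0]}, [2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="variance"):
            ts.enrichment_scores(flat)


class TestCalibration:
    def test_reference_worked_example(self):
        assert ts.calibrate_absolute(5, 4, 500) == pytest.approx(1000.0)

    def test_score_equal_to_reference_returns_reference_count(self):
        assert ts.calibrate_absolute(4.2, 4.2, 137) == pytest.approx(137.0)

    def test_fold_change_examples(self):
        # published rounding: 2^2.58 printed as 5.97 -> 597 cells (+/-1)
        assert abs(ts.calibrate_absolute(2.58, 0, 100) - 597) <= 1
        assert ts.fold_change(1.0) == pytest.approx(2.0)

    def test_round_trip_recovers_score_difference(self):
        count = ts.calibrate_absolute(6.3, 4.0, 250)
        assert np.log2(count / 250) == pytest.approx(2.3, rel=1e-12)

    def test_nonpositive_reference_count_rejected(self):
        with pytest.raises(ValueError):
            ts.calibrate_absolute(5, 4, 0)


class TestRelativeAndAnchored:
    def _table(self):
        scores = pd.DataFrame(
            {"T-cells": [3.0, 5.0, 7.0], "B-cells": [6.0, 2.0, 4.0]},
            index=["n1", "n2", "q1"],
        )
        return ts.CellScoreTable(scores)

    def test_baseline_mean_becomes_zero(self):
        out = ts.relative_to_baseline(self._table(), ["n1", "n2"])
        np.testing.assert_allclose(
            out.scores.loc[["n1", "n2"]].mean(axis=0), 0.0, atol=1e-12
        )
        assert out.scores.loc["q1", "T-cells"] == pytest.approx(3.0)

    def test_single_baseline_sample_row_becomes_zero(self):
        out = ts.relative_to_baseline(self._table(), ["n1"])
        np.testing.assert_allclose(out.scores.loc["n1"], 0.0, atol=1e-12)

    def test_empty_or_unknown_baseline_errors(self):
        with pytest.raises(ValueError, match="empty"):
            ts.relative_to_baseline(self._table(), [])
        with pytest.raises(ValueError, match="nope"):
            ts.relative_to_baseline(self._table(), ["nope"])

    def test_anchor_column_zero_and_contrasts_correct(self):
        out = ts.normalize_to_cell_type(self._table(), "T-cells")
        np.testing.assert_allclose(out.scores["T-cells"], 0.0, atol=1e-12)
        assert out.scores.loc["n1", "B-cells"] == pytest.approx(3.0)

    def test_anchored_scores_invariant_to_per_sample_normalization(self, rng):
        df = pd.DataFrame(
            rng.normal(6, 1, (4, 8)),
            index=["CD3D", "CD3E", "CD19", "MS4A1"],
            columns=[f"s{i}" for i in range(8)],
        )
        ms = ts.MarkerSet(
            [
                ts.CellTypeMarkers("T-cells", ["CD3D", "CD3E"]),
                ts.CellTypeMarkers("B-cells", ["CD19", "MS4A1"]),
            ]
        )
        base = ts.normalize_to_cell_type(
            ts.cell_scores(_log2_matrix(df), ms), "T-cells"
        )
        shifted = ts.normalize_to_cell_type(
            ts.cell_scores(_log2_matrix(df + rng.normal(0, 2, 8)), ms), "T-cells"
        )
        pd.testing.assert_frame_equal(base.scores, shifted.scores)


class TestShiftEquivariance:
    def _scored(self, df):
        ms = ts.MarkerSet(
            [
                ts.CellTypeMarkers("T-cells", ["CD3D", "CD3E"]),
                ts.CellTypeMarkers("CD45", ["PTPRC"], single_gene=True),
            ]
        )
        table = ts.cell_scores(_log2_matrix(df), ms)
        table = ts.total_tils(table, df.loc["PTPRC"], threshold=0.6)
        return ts.enrichment_scores(table)

    def test_per_sample_shift_moves_scores_and_tils_by_c(self, rng):
        df = pd.DataFrame(
            rng.normal(6, 0.3, (3, 10)) + rng.normal(0, 1, 10),  # correlated genes
            index=["CD3D", "CD3E", "PTPRC"],
            columns=[f"s{i}" for i in range(10)],
        )
        base = self._scored(df)
        c = 1.7
        df_shift = df.copy()
        df_shift["s3"] += c
        shifted = self._scored(df_shift)
        np.testing.assert_allclose(
            shifted.scores.loc["s3"], base.scores.loc["s3"] + c, rtol=1e-12
        )
        assert shifted.total_tils["s3"] == pytest.approx(
            base.total_tils["s3"] + c
        )

    def test_global_shift_leaves_enrichment_and_relative_scores_unchanged(self, rng):
        df = pd.DataFrame(
            rng.normal(6, 0.3, (3, 10)) + rng.normal(0, 1, 10),
            index=["CD3D", "CD3E", "PTPRC"],
            columns=[f"s{i}" for i in range(10)],
        )
        base = self._scored(df)
        shifted = self._scored(df + 2.5)
        np.testing.assert_allclose(
            shifted.enrichment.to_numpy(), base.enrichment.to_numpy(), atol=1e-9
        )
        rel_base = ts.relative_to_baseline(base, ["s0", "s1"])
        rel_shift = ts.relative_to_baseline(shifted, ["s0", "s1"])
        np.testing.assert_allclose(
            rel_shift.scores.to_numpy(), rel_base.scores.to_numpy(), atol=1e-9
        )


class TestCellScoreModel:
    def test_bundled_markers_on_simulated_full_panel(self, rng):
        ms = ts.bundled_markers()
        genes = ms.all_genes
        n = 40
        # one latent infiltrate driving everything, plus gene noise
        latent = rng.normal(0, 1, n)
        data = pd.DataFrame(
            {f"s{i}": latent[i] + rng.normal(6, 0.3, len(genes)) for i in range(n)},
            index=genes,
        )
        res = ts.CellScoreModel(_log2_matrix(data)).fit()
        assert res.scores.shape[1] == 15  # 14 scored cell types + CD4 derived
        assert "CD4 cells" in res.scores.columns
        assert res.total_tils is not None
        assert res.enrichment is not None
        summary = res.summary()
        assert summary.loc["T-cells", "n_markers"] == 6

    def test_cd4_absent_when_cd8_markers_missing(self, rng):
        ms = ts.bundled_markers()
        genes = [g for g in ms.all_genes if g not in ("CD8A", "CD8B")]
        data = pd.DataFrame(
            rng.normal(6, 1, (len(genes), 10)),
            index=genes,
            columns=[f"s{i}" for i in range(10)],
        )
        with pytest.warns(UserWarning):
            res = ts.CellScoreModel(_log2_matrix(data)).fit(
                compute_total_tils=False
            )
        assert "CD4 cells" not in res.scores.columns
        assert "CD8 T cells" not in res.scores.columns

    def test_frozen_tils_list_bypasses_correlation_rule(self, rng):
        df = pd.DataFrame(
            rng.normal(6, 1, (3, 10)),
            index=["CD3D", "CD3E", "PTPRC"],
            columns=[f"s{i}" for i in range(10)],
        )
        ms = ts.MarkerSet(
            [
                ts.CellTypeMarkers("T-cells", ["CD3D", "CD3E"]),
                ts.CellTypeMarkers("CD45", ["PTPRC"], single_gene=True),
            ]
        )
        res = ts.CellScoreModel(_log2_matrix(df), ms).fit(
            frozen_tils_cell_types=["T-cells"]
        )
        assert res.table.tils_included == ["T-cells"]
        np.testing.assert_allclose(res.total_tils, res.scores["T-cells"])
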