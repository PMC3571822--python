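"""Pixel counting, train/validation splitting, OLS calibration, CSV export."""

import numpy as np
import pandas as pd
import pytest

from vinepix.classifier import ClassRegistry, LabelImage
from vinepix.quantify import (
    CalibrationModel,
    ClassCounts,
    aggregate_leaf_count,
    count_pixels,
    evaluate,
    fit_linear,
    grape_count,
    read_results,
    records_from_tables,
    split_train_validation,
    write_results,
)

from conftest import exact_class


@pytest.fixture
def registry():
    return ClassRegistry(
        [
            exact_class("Background", (235, 235, 235), roles=("background",)),
            exact_class("Leaves young", (90, 150, 70), roles=("leaf",)),
            exact_class("Leaves old", (60, 110, 50), roles=("leaf",)),
            exact_class("Grape", (50, 45, 75), roles=("grape",)),
        ]
    )


class TestCountPixels:
    def test_uniform_field(self, registry):
        labels = np.full((10, 10), 2, dtype=np.int32)
        cc = count_pixels(LabelImage(labels, registry), "img")
        assert cc.counts == {"Background": 0, "Leaves young": 0, "Leaves old": 100, "Grape": 0}
        assert cc.total == 100

    def test_matches_histogram_oracle(self, rng, registry):
        labels = rng.integers(0, 4, size=(33, 21)).astype(np.int32)
        cc = count_pixels(LabelImage(labels, registry))
        for k, name in enumerate(registry.names):
            assert cc.counts[name] == int((labels == k).sum())
        assert sum(cc.counts.values()) == cc.total == labels.size

    def test_grape_fraction_of_validation_roi(self, registry):
        """648 grape pixels out of a 30x30 ROI is a 72% grape share."""
        labels = np.zeros((30, 30), dtype=np.int32)
        labels.ravel()[:648] = 3
        cc = count_pixels(LabelImage(labels, registry))
        assert cc.counts["Grape"] / cc.total == pytest.approx(0.72)

    def test_roi_restricts_the_tally(self, registry):
        labels = np.full((10, 10), -1, dtype=np.int32)
        labels[2:6, 2:7] = 1
        cc = count_pixels(LabelImage(labels, registry, roi=(2, 6, 2, 7)))
        assert cc.total == 20
        assert cc.counts["Leaves young"] == 20


class TestAggregation:
    def test_leaf_grades_added(self, registry):
        cc = ClassCounts("x", {"Leaves young": 10, "Leaves old": 20, "Grape": 5}, 35)
        assert aggregate_leaf_count(cc, registry) == 30
        assert grape_count(cc, registry) == 5

    def test_single_merged_leaf_class(self):
        reg = ClassRegistry(
            [
                exact_class("Background", (235, 235, 235), roles=("background",)),
                exact_class("Leaves", (80, 140, 60), roles=("leaf",)),
            ]
        )
        assert aggregate_leaf_count(ClassCounts("x", {"Leaves": 42}, 42), reg) == 42

    def test_zero_leaf_pixels(self, registry):
        assert aggregate_leaf_count(ClassCounts("x", {}, 0), registry) == 0

    def test_no_leaf_role_errors(self):
        reg = ClassRegistry(
            [exact_class("a", (0, 0, 0)), exact_class("b", (9, 9, 9))]
        )
        with pytest.raises(ValueError, match="leaf"):
            aggregate_leaf_count(ClassCounts("x", {}, 0), reg)


class TestSplit:
    def test_thirty_records_split_twenty_ten(self):
        records = list(range(30))
        train, val = split_train_validation(records, 2 / 3, seed=1)
        assert len(train) == 20 and len(val) == 10
        assert sorted(train + val) == records

    def test_seventy_records_split_forty_seven(self):
        train, val = split_train_validation(list(range(70)), 2 / 3, seed=0)
        assert len(train) == 47 and len(val) == 23

    def test_same_seed_same_partition(self):
        records = list(range(12))
        assert split_train_validation(records, 0.5, seed=9) == split_train_validation(
            records, 0.5, seed=9
        )

    def test_stratified_split_by_stage(self):
        records = [(i, s) for s in ("I0", "I2", "I4") for i in range(9)]
        stages = [s for _, s in records]
        train, val = split_train_validation(records, 2 / 3, seed=4, stages=stages)
        for stage in ("I0", "I2", "I4"):
            assert sum(1 for _, s in train if s == stage) == 6

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            split_train_validation([1, 2], 0.5, seed=0)


class TestFitLinear:
    def test_noiseless_line_recovered_exactly(self):
        pts = [(x, 2 * x + 1) for x in range(5)]
        model = fit_linear(pts)
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(1.0)
        assert model.r2_train == pytest.approx(1.0)

    def test_hand_least_squares(self):
        model = fit_linear([(0, 0), (1, 1), (2, 0)])
        assert model.slope == pytest.approx(0.0)
        assert model.intercept == pytest.approx(1 / 3)

    def test_degenerate_predictor(self):
        with pytest.raises(ValueError, match="degenerate predictor"):
            fit_linear([(5, 0), (5, 1), (5, 2)])

    def test_parameter_recovery_under_noise(self):
        """Slope and intercept recovered within 5% at n=200, sd = 0.1 range."""
        # intercept ~the size of the response range: the 5% tolerance is then
        # ~4 standard errors wide rather than a coin flip
        rng = np.random.default_rng(77)
        a, b = 0.5, 60.0
        x = rng.uniform(0, 100, size=200)
        y = a * x + b + rng.normal(0, 0.1 * np.ptp(a * x + b), size=200)
        model = fit_linear(list(zip(x, y)))
        assert model.slope == pytest.approx(a, rel=0.05)
        assert model.intercept == pytest.approx(b, rel=0.05)


class TestEvaluate:
    def test_perfect_predictions(self):
        model = CalibrationModel(slope=1.0, intercept=0.0)
        report = evaluate(model, [(0, 0), (1, 1), (2, 2)])
        assert report.r2 == pytest.approx(1.0)
        assert report.rmse == pytest.approx(0.0)

    def test_uniform_offset_keeps_r2_but_not_rmse(self):
        model = CalibrationModel(slope=1.0, intercept=1.0)  # predicts obs + 1
        report = evaluate(model, [(0, 0), (1, 1), (2, 2), (3, 3)])
        assert report.r2 == pytest.approx(1.0)
        assert report.rmse == pytest.approx(1.0)
        assert report.r2_one_to_one < 1.0  # the 1 - SSE/SST convention is hit

    def test_two_points_minimal(self):
        report = evaluate(CalibrationModel(1.0, 0.0), [(0, 0), (1, 2)])
        assert report.n == 2

    def test_constant_observed_flagged(self):
        report = evaluate(CalibrationModel(1.0, 0.0), [(0, 5), (1, 5), (2, 5)])
        assert report.degenerate
        assert np.isnan(report.r2)
        assert report.rmse > 0


class TestResultsCSV:
    def test_seven_by_seven_rows(self, tmp_path):
        counts = [
            ClassCounts(f"img{i}", {f"c{k}": k + i for k in range(7)}, sum(k + i for k in range(7)))
            for i in range(7)
        ]
        path = tmp_path / "counts.csv"
        write_results(counts, path)
        frame = pd.read_csv(path)
        assert len(frame) == 49
        assert list(frame.columns) == ["image_id", "class", "pixel_count", "fraction_of_total"]

    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "counts.csv"
        write_results([], path)
        assert len(pd.read_csv(path)) == 0

    def test_roundtrip_counts_exact(self, tmp_path, rng):
        counts = [
            ClassCounts(f"img{i}", {f"c{k}": int(rng.integers(0, 10000)) for k in range(4)}, 0)
            for i in range(3)
        ]
        for cc in counts:
            cc.total = sum(cc.counts.values())
        path = tmp_path / "counts.csv"
        write_results(counts, path)
        loaded = read_results(path)
        assert [cc.counts for cc in loaded] == [cc.counts for cc in counts]

    def test_model_json_roundtrip(self, tmp_path):
        model = CalibrationModel(0.5, 1.25, "yield_kg", "grape_pixels", 20, 0.9)
        path = tmp_path / "model.json"
        model.to_json(path)
        assert CalibrationModel.from_json(path) == model


class TestRecordsFromTables:
    def test_join_and_aggregate(self, registry):
        counts = [
            ClassCounts("a", {"Leaves young": 10, "Leaves old": 5, "Grape": 7}, 22),
            ClassCounts("b", {"Leaves young": 1, "Leaves old": 2, "Grape": 3}, 6),
        ]
        measurements = pd.DataFrame(
            {"image_id": ["a", "b"], "leaf_area_m2": [1.5, 0.5], "yield_kg": [2.0, 1.0]}
        )
        leaf = records_from_tables(counts, measurements, registry, "leaf_pixels", "leaf_area_m2")
        assert leaf == [("a", 15.0, 1.5), ("b", 3.0, 0.5)]
        grape = records_from_tables(counts, measurements, registry, "grape_pixels", "yield_kg")
        assert grape == [("a", 7.0, 2.0), ("b", 3.0, 1.0)]
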