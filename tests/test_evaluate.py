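"""Stratified splitting, detection metrics, and the benchmark grid."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fallcnn.evaluate import (
    SKIPPED,
    ConfusionCounts,
    cell_seed,
    compute_metrics,
    evaluate_results,
    run_benchmark,
    split_dataset,
)
from fallcnn.model import TrainConfig
from fallcnn.preprocess import SMV, TRIAXIAL, WindowTooLongError, extract_window
from fallcnn.trace_io import ADL, FALL
from fallcnn.synthetic import SyntheticConfig, generate_dataset

from test_network import TestPredict


class TestSplit:
    def test_ratios_and_stratification_on_1000(self):
        labels = [ADL] * 600 + [FALL] * 400
        split = split_dataset(labels, seed=3)
        sizes = tuple(map(len, (split.train_ids, split.val_ids, split.test_ids)))
        assert sizes == (600, 200, 200)
        for ids, n_adl, n_fall in [(split.train_ids, 360, 240),
                                   (split.val_ids, 120, 80),
                                   (split.test_ids, 120, 80)]:
            counts = [sum(1 for i in ids if labels[i] == c) for c in (ADL, FALL)]
            assert abs(counts[0] - n_adl) <= 1
            assert abs(counts[1] - n_fall) <= 1

    def test_same_seed_identical(self):
        labels = [ADL] * 30 + [FALL] * 20
        assert split_dataset(labels, seed=9) == split_dataset(labels, seed=9)

    def test_different_seeds_differ(self):
        labels = [ADL] * 600 + [FALL] * 400
        assert split_dataset(labels, seed=1) != split_dataset(labels, seed=2)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="FALL"):
            split_dataset([ADL] * 20 + [FALL] * 4)

    @given(n_adl=st.integers(5, 500), n_fall=st.integers(5, 500),
           seed=st.integers(0, 10))
    @settings(max_examples=60, deadline=None)
    def test_partition_and_proportions_property(self, n_adl, n_fall, seed):
        labels = [ADL] * n_adl + [FALL] * n_fall
        split = split_dataset(labels, seed=seed)
        all_ids = sorted(split.train_ids + split.val_ids + split.test_ids)
        assert all_ids == list(range(len(labels)))  # disjoint cover
        for ids, ratio in zip((split.train_ids, split.val_ids, split.test_ids),
                              (0.6, 0.2, 0.2)):
            for cls, n_cls in ((ADL, n_adl), (FALL, n_fall)):
                got = sum(1 for i in ids if labels[i] == cls)
                assert abs(got - ratio * n_cls) <= 1


class TestMetrics:
    @pytest.mark.parametrize("counts,expected", [
        (ConfusionCounts(tp=10, fn=0, tn=10, fp=0), (100.0, 100.0, 100.0)),
        (ConfusionCounts(tp=0, fn=10, tn=10, fp=0), (0.0, 100.0, 50.0)),
        (ConfusionCounts(tp=45, fn=5, tn=90, fp=10), (90.0, 90.0, 90.0)),
    ])
    def test_reference_tables(self, counts, expected):
        m = compute_metrics(counts)
        assert (m.sensitivity, m.specificity, m.accuracy) == pytest.approx(expected)

    def test_empty_class_identified(self):
        with pytest.raises(ValueError, match="TP\\+FN"):
            compute_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        with pytest.raises(ValueError, match="TN\\+FP"):
            compute_metrics(ConfusionCounts(tp=5, fn=5, tn=0, fp=0))

    def test_matches_hand_arithmetic_and_identity(self, rng):
        # independent recomputation on random confusion tables, plus the
        # algebraic identity Acc == (Se*P + Sp*N) / (P + N)
        for _ in range(200):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 500, size=4))
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = compute_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            assert m.sensitivity == pytest.approx(100 * tp / (fn + tp), abs=1e-12)
            assert m.specificity == pytest.approx(100 * tn / (fp + tn), abs=1e-12)
            assert m.accuracy == pytest.approx(
                100 * (tp + tn) / (tp + tn + fp + fn), abs=1e-12)
            p, n = tp + fn, tn + fp
            assert m.accuracy == pytest.approx(
                (m.sensitivity * p + m.specificity * n) / (p + n), abs=1e-9)
            assert min(m.sensitivity, m.specificity) <= m.accuracy \
                <= max(m.sensitivity, m.specificity)


class TestEvaluateModel:
    def test_always_fall_predictor_on_balanced_set(self, rng):
        res = TestPredict().untrained_results()  # zero head: always FALL
        windows = rng.normal(size=(20, 130))
        labels = [FALL] * 10 + [ADL] * 10
        counts, metrics = evaluate_results(res, windows, labels)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (10, 0, 10, 0)
        assert (metrics.sensitivity, metrics.specificity, metrics.accuracy) \
            == (100.0, 0.0, 50.0)

    def test_counts_conserved(self, rng):
        res = TestPredict().untrained_results()
        windows = rng.normal(size=(17, 130))
        labels = [FALL] * 9 + [ADL] * 8
        counts, _ = evaluate_results(res, windows, labels)
        assert counts.total == 17

    def test_empty_test_set_rejected(self):
        res = TestPredict().untrained_results()
        with pytest.raises(ValueError, match="empty"):
            evaluate_results(res, np.empty((0, 130)), [])


FAST_TC = TrainConfig(max_epochs=3)


class TestBenchmark:
    def test_grid_completeness_and_widths(self, small_dataset):
        traces, _ = small_dataset  # 25 Hz
        grid = run_benchmark([], seed=1, traces_by_dataset={"a": traces},
                             train_config=FAST_TC)
        assert len(grid.cells) == 4 * 2
        keys = {(hw, var) for (_, hw, var) in grid.cells}
        assert keys == {(hw, v) for hw in (0.5, 1.0, 1.5, 2.5)
                        for v in (SMV, TRIAXIAL)}
        assert not grid.errors

    def test_skip_rule_matches_window_too_long(self):
        traces, _ = generate_dataset(SyntheticConfig(duration_s=1.0, seed=3,
                                                     n_adl=7, n_fall=7))
        grid = run_benchmark([], seed=1, traces_by_dataset={"short": traces},
                             train_config=FAST_TC)
        for (_, hw, var), cell in grid.cells.items():
            too_long = False
            try:
                for t in traces:
                    extract_window(t, hw, var)
            except WindowTooLongError:
                too_long = True
            assert (cell == SKIPPED) == too_long  # skipped iff window too long
        assert not grid.errors

    def test_same_seed_bitwise_identical_grid_csv(self, small_dataset, tmp_path):
        traces, _ = small_dataset
        outs = []
        for d in ("one", "two"):
            out = tmp_path / d
            run_benchmark([], seed=7, traces_by_dataset={"a": traces},
                          train_config=FAST_TC, out=out)
            outs.append((out / "grid_smv.csv").read_bytes()
                        + (out / "grid_triaxial.csv").read_bytes())
        assert outs[0] == outs[1]

    def test_cell_seeds_are_independent_and_stable(self):
        s1 = cell_seed(5, "ds", 2.5, SMV)
        assert s1 == cell_seed(5, "ds", 2.5, SMV)
        assert s1 != cell_seed(5, "ds", 2.5, TRIAXIAL)
        assert s1 != cell_seed(6, "ds", 2.5, SMV)
        assert 0 <= s1 < 2**31

    def test_grid_frame_layout(self, small_dataset):
        traces, _ = small_dataset
        grid = run_benchmark([], seed=1, traces_by_dataset={"a": traces},
                             half_widths=(0.5, 1.0), variants=(SMV,),
                             train_config=FAST_TC)
        frame = grid.to_frame(SMV)
        assert list(frame.index) == ["a"]
        assert [c for c in frame.columns] == [
            ("hw_0.5s", "Se"), ("hw_0.5s", "Sp"), ("hw_0.5s", "Acc"),
            ("hw_1s", "Se"), ("hw_1s", "Sp"), ("hw_1s", "Acc")]
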