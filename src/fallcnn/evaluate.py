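"""Dataset splitting, detection metrics, and the multi-dataset benchmark.

Evaluation follows the standard fall-detection protocol: each repository is
split 60/20/20 into train/validation/test subsets, stratified so the
fall/ADL proportions of the whole dataset are preserved in every subset; the
detector is trained and tested within one repository at that repository's own
sampling rate (never resampled); and quality is reported as

* sensitivity  Se  = 100·TP/(FN+TP)   — the fraction of falls detected,
* specificity  Sp  = 100·TN/(FP+TN)   — the fraction of ADLs not alarmed,
* accuracy     Acc = 100·(TP+TN)/total,

with FALL as the positive class.  The benchmark sweeps every combination of
dataset × window half-width (±0.5/±1/±1.5/±2.5 s) × input variant
(SMV/triaxial); a combination whose window exceeds some trace's length is
recorded as SKIPPED rather than evaluated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import FallDetectorCNN, FallDetectorResults, NetworkConfig, TrainConfig
from .preprocess import (
    SMV,
    TRIAXIAL,
    STANDARD_HALF_WIDTHS,
    WindowTooLongError,
    extract_window,
)
from .trace_io import ADL, FALL, DatasetManifest, InertialTrace, read_dataset

__all__ = [
    "SplitAssignment",
    "ConfusionCounts",
    "MetricsReport",
    "BenchmarkGrid",
    "SKIPPED",
    "split_dataset",
    "compute_metrics",
    "evaluate_results",
    "evaluate_model",
    "run_benchmark",
]

SPLIT_RATIOS = (0.6, 0.2, 0.2)
SKIPPED = "SKIPPED"   # window longer than some trace at this configuration
ERROR = "ERROR"       # unexpected per-cell failure; details in BenchmarkGrid.errors


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint train/validation/test index sets covering a dataset."""

    train_ids: tuple[int, ...]
    val_ids: tuple[int, ...]
    test_ids: tuple[int, ...]
    ratios: tuple[float, float, float] = SPLIT_RATIOS
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        union = set().union(*sets)
        if len(union) != total:
            raise ValueError("split subsets are not pairwise disjoint")


def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    """Integer allocation of ``n`` items to ratio targets; remainders go to
    the largest fractional parts (ties favour earlier subsets)."""
    exact = [n * r for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    short = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def split_dataset(
    labels: Sequence[str] | Sequence[InertialTrace],
    seed: int = 0,
    ratios: tuple[float, float, float] = SPLIT_RATIOS,
) -> SplitAssignment:
    """Stratified 60/20/20 random partition of trace indices.

    Accepts either a sequence of labels or of traces.  Each class is shuffled
    and allocated to the three subsets by largest-remainder rounding, so the
    per-class proportions of every subset match the whole dataset to within
    one trace.  Deterministic for a fixed seed.
    """
    labs = [t.label if isinstance(t, InertialTrace) else t for t in labels]
    rng = np.random.default_rng(seed)
    per_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labs):
        per_class.setdefault(lab, []).append(i)
    for lab, ids in per_class.items():
        if len(ids) < 5:
            raise ValueError(
                f"class {lab!r} has only {len(ids)} traces; at least 5 are "
                f"needed to populate train/validation/test subsets"
            )
    parts: list[list[int]] = [[], [], []]
    for lab in sorted(per_class):
        ids = np.array(per_class[lab])
        rng.shuffle(ids)
        counts = _largest_remainder(len(ids), ratios)
        start = 0
        for k, c in enumerate(counts):
            parts[k].extend(int(i) for i in ids[start:start + c])
            start += c
    return SplitAssignment(
        train_ids=tuple(sorted(parts[0])),
        val_ids=tuple(sorted(parts[1])),
        test_ids=tuple(sorted(parts[2])),
        ratios=ratios,
        seed=seed,
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix tallies with FALL as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity, specificity and accuracy as percentages in [0, 100]."""

    sensitivity: float
    specificity: float
    accuracy: float


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Se, Sp and Acc from confusion counts.

    Raises when a class is absent from the test set (its denominator would
    be zero and the corresponding metric undefined).
    """
    pos = counts.fn + counts.tp
    neg = counts.fp + counts.tn
    if pos == 0:
        raise ValueError("sensitivity undefined: no falls in the test set (TP+FN == 0)")
    if neg == 0:
        raise ValueError("specificity undefined: no ADLs in the test set (TN+FP == 0)")
    return MetricsReport(
        sensitivity=100.0 * counts.tp / pos,
        specificity=100.0 * counts.tn / neg,
        accuracy=100.0 * (counts.tp + counts.tn) / counts.total,
    )


def evaluate_results(
    results: FallDetectorResults, windows, labels=None
) -> tuple[ConfusionCounts, MetricsReport]:
    """Tally a fitted detector's predictions against true labels."""
    if labels is None:
        windows = list(windows)
        labels = [w.label for w in windows]
    if len(labels) == 0:
        raise ValueError("empty test set")
    predicted = results.predict(windows)
    tp = sum(1 for p, t in zip(predicted, labels) if p == FALL and t == FALL)
    tn = sum(1 for p, t in zip(predicted, labels) if p == ADL and t == ADL)
    fp = sum(1 for p, t in zip(predicted, labels) if p == FALL and t == ADL)
    fn = sum(1 for p, t in zip(predicted, labels) if p == ADL and t == FALL)
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return counts, compute_metrics(counts)


# statsmodels-style alias: evaluate a fitted model on held-out windows
evaluate_model = evaluate_results


@dataclass
class BenchmarkGrid:
    """Metrics per (dataset, half-width, variant) cell, mirroring the
    per-repository benchmark tables; inapplicable cells hold ``SKIPPED``."""

    cells: dict[tuple[str, float, str], MetricsReport | str] = field(default_factory=dict)
    cell_seeds: dict[tuple[str, float, str], int] = field(default_factory=dict)
    errors: dict[tuple[str, float, str], str] = field(default_factory=dict)

    def to_frame(self, variant: str) -> pd.DataFrame:
        """One variant's grid as rows = datasets, column groups = half-widths
        × (Se, Sp, Acc); skipped cells are empty."""
        datasets = sorted({k[0] for k in self.cells if k[2] == variant})
        half_widths = sorted({k[1] for k in self.cells if k[2] == variant})
        cols = pd.MultiIndex.from_product(
            [[f"hw_{h:g}s" for h in half_widths], ["Se", "Sp", "Acc"]]
        )
        frame = pd.DataFrame(index=datasets, columns=cols, dtype=object)
        frame.index.name = "dataset"
        for (ds, hw, var), cell in self.cells.items():
            if var != variant:
                continue
            key = f"hw_{hw:g}s"
            if isinstance(cell, MetricsReport):
                frame.loc[ds, (key, "Se")] = round(cell.sensitivity, 2)
                frame.loc[ds, (key, "Sp")] = round(cell.specificity, 2)
                frame.loc[ds, (key, "Acc")] = round(cell.accuracy, 2)
        return frame

    def write(self, out_dir: str | Path) -> None:
        """Grid CSVs (one per variant) plus a JSON log of skips and seeds."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for variant in (SMV, TRIAXIAL):
            if any(k[2] == variant for k in self.cells):
                self.to_frame(variant).to_csv(out_dir / f"grid_{variant.lower()}.csv")
        log = {
            "skipped": sorted(
                f"{ds}|hw={hw:g}|{var}" for (ds, hw, var), c in self.cells.items()
                if c == SKIPPED
            ),
            "errors": {f"{k[0]}|hw={k[1]:g}|{k[2]}": v for k, v in self.errors.items()},
            "cell_seeds": {
                f"{k[0]}|hw={k[1]:g}|{k[2]}": s for k, s in self.cell_seeds.items()
            },
        }
        (out_dir / "benchmark_log.json").write_text(json.dumps(log, indent=2) + "\n")


def cell_seed(master_seed: int, dataset_id: str, half_width_s: float, variant: str) -> int:
    """Independent, reproducible seed for one benchmark cell, derived by
    hashing the master seed with the cell coordinates."""
    key = f"{master_seed}|{dataset_id}|{half_width_s:g}|{variant}".encode()
    return int.from_bytes(hashlib.blake2s(key, digest_size=4).digest(), "big") % (2**31)


def _benchmark_cell(
    traces: list[InertialTrace],
    half_width_s: float,
    variant: str,
    seed: int,
    train_config: TrainConfig,
    net_config: NetworkConfig,
) -> MetricsReport | str:
    try:
        windows = [extract_window(t, half_width_s, variant) for t in traces]
    except WindowTooLongError:
        return SKIPPED
    split = split_dataset([t.label for t in traces], seed=seed)
    model = FallDetectorCNN(
        [windows[i] for i in split.train_ids],
        [windows[i] for i in split.val_ids],
        config=net_config,
        train_config=train_config,
    )
    results = model.fit(seed=seed)
    _, metrics = evaluate_results(results, [windows[i] for i in split.test_ids])
    return metrics


def run_benchmark(
    manifests: Sequence[tuple[DatasetManifest, str | Path]] | Sequence[dict],
    seed: int = 0,
    out: str | Path | None = None,
    half_widths: Sequence[float] = STANDARD_HALF_WIDTHS,
    variants: Sequence[str] = (SMV, TRIAXIAL),
    train_config: TrainConfig | None = None,
    net_config: NetworkConfig | None = None,
    traces_by_dataset: dict[str, list[InertialTrace]] | None = None,
) -> BenchmarkGrid:
    """Train and test the detector per dataset × half-width × variant.

    ``manifests`` is a sequence of ``(DatasetManifest, trace_root)`` pairs;
    alternatively pass ``traces_by_dataset`` with in-memory traces keyed by
    dataset id.  Every cell uses the dataset's own sampling rate (the input
    width therefore differs across datasets), a fresh network, and an
    independent seed derived from ``(seed, dataset, half-width, variant)``.
    Per-cell failures are recorded and do not abort the remaining cells.
    """
    train_config = train_config or TrainConfig()
    net_config = net_config or NetworkConfig()
    datasets: dict[str, list[InertialTrace]] = {}
    if traces_by_dataset is not None:
        datasets.update(traces_by_dataset)
    for entry in manifests or []:
        manifest, root = entry
        datasets[manifest.dataset_id] = read_dataset(root, manifest)

    grid = BenchmarkGrid()
    for ds_id in sorted(datasets):
        traces = datasets[ds_id]
        for hw in half_widths:
            for variant in variants:
                key = (ds_id, float(hw), variant)
                cseed = cell_seed(seed, ds_id, float(hw), variant)
                grid.cell_seeds[key] = cseed
                try:
                    grid.cells[key] = _benchmark_cell(
                        traces, float(hw), variant, cseed, train_config, net_config
                    )
                except Exception as exc:  # record, keep sweeping
                    grid.cells[key] = ERROR
                    grid.errors[key] = f"{type(exc).__name__}: {exc}"
    if out is not None:
        grid.write(out)
    return grid
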