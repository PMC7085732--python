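"""Reading and writing wearable accelerometer traces.

Public fall repositories (SisFall, UMAFall, MobiAct, ...) each use their own
file layout, units (g, m/s², raw ADC counts) and naming scheme.  This module
normalizes all of them to one canonical representation — an
:class:`InertialTrace` in m/s² — driven by a small declarative
:class:`DatasetManifest` instead of per-repository parser code.

Samples are never resampled, filtered or re-ordered: the classifier downstream
consumes raw sensor data, so a trace read here has exactly the sample count and
order of the file on disk, scaled by a single multiplicative unit conversion.
"""

from __future__ import annotations

import fnmatch
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ADL",
    "FALL",
    "InertialTrace",
    "DatasetManifest",
    "ManifestError",
    "TraceFormatError",
    "read_manifest",
    "read_trace",
    "write_trace",
]

#: The two movement classes of the binary detection task.
ADL = "ADL"
FALL = "FALL"
_LABELS = (ADL, FALL)


class ManifestError(ValueError):
    """A dataset manifest is missing a field or violates an invariant."""


class TraceFormatError(ValueError):
    """A trace file cannot be parsed under the active manifest."""


@dataclass(frozen=True)
class InertialTrace:
    """One recorded movement: triaxial acceleration in m/s² at a fixed rate.

    Parameters
    ----------
    samples : ndarray, shape (N, 3)
        Acceleration (Ax, Ay, Az) per sample, in m/s².
    fs : float
        Sampling rate in Hz; strictly positive.
    label : str
        ``"ADL"`` or ``"FALL"``.
    subject_id, activity_code, dataset_id : str
        Opaque provenance identifiers.
    """

    samples: np.ndarray
    fs: float
    label: str
    subject_id: str = ""
    activity_code: str = ""
    dataset_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"samples must have shape (N, 3), got {arr.shape}")
        if arr.shape[0] < 1:
            raise ValueError("trace must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ValueError("trace contains non-finite acceleration values")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}, got {self.label!r}")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration_s(self) -> float:
        """Trace duration in seconds, (N - 1) / fs."""
        return (len(self) - 1) / self.fs


@dataclass(frozen=True)
class DatasetManifest:
    """Declarative description of how to ingest one repository's files.

    ``unit_scale`` multiplies raw file values into m/s² (e.g. 9.81 for data
    stored in g, or the ADC count-to-physical factor for integer recordings).
    ``label_rule`` maps an activity code — the first ``_``-separated token of
    the file stem, or a unique prefix of it — to a class label.
    """

    dataset_id: str
    fs_nominal: float
    unit_scale: float
    axis_columns: Mapping[str, str | int] = field(
        default_factory=lambda: {"x": "ax", "y": "ay", "z": "az"}
    )
    label_rule: Mapping[str, str] = field(default_factory=dict)
    trace_glob: str = "*.csv"
    delimiter: str = ","
    has_header: bool = True

    def __post_init__(self) -> None:
        if not (self.fs_nominal > 0):
            raise ManifestError(f"fs_nominal must be positive, got {self.fs_nominal}")
        if not (self.unit_scale > 0):
            raise ManifestError(f"unit_scale must be positive, got {self.unit_scale}")
        if set(self.axis_columns) != {"x", "y", "z"}:
            raise ManifestError(
                f"axis_columns must name exactly x, y, z; got {sorted(self.axis_columns)}"
            )
        if len(set(self.axis_columns.values())) != 3:
            raise ManifestError("axis_columns must reference three distinct columns")
        for code, label in self.label_rule.items():
            if label not in _LABELS:
                raise ManifestError(
                    f"label_rule maps {code!r} to {label!r}; labels must be in {_LABELS}"
                )

    def label_for(self, path: str | Path) -> str:
        """Resolve the class label of a trace file from its name.

        The first ``_``-separated token of the stem is matched exactly against
        the rule's codes; failing that, a unique code prefix of the stem is
        accepted.  Ambiguous or absent matches raise :class:`ManifestError`.
        """
        stem = Path(path).stem
        token = stem.split("_")[0]
        if token in self.label_rule:
            return self.label_rule[token]
        hits = [c for c in self.label_rule if stem.startswith(c)]
        if len(hits) == 1:
            return self.label_rule[hits[0]]
        if len(hits) > 1:
            raise ManifestError(f"label_rule matches {stem!r} ambiguously: {sorted(hits)}")
        raise ManifestError(f"label_rule does not resolve a label for {stem!r}")

    def resolve_traces(self, root: str | Path) -> list[Path]:
        """All files under ``root`` matched by ``trace_glob``, sorted by name."""
        root = Path(root)
        return sorted(p for p in root.rglob("*") if fnmatch.fnmatch(p.name, self.trace_glob))


_REQUIRED_FIELDS = ("dataset_id", "fs_nominal", "unit_scale")


def read_manifest(path: str | Path) -> DatasetManifest:
    """Load and validate a dataset manifest from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ManifestError(f"manifest {path} is not a mapping")
    for name in _REQUIRED_FIELDS:
        if name not in raw:
            raise ManifestError(f"manifest {path} is missing required field {name!r}")
    known = {
        "dataset_id", "fs_nominal", "unit_scale", "axis_columns",
        "label_rule", "trace_glob", "delimiter", "has_header",
    }
    unknown = set(raw) - known
    if unknown:
        raise ManifestError(f"manifest {path} has unknown fields {sorted(unknown)}")
    return DatasetManifest(**raw)


def read_trace(path: str | Path, manifest: DatasetManifest) -> InertialTrace:
    """Parse one delimited-text trace file into canonical units.

    Values equal the file's raw values times ``manifest.unit_scale``, in file
    order; the sampling rate is the manifest's nominal constant.  No
    resampling is ever applied.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path,
            sep=manifest.delimiter,
            header=0 if manifest.has_header else None,
            skipinitialspace=True,
        )
    except pd.errors.EmptyDataError:
        raise TraceFormatError(f"{path}: empty trace file") from None
    if frame.shape[0] == 0:
        raise TraceFormatError(f"{path}: empty trace file")

    cols = []
    for axis in ("x", "y", "z"):
        sel = manifest.axis_columns[axis]
        if isinstance(sel, int):
            if sel >= frame.shape[1]:
                raise TraceFormatError(
                    f"{path}: column index {sel} for axis {axis} out of range "
                    f"({frame.shape[1]} columns)"
                )
            col = frame.iloc[:, sel]
        else:
            if sel not in frame.columns:
                raise TraceFormatError(f"{path}: missing column {sel!r} for axis {axis}")
            col = frame[sel]
        numeric = pd.to_numeric(col, errors="coerce")
        bad = numeric.index[numeric.isna() & col.notna()]
        if len(bad) > 0:
            raise TraceFormatError(
                f"{path}: non-numeric value in axis {axis} at data row {int(bad[0])}"
            )
        if numeric.isna().any():
            row = int(numeric.index[numeric.isna()][0])
            raise TraceFormatError(f"{path}: missing value in axis {axis} at data row {row}")
        cols.append(numeric.to_numpy(dtype=float))

    samples = np.column_stack(cols) * manifest.unit_scale
    meta = _read_sidecar(path)
    label = meta.get("label") if meta else None
    if label is None:
        label = manifest.label_for(path)
    return InertialTrace(
        samples=samples,
        fs=manifest.fs_nominal,
        label=label,
        subject_id=meta.get("subject_id", "") if meta else "",
        activity_code=meta.get("activity_code", "") if meta else "",
        dataset_id=manifest.dataset_id,
    )


def write_trace(trace: InertialTrace, path: str | Path) -> Path:
    """Write a trace as a canonical CSV plus a JSON metadata sidecar.

    The CSV has a header row ``ax,ay,az`` and one sample per row in m/s²;
    reading it back with an identity manifest reproduces the trace to
    numeric-text precision (values are printed with 17 significant digits).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        fh.write("ax,ay,az\n")
        for ax, ay, az in trace.samples:
            fh.write(f"{ax:.17g},{ay:.17g},{az:.17g}\n")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "label": trace.label,
                "fs": trace.fs,
                "subject_id": trace.subject_id,
                "activity_code": trace.activity_code,
                "dataset_id": trace.dataset_id,
            },
            indent=0,
            sort_keys=True,
        )
        + "\n"
    )
    return path


def _read_sidecar(path: Path) -> dict | None:
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return None


def read_dataset(
    root: str | Path, manifest: DatasetManifest
) -> list[InertialTrace]:
    """Read every trace the manifest resolves under ``root``."""
    paths = manifest.resolve_traces(root)
    return [read_trace(p, manifest) for p in paths]
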