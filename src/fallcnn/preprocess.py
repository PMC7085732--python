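"""Peak-centered observation-window extraction.

A fall produces a sharp spike of the acceleration magnitude at ground impact,
so the classifier looks only at a fixed-duration window centered on the global
magnitude peak of each trace.  Three primitives implement that front end:

* :func:`compute_smv` — the Signal Magnitude Vector, the per-sample Euclidean
  norm of the three acceleration components;
* :func:`locate_peak` — the index and value of the SMV maximum;
* :func:`extract_window` — a symmetric window of half-width ``T_W/2`` seconds
  around the peak, in either the SMV variant (one magnitude series) or the
  TRIAXIAL variant (the three raw axis series, concatenated per axis).

With ``n = 2·floor(half_width_s·fs) + 1`` samples per axis, a 200 Hz trace at
half-width 2.5 s yields 1001 features (SMV) or 3003 (triaxial).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace_io import InertialTrace

__all__ = [
    "SMV",
    "TRIAXIAL",
    "ObservationWindow",
    "WindowTooLongError",
    "compute_smv",
    "locate_peak",
    "window_samples_per_axis",
    "window_width",
    "extract_window",
]

SMV = "SMV"
TRIAXIAL = "TRIAXIAL"
_VARIANTS = (SMV, TRIAXIAL)

#: The four half-widths (seconds) of the benchmark protocol.
STANDARD_HALF_WIDTHS = (0.5, 1.0, 1.5, 2.5)


class WindowTooLongError(ValueError):
    """The requested window holds more samples than the trace provides."""


@dataclass(frozen=True)
class ObservationWindow:
    """Fixed-length classifier input extracted around the acceleration peak.

    ``values`` is the flat feature vector: the SMV series for the SMV variant,
    or the concatenation ``[Ax-block, Ay-block, Az-block]`` for the TRIAXIAL
    variant (each block ``n`` samples, temporally contiguous per axis).
    """

    values: np.ndarray
    variant: str
    half_width_s: float
    fs: float
    peak_index: int
    label: str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}, got {self.variant!r}")
        n = window_samples_per_axis(self.half_width_s, self.fs)
        expected = n if self.variant == SMV else 3 * n
        if vals.shape != (expected,):
            raise ValueError(
                f"{self.variant} window at half-width {self.half_width_s}s, "
                f"fs {self.fs}Hz must have {expected} values, got {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("window contains non-finite values")
        if self.variant == SMV and np.any(vals < 0):
            raise ValueError("SMV window values must be non-negative")
        object.__setattr__(self, "values", vals)

    @property
    def width(self) -> int:
        """Number of input features (the 1 × width 'image' fed to the CNN)."""
        return int(self.values.shape[0])


def compute_smv(trace: InertialTrace | np.ndarray) -> np.ndarray:
    """Signal Magnitude Vector: ``sqrt(Ax² + Ay² + Az²)`` per sample, m/s²."""
    samples = trace.samples if isinstance(trace, InertialTrace) else np.asarray(trace, float)
    return np.sqrt(np.sum(samples * samples, axis=1))


def locate_peak(smv: np.ndarray) -> tuple[int, float]:
    """Index and value of the SMV maximum; earliest index on ties, 0-based."""
    smv = np.asarray(smv, dtype=float)
    if smv.size == 0:
        raise ValueError("cannot locate the peak of an empty sequence")
    idx = int(np.argmax(smv))  # np.argmax returns the first maximum
    return idx, float(smv[idx])


def window_samples_per_axis(half_width_s: float, fs: float) -> int:
    """Per-axis sample count ``n = 2·floor(half_width_s·fs) + 1``."""
    if half_width_s <= 0 or fs <= 0:
        raise ValueError("half_width_s and fs must be positive")
    return 2 * int(np.floor(half_width_s * fs)) + 1


def window_width(half_width_s: float, fs: float, variant: str = SMV) -> int:
    """Total feature count of a window: ``n`` for SMV, ``3n`` for TRIAXIAL."""
    n = window_samples_per_axis(half_width_s, fs)
    if variant == SMV:
        return n
    if variant == TRIAXIAL:
        return 3 * n
    raise ValueError(f"variant must be one of {_VARIANTS}, got {variant!r}")


def _centered_indices(peak: int, n_trace: int, n_window: int) -> np.ndarray:
    """Source indices of a window centered on ``peak``, edges replicated.

    When the peak sits within half a window of either trace end, out-of-range
    indices are clipped to the boundary sample (replication, not zero-fill:
    zero acceleration looks like free fall and would fabricate a fall
    signature).
    """
    half = (n_window - 1) // 2
    idx = np.arange(peak - half, peak + half + 1)
    return np.clip(idx, 0, n_trace - 1)


def extract_window(
    trace: InertialTrace,
    half_width_s: float,
    variant: str = SMV,
) -> ObservationWindow:
    """Extract the peak-centered observation window from a trace.

    Raises :class:`WindowTooLongError` when the window would hold more samples
    than the trace — the benchmark records such configurations as skipped.
    """
    n = window_samples_per_axis(half_width_s, fs=trace.fs)
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}, got {variant!r}")
    if n > len(trace):
        raise WindowTooLongError(
            f"window of {n} samples (half-width {half_width_s}s at {trace.fs}Hz) "
            f"exceeds trace length {len(trace)}"
        )
    smv = compute_smv(trace)
    peak, _ = locate_peak(smv)
    idx = _centered_indices(peak, len(trace), n)
    if variant == SMV:
        values = smv[idx]
    else:
        values = np.concatenate(
            [trace.samples[idx, 0], trace.samples[idx, 1], trace.samples[idx, 2]]
        )
    return ObservationWindow(
        values=values,
        variant=variant,
        half_width_s=half_width_s,
        fs=trace.fs,
        peak_index=peak,
        label=trace.label,
    )
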