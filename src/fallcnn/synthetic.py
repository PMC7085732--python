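"""Synthetic triaxial accelerometer traces with ADL and fall dynamics.

Real fall repositories record waist-worn accelerometry of daily activities
and (mimicked) falls.  This generator reproduces the signal structure the
detector relies on, so the whole pipeline is testable without downloading any
repository:

* **ADL traces** — periodic locomotion (a gait-frequency sinusoid superposed
  on the 1 g gravity vector) or a postural transition (a slow re-orientation
  of gravity with a small magnitude bump), plus Gaussian sensor noise.  Their
  magnitude never approaches zero and never reaches fall-impact levels.
* **Fall traces** — in order: a quiet/walking prefix near 1 g, a free-fall
  dip where the magnitude drops toward zero, an impact spike that is the
  trace's global magnitude maximum, and post-impact rest at 1 g with a
  rotated orientation (the subject lies on the ground), plus noise.

Defaults produce strongly separable classes; ``SyntheticConfig.hard()``
narrows the margins (weak impacts, more noise) to exercise
imperfect-classifier code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import yaml

from .trace_io import ADL, FALL, DatasetManifest, InertialTrace, write_trace

__all__ = [
    "G0",
    "SyntheticConfig",
    "generate_adl_trace",
    "generate_fall_trace",
    "generate_dataset",
]

#: Standard gravity, m/s² per g.
G0 = 9.81

#: Minimum fall-trace duration: prefix + free fall + impact + rest must fit.
MIN_FALL_DURATION_S = 1.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters (accelerations in g, durations in seconds)."""

    fs: float = 50.0
    duration_s: float = 10.0
    n_adl: int = 60
    n_fall: int = 40
    impact_peak_g: float = 4.0
    freefall_floor_g: float = 0.2
    freefall_duration_s: float = 0.4
    gait_frequency_hz: float = 2.0
    noise_sd_g: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.impact_peak_g > 1.0 > self.freefall_floor_g >= 0.0):
            raise ValueError(
                "need impact_peak_g > 1 g > freefall_floor_g >= 0; got "
                f"impact {self.impact_peak_g} g, floor {self.freefall_floor_g} g"
            )
        if self.fs <= 0 or self.duration_s <= 0 or self.freefall_duration_s <= 0:
            raise ValueError("fs and durations must be positive")
        if self.n_adl < 0 or self.n_fall < 0:
            raise ValueError("trace counts must be non-negative")

    @classmethod
    def hard(cls, **overrides) -> "SyntheticConfig":
        """Low-margin regime: weak impacts (1.8 g) and strong noise (0.15 g)."""
        base = cls(impact_peak_g=1.8, noise_sd_g=0.15)
        return replace(base, **overrides)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perpendicular(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    v -= v.dot(u) * u
    return v / np.linalg.norm(v)


def _n_samples(cfg: SyntheticConfig) -> int:
    # inclusive time grid 0..duration, so a 1 s trace at 50 Hz has 51 samples
    return int(round(cfg.fs * cfg.duration_s)) + 1


def _walking(t: np.ndarray, u: np.ndarray, w: np.ndarray,
             freq: float, amp_g: float, phase: float) -> np.ndarray:
    """Gait dynamics: vertical bobbing along gravity plus lateral sway."""
    vertical = (1.0 + amp_g * np.sin(2 * np.pi * freq * t + phase))
    lateral = 0.4 * amp_g * np.cos(2 * np.pi * freq * t + phase)
    return G0 * (vertical[:, None] * u + lateral[:, None] * w)


def generate_adl_trace(
    cfg: SyntheticConfig,
    rng=None,
    kind: str = "auto",
    trace_meta: dict | None = None,
) -> InertialTrace:
    """One activity-of-daily-living trace.

    ``kind`` selects ``"walking"`` (periodic locomotion), ``"transition"``
    (postural change) or ``"auto"`` (random choice).  The magnitude stays well
    clear of both the free-fall floor and fall-impact levels.
    """
    rng = _as_rng(rng if rng is not None else cfg.seed)
    if kind not in ("auto", "walking", "transition"):
        raise ValueError(f"unknown ADL kind {kind!r}")
    if kind == "auto":
        kind = "walking" if rng.random() < 0.7 else "transition"
    n = _n_samples(cfg)
    t = np.arange(n) / cfg.fs
    u = _unit_vector(rng)
    w = _perpendicular(u, rng)
    amp = min(0.25, 0.25 * (cfg.impact_peak_g - 1.0))
    phase = rng.uniform(0, 2 * np.pi)

    if kind == "walking":
        signal = _walking(t, u, w, cfg.gait_frequency_hz, amp, phase)
    else:
        # slow re-orientation of the gravity vector (sit-to-stand style)
        u2 = _unit_vector(rng)
        t0 = rng.uniform(0.2, 0.6) * cfg.duration_s
        width = max(0.5, 0.1 * cfg.duration_s)
        mix = 0.5 * (1 + np.tanh((t - t0) / (width / 2)))
        direction = (1 - mix)[:, None] * u + mix[:, None] * u2
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        bump = 1.0 + amp * np.exp(-0.5 * ((t - t0) / (width / 2)) ** 2)
        signal = G0 * bump[:, None] * direction

    signal = signal + rng.normal(0.0, cfg.noise_sd_g * G0, size=(n, 3))
    meta = trace_meta or {}
    return InertialTrace(samples=signal, fs=cfg.fs, label=ADL, **meta)


def generate_fall_trace(
    cfg: SyntheticConfig,
    rng=None,
    trace_meta: dict | None = None,
) -> InertialTrace:
    """One fall trace: prefix ≈ 1 g, free-fall dip, impact spike (the global
    magnitude maximum), then post-impact rest with rotated orientation."""
    if cfg.duration_s < MIN_FALL_DURATION_S:
        raise ValueError(
            f"fall dynamics (free fall + impact + rest) need at least "
            f"{MIN_FALL_DURATION_S} s; got duration_s={cfg.duration_s}"
        )
    rng = _as_rng(rng if rng is not None else cfg.seed)
    n = _n_samples(cfg)
    t = np.arange(n) / cfg.fs
    u = _unit_vector(rng)          # upright orientation
    w = _perpendicular(u, rng)
    u2 = _unit_vector(rng)         # lying-on-the-ground orientation

    ff_dur = min(cfg.freefall_duration_s, 0.25 * cfg.duration_s)
    impact_dur = max(0.1, 3.0 / cfg.fs)
    # impact lands just past the middle so every window size stays centered
    t_impact = np.clip(0.55 * cfg.duration_s, ff_dur + 0.1,
                       cfg.duration_s - impact_dur - 0.1)
    t_ff = t_impact - ff_dur

    signal = np.empty((n, 3))
    pre = t < t_ff
    amp = min(0.15, 0.15 * (cfg.impact_peak_g - 1.0))
    phase = rng.uniform(0, 2 * np.pi)
    signal[pre] = _walking(t[pre], u, w, cfg.gait_frequency_hz, amp, phase)[:]

    ff = (t >= t_ff) & (t < t_impact)
    signal[ff] = G0 * cfg.freefall_floor_g * u

    post = t >= t_impact + impact_dur
    signal[post] = G0 * u2

    imp = (t >= t_impact) & (t < t_impact + impact_dur)
    peak_g = rng.normal(cfg.impact_peak_g, 0.08 * cfg.impact_peak_g)
    peak_g = max(peak_g, 1.2 * min(cfg.impact_peak_g, 2.0))
    direction = _unit_vector(rng)
    envelope = np.sin(np.pi * (t[imp] - t_impact) / impact_dur)
    # guarantee the sampled envelope actually attains the drawn peak
    if envelope.size:
        envelope /= max(envelope.max(), 1e-9)
    signal[imp] = G0 * peak_g * envelope[:, None] * direction

    signal = signal + rng.normal(0.0, cfg.noise_sd_g * G0, size=(n, 3))

    # the impact must carry the global magnitude maximum even after noise
    smv = np.sqrt((signal ** 2).sum(axis=1))
    imp_idx = np.flatnonzero(imp)
    if imp_idx.size and np.argmax(smv) not in imp_idx:
        # extremely rare under any sane noise level: re-assert the spike
        j = imp_idx[np.argmax(smv[imp_idx])]
        signal[j] = direction * (smv.max() * 1.05)

    meta = trace_meta or {}
    return InertialTrace(samples=signal, fs=cfg.fs, label=FALL, **meta)


def generate_dataset(
    cfg: SyntheticConfig,
    out_dir: str | Path | None = None,
) -> tuple[list[InertialTrace], DatasetManifest]:
    """A labeled collection of ``n_adl + n_fall`` traces plus its manifest.

    Per-trace seeds derive from ``cfg.seed``, so regeneration with the same
    configuration is byte-identical.  When ``out_dir`` is given, canonical
    CSV trace files and a ``manifest.yaml`` are written there.
    """
    if cfg.n_adl + cfg.n_fall < 10:
        raise ValueError("a dataset needs at least 10 traces in total")
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_adl + cfg.n_fall)
    dataset_id = f"synthetic-fs{cfg.fs:g}"
    traces: list[InertialTrace] = []
    for i in range(cfg.n_adl):
        traces.append(generate_adl_trace(
            cfg, np.random.default_rng(seeds[i]),
            trace_meta={"subject_id": f"S{i:03d}", "activity_code": f"D{i:03d}",
                        "dataset_id": dataset_id},
        ))
    for i in range(cfg.n_fall):
        traces.append(generate_fall_trace(
            cfg, np.random.default_rng(seeds[cfg.n_adl + i]),
            trace_meta={"subject_id": f"S{cfg.n_adl + i:03d}",
                        "activity_code": f"F{i:03d}", "dataset_id": dataset_id},
        ))
    manifest = DatasetManifest(
        dataset_id=dataset_id,
        fs_nominal=cfg.fs,
        unit_scale=1.0,
        label_rule={"D": ADL, "F": FALL},
        trace_glob="*.csv",
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for trace in traces:
            write_trace(trace, out_dir / f"{trace.activity_code}_{trace.subject_id}.csv")
        manifest_dict = {
            "dataset_id": manifest.dataset_id,
            "fs_nominal": manifest.fs_nominal,
            "unit_scale": manifest.unit_scale,
            "label_rule": dict(manifest.label_rule),
            "trace_glob": manifest.trace_glob,
        }
        (out_dir / "manifest.yaml").write_text(
            yaml.safe_dump(manifest_dict, sort_keys=True)
        )
    return traces, manifest
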