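"""Core data containers shared across the decoding pipeline.

All time quantities are seconds, all angles degrees, all rates Hz.
Containers validate their invariants on construction so that downstream
stages can assume well-formed data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "KinematicsSeries",
    "SpikeTrain",
    "ContinuousSignal",
    "FeatureSeries",
    "Normalization",
    "DecoderDataset",
]

_SPACING_TOL = 1e-9

JOINTS = ("hip", "knee", "ankle")


def _arr(x, dtype=float) -> np.ndarray:
    return np.asarray(x, dtype=dtype)


@dataclass
class KinematicsSeries:
    """Uniformly sampled hip/knee/ankle joint-angle trajectories."""

    times: np.ndarray
    hip: np.ndarray
    knee: np.ndarray
    ankle: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.times = _arr(self.times)
        self.hip = _arr(self.hip)
        self.knee = _arr(self.knee)
        self.ankle = _arr(self.ankle)
        self.rate = float(self.rate)
        n = self.times.size
        if n == 0:
            raise ValueError("KinematicsSeries must be non-empty")
        for name in JOINTS:
            a = getattr(self, name)
            if a.size != n:
                raise ValueError(f"{name} length {a.size} != times length {n}")
            if not np.all((a > 0.0) & (a <= 180.0)):
                raise ValueError(f"{name} angles must lie in (0, 180] degrees")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if n > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.rate)) > _SPACING_TOL:
                raise ValueError("time spacing inconsistent with rate")

    @property
    def angles(self) -> np.ndarray:
        """(n, 3) matrix with columns hip, knee, ankle."""
        return np.stack([self.hip, self.knee, self.ankle], axis=1)

    @property
    def t0(self) -> float:
        return float(self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) + 1.0 / self.rate

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class SpikeTrain:
    """Sorted spike event times for one unit; unit_id 0 is the multiunit pool."""

    times: np.ndarray
    unit_id: int
    duration: float

    def __post_init__(self) -> None:
        self.times = _arr(self.times)
        self.unit_id = int(self.unit_id)
        self.duration = float(self.duration)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] > self.duration:
                raise ValueError("spike times must lie in [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def mean_rate(self) -> float:
        return self.n_spikes / self.duration


@dataclass
class ContinuousSignal:
    """Uniformly sampled real-valued trace (raw/filtered voltage or feature)."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = _arr(self.samples)
        self.fs = float(self.fs)
        self.t0 = float(self.t0)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.size == 0:
            raise ValueError("samples must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass
class FeatureSeries:
    """A continuous feature stream derived from one spike train.

    ``kind`` is ``"fr"`` (smoothed firing rate, spikes/s, >= 0) or ``"isi"``
    (spline-resampled interspike intervals, seconds, > 0).
    """

    values: np.ndarray
    fs: float
    t0: float
    kind: str
    unit_id: int

    def __post_init__(self) -> None:
        self.values = _arr(self.values)
        self.fs = float(self.fs)
        self.t0 = float(self.t0)
        self.kind = str(self.kind).lower()
        self.unit_id = int(self.unit_id)
        if self.kind not in ("fr", "isi"):
            raise ValueError("kind must be 'fr' or 'isi'")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if self.kind == "fr" and np.any(self.values < 0):
            raise ValueError("FR values must be >= 0")
        if self.kind == "isi" and np.any(self.values <= 0):
            raise ValueError("ISI values must be > 0")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class Normalization:
    """Invertible per-column affine map ``z = (x - offset) / scale``."""

    offset: np.ndarray
    scale: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.offset = _arr(self.offset)
        self.scale = _arr(self.scale)
        self.columns = list(self.columns)
        if not (self.offset.size == self.scale.size == len(self.columns)):
            raise ValueError("normalization fields must have equal length")
        if np.any(self.scale == 0):
            raise ValueError("scale must be nonzero")

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.offset) / self.scale

    def invert(self, z: np.ndarray) -> np.ndarray:
        return z * self.scale + self.offset


@dataclass
class DecoderDataset:
    """Time-aligned lagged-feature inputs and joint-angle targets."""

    inputs: np.ndarray
    targets: np.ndarray
    times: np.ndarray
    fs: float
    lag_count: int
    normalization: Normalization
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.inputs = _arr(self.inputs)
        self.targets = _arr(self.targets)
        self.times = _arr(self.times)
        self.fs = float(self.fs)
        self.lag_count = int(self.lag_count)
        if self.inputs.ndim != 2 or self.targets.ndim != 2:
            raise ValueError("inputs and targets must be 2-D")
        if self.inputs.shape[0] != self.targets.shape[0]:
            raise ValueError("inputs and targets must have equal row counts")
        if self.times.size != self.inputs.shape[0]:
            raise ValueError("times must align with rows")
        if not np.all(np.isfinite(self.inputs)) or not np.all(
            np.isfinite(self.targets)
        ):
            raise ValueError("dataset entries must be finite")
        if self.inputs.shape[1] != len(self.normalization.columns):
            raise ValueError("normalization columns mismatch input width")

    @property
    def n_rows(self) -> int:
        return int(self.inputs.shape[0])

    @property
    def n_inputs(self) -> int:
        return int(self.inputs.shape[1])

    def raw_inputs(self) -> np.ndarray:
        """Undo the stored per-column normalization."""
        return self.normalization.invert(self.inputs)

    def slice_rows(self, start: int, stop: Optional[int] = None) -> "DecoderDataset":
        sl = slice(start, stop)
        return DecoderDataset(
            inputs=self.inputs[sl],
            targets=self.targets[sl],
            times=self.times[sl],
            fs=self.fs,
            lag_count=self.lag_count,
            normalization=self.normalization,
            meta=dict(self.meta),
        )


def concat_datasets(datasets: list[DecoderDataset]) -> DecoderDataset:
    """Concatenate row-compatible datasets (e.g. multiple trials)."""
    if not datasets:
        raise ValueError("no datasets to concatenate")
    first = datasets[0]
    for d in datasets[1:]:
        if d.normalization.columns != first.normalization.columns:
            raise ValueError("datasets have differing columns")
        if d.fs != first.fs or d.lag_count != first.lag_count:
            raise ValueError("datasets have differing fs/lag_count")
    return DecoderDataset(
        inputs=np.vstack([d.inputs for d in datasets]),
        targets=np.vstack([d.targets for d in datasets]),
        times=np.concatenate([d.times for d in datasets]),
        fs=first.fs,
        lag_count=first.lag_count,
        normalization=first.normalization,
        meta=dict(first.meta),
    )
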