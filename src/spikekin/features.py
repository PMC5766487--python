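"""Spike-train feature streams and decoder dataset assembly.

Two streams are produced per spike train: a sliding-window firing rate
(300 ms window, 50 ms hop -> 20 Hz) smoothed by a linear-phase FIR
low-pass, and the interspike-interval series resampled to the same 20 Hz
clock through a natural cubic spline.  ``build_dataset`` time-aligns the
streams with the (decimated) joint-angle targets and stacks lagged copies
into the decoder's input matrix.
"""
from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .core import (
    DecoderDataset,
    FeatureSeries,
    KinematicsSeries,
    Normalization,
    SpikeTrain,
)

__all__ = [
    "compute_fr",
    "smooth_fr",
    "fr_smoother_taps",
    "compute_isi",
    "build_dataset",
    "decimate_kinematics",
]

FR_WINDOW_S = 0.300
FR_HOP_S = 0.050  # 300 ms window slid with 250 ms overlap
FEATURE_RATE_HZ = 20.0

# The 10 Hz cutoff sits at the 20 Hz Nyquist; the transition band is an
# interpretation: passband edge 8 Hz, stopband edge 10 Hz.
FR_PASS_EDGE_HZ = 8.0
FR_STOP_EDGE_HZ = 10.0
FR_STOP_ATTEN_DB = 60.0

DEFAULT_LAG_COUNT = 2
_ZERO_VAR_TOL = 1e-12


def compute_fr(
    train: SpikeTrain,
    window_s: float = FR_WINDOW_S,
    hop_s: float = FR_HOP_S,
    span: Optional[tuple[float, float]] = None,
) -> FeatureSeries:
    """Causal sliding-window firing rate in spikes/s.

    The value at output time t is the spike count in (t - window_s, t]
    divided by window_s; output times run from span[0] to span[1] in hops
    of ``hop_s`` (span defaults to [0, duration]).
    """
    if not window_s > hop_s > 0:
        raise ValueError("need window_s > hop_s > 0")
    if window_s > train.duration:
        raise ValueError("window longer than the recording")
    t_start, t_end = span if span is not None else (0.0, train.duration)
    n = int(np.floor((t_end - t_start) / hop_s + 1e-9)) + 1
    fs_out = 1.0 / hop_s
    # same arithmetic as FeatureSeries.times so the grids agree bitwise
    t = t_start + np.arange(n) / fs_out
    hi = np.searchsorted(train.times, t + 1e-12, side="left")
    lo = np.searchsorted(train.times, t - window_s + 1e-12, side="left")
    counts = hi - lo
    return FeatureSeries(
        values=counts / window_s,
        fs=fs_out,
        t0=t_start,
        kind="fr",
        unit_id=train.unit_id,
    )


def fr_smoother_taps(fs: float = FEATURE_RATE_HZ) -> np.ndarray:
    """Kaiser-window FIR low-pass taps (8 Hz pass, 10 Hz stop, 60 dB)."""
    nyq = fs / 2.0
    width = (FR_STOP_EDGE_HZ - FR_PASS_EDGE_HZ) / nyq
    numtaps, beta = sps.kaiserord(FR_STOP_ATTEN_DB, width)
    numtaps |= 1  # odd length -> integer group delay
    cutoff = 0.5 * (FR_PASS_EDGE_HZ + FR_STOP_EDGE_HZ)
    return sps.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs)


def smooth_fr(fr: FeatureSeries) -> FeatureSeries:
    """Low-pass the FR stream; group delay compensated, negatives clipped."""
    if fr.kind != "fr":
        raise ValueError("smooth_fr expects an FR series")
    taps = fr_smoother_taps(fr.fs)
    if fr.values.size < taps.size:
        raise ValueError(
            f"series of length {fr.values.size} shorter than filter ({taps.size})"
        )
    half = (taps.size - 1) // 2
    padded = np.concatenate(
        [np.full(half, fr.values[0]), fr.values, np.full(half, fr.values[-1])]
    )
    out = np.convolve(padded, taps, mode="valid")
    return FeatureSeries(
        values=np.maximum(out, 0.0),
        fs=fr.fs,
        t0=fr.t0,
        kind="fr",
        unit_id=fr.unit_id,
    )


def compute_isi(
    train: SpikeTrain,
    fs_out: float = FEATURE_RATE_HZ,
    span: Optional[tuple[float, float]] = None,
) -> FeatureSeries:
    """Interspike-interval series resampled to a uniform clock.

    Knots sit at each spike time t_k (k >= 2) with value t_k - t_{k-1}; a
    natural cubic spline through the knots is evaluated on the uniform
    ``fs_out`` grid over ``span``; outside the knot range the nearest knot
    value is held (spline extrapolation diverges across silent gaps).
    """
    if train.n_spikes < 4:
        raise ValueError(
            f"unit {train.unit_id}: need >= 4 spikes for the ISI spline, "
            f"got {train.n_spikes}"
        )
    t_start, t_end = span if span is not None else (0.0, train.duration)
    knot_t = train.times[1:]
    knot_v = np.diff(train.times)
    spline = CubicSpline(knot_t, knot_v, bc_type="natural")
    n = int(np.floor((t_end - t_start) * fs_out + 1e-9)) + 1
    t = t_start + np.arange(n) / fs_out
    vals = spline(np.clip(t, knot_t[0], knot_t[-1]))
    # spline can undershoot between knots; ISI values must stay positive
    vals = np.maximum(vals, 1e-6)
    return FeatureSeries(
        values=vals, fs=fs_out, t0=t_start, kind="isi", unit_id=train.unit_id
    )


def decimate_kinematics(
    kin: KinematicsSeries, fs_out: float = FEATURE_RATE_HZ
) -> KinematicsSeries:
    """Anti-alias filter and decimate the 100 Hz angles to the feature rate."""
    ratio = kin.rate / fs_out
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError("kinematics rate must be an integer multiple of fs_out")
    if q == 1:
        return kin
    cols = []
    for name in ("hip", "knee", "ankle"):
        x = getattr(kin, name)
        y = sps.decimate(x, q, n=8, ftype="iir", zero_phase=True)
        cols.append(np.clip(y, 1e-9, 180.0))
    times = kin.times[::q][: cols[0].size]
    return KinematicsSeries(
        times=times, hip=cols[0], knee=cols[1], ankle=cols[2], rate=fs_out
    )


def _align_indices(features: Sequence[FeatureSeries], times: np.ndarray) -> np.ndarray:
    """Row indices of `times` covered by every feature grid (exact alignment)."""
    t_lo = max(f.t0 for f in features)
    t_hi = min(f.times[-1] for f in features)
    mask = (times >= t_lo - 1e-9) & (times <= t_hi + 1e-9)
    if not np.any(mask):
        raise ValueError("feature and kinematics time spans do not overlap")
    return np.flatnonzero(mask)


def build_dataset(
    features: Sequence[FeatureSeries],
    kin: KinematicsSeries,
    lag_count: int = DEFAULT_LAG_COUNT,
    normalization: Optional[Normalization] = None,
) -> DecoderDataset:
    """Assemble a time-aligned lagged-input / joint-angle-target dataset.

    Kinematics are decimated to the shared feature rate; each input row at
    time t holds the current and ``lag_count`` past samples of every
    feature, z-scored per column (statistics computed here unless an
    existing ``normalization`` — e.g. from the training portion — is
    supplied); rows with incomplete lag history are dropped.  Zero-variance
    columns are dropped with a warning.
    """
    if not features:
        raise ValueError("no feature series given")
    fs = features[0].fs
    for f in features:
        if abs(f.fs - fs) > 1e-9:
            raise ValueError("all feature series must share one rate")
    if lag_count < 0:
        raise ValueError("lag_count must be >= 0")

    kin20 = decimate_kinematics(kin, fs)
    rows = _align_indices(features, kin20.times)
    times = kin20.times[rows]
    targets = kin20.angles[rows]

    raw_cols, names = [], []
    for f in features:
        # feature sample index for each aligned timestamp
        idx = np.round((times - f.t0) * f.fs).astype(int)
        if np.any(np.abs(times - (f.t0 + idx / f.fs)) > 1e-6):
            raise ValueError("feature grid misaligned with kinematics grid")
        for lag in range(lag_count + 1):
            shifted = idx - lag
            raw_cols.append((f, shifted))
            names.append(f"{f.kind}{f.unit_id}_lag{lag}")

    valid = np.ones(times.size, dtype=bool)
    cols = []
    for f, shifted in raw_cols:
        ok = (shifted >= 0) & (shifted < f.values.size)
        valid &= ok
        cols.append((f.values, shifted))
    x = np.column_stack(
        [vals[np.clip(sh, 0, vals.size - 1)] for vals, sh in cols]
    )[valid]
    times = times[valid]
    targets = targets[valid]

    if normalization is None:
        offset = x.mean(axis=0)
        scale = x.std(axis=0)
        keep = scale > _ZERO_VAR_TOL
        if not np.all(keep):
            dropped = [n for n, k in zip(names, keep) if not k]
            warnings.warn(f"dropping zero-variance columns: {dropped}", stacklevel=2)
        names = [n for n, k in zip(names, keep) if k]
        x = x[:, keep]
        normalization = Normalization(offset[keep], scale[keep], names)
    else:
        keep = [i for i, n in enumerate(names) if n in normalization.columns]
        if [names[i] for i in keep] != normalization.columns:
            raise ValueError("supplied normalization does not match feature columns")
        x = x[:, keep]

    return DecoderDataset(
        inputs=normalization.apply(x),
        targets=targets,
        times=times,
        fs=fs,
        lag_count=lag_count,
        normalization=normalization,
        meta={
            "kinds": sorted({f.kind for f in features}),
            "unit_ids": sorted({f.unit_id for f in features}),
            "fs": fs,
            "lag_count": lag_count,
        },
    )
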