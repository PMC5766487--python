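"""Synthetic limb kinematics, position-tuned spiking units, and raw traces.

The generator produces stepping-like periodic joint trajectories, spike
trains from units whose firing rate is driven by the joint angles
(inhomogeneous Poisson thinning with refractory censoring), and optionally
a raw extracellular trace rendered from per-unit waveform templates plus
Gaussian noise.  Every generator is a pure function of its arguments,
including the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import ContinuousSignal, KinematicsSeries, SpikeTrain

__all__ = [
    "UnitTuning",
    "EncodingModel",
    "gen_kinematics",
    "gen_spikes",
    "gen_raw",
    "make_waveform",
    "tuned_population",
]

DEFAULT_ANGLE_RANGES = ((90.0, 140.0), (70.0, 130.0), (60.0, 120.0))
DEFAULT_REFRACTORY_S = 1.5e-3
_ENVELOPE = 0.95  # peak amplitude as a fraction of the half-range


@dataclass
class UnitTuning:
    """Angle-to-rate encoding of one unit.

    Drive is ``baseline_rate + gains . (hip, knee, ankle)`` in Hz (for the
    exponential nonlinearity the drive is log-rate).  ``waveform_amp`` scales
    the default biphasic template used when rendering raw traces.
    """

    baseline_rate: float
    gains: np.ndarray
    refractory_s: float = DEFAULT_REFRACTORY_S
    waveform_amp: float = 1.0
    waveform_template: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=float)
        if self.gains.shape != (3,):
            raise ValueError("gains must have one weight per joint (3)")
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be >= 0")
        if self.waveform_template is not None:
            self.waveform_template = np.asarray(self.waveform_template, float)

    def rate(self, angles: np.ndarray, nonlinearity: str) -> np.ndarray:
        drive = self.baseline_rate + angles @ self.gains
        if nonlinearity == "relu":
            lam = np.maximum(drive, 0.0)
        elif nonlinearity == "exp":
            lam = np.exp(drive)
        else:
            raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
        if np.any(lam < 0) or not np.all(np.isfinite(lam)):
            raise AssertionError("rates must be finite and >= 0")
        return lam


@dataclass
class EncodingModel:
    """A population of tuned units sharing one rate nonlinearity."""

    units: list[UnitTuning]
    nonlinearity: str = "relu"

    def __post_init__(self) -> None:
        if self.nonlinearity not in ("relu", "exp"):
            raise ValueError("nonlinearity must be 'relu' or 'exp'")

    @property
    def n_units(self) -> int:
        return len(self.units)


def gen_kinematics(
    duration: float,
    cycle_period: float,
    angle_ranges: Sequence[tuple[float, float]] = DEFAULT_ANGLE_RANGES,
    jitter: float = 0.0,
    rate: float = 100.0,
    seed: int = 0,
    phase_offsets: Sequence[float] = (0.0, 0.7, 1.4),
    harmonic: float = 0.25,
) -> KinematicsSeries:
    """Generate smooth stepping-like periodic hip/knee/ankle trajectories.

    Each joint follows a fundamental-plus-second-harmonic waveform of
    ``cycle_period`` confined to its (lo, hi) range, with cycle-to-cycle
    period and amplitude jitter controlled by ``jitter`` in [0, 1).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if cycle_period <= 0:
        raise ValueError("cycle_period must be positive")
    if not 0.0 <= jitter < 1.0:
        raise ValueError("jitter must lie in [0, 1)")
    if len(angle_ranges) != 3:
        raise ValueError("angle_ranges needs one (lo, hi) pair per joint")
    for lo, hi in angle_ranges:
        if not lo < hi:
            raise ValueError("each angle range needs lo < hi")

    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    # Per-nominal-cycle frequency and amplitude perturbations; the phase is
    # the cumulative integral of the piecewise-constant instantaneous
    # frequency so the trajectory stays continuous across cycles.
    n_cycles = int(np.ceil(duration / cycle_period)) + 1
    if jitter > 0:
        freq_fac = 1.0 + jitter * rng.uniform(-1.0, 1.0, size=n_cycles)
        amp_fac = 1.0 - jitter * rng.uniform(0.0, 1.0, size=n_cycles)
    else:
        freq_fac = np.ones(n_cycles)
        amp_fac = np.ones(n_cycles)

    cycle_idx = np.minimum((t // cycle_period).astype(int), n_cycles - 1)
    omega = (2.0 * np.pi / cycle_period) * freq_fac[cycle_idx]
    dt = 1.0 / rate
    phase = np.concatenate(([0.0], np.cumsum(omega[:-1] * dt)))
    if jitter == 0:
        phase = 2.0 * np.pi * t / cycle_period  # exact, avoids cumsum rounding
    envelope = _ENVELOPE * amp_fac[cycle_idx]

    angles = []
    for j, (lo, hi) in enumerate(angle_ranges):
        mid = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo)
        th = phase + phase_offsets[j]
        wave = (np.sin(th) + harmonic * np.sin(2.0 * th + 0.5)) / (1.0 + harmonic)
        angles.append(mid + half * envelope * wave)

    return KinematicsSeries(
        times=t, hip=angles[0], knee=angles[1], ankle=angles[2], rate=rate
    )


def _censor_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    if refractory_s <= 0 or times.size < 2:
        return times
    kept = [times[0]]
    last = times[0]
    for tt in times[1:]:
        if tt - last >= refractory_s:
            kept.append(tt)
            last = tt
    return np.asarray(kept)


def _dedupe_strict(times: np.ndarray) -> np.ndarray:
    """Nudge exact duplicates so merged pools stay strictly increasing."""
    while times.size > 1 and np.any(np.diff(times) <= 0):
        dup = np.concatenate(([False], np.diff(times) <= 0))
        times = np.sort(times + dup * 1e-12)
    return times


def gen_spikes(
    kin: KinematicsSeries, model: EncodingModel, seed: int = 0
) -> list[SpikeTrain]:
    """Draw per-unit spike trains tuned to the joint angles.

    Spikes are generated by thinning a homogeneous Poisson process against
    the piecewise-linearly interpolated rate ``nonlinearity(baseline +
    gains . angles(t))``, then refractory-censored.  The returned list holds
    the merged multiunit pool as ``unit_id`` 0 followed by units 1..N.
    """
    if model.n_units < 1:
        raise ValueError("model needs at least one unit")
    duration = kin.duration
    angles = kin.angles
    rel_t = kin.times - kin.t0
    seeds = np.random.SeedSequence(seed).spawn(model.n_units)
    trains: list[SpikeTrain] = []
    for i, unit in enumerate(model.units, start=1):
        rng = np.random.default_rng(seeds[i - 1])
        lam = unit.rate(angles, model.nonlinearity)
        lam_max = float(lam.max())
        if lam_max <= 0:
            trains.append(SpikeTrain(np.empty(0), i, duration))
            continue
        n_cand = rng.poisson(lam_max * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        lam_at = np.interp(cand, rel_t, lam)
        keep = rng.uniform(0.0, lam_max, size=n_cand) < lam_at
        times = _censor_refractory(cand[keep], unit.refractory_s)
        trains.append(SpikeTrain(times, i, duration))

    pooled = _dedupe_strict(np.sort(np.concatenate([tr.times for tr in trains])))
    pool = SpikeTrain(pooled, 0, duration)
    return [pool] + trains


def make_waveform(
    fs: float, amp: float = 1.0, width_s: float = 4e-4, phase: float = 0.6
) -> np.ndarray:
    """Biphasic extracellular-like spike template with peak at its argmax."""
    half = int(round(3 * width_s * fs))
    tt = np.arange(-half, half + 1) / fs
    w = -amp * np.exp(-0.5 * (tt / width_s) ** 2) * np.cos(
        2.0 * np.pi * tt / (4 * width_s) + phase
    )
    return w


def gen_raw(
    trains: Sequence[SpikeTrain],
    model: EncodingModel,
    fs: float = 20000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration: Optional[float] = None,
) -> ContinuousSignal:
    """Render a raw extracellular trace from spike trains.

    Each spike contributes its unit's waveform template (peak sample aligned
    to the spike time); white Gaussian noise of ``noise_sd`` is added.  Pass
    single-unit trains only — a multiunit pool (id 0) alongside its units
    would double-count spikes, so id-0 trains are skipped when any other
    train is present.
    """
    if fs < 10000.0:
        raise ValueError("fs must be >= 10 kHz for raw rendering")
    if not trains:
        raise ValueError("no spike trains given")
    if duration is None:
        duration = max(tr.duration for tr in trains)
    n = int(round(duration * fs))
    if n < 1:
        raise ValueError("duration too short for one sample")
    rng = np.random.default_rng(seed)
    trace = np.zeros(n)

    many = len(trains) > 1
    for tr in trains:
        if many and tr.unit_id == 0:
            continue
        unit = None
        if 1 <= tr.unit_id <= model.n_units:
            unit = model.units[tr.unit_id - 1]
        if unit is not None and unit.waveform_template is not None:
            w = unit.waveform_template
        else:
            amp = unit.waveform_amp if unit is not None else 1.0
            w = make_waveform(fs, amp=amp)
        if w.size > n:
            raise ValueError("waveform template longer than trace")
        peak = int(np.argmax(np.abs(w)))
        for t_spk in tr.times:
            start = int(round(t_spk * fs)) - peak
            lo = max(start, 0)
            hi = min(start + w.size, n)
            if hi > lo:
                trace[lo:hi] += w[lo - start : hi - start]

    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=n)
    return ContinuousSignal(trace, fs=fs, t0=0.0)


def tuned_population(
    n_units: int,
    seed: int = 0,
    rate_range: tuple[float, float] = (10.0, 80.0),
    angle_ranges: Sequence[tuple[float, float]] = DEFAULT_ANGLE_RANGES,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> EncodingModel:
    """Build ``n_units`` extension-tuned units with rates spanning ``rate_range``.

    Gains are positive (rate rises with extension); baseline is solved per
    unit so the drive maps the reachable angle span onto ``rate_range``.
    """
    rng = np.random.default_rng(seed)
    lo_r, hi_r = rate_range
    units = []
    for i in range(n_units):
        w = rng.uniform(0.2, 1.0, size=3)
        lo_drive = sum(wj * r[0] for wj, r in zip(w, angle_ranges))
        hi_drive = sum(wj * r[1] for wj, r in zip(w, angle_ranges))
        scale = (hi_r - lo_r) / (hi_drive - lo_drive)
        gains = w * scale
        baseline = lo_r - lo_drive * scale
        units.append(
            UnitTuning(
                baseline_rate=baseline,
                gains=gains,
                refractory_s=refractory_s,
                waveform_amp=1.0 + 0.5 * i,
            )
        )
    return EncodingModel(units=units, nonlinearity="relu")
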