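"""Decoding metrics and analyses: range-normalized RMS error, coefficient
of determination, histogram mutual information, most-informative-unit
selection, and marker-to-joint-angle conversion."""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import KinematicsSeries, SpikeTrain
from .features import compute_fr, compute_isi, decimate_kinematics, smooth_fr

__all__ = [
    "MARKER_NAMES",
    "ScoreReport",
    "joint_angles_from_markers",
    "compute_nrms",
    "compute_r2",
    "mutual_information",
    "select_most_informative_unit",
    "score_report",
]

MARKER_NAMES = ("iliac_crest", "hip", "knee", "ankle", "mtp")
JOINTS = ("hip", "knee", "ankle")
DEFAULT_MI_BINS = 16


@dataclass
class ScoreReport:
    """Per-joint NRMS (%) and R^2 (%) with their means."""

    nrms: dict[str, float]
    r2: dict[str, float]
    n_points: int

    @property
    def mean_nrms(self) -> float:
        return float(np.mean([self.nrms[j] for j in JOINTS]))

    @property
    def mean_r2(self) -> float:
        return float(np.mean([self.r2[j] for j in JOINTS]))

    def to_dict(self) -> dict:
        return {
            "nrms": dict(self.nrms),
            "r2": dict(self.r2),
            "mean_nrms": self.mean_nrms,
            "mean_r2": self.mean_r2,
            "n_points": self.n_points,
        }


def _segment_angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle at `vertex` between points a and b by the law of cosines, degrees."""
    la = np.linalg.norm(a - vertex, axis=-1)
    lb = np.linalg.norm(b - vertex, axis=-1)
    lc = np.linalg.norm(a - b, axis=-1)
    if np.any(la <= 0) or np.any(lb <= 0):
        raise ValueError("coincident adjacent markers (zero segment length)")
    cos = (la**2 + lb**2 - lc**2) / (2.0 * la * lb)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def joint_angles_from_markers(
    times: np.ndarray, positions: np.ndarray, rate: float | None = None
) -> KinematicsSeries:
    """Hip/knee/ankle angles from the five marker positions.

    ``positions`` is (n_frames, 5, 3) ordered iliac crest, hip, knee,
    ankle, MTP.  Hip angle sits at the hip marker between iliac crest and
    knee; knee at the knee between hip and ankle; ankle at the ankle
    between knee and MTP.
    """
    times = np.asarray(times, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 3 or pos.shape[1:] != (5, 3):
        raise ValueError("positions must be (n_frames, 5, 3)")
    if times.size != pos.shape[0]:
        raise ValueError("one time per frame required")
    iliac, hip, knee, ankle, mtp = (pos[:, i, :] for i in range(5))
    hip_a = _segment_angle(iliac, hip, knee)
    knee_a = _segment_angle(hip, knee, ankle)
    ankle_a = _segment_angle(knee, ankle, mtp)
    if rate is None:
        if times.size < 2:
            raise ValueError("rate required for single-frame input")
        rate = 1.0 / float(np.mean(np.diff(times)))
    return KinematicsSeries(
        times=times, hip=hip_a, knee=knee_a, ankle=ankle_a, rate=rate
    )


def _check_pair(measured: np.ndarray, predicted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(measured, dtype=float)
    xh = np.asarray(predicted, dtype=float)
    if x.shape != xh.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {xh.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    return x, xh


def compute_nrms(measured, predicted) -> float:
    """RMS error normalized by the measured range, in percent."""
    x, xh = _check_pair(measured, predicted)
    rng = x.max() - x.min()
    if rng == 0:
        raise ValueError("measured series is constant (zero range)")
    return float(np.sqrt(np.mean((x - xh) ** 2)) / rng * 100.0)


def compute_r2(measured, predicted) -> float:
    """Coefficient of determination in percent (may be negative)."""
    x, xh = _check_pair(measured, predicted)
    denom = np.sum((x - x.mean()) ** 2)
    if denom == 0:
        raise ValueError("measured series is constant")
    return float((1.0 - np.sum((x - xh) ** 2) / denom) * 100.0)


def _quantile_edges(a: np.ndarray, bins: int) -> np.ndarray:
    edges = np.quantile(a, np.linspace(0.0, 1.0, bins + 1))
    edges = np.unique(edges)
    edges[0] -= 1e-12
    edges[-1] += 1e-12
    return edges


def mutual_information(a, b, bins: int = DEFAULT_MI_BINS) -> float:
    """Plug-in mutual information in bits from an equal-frequency 2-D histogram.

    Each variable is discretized at its own quantile bin edges; negative
    rounding artifacts are clipped at 0.  Constant inputs yield 0 with a
    warning.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("inputs must have equal length")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("degenerate (constant) input; MI = 0", stacklevel=2)
        return 0.0
    ea = _quantile_edges(a, bins)
    eb = _quantile_edges(b, bins)
    joint, _, _ = np.histogram2d(a, b, bins=[ea, eb])
    pxy = joint / joint.sum()
    # marginals and the total are summed in a canonical (sorted) order so
    # that mi(a, b) == mi(b, a) holds bitwise (the histogram transposes)
    px = np.ascontiguousarray(np.sort(pxy, axis=1)).sum(axis=1)[:, None]
    py = np.ascontiguousarray(np.sort(pxy.T, axis=1)).sum(axis=1)[None, :]
    nz = pxy > 0
    terms = pxy[nz] * np.log2(pxy[nz] / (px * py)[nz])
    mi = float(np.sum(np.sort(terms)))
    return max(mi, 0.0)


def _unit_feature(
    train: SpikeTrain, kind: str, span: tuple[float, float], fs: float
):
    if kind == "fr":
        return smooth_fr(compute_fr(train, span=span))
    if kind == "isi":
        return compute_isi(train, fs_out=fs, span=span)
    raise ValueError("feature must be 'fr' or 'isi'")


def select_most_informative_unit(
    trains: Sequence[SpikeTrain],
    kin: KinematicsSeries,
    feature: str = "fr",
    bins: int = DEFAULT_MI_BINS,
    feature_rate: float = 20.0,
) -> int:
    """Sorted unit whose feature stream carries the most joint-angle MI.

    Computes the chosen feature per unit (the multiunit pool, id 0, is not
    a candidate), the MI against each joint angle, ranks by the mean MI
    across the three joints, and returns the argmax; ties break toward the
    lower unit id.  Units whose feature cannot be computed (e.g. < 4 spikes
    for ISI) are skipped.
    """
    units = [tr for tr in trains if tr.unit_id != 0]
    if not units:
        raise ValueError("no sorted units to rank")
    kin_lo = decimate_kinematics(kin, feature_rate)
    span = (float(kin_lo.times[0]), float(kin_lo.times[-1]))
    best_id, best_mi = None, -np.inf
    for tr in sorted(units, key=lambda t: t.unit_id):
        try:
            feat = _unit_feature(tr, feature, span, feature_rate)
        except ValueError:
            continue
        n = min(len(feat), len(kin_lo))
        vals = feat.values[:n]
        mis = [
            mutual_information(vals, getattr(kin_lo, j)[:n], bins=bins)
            for j in JOINTS
        ]
        mean_mi = float(np.mean(mis))
        if mean_mi > best_mi + 1e-15:
            best_id, best_mi = tr.unit_id, mean_mi
    if best_id is None:
        raise ValueError("no unit had a computable feature stream")
    return best_id


def score_report(measured, predicted) -> ScoreReport:
    """Per-joint NRMS/R^2 and their means for aligned (n, 3) angle arrays.

    Accepts KinematicsSeries or plain arrays with columns hip, knee, ankle.
    """
    x = measured.angles if isinstance(measured, KinematicsSeries) else np.asarray(measured, float)
    xh = predicted.angles if isinstance(predicted, KinematicsSeries) else np.asarray(predicted, float)
    if x.shape != xh.shape:
        raise ValueError("measured and predicted must be aligned")
    nrms = {j: compute_nrms(x[:, k], xh[:, k]) for k, j in enumerate(JOINTS)}
    r2 = {j: compute_r2(x[:, k], xh[:, k]) for k, j in enumerate(JOINTS)}
    return ScoreReport(nrms=nrms, r2=r2, n_points=int(x.shape[0]))
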