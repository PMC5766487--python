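"""Raw-trace preprocessing: band-pass filtering, amplitude-threshold spike
detection, snippet extraction, simplified PCA/k-means sorting, and low-rate
unit rejection."""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core import ContinuousSignal, SpikeTrain

__all__ = [
    "SnippetSet",
    "bandpass_filter",
    "bandpass_sos",
    "estimate_noise_sd",
    "detect_spikes",
    "sort_spikes",
    "snippets_to_trains",
    "filter_low_rate_units",
]

BAND_LO_HZ = 300.0
BAND_HI_HZ = 3000.0
FILTER_ORDER = 4
PASSBAND_RIPPLE_DB = 0.2  # per stage; cascade stays well under 1 dB
STOPBAND_ATTEN_DB = 50.0

DEAD_TIME_S = 1.0e-3
SNIPPET_PRE_S = 0.8e-3
SNIPPET_POST_S = 1.6e-3
MIN_RATE_HZ = 2.0 / 60.0  # twice the one-spike-per-minute rejection floor

_MAD_TO_SD = 0.6745


@dataclass
class SnippetSet:
    """Aligned spike waveforms around detection peaks, optionally labeled."""

    snippets: np.ndarray  # (n_events, window) matrix
    peak_times: np.ndarray  # seconds
    fs: float
    labels: Optional[np.ndarray] = None  # unit ids 1..K; None before sorting

    def __post_init__(self) -> None:
        self.snippets = np.asarray(self.snippets, dtype=float)
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.snippets.ndim != 2:
            raise ValueError("snippets must be a 2-D matrix")
        if self.peak_times.size != self.snippets.shape[0]:
            raise ValueError("one peak_time per snippet required")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.size != self.peak_times.size:
                raise ValueError("one label per snippet required")

    @property
    def n_events(self) -> int:
        return int(self.snippets.shape[0])

    @property
    def n_units(self) -> int:
        return 0 if self.labels is None else int(np.unique(self.labels).size)


def bandpass_sos(fs: float) -> np.ndarray:
    """Cascade of 4th-order elliptic high-pass (300 Hz) and low-pass (3 kHz)."""
    if fs <= 2 * BAND_HI_HZ:
        raise ValueError(
            f"fs={fs} too low for the {BAND_HI_HZ} Hz band edge (need > {2 * BAND_HI_HZ})"
        )
    hp = sps.ellip(
        FILTER_ORDER, PASSBAND_RIPPLE_DB, STOPBAND_ATTEN_DB, BAND_LO_HZ,
        btype="highpass", fs=fs, output="sos",
    )
    lp = sps.ellip(
        FILTER_ORDER, PASSBAND_RIPPLE_DB, STOPBAND_ATTEN_DB, BAND_HI_HZ,
        btype="lowpass", fs=fs, output="sos",
    )
    return np.vstack([hp, lp])


def bandpass_filter(raw: ContinuousSignal, zero_phase: bool = False) -> ContinuousSignal:
    """300–3000 Hz elliptic band-pass; causal by default."""
    sos = bandpass_sos(raw.fs)
    if zero_phase:
        out = sps.sosfiltfilt(sos, raw.samples)
    else:
        out = sps.sosfilt(sos, raw.samples)
    return ContinuousSignal(out, fs=raw.fs, t0=raw.t0)


def estimate_noise_sd(filtered: ContinuousSignal) -> float:
    """Robust noise SD: median(|samples|) / 0.6745 (spike-resistant)."""
    return float(np.median(np.abs(filtered.samples)) / _MAD_TO_SD)


def detect_spikes(
    filtered: ContinuousSignal,
    mult: float = 4.0,
    align_window_ms: float = 1.0,
    dead_time_s: float = DEAD_TIME_S,
    pre_s: float = SNIPPET_PRE_S,
    post_s: float = SNIPPET_POST_S,
    noise_sd: Optional[float] = None,
) -> SnippetSet:
    """Detect spikes as upward crossings of |signal| above ``mult``·noise-SD.

    Each crossing is aligned to the local absolute-amplitude peak within
    ``align_window_ms``; events closer than ``dead_time_s`` are merged
    (first kept); snippets are cut ``pre_s`` before to ``post_s`` after the
    peak, dropping events too close to the trace edges.
    """
    if mult <= 0:
        raise ValueError("mult must be positive")
    x = filtered.samples
    fs = filtered.fs
    if noise_sd is None:
        noise_sd = estimate_noise_sd(filtered)
    thr = mult * noise_sd
    if thr <= 0:
        raise ValueError("zero detection threshold (all-zero signal?)")

    a = np.abs(x)
    above = a >= thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate(([0], crossings))

    align = max(1, int(round(align_window_ms * 1e-3 * fs)))
    peaks = []
    for c in crossings:
        seg = a[c : c + align + 1]
        peaks.append(c + int(np.argmax(seg)))

    # dead-time merge: keep the first event, drop followers inside dead time
    dead = int(round(dead_time_s * fs))
    kept: list[int] = []
    for p in sorted(set(peaks)):
        if not kept or p - kept[-1] >= dead:
            kept.append(p)

    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    snips, times = [], []
    for p in kept:
        if p - n_pre < 0 or p + n_post >= x.size:
            continue
        snips.append(x[p - n_pre : p + n_post + 1])
        times.append(filtered.t0 + p / fs)
    if snips:
        mat = np.asarray(snips)
    else:
        mat = np.empty((0, n_pre + n_post + 1))
    return SnippetSet(snippets=mat, peak_times=np.asarray(times), fs=fs)


def _pca(x: np.ndarray, k: int) -> np.ndarray:
    xc = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    return xc @ vt[:k].T


def sort_spikes(
    snips: SnippetSet,
    max_units: int = 5,
    n_components: int = 3,
    min_silhouette: float = 0.5,
    seed: int = 0,
) -> SnippetSet:
    """Cluster snippets into putative units (simplified sorter).

    Features are the first principal components of the snippet matrix;
    k-means is run for k = 2..max_units and the silhouette criterion picks
    the count (one unit when the best silhouette is below
    ``min_silhouette``).  Labels 1..K are assigned by decreasing cluster
    size.  Clustering is performed in a canonical peak-time order so the
    partition is invariant to snippet permutation.
    """
    n = snips.n_events
    if n < 2:
        raise ValueError("need at least 2 snippets to sort")
    order = np.argsort(snips.peak_times, kind="stable")
    mat = snips.snippets[order]
    k_feat = min(n_components, mat.shape[1], n - 1)
    feats = _pca(mat, k_feat)

    max_k = min(max_units, n)
    best_k, best_score, best_labels = 1, -np.inf, np.zeros(n, dtype=int)
    for k in range(2, max_k + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        lab = km.fit_predict(feats)
        if np.unique(lab).size < 2:
            continue
        try:
            score = silhouette_score(feats, lab)
        except ValueError:
            continue
        if score > best_score:
            best_k, best_score, best_labels = k, score, lab

    if best_k == 1 or best_score < min_silhouette:
        final = np.ones(n, dtype=int)
    else:
        # relabel 1..K by decreasing cluster size (ties: smaller old label)
        sizes = np.bincount(best_labels)
        rank = np.argsort(np.argsort(-sizes, kind="stable"), kind="stable")
        final = rank[best_labels] + 1

    labels = np.empty(n, dtype=int)
    labels[order] = final
    return SnippetSet(
        snippets=snips.snippets,
        peak_times=snips.peak_times,
        fs=snips.fs,
        labels=labels,
    )


def snippets_to_trains(snips: SnippetSet, duration: float) -> list[SpikeTrain]:
    """Per-unit spike trains from a sorted SnippetSet, pool (id 0) first."""
    if snips.labels is None:
        raise ValueError("snippets must be sorted first")
    trains = [SpikeTrain(np.sort(snips.peak_times), 0, duration)]
    for uid in np.unique(snips.labels):
        t = np.sort(snips.peak_times[snips.labels == uid])
        trains.append(SpikeTrain(t, int(uid), duration))
    return trains


def filter_low_rate_units(
    trains: Sequence[SpikeTrain], min_rate: float = MIN_RATE_HZ
) -> list[SpikeTrain]:
    """Drop units firing below ``min_rate``; the multiunit pool (id 0) stays."""
    kept = []
    for tr in trains:
        if tr.unit_id == 0 or tr.mean_rate >= min_rate:
            kept.append(tr)
        else:
            warnings.warn(
                f"unit {tr.unit_id} rejected at {tr.mean_rate * 60:.2f} spikes/min",
                stacklevel=2,
            )
    return kept
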