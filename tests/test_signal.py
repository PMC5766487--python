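import numpy as np
import pytest
from scipy import signal as sps, stats

from spikekin.core import ContinuousSignal, SpikeTrain
from spikekin.signal import (
    SnippetSet,
    bandpass_filter,
    bandpass_sos,
    detect_spikes,
    estimate_noise_sd,
    filter_low_rate_units,
    snippets_to_trains,
    sort_spikes,
)
from spikekin.synth import make_waveform

FS = 20000.0


def _sine(freq, duration=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return ContinuousSignal(np.sin(2 * np.pi * freq * t), fs)


class TestBandpass:
    def test_passband_tone_preserved(self):
        sig = _sine(1000.0)
        out = bandpass_filter(sig)
        # steady-state RMS within 1 dB of input RMS
        rms_in = np.sqrt(np.mean(sig.samples[10000:] ** 2))
        rms_out = np.sqrt(np.mean(out.samples[10000:] ** 2))
        assert rms_out / rms_in > 10 ** (-1.0 / 20.0)

    def test_50hz_attenuated(self):
        w, h = sps.sosfreqz(bandpass_sos(FS), worN=[50.0], fs=FS)
        assert 20 * np.log10(np.abs(h[0])) < -20.0

    def test_zero_in_zero_out(self):
        out = bandpass_filter(ContinuousSignal(np.zeros(1000), FS))
        np.testing.assert_array_equal(out.samples, np.zeros(1000))

    def test_fs_too_low_rejected(self):
        with pytest.raises(ValueError, match="band edge"):
            bandpass_filter(ContinuousSignal(np.zeros(100), 5000.0))

    def test_passband_flat_within_1db(self):
        freqs = np.linspace(400.0, 2500.0, 50)
        _, h = sps.sosfreqz(bandpass_sos(FS), worN=freqs, fs=FS)
        db = 20 * np.log10(np.abs(h))
        assert db.max() <= 0.1 and db.min() >= -1.0

    def test_rolloff_through_transition_bands(self):
        # response decreases monotonically moving away from the passband
        # through each transition band (the elliptic stopband itself is
        # equiripple, so monotonicity is only required up to the band edge)
        lo = np.array([170.0, 210.0, 250.0, 290.0])
        _, h = sps.sosfreqz(bandpass_sos(FS), worN=lo, fs=FS)
        assert np.all(np.diff(np.abs(h)) > 0)  # rising toward the passband
        hi = np.array([3050.0, 3150.0, 3300.0, 3500.0])
        _, h = sps.sosfreqz(bandpass_sos(FS), worN=hi, fs=FS)
        assert np.all(np.diff(np.abs(h)) < 0)
        # and the stopbands actually attenuate
        _, h = sps.sosfreqz(bandpass_sos(FS), worN=[50.0, 8000.0], fs=FS)
        assert np.all(20 * np.log10(np.abs(h)) < -40.0)

    def test_zero_phase_mode(self):
        rng = np.random.default_rng(0)
        sig = ContinuousSignal(rng.normal(size=4000), FS)
        out = bandpass_filter(sig, zero_phase=True)
        assert len(out) == len(sig)


class TestNoiseSd:
    def test_gaussian_calibration(self):
        x = np.random.default_rng(1).normal(0.0, 1.0, size=10**6)
        est = estimate_noise_sd(ContinuousSignal(x, FS))
        assert 0.99 < est < 1.01

    def test_zero_signal(self):
        assert estimate_noise_sd(ContinuousSignal(np.zeros(100), FS)) == 0.0

    def test_robust_to_spikes(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 1.0, size=10**6)
        idx = rng.choice(x.size, size=x.size // 100, replace=False)
        x[idx] = 50.0
        est = estimate_noise_sd(ContinuousSignal(x, FS))
        assert 0.98 < est < 1.05


def _insert(template, times, duration=2.0, fs=FS):
    x = np.zeros(int(duration * fs))
    peak = int(np.argmax(np.abs(template)))
    for t in times:
        s = int(round(t * fs)) - peak
        x[s : s + template.size] += template
    return ContinuousSignal(x, fs)


class TestDetect:
    def test_inserted_templates_all_found(self):
        w = make_waveform(FS, amp=6.0)  # 6 sigma-equivalent with noise_sd=1
        times = 0.1 + 0.05 * np.arange(10)
        sig = _insert(w, times)
        snips = detect_spikes(sig, mult=4.0, noise_sd=1.0)
        assert snips.n_events == 10
        np.testing.assert_allclose(snips.peak_times, times, atol=1.0 / FS)

    def test_below_threshold_empty(self):
        w = make_waveform(FS, amp=3.0)
        sig = _insert(w, [0.5])
        snips = detect_spikes(sig, mult=4.0, noise_sd=1.0)
        assert snips.n_events == 0

    def test_dead_time_merges(self):
        w = make_waveform(FS, amp=6.0)
        sig = _insert(w, [0.5, 0.5006])  # 0.6 ms apart < 1 ms dead time
        snips = detect_spikes(sig, mult=4.0, noise_sd=1.0)
        assert snips.n_events == 1

    def test_zero_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            detect_spikes(ContinuousSignal(np.zeros(1000), FS))

    def test_false_positive_rate_bound(self):
        # iid Gaussian at 4 sigma: upward-crossing probability per sample is
        # ~P(|x| >= 4) = 6.33e-5; observed events must stay within 3x of it
        x = np.random.default_rng(3).normal(size=400_000)
        snips = detect_spikes(ContinuousSignal(x, FS), mult=4.0, noise_sd=1.0)
        bound = 2 * stats.norm.sf(4.0) * x.size
        assert 0 < snips.n_events < 3 * bound


def _snippet_bank(templates, counts, noise, seed):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k, (tpl, n) in enumerate(zip(templates, counts)):
        rows.append(tpl + rng.normal(0.0, noise, size=(n, tpl.size)))
        labels.extend([k] * n)
    mat = np.vstack(rows)
    times = np.arange(mat.shape[0]) * 0.01
    return SnippetSet(mat, times, FS), np.array(labels)


def _agreement(found, truth):
    from itertools import permutations

    ids_f = np.unique(found)
    best = 0.0
    for perm in permutations(np.unique(truth), ids_f.size):
        mapping = dict(zip(ids_f, perm))
        best = max(best, np.mean([mapping[f] == t for f, t in zip(found, truth)]))
    return best


class TestSort:
    t1 = make_waveform(FS, amp=5.0, width_s=3e-4)
    t2 = -make_waveform(FS, amp=8.0, width_s=5e-4)
    t3 = make_waveform(FS, amp=10.0, width_s=4e-4, phase=2.0)

    def _pad(self, *tpls):
        n = max(t.size for t in tpls)
        return [np.pad(t, (0, n - t.size)) for t in tpls]

    def test_two_units_recovered(self):
        a, b = self._pad(self.t1, self.t2)
        snips, truth = _snippet_bank([a, b], [60, 40], noise=0.05, seed=0)
        out = sort_spikes(snips, max_units=5)
        assert out.n_units == 2
        assert _agreement(out.labels, truth) >= 0.95

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_identical_snippets_one_unit(self):
        a, = self._pad(self.t1)
        snips = SnippetSet(np.tile(a, (20, 1)), np.arange(20) * 0.01, FS)
        out = sort_spikes(snips, max_units=5)
        assert out.n_units == 1

    def test_three_units_most_seeds(self):
        a, b, c = self._pad(self.t1, self.t2, self.t3)
        wins = 0
        for seed in range(10):
            snips, _ = _snippet_bank([a, b, c], [40, 40, 40], noise=0.3, seed=seed)
            wins += sort_spikes(snips, max_units=5).n_units == 3
        assert wins >= 8

    def test_permutation_invariant_partition(self):
        a, b = self._pad(self.t1, self.t2)
        snips, _ = _snippet_bank([a, b], [30, 30], noise=0.1, seed=1)
        out1 = sort_spikes(snips, max_units=4)
        perm = np.random.default_rng(0).permutation(snips.n_events)
        shuffled = SnippetSet(snips.snippets[perm], snips.peak_times[perm], FS)
        out2 = sort_spikes(shuffled, max_units=4)
        # same partition: labels at matching peak_times must agree up to
        # a relabeling, which the size-ordering makes exact
        order1 = np.argsort(out1.peak_times)
        order2 = np.argsort(out2.peak_times)
        np.testing.assert_array_equal(
            out1.labels[order1], out2.labels[order2]
        )

    def test_labels_ordered_by_size(self):
        a, b = self._pad(self.t1, self.t2)
        snips, _ = _snippet_bank([a, b], [70, 30], noise=0.05, seed=2)
        out = sort_spikes(snips, max_units=4)
        sizes = np.bincount(out.labels)[1:]
        assert np.all(np.diff(sizes) <= 0)

    def test_too_few_snippets(self):
        a, = self._pad(self.t1)
        snips = SnippetSet(a[None, :], np.array([0.0]), FS)
        with pytest.raises(ValueError, match="2 snippets"):
            sort_spikes(snips)


class TestLowRateFilter:
    def test_slow_unit_removed(self):
        slow = SpikeTrain(np.array([10.0]), 1, 300.0)  # 1 spike / 300 s
        with pytest.warns(UserWarning, match="rejected"):
            kept = filter_low_rate_units([slow], min_rate=1.0 / 30.0)
        assert kept == []

    def test_fast_unit_kept(self):
        fast = SpikeTrain(np.arange(0.0, 10.0, 0.1) + 0.05, 1, 10.0)
        assert filter_low_rate_units([fast]) == [fast]

    def test_pool_never_removed(self):
        pool = SpikeTrain(np.array([5.0]), 0, 300.0)
        assert filter_low_rate_units([pool]) == [pool]

    def test_empty(self):
        assert filter_low_rate_units([]) == []


class TestSnippetsToTrains:
    def test_round_trip(self):
        mat = np.zeros((4, 5))
        labels = np.array([1, 2, 1, 2])
        snips = SnippetSet(mat, np.array([0.1, 0.2, 0.3, 0.4]), FS, labels=labels)
        trains = snippets_to_trains(snips, duration=1.0)
        assert trains[0].unit_id == 0 and trains[0].n_spikes == 4
        assert [t.n_spikes for t in trains[1:]] == [2, 2]
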