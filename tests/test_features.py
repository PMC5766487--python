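import numpy as np
import pytest
from scipy import signal as sps

from spikekin.core import FeatureSeries, SpikeTrain
from spikekin.features import (
    build_dataset,
    compute_fr,
    compute_isi,
    decimate_kinematics,
    fr_smoother_taps,
    smooth_fr,
)

from conftest import poisson_train


def brute_force_fr(times, grid, window):
    """Independent windowed-count oracle: count in (t - w, t] / w.

    The 1e-12 slack resolves float ties at the window edges the same way
    as the contract states them: a spike exactly at t is inside, a spike
    exactly at t - w is outside.
    """
    out = np.empty(grid.size)
    for i, t in enumerate(grid):
        out[i] = np.sum((times >= t - window + 1e-12) & (times < t + 1e-12))
    return out / window


class TestComputeFr:
    def test_empty_train_zero(self):
        fr = compute_fr(SpikeTrain(np.empty(0), 1, 10.0))
        assert np.all(fr.values == 0.0)
        assert fr.fs == 20.0

    def test_regular_10ms_spiking(self):
        times = np.arange(0.01, 10.0, 0.01)
        fr = compute_fr(SpikeTrain(times, 1, 10.0))
        # after the 300 ms transient every full window holds exactly 30
        # spikes (the final grid point at t = 10.0 sees only 29: the train
        # ends at 9.99)
        steady = fr.values[int(0.3 * 20) : -1]
        np.testing.assert_allclose(steady, 100.0)

    def test_single_spike_window_membership(self):
        fr = compute_fr(SpikeTrain(np.array([1.0]), 1, 3.0))
        t = fr.times
        nz = fr.values > 0
        assert np.array_equal(nz, (t >= 1.0 - 1e-12) & (t < 1.3 - 1e-12))
        np.testing.assert_allclose(fr.values[nz], 1.0 / 0.3)

    def test_matches_brute_force(self):
        for seed in range(20):
            tr = poisson_train(rate=30.0, duration=5.0, seed=seed)
            fr = compute_fr(tr)
            expected = brute_force_fr(tr.times, fr.times, 0.3)
            np.testing.assert_allclose(fr.values, expected)

    def test_window_longer_than_recording(self):
        with pytest.raises(ValueError, match="window"):
            compute_fr(SpikeTrain(np.array([0.05]), 1, 0.2))

    def test_mean_rate_consistency(self):
        # long stationary Poisson train: mean FR ~ true rate within 3 MC SDs
        rate, dur = 25.0, 200.0
        tr = poisson_train(rate, dur, seed=42)
        fr = compute_fr(tr)
        mean = fr.values[6:].mean()
        # the windowed mean is ~ total count / duration; SE = sqrt(rate/dur)
        assert abs(mean - rate) < 3 * np.sqrt(rate / dur) + 0.5


class TestSmoothFr:
    def _const(self, v, n=200):
        return FeatureSeries(np.full(n, v), 20.0, 0.0, "fr", 1)

    def test_dc_gain(self):
        out = smooth_fr(self._const(7.0))
        np.testing.assert_allclose(out.values[50:-50], 7.0, rtol=1e-3)

    def test_nyquist_attenuated(self):
        taps = fr_smoother_taps(20.0)
        _, h = sps.freqz(taps, worN=[10.0], fs=20.0)
        gain = np.abs(h[0])
        assert gain < 10 ** (-40 / 20.0)  # designed stopband reaches Nyquist
        n = 400
        x = 50.0 + 10.0 * (-1.0) ** np.arange(n)  # 10 Hz alternation
        out = smooth_fr(FeatureSeries(x, 20.0, 0.0, "fr", 1))
        steady = out.values[100:300]
        alt = (-1.0) ** np.arange(100, 300)
        amp_out = abs(np.mean((steady - steady.mean()) * alt))
        assert amp_out <= 10.0 * max(3 * gain, 1e-4)

    def test_impulse_response_delay_compensated(self):
        taps = fr_smoother_taps(20.0)
        n = 6 * taps.size
        x = np.zeros(n)
        mid = n // 2
        x[mid] = 1.0
        out = smooth_fr(FeatureSeries(x, 20.0, 0.0, "fr", 1))
        half = (taps.size - 1) // 2
        np.testing.assert_allclose(
            out.values[mid - half : mid + half + 1], np.maximum(taps, 0.0), atol=1e-12
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            smooth_fr(self._const(1.0, n=5))

    def test_wrong_kind_rejected(self):
        isi = FeatureSeries(np.full(100, 0.05), 20.0, 0.0, "isi", 1)
        with pytest.raises(ValueError, match="FR"):
            smooth_fr(isi)


class TestComputeIsi:
    def test_regular_spiking_constant(self):
        times = np.arange(0.05, 5.0, 0.05)
        isi = compute_isi(SpikeTrain(times, 1, 5.0))
        np.testing.assert_allclose(isi.values, 0.05, atol=1e-9)

    def test_interpolates_knots(self):
        times = np.array([0.1, 0.11, 0.13, 0.16, 0.20])  # ISIs 10,20,30,40 ms
        tr = SpikeTrain(times, 1, 1.0)
        isi = compute_isi(tr)
        from scipy.interpolate import CubicSpline

        spline = CubicSpline(times[1:], np.diff(times), bc_type="natural")
        at_knots = spline(times[1:])
        np.testing.assert_allclose(at_knots, np.diff(times), atol=1e-9)

    def test_knot_values_on_grid(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0.0, 10.0, size=50))
        tr = SpikeTrain(times, 1, 10.0)
        isi = compute_isi(tr, fs_out=1000.0)  # fine grid hits near the knots
        from scipy.interpolate import CubicSpline

        spline = CubicSpline(times[1:], np.diff(times), bc_type="natural")
        inside = (isi.times >= times[1]) & (isi.times <= times[-1])
        expected = np.maximum(spline(isi.times[inside]), 1e-6)
        np.testing.assert_allclose(isi.values[inside], expected, atol=1e-12)

    def test_hold_outside_knots(self):
        times = np.array([4.0, 4.1, 4.25, 4.3, 4.5])
        isi = compute_isi(SpikeTrain(times, 1, 10.0), span=(0.0, 9.0))
        first_knot_value = 0.1
        last_knot_value = 0.2
        np.testing.assert_allclose(isi.values[isi.times < 4.1], first_knot_value)
        np.testing.assert_allclose(
            isi.values[isi.times > 4.5], last_knot_value, atol=1e-12
        )

    def test_too_few_spikes(self):
        with pytest.raises(ValueError, match="unit 7"):
            compute_isi(SpikeTrain(np.array([0.1, 0.2, 0.3]), 7, 1.0))


class TestDecimate:
    def test_rate_and_length(self, small_kin):
        k20 = decimate_kinematics(small_kin, 20.0)
        assert k20.rate == 20.0
        assert len(k20) == len(small_kin) // 5 + (len(small_kin) % 5 > 0)

    def test_non_integer_ratio_rejected(self, small_kin):
        with pytest.raises(ValueError, match="integer"):
            decimate_kinematics(small_kin, 30.0)


class TestBuildDataset:
    def _feature(self, values, kind="fr", unit=1):
        return FeatureSeries(values, 20.0, 0.0, kind, unit)

    def test_lag_zero_single_column(self, small_kin, rng):
        f = self._feature(rng.uniform(1, 10, size=120))
        ds = build_dataset([f], small_kin, lag_count=0)
        assert ds.inputs.shape[1] == 1
        z = (f.values[: ds.n_rows] - f.values[: ds.n_rows].mean()) / f.values[
            : ds.n_rows
        ].std()
        np.testing.assert_allclose(ds.inputs[:, 0], z, atol=1e-9)

    def test_lag_indexing_oracle(self, small_kin, rng):
        f = self._feature(rng.uniform(1, 10, size=120))
        ds = build_dataset([f], small_kin, lag_count=2)
        raw = ds.raw_inputs()
        # row t holds values at t, t-1, t-2 hops
        idx = np.round((ds.times - f.t0) * f.fs).astype(int)
        for lag in range(3):
            np.testing.assert_allclose(raw[:, lag], f.values[idx - lag], atol=1e-9)

    def test_rows_with_incomplete_history_dropped(self, small_kin, rng):
        f = self._feature(rng.uniform(1, 10, size=120))
        d0 = build_dataset([f], small_kin, lag_count=0)
        d2 = build_dataset([f], small_kin, lag_count=2)
        assert d2.n_rows == d0.n_rows - 2

    def test_normalization_round_trip(self, small_kin, rng):
        f = self._feature(rng.uniform(1, 10, size=120))
        ds = build_dataset([f], small_kin, lag_count=1)
        idx = np.round((ds.times - f.t0) * f.fs).astype(int)
        np.testing.assert_allclose(ds.raw_inputs()[:, 0], f.values[idx], atol=1e-9)

    def test_constant_column_dropped(self, small_kin):
        const = self._feature(np.full(120, 3.0))
        varying = self._feature(np.linspace(1, 10, 120), unit=2)
        with pytest.warns(UserWarning, match="zero-variance"):
            ds = build_dataset([const, varying], small_kin, lag_count=0)
        assert ds.inputs.shape[1] == 1
        assert ds.normalization.columns == ["fr2_lag0"]

    def test_supplied_normalization_reused(self, small_kin, rng):
        f = self._feature(rng.uniform(1, 10, size=120))
        ds1 = build_dataset([f], small_kin, lag_count=1)
        ds2 = build_dataset([f], small_kin, lag_count=1,
                            normalization=ds1.normalization)
        np.testing.assert_array_equal(ds1.inputs, ds2.inputs)

    def test_disjoint_spans_rejected(self, small_kin):
        f = FeatureSeries(np.ones(50), 20.0, 100.0, "fr", 1)
        with pytest.raises(ValueError, match="overlap"):
            build_dataset([f], small_kin, lag_count=0)

    def test_targets_aligned(self, small_kin, rng):
        f = self._feature(rng.uniform(1, 10, size=120))
        ds = build_dataset([f], small_kin, lag_count=0)
        k20 = decimate_kinematics(small_kin, 20.0)
        np.testing.assert_allclose(ds.targets, k20.angles[: ds.n_rows])
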