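"""Preprocessing chain: resampling, rejection, filtering, interpolation,
referencing, baseline and pipeline-order enforcement."""

import numpy as np
import pytest

from teptools.forward import dipole_potentials
from teptools.headmodel import build_sphere_model
from teptools.preprocess import (
    Evoked,
    PipelineOrderError,
    PreprocessingError,
    RejectionCriteria,
    average_and_filter,
    average_reference,
    bandpass_evoked,
    baseline_correct,
    downsample,
    interpolate_bad,
    reject_artifacts,
    rejection_sensitivity,
    spline_interpolate,
)
from teptools.simulate import (
    CLEAN,
    DEFAULT_TEMPLATE,
    EpochSet,
    sample_subject,
    simulate_block,
)


def _epochs_from_array(data, fs=1450.0, t0=None, channels=None):
    n_tr, n_ch, n_s = data.shape
    return EpochSet(
        data=data,
        fs=fs,
        t0_index=n_s // 2 if t0 is None else t0,
        channels=tuple(channels or (f"CH{i}" for i in range(n_ch))),
        subject_id="S00",
        condition="pre",
        trial_flags=np.zeros(n_tr, dtype=np.int8),
    )


def _evoked(data, fs=725.0, t0=None, channels=None,
            log=("average", "filter")):
    n_ch, n_s = data.shape
    return Evoked(
        data=data,
        fs=fs,
        t0_index=n_s // 2 if t0 is None else t0,
        channels=tuple(channels or (f"CH{i}" for i in range(n_ch))),
        n_trials_used=1,
        processing_log=tuple(log),
    )


class TestDownsample:
    def test_factor_two_halves_samples_and_keeps_pulse(self):
        ep = _epochs_from_array(np.random.default_rng(0).normal(size=(2, 4, 2320)))
        out = downsample(ep, 725.0)
        assert out.data.shape == (2, 4, 1160)
        assert out.fs == 725.0
        assert out.times[out.t0_index] == 0.0

    def test_constant_signal_preserved(self):
        ep = _epochs_from_array(np.full((1, 3, 2320), 7.5))
        out = downsample(ep, 725.0)
        interior = out.data[0, :, 50:-50]
        assert np.allclose(interior, 7.5, atol=1e-9)

    def test_passband_sinusoid_amplitude_within_one_percent(self):
        fs = 1450.0
        t = np.arange(2320) / fs
        sine = 3.0 * np.sin(2 * np.pi * 10.0 * t)
        ep = _epochs_from_array(np.tile(sine, (1, 2, 1)), fs=fs)
        out = downsample(ep, 725.0)
        # sinusoid fit on interior samples (edge effects excluded)
        tt = np.arange(out.data.shape[2])[100:-100] / out.fs
        y = out.data[0, 0, 100:-100]
        A = np.column_stack([np.sin(2 * np.pi * 10 * tt), np.cos(2 * np.pi * 10 * tt)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.hypot(*coef) == pytest.approx(3.0, rel=0.01)

    def test_upsampling_rejected(self):
        ep = _epochs_from_array(np.zeros((1, 2, 100)), fs=725.0)
        with pytest.raises(PreprocessingError):
            downsample(ep, 1450.0)

    def test_non_integer_ratio_rejected(self):
        ep = _epochs_from_array(np.zeros((1, 2, 100)), fs=1450.0)
        with pytest.raises(PreprocessingError):
            downsample(ep, 700.0)


class TestRejectArtifacts:
    def test_large_amplitude_trial_removed(self):
        t = np.arange(500) / 725.0
        slow = 5.0 * np.sin(2 * np.pi * 7.0 * t)
        data = np.tile(slow, (3, 4, 1))
        data[1, 2, 100] = 200.0
        ep = _epochs_from_array(data, fs=725.0)
        out, report = reject_artifacts(ep, RejectionCriteria(abs_amplitude_limit=100.0))
        assert out.n_trials == 2
        assert report.loc[1, "kept"] == False  # noqa: E712
        assert "abs_amplitude" in report.loc[1, "rule"]

    def test_clean_trials_mostly_retained(self, leadfield_reduced):
        # rejection runs after downsampling, as in the recording workflow
        template = {**DEFAULT_TEMPLATE, "artifact_rate": 0.0}
        subject = sample_subject(11, template)
        ep = downsample(
            simulate_block(subject, 1.0, leadfield_reduced, n_trials=100,
                           rng=np.random.default_rng(5))
        )
        out, _ = reject_artifacts(ep)
        assert out.n_trials >= 95

    def test_artifact_trials_detected_with_high_sensitivity(self, leadfield_reduced):
        subject = sample_subject(12)  # default artifact_rate 0.3
        ep = downsample(
            simulate_block(subject, 1.0, leadfield_reduced, n_trials=180,
                           rng=np.random.default_rng(6))
        )
        out, report = reject_artifacts(ep)
        assert rejection_sensitivity(report) >= 0.9
        # retained count is reported and plausible (~120/180 in this regime)
        assert out.n_trials == int(report["kept"].sum())
        assert 90 <= out.n_trials <= 150

    def test_all_rejected_raises(self):
        data = np.full((2, 3, 200), 500.0)
        data += np.random.default_rng(0).normal(size=data.shape)
        ep = _epochs_from_array(data, fs=725.0)
        with pytest.raises(PreprocessingError):
            reject_artifacts(ep)


class TestAverageAndFilter:
    def test_identical_trials_average_to_the_filtered_trial(self):
        rng = np.random.default_rng(2)
        trial = rng.normal(size=(4, 800))
        ep = _epochs_from_array(np.stack([trial, trial]), fs=725.0)
        out = average_and_filter(ep)
        assert np.allclose(out.data, bandpass_evoked(trial, 725.0, (2.0, 40.0)),
                           rtol=1e-12, atol=1e-12)
        assert out.processing_log == ("average", "filter")
        assert out.n_trials_used == 2

    @pytest.mark.parametrize(
        "freq,check",
        [(60.0, lambda r: r < 0.10), (10.0, lambda r: abs(r - 1.0) < 0.05)],
    )
    def test_band_edges(self, freq, check):
        fs = 725.0
        t = np.arange(1450) / fs
        sine = np.sin(2 * np.pi * freq * t)
        ep = _epochs_from_array(np.tile(sine, (1, 2, 1)), fs=fs)
        out = average_and_filter(ep)
        interior = slice(200, -200)
        ratio = out.data[0, interior].std() / sine[interior].std()
        assert check(ratio)

    def test_band_outside_nyquist_rejected(self):
        ep = _epochs_from_array(np.zeros((1, 2, 500)), fs=725.0)
        with pytest.raises(PreprocessingError):
            average_and_filter(ep, band=(2.0, 400.0))


class TestInterpolateBad:
    def test_constant_field_reproduced(self, montage):
        data = np.full((60, 50), 4.2)
        ev = _evoked(data, channels=montage.channels)
        out = interpolate_bad(ev, montage)
        assert np.allclose(out.data, 4.2, atol=1e-6)

    def test_bad_columns_rewritten_others_untouched(self, montage):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(60, 30))
        ev = _evoked(data, channels=montage.channels)
        out = interpolate_bad(ev, montage)
        bad_idx = [montage.index(c) for c in ("P2", "CP2")]
        good_idx = [i for i in range(60) if i not in bad_idx]
        assert out.data.shape == data.shape
        assert np.array_equal(out.data[good_idx], data[good_idx])
        assert not np.allclose(out.data[bad_idx], data[bad_idx])

    def test_leave_one_out_error_below_five_percent(self, montage, sphere):
        # smooth dipolar topographies: deep sources through the skull
        rng = np.random.default_rng(4)
        interior = [i for i in range(60) if montage.positions[i, 2] > 0.25]
        for _ in range(5):
            u = rng.normal(size=3)
            u[2] = abs(u[2])
            u /= np.linalg.norm(u)
            src = rng.uniform(30.0, 45.0) * u
            mom = rng.normal(size=3)
            topo = dipole_potentials(sphere, montage.positions, src[None],
                                     mom[None] / np.linalg.norm(mom)).ravel()
            scale = np.abs(topo).max()
            for i in interior:
                good = [j for j in range(60) if j != i]
                est = spline_interpolate(
                    montage.positions[good], topo[good][:, None],
                    montage.positions[i][None],
                )[0, 0]
                assert abs(est - topo[i]) / scale < 0.05

    def test_too_many_bad_channels_refused(self, montage):
        from teptools.montage import Montage

        many_bad = Montage(
            montage.channels, montage.positions,
            frozenset(montage.channels[:20]),
        )
        ev = _evoked(np.zeros((60, 10)), channels=montage.channels)
        with pytest.raises(PreprocessingError):
            interpolate_bad(ev, many_bad)


class TestReferenceAndBaseline:
    def test_average_reference_zeroes_channel_sum(self):
        rng = np.random.default_rng(5)
        ev = _evoked(rng.normal(size=(6, 40)) + 7.0)
        out = average_reference(ev)
        assert np.allclose(out.data.sum(axis=0), 0.0, atol=1e-9)

    def test_average_reference_idempotent(self):
        ev = average_reference(_evoked(np.random.default_rng(6).normal(size=(5, 30))))
        again = average_reference(ev)
        assert np.allclose(again.data, ev.data, atol=1e-12)

    def test_common_offset_removed(self):
        base = np.random.default_rng(7).normal(size=(4, 20))
        base -= base.mean(axis=0, keepdims=True)
        out = average_reference(_evoked(base + 7.0))
        assert np.allclose(out.data, base, atol=1e-12)

    def test_baseline_mean_zero_after_correction(self):
        rng = np.random.default_rng(8)
        ev = _evoked(rng.normal(size=(4, 1160)), fs=725.0, t0=580)
        out = baseline_correct(average_reference(ev))
        t = out.times
        sel = (t >= -300) & (t < -50)
        assert np.allclose(out.data[:, sel].mean(axis=1), 0.0, atol=1e-9)

    def test_zero_baseline_signal_unchanged(self):
        data = np.zeros((3, 1160))
        data[:, 800:] = 5.0  # post-pulse step only
        ev = average_reference(_evoked(data, fs=725.0, t0=580))
        out = baseline_correct(ev)
        assert np.allclose(out.data, ev.data, atol=1e-12)

    def test_linear_trend_keeps_slope_loses_mean(self):
        fs, t0 = 725.0, 580
        times = (np.arange(1160) - t0) * 1000.0 / fs
        slope = 0.01  # uV per ms
        data = np.tile(slope * times, (3, 1))
        # exercise baseline_correct alone (reference step marked as done)
        ev = _evoked(data, fs=fs, t0=t0,
                     log=("average", "filter", "average_reference"))
        out = baseline_correct(ev)
        sel = (times >= -300) & (times < -50)
        expected_mean = slope * times[sel].mean()  # analytic ramp mean
        assert np.allclose(out.data, data - expected_mean, atol=1e-9)
        d = np.diff(out.data[0])
        assert np.allclose(d, slope * 1000.0 / fs, atol=1e-12)

    def test_window_outside_epoch_rejected(self):
        ev = average_reference(_evoked(np.zeros((3, 100)), fs=725.0, t0=50))
        with pytest.raises(PreprocessingError):
            baseline_correct(ev, window=(-900.0, -800.0))


class TestPipelineOrder:
    def test_baseline_requires_reference(self):
        ev = _evoked(np.zeros((3, 1160)), fs=725.0, t0=580)
        with pytest.raises(PipelineOrderError):
            baseline_correct(ev)

    def test_interpolation_cannot_follow_reference(self, montage):
        ev = average_reference(_evoked(np.zeros((60, 20)), channels=montage.channels))
        with pytest.raises(PipelineOrderError):
            interpolate_bad(ev, montage)

    def test_log_is_complete_audit_trail(self, leadfield_reduced, montage):
        from teptools.preprocess import preprocess_evoked

        subject = sample_subject(13)
        ep = simulate_block(subject, 1.0, leadfield_reduced, n_trials=25,
                            rng=np.random.default_rng(7))
        evoked, _ = preprocess_evoked(ep, montage)
        assert evoked.processing_log == (
            "average", "filter", "interpolate_bad", "average_reference",
            "baseline_correct",
        )


class TestEdfImport:
    def _write_minimal_edf(self, path, data, fs):
        """Hand-craft a minimal EDF file (int16 records, uV physical units)."""
        n_ch, n_samples = data.shape
        n_records = 1
        header = b""
        header += b"0".ljust(8)
        header += b"synthetic patient".ljust(80)
        header += b"synthetic recording".ljust(80)
        header += b"01.01.20".ljust(8)
        header += b"00.00.00".ljust(8)
        header += str(256 * (1 + n_ch)).encode().ljust(8)
        header += b"".ljust(44)
        header += str(n_records).encode().ljust(8)
        header += str(n_samples / fs).encode()[:8].ljust(8)
        header += str(n_ch).encode().ljust(4)
        for i in range(n_ch):
            header += f"CH{i}".encode().ljust(16)
        header += b"".ljust(80) * n_ch          # transducer
        header += b"uV".ljust(8) * n_ch         # physical dimension
        header += b"-200".ljust(8) * n_ch       # physical min
        header += b"200".ljust(8) * n_ch        # physical max
        header += b"-32768".ljust(8) * n_ch     # digital min
        header += b"32767".ljust(8) * n_ch      # digital max
        header += b"".ljust(80) * n_ch          # prefiltering
        header += str(n_samples).encode().ljust(8) * n_ch
        header += b"".ljust(32) * n_ch
        digital = np.round(data / 200.0 * 32767.0).astype("<i2")
        path.write_bytes(header + digital.tobytes())

    def test_concatenated_trials_round_trip(self, tmp_path):
        from teptools.preprocess import epochs_from_edf

        rng = np.random.default_rng(9)
        fs = 100.0
        trials = rng.uniform(-150, 150, size=(2, 3, 50))  # 2 trials, 3 ch
        concat = np.concatenate([trials[0], trials[1]], axis=1)
        path = tmp_path / "mini.edf"
        self._write_minimal_edf(path, concat, fs)
        ep = epochs_from_edf(path, n_samples_per_trial=50, t0_index=25)
        assert ep.data.shape == (2, 3, 50)
        assert ep.fs == fs
        # int16 quantization: ~0.006 uV steps
        assert np.allclose(ep.data, trials, atol=0.05)
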