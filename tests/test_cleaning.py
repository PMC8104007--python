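"""Artifact-correction contracts: AAS, QRS detection, BCG, filters,
epoch replacement, average reference."""

from __future__ import annotations

import numpy as np
import pytest

from oscoupler.cleaning import (
    CleanConfig,
    detect_qrs,
    filter_chain,
    remove_bcg,
    remove_gradient_artifact,
    replace_bad_epochs,
    rereference_average,
)
from oscoupler.recording import EEGRecording
from oscoupler.simulate import _qrs_shape, simulate_eeg


def _rec_with_artifact(artifact_amp=50.0, rate=500.0, n_trig=30, tr=2.1):
    spacing = int(tr * rate)
    n = spacing * n_trig
    t = np.arange(n) / rate
    signal = np.sin(2 * np.pi * 0.7 * t)
    wave = artifact_amp * np.sin(2 * np.pi * 20.0 * np.arange(spacing) / rate)
    art = np.zeros(n)
    trig = np.arange(n_trig) * spacing
    for s in trig:
        art[s : s + spacing] += wave
    data = np.vstack([signal + art, 0.5 * signal + art])
    return (
        EEGRecording(data=data, rate=rate, labels=["A", "B"], triggers=trig),
        np.vstack([signal, 0.5 * signal]),
    )


def _trlocked_power(data, triggers, spacing):
    ep = np.stack([data[:, s : s + spacing] for s in triggers])
    return float(np.mean(ep.mean(axis=0) ** 2))


class TestGradientAAS:
    def test_identical_artifact_cancels_exactly(self):
        """A TR-identical artifact is removed to numerical precision; the
        leftover distortion of the underlying signal is bounded by the
        1/window share of the signal that enters the template."""
        rec, clean = _rec_with_artifact()
        out = remove_gradient_artifact(rec, CleanConfig(aas_window=21))
        resid = out.data - clean
        # artifact-only portion vanishes: rerun on pure artifact
        pure = EEGRecording(
            data=rec.data - clean, rate=rec.rate, labels=rec.labels,
            triggers=rec.triggers,
        )
        pure_out = remove_gradient_artifact(pure, CleanConfig(aas_window=21))
        assert np.abs(pure_out.data).max() < 1e-10
        # signal distortion bounded by ~ (1/window) x signal amplitude
        assert np.abs(resid).max() < 2.0 / 21

    def test_zero_artifact_near_identity(self):
        """With no artifact the only change is the signal's own TR-locked
        sliding mean — bounded by the ~1/window share AAS inherently takes."""
        rec, clean = _rec_with_artifact(artifact_amp=0.0)
        out = remove_gradient_artifact(rec, CleanConfig(aas_window=21))
        assert np.abs(out.data - rec.data).max() < 2.0 / 21

    def test_simulated_artifact_power_ratio(self, small_cfg, small_eeg):
        """On the seeded simulation the TR-locked average power drops by
        more than 100x."""
        out = remove_gradient_artifact(small_eeg)
        sp = int(round(small_eeg.trigger_spacing()))
        before = _trlocked_power(small_eeg.data[:-1], small_eeg.triggers, sp)
        after = _trlocked_power(out.data[:-1], out.triggers, sp)
        assert after / before < 1e-2

    def test_aas_idempotent(self, small_eeg):
        """Second application changes the output by <1% of the first
        correction's magnitude."""
        once = remove_gradient_artifact(small_eeg)
        twice = remove_gradient_artifact(once)
        first_mag = float(np.sqrt(np.mean((once.data - small_eeg.data) ** 2)))
        second_mag = float(np.sqrt(np.mean((twice.data - once.data) ** 2)))
        assert second_mag < 0.01 * first_mag

    def test_irregular_triggers_rejected(self):
        rec, _ = _rec_with_artifact()
        bad = rec.triggers.copy()
        bad[10] += int(0.2 * rec.rate)
        rec2 = EEGRecording(data=rec.data, rate=rec.rate, labels=rec.labels,
                            triggers=np.sort(bad))
        with pytest.raises(ValueError, match="spacing"):
            remove_gradient_artifact(rec2)

    def test_too_few_triggers_rejected(self):
        rec, _ = _rec_with_artifact(n_trig=10)
        with pytest.raises(ValueError, match="triggers"):
            remove_gradient_artifact(rec, CleanConfig(aas_window=21))


def _ecg(rate=500.0, duration=200.0, rr=1.0, rr_sd=0.06, seed=7):
    rng = np.random.default_rng(seed)
    n = int(duration * rate)
    true = []
    t = 0.5
    while t < duration - 0.5:
        true.append(int(round(t * rate)))
        t += max(0.3, rng.normal(rr, rr_sd))
    ecg = np.zeros(n)
    half = int(0.05 * rate)
    for c in true:
        lo, hi = max(0, c - half), min(n, c + half)
        ecg[lo:hi] += 800.0 * _qrs_shape((np.arange(lo, hi) - c) / rate)
    return ecg, np.asarray(true), rng


class TestQRS:
    def test_clean_ecg_exact_recovery(self):
        ecg, true, _ = _ecg()
        peaks = detect_qrs(ecg, 500.0)
        assert len(peaks) == len(true)
        err = np.abs(peaks - true)
        assert err.max() <= 1

    def test_noisy_ecg_recovery(self):
        """With additive noise at 10% of the R amplitude, >= 99% of peaks
        land within +-2 samples at 500 Hz."""
        ecg, true, rng = _ecg()
        noisy = ecg + rng.normal(0, 80.0, ecg.size)
        peaks = detect_qrs(noisy, 500.0)
        d = np.abs(peaks[:, None] - true[None, :]).min(axis=1)
        assert (d <= 2).mean() >= 0.99
        assert abs(len(peaks) - len(true)) <= 2

    def test_flatline_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            detect_qrs(np.zeros(10000), 500.0)

    def test_short_ecg_rejected(self):
        with pytest.raises(ValueError, match="10 s"):
            detect_qrs(np.random.default_rng(0).normal(size=100), 500.0)


class TestBCG:
    def _rec_with_bcg(self, amp=40.0, rate=500.0):
        ecg, true, rng = _ecg(rate=rate, duration=120.0)
        n = ecg.size
        base = np.vstack(
            [np.sin(2 * np.pi * 9.5 * np.arange(n) / rate + p) for p in (0.0, 1.0)]
        )
        tmpl = np.exp(-(((np.arange(int(0.4 * rate)) / rate - 0.15) / 0.08) ** 2))
        data = base.copy()
        delay = int(0.21 * rate)
        for c in true:
            s = c + delay
            if s + tmpl.size <= n:
                data[:, s : s + tmpl.size] += amp * tmpl
        trig = np.arange(50) * int(2.1 * rate)
        rec = EEGRecording(data=data, rate=rate, labels=["A", "B"], triggers=trig)
        return rec, base, true

    def test_identical_template_cancels(self):
        rec, base, true = self._rec_with_bcg()
        peaks = true
        out = remove_bcg(rec, peaks)
        delay, L = int(0.21 * 500), int(0.4 * 500)
        ok = [p for p in peaks if p + delay + L <= rec.n_samples]
        before = np.stack([(rec.data - base)[:, p + delay : p + delay + L] for p in ok])
        after = np.stack([(out.data - base)[:, p + delay : p + delay + L] for p in ok])
        assert np.mean(after.mean(0) ** 2) < 1e-3 * np.mean(before.mean(0) ** 2)

    def test_zero_template_identity(self):
        rec, base, true = self._rec_with_bcg(amp=0.0)
        out = remove_bcg(rec, true)
        # template estimated from artifact-free data only removes the
        # R-locked mean of the background, which is tiny
        assert np.sqrt(np.mean((out.data - rec.data) ** 2)) < 0.2

    def test_simulated_bcg_attenuation(self, small_cfg, small_eeg):
        """Seeded simulation: R-locked average power drops >= 10x."""
        no_grad = remove_gradient_artifact(small_eeg)
        peaks = detect_qrs(no_grad.channel("ECG"), no_grad.rate)
        out = remove_bcg(no_grad, peaks)
        delay = int(small_cfg.artifact.bcg_delay * no_grad.rate)
        L = int(0.4 * no_grad.rate)
        ok = [p for p in peaks if p + delay + L <= no_grad.n_samples]

        def rlocked(d):
            ep = np.stack([d[:-1, p + delay : p + delay + L] for p in ok])
            return float(np.mean(ep.mean(axis=0) ** 2))

        assert rlocked(out.data) / rlocked(no_grad.data) < 1e-1

    def test_too_few_beats_rejected(self):
        rec, _, _ = self._rec_with_bcg()
        with pytest.raises(ValueError, match="beats"):
            remove_bcg(rec, np.arange(5) * 500)


class TestFilterChain:
    @pytest.mark.parametrize(
        "freq, lo, hi",
        [
            (10.0, 0.7, 1.01),   # passband
            (50.0, 0.0, 0.1),    # notch
            (18.0, 0.0, 0.1),    # slice-harmonic reject
            (25.0, 0.7, 1.01),
            (2.0, 0.7, 1.01),
        ],
    )
    def test_magnitude_response(self, freq, lo, hi):
        rate = 500.0
        t = np.arange(int(30 * rate)) / rate
        x = np.sin(2 * np.pi * freq * t)
        rec = EEGRecording(data=x[None, :], rate=rate, labels=["A"],
                           triggers=np.array([0]))
        out = filter_chain(rec)
        y = out.data[0]
        mid = y[y.size // 4 : 3 * y.size // 4]
        amp = np.sqrt(2.0) * mid.std()
        assert lo <= amp <= hi

    def test_output_rate_and_triggers(self, small_eeg):
        out = filter_chain(small_eeg)
        assert out.rate == 256.0
        expected = np.round(small_eeg.triggers * 256.0 / small_eeg.rate)
        assert np.array_equal(out.triggers, expected.astype(int))
        assert out.n_channels == small_eeg.n_channels

    def test_nyquist_validation(self):
        with pytest.raises(ValueError, match="Nyquist"):
            CleanConfig(bandpass=(0.5, 300.0))


class TestReplaceBadEpochs:
    def _rec(self):
        rate, tr, n_ep = 100.0, 2.0, 8
        spacing = int(tr * rate)
        data = np.concatenate(
            [np.full(spacing, float(i)) for i in range(n_ep)]
        )[None, :]
        trig = np.arange(n_ep) * spacing
        return EEGRecording(data=data, rate=rate, labels=["A"], triggers=trig), spacing

    def test_empty_bad_is_identity(self):
        rec, _ = self._rec()
        out = replace_bad_epochs(rec, [])
        assert np.array_equal(out.data, rec.data)

    def test_nearest_good_neighbor_earlier_on_tie(self):
        rec, sp = self._rec()
        out = replace_bad_epochs(rec, [5])
        assert np.all(out.data[0, 5 * sp : 6 * sp] == 4.0)

    def test_boundary_uses_next_epoch(self):
        rec, sp = self._rec()
        out = replace_bad_epochs(rec, [0])
        assert np.all(out.data[0, :sp] == 1.0)

    def test_all_bad_rejected(self):
        rec, _ = self._rec()
        with pytest.raises(ValueError, match="all epochs"):
            replace_bad_epochs(rec, list(range(8)))

    def test_out_of_range_rejected(self):
        rec, _ = self._rec()
        with pytest.raises(ValueError, match="outside"):
            replace_bad_epochs(rec, [99])


class TestAverageReference:
    def test_symmetric_pair_unchanged(self):
        rec = EEGRecording(
            data=np.array([[1.0, 1.0], [-1.0, -1.0]]), rate=10.0,
            labels=["A", "B"], triggers=np.array([0]),
        )
        out = rereference_average(rec)
        assert np.allclose(out.data, rec.data)

    def test_constant_offset_removed(self):
        rec = EEGRecording(
            data=np.array([[2.0, 2.0], [4.0, 4.0]]), rate=10.0,
            labels=["A", "B"], triggers=np.array([0]),
        )
        out = rereference_average(rec)
        assert np.allclose(out.data, [[-1.0, -1.0], [1.0, 1.0]])

    def test_zero_mean_postcondition_and_ecg_excluded(self, rng):
        data = rng.normal(size=(5, 200))
        rec = EEGRecording(
            data=data, rate=100.0, labels=["A", "B", "C", "D", "ECG"],
            triggers=np.array([0]), ecg="ECG",
        )
        out = rereference_average(rec)
        assert np.abs(out.data[:4].mean(axis=0)).max() < 1e-12
        assert np.array_equal(out.data[4], data[4])


class TestInvariants:
    def test_shape_and_labels_preserved(self, small_eeg):
        out = remove_gradient_artifact(small_eeg)
        assert out.data.shape == small_eeg.data.shape
        assert out.labels == small_eeg.labels

    def test_history_records_stages(self, small_eeg):
        from oscoupler.cleaning import clean_chain

        out = clean_chain(small_eeg)
        stages = [h["stage"] for h in out.history]
        for expected in (
            "remove_gradient_artifact",
            "remove_bcg",
            "filter_chain",
            "replace_bad_epochs",
            "rereference_average",
        ):
            assert expected in stages
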