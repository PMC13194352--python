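"""Fiducial detection accuracy against generator ground truth."""

import numpy as np
import pandas as pd
import pytest

from asdscreen import delineate as dl
from asdscreen import preprocess as pp
from asdscreen import synth


def _match(detected, truth, tol_ms):
    """(n true matched, n detected matched) with one-to-one greedy pairing."""
    used = np.zeros(detected.size, bool)
    hits = 0
    for t in truth:
        d = np.abs(detected - t)
        d[used] = np.inf
        if d.size and d.min() <= tol_ms:
            used[np.argmin(d)] = True
            hits += 1
    return hits, used.sum()


class TestDetectRPeaks:
    def test_clean_recovery_within_4ms(self, clean_filtered):
        ecg_f, _, gt = clean_filtered
        r = dl.detect_r_peaks(ecg_f)
        assert r.size == gt.n_beats
        assert np.max(np.abs(r - gt.r_peak_ms)) <= 4.0

    def test_flatline_gives_no_peaks(self):
        assert dl.detect_r_peaks(np.zeros(5000)).size == 0

    def test_noisy_sensitivity_and_precision(self):
        sens, prec = [], []
        for seed in range(20):
            ecg, gt = synth.generate_ecg(
                86, 30, 0.02, seed=seed, noise_snr_db=10.0
            )
            r = dl.detect_r_peaks(pp.bandpass_ecg(ecg))
            hits, matched = _match(r, gt.r_peak_ms, tol_ms=50.0)
            sens.append(hits / gt.n_beats)
            prec.append(matched / max(r.size, 1))
        assert np.mean(sens) >= 0.95
        assert np.mean(prec) >= 0.95

    def test_refractory_enforced(self, clean_filtered):
        ecg_f, _, _ = clean_filtered
        r = dl.detect_r_peaks(ecg_f)
        assert np.all(np.diff(r) > 200.0)


class TestDetectQOnset:
    def test_clean_error_within_4ms(self, clean_filtered):
        ecg_f, _, gt = clean_filtered
        r = dl.detect_r_peaks(ecg_f)
        q = dl.detect_q_onset(ecg_f, r)
        assert np.nanmax(np.abs(q - gt.q_onset_ms)) <= 4.0

    def test_empty_r_peaks_empty_output(self):
        assert dl.detect_q_onset(np.zeros(1000), np.array([])).size == 0

    def test_truncated_window_marks_beat_invalid(self, clean_filtered):
        ecg_f, _, _ = clean_filtered
        q = dl.detect_q_onset(ecg_f, np.array([30.0, 400.0]))
        assert np.isnan(q[0]) and np.isfinite(q[1])

    def test_noisy_median_error_within_8ms(self):
        errs = []
        for seed in range(10):
            ecg, gt = synth.generate_ecg(86, 30, 0.02, seed=seed, noise_snr_db=10.0)
            ecg_f = pp.bandpass_ecg(ecg)
            r = dl.detect_r_peaks(ecg_f)
            if r.size != gt.n_beats:
                continue
            q = dl.detect_q_onset(ecg_f, r)
            errs.extend(np.abs(q - gt.q_onset_ms)[np.isfinite(q)])
        assert np.median(errs) <= 8.0


class TestPcgEnvelope:
    def test_single_burst_argmax_aligned(self):
        fs = 2000.0
        t = np.arange(0, 1, 1 / fs) * 1000.0
        x = np.exp(-0.5 * ((t - 500.0) / 5.0) ** 2) * np.cos(
            2 * np.pi * 0.1 * (t - 500.0)
        )
        env = dl.pcg_envelope(x)
        assert abs(t[np.argmax(env)] - 500.0) <= 2.0

    def test_two_bursts_separated_40ms(self):
        fs = 2000.0
        t = np.arange(0, 1, 1 / fs) * 1000.0
        x = sum(
            np.exp(-0.5 * ((t - c) / 4.0) ** 2) * np.cos(2 * np.pi * 0.1 * (t - c))
            for c in (480.0, 520.0)
        )
        env = dl.pcg_envelope(x)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(env, height=0.5 * env.max())
        assert peaks.size == 2
        assert abs((t[peaks[1]] - t[peaks[0]]) - 40.0) <= 2.0

    def test_zero_input_zero_envelope(self):
        assert not np.any(dl.pcg_envelope(np.zeros(4000)))


class TestSegmentS1S2:
    def test_clean_peak_errors_within_2ms(self, clean_filtered):
        _, pcg_f, gt = clean_filtered
        env = dl.pcg_envelope(pcg_f)
        seg = dl.segment_s1_s2(env, gt.r_peak_ms)
        assert seg["valid"].all()
        # coarse S1 peak allows the envelope-smoothing displacement; the
        # pipeline refines it on the fine envelope
        assert np.max(np.abs(seg["s1_peak_ms"] - gt.s1_peak_ms)) <= 4.0
        assert np.max(np.abs(seg["s2_peak_ms"] - gt.a2_peak_ms)) <= 4.0

    def test_suppressed_s2_invalidates_only_that_beat(self, clean_beats):
        ecg, pcg, gt = clean_beats
        pcg = pcg.copy()
        k = 10
        fs = 2000.0
        lo = int((gt.a2_peak_ms[k] - 30) / 1000 * fs)
        hi = int((gt.p2_peak_ms[k] + 60) / 1000 * fs)
        pcg[lo:hi] = 0.0
        env = dl.pcg_envelope(pp.bandpass_pcg(pcg))
        seg = dl.segment_s1_s2(env, gt.r_peak_ms)
        assert not seg.loc[k, "valid"]
        assert seg["valid"].drop(k).all()

    def test_moderate_noise_beats_mostly_valid(self):
        n_valid = n_total = 0
        errs = []
        for seed in range(5):
            ecg, gt = synth.generate_ecg(86, 50, 0.02, seed=seed)
            pcg, gt = synth.generate_pcg(
                gt, 39.65, 96.2, 238.5, noise_snr_db=15.0, seed=seed + 100
            )
            env = dl.pcg_envelope(pp.bandpass_pcg(pcg))
            seg = dl.segment_s1_s2(env, gt.r_peak_ms)
            n_total += len(seg)
            ok = seg["valid"]
            n_valid += ok.sum()
            errs.extend(np.abs(seg.loc[ok, "s1_peak_ms"] - gt.s1_peak_ms[ok]))
        assert n_valid / n_total >= 0.95
        assert np.mean(np.asarray(errs) <= 4.0) >= 0.95


class TestSplitS2:
    def _estimate(self, pcg_f, gt, r_peaks=None):
        env = dl.pcg_envelope(pcg_f)
        seg = dl.segment_s1_s2(env, gt.r_peak_ms if r_peaks is None else r_peaks)
        out = []
        for k in range(len(seg)):
            win = (seg.loc[k, "s2_onset_ms"] - 20.0, seg.loc[k, "s2_onset_ms"] + 120.0)
            a2, p2 = dl.split_s2(pcg_f, win)
            out.append((a2, p2))
        return np.asarray(out)

    def test_reference_split_within_2ms(self, clean_filtered):
        _, pcg_f, gt = clean_filtered
        est = self._estimate(pcg_f, gt)
        split = est[:, 1] - est[:, 0]
        assert np.max(np.abs(split - 39.65)) <= 2.0

    def test_zero_split_reports_coincident_peaks(self):
        _, gt = synth.generate_ecg(86, 10, 0.0, seed=1)
        pcg, gt = synth.generate_pcg(gt, 0.0, 96.2, 238.5, noise_snr_db=30, seed=2)
        est = self._estimate(pp.bandpass_pcg(pcg), gt)
        split = est[:, 1] - est[:, 0]
        assert np.max(np.abs(split)) <= 2.0

    def test_translation_invariance(self, clean_beats):
        _, pcg, gt = clean_beats
        pcg_f = pp.bandpass_pcg(pcg)
        shift_ms = 250.0
        shifted = np.concatenate([np.zeros(int(shift_ms * 2)), pcg_f])
        k = 5
        on = gt.a2_peak_ms[k] - 15.0
        a2a, p2a = dl.split_s2(pcg_f, (on - 20.0, on + 120.0))
        a2b, p2b = dl.split_s2(shifted, (on + shift_ms - 20.0, on + shift_ms + 120.0))
        assert (p2b - a2b) == pytest.approx(p2a - a2a, abs=0.05)

    def test_empty_window_raises(self, clean_filtered):
        _, pcg_f, _ = clean_filtered
        with pytest.raises(ValueError):
            dl.split_s2(pcg_f, (100.0, 100.5))

    def test_monotone_degradation_with_noise(self):
        mean_err = []
        for snr in (30.0, 20.0, 15.0, 10.0):
            errs = []
            for seed in range(20):
                _, gt = synth.generate_ecg(86, 10, 0.0, seed=seed)
                pcg, gt = synth.generate_pcg(
                    gt, 39.65, 96.2, 238.5, noise_snr_db=snr, seed=seed + 1000
                )
                est = self._estimate(pp.bandpass_pcg(pcg), gt)
                errs.extend(np.abs((est[:, 1] - est[:, 0]) - 39.65))
            mean_err.append(np.mean(errs))
        assert all(b >= a - 0.05 for a, b in zip(mean_err, mean_err[1:]))


class TestSelectBeats:
    def _ann(self, n, rr=700.0):
        r = np.arange(n) * rr + 400.0
        return pd.DataFrame(
            {
                "q_onset_ms": r - 36.0,
                "r_peak_ms": r,
                "s1_onset_ms": r + 80.0,
                "s1_peak_ms": r + 96.2 - 36.0 + 36.0,
                "s2_onset_ms": r + 320.0,
                "a2_peak_ms": r + 334.7,
                "p2_peak_ms": r + 374.35,
                "rr_ms": rr,
                "valid": True,
            }
        )

    def test_earliest_run_selected(self):
        ann = self._ann(60)
        sel = dl.select_beats(ann, None, np.ones(60, bool), n_required=30)
        assert list(sel.index) == list(range(30))

    def test_run_restarts_after_masked_beats(self):
        ann = self._ann(60)
        flags = np.ones(60, bool)
        flags[4:8] = False  # beats 5-8 unusable
        sel = dl.select_beats(ann, None, flags, n_required=30)
        assert sel.index[0] == 8

    def test_artifact_windows_excluded_via_mask(self):
        ann = self._ann(60)
        dur = (ann["p2_peak_ms"].iloc[-1] + 500.0) / 1000.0
        n_win = int(np.ceil(dur))
        valid = np.ones(n_win, bool)
        valid[3:6] = False  # 3-6 s: overlaps beats ~4-8
        mask = pp.ArtifactMask(
            valid=valid,
            amp_variation=np.zeros(n_win),
            snr_db=np.full(n_win, 30.0),
            window_s=1.0,
            duration_s=dur,
        )
        sel = dl.select_beats(ann, mask, np.ones(60, bool), n_required=30)
        assert sel.index[0] >= 8

    def test_fallback_to_longest_run_with_warning(self):
        ann = self._ann(12)
        with pytest.warns(UserWarning, match="longest run"):
            sel = dl.select_beats(ann, None, np.ones(12, bool), n_required=30)
        assert len(sel) == 12

    def test_zero_qualifying_beats_raises(self):
        ann = self._ann(10)
        with pytest.raises(ValueError, match="excluded"):
            dl.select_beats(ann, None, np.zeros(10, bool), n_required=30)
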