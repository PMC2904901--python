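"""Phasic stage: segmentation, reconstruction, scoring, event attribution."""

import numpy as np
import pytest

from scdecomp import (
    BatemanParams,
    EventMarker,
    Signal,
    attribute_to_events,
    decompose_phasic,
    filter_significant,
    log_amplitude,
    reconstruct_scr,
    run_decomposition,
    trough_to_peak,
)

from conftest import FS, raised_cosine, scr_signal


@pytest.fixture(scope="module")
def single_scr(slow_kernel):
    sig, q0 = scr_signal([(20.0, 2.0)], slow_kernel, duration_s=120.0, bump_width=1.5)
    return sig, q0


class TestDecomposePhasic:
    def test_single_clean_scr(self, slow_kernel, single_scr):
        sig, _ = single_scr
        dd = decompose_phasic(sig, slow_kernel)
        assert len(dd.impulses) == 1
        assert len(dd.po_components) == 0
        imp = dd.impulses[0]
        assert imp.onset_time == pytest.approx(20.0, abs=2 / FS)
        assert imp.area == pytest.approx(1.5, rel=0.02)  # amp * width / 2

    def test_scr_with_pore_opening_bump(self, slow_kernel):
        n = int(120 * FS)
        t = np.arange(n) / FS
        flat = np.convolve(
            raised_cosine(t, 20, 1.5, 3.0), slow_kernel.samples * slow_kernel.dt
        )[:n]
        peaked = flat + raised_cosine(t, 21.5, 3.0, 0.08)
        dd = decompose_phasic(Signal(peaked, fs=FS), slow_kernel)
        assert len(dd.impulses) == 1
        assert len(dd.po_components) == 1
        po = dd.po_components[0]
        assert po.parent == 0
        assert po.onset_time >= dd.impulses[0].onset_time
        assert po.amplitude == pytest.approx(0.08, rel=0.15)

    def test_two_scrs_correct_onsets(self, slow_kernel):
        sig, _ = scr_signal([(20.0, 2.0), (24.0, 1.5)], slow_kernel, duration_s=120.0)
        dd = decompose_phasic(sig, slow_kernel)
        assert len(dd.impulses) == 2
        assert dd.impulses[0].onset_time == pytest.approx(20.0, abs=2 / FS)
        assert dd.impulses[1].onset_time == pytest.approx(24.0, abs=2 / FS)

    def test_impulses_seven_hundred_ms_apart_resolved(self, slow_kernel):
        sig, _ = scr_signal(
            [(20.0, 3.0), (20.7, 3.0)], slow_kernel, duration_s=80.0, bump_width=0.5
        )
        dd = decompose_phasic(sig, slow_kernel)
        assert len(dd.impulses) == 2

    def test_empty_input(self, slow_kernel):
        dd = decompose_phasic(Signal(np.zeros(200), fs=FS), slow_kernel)
        assert dd.impulses == [] and dd.po_components == []


class TestReconstruct:
    def test_single_scr_round_trip(self, slow_kernel, single_scr):
        sig, _ = single_scr
        dd = decompose_phasic(sig, slow_kernel)
        scr = reconstruct_scr(dd.impulses[0], dd.po_for(0), dd, slow_kernel)
        start = int(round(scr.waveform.t0 * FS))
        m = min(len(scr.waveform), len(sig) - start)
        err = np.abs(scr.waveform.values[:m] - sig.values[start : start + m])
        assert err.max() < 1e-3

    def test_without_po_waveform_is_pure_convolution(self, slow_kernel, single_scr):
        sig, _ = single_scr
        dd = decompose_phasic(sig, slow_kernel)
        scr = reconstruct_scr(dd.impulses[0], None, dd, slow_kernel)
        assert scr.po is None
        assert scr.area == pytest.approx(dd.impulses[0].area, abs=1e-12)

    def test_full_recording_recomposition(self, slow_kernel):
        sig, _ = scr_signal(
            [(40.0, 2.0), (90.0, 4.0), (160.0, 1.5)],
            slow_kernel,
            duration_s=300.0,
            baseline=1.5,
            noise_sigma=0.003,
        )
        res = run_decomposition(sig, BatemanParams(0.75, 20.0))
        resid = sig.values - res.recomposed.values
        assert np.sqrt(np.mean(resid**2)) == pytest.approx(res.rmse, abs=1e-12)
        assert res.rmse < 0.05

    def test_area_additivity_invariant(self, slow_kernel):
        n = int(120 * FS)
        t = np.arange(n) / FS
        flat = np.convolve(
            raised_cosine(t, 20, 1.5, 3.0), slow_kernel.samples * slow_kernel.dt
        )[:n]
        peaked = flat + raised_cosine(t, 21.5, 3.0, 0.08)
        res = run_decomposition(
            Signal(peaked + 1.0, fs=FS), BatemanParams(0.75, 20.0)
        )
        for scr in res.scrs:
            expected = scr.impulse.area + (scr.po.area if scr.po else 0.0)
            assert scr.area == pytest.approx(expected, abs=1e-6)


class TestFilterSignificant:
    def _fake_scr(self, amp, slow_kernel, sig_dd):
        scr = reconstruct_scr(sig_dd.impulses[0], None, sig_dd, slow_kernel)
        from dataclasses import replace

        return replace(scr, amplitude=amp)

    def test_threshold_inclusive(self, slow_kernel, single_scr):
        sig, _ = single_scr
        dd = decompose_phasic(sig, slow_kernel)
        scrs = [self._fake_scr(a, slow_kernel, dd) for a in (0.02, 0.009, 0.011, 0.01)]
        kept = filter_significant(scrs)
        assert [s.amplitude for s in kept] == [0.02, 0.011, 0.01]

    def test_empty_list(self):
        assert filter_significant([]) == []

    def test_sub_threshold_po_detached(self, slow_kernel):
        n = int(120 * FS)
        t = np.arange(n) / FS
        flat = np.convolve(
            raised_cosine(t, 20, 1.5, 3.0), slow_kernel.samples * slow_kernel.dt
        )[:n]
        peaked = flat + raised_cosine(t, 21.5, 3.0, 0.008)  # small PO bump
        dd = decompose_phasic(Signal(peaked, fs=FS), slow_kernel)
        assert dd.po_components
        scr = reconstruct_scr(dd.impulses[0], dd.po_for(0), dd, slow_kernel)
        kept = filter_significant([scr], min_po_amp=0.02)
        assert len(kept) == 1
        assert kept[0].po is None
        assert kept[0].area == pytest.approx(kept[0].impulse.area, abs=1e-12)


class TestAttributeToEvents:
    def _scrs(self, slow_kernel, onsets):
        sig, _ = scr_signal([(o, 3.0) for o in onsets], slow_kernel, duration_s=120.0)
        res = run_decomposition(sig, BatemanParams(0.75, 20.0))
        return sorted(res.scrs, key=lambda s: s.onset_time)

    def test_simple_attribution(self, slow_kernel):
        scrs = self._scrs(slow_kernel, [22.0])
        out = attribute_to_events(scrs, [EventMarker(20.0, "stim")], window=(1, 4))
        assert out[0].event_label == "stim"
        assert out[0].latency == pytest.approx(2.0, abs=0.1)

    def test_outside_window_not_attributed(self, slow_kernel):
        scrs = self._scrs(slow_kernel, [20.5])
        out = attribute_to_events(scrs, [EventMarker(20.0, "stim")], window=(1, 4))
        assert out[0].event_label is None

    def test_earlier_event_wins(self, slow_kernel):
        scrs = self._scrs(slow_kernel, [29.2])
        events = [EventMarker(24.0, "a"), EventMarker(28.0, "b")]
        out = attribute_to_events(scrs, events, window=(1, 4))
        # SCR at 29.2 qualifies for neither 'a' (latency 5.2) ... only 'b'
        assert out[0].event_label == "b"
        assert out[0].latency == pytest.approx(1.2, abs=0.1)

    def test_each_scr_used_once(self, slow_kernel):
        scrs = self._scrs(slow_kernel, [26.0])
        events = [EventMarker(24.0, "a"), EventMarker(24.5, "b")]
        out = attribute_to_events(scrs, events, window=(1, 4))
        assert out[0].event_label == "a"  # earlier event takes the only SCR


class TestTroughToPeak:
    def test_single_scr_amplitude(self, slow_kernel, single_scr):
        sig, _ = single_scr
        true_amp = sig.values.max()
        rows = trough_to_peak(sig, min_amp=0.01)
        assert len(rows) == 1
        onset, peak, amp = rows[0]
        assert amp == pytest.approx(true_amp, rel=0.05)
        assert onset < peak

    def test_superposed_second_scr_underestimated(self, slow_kernel):
        n = int(120 * FS)
        t = np.arange(n) / FS
        hd = slow_kernel.samples * slow_kernel.dt
        w1 = np.convolve(raised_cosine(t, 50, 1.5, 12.0), hd)[:n]
        w2 = np.convolve(raised_cosine(t, 54, 1.5, 3.0), hd)[:n]
        rows = trough_to_peak(Signal(w1 + w2, fs=FS), min_amp=0.01)
        second = [r for r in rows if abs(r[0] - 54) < 3]
        assert second
        assert second[0][2] < w2.max()  # recovery slope bias

    def test_flat_signal_no_detections(self):
        assert trough_to_peak(Signal(np.full(500, 2.0), fs=FS)) == []


class TestLogAmplitude:
    def test_closed_forms_and_monotonicity(self):
        assert log_amplitude(0.0) == 0.0
        assert log_amplitude(np.e - 1) == pytest.approx(1.0, abs=1e-12)
        values = [log_amplitude(a) for a in (0.01, 0.1, 0.5, 2.0)]
        assert values == sorted(values)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_amplitude(-0.1)
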