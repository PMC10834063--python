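import numpy as np
import pytest

from memti.mti_drive import Waveform
from memti.neuro_hh import (
    HHParams,
    SpikeTrain,
    StimulusSpec,
    SweepRow,
    _dstate,
    _gates_inf,
    amplitude_sweep,
    detect_spikes,
    hh_simulate,
    interface_current,
    lowpass,
    min_exposure_for_spike,
    plateau_onset,
    resting_potential,
    time_rescale,
    zero_spike_threshold,
)


def _sine(freq_hz: float, amp: float, duration_s: float, fs: float = 1e4) -> Waveform:
    t = np.arange(0, duration_s, 1 / fs)
    return Waveform(time=t, values=amp * np.sin(2 * np.pi * freq_hz * t), unit="uA/cm2")


class TestInterfaceCurrent:
    def test_zero_voltage(self):
        w = Waveform(time=np.linspace(0, 1, 10), values=np.zeros(10), unit="V")
        assert np.all(interface_current(w, StimulusSpec()).values == 0.0)

    def test_ohms_law_arithmetic(self):
        # 0.3 V across 1 MΩ is 0.3 μA before area normalization
        w = Waveform(time=np.linspace(0, 1, 10), values=np.full(10, 0.3), unit="V")
        spec = StimulusSpec(interface_resistance=1e6, effective_area=1.0)
        i = interface_current(w, spec)
        assert i.values[0] == pytest.approx(0.3, rel=1e-12)
        assert i.unit == "uA/cm2"

    def test_halving_resistance_doubles_current(self):
        w = Waveform(time=np.linspace(0, 1, 10), values=np.full(10, 0.1), unit="V")
        i1 = interface_current(w, StimulusSpec(interface_resistance=1e6))
        i2 = interface_current(w, StimulusSpec(interface_resistance=0.5e6))
        assert np.allclose(i2.values, 2 * i1.values)


class TestLowpass:
    def test_dc_gain_unity(self):
        t = np.arange(0, 1e-6, 1 / 3e9)
        w = Waveform(time=t, values=np.full_like(t, 2.5))
        out = lowpass(w, 100e6)
        assert np.allclose(out.values, 2.5, rtol=1e-3)

    def test_passband_62mhz(self):
        t = np.arange(0, 2e-6, 1 / 3e9)
        w = Waveform(time=t, values=np.sin(2 * np.pi * 62e6 * t))
        out = lowpass(w, 100e6)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert np.abs(out.values[mid]).max() > 0.7

    def test_stopband_188mhz(self):
        # 4th-order Butterworth applied twice: |H(1.88 fc)|² ≈ 0.0064
        t = np.arange(0, 2e-6, 1 / 3e9)
        w = Waveform(time=t, values=np.sin(2 * np.pi * 188e6 * t))
        out = lowpass(w, 100e6)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert np.abs(out.values[mid]).max() < 0.1

    def test_cutoff_above_nyquist_rejected(self):
        t = np.arange(0, 1e-3, 1e-6)
        w = Waveform(time=t, values=np.zeros_like(t))
        with pytest.raises(ValueError):
            lowpass(w, 1e6)


class TestTimeRescale:
    def test_identity_factor(self):
        w = _sine(62.0, 1.0, 0.1)
        out = time_rescale(w, 1.0)
        assert np.array_equal(out.time, w.time)
        assert np.array_equal(out.values, w.values)

    def test_62mhz_maps_to_62hz(self):
        t = np.arange(0, 1e-6, 1 / 3e9)
        w = Waveform(time=t, values=np.sin(2 * np.pi * 62e6 * t))
        out = time_rescale(w, 1e6)
        from memti.core_dynamics import tone_amplitude

        assert tone_amplitude(out, 62.0) == pytest.approx(1.0, rel=1e-2)

    def test_round_trip(self):
        w = _sine(62.0, 1.0, 0.1)
        back = time_rescale(time_rescale(w, 1e6), 1e-6)
        assert np.allclose(back.time, w.time)


class TestHHDynamics:
    def test_resting_state_is_fixed_point(self):
        p = HHParams()
        v_rest = resting_potential(p)
        n, m, h = _gates_inf(v_rest)
        dv, dn, dm, dh = _dstate(v_rest, n, m, h, 0.0, p)
        assert abs(dv) < 1e-6

    def test_no_stimulus_stays_at_rest(self):
        p = HHParams()
        trace = hh_simulate(None, p, duration=500.0)
        st = detect_spikes(trace)
        assert st.count == 0
        assert np.abs(trace.v_m - trace.v_m[0]).max() < 1.0

    def test_sustained_dc_fires_repetitively(self):
        t = np.arange(0, 0.2, 1e-4)
        w = Waveform(time=t, values=np.full_like(t, 15.0), unit="uA/cm2")
        trace = hh_simulate(w, duration=200.0)
        st = detect_spikes(trace)
        assert st.count >= 5
        # spike shape brackets the repolarization/depolarization levels
        assert 25.0 < trace.v_m.max() < 45.0
        assert trace.v_m.min() < -70.0

    def test_gates_remain_in_unit_interval(self):
        t = np.arange(0, 0.1, 1e-4)
        w = Waveform(time=t, values=np.full_like(t, 20.0), unit="uA/cm2")
        trace = hh_simulate(w, duration=100.0)
        for g in (trace.n, trace.m, trace.h):
            assert g.min() >= 0.0 and g.max() <= 1.0

    def test_step_halving_convergence(self):
        t = np.arange(0, 0.2, 1e-4)
        w = Waveform(time=t, values=np.full_like(t, 12.0), unit="uA/cm2")
        t1 = detect_spikes(hh_simulate(w, duration=200.0, dt=0.01))
        t2 = detect_spikes(hh_simulate(w, duration=200.0, dt=0.005))
        assert t1.count == t2.count
        assert np.abs(t1.spike_times - t2.spike_times).max() < 0.1

    def test_nonfinite_state_aborts_with_diagnostic(self):
        # a pathological initial voltage overflows the gate rates; the
        # integrator must abort with a timestamped diagnostic, not emit NaNs
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            with pytest.raises(FloatingPointError, match="t ="):
                hh_simulate(None, v0=-1e5, duration=1.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HHParams(VK=-50.0, VL=-54.4, VNa=50.0)


class TestDetectSpikes:
    def test_flat_trace(self):
        from memti.neuro_hh import HHTrace

        t = np.linspace(0, 100, 1000)
        tr = HHTrace(time=t, v_m=np.full_like(t, -65.0),
                     n=np.empty(0), m=np.empty(0), h=np.empty(0))
        assert detect_spikes(tr).count == 0

    def test_triangle_wave_counts_crossings(self):
        from memti.neuro_hh import HHTrace

        t = np.linspace(0, 30, 3001)
        # one symmetric triangular peak (apex +70 mV) per 10 ms period
        v = -80.0 + 150.0 * (1.0 - np.abs((t % 10.0) - 5.0) / 5.0)
        tr = HHTrace(time=t, v_m=v, n=np.empty(0), m=np.empty(0), h=np.empty(0))
        assert detect_spikes(tr, threshold=0.0, refractory=2.0).count == 3

    def test_count_invariant_over_threshold_band(self):
        t = np.arange(0, 0.2, 1e-4)
        w = Waveform(time=t, values=np.full_like(t, 15.0), unit="uA/cm2")
        trace = hh_simulate(w, duration=200.0)
        counts = {
            detect_spikes(trace, threshold=th).count
            for th in np.linspace(-20.0, 10.0, 7)
        }
        assert len(counts) == 1


@pytest.fixture(scope="module")
def sine_rows():
    stim = _sine(62.0, 1.0, 0.5)
    peaks = np.array([0.5, 1.0, 1.5, 2.5, 5.0, 10.0, 20.0])
    return peaks, amplitude_sweep(
        stim, 1.0 / peaks, HHParams(), StimulusSpec(exposure=500.0)
    )


class TestAmplitudeSweep:
    def test_zero_current_no_spikes(self):
        stim = _sine(62.0, 1.0, 0.2)
        rows = amplitude_sweep(stim, np.array([1e9]), HHParams(),
                               StimulusSpec(exposure=200.0))
        assert rows[0].count == 0

    def test_threshold_structure_exists(self, sine_rows):
        peaks, rows = sine_rows
        counts = np.array([r.count for r in rows])
        assert counts[0] == 0  # subthreshold
        assert counts[-1] > 0  # suprathreshold
        # no re-entrant zero band above 1.5x the first spiking amplitude
        first = np.nonzero(counts > 0)[0][0]
        above = peaks >= 1.5 * peaks[first]
        assert np.all(counts[above] > 0)

    def test_high_amplitude_entrains_one_to_one(self, sine_rows):
        peaks, rows = sine_rows
        # 0.5 s of 62 Hz: 1:1 locking gives 31 ± 1 spikes
        assert abs(rows[-1].count - 31) <= 1
        assert rows[-1].regular

    def test_invalid_scale_rejected(self):
        stim = _sine(62.0, 1.0, 0.2)
        with pytest.raises(ValueError):
            amplitude_sweep(stim, np.array([-1.0]), HHParams(), StimulusSpec())

    def test_helper_extractors(self, sine_rows):
        peaks, rows = sine_rows
        thr = zero_spike_threshold(rows)
        assert thr == pytest.approx(peaks[np.array([r.count for r in rows]) == 0].max())
        onset = plateau_onset(rows)
        assert onset is not None
        assert onset.count == rows[-1].count


class TestMinExposure:
    def test_subthreshold_returns_sentinel(self):
        stim = _sine(62.0, 0.5, 0.2)
        assert min_exposure_for_spike(stim, HHParams(), StimulusSpec()) is None

    def test_strong_stimulus_fast_charging(self):
        stim = _sine(62.0, 50.0, 0.2)
        t_min = min_exposure_for_spike(stim, HHParams(), StimulusSpec())
        assert t_min is not None
        assert t_min <= 2.0

    def test_resolution_bound(self):
        stim = _sine(62.0, 10.0, 0.2)
        t_min = min_exposure_for_spike(
            stim, HHParams(), StimulusSpec(), resolution=0.5
        )
        # re-running at finer resolution may only shrink the estimate
        t_fine = min_exposure_for_spike(
            stim, HHParams(), StimulusSpec(), resolution=0.25
        )
        assert t_fine <= t_min + 0.25
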