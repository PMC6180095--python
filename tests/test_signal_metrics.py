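"""Filtering, resultant and HIC engine tests.

The HIC oracle here is an independent exhaustive double loop over all
ordered sample pairs with its own trapezoid integration, never the row-scan
implementation under test.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from playfall import (
    AlignmentError,
    HICResult,
    InvalidParameterError,
    TriaxSignal,
    UniformSignal,
    UnitError,
    butterworth_filtfilt,
    hic,
    hic_variants,
    hic_window_duration,
    peak_metrics,
    resultant,
)

FS = 20_000.0
DT = 1.0 / FS


def usig(samples, dt=DT, unit="g", t0=0.0):
    return UniformSignal(t0, dt, np.asarray(samples, dtype=float), unit)


def haversine(peak, duration, dt=DT, pad=0.0):
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    a = peak * np.sin(np.pi * t / duration) ** 2
    npad = int(round(pad / dt))
    return np.concatenate([np.zeros(npad), a, np.zeros(npad)])


def hic_bruteforce(samples, dt, window_limit=math.inf):
    """Exhaustive double-loop HIC with per-pair trapezoid integration."""
    n = len(samples)
    best = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            span = (j - i) * dt
            if span > window_limit * (1 + 1e-12):
                break
            integral = np.trapezoid(samples[i : j + 1], dx=dt)
            mean = max(integral / span, 0.0)
            best = max(best, span * mean**2.5)
    return best


class TestButterworthFiltfilt:
    def test_dc_gain_is_unity(self):
        sig = usig(np.full(400, 7.25))
        out = butterworth_filtfilt(sig, 1000.0)
        assert np.allclose(out.samples, 7.25, rtol=1e-9)

    def test_repeated_filtering_leaves_constant_unchanged(self):
        sig = usig(np.full(300, 3.0))
        for _ in range(3):
            sig = butterworth_filtfilt(sig, 500.0)
        assert np.allclose(sig.samples, 3.0, rtol=1e-8)

    def test_two_pass_attenuation_at_cutoff_is_half(self):
        # each pass is -3 dB at the cutoff; forward+backward gives 0.5
        f_c = 500.0
        t = np.arange(0, 0.5, DT)
        sig = usig(np.sin(2 * np.pi * f_c * t))
        out = butterworth_filtfilt(sig, f_c)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        amp = np.max(np.abs(out.samples[mid]))
        assert amp == pytest.approx(0.5, rel=0.02)

    def test_zero_phase_preserves_symmetric_pulse_peak(self):
        samples = haversine(150.0, 0.010, pad=0.005)
        out = butterworth_filtfilt(usig(samples), 2077.5)
        assert int(np.argmax(out.samples)) == int(np.argmax(samples))

    def test_metadata_preserved(self):
        sig = usig(haversine(100.0, 0.01), t0=0.25)
        out = butterworth_filtfilt(sig, 180.0)
        assert (out.t0, out.dt, out.n, out.unit) == (sig.t0, sig.dt, sig.n, sig.unit)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        sig = usig(np.zeros(100) + 1.0)
        with pytest.raises(InvalidParameterError, match="Nyquist"):
            butterworth_filtfilt(sig, FS / 2)


class TestResultant:
    def test_pythagorean_constant(self):
        tri = TriaxSignal.from_arrays(
            0.0, DT, np.full(10, 3.0), np.full(10, 4.0), np.zeros(10), unit="g"
        )
        assert np.allclose(resultant(tri).samples, 5.0)

    def test_single_axis_gives_absolute_value(self):
        a = np.array([-2.0, 1.0, -3.5, 0.0])
        tri = TriaxSignal.from_arrays(0.0, DT, a, np.zeros(4), np.zeros(4), unit="g")
        assert np.allclose(resultant(tri).samples, np.abs(a))

    def test_matches_elementwise_oracle(self, rng):
        x, y, z = rng.normal(size=(3, 64))
        tri = TriaxSignal.from_arrays(0.0, DT, x, y, z, unit="m_s2")
        oracle = np.array([math.sqrt(a * a + b * b + c * c) for a, b, c in zip(x, y, z)])
        assert np.allclose(resultant(tri).samples, oracle, rtol=0, atol=1e-12)

    def test_misaligned_channels_rejected(self):
        a = UniformSignal(0.0, DT, np.zeros(10) + 1, "g")
        b = UniformSignal(0.0, DT, np.zeros(11) + 1, "g")
        with pytest.raises(AlignmentError):
            TriaxSignal(a, a, b)


class TestHIC:
    def test_constant_pulse_closed_form(self):
        # 100 g for 10 ms: HIC = 0.010 * 100^2.5 = 1000 exactly
        sig = usig(np.full(201, 100.0))  # 201 samples at 20 kHz spans 10 ms
        r = hic(sig)
        assert r.value == pytest.approx(1000.0, rel=1e-12)
        assert r.duration == pytest.approx(0.010, rel=1e-12)

    def test_constant_pulse_with_window_cap(self):
        sig = usig(np.full(401, 100.0))  # 20 ms
        r = hic(sig, window_limit=0.015)
        assert r.value == pytest.approx(1500.0, rel=1e-12)
        assert r.duration <= 0.015 * (1 + 1e-9)

    def test_haversine_matches_bruteforce_oracle(self):
        samples = haversine(150.0, 0.010)
        sig = usig(samples)
        r = hic(sig)
        assert r.value == pytest.approx(hic_bruteforce(samples, DT), rel=1e-9)

    def test_windowed_haversine_matches_bruteforce_oracle(self):
        samples = haversine(120.0, 0.025)
        sig = usig(samples)
        for limit in (0.005, 0.015):
            assert hic(sig, limit).value == pytest.approx(
                hic_bruteforce(samples, DT, limit), rel=1e-9
            )

    def test_achieving_window_matches_bruteforce_argmax(self):
        samples = haversine(150.0, 0.010)
        r = hic(usig(samples))
        n = len(samples)
        best, best_pair = 0.0, (0, 1)
        for i in range(n - 1):
            for j in range(i + 1, n):
                span = (j - i) * DT
                mean = max(np.trapezoid(samples[i : j + 1], dx=DT) / span, 0.0)
                val = span * mean**2.5
                if val > best * (1 + 1e-12):
                    best, best_pair = val, (i, j)
        assert hic_window_duration(r) == pytest.approx((best_pair[1] - best_pair[0]) * DT, rel=1e-9)

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_amplitude_scaling_law(self, c, rng):
        samples = np.abs(rng.normal(50.0, 20.0, size=120))
        base = hic(usig(samples)).value
        scaled = hic(usig(c * samples)).value
        assert scaled == pytest.approx(c**2.5 * base, rel=1e-9)

    def test_time_stretch_scales_constant_pulse_hic(self):
        a = np.full(101, 80.0)
        h1 = hic(usig(a, dt=DT)).value
        h3 = hic(usig(a, dt=3 * DT)).value
        assert h3 == pytest.approx(3.0 * h1, rel=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_window_cap_ordering(self, seed):
        rng = np.random.default_rng(seed)
        dur = rng.uniform(0.004, 0.06)
        samples = haversine(rng.uniform(20, 200), dur, dt=5e-4)
        sig = usig(samples, dt=5e-4)
        v = {k: r.value for k, r in hic_variants(sig).items()}
        assert v["hic15"] <= v["hic36"] * (1 + 1e-12)
        assert v["hic36"] <= v["hic"] * (1 + 1e-12)

    def test_sub_15ms_pulse_makes_all_variants_equal(self):
        # short stopping pulses: the achieving window fits inside 15 ms,
        # so HIC15, HIC36 and unlimited HIC coincide
        samples = haversine(150.0, 0.010)
        v = {k: r.value for k, r in hic_variants(usig(samples)).items()}
        assert v["hic15"] == pytest.approx(v["hic"], rel=1e-12)
        assert v["hic36"] == pytest.approx(v["hic"], rel=1e-12)

    def test_all_zero_signal_shortest_earliest_window(self):
        r = hic(usig(np.zeros(50), t0=1.0))
        assert r.value == 0.0
        assert r.t1 == pytest.approx(1.0)
        assert r.duration == pytest.approx(DT)

    def test_non_g_unit_rejected(self):
        with pytest.raises(UnitError):
            hic(usig(np.ones(10), unit="m_s2"))

    def test_window_result_invariants(self):
        with pytest.raises(InvalidParameterError):
            HICResult(value=1.0, t1=0.01, t2=0.005)
        with pytest.raises(InvalidParameterError):
            HICResult(value=-1.0, t1=0.0, t2=0.01)


class TestPeakMetrics:
    def test_constant_single_axis(self):
        n = 300
        lin = TriaxSignal.from_arrays(
            0.0, DT, np.full(n, 100.0), np.zeros(n), np.zeros(n), unit="g"
        )
        peaks = peak_metrics(lin)
        assert peaks.peak_lin_g == pytest.approx(100.0, rel=1e-6)
        assert peaks.peak_ang_acc_rad_s2 is None

    def test_zero_angular_channels_give_zero_peaks(self):
        a = haversine(50.0, 0.012, pad=0.0015)
        m = len(a)
        lin = TriaxSignal.from_arrays(0.0, DT, a, np.zeros(m), np.zeros(m), unit="g")
        ang = TriaxSignal.from_arrays(0.0, DT, np.zeros(m), np.zeros(m), np.zeros(m), unit="rad_s2")
        peaks = peak_metrics(lin, ang_acc=ang)
        assert peaks.peak_ang_acc_rad_s2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_filter_then_resultant_recomputation(self, rng):
        m = 400
        arrs = rng.normal(0.0, 30.0, size=(3, m))
        lin = TriaxSignal.from_arrays(0.0, DT, *arrs, unit="g")
        peaks = peak_metrics(lin)
        filt = [butterworth_filtfilt(c, 180.0) for c in (lin.x, lin.y, lin.z)]
        oracle = float(np.max(np.sqrt(sum(f.samples**2 for f in filt))))
        assert peaks.peak_lin_g == pytest.approx(oracle, rel=1e-12)
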