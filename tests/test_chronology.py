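"""Wavelet periodicity, growth-rate calibration and phase synchronization."""

import numpy as np
import pytest

from sealniche.chronology import (
    ChronologyError,
    ChronologyResult,
    SynchronizationError,
    WhiskerChronology,
    WhiskerSeries,
    WindowCoverageError,
    assign_times,
    detect_period,
    estimate_growth_rate,
    phase_synchronize,
    refine_period,
    truncate_common_window,
    wavelet_power,
)


def _sine_series(period_mm, n, spacing=3.0, noise=0.0, seed=0, trend=0.0):
    rng = np.random.default_rng(seed)
    x = spacing * (np.arange(n) + 0.5)
    return np.sin(2 * np.pi * x / period_mm) + trend * x + noise * rng.standard_normal(n)


def _fft_period(values, spacing):
    """Independent periodogram oracle: argmax of the zero-padded FFT."""
    v = values - values.mean()
    v = v - np.polyval(np.polyfit(np.arange(v.size), v, 1), np.arange(v.size))
    n_pad = 16 * v.size
    spec = np.abs(np.fft.rfft(v, n_pad))
    freqs = np.fft.rfftfreq(n_pad, d=spacing)
    spec[0] = 0.0
    return 1.0 / freqs[np.argmax(spec)]


def test_pure_sine_ridge_sits_at_the_tone():
    wp = wavelet_power(_sine_series(60.0, 80), 3.0)
    assert (wp.power >= 0).all()
    det = detect_period(wp)
    assert det.periodic and det.consistent
    assert det.period_mm == pytest.approx(60.0, rel=0.05)
    # ridge holds the tone across most of the series
    ridge_ok = np.abs(det.ridge_periods_mm / 60.0 - 1.0) < 0.1
    assert ridge_ok.mean() > 0.8


def test_scale_range_spans_spec():
    wp = wavelet_power(_sine_series(60.0, 80), 3.0)
    assert wp.periods_mm.min() <= 4 * 3.0
    assert wp.periods_mm.max() >= 80 * 3.0 / 2


def test_white_noise_is_not_periodic():
    rng = np.random.default_rng(11)
    wp = wavelet_power(rng.standard_normal(80), 3.0)
    det = detect_period(wp, seed=1)
    assert not det.periodic


def test_linear_trend_does_not_shift_the_period():
    det_plain = detect_period(wavelet_power(_sine_series(60.0, 80), 3.0))
    det_trend = detect_period(wavelet_power(_sine_series(60.0, 80, trend=0.05), 3.0))
    assert det_trend.periodic
    assert det_trend.period_mm == pytest.approx(det_plain.period_mm, rel=0.05)


def test_constant_series_flags_false():
    wp = wavelet_power(np.zeros(40) + 1.0, 3.0)
    det = detect_period(wp)
    assert not det.periodic and not det.consistent
    assert np.isnan(det.period_mm)


def test_short_series_rejected_by_transform():
    with pytest.raises(ValueError, match="too short"):
        wavelet_power(np.arange(8.0), 3.0)


def test_split_period_series_is_inconsistent():
    half1 = _sine_series(40.0, 54)
    half2 = _sine_series(80.0, 54)
    det = detect_period(wavelet_power(np.r_[half1, half2], 3.0))
    assert not det.consistent


@pytest.mark.parametrize("period", [24.0, 45.0, 62.0, 90.0])
def test_detect_period_matches_fft_oracle_on_tones(period):
    """Wavelet ridge and an FFT periodogram agree within one scale step."""
    values = _sine_series(period, 96, noise=0.05, seed=3)
    det = detect_period(wavelet_power(values, 3.0))
    fft_p = _fft_period(values, 3.0)
    step = 2.0 ** (1.0 / 24.0)  # one voice of the scale grid
    assert det.periodic
    assert 1.0 / (step * 1.5) < det.period_mm / fft_p < step * 1.5


def _series_of(n, spacing=3.0):
    vals = np.zeros(n)
    return WhiskerSeries("T1", "M", vals, vals, section_mm=spacing)


@pytest.mark.parametrize(
    "period,expected_growth",
    [(62.05, 0.17), (32.85, 0.09)],
)
def test_growth_rate_is_period_over_year(period, expected_growth):
    n_cycles, g = estimate_growth_rate(_series_of(62), period)
    assert g == pytest.approx(expected_growth)
    assert n_cycles == pytest.approx(62 * 3.0 / period)


def test_growth_rate_cycle_count_division():
    n_cycles, _ = estimate_growth_rate(_series_of(62), 62.0)
    assert n_cycles == pytest.approx(3.0)


def test_growth_rate_requires_a_period():
    with pytest.raises(ChronologyError, match="T1"):
        estimate_growth_rate(_series_of(62), float("nan"))


def test_assign_times_arithmetic_and_scaling():
    s = _series_of(10)
    t = assign_times(s, 0.15)
    assert t[0] == pytest.approx(1.5 / 0.15)  # 10 days
    assert np.allclose(np.diff(assign_times(s, 0.09)), 3.0 / 0.09)
    assert np.allclose(assign_times(s, 0.30), t / 2.0)
    with pytest.raises(ValueError):
        assign_times(s, 0.0)


# ---------------------------------------------------------------------------
# Phase synchronization
# ---------------------------------------------------------------------------


def _chronology_from_signal(ind, phase_days, growth=0.17, n_years=4.0,
                            noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(n_years * 365 * growth / 3.0)
    mid = 3.0 * (np.arange(n) + 0.5)
    t = mid / growth
    vals = np.sin(2 * np.pi * (t - phase_days) / 365.0) + noise * rng.standard_normal(n)
    series = WhiskerSeries(ind, "M", vals, vals)
    return ChronologyResult(
        individual=ind, sex="M", detections={}, chosen_isotope="d13c",
        period_mm=growth * 365.0, n_cycles=n_years, growth_rate=growth,
        days_per_year=365.0, section_times_days=t, series=series,
    )


def test_lag_zero_for_identical_series():
    ref = _chronology_from_signal("R", 0.0)
    assert phase_synchronize(ref, ref) == 0.0


def test_recovers_injected_delay():
    ref = _chronology_from_signal("R", 0.0, noise=0.02, seed=1)
    tgt = _chronology_from_signal("T", 30.0, noise=0.02, seed=2)
    lag = phase_synchronize(tgt, ref)
    assert lag == pytest.approx(30.0, abs=1.0)


def test_antiphase_lag_hits_the_half_period_boundary():
    ref = _chronology_from_signal("R", 0.0)
    tgt = _chronology_from_signal("T", 182.5)
    lag = phase_synchronize(tgt, ref)
    assert abs(lag) in (182.0, 183.0)


def test_synchronization_needs_one_cycle_of_overlap():
    ref = _chronology_from_signal("R", 0.0, n_years=1.05)
    tgt = _chronology_from_signal("T", 0.0, n_years=1.05)
    tgt.section_times_days = tgt.section_times_days + 5000.0  # no overlap
    with pytest.raises(SynchronizationError):
        phase_synchronize(tgt, ref)


# ---------------------------------------------------------------------------
# Common window
# ---------------------------------------------------------------------------


def test_window_section_count_at_male_growth():
    res = _chronology_from_signal("A", 0.0, growth=0.17, n_years=4.0)
    res.phase_lag_days = 0.0
    df = truncate_common_window([res])
    assert len(df) == 51  # floor(912.5 * 0.17 / 3)


def test_zero_window_is_empty():
    res = _chronology_from_signal("A", 0.0)
    res.phase_lag_days = 0.0
    assert truncate_common_window([res], window_years=0.0).empty


def test_window_coverage_error_names_offenders():
    long = _chronology_from_signal("LONG", 0.0, n_years=4.0)
    short = _chronology_from_signal("SHORT", 0.0, n_years=1.2)
    for r in (long, short):
        r.phase_lag_days = 0.0
    with pytest.raises(WindowCoverageError, match="SHORT"):
        truncate_common_window([long, short])


def test_window_retains_equal_time_spans_not_sections(chron1):
    """Every individual contributes ~2.5 years, in different section counts."""
    window = chron1["window"]
    spans = {}
    counts = {}
    for res in chron1["results"]:
        sub = window[window.individual == res.individual]
        counts[res.individual] = len(sub)
        spans[res.individual] = len(sub) * 3.0 / res.growth_rate
    days_per_section = {r.individual: r.days_per_section for r in chron1["results"]}
    for ind, span in spans.items():
        # up to one partial section can be trimmed at each window edge
        assert abs(span - 912.5) <= 2.0 * days_per_section[ind] + 1e-9
    assert max(counts.values()) > 1.3 * min(counts.values())  # males vs females


def test_full_fit_recovers_growth_on_population(pop1, chron1):
    """End-to-end: estimated growth within 5% of each animal's truth."""
    for res in chron1["results"]:
        g_true = pop1.individual_truth(res.individual).growth_rate
        assert res.growth_rate == pytest.approx(g_true, rel=0.05)
        assert res.days_per_section * res.growth_rate == pytest.approx(3.0)


def test_unperiodic_whisker_raises_chronology_error():
    rng = np.random.default_rng(0)
    w = WhiskerSeries("N1", "M", rng.standard_normal(60), rng.standard_normal(60))
    with pytest.raises(ChronologyError, match="N1"):
        WhiskerChronology(w).fit()
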