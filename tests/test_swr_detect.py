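import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import ripplesync as rs
from ripplesync.exceptions import DegenerateSignalError, NyquistError
from ripplesync.motion import ImmobilityMask
from ripplesync.signal_io import LfpTrace
from ripplesync.swr_detect import EnvelopeZ, detect_events, event_spectrum, ripple_envelope_z

from oracles import detect_events_bruteforce

FS = 2000.0


def _trace(samples, fs=FS):
    return LfpTrace(np.asarray(samples, float), fs=fs)


def _all_immobile(n, fs=FS):
    return ImmobilityMask(mask=np.ones(n, bool), fs=fs)


# ---------------------------------------------------------------- envelope


def test_out_of_band_signal_not_detected(rng):
    t = np.arange(0, 10, 1 / FS)
    sig = 100.0 * np.sin(2 * np.pi * 50.0 * t) + rng.normal(0, 1.0, t.size)
    envz = ripple_envelope_z(_trace(sig))
    events = detect_events(envz, _all_immobile(t.size))
    assert events.empty


def test_burst_detected_and_matches_rms_oracle(rng):
    """A 200 Hz burst at 8x the noise SD must push z above 5 inside the burst.

    Cross-checked against a windowed-RMS estimate of band power, an
    independent route to the same quantity.
    """
    t = np.arange(0, 20, 1 / FS)
    noise = rng.normal(0, 10.0, t.size)
    burst = 80.0 * np.exp(-((t - 10.0) ** 2) / (2 * 0.01**2)) * np.sin(2 * np.pi * 200 * t)
    envz = ripple_envelope_z(_trace(noise + burst))
    inside = slice(int(9.95 * FS), int(10.05 * FS))
    assert envz.z[inside].max() > 5.0
    # oracle: short-time RMS of the band-passed trace peaks in the same window
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, [150, 250], btype="bandpass", fs=FS, output="sos")
    bp = sosfiltfilt(sos, noise + burst)
    rms = np.sqrt(np.convolve(bp**2, np.ones(40) / 40, mode="same"))
    assert abs(int(np.argmax(rms)) - int(np.argmax(envz.z))) < 0.01 * FS


def test_z_is_scale_and_offset_invariant(rng):
    sig = rng.normal(0, 10, int(5 * FS))
    a = ripple_envelope_z(_trace(sig))
    b = ripple_envelope_z(_trace(sig * 10.0 + 500.0))
    assert np.allclose(a.z, b.z, atol=1e-9)


def test_normalization_epoch_statistics(rng):
    """z has mean ~0 and SD ~1 over the normalization epoch (edges excluded)."""
    sig = rng.normal(0, 10, int(5 * FS))
    envz = ripple_envelope_z(_trace(sig))
    n_edge = int(0.5 * FS)
    core = envz.z[n_edge:-n_edge]
    assert abs(core.mean()) < 1e-6
    assert abs(core.std() - 1.0) < 1e-6


def test_constant_signal_degenerate():
    with pytest.raises(DegenerateSignalError):
        ripple_envelope_z(_trace(np.full(int(2 * FS), 3.0)))


def test_nyquist_guard():
    with pytest.raises(NyquistError):
        ripple_envelope_z(_trace(np.random.default_rng(0).normal(0, 1, 1000), fs=400.0))


# ---------------------------------------------------------------- detection


def _envz_from_z(z, fs=FS):
    return EnvelopeZ(z=np.asarray(z, float), fs=fs, band=(150.0, 250.0), mu=0.0, sigma=1.0)


def test_constructed_run_duration_and_peak():
    z = np.zeros(8000)
    z[2000:2060] = 6.0
    z[2030] = 7.0
    events = detect_events(_envz_from_z(z), _all_immobile(z.size))
    assert len(events) == 1
    ev = events.iloc[0]
    assert ev["duration_ms"] == pytest.approx(30.0)
    assert 1.0 <= ev["peak_time_s"] < 1.03
    assert ev["amplitude_z"] == pytest.approx(7.0)


def test_zero_envelope_empty_table():
    events = detect_events(_envz_from_z(np.zeros(4000)), _all_immobile(4000))
    assert events.empty


@pytest.mark.parametrize(
    "merge_gap_ms,n_expected,duration_expected",
    [(10.0, 1, 44.0), (2.0, 2, 20.0)],
)
def test_gap_merging(merge_gap_ms, n_expected, duration_expected):
    z = np.zeros(8000)
    z[1000:1040] = 6.0  # 20 ms
    z[1048:1088] = 6.0  # 4 ms gap, then 20 ms
    events = detect_events(_envz_from_z(z), _all_immobile(z.size), merge_gap_ms=merge_gap_ms)
    assert len(events) == n_expected
    assert events.iloc[0]["duration_ms"] == pytest.approx(duration_expected)


def test_event_gated_by_peak_immobility():
    z = np.zeros(8000)
    z[1000:1060] = 6.0
    mobile = ImmobilityMask(mask=np.zeros(z.size, bool), fs=FS)
    assert detect_events(_envz_from_z(z), mobile).empty
    assert len(detect_events(_envz_from_z(z), _all_immobile(z.size))) == 1


def test_threshold_monotonicity(rng):
    z = rng.normal(0, 2.5, 10_000).cumsum() * 0.02 + rng.normal(0, 2, 10_000)
    counts = [
        len(detect_events(_envz_from_z(z), _all_immobile(z.size), threshold_sd=thr))
        for thr in (3.0, 4.0, 5.0, 6.0)
    ]
    assert counts == sorted(counts, reverse=True)


@pytest.mark.parametrize("merge_gap_ms", [0.0, 2.0, 10.0])
def test_detection_equals_bruteforce_oracle(merge_gap_ms, rng):
    for _ in range(5):
        z = rng.normal(3.0, 2.0, 10_000)
        immobile = rng.uniform(size=z.size) < 0.7
        mask = ImmobilityMask(mask=immobile, fs=FS)
        events = detect_events(
            _envz_from_z(z), mask, merge_gap_ms=merge_gap_ms, min_duration_ms=5.0
        )
        expected = detect_events_bruteforce(z, FS, 5.0, merge_gap_ms, 5.0, immobile)
        got = [
            (int(round(row["start_s"] * FS)), int(round(row["end_s"] * FS)))
            for _, row in events.iterrows()
        ]
        assert got == expected


def test_detection_invariant_to_trace_scaling(rng):
    sig = rng.normal(0, 10, int(10 * FS))
    sig[10000:10100] += 200 * np.sin(2 * np.pi * 200 * np.arange(100) / FS)
    mask = _all_immobile(sig.size)
    a = detect_events(ripple_envelope_z(_trace(sig)), mask)
    b = detect_events(ripple_envelope_z(_trace(sig * 7.0 - 40.0)), mask)
    assert np.allclose(a["peak_time_s"], b["peak_time_s"], atol=1e-9)


# ---------------------------------------------------------------- spectra


def test_pure_tone_frequency_peak(rng):
    t = np.arange(0, 4, 1 / FS)
    sig = 50 * np.sin(2 * np.pi * 200.0 * t) + rng.normal(0, 0.5, t.size)
    mp, fp = event_spectrum(_trace(sig), 2.0, 2.03)
    df = 1.0 / 0.064  # 64 ms window -> 15.6 Hz resolution
    assert abs(fp - 200.0) <= df


def test_amplitude_doubling_adds_6db(rng):
    t = np.arange(0, 4, 1 / FS)
    base = np.sin(2 * np.pi * 210.0 * t) + 0.01 * rng.standard_normal(t.size)
    mp1, _ = event_spectrum(_trace(50 * base), 2.0, 2.03)
    mp2, _ = event_spectrum(_trace(100 * base), 2.0, 2.03)
    assert mp2 - mp1 == pytest.approx(20 * np.log10(2), abs=0.01)


def test_white_noise_peak_has_no_bin_preference(rng):
    """freq_peak on white noise should be uniform over the band's bins."""
    from scipy.stats import chisquare

    counts = {}
    for _ in range(1000):
        sig = rng.standard_normal(int(0.3 * FS))
        _, fp = event_spectrum(_trace(sig), 0.10, 0.15)
        counts[fp] = counts.get(fp, 0) + 1
    observed = np.array(list(counts.values()))
    assert chisquare(observed).pvalue > 0.01


# ---------------------------------------------------------------- sharp waves


def test_sharp_wave_window_boundary(rng):
    """Peaks at +20 ms flag the ripple; peaks at +40 ms do not."""
    t = np.arange(0, 30, 1 / FS)
    sig = rng.normal(0, 10.0, t.size)
    # two ripples; a large slow transient 20 ms after the first, 40 ms after the second
    for t_r, dt_sw in ((10.0, 0.020), (20.0, 0.040)):
        sig += 150 * np.exp(-((t - t_r) ** 2) / (2 * 0.008**2)) * np.sin(2 * np.pi * 200 * t)
        tc = t_r + dt_sw
        sigma = 0.040 / 2.355
        sig += -300.0 * ((t - tc) / sigma) * np.exp(0.5 - (t - tc) ** 2 / (2 * sigma**2))
    lfp = _trace(sig)
    events = detect_events(ripple_envelope_z(lfp), _all_immobile(t.size), lfp=lfp)
    assert len(events) == 2
    flagged, pct = rs.sharp_wave_flags(lfp, events)
    assert flagged["has_sharp_wave"].tolist() == [True, False]
    assert pct == pytest.approx(50.0)


# ---------------------------------------------------------------- summaries


def test_density_arithmetic():
    events = pd.DataFrame({"duration_ms": np.full(6, 30.0)})
    mask = ImmobilityMask(mask=np.ones(int(60 * FS), bool), fs=FS)
    summ = rs.summarize(events, mask)
    assert summ.density_hz == pytest.approx(0.1)


@pytest.mark.parametrize(
    "durations,expected",
    [([20.0, 30.0], 0.5), ([25.0, 25.0, 25.0], 0.0)],
)
def test_fraction_long_strict(durations, expected):
    events = pd.DataFrame({"duration_ms": durations})
    mask = ImmobilityMask(mask=np.ones(int(10 * FS), bool), fs=FS)
    assert rs.summarize(events, mask, long_cutoff_ms=25.0).fraction_long == expected


def test_zero_immobile_time_is_error():
    events = pd.DataFrame({"duration_ms": [30.0]})
    mask = ImmobilityMask(mask=np.zeros(1000, bool), fs=FS)
    with pytest.raises(ZeroDivisionError):
        rs.summarize(events, mask)


def test_durations_track_injected_widths():
    """Detected durations increase monotonically with injected envelope widths."""
    cfg = rs.preset_config(
        "wt",
        duration_s=400.0,
        seed=5,
        ripple_rate_hz=0.12,
        width_range_ms=(8.0, 30.0),
        coupled_fraction=0.0,
    )
    lfp_ca1, _, track, truth = rs.generate_session(cfg)
    mask = rs.immobility_mask(rs.compute_speed(track), lfp_ca1)
    events = rs.detect_events(rs.ripple_envelope_z(lfp_ca1), mask, lfp=lfp_ca1)
    score = rs.score_detection(truth.ca1, events)
    assert score.recall > 0.9
    det = events.sort_values("peak_time_s")
    tr = truth.ca1.sort_values("peak_time_s")
    merged = pd.merge_asof(
        det, tr, left_on="peak_time_s", right_on="peak_time_s",
        direction="nearest", tolerance=0.02, suffixes=("_det", "_true"),
    ).dropna(subset=["width_ms"])
    rho = spearmanr(merged["width_ms"], merged["duration_ms_det"]).statistic
    assert rho > 0.9
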