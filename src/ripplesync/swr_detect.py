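"""Sharp-wave ripple detection and per-event metrics.

The detector follows the classical envelope-thresholding scheme: the LFP is
band-pass filtered in the ripple band (150-250 Hz), the instantaneous
magnitude of the analytic signal (Hilbert envelope) is z-scored against its
session statistics, and maximal runs of samples whose z-value exceeds 5
standard deviations are taken as ripple events, gated to times when the
animal is immobile.  Event duration is the supra-threshold extent; amplitude
is the peak z-value.  Per-event spectral metrics (mean ripple-band power in
dB/Hz and the frequency of the power-spectrum peak) are computed on the raw,
unfiltered snippet.  Sharp-wave co-occurrence applies the same machinery to
the 1-50 Hz band and asks whether a sharp-wave peak falls within +/-30 ms of
the ripple peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import DegenerateSignalError, NyquistError
from .motion import ImmobilityMask
from .signal_io import EVENT_COLUMNS, LfpTrace, empty_event_table, validate_event_table

RIPPLE_BAND = (150.0, 250.0)
SHARP_WAVE_BAND = (1.0, 50.0)
DETECTION_THRESHOLD_SD = 5.0
#: seconds excluded at each edge when estimating envelope mean/SD
EDGE_EXCLUDE_S = 0.5


@dataclass(frozen=True)
class EnvelopeZ:
    """Z-scored Hilbert envelope of a band-passed trace.

    ``z = (envelope - mu) / sigma`` where ``mu`` and ``sigma`` are the
    envelope mean and SD over the normalization epoch (filter edge
    transients excluded).  By construction mean(z) ~ 0 and SD(z) ~ 1 over
    that epoch.
    """

    z: np.ndarray
    fs: float
    band: tuple[float, float]
    mu: float
    sigma: float
    t0: float = 0.0

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.z.size) / self.fs


@dataclass(frozen=True)
class SwrSummary:
    """Session-level event summary for one electrode."""

    n_events: int
    density_hz: float
    mean_duration_ms: float
    fraction_long: float
    long_cutoff_ms: float


def _bandpass_sos(band: tuple[float, float], fs: float, order: int = 4):
    low, high = band
    if fs <= 2.0 * high:
        raise NyquistError(
            f"sampling rate {fs} Hz cannot support a band up to {high} Hz"
        )
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def ripple_envelope_z(
    lfp: LfpTrace,
    band: tuple[float, float] = RIPPLE_BAND,
    norm_epoch: str = "whole_session",
    mask: ImmobilityMask | None = None,
    squared: bool = False,
) -> EnvelopeZ:
    """Band-pass, Hilbert-transform and z-score one LFP trace.

    The filter is a zero-phase 4th-order Butterworth applied
    forward-backward (so event timing is not skewed), the envelope is the
    magnitude of the analytic signal, and ``mu``/``sigma`` are estimated
    over ``norm_epoch`` with the first and last 0.5 s excluded to avoid
    filter transients.

    Parameters
    ----------
    lfp : LfpTrace
    band : (low_hz, high_hz)
        Pass band; ripple band 150-250 Hz by default.
    norm_epoch : {"whole_session", "immobile_only"}
        Samples used to estimate the envelope mean and SD.  The
        ``immobile_only`` option requires ``mask``.
    mask : ImmobilityMask, optional
        Needed only for ``norm_epoch="immobile_only"``.
    squared : bool
        Use the squared envelope (power) instead of the magnitude.
    """
    if norm_epoch not in ("whole_session", "immobile_only"):
        raise ValueError(f"unknown norm_epoch {norm_epoch!r}")
    if norm_epoch == "immobile_only" and mask is None:
        raise ValueError("immobile_only normalization requires an immobility mask")
    if lfp.duration < 1.0:
        raise DegenerateSignalError("trace shorter than 1 s")
    if np.ptp(lfp.samples) == 0:
        raise DegenerateSignalError("constant signal: envelope SD is zero")
    sos = _bandpass_sos(band, lfp.fs)
    filtered = sps.sosfiltfilt(sos, lfp.samples)
    envelope = np.abs(sps.hilbert(filtered))
    if squared:
        envelope = envelope**2
    n_edge = int(round(EDGE_EXCLUDE_S * lfp.fs))
    keep = np.zeros(envelope.size, dtype=bool)
    if envelope.size > 2 * n_edge + 1:
        keep[n_edge : envelope.size - n_edge] = True
    else:
        keep[:] = True
    if norm_epoch == "immobile_only":
        keep &= mask.mask
        if not keep.any():
            raise DegenerateSignalError("no immobile samples to normalize against")
    mu = float(envelope[keep].mean())
    sigma = float(envelope[keep].std())
    if sigma == 0.0:
        raise DegenerateSignalError("constant signal: envelope SD is zero")
    z = (envelope - mu) / sigma
    return EnvelopeZ(z=z, fs=lfp.fs, band=tuple(band), mu=mu, sigma=sigma, t0=lfp.t0)


def _supra_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, stop) index pairs."""
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    """Merge runs separated by fewer than ``max_gap`` samples."""
    if not runs:
        return []
    merged = [runs[0]]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < max_gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return merged


def detect_events(
    envz: EnvelopeZ,
    mask: ImmobilityMask | None,
    threshold_sd: float = DETECTION_THRESHOLD_SD,
    merge_gap_ms: float = 10.0,
    min_duration_ms: float = 5.0,
    *,
    lfp: LfpTrace | None = None,
    region: str = "CA1",
    electrode_id: str = "e0",
    session_id: str = "s0",
) -> pd.DataFrame:
    """Segment supra-threshold envelope runs into events.

    Events are maximal runs of samples with ``z > threshold_sd``; runs
    separated by less than ``merge_gap_ms`` are merged, and merged runs
    shorter than ``min_duration_ms`` are discarded.  When an immobility
    mask is given an event is kept iff the sample at its z-peak is
    immobile.  Duration is the merged supra-threshold extent, ``peak_time``
    the argmax of z within the event, and amplitude that maximum.

    Returns an event table (possibly empty); the spectral columns are NaN
    until filled by :func:`event_spectrum`, and ``peak_to_trough_uv`` is
    filled from the raw trace when ``lfp`` is given.
    """
    z = envz.z
    if mask is not None and len(mask) != z.size:
        raise ValueError("mask and envelope must have the same length")
    runs = _supra_runs(z > threshold_sd)
    gap_samples = merge_gap_ms / 1000.0 * envz.fs
    runs = _merge_runs(runs, gap_samples)
    min_samples = min_duration_ms / 1000.0 * envz.fs
    rows = []
    if lfp is not None:
        region = lfp.region
        electrode_id = lfp.electrode_id
        session_id = lfp.session_id
    for start, stop in runs:
        if stop - start < min_samples:
            continue
        seg = z[start:stop]
        i_peak = start + int(np.argmax(seg))
        if mask is not None and not mask.mask[i_peak]:
            continue
        p2t = np.nan
        if lfp is not None:
            raw_seg = lfp.samples[start:stop]
            p2t = float(raw_seg.max() - raw_seg.min())
        rows.append(
            {
                "session_id": session_id,
                "electrode_id": electrode_id,
                "region": region,
                "start_s": envz.t0 + start / envz.fs,
                "end_s": envz.t0 + stop / envz.fs,
                "peak_time_s": envz.t0 + i_peak / envz.fs,
                "duration_ms": (stop - start) / envz.fs * 1000.0,
                "amplitude_z": float(seg.max()),
                "peak_to_trough_uv": p2t,
                "mean_power_db": np.nan,
                "freq_peak_hz": np.nan,
                "has_sharp_wave": False,
            }
        )
    if not rows:
        return empty_event_table()
    return validate_event_table(pd.DataFrame(rows, columns=EVENT_COLUMNS))


def event_spectrum(
    lfp: LfpTrace,
    start_s: float,
    end_s: float,
    band: tuple[float, float] = RIPPLE_BAND,
    pad_ms: float = 64.0,
) -> tuple[float, float]:
    """Mean ripple-band power (dB/Hz) and frequency peak of one event.

    The raw (unfiltered) snippet is taken around the event midpoint, padded
    symmetrically to at least ``pad_ms`` for spectral support, and its PSD
    estimated by a Hann-windowed periodogram.  ``mean_power_db`` is the mean
    of ``10*log10(PSD)`` over the bins inside ``band``; ``freq_peak`` is
    the frequency of the largest PSD value inside the band.
    """
    fs = lfp.fs
    n_min = int(round(pad_ms / 1000.0 * fs))
    mid = 0.5 * (start_s + end_s)
    n_evt = int(round((end_s - start_s) * fs))
    n_win = max(n_evt, n_min)
    i_mid = lfp.index_at(mid)
    i0 = max(0, i_mid - n_win // 2)
    i1 = min(lfp.n_samples, i0 + n_win)
    i0 = max(0, i1 - n_win)
    snippet = lfp.samples[i0:i1]
    if snippet.size < 2:
        raise ValueError("event window shorter than 2 samples")
    freqs, psd = sps.periodogram(snippet, fs=fs, window="hann")
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError("no PSD bins inside the requested band")
    psd_band = psd[in_band]
    with np.errstate(divide="ignore"):
        mean_power_db = float(np.mean(10.0 * np.log10(psd_band)))
    freq_peak = float(freqs[in_band][int(np.argmax(psd_band))])
    return mean_power_db, freq_peak


def attach_spectra(
    lfp: LfpTrace, events: pd.DataFrame, band: tuple[float, float] = RIPPLE_BAND
) -> pd.DataFrame:
    """Fill ``mean_power_db`` and ``freq_peak_hz`` for every event in place."""
    events = events.copy()
    for i, row in events.iterrows():
        mp, fp = event_spectrum(lfp, row["start_s"], row["end_s"], band=band)
        events.loc[i, "mean_power_db"] = mp
        events.loc[i, "freq_peak_hz"] = fp
    return events


def sharp_wave_flags(
    lfp: LfpTrace,
    events: pd.DataFrame,
    sw_band: tuple[float, float] = SHARP_WAVE_BAND,
    sw_threshold_sd: float = DETECTION_THRESHOLD_SD,
    window_ms: float = 30.0,
) -> tuple[pd.DataFrame, float]:
    """Flag ripple events that co-occur with a sharp wave.

    Sharp-wave events are detected independently with the same
    envelope-threshold machinery on the 1-50 Hz band (no immobility gate).
    A ripple is flagged when any sharp-wave peak lies within
    ``+/- window_ms`` of its own peak (peak-to-peak anchoring).

    Returns the updated table and the co-occurrence percentage (NaN for an
    empty table).
    """
    envz_sw = ripple_envelope_z(lfp, band=sw_band)
    sw_events = detect_events(
        envz_sw, mask=None, threshold_sd=sw_threshold_sd, lfp=lfp
    )
    events = events.copy()
    if events.empty:
        return events, float("nan")
    sw_peaks = np.sort(sw_events["peak_time_s"].to_numpy()) if not sw_events.empty else np.array([])
    w = window_ms / 1000.0
    flags = np.zeros(len(events), dtype=bool)
    if sw_peaks.size:
        peaks = events["peak_time_s"].to_numpy()
        lo = np.searchsorted(sw_peaks, peaks - w, side="left")
        hi = np.searchsorted(sw_peaks, peaks + w, side="right")
        flags = hi > lo
    events["has_sharp_wave"] = flags
    pct = 100.0 * flags.mean()
    return events, float(pct)


def summarize(
    events: pd.DataFrame, mask: ImmobilityMask, long_cutoff_ms: float = 25.0
) -> SwrSummary:
    """Event density, mean duration and long-event fraction.

    Density is events per second of immobile time; ``fraction_long`` is the
    fraction of events with duration strictly greater than
    ``long_cutoff_ms``.
    """
    t_imm = mask.total_immobile_duration
    if t_imm <= 0:
        raise ZeroDivisionError("density undefined: zero immobile time")
    n = len(events)
    durations = events["duration_ms"].to_numpy(float)
    return SwrSummary(
        n_events=n,
        density_hz=n / t_imm,
        mean_duration_ms=float(durations.mean()) if n else float("nan"),
        fraction_long=float((durations > long_cutoff_ms).mean()) if n else float("nan"),
        long_cutoff_ms=long_cutoff_ms,
    )
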