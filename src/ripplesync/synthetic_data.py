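"""Seeded generator of paired CA1/MEC LFP sessions with ground truth.

The generator produces the statistical structure the analysis assumes, so
every stage of the pipeline can be exercised and scored without recorded
data:

* 1/f-like background noise per channel (independent between regions);
* ripple bursts: windowed sinusoids at a ripple-band carrier, placed by a
  Poisson process restricted to immobile epochs.  The default envelope
  rises quickly and decays exponentially (an alpha-like window); a
  symmetric Gaussian window is available.  The asymmetric default matters
  for directed-influence analyses: an exponential tail is (near-)exactly
  linearly self-predictable, so the follower region's past adds no
  spurious "reverse" information, whereas perfectly symmetric smooth
  envelopes make the two regions mutually predictive regardless of lead
  direction;
* sharp waves: slow biphasic transients co-added with each ripple with a
  configurable probability;
* cross-region coupling: ripple propagation from the leading region to the
  following one.  The lead region is implied by the sign of the configured
  lag (negative = MEC leads CA1); a coupled fraction of lead-region events
  is copied into the other region at the lag (mean + per-event Gaussian
  jitter) with rescaled amplitude, the remainder placed independently;
* a position track realizing an alternating mobile/immobile block schedule
  at the camera rate.

Identical seeds give bit-identical sessions.  Presets named after the two
cohorts of interest ship with the package: ``wt`` (MEC leads CA1 by 8.9 ms,
strong coupling) and ``ad`` (MEC lags CA1 by 23.2 ms, weaker coupling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter1d

from .exceptions import ConfigError
from .signal_io import LfpTrace, PositionTrack

TRUTH_COLUMNS = [
    "peak_time_s",
    "width_ms",  # envelope width parameter (Gaussian SD or exponential decay)
    "duration_ms",  # envelope full width at half maximum
    "amplitude_uv",
    "has_sharp_wave",
    "partner",  # index of the coupled event in the other region's table, -1 if none
    "lag_ms",  # realized MEC minus CA1 peak-time lag of the pair, NaN if none
]


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic dual-site session.

    Rates are per second of immobile time; amplitudes are multiples of the
    broadband background SD; the ripple envelope width parameter (the
    Gaussian SD or the exponential decay constant, in ms) is drawn
    lognormally unless ``width_range_ms`` pins a uniform range.
    """

    fs: float = 2000.0
    duration_s: float = 600.0
    pos_fs: float = 50.0
    # background
    noise_exponent: float = 1.0
    noise_sd_uv: float = 30.0
    # ripple bursts
    ripple_rate_hz: float = 0.1
    ripple_freq_hz: float = 200.0
    width_median_ms: float = 8.0
    width_sigma: float = 0.35
    width_range_ms: tuple[float, float] | None = None
    min_width_ms: float = 7.0
    ripple_amplitude_sd: float = 8.0
    amplitude_jitter: float = 0.1
    ripple_env_shape: str = "exp"  # fast rise / exponential decay; or "gaussian"
    ripple_rise_ms: float = 6.0  # rise time constant of the "exp" shape
    ripple_mod_depth: float = 0.0
    ripple_mod_tau_ms: float = 4.0
    min_separation_s: float = 0.25
    # sharp waves
    sharp_wave_prob: float = 0.95
    sharp_wave_amplitude_sd: float = 8.0
    sharp_wave_width_ms: float = 40.0
    # MEC coupling (negative lag = MEC leads)
    coupled_fraction: float = 0.8
    lag_mean_ms: float = -8.9
    lag_jitter_ms: float = 5.0
    coupling_waveform: str = "propagated"  # or "independent"
    # mobility schedule
    mobile_block_s: float = 20.0
    immobile_block_s: float = 20.0
    mobile_speed_cm_s: float = 15.0
    track_length_cm: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fs",
            "duration_s",
            "pos_fs",
            "noise_sd_uv",
            "ripple_rate_hz",
            "sharp_wave_prob",
            "lag_jitter_ms",
            "sharp_wave_width_ms",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if not 0.0 <= self.coupled_fraction <= 1.0:
            raise ConfigError("coupled_fraction must lie in [0, 1]")
        if not 0.0 <= self.sharp_wave_prob <= 1.0:
            raise ConfigError("sharp_wave_prob must lie in [0, 1]")
        if self.mobile_block_s < 0 or self.immobile_block_s < 0:
            raise ConfigError("block durations must be nonnegative")
        if self.immobile_block_s == 0 and self.ripple_rate_hz > 0:
            raise ConfigError("impossible schedule: events requested but no immobile time")


@dataclass(frozen=True)
class GroundTruth:
    """Injected event catalogs and the immobility schedule."""

    ca1: pd.DataFrame
    mec: pd.DataFrame
    immobile_intervals: list[tuple[float, float]]

    @property
    def immobile_duration(self) -> float:
        return float(sum(b - a for a, b in self.immobile_intervals))


@dataclass(frozen=True)
class DetectionScore:
    """Greedy one-to-one truth/detection match summary."""

    recall: float
    precision: float  # NaN when there are no detections
    n_truth: int
    n_detected: int
    n_matched: int
    timing_errors_ms: np.ndarray  # detected peak - true peak, per match


def load_presets() -> dict:
    """Cohort presets shipped with the package (YAML)."""
    text = resources.files("ripplesync").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def preset_config(name: str, **overrides) -> SynthConfig:
    """A SynthConfig for a named preset, with optional field overrides."""
    presets = load_presets()
    if name not in presets:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(presets)}")
    params = dict(presets[name])
    params.update(overrides)
    return SynthConfig(**params)


def immobility_schedule(cfg: SynthConfig) -> list[tuple[float, float]]:
    """Immobile intervals of the alternating block schedule (mobile first)."""
    out: list[tuple[float, float]] = []
    period = cfg.mobile_block_s + cfg.immobile_block_s
    if period <= 0:
        raise ConfigError("impossible schedule: zero-length blocks")
    t = cfg.mobile_block_s
    while t < cfg.duration_s:
        out.append((t, min(t + cfg.immobile_block_s, cfg.duration_s)))
        t += period
    return out


def _pink_noise(n: int, exponent: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent Gaussian noise normalized to the requested SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    noise = np.fft.irfft(spec * scale, n=n)
    return noise / noise.std() * sd


def _draw_times_in_intervals(
    intervals: list[tuple[float, float]],
    n: int,
    rng: np.random.Generator,
    margin: float = 0.15,
) -> np.ndarray:
    """Uniform samples over the union of intervals, shrunk by a margin."""
    shrunk = [(a + margin, b - margin) for a, b in intervals if b - a > 2 * margin]
    if not shrunk or n == 0:
        return np.empty(0)
    lengths = np.array([b - a for a, b in shrunk])
    weights = lengths / lengths.sum()
    choice = rng.choice(len(shrunk), size=n, p=weights)
    u = rng.uniform(size=n)
    starts = np.array([a for a, _ in shrunk])
    return np.sort(starts[choice] + u * lengths[choice])


def _draw_flags_exact(n: int, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean flags whose realized fraction equals ``prob`` up to rounding.

    A stratified draw (exactly round(prob * n) True values at random
    positions) keeps the generator's realized co-occurrence rate pinned to
    its configuration instead of fluctuating binomially.
    """
    k = int(round(prob * n))
    flags = np.zeros(n, dtype=bool)
    flags[rng.choice(n, size=k, replace=False)] = True
    return flags


def _enforce_separation(times: np.ndarray, min_sep: float) -> np.ndarray:
    if times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= min_sep:
            kept.append(t)
    return np.asarray(kept)


def _ripple_envelope(t_rel: np.ndarray, width_s: float, shape: str, rise_s: float) -> np.ndarray:
    """Unit-peak burst envelope, centered so its maximum sits at t_rel = 0."""
    if shape == "gaussian":
        return np.exp(-(t_rel**2) / (2 * width_s**2))
    if shape == "exp":
        # alpha-like: (1 - e^(-t/rise)) e^(-t/decay), shifted to peak at 0
        t_pk = rise_s * np.log1p(width_s / rise_s)
        t = t_rel + t_pk
        env = np.where(t > 0, -np.expm1(-np.maximum(t, 0) / rise_s) * np.exp(-t / width_s), 0.0)
        peak = -np.expm1(-t_pk / rise_s) * np.exp(-t_pk / width_s)
        return env / peak
    raise ConfigError(f"unknown ripple_env_shape {shape!r}")


def _ripple_waveform(
    t_rel: np.ndarray,
    width_s: float,
    amplitude: float,
    freq: float,
    phase: float,
    shape: str = "gaussian",
    rise_s: float = 0.004,
) -> np.ndarray:
    env = _ripple_envelope(t_rel, width_s, shape, rise_s)
    return amplitude * env * np.cos(2 * np.pi * freq * t_rel + phase)


def _sharp_wave_waveform(t_rel: np.ndarray, width_s: float, amplitude: float) -> np.ndarray:
    """Biphasic slow transient: derivative-of-Gaussian scaled to peak amplitude."""
    sigma = width_s / 2.355  # width given as the FWHM of the underlying Gaussian
    return -amplitude * (t_rel / sigma) * np.exp(0.5 - t_rel**2 / (2 * sigma**2))


def _add_events(
    trace: np.ndarray,
    cfg: SynthConfig,
    times: np.ndarray,
    widths_ms: np.ndarray,
    amps: np.ndarray,
    phases: np.ndarray,
    sw_flags: np.ndarray,
    mod_seeds: np.ndarray,
) -> None:
    """Add ripple bursts (plus optional sharp waves) to a trace in place.

    Each burst's stochastic envelope modulation is keyed by its own
    ``mod_seed`` so a propagated (coupled) event in the other region can
    reproduce the same envelope trajectory.
    """
    fs = cfg.fs
    n = trace.size
    sw_amp = cfg.sharp_wave_amplitude_sd * cfg.noise_sd_uv
    sw_width_s = cfg.sharp_wave_width_ms / 1000.0
    tau = max(cfg.ripple_mod_tau_ms, 1e-3) / 1000.0 * fs
    for tp, w_ms, a, ph, sw, mseed in zip(
        times, widths_ms, amps, phases, sw_flags, mod_seeds
    ):
        w_s = w_ms / 1000.0
        half = 4 * w_s if cfg.ripple_env_shape == "gaussian" else 8 * w_s
        i0 = max(0, int(np.floor((tp - half) * fs)))
        i1 = min(n, int(np.ceil((tp + half) * fs)) + 1)
        t_rel = np.arange(i0, i1) / fs - tp
        burst = _ripple_waveform(
            t_rel,
            w_s,
            a,
            cfg.ripple_freq_hz,
            ph,
            shape=cfg.ripple_env_shape,
            rise_s=cfg.ripple_rise_ms / 1000.0,
        )
        if cfg.ripple_mod_depth > 0:
            # ripple envelopes wax and wane cycle-to-cycle; a deterministic
            # Gaussian window would be unrealistically self-predictable
            mod_rng = np.random.default_rng(int(mseed))
            n_mod = int(np.ceil(2 * half * fs)) + 3
            eta = gaussian_filter1d(mod_rng.standard_normal(n_mod), tau)[: t_rel.size]
            sd = eta.std()
            if sd > 0:
                burst *= np.clip(1.0 + cfg.ripple_mod_depth * eta / sd, 0.0, None)
        trace[i0:i1] += burst
        if sw:
            half_sw = 2.5 * sw_width_s
            j0 = max(0, int(np.floor((tp - half_sw) * fs)))
            j1 = min(n, int(np.ceil((tp + half_sw) * fs)) + 1)
            t_sw = np.arange(j0, j1) / fs - tp
            trace[j0:j1] += _sharp_wave_waveform(t_sw, sw_width_s, sw_amp)


def _draw_widths(cfg: SynthConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.width_range_ms is not None:
        lo, hi = cfg.width_range_ms
        widths = rng.uniform(lo, hi, size=n)
    else:
        widths = cfg.width_median_ms * np.exp(rng.normal(0.0, cfg.width_sigma, size=n))
    return np.maximum(widths, cfg.min_width_ms)


def _fwhm_ms(widths_ms: np.ndarray, shape: str, rise_ms: float) -> np.ndarray:
    """Envelope full width at half maximum, per event."""
    if shape == "gaussian":
        return 2.355 * np.asarray(widths_ms, float)
    out = np.empty(len(widths_ms))
    for i, w in enumerate(widths_ms):
        t = np.linspace(-4 * w, 10 * w, 2048) / 1000.0
        env = _ripple_envelope(t, w / 1000.0, shape, rise_ms / 1000.0)
        above = t[env >= 0.5]
        out[i] = (above[-1] - above[0]) * 1000.0 if above.size else 0.0
    return out


def _truth_frame(
    times: np.ndarray,
    widths_ms: np.ndarray,
    amps: np.ndarray,
    sw_flags: np.ndarray,
    partners: np.ndarray,
    lags_ms: np.ndarray,
    cfg: SynthConfig,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_time_s": times,
            "width_ms": widths_ms,
            "duration_ms": _fwhm_ms(widths_ms, cfg.ripple_env_shape, cfg.ripple_rise_ms),
            "amplitude_uv": amps,
            "has_sharp_wave": sw_flags.astype(bool),
            "partner": partners.astype(int),
            "lag_ms": lags_ms,
        },
        columns=TRUTH_COLUMNS,
    )


def generate_session(
    cfg: SynthConfig, session_id: str = "synth"
) -> tuple[LfpTrace, LfpTrace, PositionTrack, GroundTruth]:
    """Simulate one dual-site session.

    Returns the CA1 trace, the MEC trace, the 50 Hz position track and the
    ground-truth catalogs.  Event placement, waveform parameters, noise and
    the position trace all derive deterministically from ``cfg.seed``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_noise_ca1, rng_noise_mec, rng_events = [
        np.random.default_rng(child) for child in ss.spawn(3)
    ]
    n = int(round(cfg.duration_s * cfg.fs))
    intervals = immobility_schedule(cfg)
    t_imm = sum(b - a for a, b in intervals)

    expected = cfg.ripple_rate_hz * t_imm
    if 0 < expected < 1:
        warnings.warn(
            f"expected event count {expected:.2f} < 1; session will often be empty",
            stacklevel=2,
        )

    # --- leader events --------------------------------------------------
    # The region whose ripples come first is the "leader"; coupled events
    # in the other region are delayed, rescaled copies of the leader's
    # envelope (ripple propagation), the rest are independent.
    leader_is_mec = cfg.lag_mean_ms < 0
    delay_s = abs(cfg.lag_mean_ms) / 1000.0

    n_lead = rng_events.poisson(expected)
    t_lead = _draw_times_in_intervals(intervals, n_lead, rng_events)
    t_lead = _enforce_separation(t_lead, cfg.min_separation_s)
    n_lead = t_lead.size
    w_lead = _draw_widths(cfg, n_lead, rng_events)
    a_lead = (
        cfg.ripple_amplitude_sd
        * cfg.noise_sd_uv
        * np.exp(rng_events.normal(0.0, cfg.amplitude_jitter, size=n_lead))
    )
    ph_lead = rng_events.uniform(0, 2 * np.pi, size=n_lead)
    sw_lead = _draw_flags_exact(n_lead, cfg.sharp_wave_prob, rng_events)
    ms_lead = rng_events.integers(0, 2**31, size=n_lead)

    # --- follower: propagated copies plus an independent remainder ------
    coupled = rng_events.uniform(size=n_lead) < cfg.coupled_fraction
    delays = delay_s + rng_events.normal(0.0, cfg.lag_jitter_ms / 1000.0, size=n_lead)
    t_prop = t_lead[coupled] + delays[coupled]
    partners_prop = np.flatnonzero(coupled)
    in_session = (t_prop > 0.5) & (t_prop < cfg.duration_s - 0.5)
    t_prop = t_prop[in_session]
    partners_prop = partners_prop[in_session]
    if cfg.coupling_waveform == "propagated":
        # follower events are delayed, rescaled copies of the leader burst
        w_prop = w_lead[partners_prop]
        a_prop = a_lead[partners_prop] * np.exp(
            rng_events.normal(0.0, cfg.amplitude_jitter, size=t_prop.size)
        )
        ms_prop = ms_lead[partners_prop]
    elif cfg.coupling_waveform == "independent":
        # only event timing is coupled; waveforms drawn fresh
        w_prop = _draw_widths(cfg, t_prop.size, rng_events)
        a_prop = (
            cfg.ripple_amplitude_sd
            * cfg.noise_sd_uv
            * np.exp(rng_events.normal(0.0, cfg.amplitude_jitter, size=t_prop.size))
        )
        ms_prop = rng_events.integers(0, 2**31, size=t_prop.size)
    else:
        raise ConfigError(f"unknown coupling_waveform {cfg.coupling_waveform!r}")

    n_ind = rng_events.poisson((1.0 - cfg.coupled_fraction) * expected)
    t_ind = _draw_times_in_intervals(intervals, n_ind, rng_events)
    w_ind = _draw_widths(cfg, t_ind.size, rng_events)
    a_ind = (
        cfg.ripple_amplitude_sd
        * cfg.noise_sd_uv
        * np.exp(rng_events.normal(0.0, cfg.amplitude_jitter, size=t_ind.size))
    )
    ms_ind = rng_events.integers(0, 2**31, size=t_ind.size)
    if t_prop.size and t_ind.size:
        near = np.min(np.abs(t_ind[:, None] - t_prop[None, :]), axis=1)
        keep = near >= cfg.min_separation_s
        t_ind, w_ind, a_ind, ms_ind = t_ind[keep], w_ind[keep], a_ind[keep], ms_ind[keep]

    t_fol = np.concatenate([t_prop, t_ind])
    w_fol = np.concatenate([w_prop, w_ind])
    a_fol = np.concatenate([a_prop, a_ind])
    ms_fol = np.concatenate([ms_prop, ms_ind])
    partners_fol = np.concatenate([partners_prop, -np.ones(t_ind.size)])
    order = np.argsort(t_fol)
    t_fol, w_fol, a_fol, ms_fol, partners_fol = (
        t_fol[order],
        w_fol[order],
        a_fol[order],
        ms_fol[order],
        partners_fol[order],
    )
    n_fol = t_fol.size
    ph_fol = rng_events.uniform(0, 2 * np.pi, size=n_fol)
    sw_fol = _draw_flags_exact(n_fol, cfg.sharp_wave_prob, rng_events)

    # cross-reference: leader row -> follower row, and realized lags
    partners_lead = -np.ones(n_lead)
    lags_fol = np.full(n_fol, np.nan)
    lags_lead = np.full(n_lead, np.nan)
    for j in range(n_fol):
        i = int(partners_fol[j])
        if i >= 0:
            partners_lead[i] = j
            # lag is MEC minus CA1 by convention
            if leader_is_mec:
                lag = (t_lead[i] - t_fol[j]) * 1000.0
            else:
                lag = (t_fol[j] - t_lead[i]) * 1000.0
            lags_fol[j] = lag
            lags_lead[i] = lag

    # --- traces ---------------------------------------------------------
    lead_trace = _pink_noise(
        n, cfg.noise_exponent, cfg.noise_sd_uv, rng_noise_mec if leader_is_mec else rng_noise_ca1
    )
    fol_trace = _pink_noise(
        n, cfg.noise_exponent, cfg.noise_sd_uv, rng_noise_ca1 if leader_is_mec else rng_noise_mec
    )
    _add_events(lead_trace, cfg, t_lead, w_lead, a_lead, ph_lead, sw_lead, ms_lead)
    _add_events(fol_trace, cfg, t_fol, w_fol, a_fol, ph_fol, sw_fol, ms_fol)

    truth_lead = _truth_frame(t_lead, w_lead, a_lead, sw_lead, partners_lead, lags_lead, cfg)
    truth_fol = _truth_frame(t_fol, w_fol, a_fol, sw_fol, partners_fol, lags_fol, cfg)
    if leader_is_mec:
        mec_trace, ca1_trace = lead_trace, fol_trace
        truth_mec, truth_ca1 = truth_lead, truth_fol
    else:
        ca1_trace, mec_trace = lead_trace, fol_trace
        truth_ca1, truth_mec = truth_lead, truth_fol

    lfp_ca1 = LfpTrace(
        samples=ca1_trace, fs=cfg.fs, region="CA1", electrode_id="ca1_0", session_id=session_id
    )
    lfp_mec = LfpTrace(
        samples=mec_trace, fs=cfg.fs, region="MEC", electrode_id="mec_0", session_id=session_id
    )

    track = _position_track(cfg)
    truth = GroundTruth(ca1=truth_ca1, mec=truth_mec, immobile_intervals=intervals)
    return lfp_ca1, lfp_mec, track, truth


def _position_track(cfg: SynthConfig) -> PositionTrack:
    """Back-and-forth running during mobile blocks, frozen while immobile."""
    dt = 1.0 / cfg.pos_fs
    times = np.arange(0.0, cfg.duration_s, dt)
    period = cfg.mobile_block_s + cfg.immobile_block_s
    phase = np.mod(times, period) if period > 0 else np.zeros_like(times)
    mobile = phase < cfg.mobile_block_s
    speed = np.where(mobile, cfg.mobile_speed_cm_s, 0.0)
    dist = np.concatenate([[0.0], np.cumsum(speed[:-1] * dt)])
    span = 2.0 * cfg.track_length_cm
    m = np.mod(dist, span)
    x = np.where(m <= cfg.track_length_cm, m, span - m)
    y = np.zeros_like(x)
    return PositionTrack(times=times, x=x, y=y, fs_nominal=cfg.pos_fs)


def score_detection(
    truth: pd.DataFrame, detected: pd.DataFrame, tol_ms: float = 20.0
) -> DetectionScore:
    """Greedy one-to-one matching of detected peaks to truth peaks.

    Candidate (truth, detection) pairs within ``tol_ms`` are matched in
    order of increasing absolute timing error; each event participates in
    at most one match.  Precision is NaN when there are no detections.
    """
    t_true = truth["peak_time_s"].to_numpy(float)
    t_det = detected["peak_time_s"].to_numpy(float)
    tol = tol_ms / 1000.0
    pairs = []
    for i, tt in enumerate(t_true):
        j0 = np.searchsorted(t_det, tt - tol)
        j1 = np.searchsorted(t_det, tt + tol, side="right")
        for j in range(j0, j1):
            pairs.append((abs(t_det[j] - tt), i, j))
    pairs.sort()
    used_t, used_d = set(), set()
    errors = []
    for _, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        errors.append((t_det[j] - t_true[i]) * 1000.0)
    n_matched = len(errors)
    recall = n_matched / t_true.size if t_true.size else float("nan")
    precision = n_matched / t_det.size if t_det.size else float("nan")
    return DetectionScore(
        recall=recall,
        precision=precision,
        n_truth=int(t_true.size),
        n_detected=int(t_det.size),
        n_matched=n_matched,
        timing_errors_ms=np.asarray(errors),
    )
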