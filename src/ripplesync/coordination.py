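"""Cross-region SWR timing: duration-normalized cross-correlogram and peak lag.

MEC ripple peak times are histogrammed relative to each CA1 ripple peak
within +/-100 ms; counts are normalized by the session's total immobile
duration so sessions of different lengths are comparable.  Negative lags
mean the MEC event precedes the CA1 event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motion import ImmobilityMask

DEFAULT_WINDOW_MS = 100.0
DEFAULT_BIN_MS = 5.0


@dataclass(frozen=True)
class CrossCorrelogram:
    """Binned, duration-normalized counts of MEC SWRs around CA1 SWR times.

    ``rate[i]`` is (pair count in bin i) / total immobile duration, in
    counts per second of immobile time per bin.  ``bin_centers`` are lag
    midpoints in ms; lag = MEC peak time - CA1 peak time, so negative lags
    mean MEC leads.
    """

    bin_centers: np.ndarray
    rate: np.ndarray
    counts: np.ndarray
    n_reference: int
    immobile_duration_s: float
    bin_ms: float

    def total_pairs(self) -> int:
        return int(self.counts.sum())


def cross_correlogram(
    ca1_events: pd.DataFrame,
    mec_events: pd.DataFrame,
    mask: ImmobilityMask,
    window_ms: float = DEFAULT_WINDOW_MS,
    bin_ms: float = DEFAULT_BIN_MS,
) -> CrossCorrelogram:
    """Histogram MEC ripple peaks around CA1 ripple peaks.

    For each CA1 peak time ``t``, every MEC peak ``u`` with
    ``u - t`` in ``[-window_ms, +window_ms]`` increments the bin whose
    center is nearest to ``u - t``; bin centers are spaced ``bin_ms`` apart
    with one bin centered at zero lag.  Counts are divided by the total
    immobile duration.  An empty reference table yields an all-zero
    correlogram (not an error).
    """
    t_imm = mask.total_immobile_duration
    if t_imm <= 0:
        raise ZeroDivisionError("zero immobile time: correlogram rate undefined")
    n_half = int(round(window_ms / bin_ms))
    centers = np.arange(-n_half, n_half + 1) * bin_ms
    counts = np.zeros(centers.size, dtype=np.int64)
    triggers = np.sort(ca1_events["peak_time_s"].to_numpy(float))
    targets = np.sort(mec_events["peak_time_s"].to_numpy(float))
    w = window_ms / 1000.0
    if triggers.size and targets.size:
        lo = np.searchsorted(targets, triggers - w, side="left")
        hi = np.searchsorted(targets, triggers + w, side="right")
        for t, a, b in zip(triggers, lo, hi):
            if b <= a:
                continue
            lags_ms = (targets[a:b] - t) * 1000.0
            lags_ms = lags_ms[np.abs(lags_ms) <= window_ms]
            idx = np.rint(lags_ms / bin_ms).astype(int) + n_half
            np.add.at(counts, idx, 1)
    return CrossCorrelogram(
        bin_centers=centers,
        rate=counts / t_imm,
        counts=counts,
        n_reference=int(triggers.size),
        immobile_duration_s=t_imm,
        bin_ms=bin_ms,
    )


def peak_lag(xc: CrossCorrelogram, smooth_bins: int = 3) -> float | None:
    """Lag (ms) of the correlogram maximum after boxcar smoothing.

    The rate is smoothed with an odd ``smooth_bins`` boxcar (edge bins use
    the partial window mean), and the center of the argmax bin is
    returned.  Exact ties are broken toward the smallest absolute lag,
    then toward the negative lag.  Returns None for an all-zero
    correlogram (undefined lag).
    """
    if smooth_bins < 1 or smooth_bins % 2 == 0:
        raise ValueError("smooth_bins must be a positive odd integer")
    rate = xc.rate
    if not np.any(rate > 0):
        return None
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins)
        num = np.convolve(rate, kernel, mode="same")
        den = np.convolve(np.ones_like(rate), kernel, mode="same")
        smoothed = num / den
    else:
        smoothed = rate
    best = smoothed.max()
    tied = np.flatnonzero(np.isclose(smoothed, best, rtol=0, atol=1e-15))
    lags = xc.bin_centers[tied]
    order = np.lexsort((lags, np.abs(lags)))  # smallest |lag|, then negative first
    return float(lags[order[0]])


def correlogram_to_dict(xc: CrossCorrelogram, lag_ms: float | None = None) -> dict:
    """JSON-ready representation (see signal_io.write_json_result)."""
    return {
        "bin_centers_ms": xc.bin_centers.tolist(),
        "rate_per_s": xc.rate.tolist(),
        "counts": xc.counts.tolist(),
        "n_reference": xc.n_reference,
        "immobile_duration_s": xc.immobile_duration_s,
        "bin_ms": xc.bin_ms,
        "peak_lag_ms": lag_ms,
        "peak_lag_defined": lag_ms is not None,
    }


def correlogram_from_dict(d: dict) -> tuple[CrossCorrelogram, float | None]:
    xc = CrossCorrelogram(
        bin_centers=np.asarray(d["bin_centers_ms"], float),
        rate=np.asarray(d["rate_per_s"], float),
        counts=np.asarray(d["counts"], np.int64),
        n_reference=int(d["n_reference"]),
        immobile_duration_s=float(d["immobile_duration_s"]),
        bin_ms=float(d["bin_ms"]),
    )
    return xc, d.get("peak_lag_ms")
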