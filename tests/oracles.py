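"""Independent brute-force reference implementations used only by tests.

These deliberately use naive explicit loops so they share no code with the
package's vectorized implementations.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def detect_events_bruteforce(
    z: np.ndarray,
    fs: float,
    threshold: float,
    merge_gap_ms: float,
    min_duration_ms: float,
    immobile: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Explicit scan-and-merge event segmentation; returns (start, stop) index pairs."""
    above = [bool(v > threshold) for v in z]
    runs = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    gap = merge_gap_ms / 1000.0 * fs
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    min_len = min_duration_ms / 1000.0 * fs
    out = []
    for start, stop in merged:
        if stop - start < min_len:
            continue
        peak = start
        for k in range(start, stop):
            if z[k] > z[peak]:
                peak = k
        if immobile is not None and not immobile[peak]:
            continue
        out.append((start, stop))
    return out


def ranksum_exact_p(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    n, n_a = len(pooled), len(a)
    mean_w = n_a * (n + 1) / 2.0
    count = total = 0
    for combo in combinations(range(1, n + 1), n_a):
        w = sum(combo)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def ks_statistic_bruteforce(a, b) -> float:
    """sup |ECDF_a - ECDF_b| by direct evaluation at every pooled point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    d = 0.0
    for v in np.concatenate([a, b]):
        fa = np.mean(a <= v)
        fb = np.mean(b <= v)
        d = max(d, abs(fa - fb))
    return d


def bh_reject_bruteforce(p_values, alpha=0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags, straight from the definition."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= alpha * k / m:
            k_max = k
    reject = np.zeros(m, bool)
    reject[order[:k_max]] = True
    return reject


def xcorr_counts_bruteforce(triggers, targets, window_ms, bin_ms) -> np.ndarray:
    """Double loop over all event pairs."""
    n_half = int(round(window_ms / bin_ms))
    counts = np.zeros(2 * n_half + 1, dtype=int)
    for t in triggers:
        for u in targets:
            lag_ms = (u - t) * 1000.0
            if abs(lag_ms) <= window_ms:
                counts[int(round(lag_ms / bin_ms)) + n_half] += 1
    return counts
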