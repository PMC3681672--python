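"""Multiscale Haar-wavelet breakpoint detection with FDR selection.

Changepoints in a noisy piecewise-constant profile are found from
step-kernel (Haar) coefficients at dyadic scales 2**haar_start ..
2**haar_end probes.  At half-window h the coefficient at position i is

    c_i = ( sum x[i : i+h] - sum x[i-h : i] ) / sqrt(2 h),

which is N(0, sigma^2) under white noise, with sigma estimated robustly
from first differences (MAD).  Local maxima of |c| are collected at every
scale, Benjamini-Hochberg selected at the requested FDR level across all
scales, unified from fine to coarse (a coarse peak within its half-window
of an already accepted breakpoint is dropped), and each surviving
breakpoint is refined at probe resolution by maximizing the local mean
difference.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.stats import norm


def _noise_sigma(x: np.ndarray) -> float:
    """Robust noise scale from lag-1 differences (MAD estimator)."""
    d = np.diff(x)
    if len(d) == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d)))) * 1.4826 / math.sqrt(2.0)


def _scale_peaks(x: np.ndarray, h: int, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """(positions, |z| scores) of local maxima of the scale-h coefficients."""
    n = len(x)
    if n < 2 * h:
        return np.array([], dtype=int), np.array([])
    s = np.concatenate([[0.0], np.cumsum(x)])
    # c[i]: break between i-1 and i, valid for i in [h, n-h]
    i = np.arange(h, n - h + 1)
    c = (s[i + h] - s[i]) - (s[i] - s[i - h])
    z = np.abs(c) / (sigma * math.sqrt(2.0 * h))
    # suppression window ~h so two true boundaries >= h apart both survive
    loc_max = maximum_filter1d(z, size=max(h | 1, 3), mode="constant") == z
    # suppress plateau duplicates: keep first position of equal-value runs
    keep = loc_max & np.concatenate([[True], z[1:] != z[:-1]])
    return i[keep], z[keep]


def _refine(x: np.ndarray, b: int, radius: int, window: int) -> int:
    """Refine breakpoint b by maximizing the local mean difference."""
    n = len(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    best, best_stat = b, -1.0
    for j in range(max(window, b - radius), min(n - window, b + radius) + 1):
        left = (s[j] - s[j - window]) / window
        right = (s[j + window] - s[j]) / window
        stat = abs(right - left)
        if stat > best_stat:
            best, best_stat = j, stat
    return best


def haar_breakpoints(
    x: np.ndarray,
    haar_start: int = 3,
    haar_end: int = 9,
    fdr_q: float = 1e-4,
    sigma: float | None = None,
) -> list[int]:
    """Breakpoint indices of one profile (index i = break between i-1, i).

    Sorted, deduplicated; an empty list when the profile is shorter than
    twice the smallest scale or no coefficient survives FDR selection.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 ** (haar_start + 1):
        return []
    if sigma is None:
        sigma = _noise_sigma(x)
    if sigma <= 0:
        sigma = 1e-12  # noiseless profile: any true step is infinitely significant

    scales = [2 ** s for s in range(haar_start, haar_end + 1)]
    all_pos: list[np.ndarray] = []
    all_z: list[np.ndarray] = []
    all_scale: list[np.ndarray] = []
    for h in scales:
        pos, z = _scale_peaks(x, h, sigma)
        all_pos.append(pos)
        all_z.append(z)
        all_scale.append(np.full(len(pos), h))
    pos = np.concatenate(all_pos) if all_pos else np.array([], dtype=int)
    if len(pos) == 0:
        return []
    z = np.concatenate(all_z)
    hs = np.concatenate(all_scale)

    # Benjamini-Hochberg on the pooled peak p-values
    p = 2.0 * norm.sf(np.minimum(z, 40.0))
    order = np.argsort(p)
    m = len(p)
    thresh_rank = -1
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= fdr_q * rank / m:
            thresh_rank = rank
    if thresh_rank < 0:
        return []
    selected = order[:thresh_rank]

    # unify fine -> coarse: drop a peak within half its window of one kept
    # (coarse echoes of the same step; downstream refinement validates and
    # de-duplicates whatever survives)
    sel = sorted(selected, key=lambda i: (hs[i], -z[i]))
    kept: list[tuple[int, int]] = []  # (position, scale)
    for i in sel:
        if all(abs(int(pos[i]) - kb) >= max(2, hs[i] // 2) for kb, _ in kept):
            kept.append((int(pos[i]), int(hs[i])))

    refined = sorted(
        {
            _refine(x, b, radius=max(4, min(h, 32)), window=min(16, max(4, h)))
            for b, h in kept
        }
    )
    return [b for b in refined if 0 < b < n]
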