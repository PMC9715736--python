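"""GFP computation and extraction of topographies at GFP local maxima.

The global field power (GFP) at time ``t`` is the spatial standard
deviation of the scalp potential,

    GFP(t) = sqrt( sum_i (V_i(t) - V_mean(t))^2 / N ),

with ``N`` the number of electrodes and the population divisor ``N`` (not
``N - 1``).  Local GFP maxima mark the moments of highest topographic
signal-to-noise; the maps at those samples ("original maps") are the input
to prototype clustering.
"""

from __future__ import annotations

import numpy as np

from .containers import EEGRecording, GFPSeries, PeakMaps


def compute_gfp(rec: EEGRecording) -> GFPSeries:
    """Spatial standard deviation of every time sample (divisor ``N``)."""
    if rec.n_channels < 2:
        raise ValueError("GFP requires at least 2 channels")
    centered = rec.data - rec.data.mean(axis=0, keepdims=True)
    values = np.sqrt(np.mean(centered**2, axis=0))
    return GFPSeries(values=values, fs=rec.fs)


def find_gfp_peaks(gfp: GFPSeries, min_separation_ms: float = 10.0) -> np.ndarray:
    """Indices of strict local maxima of the GFP series.

    A sample is a peak if it exceeds both neighbors; a flat run bounded by
    strictly smaller values counts as one peak at its first sample.  When
    two peaks fall within ``min_separation_ms`` of each other the larger
    survives (ties keep the earlier one).  Endpoints are never peaks.
    """
    v = gfp.values
    n = len(v)
    if n < 3:
        raise ValueError("GFP series must have at least 3 samples")

    peaks: list[int] = []
    t = 1
    while t < n - 1:
        if v[t] <= v[t - 1]:
            t += 1
            continue
        # v[t] > v[t-1]; scan over any plateau
        u = t
        while u + 1 < n and v[u + 1] == v[t]:
            u += 1
        if u < n - 1 and v[u + 1] < v[t]:
            peaks.append(t)          # plateau counts once, at its first sample
        t = u + 1
    if not peaks:
        return np.array([], dtype=int)

    min_sep = int(round(min_separation_ms * gfp.fs / 1000.0))
    if min_sep <= 0:
        return np.asarray(peaks, dtype=int)

    # greedy pruning: highest peak first, drop any neighbor closer than min_sep
    idx = np.asarray(peaks, dtype=int)
    order = np.lexsort((idx, -v[idx]))   # by height desc, then index asc
    keep = np.ones(len(idx), dtype=bool)
    taken: list[int] = []
    for j in order:
        if any(abs(idx[j] - s) < min_sep for s in taken):
            keep[j] = False
        else:
            taken.append(idx[j])
    return idx[keep]


def extract_peak_maps(rec: EEGRecording, peaks: np.ndarray, gfp: GFPSeries | None = None) -> PeakMaps:
    """Collect the topographic map at each peak sample.

    Row ``j`` of the result is the recording's column at ``peaks[j]``.
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size and (peaks.min() < 0 or peaks.max() >= rec.n_samples):
        raise IndexError("peak index out of range")
    if gfp is None:
        gfp = compute_gfp(rec)
    if peaks.size == 0:
        return PeakMaps(
            maps=np.empty((0, rec.n_channels)),
            peak_indices=np.empty(0, dtype=int),
            peak_gfp=np.empty(0),
        )
    return PeakMaps(
        maps=rec.data[:, peaks].T.copy(),
        peak_indices=peaks,
        peak_gfp=gfp.values[peaks],
    )


def segment_recording(rec: EEGRecording, min_separation_ms: float = 10.0) -> tuple[GFPSeries, PeakMaps]:
    """Convenience: GFP series plus peak maps in one call."""
    gfp = compute_gfp(rec)
    peaks = find_gfp_peaks(gfp, min_separation_ms=min_separation_ms)
    return gfp, extract_peak_maps(rec, peaks, gfp)
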