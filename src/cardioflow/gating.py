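"""Retrospective gating: synchronize per-slice sequences into a 4-D series.

A slice-scanned acquisition images each z plane for several cardiac cycles,
but the cardiac phase at the start of each slice's sequence is arbitrary.
Assuming a regular rhythm, the cardiac period is estimated from the temporal
autocorrelation of each sequence, and the relative phase between adjacent
slices is recovered by minimizing a circular pixel-wise Euclidean distance
over all integer shifts within one period. Chaining the adjacent-pair shifts
aligns every slice to a common phase, and one period per slice is stacked
into a ``(time, z, y, x)`` volume series.
"""

from __future__ import annotations


import numpy as np
from scipy.signal import find_peaks

from .datatypes import (
    AperiodicSignalError,
    IndistinguishablePhasesError,
    SliceScan,
    SyncResult,
    Volume4D,
)

__all__ = [
    "estimate_period",
    "sequence_distance",
    "estimate_relative_shift",
    "synchronize_scan",
    "assign_phases_by_timestamp",
]


def estimate_period(
    seq: np.ndarray,
    prominence_threshold: float = 0.1,
    min_period: int = 2,
) -> tuple[float, float]:
    """Estimate the cardiac period (frames) of one image time sequence.

    The frame-vectorized sequence is mean-subtracted per pixel and its
    temporal autocorrelation computed; the period is the lag of the first
    peak with normalized prominence above ``prominence_threshold``, refined
    to sub-frame precision by parabolic interpolation around the peak.

    Returns ``(period_frames, confidence)`` where confidence is the peak's
    normalized prominence.

    Raises :class:`AperiodicSignalError` if the sequence has no variance or
    no sufficiently prominent autocorrelation peak.
    """
    seq = np.asarray(seq, dtype=np.float64)
    n = seq.shape[0]
    x = seq.reshape(n, -1)
    x = x - x.mean(axis=0)
    power = float(np.sum(x * x))
    if power <= 0.0 or not np.isfinite(power):
        raise AperiodicSignalError("sequence has no temporal variance")

    # summed per-pixel autocorrelation via FFT over time
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    spec = np.fft.rfft(x, n=nfft, axis=0)
    corr = np.fft.irfft(np.sum(spec * np.conj(spec), axis=1), n=nfft)[:n].real
    overlap = n - np.arange(n)
    corr = corr / overlap                 # unbiased estimate per lag
    corr = corr / corr[0]                 # correlation-coefficient scale

    peaks, props = find_peaks(corr[min_period:], prominence=prominence_threshold)
    if peaks.size == 0:
        raise AperiodicSignalError(
            f"no autocorrelation peak with prominence >= {prominence_threshold}"
        )
    lag = int(peaks[0]) + min_period
    confidence = float(props["prominences"][0])

    # parabolic sub-frame refinement on the three samples around the peak;
    # the refinement stays within half a frame of the integer argmax
    if 1 <= lag < n - 1:
        y0, y1, y2 = corr[lag - 1], corr[lag], corr[lag + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom != 0.0:
            delta = 0.5 * (y0 - y2) / denom
            lag = lag + float(np.clip(delta, -0.5, 0.5))
    return float(lag), confidence


def _one_period_window(seq: np.ndarray, length: int) -> np.ndarray:
    if seq.shape[0] < length:
        raise ValueError(
            f"sequence of {seq.shape[0]} frames shorter than one period ({length})"
        )
    return np.asarray(seq[:length], dtype=np.float64)


def _mean_normalize(window: np.ndarray) -> np.ndarray:
    m = window.mean()
    return window / m if m != 0 else window


def sequence_distance(
    seqA: np.ndarray,
    seqB: np.ndarray,
    shift: int,
    period: float,
    normalize: bool = False,
) -> float:
    """Circular pixel-wise Euclidean distance between two sequences at a shift.

    Over one period window ``L = round(period)``::

        D(s) = sum_t || A_t - B_{(t + s) mod L} ||_2

    with B circularly indexed within its first L frames. With
    ``normalize=True`` each window is first divided by its mean intensity
    (the normalization :func:`estimate_relative_shift` applies).
    """
    L = int(round(period))
    A = _one_period_window(seqA, L)
    B = _one_period_window(seqB, L)
    if A.shape[1:] != B.shape[1:]:
        raise ValueError("sequences must share their in-plane shape")
    if normalize:
        A, B = _mean_normalize(A), _mean_normalize(B)
    s = int(shift) % L
    idx = (np.arange(L) + s) % L
    diff = A - B[idx]
    return float(np.sum(np.sqrt(np.sum(diff.reshape(L, -1) ** 2, axis=1))))


def _distance_profile(A: np.ndarray, B: np.ndarray, L: int) -> np.ndarray:
    """D(s) for all integer shifts s in [0, L); windows already normalized."""
    a = A.reshape(L, -1)
    b = B.reshape(L, -1)
    prof = np.empty(L)
    for s in range(L):
        idx = (np.arange(L) + s) % L
        prof[s] = np.sum(np.sqrt(np.sum((a - b[idx]) ** 2, axis=1)))
    return prof


def estimate_relative_shift(
    seqA: np.ndarray,
    seqB: np.ndarray,
    period: float,
    flat_tolerance: float = 1e-8,
) -> tuple[int, np.ndarray]:
    """Integer circular shift of B that best aligns it to A's cardiac phase.

    Both sequences are windowed to one period, divided by their mean
    intensity (removing per-slice illumination differences), and the
    pixel-wise Euclidean distance is minimized over all integer shifts in
    ``[0, round(period))``; ties break toward the smallest shift. Returns
    the shift and the full distance profile for diagnostics.

    Raises :class:`IndistinguishablePhasesError` when the profile is flat.
    """
    L = int(round(period))
    A = _mean_normalize(_one_period_window(seqA, L))
    B = _mean_normalize(_one_period_window(seqB, L))
    if A.shape[1:] != B.shape[1:]:
        raise ValueError("sequences must share their in-plane shape")
    prof = _distance_profile(A, B, L)
    spread = float(prof.max() - prof.min())
    scale = max(float(prof.max()), 1.0)
    if spread <= flat_tolerance * scale:
        raise IndistinguishablePhasesError(
            "distance profile is flat; sequences carry no phase information"
        )
    return int(np.argmin(prof)), prof


def synchronize_scan(
    scan: SliceScan,
    prominence_threshold: float = 0.1,
    canonical_phase: bool = False,
) -> tuple[Volume4D, SyncResult]:
    """Retrospectively gate a slice scan into one cardiac cycle of volumes.

    The period is estimated per slice and pooled by the median. Relative
    shifts are estimated between adjacent z slices (the most similar pairs)
    and chained by cumulative summation modulo the period, yielding each
    slice's phase offset relative to slice 0. Each slice's one-period window
    is circularly rolled to slice 0's phase and the slices stacked into
    ``(time, z, y, x)``.

    With ``canonical_phase=True`` the merged volume is additionally rolled so
    that the frame of maximum total intensity defines phase 0, making the
    output independent of which slice happens to be first (e.g. invariant to
    reversing the z order, up to the z flip).
    """
    if scan.n_slices < 2:
        raise ValueError("need at least 2 slices to synchronize")

    periods, confidences = [], []
    for seq in scan.sequences:
        try:
            p, conf = estimate_period(seq, prominence_threshold=prominence_threshold)
        except AperiodicSignalError:
            # weak-signal edge slices may show no clear peak; the median
            # pooling below is robust to them
            p, conf = np.nan, 0.0
        periods.append(p)
        confidences.append(conf)
    periods = np.asarray(periods)
    if np.all(np.isnan(periods)):
        raise AperiodicSignalError("no slice shows a usable cardiac period")
    period = float(np.nanmedian(periods))
    L = int(round(period))

    pair_shifts = []
    pair_profiles = []
    for k in range(scan.n_slices - 1):
        try:
            s, prof = estimate_relative_shift(
                scan.sequences[k], scan.sequences[k + 1], L
            )
        except IndistinguishablePhasesError as err:
            raise IndistinguishablePhasesError(
                f"slices {k} and {k + 1}: {err}"
            ) from err
        pair_shifts.append(s)
        pair_profiles.append(prof)

    # pairwise shift s_k satisfies B_{t+s} ~ A_t, i.e. s_k = offset_k - offset_{k+1};
    # the cumulative sum is offset_0 - offset_k, so each slice's phase offset
    # relative to slice 0 is its negation (mod L).
    cum = np.concatenate([[0], np.cumsum(pair_shifts)]) % L
    shifts = (-cum) % L

    aligned = np.stack(
        [np.roll(_one_period_window(seq, L), int(sh), axis=0)
         for seq, sh in zip(scan.sequences, shifts)],
        axis=1,
    )

    phase_origin = 0
    if canonical_phase:
        totals = aligned.reshape(L, -1).sum(axis=1)
        phase_origin = int(np.argmax(totals))
        aligned = np.roll(aligned, -phase_origin, axis=0)

    z_steps = np.diff(scan.z_positions_um)
    z_step = float(z_steps[0]) if z_steps.size else scan.pixel_size_um
    volume = Volume4D(
        data=aligned.astype(np.float32),
        spacing_um=(z_step, scan.pixel_size_um, scan.pixel_size_um),
        frame_interval_s=1.0 / scan.frame_rate_hz,
        phase_origin=0,
    )
    sync = SyncResult(
        period_frames=period,
        shifts=shifts.astype(int),
        pair_distances=pair_profiles,
        per_slice_periods=periods,
        confidences=np.asarray(confidences),
        phase_origin=phase_origin,
    )
    return volume, sync


def assign_phases_by_timestamp(
    reference_seq: np.ndarray,
    target_frame_times_s: np.ndarray,
    sync: SyncResult,
    frame_rate_hz: float,
) -> np.ndarray:
    """Map concurrently acquired frames to cardiac phase via the common clock.

    The reference sequence (already synchronized; its ``sync.phase_origin``
    frame defines phase 0) shares the acquisition clock with the target
    frames, so each target time maps to a phase in [0, 1) through the frame
    rate and the estimated period.
    """
    times = np.asarray(target_frame_times_s, dtype=float)
    n_ref = reference_seq.shape[0]
    span = (n_ref - 1) / frame_rate_hz
    if np.any(times < 0) or np.any(times > span):
        raise ValueError(
            f"target times must lie within the reference span [0, {span:.6g}] s"
        )
    frames = times * frame_rate_hz
    return ((frames - sync.phase_origin) / sync.period_frames) % 1.0
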