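"""Lift-phase detection from the pelvis x-trajectory.

A sitting-pivot transfer shows three phases in the pelvis position along the
transfer (x) axis: a pre-lift plateau while the person sets up, a rising
*lift phase* while the pelvis translates between surfaces, and a landing
plateau.  The trajectory is low-pass filtered (Butterworth, default 15 Hz
cutoff, zero-phase) and the lift window is bounded by the last sample still
at the first-plateau level before the half-rise point and the first sample
reaching the landing-plateau level after it.

"At plateau level" combines two candidate rules, which makes the boundary
both exact on clean data and robust to jitter: (i) on the filtered series,
a tight band of ``max(0.5 × robust noise SD, 0.2% of total displacement)``
around the plateau level — on noiseless data this degenerates to the exact
last-minimum / first-maximum sample the phase definition names; (ii) on a
short moving-average copy, a band of ``3 × SD / sqrt(window)`` —
insensitive to single-sample noise excursions.  The lift start is the later
of the two candidates and the lift end the earlier, so whichever rule is
sharper for the data at hand wins.  The noise SD is estimated robustly from
the median absolute first difference of the filtered series.

Transfers in the -x direction are detected by the sign of the net
displacement and analysed on the negated series; ``PhaseSegmentation.direction``
records the orientation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import MissingDataError, NoPlateauError, NoTransferError, SegmentationError

__all__ = [
    "PhaseSegmentation",
    "lowpass_filter",
    "interpolate_gaps",
    "detect_phases",
]

#: net displacement below this (mm) is treated as "no transfer"
NOISE_FLOOR_MM = 100.0


@dataclass
class PhaseSegmentation:
    """Lift-phase window on a pelvis x-trajectory.

    ``filtered_x`` is the filtered, orientation-normalized series (negated
    when the transfer ran toward -x) retained for audit; ``direction`` is
    +1 / -1 for transfers toward +x / -x.
    """

    lift_start_idx: int
    lift_end_idx: int
    filtered_x: np.ndarray
    direction: int = 1

    def __post_init__(self) -> None:
        n = len(self.filtered_x)
        if not (0 <= self.lift_start_idx < self.lift_end_idx < n):
            raise SegmentationError(
                f"invalid lift window [{self.lift_start_idx}, {self.lift_end_idx}] "
                f"for {n} frames"
            )
        if not self.filtered_x[self.lift_end_idx] > self.filtered_x[self.lift_start_idx]:
            raise SegmentationError("lift phase must be rising on the filtered series")

    @property
    def lift_slice(self) -> slice:
        """Inclusive lift window as a slice."""
        return slice(self.lift_start_idx, self.lift_end_idx + 1)

    @property
    def n_lift_frames(self) -> int:
        return self.lift_end_idx - self.lift_start_idx + 1


def lowpass_filter(
    x: np.ndarray,
    rate: float,
    cutoff: float = 15.0,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Low-pass Butterworth filter, forward-backward (zero phase) by default.

    A cutoff at or above the Nyquist frequency is clamped to 0.99 x Nyquist
    with a warning (a digital Butterworth is undefined there); at the
    nominal 30 Hz sensor rate the default 15 Hz cutoff is therefore nearly
    transparent.  ``zero_phase=False`` applies a single causal pass for
    sensitivity checks (it lags the signal by the filter's group delay).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise SegmentationError("expected a 1-D series")
    if not np.isfinite(x).all():
        raise SegmentationError(
            "series contains missing samples; interpolate first (interpolate_gaps)"
        )
    nyq = rate / 2.0
    if cutoff >= nyq:
        warnings.warn(
            f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz; clamping to {0.99 * nyq:.3g} Hz",
            stacklevel=2,
        )
        cutoff = 0.99 * nyq
    sos = signal.butter(order, cutoff / nyq, btype="low", output="sos")
    padlen = 3 * (2 * order + 1)
    if len(x) <= padlen:
        raise SegmentationError(
            f"series too short to filter: {len(x)} samples <= pad length {padlen}"
        )
    if zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def interpolate_gaps(
    x: np.ndarray, rate: float, max_gap_s: float = 0.5
) -> np.ndarray:
    """Linearly interpolate NaN runs; a run longer than ``max_gap_s`` aborts.

    Sensors can lose sight of body segments mid-transfer; short gaps are
    bridged, but long ones make the trial unusable and must fail loudly.
    Leading/trailing gaps are filled with the nearest tracked value.
    """
    x = np.asarray(x, dtype=float).copy()
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    if bad.all():
        raise MissingDataError("series is entirely missing")
    # longest run of missing samples
    run, longest = 0, 0
    for b in bad:
        run = run + 1 if b else 0
        longest = max(longest, run)
    if longest / rate > max_gap_s:
        raise MissingDataError(
            f"missing run of {longest} samples ({longest / rate:.2f} s) exceeds "
            f"{max_gap_s} s; trial rejected"
        )
    idx = np.arange(len(x))
    x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x


def detect_phases(
    pelvis_x: np.ndarray,
    rate: float,
    cutoff: float = 15.0,
    order: int = 4,
    zero_phase: bool = True,
    noise_floor: float = NOISE_FLOOR_MM,
    band_floor_frac: float = 0.002,
    dwell_s: float = 0.2,
    max_gap_s: float = 0.5,
    smooth_window: int = 5,
) -> PhaseSegmentation:
    """Detect the lift window on a pelvis x-trajectory (mm).

    Raises :class:`NoTransferError` when net displacement is below
    ``noise_floor`` mm, :class:`NoPlateauError` when the series lacks a
    resolvable pre-lift or landing plateau (e.g. a monotone ramp), and
    :class:`MissingDataError` for over-long missing runs.
    """
    x = interpolate_gaps(np.asarray(pelvis_x, dtype=float), rate, max_gap_s)
    xf = lowpass_filter(x, rate, cutoff=cutoff, order=order, zero_phase=zero_phase)

    n = len(xf)
    m = max(3, n // 10)
    net = float(np.median(xf[-m:]) - np.median(xf[:m]))
    if abs(net) < noise_floor:
        raise NoTransferError(
            f"net pelvis displacement {abs(net):.1f} mm is below the "
            f"{noise_floor:.0f} mm noise floor; no transfer detected"
        )
    direction = 1 if net > 0 else -1
    w = xf * direction

    # robust plateau levels (medians of the first/last tenth) anchor all
    # thresholds; global extremes are noise-sensitive at high jitter
    base = float(np.median(w[:m]))
    top = float(np.median(w[-m:]))
    disp = top - base
    diffs = np.diff(w)
    sigma = 1.4826 * float(np.median(np.abs(diffs - np.median(diffs)))) / np.sqrt(2.0)

    # landmark crossings are read off a short moving-average copy so a single
    # noise excursion cannot masquerade as the rise
    mw = max(1, int(smooth_window))
    pad = np.pad(w, (mw // 2, mw - 1 - mw // 2), mode="edge")
    smoothed = np.convolve(pad, np.ones(mw) / mw, mode="valid")
    rise10 = int(np.argmax(smoothed >= base + 0.10 * disp))
    rise90 = int(np.argmax(smoothed >= base + 0.90 * disp))
    half = int(np.argmax(smoothed >= base + 0.50 * disp))
    if rise10 == 0 or rise90 >= n - 1 or half <= 0:
        raise NoPlateauError("trajectory rises immediately; no pre-lift plateau")
    level_start = float(np.median(w[:rise10]))
    level_end = float(np.median(w[rise90:]))

    # plateau existence: the series must dwell near each plateau level
    dwell_band = max(3.0 * sigma, 0.02 * disp)
    n_dwell = max(3, int(round(dwell_s * rate)))
    if int(np.sum(np.abs(w[:half] - level_start) <= dwell_band)) < n_dwell:
        raise NoPlateauError("no resolvable pre-lift plateau")
    if int(np.sum(np.abs(w[half:] - level_end) <= dwell_band)) < n_dwell:
        raise NoPlateauError("no resolvable landing plateau")

    floor = band_floor_frac * disp
    band_tight = max(0.5 * sigma, floor)
    band_smooth = max(3.0 * sigma / np.sqrt(mw), floor)

    def last_below(series: np.ndarray, band: float) -> int | None:
        hits = np.nonzero(series[:half] <= level_start + band)[0]
        return int(hits[-1]) if hits.size else None

    def first_above(series: np.ndarray, band: float) -> int | None:
        hits = np.nonzero(series[half:] >= level_end - band)[0]
        return half + int(hits[0]) if hits.size else None

    starts = [c for c in (last_below(w, band_tight), last_below(smoothed, band_smooth)) if c is not None]
    ends = [c for c in (first_above(w, band_tight), first_above(smoothed, band_smooth)) if c is not None]
    if not starts:
        raise NoPlateauError("no sample at pre-lift plateau level before half-rise")
    if not ends:
        raise NoPlateauError("no sample at landing plateau level after half-rise")
    start = max(starts)
    end = min(ends)
    if not start < end:
        raise SegmentationError("degenerate lift window")

    return PhaseSegmentation(
        lift_start_idx=start,
        lift_end_idx=end,
        filtered_x=w,
        direction=direction,
    )
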