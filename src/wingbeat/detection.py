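"""Passage-event detection (PEDA).

A sliding RMS window is run over the normalized sensor signal; maximal runs
of windows whose RMS exceeds a threshold become candidate passage events.
Each event keeps a padded context (default 50 ms each side) of raw signal.
A "standard group" filter then keeps only events suitable for species
characterization: core duration of at least 100 ms and a direct passage,
operationalized here as the interior RMS profile never dipping below a
configured fraction of the event's peak RMS (an indirect passage shows a
mid-event drop in signal strength).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import SignalTrack

__all__ = [
    "DetectionConfig",
    "RMSSeries",
    "EventRecord",
    "rms_profile",
    "auto_threshold",
    "detect_events",
    "standard_group_filter",
    "run_detection",
]


@dataclass
class DetectionConfig:
    """Detection parameters.

    ``window_ms``/``overlap_ms`` define the RMS sliding window (defaults
    30/10 ms, i.e. a 20 ms hop).  ``threshold`` is the dimensionless RMS
    detection threshold; ``None`` selects the automatic rule
    ``auto_k`` x median background RMS.  ``pad_ms`` of raw signal is kept
    each side of the event; ``min_duration_ms`` is the standard-group core
    duration floor; runs separated by at most ``merge_gap_ms`` of
    sub-threshold windows are merged; ``dip_fraction`` is the direct-passage
    tolerance (interior RMS below this fraction of the peak rejects).
    """

    window_ms: float = 30.0
    overlap_ms: float = 10.0
    threshold: float | None = None
    auto_k: float = 5.0
    pad_ms: float = 50.0
    min_duration_ms: float = 100.0
    merge_gap_ms: float = 0.0
    dip_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.overlap_ms < self.window_ms:
            raise ValueError("require 0 < overlap_ms < window_ms")
        if self.threshold is not None and not self.threshold > 0:
            raise ValueError("threshold must be positive")
        if self.pad_ms < 0 or self.min_duration_ms <= 0:
            raise ValueError("pad_ms must be >= 0 and min_duration_ms > 0")

    @property
    def hop_ms(self) -> float:
        return self.window_ms - self.overlap_ms


@dataclass
class RMSSeries:
    """Windowed RMS profile of a track."""

    times: np.ndarray  # window-start times, s
    values: np.ndarray  # RMS per window, dimensionless
    window_s: float
    hop_s: float
    fs: float


@dataclass
class EventRecord:
    """One detected passage event.

    Core bounds are the threshold-crossing bounds at window granularity;
    padded bounds add the configured context each side (clamped to the
    track).  ``duration_ms`` is the core duration without padding.
    """

    core_start_s: float
    core_end_s: float
    padded_start_s: float
    padded_end_s: float
    waveform: np.ndarray
    fs: float
    peak_rms: float
    duration_ms: float
    rms_values: np.ndarray = field(default_factory=lambda: np.array([]))
    standard_group: bool = False
    rejection_reason: str = ""


def rms_profile(track: SignalTrack, config: DetectionConfig) -> RMSSeries:
    """Compute the sliding-window RMS profile of a track.

    Each value is sqrt(mean(x_i^2)) over one window; windows advance by
    ``window_ms - overlap_ms``.  A trailing partial window is dropped.
    """
    n_win = int(round(config.window_ms * 1e-3 * track.fs))
    n_hop = int(round(config.hop_ms * 1e-3 * track.fs))
    if n_win < 1 or n_hop < 1:
        raise ValueError("window/hop shorter than one sample at this rate")
    if len(track) < n_win:
        raise ValueError("track shorter than one RMS window")
    n_frames = 1 + (len(track) - n_win) // n_hop
    frames = np.lib.stride_tricks.sliding_window_view(track.samples, n_win)[::n_hop]
    frames = frames[:n_frames]
    values = np.sqrt(np.mean(frames**2, axis=1))
    times = np.arange(n_frames) * n_hop / track.fs
    return RMSSeries(times, values, n_win / track.fs, n_hop / track.fs, track.fs)


def auto_threshold(rms: RMSSeries, k: float = 5.0) -> float:
    """Automatic detection threshold: ``k`` times the median window RMS.

    The median is robust to the sparse, high-RMS passage events, so it
    tracks the background (noise) level.
    """
    return k * float(np.median(rms.values))


def detect_events(
    rms: RMSSeries, track: SignalTrack, config: DetectionConfig
) -> list[EventRecord]:
    """Turn supra-threshold RMS runs into padded event records.

    A passing event is a maximal run of windows with RMS strictly above the
    threshold; runs separated by at most ``merge_gap_ms`` are merged.  Core
    bounds span from the start of the first supra-threshold window to the
    end of the last; padded bounds add ``pad_ms`` each side, clamped to the
    track.
    """
    thr = config.threshold
    if thr is None:
        thr = auto_threshold(rms, config.auto_k)
    above = rms.values > thr
    if not above.any():
        return []

    idx = np.flatnonzero(above)
    # split into runs, merging sub-threshold gaps of <= merge_gap_ms
    max_gap_frames = int(np.floor(config.merge_gap_ms * 1e-3 / rms.hop_s)) + 1
    breaks = np.flatnonzero(np.diff(idx) > max_gap_frames)
    run_starts = np.concatenate(([0], breaks + 1))
    run_ends = np.concatenate((breaks, [len(idx) - 1]))

    events: list[EventRecord] = []
    pad_s = config.pad_ms * 1e-3
    for rs, re in zip(run_starts, run_ends):
        first, last = idx[rs], idx[re]
        core_start = rms.times[first]
        core_end = rms.times[last] + rms.window_s
        padded_start = max(0.0, core_start - pad_s)
        padded_end = min(len(track) / track.fs, core_end + pad_s)
        i0 = int(round(padded_start * track.fs))
        i1 = int(round(padded_end * track.fs))
        run_values = rms.values[first : last + 1]
        events.append(
            EventRecord(
                core_start_s=float(core_start),
                core_end_s=float(core_end),
                padded_start_s=float(padded_start),
                padded_end_s=float(padded_end),
                waveform=track.samples[i0:i1].copy(),
                fs=track.fs,
                peak_rms=float(run_values.max()),
                duration_ms=float((core_end - core_start) * 1e3),
                rms_values=run_values.copy(),
            )
        )
    return events


def _has_dip(rms_values: np.ndarray, dip_fraction: float) -> bool:
    """True when the profile dips below ``dip_fraction`` of both flanking maxima."""
    if rms_values.size < 3:
        return False
    left_max = np.maximum.accumulate(rms_values)[:-2]
    right_max = np.maximum.accumulate(rms_values[::-1])[::-1][2:]
    interior = rms_values[1:-1]
    return bool(np.any(interior < dip_fraction * np.minimum(left_max, right_max)))


def standard_group_filter(
    events: list[EventRecord], config: DetectionConfig
) -> list[EventRecord]:
    """Flag events that qualify for the characterization standard group.

    An event qualifies iff its core duration is at least
    ``min_duration_ms`` and it is a direct passage: its RMS profile has no
    genuine mid-event dip.  A window counts as a dip when its RMS falls
    below ``dip_fraction`` times the smaller of the running maxima to its
    left and right — so any unimodal (single rise and fall) profile passes
    regardless of envelope shape, while a two-lobed profile whose valley
    drops below the fraction is rejected.  Rejected events keep a
    ``rejection_reason`` of "duration" or "dip".
    """
    for ev in events:
        if ev.duration_ms < config.min_duration_ms:
            ev.standard_group = False
            ev.rejection_reason = "duration"
            continue
        if _has_dip(ev.rms_values, config.dip_fraction):
            ev.standard_group = False
            ev.rejection_reason = "dip"
            continue
        ev.standard_group = True
        ev.rejection_reason = ""
    return events


def run_detection(
    track: SignalTrack, config: DetectionConfig | None = None
) -> list[EventRecord]:
    """Full detection pass: RMS profile, thresholding, standard-group flags."""
    config = config or DetectionConfig()
    rms = rms_profile(track, config)
    events = detect_events(rms, track, config)
    return standard_group_filter(events, config)
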