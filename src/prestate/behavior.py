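"""Behavioral and EMG metrics: movement onset/offset detection from
kinematic traces, reaction time, movement duration, and band-passed RMS EMG
(in-movement or pre-movement windows)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MovementEvents:
    """Cue/onset/offset sample indices for one trial."""

    cue_index: int
    onset_index: int
    offset_index: int
    srate: float

    def __post_init__(self) -> None:
        if not (self.cue_index <= self.onset_index < self.offset_index):
            raise ValueError("need cue <= onset < offset")


def detect_onsets(
    trace: np.ndarray,
    srate: float,
    cue_index: int = 0,
    threshold_fraction: float = 0.1,
    smooth_samples: int = 1,
) -> MovementEvents | None:
    """Threshold-crossing onset/offset detection on a kinematic trace.

    Onset is the first sample after the cue where the trace exceeds
    ``threshold_fraction`` of the trial peak while rising; offset is the last
    sample above threshold while falling.  ``smooth_samples`` applies a
    centered moving average first (useful for noisy IMU traces).  Returns
    None (with a logged warning) if the trace never crosses threshold.
    """
    x = np.asarray(trace, dtype=float)
    if smooth_samples > 1:
        kernel = np.ones(smooth_samples) / smooth_samples
        x = np.convolve(x, kernel, mode="same")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite kinematic trace")
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    peak = x.max()
    if peak <= 0:
        logger.warning("flat or non-positive kinematic trace; no movement detected")
        return None
    thr = threshold_fraction * peak
    above = x > thr
    if not above.any():
        logger.warning("trace never crosses threshold; trial dropped")
        return None
    idx = np.flatnonzero(above)
    idx = idx[idx >= cue_index]
    if idx.size == 0:
        logger.warning("no supra-threshold samples after the cue; trial dropped")
        return None
    onset = int(idx[0])
    offset = int(idx[-1])
    if offset <= onset:
        logger.warning("degenerate supra-threshold interval; trial dropped")
        return None
    return MovementEvents(cue_index=int(cue_index), onset_index=onset,
                          offset_index=offset, srate=srate)


def reaction_time(events: MovementEvents) -> float:
    """Cue-to-onset latency in milliseconds."""
    return (events.onset_index - events.cue_index) / events.srate * 1000.0


def movement_duration(events: MovementEvents) -> float:
    """Onset-to-offset duration in milliseconds."""
    return (events.offset_index - events.onset_index) / events.srate * 1000.0


def rms(x: np.ndarray) -> float:
    """Plain root-mean-square: sqrt(mean(x**2))."""
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean(x**2)))


def rms_emg(
    emg: np.ndarray,
    events: MovementEvents,
    srate: float,
    *,
    band: tuple[float, float] = (20.0, 450.0),
    window: str = "in-movement",
    premovement_ms: float = 500.0,
    order: int = 4,
) -> float | None:
    """Band-passed RMS EMG amplitude over the movement or pre-movement window.

    The signal is band-pass filtered (Butterworth, zero-phase, 20-450 Hz by
    default), then squared, averaged and square-rooted over ``[onset,
    offset)`` ("in-movement") or the ``premovement_ms`` before onset
    ("pre-movement").  Trials whose window is too short to filter are
    dropped (None, logged).
    """
    if srate <= 2 * band[1]:
        raise ValueError(f"EMG srate {srate} too low for band {band}")
    x = np.asarray(emg, dtype=float)
    if window == "in-movement":
        a, b = events.onset_index, events.offset_index
    elif window == "pre-movement":
        b = events.onset_index
        a = b - int(round(premovement_ms / 1000.0 * srate))
    else:
        raise ValueError("window must be 'in-movement' or 'pre-movement'")
    a = max(a, 0)
    seg = x[a:b]
    if seg.size <= 3 * order:
        logger.warning("EMG window too short to filter; trial dropped")
        return None
    sos = signal.butter(order, band, btype="bandpass", fs=srate, output="sos")
    filt = signal.sosfiltfilt(sos, seg)
    return rms(filt)
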