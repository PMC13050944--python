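"""Preprocessing chain for continuous or epoched EEG.

Band-pass filtering (4th-order Butterworth, zero-phase), integer-ratio
downsampling with anti-alias filtering, optional mains band-stop,
variance-based bad-channel flagging, inverse-distance interpolation from the
3 nearest montage neighbors, common average reference, and onset-locked
pre-movement epoch extraction with whole-epoch baseline correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .montage import ChannelNeighborhood

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification (defaults follow the 0.5-30 Hz study band)."""

    low_hz: float = 0.5
    high_hz: float = 30.0
    order: int = 4

    def validate(self, srate: float) -> None:
        if not (0 < self.low_hz < self.high_hz < srate / 2):
            raise ValueError(
                f"passband ({self.low_hz}, {self.high_hz}) Hz invalid for srate {srate}"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


def bandpass(data: np.ndarray, spec: FilterSpec, srate: float) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass along the last axis."""
    spec.validate(srate)
    x = np.asarray(data, dtype=float)
    if x.shape[-1] <= 3 * spec.order:
        raise ValueError("series too short for the requested filter order")
    sos = signal.butter(spec.order, [spec.low_hz, spec.high_hz],
                        btype="bandpass", fs=srate, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def bandstop_mains(data: np.ndarray, srate: float, mains_hz: float = 50.0,
                   width_hz: float = 2.0, order: int = 2) -> np.ndarray:
    """Zero-phase band-stop at the mains frequency (no-op if above Nyquist)."""
    if mains_hz + width_hz >= srate / 2:
        logger.info("mains %.0f Hz above Nyquist at srate %.0f; band-stop skipped",
                    mains_hz, srate)
        return np.asarray(data, dtype=float)
    sos = signal.butter(order, [mains_hz - width_hz, mains_hz + width_hz],
                        btype="bandstop", fs=srate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)


def downsample(data: np.ndarray, srate_in: float, srate_out: float) -> np.ndarray:
    """Anti-alias filter then decimate by the integer ratio srate_in/srate_out.

    Output length is ``floor(n * srate_out / srate_in)``.
    """
    ratio = srate_in / srate_out
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(f"srate_in must be an integer multiple of srate_out (ratio {ratio})")
    x = np.asarray(data, dtype=float)
    if q == 1:
        return x.copy()
    sos = signal.butter(8, 0.8 * (srate_out / 2), btype="low", fs=srate_in, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=-1)
    n_out = x.shape[-1] // q
    return y[..., : n_out * q : q]


def flag_bad_channels(data: np.ndarray, z_thresh: float = 5.0) -> list[int]:
    """Flag channels whose log-variance deviates > ``z_thresh`` robust z-scores.

    A deliberately simple stand-in for artifact-subspace bad-channel
    detection, sufficient for synthetic or pre-cleaned recordings.
    """
    x = np.asarray(data, dtype=float)
    lv = np.log(np.var(x, axis=-1) + 1e-30)
    med = np.median(lv)
    mad = np.median(np.abs(lv - med)) * 1.4826
    if mad == 0:
        return []
    z = (lv - med) / mad
    return [int(i) for i in np.flatnonzero(np.abs(z) > z_thresh)]


def interpolate_bad_channels(
    data: np.ndarray, bad: list[int] | set[int], nbhd: ChannelNeighborhood
) -> np.ndarray:
    """Replace bad channels by the inverse-distance-weighted mean of their
    nearest good neighbors (3 by default, per the neighborhood)."""
    x = np.asarray(data, dtype=float).copy()
    bad = set(int(b) for b in bad)
    if len(bad) >= x.shape[0]:
        raise ValueError("bad channels must be a strict subset of channels")
    for b in bad:
        nbrs = nbhd.neighbors[b]
        dists = nbhd.distances[b]
        good = [(int(n), float(d)) for n, d in zip(nbrs, dists) if int(n) not in bad]
        if not good:
            raise ValueError(f"all neighbors of channel {b} are bad; cannot interpolate")
        w = np.array([1.0 / d for _, d in good])
        w /= w.sum()
        x[b] = sum(wi * x[n] for (n, _), wi in zip(good, w))
    return x


def rereference_average(data: np.ndarray) -> np.ndarray:
    """Common average reference: subtract the channel mean at every sample."""
    x = np.asarray(data, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("average reference needs >= 2 channels")
    return x - x.mean(axis=0, keepdims=True)


def extract_premovement_epochs(
    data: np.ndarray,
    onsets: np.ndarray | list[int],
    srate: float,
    window_ms: tuple[float, float] = (-500.0, 0.0),
    baseline_correct: bool = True,
) -> np.ndarray:
    """Cut onset-locked epochs from continuous (channels, samples) data.

    The window is half-open ``[onset + start, onset + end)`` so the onset
    sample itself is excluded; each channel's whole-epoch mean is subtracted
    (baseline correction).  Onsets without enough preceding data are dropped
    with a logged warning.  Returns (n_epochs, channels, samples_per_epoch).
    """
    x = np.asarray(data, dtype=float)
    n0 = int(round(window_ms[0] / 1000.0 * srate))
    n1 = int(round(window_ms[1] / 1000.0 * srate))
    if n1 <= n0:
        raise ValueError("empty epoch window")
    epochs = []
    for onset in onsets:
        a, b = int(onset) + n0, int(onset) + n1
        if a < 0 or b > x.shape[-1]:
            logger.warning("onset %d too close to the recording edge; trial dropped", onset)
            continue
        ep = x[:, a:b].copy()
        if baseline_correct:
            ep -= ep.mean(axis=1, keepdims=True)
        epochs.append(ep)
    return np.array(epochs) if epochs else np.empty((0, x.shape[0], n1 - n0))
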