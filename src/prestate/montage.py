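"""Electrode montage utilities.

The study montage is a 32-channel 10-10 cap. Idealized 3-D electrode
positions come from MNE's bundled standard montage files and are reduced to
unit vectors on a sphere, which is all the neighbor search and the spherical
head model need.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

#: The 32 channels of the study cap, in acquisition order.
STUDY_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fz", "F3", "F7", "F9", "FC5", "FC1", "C3", "T7", "CP5", "CP1",
    "Pz", "P3", "P7", "P9", "O1", "Oz", "O2", "P10", "P8", "P4", "CP2",
    "CP6", "T8", "C4", "Cz", "FC2", "FC6", "F10", "F8", "F4", "Fp2",
)


@dataclass(frozen=True)
class ChannelNeighborhood:
    """k nearest montage neighbors per channel, with distances.

    ``neighbors[i]`` are the indices of the ``k`` channels closest to channel
    ``i`` (never including ``i`` itself); ``distances[i]`` are the matching
    chord distances between unit-sphere positions.
    """

    channel_labels: tuple[str, ...]
    neighbors: np.ndarray  # (n_channels, k) int
    distances: np.ndarray  # (n_channels, k) float

    def __post_init__(self) -> None:
        n, k = self.neighbors.shape
        if k < 1:
            raise ValueError("neighborhood needs k >= 1")
        if any(self.neighbors[i].min() >= 0 and i in self.neighbors[i] for i in range(n)):
            raise ValueError("a channel may not be its own neighbor")


@lru_cache(maxsize=8)
def _standard_positions(channels: tuple[str, ...]) -> np.ndarray:
    import mne  # deferred: mne import is slow

    mont = mne.channels.make_standard_montage("colin27_1005")
    pos = mont.get_positions()["ch_pos"]
    missing = [c for c in channels if c not in pos]
    if missing:
        raise KeyError(f"channels not in standard 10-10 montage: {missing}")
    return np.array([pos[c] for c in channels], dtype=float)


def channel_positions(channels: tuple[str, ...] | list[str] = STUDY_CHANNELS) -> np.ndarray:
    """Unit-sphere positions (n_channels, 3) for the given 10-10 labels."""
    xyz = _standard_positions(tuple(channels)).copy()
    xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
    return xyz


def neighborhood(
    channels: tuple[str, ...] | list[str] = STUDY_CHANNELS, k: int = 3
) -> ChannelNeighborhood:
    """Build the k-nearest-neighbor structure used for bad-channel repair."""
    xyz = channel_positions(channels)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1)[:, :k]
    dist = np.take_along_axis(d, order, axis=1)
    return ChannelNeighborhood(tuple(channels), order, dist)
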