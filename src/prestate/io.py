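"""File formats and configuration.

Plain-text ``.ep`` matrices (one time sample per row, whitespace-separated
channel columns -- the CARTOOL-compatible dialect), JSON sidecars for epoch
sets and template sets, EDF reading via MNE, and the TOML pipeline
configuration with provenance hashing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synth import EpochSet


# ---------------------------------------------------------------------------
# .ep text matrices
# ---------------------------------------------------------------------------

def write_ep(path: str | Path, data: np.ndarray) -> None:
    """Write a (channels, samples) array as text: one sample per row."""
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D (channels, samples) array")
    with open(path, "w") as fh:
        for t in range(x.shape[1]):
            fh.write("\t".join(format(v, ".9g") for v in x[:, t]) + "\n")


def read_ep(path: str | Path) -> np.ndarray:
    """Read an ``.ep`` text matrix back as (channels, samples)."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            vals = line.split()
            try:
                row = [float(v) for v in vals]
            except ValueError as err:
                raise ValueError(f"{path}: bad number on line {ln}") from err
            if rows and len(row) != len(rows[0]):
                raise ValueError(
                    f"{path}: ragged row on line {ln} "
                    f"({len(row)} values, expected {len(rows[0])})"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty .ep file")
    return np.asarray(rows, dtype=float).T


# ---------------------------------------------------------------------------
# EpochSet on-disk layout
# ---------------------------------------------------------------------------

def save_epochset(epochs: EpochSet, directory: str | Path) -> None:
    """One ``.ep`` file per trial plus a JSON sidecar with montage, rate and
    (when present) the planted ground-truth labels."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for s in range(epochs.n_subjects):
        for c in range(epochs.n_conditions):
            for tr in range(epochs.n_trials):
                write_ep(d / f"s{s:02d}_c{c}_t{tr:02d}.ep", epochs.data[s, c, tr])
    meta = dict(
        channel_labels=list(epochs.channel_labels),
        srate=epochs.srate,
        epoch_window=list(epochs.epoch_window),
        shape=list(epochs.data.shape),
        planted_labels=(
            epochs.planted_labels.tolist() if epochs.planted_labels is not None else None
        ),
    )
    (d / "epochs.json").write_text(json.dumps(meta))


def load_epochset(directory: str | Path) -> EpochSet:
    d = Path(directory)
    meta = json.loads((d / "epochs.json").read_text())
    S, C, T, ch, n = meta["shape"]
    data = np.empty((S, C, T, ch, n))
    for s in range(S):
        for c in range(C):
            for tr in range(T):
                data[s, c, tr] = read_ep(d / f"s{s:02d}_c{c}_t{tr:02d}.ep")
    planted = meta.get("planted_labels")
    return EpochSet(
        data=data,
        channel_labels=tuple(meta["channel_labels"]),
        srate=meta["srate"],
        epoch_window=tuple(meta["epoch_window"]),
        planted_labels=np.asarray(planted, dtype=int) if planted is not None else None,
    )


def save_templates(maps: np.ndarray, path: str | Path, meta: dict | None = None) -> None:
    """Template maps as a K x channels ``.ep`` matrix plus JSON metadata."""
    write_ep(Path(path), np.asarray(maps).T)        # K rows x channel columns
    if meta is not None:
        Path(path).with_suffix(".json").write_text(json.dumps(meta, sort_keys=True))


def read_edf(path: str | Path) -> tuple[np.ndarray, list[str], float]:
    """Read a continuous EDF recording: (channels x samples in uV, labels, srate)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data() * 1e6, list(raw.ch_names), float(raw.info["sfreq"])


def read_onsets(path: str | Path) -> np.ndarray:
    """Onset sample indices, one integer per line."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return np.asarray([int(v) for v in lines], dtype=int)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end pipeline, with study-shaped defaults."""

    seed: int = 0
    # synthetic data
    n_subjects: int = 10
    n_conditions: int = 5
    n_trials: int = 10
    n_channels: int = 32
    n_samples: int = 125
    srate: float = 250.0
    n_maps: int = 8
    snr: float = 2.0
    segment_dwell: float = 10.0
    load_sensitive_map: int | None = 1
    # preprocessing
    band_low_hz: float = 0.5
    band_high_hz: float = 30.0
    filter_order: int = 4
    apply_bandpass: bool = False   # synthetic epochs are already band-limited
    # microstates
    k_min: int = 2
    k_max: int = 12
    n_restarts: int = 20
    use_meta_criterion: bool = True
    peaks_only: bool = True
    # statistics
    alpha: float = 0.05
    dunn_adjustment: str = "bonferroni"
    baseline_condition: int = 0    # excluded from load-effect tests
    # sources
    grid_spacing_mm: float = 12.0
    sloreta_alpha: str | float = "auto"
    n_permutations: int = 5000
    run_sources: bool = True
    # reporting
    figures: bool = False

    def validate(self) -> None:
        if not (1 <= self.k_min <= self.k_max <= self.n_channels):
            raise ValueError("need 1 <= k_min <= k_max <= n_channels")
        if self.n_subjects < 1 or self.n_conditions < 2 or self.n_trials < 1:
            raise ValueError("invalid study dimensions")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Stable hash of the full configuration, stamped into every output."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
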