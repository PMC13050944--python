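"""Synthetic multi-subject EEG with planted microstate structure.

Emulates the design of the study this package models: 10 subjects x 5 lifted
load conditions x 10 trials of 500-ms pre-movement epochs at 250 Hz on a
32-channel 10-10 montage.  Every epoch is a sequence of dwell segments; each
segment expresses one of K planted template topographies under a smooth
positive amplitude envelope and a random polarity sign, on top of spatially
correlated 1/f background noise at a requested SNR.  The realized per-sample
segment labels are returned, so every downstream stage can be checked
against a known ground truth.

Also generates the companion behavioral table (reaction time, movement
duration, RMS EMG), kinematic flexion-extension traces and surface-EMG
traces with load-scaled amplitude, mirroring the study's IMU/EMG recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import STUDY_CHANNELS

# Study-shaped defaults: 10 subjects, 5 load conditions (0 kg baseline plus
# four graded loads), 10 trials per condition, 500 ms at 250 Hz, 32 channels.
N_SUBJECTS = 10
N_CONDITIONS = 5
N_TRIALS = 10
N_CHANNELS = 32
N_SAMPLES = 125
SRATE = 250.0
CONDITION_LOADS_KG = (0.0, 2.5, 4.5, 6.5, 8.0)

#: default mean microstate dwell (samples at 250 Hz; 40 ms is a typical
#: microstate duration)
DEFAULT_DWELL = 10.0
DEFAULT_SNR = 2.0


@dataclass
class GroundTruth:
    """Generative ground truth planted into a synthetic data set."""

    maps: np.ndarray          # (K, n_channels), centered, unit L2 norm
    prevalence: np.ndarray    # (n_subjects, n_conditions, K), rows sum to 1
    segment_dwell: float = DEFAULT_DWELL   # mean dwell, samples
    snr: float = DEFAULT_SNR               # signal RMS / noise RMS
    emg_scale: np.ndarray = field(
        default_factory=lambda: np.array([0.2, 1.0, 1.4, 1.8, 2.2])
    )
    rt_shift: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 10.0, 20.0, 40.0, 55.0])
    )  # ms, per condition
    map_jitter: float = 0.0   # per-trial angular jitter of planted maps
    seed: int = 0

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        self.prevalence = np.asarray(self.prevalence, dtype=float)
        if not np.allclose(self.maps.mean(axis=1), 0.0, atol=1e-9):
            raise ValueError("planted maps must have zero channel mean")
        if not np.allclose(np.linalg.norm(self.maps, axis=1), 1.0, atol=1e-9):
            raise ValueError("planted maps must have unit L2 norm")
        if self.prevalence.ndim != 3 or self.prevalence.shape[2] != self.maps.shape[0]:
            raise ValueError("prevalence must be (subjects, conditions, K)")
        if np.any(self.prevalence < 0) or not np.allclose(
            self.prevalence.sum(axis=2), 1.0, atol=1e-9
        ):
            raise ValueError("prevalences must be non-negative and sum to 1")
        if self.segment_dwell < 1:
            raise ValueError("segment_dwell must be >= 1 sample")
        if not self.snr > 0:
            raise ValueError("snr must be positive")


@dataclass
class EpochSet:
    """Epoched EEG organized subject x condition x trial x channel x sample."""

    data: np.ndarray
    channel_labels: tuple[str, ...] = STUDY_CHANNELS
    srate: float = SRATE
    epoch_window: tuple[float, float] = (-500.0, 0.0)  # ms relative to onset
    planted_labels: np.ndarray | None = None  # same leading shape, per-sample map index

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5:
            raise ValueError("data must be 5-D (subject, condition, trial, channel, sample)")
        if self.data.shape[3] != len(self.channel_labels):
            raise ValueError("channel count does not match channel_labels")
        if self.epoch_window[1] > 0:
            raise ValueError("pre-movement epochs must end at or before onset")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]


def random_orthonormal_maps(k: int, n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """K mutually orthogonal, average-referenced, unit-norm template maps."""
    if k > n_channels - 1:
        raise ValueError("at most n_channels - 1 orthogonal centered maps exist")
    A = rng.standard_normal((n_channels, k))
    A -= A.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(A)
    Q = Q - Q.mean(axis=0, keepdims=True)        # centered subspace is closed under QR
    Q /= np.linalg.norm(Q, axis=0, keepdims=True)
    return Q.T


def make_ground_truth(
    n_maps: int = 8,
    n_channels: int = N_CHANNELS,
    n_subjects: int = N_SUBJECTS,
    n_conditions: int = N_CONDITIONS,
    *,
    seed: int = 0,
    prevalence: np.ndarray | None = None,
    load_sensitive_map: int | None = None,
    **kwargs,
) -> GroundTruth:
    """Build a GroundTruth with random orthogonalized templates.

    With ``load_sensitive_map`` set, that map's prevalence declines linearly
    across conditions (from ~2x to ~0.5x its uniform share) while the others
    stay uniform -- the qualitative load effect the study reports for its
    load-sensitive maps.
    """
    rng = np.random.default_rng(seed)
    maps = random_orthonormal_maps(n_maps, n_channels, rng)
    if prevalence is None:
        prev = np.full((n_subjects, n_conditions, n_maps), 1.0 / n_maps)
        if load_sensitive_map is not None:
            hi, lo = 2.0 / n_maps, 0.5 / n_maps
            fracs = np.linspace(hi, lo, n_conditions)
            for c, f in enumerate(fracs):
                prev[:, c, :] = (1.0 - f) / (n_maps - 1)
                prev[:, c, load_sensitive_map] = f
    else:
        prev = np.asarray(prevalence, dtype=float)
        if prev.ndim == 1:
            prev = np.broadcast_to(prev, (n_subjects, n_conditions, n_maps)).copy()
        elif prev.ndim == 2:
            prev = np.broadcast_to(prev[None], (n_subjects, n_conditions, n_maps)).copy()
    return GroundTruth(maps=maps, prevalence=prev, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# EEG epochs
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                srate: float) -> np.ndarray:
    """Spatially correlated 1/f noise: independent pink channels mixed
    through a random smoothing matrix, then average-referenced."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / srate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** -0.5          # amplitude ~ f^-1/2 -> power ~ 1/f
    spec = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    mix = np.eye(n_channels) + 0.5 * rng.standard_normal((n_channels, n_channels)) / np.sqrt(n_channels)
    x = mix @ x
    x -= x.mean(axis=0, keepdims=True)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _segment_plan(
    rng: np.random.Generator, n_samples: int, dwell: float, prev: np.ndarray
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Draw geometric dwell segments covering the epoch.

    Returns per-sample labels and a list of (start, length, map index).
    """
    p = min(1.0, 1.0 / dwell)
    labels = np.empty(n_samples, dtype=int)
    segments: list[tuple[int, int, int]] = []
    t = 0
    k_maps = prev.size
    while t < n_samples:
        length = int(rng.geometric(p))
        length = min(length, n_samples - t)
        k = int(rng.choice(k_maps, p=prev))
        labels[t : t + length] = k
        segments.append((t, length, k))
        t += length
    return labels, segments


def generate_epochs(
    truth: GroundTruth,
    n_subjects: int = N_SUBJECTS,
    n_conditions: int = N_CONDITIONS,
    n_trials: int = N_TRIALS,
    n_channels: int = N_CHANNELS,
    n_samples: int = N_SAMPLES,
    srate: float = SRATE,
) -> EpochSet:
    """Generate epoched EEG with planted microstate segments.

    Within a segment the signal is ``planted_map[k] * envelope(t) * sign``
    with a half-sine positive envelope (GFP peaks at segment centers) and a
    random per-segment polarity sign; spatially correlated pink noise is
    added at the requested SNR (signal RMS / noise RMS per trial).
    """
    K, C = truth.maps.shape
    if n_channels != C:
        raise ValueError(f"n_channels={n_channels} does not match planted map dimension {C}")
    if truth.prevalence.shape[:2] != (n_subjects, n_conditions):
        raise ValueError("prevalence table does not match subject/condition counts")
    rng = np.random.default_rng(truth.seed)
    data = np.empty((n_subjects, n_conditions, n_trials, C, n_samples))
    planted = np.empty((n_subjects, n_conditions, n_trials, n_samples), dtype=int)
    for s in range(n_subjects):
        for c in range(n_conditions):
            prev = truth.prevalence[s, c]
            for tr in range(n_trials):
                maps = truth.maps
                if truth.map_jitter > 0:
                    jit = rng.standard_normal(maps.shape) * truth.map_jitter
                    maps = maps + jit
                    maps -= maps.mean(axis=1, keepdims=True)
                    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
                labels, segments = _segment_plan(rng, n_samples, truth.segment_dwell, prev)
                sig = np.zeros((C, n_samples))
                for start, length, k in segments:
                    env = 0.25 + np.sin(np.pi * (np.arange(length) + 0.5) / length)
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    sig[:, start : start + length] = sign * np.outer(maps[k], env)
                sig_rms = np.sqrt(np.mean(sig**2))
                if np.isfinite(truth.snr):
                    noise = _pink_noise(rng, C, n_samples, srate)
                    sig = sig + noise * (sig_rms / truth.snr)
                data[s, c, tr] = sig
                planted[s, c, tr] = labels
    return EpochSet(data=data, channel_labels=STUDY_CHANNELS[:C] if C == N_CHANNELS
                    else tuple(f"ch{i}" for i in range(C)),
                    srate=srate, planted_labels=planted)


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

def generate_behavior(
    truth: GroundTruth,
    n_subjects: int = N_SUBJECTS,
    n_conditions: int = N_CONDITIONS,
    *,
    base_rt_ms: float = 450.0,
    base_duration_ms: float = 2500.0,
    base_rms_emg_uv: float = 50.0,
    base_premovement_emg_uv: float = 5.0,
    subject_sd_ms: float = 40.0,
    noise_sd_ms: float = 30.0,
    emg_noise_cv: float = 0.15,
) -> pd.DataFrame:
    """Per subject x condition behavioral table.

    Reaction time = base + condition shift + subject effect + noise; RMS EMG
    scales multiplicatively with the per-condition ``emg_scale`` (so a
    monotone scale yields stochastically ordered EMG); movement duration and
    pre-movement EMG carry no planted load effect, matching the study's null
    findings for those measures.
    """
    rng = np.random.default_rng(truth.seed + 1)
    rt_shift = np.asarray(truth.rt_shift, dtype=float)[:n_conditions]
    emg_scale = np.asarray(truth.emg_scale, dtype=float)[:n_conditions]
    rows = []
    for s in range(n_subjects):
        subj_rt = rng.normal(0.0, subject_sd_ms)
        subj_emg = np.exp(rng.normal(0.0, 0.2))
        for c in range(n_conditions):
            rt = base_rt_ms + rt_shift[c] + subj_rt + rng.normal(0.0, noise_sd_ms)
            dur = base_duration_ms + subj_rt * 2 + rng.normal(0.0, 4 * noise_sd_ms)
            emg = base_rms_emg_uv * emg_scale[c] * subj_emg * np.exp(
                rng.normal(0.0, emg_noise_cv)
            )
            pre = base_premovement_emg_uv * subj_emg * np.exp(rng.normal(0.0, emg_noise_cv))
            rows.append(
                dict(subject=s, condition=c,
                     reaction_time_ms=max(rt, 1.0),
                     movement_duration_ms=max(dur, 1.0),
                     rms_emg=emg, pre_movement_rms_emg=pre)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EMG and kinematics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialLayout:
    """Timing of one block of trials for EMG/kinematic synthesis."""

    n_trials: int = 10
    trial_len_s: float = 10.0
    cue_time_s: float = 1.0
    srate_emg: float = 4000.0   # study EMG rate
    srate_kin: float = 60.0     # study IMU rate


def generate_emg_and_onsets(
    truth: GroundTruth,
    layout: TrialLayout = TrialLayout(),
    condition: int = 1,
    *,
    rt_ms: float = 450.0,
    movement_s: float = 2.5,
    kin_noise: float = 0.0,
) -> dict:
    """Synthesize per-trial EMG (4000 Hz) and kinematic traces (60 Hz).

    The kinematic flexion-extension trace is a trapezoid rising at movement
    onset and falling at offset; EMG is 20-450 Hz band-limited noise whose
    amplitude inside [onset, offset] scales with the condition's
    ``emg_scale``.  Returns the traces plus the true onset/offset indices at
    both sampling rates.
    """
    rng = np.random.default_rng(truth.seed + 2 + 1000 * condition)
    scale = float(np.asarray(truth.emg_scale)[condition])
    n_kin = int(layout.trial_len_s * layout.srate_kin)
    n_emg = int(layout.trial_len_s * layout.srate_emg)
    kin_traces, emg_traces = [], []
    onsets_kin, offsets_kin, onsets_emg, offsets_emg, cues_kin = [], [], [], [], []
    rise_s, fall_s = 0.5, 0.5
    for _ in range(layout.n_trials):
        onset_s = layout.cue_time_s + rt_ms / 1000.0
        offset_s = onset_s + movement_s
        t_kin = np.arange(n_kin) / layout.srate_kin
        kin = np.interp(
            t_kin,
            [0, onset_s, onset_s + rise_s, offset_s - fall_s, offset_s, layout.trial_len_s],
            [0, 0, 1.0, 1.0, 0, 0],
        )
        if kin_noise > 0:
            kin = kin + rng.normal(0.0, kin_noise, n_kin)
        t_emg = np.arange(n_emg) / layout.srate_emg
        # band-limited noise shaped in the frequency domain (20-450 Hz)
        freqs = np.fft.rfftfreq(n_emg, 1.0 / layout.srate_emg)
        spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
        spec[(freqs < 20) | (freqs > 450)] = 0.0
        carrier = np.fft.irfft(spec, n=n_emg)
        carrier /= np.sqrt(np.mean(carrier**2))
        amp = np.where((t_emg >= onset_s) & (t_emg < offset_s), 1.0, 0.02) * scale
        emg_traces.append(carrier * amp)
        kin_traces.append(kin)
        cues_kin.append(int(round(layout.cue_time_s * layout.srate_kin)))
        onsets_kin.append(int(round(onset_s * layout.srate_kin)))
        offsets_kin.append(int(round(offset_s * layout.srate_kin)))
        onsets_emg.append(int(round(onset_s * layout.srate_emg)))
        offsets_emg.append(int(round(offset_s * layout.srate_emg)))
    return dict(
        emg=np.array(emg_traces), kinematics=np.array(kin_traces),
        cue_kin=np.array(cues_kin),
        onset_kin=np.array(onsets_kin), offset_kin=np.array(offsets_kin),
        onset_emg=np.array(onsets_emg), offset_emg=np.array(offsets_emg),
        srate_emg=layout.srate_emg, srate_kin=layout.srate_kin,
    )
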