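"""Synthetic motor-imagery EEG and questionnaire generator.

Emulates the study recordings: a 32-channel 10-20 montage carrying 1/f
background noise, two alpha-band sources over the sensorimotor cortices
(centred on C3 and C4 with a Gaussian spatial profile), and event-locked,
lateralized suppression of alpha amplitude during each cued motor-imagery
period. Ground-truth modulation parameters are returned alongside every
recording so downstream stages can be validated by parameter recovery.

Conventions
-----------
* A left-hand cue suppresses the right-hemisphere source (C4, contralateral)
  by ``erd_contra_pct`` and the left-hemisphere source (C3) by
  ``erd_ipsi_pct``; right-hand cues mirror this.
* Power scales with amplitude squared, so a target power change of ``p`` %
  is injected as an amplitude factor ``sqrt(1 + p/100)``.
* Suppression starts ``reaction_time_s`` after the cue and is gated by a
  100 ms raised-cosine ramp to avoid spectral splatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io_brainvision import Recording, MARKER_LEFT, MARKER_RIGHT, standard_positions

__all__ = [
    "CHANNELS_32",
    "SimulationConfig",
    "generate_recording",
    "generate_questionnaires",
]

#: 32-channel actiCAP-style 10-20 layout used by the study hardware.
CHANNELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
]

FRONTAL_CHANNELS = ["Fp1", "Fp2", "F7", "F8"]

RAMP_S = 0.1  # raised-cosine gate length for ERD onset/offset


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one synthetic subject/condition recording.

    Defaults follow the extended-protocol study conditions: 15 trials per
    class of 5 s rest + 5 s motor imagery at 250 Hz, with a -40 % / -20 %
    contralateral/ipsilateral alpha-power suppression and a 0.5 s reaction
    latency (inside the first post-cue second that the analysis excludes).
    Set ``rest_duration_s = mi_duration_s = 10``, 20 trials per class and
    500 Hz for the pilot protocol.
    """

    n_trials_per_class: int = 15
    rest_duration_s: float = 5.0
    mi_duration_s: float = 5.0
    sampling_rate: float = 250.0
    erd_contra_pct: float = -40.0
    erd_ipsi_pct: float = -20.0
    alpha_freq_hz: float = 10.0
    alpha_amplitude_uv: float = 8.0
    noise_exponent: float = 1.0
    noise_amplitude_uv: float = 4.0
    blinks: bool = False
    line_noise: bool = False
    reaction_time_s: float = 0.5
    seed: int = 0
    likert_means: dict = field(
        default_factory=lambda: {"Control": 3.3, "Embodied": 5.1}
    )
    likert_sd: float = 1.3
    channel_names: list = field(default_factory=lambda: list(CHANNELS_32))
    #: Gaussian spatial kernel width on the unit scalp for the alpha sources.
    source_sigma: float = 0.35
    #: Gaussian width (unit-scalp distance) of the spatial blur applied to the
    #: background noise; emulates volume-conduction smearing, which keeps
    #: neighbouring clean channels correlated well above 0.5 even after
    #: common-average referencing. 0 disables the blur.
    noise_smoothing_sigma: float = 0.55
    #: Per-subject scaling of both ERD targets (1.0 = exactly the configured
    #: values); cohort simulations draw this to emulate between-subject spread.
    erd_gain: float = 1.0

    def __post_init__(self):
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if self.rest_duration_s <= 0 or self.mi_duration_s <= 0:
            raise ValueError("durations must be positive")
        if not 8.0 <= self.alpha_freq_hz <= 12.0:
            raise ValueError("alpha_freq_hz must lie in [8, 12]")
        for p in (self.erd_contra_pct, self.erd_ipsi_pct):
            if p <= -100.0:
                raise ValueError("ERD percentages must be > -100")
        for m in self.likert_means.values():
            if not 1.0 <= m <= 7.0:
                raise ValueError("likert_means must lie in [1, 7]")

    @property
    def total_duration_s(self) -> float:
        return 2 * self.n_trials_per_class * (self.rest_duration_s + self.mi_duration_s)


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, exponent: float, rms_uv: float) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent power spectrum, scaled to rms_uv."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    spectrum = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * shaping
    noise = np.fft.irfft(spectrum, n=n_samples, axis=1)
    rms = noise.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return noise / rms * rms_uv


def _spatial_profile(positions: np.ndarray, center_idx: int, sigma: float) -> np.ndarray:
    d = np.linalg.norm(positions - positions[center_idx], axis=1)
    return np.exp(-(d ** 2) / (2.0 * sigma ** 2))


def _gate(n: int, fs: float, start: float, stop: float, ramp_s: float = RAMP_S) -> np.ndarray:
    """0->1->0 raised-cosine gate active on [start, stop] seconds."""
    t = np.arange(n) / fs
    g = np.zeros(n)
    g[(t >= start) & (t < stop)] = 1.0
    n_ramp = max(int(round(ramp_s * fs)), 1)
    i0 = int(round(start * fs))
    i1 = int(round(stop * fs))
    up = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    j0, j1 = max(i0, 0), min(i0 + n_ramp, n)
    g[j0:j1] = up[j0 - i0:j1 - i0]
    j0, j1 = max(i1 - n_ramp, 0), min(i1, n)
    g[j0:j1] = up[::-1][j0 - (i1 - n_ramp):j1 - (i1 - n_ramp)]
    return g


def generate_recording(config: SimulationConfig) -> tuple[Recording, dict]:
    """Simulate one continuous MI-training recording.

    Returns the :class:`Recording` (one cue marker per trial at MI onset,
    balanced randomized class order) and a ground-truth dict with the class
    sequence, injected per-class ERD targets at C3/C4, and the implied
    lateralization index.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    names = list(cfg.channel_names)
    positions = standard_positions(names)
    idx_c3, idx_c4 = names.index("C3"), names.index("C4")

    trial_s = cfg.rest_duration_s + cfg.mi_duration_s
    n_trials = 2 * cfg.n_trials_per_class
    n_samples = int(round(n_trials * trial_s * fs))
    t = np.arange(n_samples) / fs

    labels = np.array(["left"] * cfg.n_trials_per_class + ["right"] * cfg.n_trials_per_class)
    rng.shuffle(labels)

    # Amplitude envelopes of the two hemispheric alpha sources over time.
    amp_factor = {
        "contra": np.sqrt(1.0 + cfg.erd_gain * cfg.erd_contra_pct / 100.0),
        "ipsi": np.sqrt(1.0 + cfg.erd_gain * cfg.erd_ipsi_pct / 100.0),
    }
    env_left_hemi = np.ones(n_samples)   # C3 source
    env_right_hemi = np.ones(n_samples)  # C4 source
    events = []
    for k, label in enumerate(labels):
        cue_s = k * trial_s + cfg.rest_duration_s
        events.append((int(round(cue_s * fs)), MARKER_LEFT if label == "left" else MARKER_RIGHT))
        start = cue_s + cfg.reaction_time_s
        stop = cue_s + cfg.mi_duration_s
        gate = _gate(n_samples, fs, start, stop)
        if label == "left":   # contralateral = right hemisphere (C4)
            env_right_hemi = env_right_hemi * (1 - gate) + gate * amp_factor["contra"]
            env_left_hemi = env_left_hemi * (1 - gate) + gate * amp_factor["ipsi"]
        else:
            env_left_hemi = env_left_hemi * (1 - gate) + gate * amp_factor["contra"]
            env_right_hemi = env_right_hemi * (1 - gate) + gate * amp_factor["ipsi"]

    phase_l, phase_r = rng.uniform(0, 2 * np.pi, size=2)
    osc_l = np.sin(2 * np.pi * cfg.alpha_freq_hz * t + phase_l) * env_left_hemi
    osc_r = np.sin(2 * np.pi * cfg.alpha_freq_hz * t + phase_r) * env_right_hemi

    topo_l = _spatial_profile(positions, idx_c3, cfg.source_sigma)
    topo_r = _spatial_profile(positions, idx_c4, cfg.source_sigma)
    # alpha_amplitude_uv is the sinusoid peak at the source-centre channel
    data = cfg.alpha_amplitude_uv * (topo_l[:, None] * osc_l + topo_r[:, None] * osc_r)
    noise = _pink_noise(rng, len(names), n_samples, fs, cfg.noise_exponent,
                        cfg.noise_amplitude_uv)
    if cfg.noise_smoothing_sigma > 0:
        d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
        kernel = np.exp(-d ** 2 / (2 * cfg.noise_smoothing_sigma ** 2))
        kernel /= np.linalg.norm(kernel, axis=1, keepdims=True)  # preserve RMS
        noise = kernel @ noise
    data += noise

    if cfg.line_noise:
        line_phase = rng.uniform(0, 2 * np.pi)
        data += 2.0 * np.sin(2 * np.pi * 50.0 * t + line_phase)[None, :]

    blink_times = []
    if cfg.blinks:
        frontal_gain = np.array([
            80.0 if ch in FRONTAL_CHANNELS else (20.0 if ch.startswith("F") else 2.0)
            for ch in names
        ])
        n_blinks = max(int(cfg.total_duration_s / 20.0), 1)
        blink_times = np.sort(rng.uniform(1.0, cfg.total_duration_s - 1.0, size=n_blinks))
        width = 0.15
        for bt in blink_times:
            pulse = np.exp(-0.5 * ((t - bt) / width) ** 2)
            data += frontal_gain[:, None] * pulse[None, :]
        blink_times = blink_times.tolist()

    rec = Recording(
        data=data,
        sampling_rate=fs,
        channel_names=names,
        channel_positions=positions,
        events=events,
        reference="M1",
        meta={
            "protocol": "extended" if cfg.mi_duration_s <= 5 else "pilot",
            "synthetic": True,
        },
    )
    contra = cfg.erd_gain * cfg.erd_contra_pct
    ipsi = cfg.erd_gain * cfg.erd_ipsi_pct
    truth = {
        "labels": labels.tolist(),
        "erd_contra_pct": contra,
        "erd_ipsi_pct": ipsi,
        # Injected window ERD per (channel, class); left cue -> C4 contralateral.
        "erd_c3_left": ipsi, "erd_c4_left": contra,
        "erd_c3_right": contra, "erd_c4_right": ipsi,
        "li_pct": ((ipsi - contra) + (ipsi - contra)) / 2.0,
        "blink_times_s": blink_times,
        "config": {k: v for k, v in asdict(cfg).items() if k != "channel_names"},
    }
    return rec, truth


# ---------------------------------------------------------------------------
# Questionnaires

_E_ITEMS = [f"E{i}" for i in range(1, 17)]
_P_ITEMS = [f"P{i}" for i in range(1, 6)]


def _truncated_likert(rng, mean, sd, size):
    """Integer 1..7 scores from a discretized truncated normal."""
    if sd == 0:
        return np.full(size, int(round(mean)))
    vals = rng.normal(mean, sd, size=size)
    return np.clip(np.rint(vals), 1, 7).astype(int)


def generate_questionnaires(config: SimulationConfig, n_subjects: int,
                            include_miq1: bool = True) -> "pandas.DataFrame":
    """Per-subject 7-point Likert item responses for both conditions.

    Items are drawn i.i.d. around the per-condition mean in
    ``config.likert_means`` with SD ``config.likert_sd``, discretized to
    {1..7}. Returns a tidy DataFrame with one row per subject x condition and
    columns E1..E16, P1..P5 (and MIQ1 unless ``include_miq1=False`` as in the
    pilot protocol).
    """
    import pandas as pd

    cfg = config
    for m in cfg.likert_means.values():
        if not 1.0 <= m <= 7.0:
            raise ValueError("likert_means must lie in [1, 7]")
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    items = _E_ITEMS + _P_ITEMS + (["MIQ1"] if include_miq1 else [])
    rows = []
    for subject in range(1, n_subjects + 1):
        for condition, mean in cfg.likert_means.items():
            scores = _truncated_likert(rng, mean, cfg.likert_sd, len(items))
            row = {"subject": f"S{subject:02d}", "condition": condition}
            row.update(dict(zip(items, scores)))
            rows.append(row)
    return pd.DataFrame(rows)
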