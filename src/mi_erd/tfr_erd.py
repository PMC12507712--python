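"""Alpha-band ERSP, ERD (%) conversion, window means, and lateralization.

ERSP is computed per trial with Morlet wavelets (1 Hz steps over the band,
cycles = f/2 clipped to [3, 6]) and a per-trial divisive baseline taken from
the symmetric pre-cue interval, expressed in dB:

    ERSP(f, t) = 10 log10( P(f, t) / mean_{t' in baseline} P(f, t') )

ERD converts dB change to percentage power change,
``ERD(%) = (10**(ERSP/10) - 1) * 100``, a strictly monotone bijection from dB
onto (-100, inf). Negative ERD means desynchronization. The analysis window
averages ERD over 1-5 s post-cue (the first second is excluded as reaction
time), and the lateralization index summarizes contralateral dominance:

    LI = ( (ERD_C3(left) - ERD_C4(left)) + (ERD_C4(right) - ERD_C3(right)) ) / 2

with positive LI meaning stronger (more negative) contralateral ERD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .preprocess import EpochSet
from .stats import TestResult, wilcoxon_signed_rank

__all__ = [
    "ERSPMap", "ERDMap", "WindowERD", "LateralizationResult",
    "compute_ersp", "ersp_to_erd", "db_to_erd_pct", "erd_pct_to_db",
    "window_mean_erd", "test_erd_vs_baseline", "lateralization_index",
    "summarize_subject", "round_half_up",
]

EDGE_PAD_S = 1.0  # reflection padding to suppress wavelet edge artifacts


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (table style).

    The value is first snapped to 10 decimal places so that binary float
    representation error (e.g. 25.05 / 2 = 12.524999999999999) does not flip
    a decimal halfway case the wrong way.
    """
    d = Decimal(repr(float(x))).quantize(Decimal("1e-10"))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ERSPMap:
    """Per-trial time-frequency power change in dB relative to baseline."""

    values: np.ndarray  # trials x channels x freqs x times
    freqs: np.ndarray
    times: np.ndarray
    channel_names: list
    labels: np.ndarray
    band: tuple
    baseline_def: str = "symmetric pre-cue interval"


@dataclass
class ERDMap:
    """Per-trial ERD (%) over post-cue times only; values are > -100 %."""

    values: np.ndarray  # trials x channels x freqs x times
    freqs: np.ndarray
    times: np.ndarray  # strictly positive, seconds post-cue
    channel_names: list
    labels: np.ndarray
    band: tuple
    baseline_def: str = "symmetric pre-cue interval"


@dataclass
class WindowERD:
    """Per-trial, per-channel mean ERD (%) over the analysis window."""

    values: np.ndarray  # trials x channels
    channel_names: list
    labels: np.ndarray
    window: tuple
    channel_grand_means: dict = field(default_factory=dict)


@dataclass
class LateralizationResult:
    li_pct: float
    erd_c3_left: float
    erd_c4_left: float
    erd_c3_right: float
    erd_c4_right: float


def compute_ersp(epochs: EpochSet, band: tuple = (8.0, 12.0),
                 freq_step: float = 1.0, baseline: tuple = None) -> ERSPMap:
    """Morlet-wavelet ERSP (dB) for every trial, channel and band frequency.

    ``baseline`` is a (tmin, tmax) pre-cue interval; by default the whole
    symmetric pre-cue half of the epoch. Epochs are reflection-padded before
    the wavelet transform so the baseline and late task window are not biased
    by convolution edge effects.
    """
    from mne.time_frequency import tfr_array_morlet

    fs = epochs.sampling_rate
    if band[1] >= fs / 2:
        raise ValueError(f"band {band} exceeds the Nyquist frequency {fs / 2:g} Hz")
    lowpass = epochs.meta.get("lowpass")
    if lowpass is not None and band[1] > lowpass:
        raise ValueError(f"band {band} outside the {lowpass:g} Hz filter passband")

    freqs = np.arange(band[0], band[1] + 1e-9, freq_step)
    n_cycles = np.clip(freqs / 2.0, 3.0, 6.0)

    n_pad = int(round(EDGE_PAD_S * fs))
    x = np.concatenate(
        [epochs.data[:, :, 1:n_pad + 1][:, :, ::-1],
         epochs.data,
         epochs.data[:, :, -n_pad - 1:-1][:, :, ::-1]],
        axis=2,
    )
    power = tfr_array_morlet(x, sfreq=fs, freqs=freqs, n_cycles=n_cycles,
                             output="power", verbose="error")
    power = power[:, :, :, n_pad:n_pad + epochs.data.shape[2]]

    times = epochs.time_axis
    if baseline is None:
        baseline = (times.min(), 0.0)
    bmask = (times >= baseline[0]) & (times < baseline[1])
    if not bmask.any():
        raise ValueError("empty baseline interval")
    p_base = power[:, :, :, bmask].mean(axis=3, keepdims=True)
    if np.any(p_base <= 0):
        raise ValueError("degenerate baseline: zero power at some (trial, channel, freq)")

    ersp = 10.0 * np.log10(power / p_base)
    return ERSPMap(values=ersp, freqs=freqs, times=times,
                   channel_names=list(epochs.channel_names),
                   labels=epochs.labels.copy(), band=tuple(band))


def db_to_erd_pct(ersp_db):
    """Eq.: ERD(%) = (10**(ERSP/10) - 1) * 100; monotone, range (-100, inf)."""
    return (np.power(10.0, np.asarray(ersp_db, dtype=float) / 10.0) - 1.0) * 100.0


def erd_pct_to_db(erd_pct):
    """Inverse map: ERSP(dB) = 10 log10(1 + ERD/100)."""
    return 10.0 * np.log10(1.0 + np.asarray(erd_pct, dtype=float) / 100.0)


def ersp_to_erd(ersp: ERSPMap) -> ERDMap:
    """Convert dB ERSP to ERD (%), restricted to post-cue times."""
    mask = ersp.times > 0
    return ERDMap(
        values=db_to_erd_pct(ersp.values[:, :, :, mask]),
        freqs=ersp.freqs.copy(),
        times=ersp.times[mask],
        channel_names=list(ersp.channel_names),
        labels=ersp.labels.copy(),
        band=ersp.band,
        baseline_def=ersp.baseline_def,
    )


def window_mean_erd(erd: ERDMap, window: tuple = (1.0, 5.0),
                    channels=("C3", "C4")) -> WindowERD:
    """Mean ERD over band frequencies and the half-open analysis window.

    A window starting before 1 s is clamped to 1 s (reaction-time exclusion)
    with a warning. Also emits per-channel grand means (all trials) for scalp
    maps, over every channel in the map.
    """
    w0, w1 = window
    if w0 < 1.0:
        warnings.warn("analysis window start clamped to 1 s (reaction-time exclusion)")
        w0 = 1.0
    tmask = (erd.times >= w0) & (erd.times < w1)
    if not tmask.any():
        raise ValueError(f"empty analysis window [{w0}, {w1}) for available times")

    mean_all = erd.values[:, :, :, tmask].mean(axis=(2, 3))  # trials x channels
    ch_idx = [erd.channel_names.index(c) for c in channels]
    grand = {c: float(mean_all[:, i].mean()) for i, c in enumerate(erd.channel_names)}
    return WindowERD(
        values=mean_all[:, ch_idx],
        channel_names=list(channels),
        labels=erd.labels.copy(),
        window=(w0, w1),
        channel_grand_means=grand,
    )


def test_erd_vs_baseline(window_erd: WindowERD, channel: str, label: str) -> TestResult:
    """One-sample Wilcoxon signed-rank of per-trial window ERD against 0 %."""
    ch = window_erd.channel_names.index(channel)
    vals = window_erd.values[window_erd.labels == label, ch]
    if vals.size < 5:
        raise ValueError(f"need >= 5 trials of class {label!r}; got {vals.size}")
    return wilcoxon_signed_rank(vals, mu0=0.0)


def lateralization_index(erd_c3_left: float, erd_c4_left: float,
                         erd_c3_right: float, erd_c4_right: float) -> LateralizationResult:
    """Lateralization index from the four class-mean window-ERD values (%).

    Positive LI indicates stronger contralateral desynchronization.
    """
    for v in (erd_c3_left, erd_c4_left, erd_c3_right, erd_c4_right):
        if not np.isfinite(v):
            raise ValueError("all four ERD inputs must be finite")
    li = ((erd_c3_left - erd_c4_left) + (erd_c4_right - erd_c3_right)) / 2.0
    return LateralizationResult(
        li_pct=float(li),
        erd_c3_left=float(erd_c3_left), erd_c4_left=float(erd_c4_left),
        erd_c3_right=float(erd_c3_right), erd_c4_right=float(erd_c4_right),
    )


def summarize_subject(window_erd: WindowERD) -> dict:
    """Class-mean window ERD at C3/C4 plus the subject's LI (%)."""
    idx = {c: window_erd.channel_names.index(c) for c in ("C3", "C4")}
    out = {}
    for ch in ("C3", "C4"):
        for label in ("left", "right"):
            vals = window_erd.values[window_erd.labels == label, idx[ch]]
            out[f"erd_{ch.lower()}_{label}"] = float(vals.mean())
    out["li_pct"] = lateralization_index(
        out["erd_c3_left"], out["erd_c4_left"],
        out["erd_c3_right"], out["erd_c4_right"],
    ).li_pct
    return out
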