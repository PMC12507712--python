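"""BrainVision (.vhdr/.vmrk/.eeg) reading and writing.

Supports the multiplexed binary dialect in IEEE float32 (default on write) and
int16-with-resolution form. Marker positions are 1-based in the .vmrk file, per
the BrainVision convention, and converted to 0-based sample indices in memory.
Vectorized data orientation and ASCII data are rejected with an explicit error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Recording",
    "UnsupportedDialectError",
    "read_brainvision",
    "write_brainvision",
    "standard_positions",
]

#: Cue-marker descriptions used throughout the package.
MARKER_LEFT = "S  1"
MARKER_RIGHT = "S  2"


class UnsupportedDialectError(ValueError):
    """Raised for BrainVision files outside the supported dialect."""


@dataclass
class Recording:
    """Continuous multichannel EEG with montage, rate, and event markers.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sampling_rate : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique 10-20-system labels, e.g. ``"C3"``, ``"C4"``.
    channel_positions : ndarray, shape (n_channels, 3)
        Unit-sphere electrode coordinates (0 for unknown labels).
    events : list of (int, str)
        0-based sample index and marker description (e.g. ``"S  1"``).
    reference : str
        Reference label, or ``"CAR"`` after common-average re-referencing.
    meta : dict
        Free-form metadata: subject id, condition tag, protocol.
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    channel_positions: np.ndarray = None
    events: list[tuple[int, str]] = field(default_factory=list)
    reference: str = "M1"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")
        if self.channel_positions is None:
            self.channel_positions = standard_positions(self.channel_names)
        self.channel_positions = np.asarray(self.channel_positions, dtype=float)
        if np.isnan(self.data).any():
            raise ValueError("data contains NaN")
        n = self.n_samples
        for idx, _ in self.events:
            if not 0 <= idx < n:
                raise ValueError(f"event sample index {idx} outside [0, {n})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            sampling_rate=self.sampling_rate,
            channel_names=list(self.channel_names),
            channel_positions=self.channel_positions.copy(),
            events=list(self.events),
            reference=self.reference,
            meta=dict(self.meta),
        )

    def to_mne(self):
        """Convert to an :class:`mne.io.RawArray` (volts) with montage set."""
        import mne

        info = mne.create_info(self.channel_names, self.sampling_rate, ch_types="eeg")
        raw = mne.io.RawArray(self.data * 1e-6, info, verbose="error")
        montage = _standard_montage()
        known = {ch for ch in self.channel_names if ch in montage.get_positions()["ch_pos"]}
        if known == set(self.channel_names):
            raw.set_montage(montage, verbose="error")
        return raw


_MONTAGE_CACHE = {}


def _standard_montage():
    import mne

    if "m" not in _MONTAGE_CACHE:
        try:
            _MONTAGE_CACHE["m"] = mne.channels.make_standard_montage("colin27_1020")
        except ValueError:  # older MNE naming
            _MONTAGE_CACHE["m"] = mne.channels.make_standard_montage("standard_1020")
    return _MONTAGE_CACHE["m"]


def standard_positions(channel_names) -> np.ndarray:
    """Unit-sphere 3-D positions for 10-20 labels (zeros for unknown names)."""
    pos_map = _standard_montage().get_positions()["ch_pos"]
    out = np.zeros((len(channel_names), 3))
    for i, name in enumerate(channel_names):
        p = pos_map.get(name)
        if p is not None and np.linalg.norm(p) > 0:
            out[i] = p / np.linalg.norm(p)
    return out


# ---------------------------------------------------------------------------
# Header parsing helpers


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = {}
        elif "=" in line and current is not None:
            key, val = line.split("=", 1)
            sections[current][key.strip()] = val.strip()
    return sections


def read_brainvision(path) -> Recording:
    """Read a BrainVision triple given the path to its .vhdr header.

    Raises
    ------
    FileNotFoundError
        If the header or a companion file it references is missing.
    UnsupportedDialectError
        For vectorized orientation, ASCII data, or binary formats other than
        IEEE_FLOAT_32 / INT_16.
    """
    vhdr = Path(path)
    if not vhdr.exists():
        raise FileNotFoundError(f"header file not found: {vhdr}")
    sections = _parse_ini(vhdr.read_text(encoding="utf-8"))
    common = sections.get("Common Infos", {})
    binary = sections.get("Binary Infos", {})

    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
    if orientation != "MULTIPLEXED":
        raise UnsupportedDialectError(
            f"unsupported data orientation {orientation!r}; only MULTIPLEXED is supported"
        )
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise UnsupportedDialectError("only BINARY DataFormat is supported")
    fmt = binary.get("BinaryFormat", "IEEE_FLOAT_32").upper()
    if fmt not in ("IEEE_FLOAT_32", "INT_16"):
        raise UnsupportedDialectError(f"unsupported BinaryFormat {fmt!r}")

    eeg_path = vhdr.parent / common["DataFile"]
    vmrk_path = vhdr.parent / common["MarkerFile"] if "MarkerFile" in common else None
    if not eeg_path.exists():
        raise FileNotFoundError(f"data file referenced by header not found: {eeg_path}")
    if vmrk_path is not None and not vmrk_path.exists():
        raise FileNotFoundError(f"marker file referenced by header not found: {vmrk_path}")

    n_channels = int(common["NumberOfChannels"])
    sampling_rate = 1e6 / float(common["SamplingInterval"])

    names, resolutions, reference = [], [], "M1"
    for i in range(1, n_channels + 1):
        entry = sections["Channel Infos"][f"Ch{i}"]
        parts = entry.split(",")
        names.append(parts[0])
        if len(parts) > 1 and parts[1]:
            reference = parts[1]
        resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)

    dtype = "<f4" if fmt == "IEEE_FLOAT_32" else "<i2"
    flat = np.fromfile(eeg_path, dtype=dtype)
    if flat.size % n_channels:
        raise ValueError("data file length is not a multiple of the channel count")
    data = flat.reshape(-1, n_channels).T.astype(float)
    data *= np.asarray(resolutions)[:, None]

    events: list[tuple[int, str]] = []
    if vmrk_path is not None:
        for key, val in _parse_ini(vmrk_path.read_text(encoding="utf-8")).get(
            "Marker Infos", {}
        ).items():
            parts = val.split(",")
            mtype, desc, pos = parts[0], parts[1], int(parts[2])
            if mtype == "Stimulus":
                events.append((pos - 1, desc))  # 1-based file -> 0-based memory

    meta, ref = {}, reference
    comment = sections.get("Comment", {})
    if "MiErdMeta" in comment:
        meta = json.loads(comment["MiErdMeta"])
        ref = meta.pop("__reference__", reference)

    return Recording(
        data=data,
        sampling_rate=sampling_rate,
        channel_names=names,
        events=events,
        reference=ref,
        meta=meta,
    )


def write_brainvision(recording: Recording, path, binary_format: str = "IEEE_FLOAT_32",
                      resolution: float = 0.1) -> dict[str, Path]:
    """Write a Recording as a .vhdr/.vmrk/.eeg triple.

    Parameters
    ----------
    path : path-like
        Basename for the triple; extensions are replaced/added.
    binary_format : {"IEEE_FLOAT_32", "INT_16"}
        On-disk sample format. INT_16 stores ``round(uV / resolution)``.
    resolution : float
        Microvolts per integer unit for the INT_16 dialect.

    Returns
    -------
    dict mapping "vhdr" / "vmrk" / "eeg" to the written paths.
    """
    binary_format = binary_format.upper()
    if binary_format not in ("IEEE_FLOAT_32", "INT_16"):
        raise UnsupportedDialectError(f"unsupported BinaryFormat {binary_format!r}")
    base = Path(path)
    if base.suffix.lower() in (".vhdr", ".vmrk", ".eeg"):
        base = base.with_suffix("")
    base.parent.mkdir(parents=True, exist_ok=True)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    res = 1.0 if binary_format == "IEEE_FLOAT_32" else resolution
    interval = 1e6 / recording.sampling_rate
    interval_str = f"{interval:.10g}"

    meta = dict(recording.meta)
    meta["__reference__"] = recording.reference
    lines = [
        "BrainVision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={recording.n_channels}",
        f"SamplingInterval={interval_str}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(recording.channel_names, start=1):
        lines.append(f"Ch{i}={name},,{res:.10g},µV")
    lines += ["", "[Comment]", f"MiErdMeta={json.dumps(meta)}", ""]
    vhdr.write_text("\n".join(lines), encoding="utf-8")

    mlines = [
        "BrainVision Data Exchange Marker File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20000101000000000000",
    ]
    for k, (sample, desc) in enumerate(recording.events, start=2):
        mlines.append(f"Mk{k}=Stimulus,{desc},{sample + 1},1,0")
    mlines.append("")
    vmrk.write_text("\n".join(mlines), encoding="utf-8")

    mux = recording.data.T  # samples x channels (multiplexed)
    if binary_format == "IEEE_FLOAT_32":
        mux.astype("<f4").tofile(eeg)
    else:
        stored = np.round(mux / res)
        if np.abs(stored).max(initial=0) > 32767:
            raise ValueError("signal exceeds INT_16 range at this resolution")
        stored.astype("<i2").tofile(eeg)

    return {"vhdr": vhdr, "vmrk": vmrk, "eeg": eeg}
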