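"""Continuous EEG I/O and the package's internal dataset bundle.

All downstream modules consume :class:`SignalRecord`, :class:`Epoch` and the
:class:`TrialTable`; readers normalise everything to microvolts and sample
indices so the rest of the pipeline never touches file-format details.

EDF/EDF+ and BrainVision files are read through :mod:`mne`.  Minimal writers
for both formats are provided so that round-trips can be exercised without
external data; they cover the plain single-record (EDF) / float32 (BrainVision)
cases only.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SignalRecord",
    "Epoch",
    "TrialTable",
    "read_edf",
    "write_edf",
    "read_brainvision",
    "write_brainvision",
    "extract_trials",
    "save_bundle",
    "load_bundle",
]

MI_LABELS = ("left", "right")
STATE_LABELS = ("low", "mid", "high")


class FormatError(ValueError):
    """Raised when a file exists but its contents violate the format."""


def _norm_channel(name: str) -> str:
    return name.strip().lower()


@dataclass
class SignalRecord:
    """Continuous multichannel EEG in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling rate in Hz.
    channel_names : list of str
        Ordered 10-20 electrode labels (e.g. C3, C4, Oz); must be unique
        after case/whitespace normalisation.
    events : list of (int, str)
        ``(sample_index, code)`` markers, each index within the record.
    """

    data: np.ndarray
    rate: float
    channel_names: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        norm = [_norm_channel(c) for c in self.channel_names]
        if len(set(norm)) != len(norm):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        n = self.data.shape[1]
        for idx, code in self.events:
            if not (0 <= idx < n):
                raise ValueError(f"event {code!r} at sample {idx} outside [0, {n})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, name: str) -> int:
        """Case-insensitive, whitespace-stripped channel lookup."""
        norm = [_norm_channel(c) for c in self.channel_names]
        key = _norm_channel(name)
        if key not in norm:
            raise KeyError(f"channel {name!r} not in {self.channel_names}")
        return norm.index(key)


@dataclass
class Epoch:
    """One labelled trial cut from a continuous record (microvolts)."""

    data: np.ndarray  # (n_channels, n_samples)
    rate: float
    channel_names: list[str]
    subject_id: str
    trial_id: str
    mi_label: str  # "left" | "right"
    state_label: str  # "low" | "mid" | "high" | "none"
    stage: int  # 1 = calibration (no induced state), 2 = induced-state blocks


TRIAL_COLUMNS = [
    "subject_id",
    "trial_id",
    "onset_sample",
    "duration_samples",
    "mi_label",
    "state_label",
    "stage",
]


@dataclass
class TrialTable:
    """Table of trial intervals and labels; one row per trial."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trial table missing columns {missing}")
        df = df[TRIAL_COLUMNS].copy()
        df["onset_sample"] = df["onset_sample"].astype(int)
        df["duration_samples"] = df["duration_samples"].astype(int)
        df["stage"] = df["stage"].astype(int)
        bad_mi = set(df["mi_label"]) - set(MI_LABELS)
        if bad_mi:
            raise ValueError(f"unknown mi_label values {bad_mi}")
        s1 = df[df["stage"] == 1]
        s2 = df[df["stage"] == 2]
        if not (s1["state_label"] == "none").all():
            raise ValueError("stage-1 rows must have state_label == 'none'")
        bad_state = set(s2["state_label"]) - set(STATE_LABELS)
        if bad_state:
            raise ValueError(f"stage-2 state_label must be low/mid/high, got {bad_state}")
        for subject, grp in df.groupby("subject_id"):
            g = grp.sort_values("onset_sample")
            ends = g["onset_sample"] + g["duration_samples"]
            if (g["onset_sample"].values[1:] < ends.values[:-1]).any():
                raise ValueError(f"overlapping trial intervals for subject {subject}")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialTable":
        return cls(pd.read_csv(path, dtype={"subject_id": str, "trial_id": str}))


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(path: str | Path) -> SignalRecord:
    """Read an EDF/EDF+ file into a :class:`SignalRecord` (microvolts).

    Annotations, when present, are mapped to ``(sample_index, code)`` events.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on corrupt headers
        raise FormatError(f"cannot parse EDF file {path}: {exc}") from exc
    return _record_from_raw(raw)


def _record_from_raw(raw) -> SignalRecord:
    data = raw.get_data() * 1e6  # mne works in volts internally
    rate = float(raw.info["sfreq"])
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        code = str(desc)
        # BrainVision marker descriptions arrive as "<type>/<code>"
        if "/" in code:
            code = code.split("/", 1)[1]
        events.append((int(round(onset * rate)), code))
    return SignalRecord(
        data=data, rate=rate, channel_names=list(raw.ch_names), events=events
    )


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, record: SignalRecord) -> None:
    """Write a plain EDF file (one data record, 16-bit), data in microvolts.

    Physical range is chosen per channel from the data, so the round-trip
    error is bounded by the 16-bit quantisation step of that range.
    """
    path = Path(path)
    data = record.data
    n_chan, n_samp = data.shape
    duration = n_samp / record.rate
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    dig_min, dig_max = -32768, 32767

    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))
        f.write(_edf_field("X X X X", 80))
        f.write(_edf_field("Startdate X X X X", 80))
        f.write(_edf_field("01.01.00", 8))
        f.write(_edf_field("00.00.00", 8))
        f.write(_edf_field(str(256 * (1 + n_chan)), 8))
        f.write(_edf_field("", 44))
        f.write(_edf_field("1", 8))
        f.write(_edf_field(f"{duration:.6g}", 8))
        f.write(_edf_field(str(n_chan), 4))
        for name in record.channel_names:
            f.write(_edf_field(name, 16))
        for _ in range(n_chan):
            f.write(_edf_field("", 80))
        for _ in range(n_chan):
            f.write(_edf_field("uV", 8))
        for pm in phys_max:
            f.write(_edf_field(f"{-pm:.6g}"[:8], 8))
        for pm in phys_max:
            f.write(_edf_field(f"{pm:.6g}"[:8], 8))
        for _ in range(n_chan):
            f.write(_edf_field(str(dig_min), 8))
        for _ in range(n_chan):
            f.write(_edf_field(str(dig_max), 8))
        for _ in range(n_chan):
            f.write(_edf_field("", 80))
        for _ in range(n_chan):
            f.write(_edf_field(str(n_samp), 8))
        for _ in range(n_chan):
            f.write(_edf_field("", 32))
        for ch in range(n_chan):
            pm = phys_max[ch]
            # EDF convention: physical = pmin + (d - dmin) * prange / drange
            scale = (2 * pm) / (dig_max - dig_min)
            dig = np.round((data[ch] - (-pm)) / scale + dig_min)
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            f.write(dig.tobytes())


# ---------------------------------------------------------------------------
# BrainVision
# ---------------------------------------------------------------------------

def read_brainvision(header_path: str | Path) -> SignalRecord:
    """Read a BrainVision triplet (.vhdr/.eeg/.vmrk) into a SignalRecord.

    Marker rows become ``(sample_index, code)`` events; both MULTIPLEXED and
    VECTORIZED data orientations are supported.
    """
    import mne

    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    cfg = configparser.ConfigParser()
    try:
        text = header_path.read_text(encoding="utf-8", errors="replace")
        lines = text.splitlines()
        # drop the banner line and comments; configparser wants sections first
        body = [l for l in lines if not l.startswith(";")]
        while body and not body[0].startswith("["):
            body.pop(0)
        cfg.read_string("\n".join(body))
        common = cfg["Common Infos"]
        for key in ("DataFile", "MarkerFile"):
            if key in common and not (header_path.parent / common[key]).exists():
                raise FormatError(
                    f"{header_path} references missing file {common[key]!r}"
                )
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse BrainVision header {header_path}: {exc}") from exc
    try:
        raw = mne.io.read_raw_brainvision(str(header_path), preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"cannot parse BrainVision data {header_path}: {exc}") from exc
    rec = _record_from_raw(raw)
    # drop mne's synthetic segment marker
    rec.events = [(i, c) for i, c in rec.events if not c.startswith("New Segment")]
    return rec


def write_brainvision(
    header_path: str | Path,
    record: SignalRecord,
    orientation: str = "MULTIPLEXED",
) -> None:
    """Write a BrainVision triplet (IEEE float32 data, microvolt units)."""
    if orientation not in ("MULTIPLEXED", "VECTORIZED"):
        raise ValueError("orientation must be MULTIPLEXED or VECTORIZED")
    header_path = Path(header_path)
    stem = header_path.with_suffix("")
    eeg_path = stem.with_suffix(".eeg")
    vmrk_path = stem.with_suffix(".vmrk")

    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        f"MarkerFile={vmrk_path.name}",
        "DataFormat=BINARY",
        f"DataOrientation={orientation}",
        f"NumberOfChannels={record.n_channels}",
        f"SamplingInterval={1e6 / record.rate:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(record.channel_names, start=1):
        header.append(f"Ch{i}={name},,1,µV")
    header_path.write_text("\n".join(header) + "\n", encoding="utf-8")

    data = record.data.astype("<f4")
    if orientation == "MULTIPLEXED":
        data = data.T  # sample-major
    eeg_path.write_bytes(data.tobytes())

    marker = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_path.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (idx, code) in enumerate(record.events, start=2):
        # BrainVision marker positions are 1-based
        marker.append(f"Mk{k}=Stimulus,{code},{idx + 1},1,0")
    vmrk_path.write_text("\n".join(marker) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------

def extract_trials(record: SignalRecord, table: TrialTable) -> list[Epoch]:
    """Cut one labelled :class:`Epoch` per trial-table row.

    The record is left unmodified; epochs are copies.  An interval that runs
    past the end of the record raises a range error naming the trial.
    """
    epochs: list[Epoch] = []
    n = record.n_samples
    for row in table.frame.itertuples(index=False):
        start = int(row.onset_sample)
        stop = start + int(row.duration_samples)
        if start < 0 or stop > n:
            raise IndexError(
                f"trial {row.trial_id}: interval [{start}, {stop}) outside record "
                f"of {n} samples"
            )
        epochs.append(
            Epoch(
                data=record.data[:, start:stop].copy(),
                rate=record.rate,
                channel_names=list(record.channel_names),
                subject_id=str(row.subject_id),
                trial_id=str(row.trial_id),
                mi_label=str(row.mi_label),
                state_label=str(row.state_label),
                stage=int(row.stage),
            )
        )
    return epochs


# ---------------------------------------------------------------------------
# Internal bundle (HDF5)
# ---------------------------------------------------------------------------

def save_bundle(path: str | Path, windowset, provenance: dict | None = None) -> None:
    """Persist a :class:`~frustmi.preprocess.WindowSet` plus provenance.

    One HDF5 file holds the window tensor, the per-window labels, the
    segmentation parameters and free-form provenance attributes (seed,
    config hash, ...), so an experiment snapshot can be reloaded exactly.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=windowset.windows, compression="gzip")
        str_dt = h5py.string_dtype("utf-8")
        for name in ("mi_label", "state_label", "subject_id", "trial_id"):
            f.create_dataset(name, data=np.asarray(getattr(windowset, name), dtype=object), dtype=str_dt)
        f.create_dataset("channel_names", data=np.asarray(windowset.channel_names, dtype=object), dtype=str_dt)
        f.attrs["window_len"] = windowset.window_len
        f.attrs["step"] = windowset.step
        f.attrs["rate"] = windowset.rate
        for k, v in (provenance or {}).items():
            f.attrs[f"prov:{k}"] = v


def load_bundle(path: str | Path):
    """Inverse of :func:`save_bundle`; returns ``(WindowSet, provenance)``."""
    from .preprocess import WindowSet

    with h5py.File(path, "r") as f:
        ws = WindowSet(
            windows=f["windows"][()],
            mi_label=np.array([s.decode() if isinstance(s, bytes) else s for s in f["mi_label"][()]]),
            state_label=np.array([s.decode() if isinstance(s, bytes) else s for s in f["state_label"][()]]),
            subject_id=np.array([s.decode() if isinstance(s, bytes) else s for s in f["subject_id"][()]]),
            trial_id=np.array([s.decode() if isinstance(s, bytes) else s for s in f["trial_id"][()]]),
            window_len=int(f.attrs["window_len"]),
            step=int(f.attrs["step"]),
            rate=float(f.attrs["rate"]),
            channel_names=[s.decode() if isinstance(s, bytes) else s for s in f["channel_names"][()]],
        )
        prov = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("prov:")}
    return ws, prov
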