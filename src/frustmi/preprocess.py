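"""Preprocessing pipeline and sliding-window segmentation.

The continuous pipeline is baseline correction (per-channel mean removal over
the whole record), a powerline notch, then a broadband bandpass — in that
order, all zero-phase so event latencies are preserved.  Trials are then cut
into fixed-length windows with a fixed step; windows never cross a trial
boundary, and each window remembers its source trial so cross-validation can
keep sibling windows together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import Epoch, SignalRecord

__all__ = ["WindowSet", "preprocess_record", "segment_windows", "segment_epochs"]

DEFAULT_WINDOW_LEN = 3000
DEFAULT_STEP = 100


@dataclass
class WindowSet:
    """Fixed-length analysis windows with aligned per-window labels.

    ``windows`` has shape (n_windows, n_channels, window_len), in microvolts
    and mean-removed per channel.  Label arrays all have length n_windows.
    """

    windows: np.ndarray
    mi_label: np.ndarray
    state_label: np.ndarray
    subject_id: np.ndarray
    trial_id: np.ndarray
    window_len: int
    step: int
    rate: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3:
            raise ValueError("windows must be 3-D (n, channels, samples)")
        if self.windows.shape[2] != self.window_len:
            raise ValueError("window length mismatch")
        n = len(self.windows)
        for name in ("mi_label", "state_label", "subject_id", "trial_id"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != {n} windows")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def stage(self) -> np.ndarray:
        """Stage per window: 1 where no state was induced, else 2."""
        return np.where(self.state_label == "none", 1, 2)

    def subset(self, mask: np.ndarray) -> "WindowSet":
        mask = np.asarray(mask)
        if mask.dtype == bool and len(mask) != len(self):
            raise ValueError("boolean mask length mismatch")
        return WindowSet(
            windows=self.windows[mask],
            mi_label=self.mi_label[mask],
            state_label=self.state_label[mask],
            subject_id=self.subject_id[mask],
            trial_id=self.trial_id[mask],
            window_len=self.window_len,
            step=self.step,
            rate=self.rate,
            channel_names=list(self.channel_names),
        )

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        first = sets[0]
        for s in sets[1:]:
            if (s.window_len, s.step, s.rate) != (first.window_len, first.step, first.rate):
                raise ValueError("incompatible WindowSets")
        return WindowSet(
            windows=np.concatenate([s.windows for s in sets]),
            mi_label=np.concatenate([s.mi_label for s in sets]),
            state_label=np.concatenate([s.state_label for s in sets]),
            subject_id=np.concatenate([s.subject_id for s in sets]),
            trial_id=np.concatenate([s.trial_id for s in sets]),
            window_len=first.window_len,
            step=first.step,
            rate=first.rate,
            channel_names=list(first.channel_names),
        )


def _check_band(rate: float, notch_hz: float, band: tuple[float, float]) -> None:
    nyq = rate / 2.0
    low, high = band
    if not (0 < low < high):
        raise ValueError(f"band edges must satisfy 0 < low < high, got {band}")
    if high >= nyq:
        raise ValueError(f"band upper edge {high} Hz must be below Nyquist {nyq} Hz")
    if not (0 < notch_hz < nyq):
        raise ValueError(f"notch frequency {notch_hz} Hz must be below Nyquist {nyq} Hz")


def preprocess_record(
    record: SignalRecord,
    notch_hz: float = 50.0,
    band: tuple[float, float] = (1.0, 40.0),
) -> SignalRecord:
    """Baseline-correct, notch-filter and bandpass a continuous record.

    Steps, in order: (1) per-channel mean removal over the whole record,
    (2) IIR notch at ``notch_hz`` (quality factor 30), (3) 4th-order
    Butterworth bandpass over ``band``.  Both filters are applied
    forward-backward (zero-phase).  Returns a new record; events carry over.
    """
    _check_band(record.rate, notch_hz, band)
    x = record.data - record.data.mean(axis=1, keepdims=True)
    b_notch, a_notch = signal.iirnotch(notch_hz, Q=30.0, fs=record.rate)
    x = signal.filtfilt(b_notch, a_notch, x, axis=1)
    sos = signal.butter(4, band, btype="bandpass", fs=record.rate, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)
    return SignalRecord(
        data=x,
        rate=record.rate,
        channel_names=list(record.channel_names),
        events=list(record.events),
    )


def window_count(length: int, window_len: int, step: int) -> int:
    """Number of sliding windows: floor((L - window_len)/step) + 1."""
    if length < window_len:
        raise ValueError(f"trial too short: {length} < window length {window_len}")
    return (length - window_len) // step + 1


def segment_windows(
    epoch: Epoch,
    window_len: int = DEFAULT_WINDOW_LEN,
    step: int = DEFAULT_STEP,
) -> WindowSet:
    """Cut one epoch into overlapping windows inheriting the epoch's labels.

    Produces exactly ``floor((L - window_len)/step) + 1`` windows at offsets
    0, step, 2*step, ...; each window is mean-removed per channel.  An epoch
    shorter than ``window_len`` raises (no silent truncation).
    """
    data = np.asarray(epoch.data, dtype=float)
    n_chan, length = data.shape
    n_win = window_count(length, window_len, step)
    offsets = np.arange(n_win) * step
    wins = np.stack([data[:, o : o + window_len] for o in offsets])
    wins = wins - wins.mean(axis=2, keepdims=True)
    n = len(wins)
    return WindowSet(
        windows=wins,
        mi_label=np.full(n, epoch.mi_label, dtype=object),
        state_label=np.full(n, epoch.state_label, dtype=object),
        subject_id=np.full(n, epoch.subject_id, dtype=object),
        trial_id=np.full(n, epoch.trial_id, dtype=object),
        window_len=window_len,
        step=step,
        rate=epoch.rate,
        channel_names=list(epoch.channel_names),
    )


def segment_epochs(
    epochs: list[Epoch],
    window_len: int = DEFAULT_WINDOW_LEN,
    step: int = DEFAULT_STEP,
) -> WindowSet:
    """Segment a list of epochs and concatenate the resulting windows."""
    if not epochs:
        raise ValueError("no epochs to segment")
    return WindowSet.concatenate(
        [segment_windows(e, window_len=window_len, step=step) for e in epochs]
    )
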