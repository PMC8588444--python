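"""Core containers: multichannel recordings and frequency-band definitions.

A :class:`Recording` is a channels x samples matrix with its sampling rate,
channel labels and subject metadata.  ``edge_margin`` tracks how many samples
at each end are contaminated by filter transients; phase statistics downstream
exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

GROUPS = ("control", "case", "unknown")
STIMULI = ("4.8Hz", "16Hz", "none")


@dataclass(frozen=True)
class BandSpec:
    """A frequency band [f_lo, f_hi] in Hz with a conventional name."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"invalid band {self.name}: need 0 < f_lo < f_hi, "
                f"got [{self.f_lo}, {self.f_hi}]"
            )

    def validate_fs(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band {self.name} [{self.f_lo}, {self.f_hi}] Hz exceeds the "
                f"Nyquist frequency {fs / 2} Hz"
            )


#: The five canonical EEG bands.
DEFAULT_BANDS = (
    BandSpec("Delta", 1.5, 4.0),
    BandSpec("Theta", 4.0, 8.0),
    BandSpec("Alpha", 8.0, 13.0),
    BandSpec("Beta", 13.0, 30.0),
    BandSpec("Gamma", 30.0, 80.0),
)


#: Extended 10-20 labels of the default 32-electrode cap (Cz is the
#: reference in the canonical montage; re-referencing drops it).
DEFAULT_MONTAGE_32 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)


def band_by_name(name: str) -> BandSpec:
    for b in DEFAULT_BANDS:
        if b.name.lower() == name.lower():
            return b
    raise KeyError(f"unknown band name {name!r}")


@dataclass
class Recording:
    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_labels: list[str]
    subject_id: str = ""
    group: str = "unknown"
    stimulus: str = "none"
    edge_margin: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "Recording":
        kw.setdefault("data", self.data.copy())
        kw.setdefault("channel_labels", list(self.channel_labels))
        return replace(self, **kw)

    def interior(self) -> np.ndarray:
        """Data with the filter edge margins trimmed from both ends."""
        m = self.edge_margin
        if m == 0:
            return self.data
        if 2 * m >= self.n_samples:
            raise ValueError(
                f"edge margin {m} leaves no interior samples of {self.n_samples}"
            )
        return self.data[:, m : self.n_samples - m]
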