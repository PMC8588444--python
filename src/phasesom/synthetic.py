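"""Synthetic two-group EEG cohorts with planted per-band phase coupling.

Generative model: each coupling entry (band, channel pair, weight w) owns a
shared narrowband source s(t) — band-pass-filtered unit-variance white
noise.  Both channels of the pair receive ``w * s(t)``; every channel also
receives independent broadband Gaussian noise.  Because the two channels
share the same narrowband waveform, their band-limited instantaneous phases
co-vary, and the resulting circular correlation grows monotonically with w.
A "control" and a "case" coupling table that differ on some edges define
the planted ground truth that the downstream pipeline must recover.

This emulates a two-group study design (e.g. control vs dyslexic readers
under amplitude-modulated noise stimulation) closely enough to exercise the
full connectivity + anomaly-detection pipeline with known answers; it makes
no attempt at biophysical realism (no volume conduction, no artefacts, no
1/f spectra).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import design_fir_ls, _filtfilt
from .recording import DEFAULT_BANDS, BandSpec, Recording

#: Default broadband noise s.d. relative to unit-variance sources; calibrated
#: once so a planted weight of 0.8 yields a band circular correlation in the
#: 0.5-0.8 range at the default sampling rate (see docs/methods.md).
DEFAULT_NOISE_SD = 0.8

Pair = tuple[int, int]


@dataclass(frozen=True)
class CouplingEntry:
    """One planted edge: a band name, an unordered channel pair, a weight."""

    band: str
    pair: Pair
    weight: float


@dataclass
class CohortSpec:
    n_control: int
    n_case: int
    n_channels: int = 31          # 32-electrode montage minus the Cz reference
    fs: float = 500.0
    duration: float = 60.0
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    coupling_control: tuple[CouplingEntry, ...] = ()
    coupling_case: tuple[CouplingEntry, ...] = ()
    noise_sd: float = DEFAULT_NOISE_SD
    am_freq: float | None = None  # optional 100% amplitude modulation of sources
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control <= 0 or self.n_case <= 0:
            raise ValueError("both group sizes must be positive")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        max_edge = max(b.f_hi for b in self.bands)
        if self.fs <= 2 * max_edge:
            raise ValueError(
                f"fs={self.fs} cannot represent bands up to {max_edge} Hz"
            )
        band_names = {b.name for b in self.bands}
        self.coupling_control = tuple(
            self._check(e, band_names) for e in self.coupling_control
        )
        self.coupling_case = tuple(
            self._check(e, band_names) for e in self.coupling_case
        )

    def _check(self, e: CouplingEntry, band_names: set[str]) -> CouplingEntry:
        if not isinstance(e, CouplingEntry):
            e = CouplingEntry(*e)
        if e.band not in band_names:
            raise ValueError(f"coupling refers to unknown band {e.band!r}")
        i, j = e.pair
        if i == j or not (0 <= i < self.n_channels and 0 <= j < self.n_channels):
            raise ValueError(f"invalid channel pair {e.pair}")
        if not (0.0 <= e.weight <= 1.0):
            raise ValueError(f"coupling weight {e.weight} outside [0, 1]")
        if i > j:
            e = CouplingEntry(e.band, (j, i), e.weight)
        return e

    def band(self, name: str) -> BandSpec:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)


@dataclass
class GroundTruth:
    """Edges whose coupling weight differs between the two group tables."""

    #: band name -> {pair: (weight_control, weight_case)}
    planted: dict[str, dict[Pair, tuple[float, float]]]

    def planted_edges(self, band: str) -> set[Pair]:
        return set(self.planted.get(band, {}))

    def effect(self, band: str, pair: Pair) -> float:
        wc, wd = self.planted[band][pair]
        return wc - wd


def _coupling_map(entries: tuple[CouplingEntry, ...]) -> dict[tuple[str, Pair], float]:
    out: dict[tuple[str, Pair], float] = {}
    for e in entries:
        key = (e.band, e.pair)
        if key in out:
            raise ValueError(f"duplicate coupling entry for {key}")
        out[key] = e.weight
    return out


def ground_truth(spec: CohortSpec) -> GroundTruth:
    ctrl = _coupling_map(spec.coupling_control)
    case = _coupling_map(spec.coupling_case)
    planted: dict[str, dict[Pair, tuple[float, float]]] = {}
    for band, pair in set(ctrl) | set(case):
        wc = ctrl.get((band, pair), 0.0)
        wd = case.get((band, pair), 0.0)
        if wc != wd:
            planted.setdefault(band, {})[pair] = (wc, wd)
    return GroundTruth(planted=planted)


def generate_band_source(
    band: BandSpec,
    fs: float,
    duration: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Zero-mean unit-variance narrowband noise concentrated in the band."""
    band.validate_fs(fs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    # sharper transition than the analysis filters: sources should carry
    # essentially all of their power strictly inside the nominal band
    fspec = design_fir_ls(band, fs, transition_width=0.1 * band.f_lo)
    if n <= 3 * fspec.n_taps:
        raise ValueError(
            f"duration {duration} s too short for the {band.name} filter "
            f"({fspec.n_taps} taps at fs={fs})"
        )
    x = rng.standard_normal(n)
    s = _filtfilt(x, fspec.coefficients)
    s = s - s.mean()
    return s / s.std()


def _modulate(s: np.ndarray, fs: float, f_am: float) -> np.ndarray:
    t = np.arange(len(s)) / fs
    m = s * (1.0 + np.cos(2 * np.pi * f_am * t))
    m = m - m.mean()
    return m / m.std()


def generate_recording(spec: CohortSpec, subject_index: int, group: str) -> Recording:
    """One subject's multichannel recording under its group's coupling table.

    Per-subject randomness is seeded from (master seed, subject index), so a
    cohort is reproducible while subjects stay independent.
    """
    if group == "control":
        entries = spec.coupling_control
    elif group == "case":
        entries = spec.coupling_case
    else:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng([spec.seed, subject_index])
    n = int(round(spec.duration * spec.fs))
    data = np.zeros((spec.n_channels, n))
    # deterministic entry order: the spec order of the group's table
    for e in entries:
        s = generate_band_source(spec.band(e.band), spec.fs, spec.duration, rng)
        if spec.am_freq is not None:
            s = _modulate(s, spec.fs, spec.am_freq)
        i, j = e.pair
        data[i] += e.weight * s
        data[j] += e.weight * s
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(data.shape)
    labels = [f"ch{i:02d}" for i in range(spec.n_channels)]
    return Recording(
        data=data,
        fs=spec.fs,
        channel_labels=labels,
        subject_id=f"sub-{subject_index:03d}",
        group=group,
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[Recording], GroundTruth]:
    """All control then all case recordings, plus the planted ground truth."""
    recs = [
        generate_recording(spec, idx, "control") for idx in range(spec.n_control)
    ]
    recs += [
        generate_recording(spec, spec.n_control + k, "case")
        for k in range(spec.n_case)
    ]
    return recs, ground_truth(spec)
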