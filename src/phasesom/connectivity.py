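"""Phase-synchrony connectivity: analytic signal, PLV, circular correlation.

The instantaneous phase of each band-limited channel is taken from the
analytic signal z(t) = x(t) + j*H{x(t)} (Hilbert transform).  Two synchrony
measures are provided:

* **PLV** — the magnitude of the time-averaged unit phasor of the phase
  difference, ``|mean(exp(j(phi_x - phi_y)))|``; 1 means perfectly locked.
* **Circular correlation** — the circular analogue of Pearson's r,
  ``sum(sin(phi_x - mx) sin(phi_y - my)) / sqrt(sum(sin^2) * sum(sin^2))``
  with ``mx, my`` the circular means.  Unlike PLV it measures co-variation
  of phase *deviations*, so a constant phase offset (e.g. volume conduction
  with fixed lag) does not masquerade as dynamic coupling.

Connectivity matrices store ``|r|`` so entries lie in [0, 1]; the raw signed
matrix is retained alongside because the sign carries information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .recording import BandSpec, Recording


class UndefinedCircularStatistic(ValueError):
    """Raised when a circular mean/correlation has a vanishing denominator."""


# ---------------------------------------------------------------------------
# analytic signal and instantaneous phase

@dataclass
class AnalyticSeries:
    """Complex analytic signal per channel, with amplitude/phase accessors."""

    z: np.ndarray  # complex, (..., n_samples)
    fs: float

    @property
    def amplitude(self) -> np.ndarray:
        """Instantaneous amplitude a(t) = |z(t)|."""
        return np.abs(self.z)

    def phase(self, unwrap: bool = False) -> np.ndarray:
        return instantaneous_phase(self, unwrap=unwrap)


def analytic_signal(series: np.ndarray, fs: float = 1.0) -> AnalyticSeries:
    """Hilbert-transform a real series into its analytic signal.

    Works on a 1-D series or a (channels, samples) matrix (last axis = time).
    """
    x = np.asarray(series, dtype=float)
    if x.shape[-1] < 8:
        raise ValueError("series too short for a meaningful analytic signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input series")
    return AnalyticSeries(z=hilbert(x, axis=-1), fs=fs)


def instantaneous_phase(a: AnalyticSeries, unwrap: bool = False) -> np.ndarray:
    """Four-quadrant instantaneous phase of an analytic signal.

    Zero-magnitude samples have no defined phase; they are reported as NaN
    with a warning (``np.angle`` would silently return 0).
    """
    z = a.z
    phi = np.angle(z)
    zero = np.abs(z) == 0.0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero-magnitude samples: phase undefined, set to NaN",
            stacklevel=2,
        )
        phi = np.where(zero, np.nan, phi)
    if unwrap:
        phi = np.unwrap(phi, axis=-1)
    return phi


# ---------------------------------------------------------------------------
# scalar circular statistics

def plv(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Phase locking value |mean exp(j(phi_x - phi_y))| in [0, 1]."""
    phase_x = np.asarray(phase_x, float)
    phase_y = np.asarray(phase_y, float)
    if phase_x.shape != phase_y.shape:
        raise ValueError("phase series must have equal length")
    if phase_x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(np.exp(1j * (phase_x - phase_y)))))


def circular_mean(phase: np.ndarray) -> float:
    """Angle of the resultant vector, in (-pi, pi].

    Raises :class:`UndefinedCircularStatistic` when the resultant length is
    (numerically) zero, e.g. for an antipodal pair {0, pi}.
    """
    phase = np.asarray(phase, float)
    if phase.size < 1:
        raise ValueError("need at least 1 sample")
    s, c = np.sum(np.sin(phase)), np.sum(np.cos(phase))
    if np.hypot(s, c) < 1e-12 * phase.size:
        raise UndefinedCircularStatistic(
            "circular mean undefined: resultant vector has zero length"
        )
    return float(np.arctan2(s, c))


def circular_correlation(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """Circular correlation coefficient of two phase series, raw in [-1, 1].

    Deviations are measured as ``sin(phi - circular_mean)``; a channel whose
    phase is constant has zero circular variance and no defined correlation.
    """
    phase_x = np.asarray(phase_x, float)
    phase_y = np.asarray(phase_y, float)
    if phase_x.shape != phase_y.shape:
        raise ValueError("phase series must have equal length")
    if phase_x.size < 3:
        raise ValueError("need at least 3 samples")
    sx = np.sin(phase_x - circular_mean(phase_x))
    sy = np.sin(phase_y - circular_mean(phase_y))
    denom = np.sqrt(np.sum(sx**2) * np.sum(sy**2))
    if denom < 1e-12:
        raise UndefinedCircularStatistic(
            "circular correlation undefined: a channel has zero circular variance"
        )
    return float(np.sum(sx * sy) / denom)


# ---------------------------------------------------------------------------
# connectivity matrices

@dataclass
class ConnectivityMatrix:
    values: np.ndarray          # C x C, symmetric, diag 1; circ_corr stored as |r|
    method: str                 # 'plv' or 'circ_corr'
    channel_labels: list[str]
    band: BandSpec | None = None
    signed_values: np.ndarray | None = None  # raw signed r (circ_corr only)
    n_samples: int = 0

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def _phases_for(rec: Recording) -> np.ndarray:
    """Wrapped instantaneous phases over interior (margin-trimmed) samples."""
    a = analytic_signal(rec.data, fs=rec.fs)
    phi = instantaneous_phase(a)
    m = rec.edge_margin
    if m:
        if 2 * m >= phi.shape[-1]:
            raise ValueError("edge margins leave no interior samples")
        phi = phi[..., m : phi.shape[-1] - m]
    return phi


def connectivity_matrix(band_rec: Recording, method: str = "circ_corr") -> ConnectivityMatrix:
    """All-pairs phase-synchrony matrix of a band-limited recording.

    Pairs whose circular correlation is undefined (a constant-phase channel)
    are flagged NaN with a warning rather than aborting the whole matrix.
    """
    if band_rec.n_channels < 2:
        raise ValueError("need at least 2 channels")
    if method not in ("plv", "circ_corr"):
        raise ValueError(f"unknown method {method!r}")
    phi = _phases_for(band_rec)
    C, n = phi.shape

    if method == "plv":
        e = np.exp(1j * phi)
        m = (e @ e.conj().T) / n
        vals = np.abs(m)
        np.fill_diagonal(vals, 1.0)
        signed = None
    else:
        sins = np.empty_like(phi)
        ok = np.ones(C, dtype=bool)
        for i in range(C):
            try:
                sins[i] = np.sin(phi[i] - circular_mean(phi[i]))
            except UndefinedCircularStatistic:
                ok[i] = False
                sins[i] = 0.0
        ss = np.sum(sins**2, axis=1)
        ok &= ss > 1e-12
        if not np.all(ok):
            bad = [band_rec.channel_labels[i] for i in np.nonzero(~ok)[0]]
            warnings.warn(
                f"channels with zero circular variance, entries set NaN: {bad}",
                stacklevel=2,
            )
        num = sins @ sins.T
        denom = np.sqrt(np.outer(ss, ss))
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = num / denom
        raw[~ok, :] = np.nan
        raw[:, ~ok] = np.nan
        np.fill_diagonal(raw, 1.0)
        signed = raw
        vals = np.abs(raw)

    # enforce exact symmetry against round-off
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 1.0)
    return ConnectivityMatrix(
        values=vals,
        method=method,
        channel_labels=list(band_rec.channel_labels),
        signed_values=signed,
        n_samples=n,
    )


def epoch_average_connectivity(
    band_rec: Recording,
    method: str = "circ_corr",
    window_s: float = 5.0,
    overlap_s: float = 0.0,
) -> ConnectivityMatrix:
    """Mean connectivity matrix across consecutive epochs of one recording.

    The filter edge margins are trimmed once, the interior is cut into
    windows, and the per-epoch matrices are averaged entry-wise.  Averaging
    across epochs stabilizes the circular-correlation estimate, whose
    per-epoch value is noisy because the circular mean of a narrowband
    channel's (near-uniform) wrapped phase is itself noisy.
    """
    from .preprocess import segment  # local import: avoids a module cycle

    trimmed = band_rec.copy_with(data=band_rec.interior(), edge_margin=0)
    segs = segment(trimmed, window_s, overlap_s)
    mats = [connectivity_matrix(s, method=method) for s in segs]
    values = np.mean([m.values for m in mats], axis=0)
    signed = None
    if mats[0].signed_values is not None:
        signed = np.mean([m.signed_values for m in mats], axis=0)
    return ConnectivityMatrix(
        values=values,
        method=method,
        channel_labels=list(band_rec.channel_labels),
        signed_values=signed,
        n_samples=sum(m.n_samples for m in mats),
    )


# ---------------------------------------------------------------------------
# feature vectors: fixed-order upper-triangle flattening

@dataclass
class FeatureVector:
    values: np.ndarray          # length C(C-1)/2
    channel_labels: list[str]
    method: str = "circ_corr"

    def __len__(self) -> int:
        return len(self.values)


def triu_pairs(n_channels: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle (i < j) pair ordering used by vectorize."""
    return [(i, j) for i in range(n_channels) for j in range(i + 1, n_channels)]


def vectorize(cm: ConnectivityMatrix, signed: bool = False) -> FeatureVector:
    """Flatten the upper triangle (i<j, row-major) into a feature vector."""
    mat = cm.signed_values if signed else cm.values
    if signed and mat is None:
        raise ValueError("no signed values stored for this matrix")
    iu = np.triu_indices(cm.n_channels, k=1)
    return FeatureVector(
        values=np.asarray(mat)[iu].copy(),
        channel_labels=list(cm.channel_labels),
        method=cm.method,
    )


def devectorize(fv: FeatureVector) -> np.ndarray:
    """Rebuild the symmetric C x C matrix (diagonal 1) from a feature vector."""
    C = len(fv.channel_labels)
    if len(fv.values) != C * (C - 1) // 2:
        raise ValueError("feature length does not match channel count")
    mat = np.eye(C)
    iu = np.triu_indices(C, k=1)
    mat[iu] = fv.values
    mat[(iu[1], iu[0])] = fv.values
    return mat
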