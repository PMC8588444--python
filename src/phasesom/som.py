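"""One-class anomaly detection with a self-organizing map (SOM).

The map is a rows x cols lattice of prototype vectors trained only on the
majority ("normal") class by competitive neighborhood updates:

    w_i(t+1) = w_i(t) + alpha(t) * h_i(t) * (x - w_i(t))

with an exponentially decaying learning rate alpha(t) and a Gaussian
neighborhood h_i(t) of shrinking width around the best matching unit (BMU).
Prototypes are linearly initialized on the plane of the first two principal
components of the training data.

Because the prototypes quantize only the normal class, a sample from a
different population lands far from every prototype: its quantization error
(QE, the distance to its BMU) is the anomaly score.  A two-Gaussian Bayes
model on QE then yields a decision threshold, and the symmetrized
Kullback-Leibler divergence between the two classes' QE histograms ranks
frequency bands by separability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .connectivity import FeatureVector


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        X = features
    else:
        X = np.asarray(
            [f.values if isinstance(f, FeatureVector) else f for f in features]
        )
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must form an (n_samples, n_features) matrix")
    return X


@dataclass(frozen=True)
class SOMSchedule:
    """Training schedule: initial rates, iteration count, exponential decay.

    ``n_iter=None`` resolves to ``n_iter_per_sample * n_samples`` at training
    time.  The learning rate decays from ``alpha0`` to ``alpha_end``; the
    Gaussian neighborhood width decays from ``sigma0`` (default half the
    larger grid side) to ``sigma_end``.
    """

    alpha0: float = 0.5
    alpha_end: float = 0.01
    sigma0: float | None = None
    sigma_end: float = 0.5
    n_iter: int | None = None
    n_iter_per_sample: int = 500
    seed: int = 0


@dataclass
class SOMModel:
    grid: tuple[int, int]
    prototypes: np.ndarray  # (rows*cols, dim)
    schedule: SOMSchedule = field(default_factory=SOMSchedule)
    trained: bool = False

    def __post_init__(self) -> None:
        rows, cols = self.grid
        if rows < 1 or cols < 1:
            raise ValueError("grid sides must be >= 1")
        if self.prototypes.shape[0] != rows * cols:
            raise ValueError("prototype count does not match grid size")
        if not np.all(np.isfinite(self.prototypes)):
            raise ValueError("non-finite prototypes")

    @property
    def n_units(self) -> int:
        return self.prototypes.shape[0]

    @property
    def dim(self) -> int:
        return self.prototypes.shape[1]

    def grid_coords(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = self.grid
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return rr.ravel().astype(float), cc.ravel().astype(float)


def init_som_pca(features, grid: tuple[int, int]) -> SOMModel:
    """Linear PCA initialization of the prototype lattice.

    Grid rows span +/-2 standard deviations along the first principal
    component, columns along the second; a 1x1 grid degenerates to the data
    mean, and rank-1 data keeps every prototype on the data's line.
    """
    X = _as_matrix(features)
    n, dim = X.shape
    if n < 2:
        raise ValueError("PCA initialization needs at least 2 samples")
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid sides must be >= 1")
    mean = X.mean(axis=0)
    Xc = X - mean
    # principal axes and their standard deviations
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    sd = s / np.sqrt(max(n - 1, 1))
    axes = np.zeros((2, dim))
    scale = np.zeros(2)
    for k in range(min(2, vt.shape[0])):
        axes[k] = vt[k]
        scale[k] = sd[k]

    def positions(m: int) -> np.ndarray:
        return np.zeros(1) if m == 1 else np.linspace(-1.0, 1.0, m)

    u = positions(rows)
    v = positions(cols)
    proto = (
        mean[None, None, :]
        + 2.0 * scale[0] * u[:, None, None] * axes[0][None, None, :]
        + 2.0 * scale[1] * v[None, :, None] * axes[1][None, None, :]
    )
    return SOMModel(grid=grid, prototypes=proto.reshape(rows * cols, dim))


@njit(cache=True)
def _train_loop(W, X, order, alphas, sigmas, gr, gc):  # pragma: no cover - numba
    d, dim = W.shape
    for t in range(order.size):
        xi = order[t]
        best = 0
        bestd = 1e300
        for i in range(d):
            s = 0.0
            for k in range(dim):
                diff = W[i, k] - X[xi, k]
                s += diff * diff
            if s < bestd:
                bestd = s
                best = i
        a = alphas[t]
        denom = 2.0 * sigmas[t] * sigmas[t]
        for i in range(d):
            dg = (gr[i] - gr[best]) ** 2 + (gc[i] - gc[best]) ** 2
            ah = a * np.exp(-dg / denom)
            if ah > 1e-12:
                for k in range(dim):
                    W[i, k] += ah * (X[xi, k] - W[i, k])


def _decay(v0: float, v_end: float, n_iter: int) -> np.ndarray:
    t = np.arange(n_iter, dtype=float)
    lam = n_iter / np.log(max(v0 / v_end, 1.0 + 1e-9))
    return v0 * np.exp(-t / lam)


def train_som(model: SOMModel, features, schedule: SOMSchedule | None = None) -> SOMModel:
    """Train by seeded online updates; returns a new model, input untouched."""
    X = _as_matrix(features)
    if X.shape[1] != model.dim:
        raise ValueError(
            f"feature dimension {X.shape[1]} != prototype dimension {model.dim}"
        )
    sch = schedule if schedule is not None else model.schedule
    n_iter = sch.n_iter if sch.n_iter is not None else sch.n_iter_per_sample * X.shape[0]
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rows, cols = model.grid
    sigma0 = sch.sigma0 if sch.sigma0 is not None else max(rows, cols) / 2.0
    sigma0 = max(sigma0, sch.sigma_end)
    rng = np.random.default_rng(sch.seed)
    order = rng.integers(0, X.shape[0], size=n_iter)
    alphas = _decay(sch.alpha0, sch.alpha_end, n_iter)
    sigmas = _decay(sigma0, sch.sigma_end, n_iter)
    W = model.prototypes.copy()
    gr, gc = model.grid_coords()
    _train_loop(W, np.ascontiguousarray(X), order, alphas, sigmas, gr, gc)
    return replace(model, prototypes=W, schedule=sch, trained=True)


def save_model(model: SOMModel, path) -> None:
    """Serialize a model as ``<path>.json`` (metadata) + ``<path>.npy`` (prototypes)."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    meta = {
        "grid": list(model.grid),
        "trained": model.trained,
        "schedule": asdict(model.schedule),
        "dim": model.dim,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    np.save(path.with_suffix(".npy"), model.prototypes)


def load_model(path) -> SOMModel:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    prototypes = np.load(path.with_suffix(".npy"))
    return SOMModel(
        grid=tuple(meta["grid"]),
        prototypes=prototypes,
        schedule=SOMSchedule(**meta["schedule"]),
        trained=meta["trained"],
    )


# ---------------------------------------------------------------------------
# BMU and quantization error

def bmu(model: SOMModel, sample: np.ndarray) -> tuple[int, float]:
    """Best matching unit: (lowest-index) nearest prototype and its distance."""
    x = np.asarray(sample, dtype=float)
    if x.shape != (model.dim,):
        raise ValueError(f"sample of dimension {x.shape} vs model {model.dim}")
    d = np.linalg.norm(model.prototypes - x, axis=1)
    i = int(np.argmin(d))  # argmin returns the first (lowest) index on ties
    return i, float(d[i])


def bmus(model: SOMModel, samples) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized BMU indices and distances for a sample matrix."""
    X = _as_matrix(samples)
    if X.shape[1] != model.dim:
        raise ValueError("dimension mismatch")
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        - 2 * X @ model.prototypes.T
        + np.sum(model.prototypes**2, axis=1)[None, :]
    )
    idx = np.argmin(d2, axis=1)
    dist = np.sqrt(np.maximum(d2[np.arange(len(X)), idx], 0.0))
    return idx, dist


@dataclass
class QESet:
    """Per-sample quantization errors with their metadata."""

    qe: np.ndarray                 # (n,) >= 0
    bmu_index: np.ndarray          # (n,) int
    groups: np.ndarray             # (n,) str labels ('control'/'case'/...)
    subject_ids: np.ndarray
    band: str = ""
    n_units: int = 0

    def __post_init__(self) -> None:
        if len(self.qe) == 0:
            raise ValueError("empty QE set")
        if np.any(self.qe < 0):
            raise ValueError("negative quantization error")

    def for_group(self, group: str) -> np.ndarray:
        return self.qe[self.groups == group]

    def receptive_field_means(self) -> np.ndarray:
        """Mean QE per unit over its receptive field; NaN for empty units."""
        out = np.full(self.n_units, np.nan)
        for i in range(self.n_units):
            mask = self.bmu_index == i
            if mask.any():
                out[i] = self.qe[mask].mean()
        return out


def quantization_errors(
    model: SOMModel,
    samples,
    groups=None,
    subject_ids=None,
    band: str = "",
) -> QESet:
    """Distance of every sample to its BMU (the anomaly score)."""
    X = _as_matrix(samples)
    if X.shape[0] == 0:
        raise ValueError("empty sample set")
    idx, dist = bmus(model, X)
    n = X.shape[0]
    groups = np.asarray(["unknown"] * n if groups is None else groups)
    subject_ids = np.asarray(
        [f"s{i}" for i in range(n)] if subject_ids is None else subject_ids
    )
    return QESet(
        qe=dist, bmu_index=idx, groups=groups, subject_ids=subject_ids,
        band=band, n_units=model.n_units,
    )


def activation_map(model: SOMModel, samples) -> np.ndarray:
    """rows x cols grid of mean QE per unit; units with no samples are NaN."""
    qs = quantization_errors(model, samples)
    return qs.receptive_field_means().reshape(model.grid)


# ---------------------------------------------------------------------------
# band relevance: symmetrized KL divergence of QE histograms

def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """D_KL(P||Q) = sum p log(p/q) in nats, for probability vectors."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("distributions must share support")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("negative probabilities")
    p = p / p.sum()
    q = q / q.sum()
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ValueError("D_KL undefined: q has zero mass where p does not")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def symmetrized_kl(p: np.ndarray, q: np.ndarray) -> float:
    """Two-way KL, 0.5 * (D(P||Q) + D(Q||P))."""
    return 0.5 * (kl_divergence(p, q) + kl_divergence(q, p))


def band_relevance(
    qe_control,
    qe_case,
    bins: int | None = None,
    smoothing: float = 1e-9,
) -> float:
    """Separability of two QE samples as symmetrized KL of shared histograms.

    Histograms use equal-width bins spanning the pooled range; the bin count
    defaults to the Freedman-Diaconis rule on the pooled sample.  A tiny
    additive smoothing keeps the divergence finite on empty bins.
    """
    a = qe_control.qe if isinstance(qe_control, QESet) else np.asarray(qe_control, float)
    b = qe_case.qe if isinstance(qe_case, QESet) else np.asarray(qe_case, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both QE sets must be non-empty")
    pooled = np.concatenate([a, b])
    if bins is None:
        edges = np.histogram_bin_edges(pooled, bins="fd")
        bins = max(len(edges) - 1, 2)
    if bins < 2:
        raise ValueError("need at least 2 histogram bins")
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        raise ValueError("degenerate QE distributions: all values identical")
    edges = np.linspace(lo, hi, bins + 1)
    p, _ = np.histogram(a, bins=edges)
    q, _ = np.histogram(b, bins=edges)
    p = p.astype(float) + smoothing
    q = q.astype(float) + smoothing
    return symmetrized_kl(p / p.sum(), q / q.sum())


# ---------------------------------------------------------------------------
# Bayes threshold on QE

@dataclass
class ThresholdModel:
    """Two-Gaussian Bayes model of QE: normal class CN vs anomaly class DD."""

    mean_cn: float
    sd_cn: float
    mean_dd: float
    sd_dd: float
    prior_cn: float
    prior_dd: float
    tau: float  # decision threshold on qe; DD iff qe > tau

    def _log_joint(self, qe: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        qe = np.asarray(qe, float)
        lc = (
            -0.5 * ((qe - self.mean_cn) / self.sd_cn) ** 2
            - np.log(self.sd_cn)
            + np.log(self.prior_cn)
        )
        ld = (
            -0.5 * ((qe - self.mean_dd) / self.sd_dd) ** 2
            - np.log(self.sd_dd)
            + np.log(self.prior_dd)
        )
        return lc, ld

    def posterior_dd(self, qe) -> np.ndarray | float:
        """P(DD | qe) under the two-class mixture marginal."""
        lc, ld = self._log_joint(qe)
        m = np.maximum(lc, ld)
        post = np.exp(ld - m) / (np.exp(lc - m) + np.exp(ld - m))
        return post if np.ndim(qe) else float(post)


def fit_threshold(qe: np.ndarray, labels: np.ndarray) -> ThresholdModel:
    """Fit class-conditional Gaussians on QE and the posterior-crossing threshold.

    ``labels``: 0 for the normal class (CN), 1 for the anomaly class (DD).
    Priors come from training frequencies; the threshold tau is the QE at
    which the two posteriors cross between the class means.
    """
    qe = np.asarray(qe, float)
    labels = np.asarray(labels, int)
    if qe.shape != labels.shape:
        raise ValueError("qe and labels must align")
    x0, x1 = qe[labels == 0], qe[labels == 1]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("need >= 2 samples per class")
    sd0, sd1 = x0.std(ddof=1), x1.std(ddof=1)
    if sd0 <= 0 or sd1 <= 0:
        raise ValueError(
            "a class has zero QE variance; add data or jitter before fitting"
        )
    n = len(qe)
    tm = ThresholdModel(
        mean_cn=float(x0.mean()), sd_cn=float(sd0),
        mean_dd=float(x1.mean()), sd_dd=float(sd1),
        prior_cn=len(x0) / n, prior_dd=len(x1) / n,
        tau=np.nan,
    )
    tm.tau = _posterior_crossing(tm)
    return tm


def _posterior_crossing(tm: ThresholdModel) -> float:
    """QE where the two class posteriors are equal, sought between the means."""
    lo, hi = sorted((tm.mean_cn, tm.mean_dd))

    def g(x: float) -> float:
        lc, ld = tm._log_joint(np.asarray(x))
        return float(lc - ld)

    if lo == hi:
        return lo
    from scipy.optimize import brentq

    if g(lo) * g(hi) < 0:
        return float(brentq(g, lo, hi, xtol=1e-12 * max(1.0, hi - lo)))
    # No sign change between the means (extreme priors or variances):
    # fall back to the quadratic roots of the log-posterior equality and
    # take the root nearest the midpoint.
    a = 0.5 * (1 / tm.sd_cn**2 - 1 / tm.sd_dd**2)
    b = tm.mean_dd / tm.sd_dd**2 - tm.mean_cn / tm.sd_cn**2
    c = (
        0.5 * (tm.mean_cn**2 / tm.sd_cn**2 - tm.mean_dd**2 / tm.sd_dd**2)
        + np.log(tm.sd_dd / tm.sd_cn)
        + np.log(tm.prior_cn / tm.prior_dd)
    )
    if abs(a) < 1e-300:
        return -c / b
    disc = b * b - 4 * a * c
    if disc < 0:
        return (lo + hi) / 2  # posteriors never cross; midpoint as best effort
    roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    return float(roots[np.argmin(np.abs(roots - (lo + hi) / 2))])


def classify(tm: ThresholdModel, qe: float) -> tuple[str, float]:
    """Label a QE value: 'case' iff qe > tau (ties -> 'control'), plus P(DD|qe)."""
    if not np.isfinite(qe):
        raise ValueError("non-finite quantization error")
    label = "case" if qe > tm.tau else "control"
    return label, float(tm.posterior_dd(qe))
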