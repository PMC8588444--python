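"""Pipeline evaluation: stratified CV, ROC/AUC, permutation and edge tests.

Cross-validation is stratified at the *subject* level so that, when a
subject contributes several epochs, all of them share a fold and no subject
leaks between train and test.  Within each fold the SOM is trained on the
control training samples only, quantization errors of all training samples
fit the Bayes threshold, and held-out samples are scored.

Group differences per connection are assessed with two-sided Mann-Whitney
tests across all C(C-1)/2 edges, Benjamini-Hochberg corrected.  Classifier
significance uses a label-permutation null: the full CV is re-run on each
permutation and the empirical p-value is the fraction of null accuracies
exceeding the observed one (a smoothed (b+1)/(B+1) variant is reported
alongside, since the raw count can be exactly zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix, triu_pairs, vectorize
from .som import (
    SOMSchedule,
    fit_threshold,
    init_som_pca,
    quantization_errors,
    train_som,
)


@dataclass(frozen=True)
class SOMConfig:
    """SOM hyperparameters used inside cross-validation folds."""

    grid: tuple[int, int] = (8, 8)
    schedule: SOMSchedule = field(default_factory=SOMSchedule)


# ---------------------------------------------------------------------------
# folds

def stratified_subject_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Assign each subject to one of k folds, preserving class proportions.

    Returns an integer fold index per subject.  Every class must have at
    least k members.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes to stratify")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} subjects; cannot make {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(len(labels), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold[test_idx] = f
    return fold


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[pd.DataFrame, float]:
    """ROC points and rank-based AUC (Mann-Whitney formulation, tie-aware)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("need both classes to compute ROC/AUC")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1)
    fpr, tpr, thr = roc_curve(labels, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return curve, float(auc)


# ---------------------------------------------------------------------------
# cross-validated SOM-QE classification

@dataclass
class CVResult:
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: np.ndarray
    band: str = ""
    stimulus: str = ""

    @property
    def k(self) -> int:
        return len(self.accuracy)

    def mean(self, metric: str) -> float:
        return float(np.mean(getattr(self, metric)))

    def sd(self, metric: str) -> float:
        return float(np.std(getattr(self, metric), ddof=1))

    def summary(self) -> pd.DataFrame:
        rows = []
        for m in ("accuracy", "sensitivity", "specificity", "auc"):
            rows.append({"metric": m, "mean": self.mean(m), "sd": self.sd(m)})
        return pd.DataFrame(rows)


def _fold_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc = (tp + tn) / len(y_true)
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return acc, sens, spec


def run_cv(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    som: SOMConfig | None = None,
    subject_ids: np.ndarray | None = None,
    band: str = "",
) -> CVResult:
    """Stratified k-fold CV of the SOM-QE anomaly classifier.

    ``labels``: 0 = control, 1 = case.  Per fold the SOM sees only control
    training samples; the Bayes threshold is fitted on the training QE of
    both classes; test samples are scored by the posterior of the anomaly
    class.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels, int)
    if subject_ids is None:
        subject_ids = np.arange(len(y))
    subject_ids = np.asarray(subject_ids)
    som = som or SOMConfig()

    subjects, first_idx = np.unique(subject_ids, return_index=True)
    subj_labels = y[first_idx]
    for s in subjects:  # a subject must not carry both labels
        if len(np.unique(y[subject_ids == s])) != 1:
            raise ValueError(f"subject {s} has inconsistent labels")
    fold_of_subject = stratified_subject_folds(subj_labels, k, seed)
    fold_by_subject = dict(zip(subjects, fold_of_subject))
    sample_fold = np.array([fold_by_subject[s] for s in subject_ids])

    accs, senss, specs, aucs = [], [], [], []
    for f in range(k):
        test = sample_fold == f
        train = ~test
        ctrl_train = X[train & (y == 0)]
        if len(ctrl_train) < 2:
            raise ValueError(f"fold {f} has fewer than 2 control training samples")
        sch = som.schedule
        sch = SOMSchedule(
            alpha0=sch.alpha0, alpha_end=sch.alpha_end, sigma0=sch.sigma0,
            sigma_end=sch.sigma_end, n_iter=sch.n_iter,
            n_iter_per_sample=sch.n_iter_per_sample, seed=sch.seed + f,
        )
        model = train_som(init_som_pca(ctrl_train, som.grid), ctrl_train, sch)
        qe_train = quantization_errors(model, X[train]).qe
        tm = fit_threshold(qe_train, y[train])
        qe_test = quantization_errors(model, X[test]).qe
        y_pred = (qe_test > tm.tau).astype(int)  # ties count as control
        # rank by the posterior log-odds of the anomaly class: monotone in the
        # posterior but free of its floating-point saturation at 1.0
        lc, ld = tm._log_joint(qe_test)
        scores = ld - lc
        acc, sens, spec = _fold_metrics(y[test], y_pred)
        _, auc = roc_auc(scores, y[test])
        accs.append(acc)
        senss.append(sens)
        specs.append(spec)
        aucs.append(auc)
    return CVResult(
        accuracy=np.array(accs), sensitivity=np.array(senss),
        specificity=np.array(specs), auc=np.array(aucs), band=band,
    )


# ---------------------------------------------------------------------------
# permutation test

@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float           # (# null > observed) / B, as printed in the field
    p_value_smoothed: float  # (b + 1) / (B + 1)

    @property
    def B(self) -> int:
        return len(self.null_accuracies)


def permutation_test(
    features: np.ndarray,
    labels: np.ndarray,
    B: int = 1000,
    k: int = 5,
    seed: int = 0,
    som: SOMConfig | None = None,
    subject_ids: np.ndarray | None = None,
) -> PermutationResult:
    """Label-permutation null for the CV accuracy of the SOM-QE classifier.

    Labels are permuted at the subject level; the full stratified CV is
    re-run for each of the B permutations.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(labels, int)
    if subject_ids is None:
        subject_ids = np.arange(len(y))
    subject_ids = np.asarray(subject_ids)
    subjects, first_idx = np.unique(subject_ids, return_index=True)
    subj_labels = y[first_idx]

    observed = run_cv(features, y, k=k, seed=seed, som=som,
                      subject_ids=subject_ids).mean("accuracy")
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        perm = rng.permutation(subj_labels)
        y_perm = np.array([perm[np.searchsorted(subjects, s)] for s in subject_ids])
        null[b] = run_cv(features, y_perm, k=k, seed=seed + b + 1, som=som,
                         subject_ids=subject_ids).mean("accuracy")
    b_count = int(np.sum(null > observed))
    return PermutationResult(
        observed_accuracy=observed,
        null_accuracies=null,
        p_value=b_count / B,
        p_value_smoothed=(b_count + 1) / (B + 1),
    )


# ---------------------------------------------------------------------------
# per-edge group tests with FDR control

@dataclass
class EdgeTestResult:
    table: pd.DataFrame  # columns: i, j, U, p, p_adj, significant, display
    channel_labels: list[str]
    alpha: float
    display_alpha: float

    def significant_edges(self) -> set[tuple[int, int]]:
        sig = self.table[self.table["significant"]]
        return set(zip(sig["i"], sig["j"]))


def _edge_features(mats) -> tuple[np.ndarray, list[str]]:
    if isinstance(mats, np.ndarray):
        if mats.ndim == 2:  # (n_subjects, n_edges)
            return mats, []
        iu = np.triu_indices(mats.shape[1], k=1)
        return mats[:, iu[0], iu[1]], []
    if len(mats) and isinstance(mats[0], ConnectivityMatrix):
        feats = np.asarray([vectorize(m).values for m in mats])
        return feats, list(mats[0].channel_labels)
    return np.asarray(mats, float), []


def edge_tests(
    matrices_control,
    matrices_case,
    alpha: float = 0.05,
    display_alpha: float = 0.01,
) -> EdgeTestResult:
    """Two-sided Mann-Whitney per edge, Benjamini-Hochberg across edges.

    Uses the exact null distribution when both groups have <= 8 subjects,
    otherwise the normal approximation with tie and continuity correction.
    The ``display`` flag marks edges below the (stricter) display threshold
    on the adjusted p-values.
    """
    Xc, labels_c = _edge_features(matrices_control)
    Xd, labels_d = _edge_features(matrices_case)
    if Xc.shape[0] < 3 or Xd.shape[0] < 3:
        raise ValueError("need at least 3 subjects per group")
    if Xc.shape[1] != Xd.shape[1]:
        raise ValueError("edge sets differ between groups")
    n_edges = Xc.shape[1]
    method = "exact" if max(Xc.shape[0], Xd.shape[0]) <= 8 else "asymptotic"
    U = np.empty(n_edges)
    p = np.empty(n_edges)
    for e in range(n_edges):
        res = stats.mannwhitneyu(
            Xc[:, e], Xd[:, e], alternative="two-sided", method=method
        )
        U[e], p[e] = res.statistic, res.pvalue
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    ch_labels = labels_c or labels_d
    C = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    pairs = triu_pairs(C) if C * (C - 1) // 2 == n_edges else [(0, e) for e in range(n_edges)]
    table = pd.DataFrame(
        {
            "i": [a for a, _ in pairs],
            "j": [b for _, b in pairs],
            "U": U,
            "p": p,
            "p_adj": p_adj,
            "significant": reject,
            "display": p_adj < display_alpha,
        }
    )
    return EdgeTestResult(
        table=table, channel_labels=ch_labels, alpha=alpha, display_alpha=display_alpha
    )
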