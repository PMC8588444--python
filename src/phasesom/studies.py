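"""Reference study configurations on synthetic cohorts.

These helpers wire the full pipeline — cohort generation, band
decomposition, phase connectivity, edge testing and SOM-QE classification —
into the study designs used throughout the documentation, the test suite
and the results-reproduction script:

* a *planted-deficit* study: a control group with strong Beta-band coupling
  on a handful of edges and a case group in which that coupling is reduced,
  mimicking a hyposynchronization deficit;
* a *null* study with no group difference, for calibration checks.

Problem sizes default to a desk-scale design (tens of subjects, one minute
per recording) chosen to keep a full multi-seed run in the minutes range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import (
    ConnectivityMatrix,
    connectivity_matrix,
    epoch_average_connectivity,
    triu_pairs,
    vectorize,
)
from .evaluation import CVResult, EdgeTestResult, SOMConfig, edge_tests, run_cv
from .preprocess import band_decompose
from .recording import band_by_name
from .som import SOMSchedule, init_som_pca, quantization_errors, train_som
from .synthetic import CohortSpec, CouplingEntry, GroundTruth, generate_cohort

BETA = band_by_name("Beta")


def planted_pairs(n_edges: int = 8) -> list[tuple[int, int]]:
    """Disjoint channel pairs (0,1), (2,3), ... used as planted edges."""
    return [(2 * k, 2 * k + 1) for k in range(n_edges)]


def planted_beta_spec(
    seed: int,
    n_control: int = 20,
    n_case: int = 10,
    n_channels: int = 16,
    fs: float = 250.0,
    duration: float = 60.0,
    w_control: float = 0.8,
    w_case: float = 0.3,
    n_edges: int = 8,
) -> CohortSpec:
    """Two-group cohort with a Beta-band coupling deficit on planted edges."""
    pairs = planted_pairs(n_edges)
    if max(j for _, j in pairs) >= n_channels:
        raise ValueError("not enough channels for the requested planted edges")
    return CohortSpec(
        n_control=n_control,
        n_case=n_case,
        n_channels=n_channels,
        fs=fs,
        duration=duration,
        coupling_control=tuple(CouplingEntry("Beta", p, w_control) for p in pairs),
        coupling_case=tuple(CouplingEntry("Beta", p, w_case) for p in pairs),
        seed=seed,
    )


def null_spec(
    seed: int,
    n_control: int = 10,
    n_case: int = 10,
    n_channels: int = 16,
    fs: float = 250.0,
    duration: float = 20.0,
) -> CohortSpec:
    """Cohort with no coupling anywhere: both groups are pure noise."""
    return CohortSpec(
        n_control=n_control, n_case=n_case, n_channels=n_channels,
        fs=fs, duration=duration, seed=seed,
    )


@dataclass
class BandStudy:
    """Per-subject Beta-band connectivity of one generated cohort."""

    matrices: list[ConnectivityMatrix]
    features: np.ndarray   # (n_subjects, n_edges)
    labels: np.ndarray     # 0 control, 1 case
    truth: GroundTruth
    spec: CohortSpec
    band: str = "Beta"

    @property
    def control_matrices(self) -> list[ConnectivityMatrix]:
        return [m for m, y in zip(self.matrices, self.labels) if y == 0]

    @property
    def case_matrices(self) -> list[ConnectivityMatrix]:
        return [m for m, y in zip(self.matrices, self.labels) if y == 1]


def band_connectivity_study(
    spec: CohortSpec,
    band_name: str = "Beta",
    method: str = "circ_corr",
    window_s: float | None = 5.0,
) -> BandStudy:
    """Generate a cohort and compute its per-subject band connectivity.

    By default each subject's matrix is the mean over consecutive 5 s
    epochs, which stabilizes the circular-correlation estimate; pass
    ``window_s=None`` for a single full-recording matrix.
    """
    band = band_by_name(band_name)
    recs, truth = generate_cohort(spec)
    matrices, feats, labels = [], [], []
    for rec in recs:
        band_rec = band_decompose(rec, [band])[band.name]
        if window_s is None:
            cm = connectivity_matrix(band_rec, method=method)
        else:
            cm = epoch_average_connectivity(band_rec, method=method, window_s=window_s)
        cm.band = band
        matrices.append(cm)
        feats.append(vectorize(cm).values)
        labels.append(0 if rec.group == "control" else 1)
    return BandStudy(
        matrices=matrices,
        features=np.asarray(feats),
        labels=np.asarray(labels),
        truth=truth,
        spec=spec,
        band=band_name,
    )


def edge_recovery(study: BandStudy, alpha: float = 0.05) -> dict:
    """Planted-edge recovery of the FDR-corrected Mann-Whitney edge tests."""
    res: EdgeTestResult = edge_tests(
        study.control_matrices, study.case_matrices, alpha=alpha
    )
    found = res.significant_edges()
    planted = study.truth.planted_edges(study.band)
    recovered = found & planted
    return {
        "result": res,
        "recovered_fraction": len(recovered) / len(planted) if planted else np.nan,
        "n_false": len(found - planted),
    }


def default_som_config(seed: int = 0) -> SOMConfig:
    """Study-scale SOM: a 3x3 map.

    With ~16 control training subjects per CV fold, a map with more units
    than training samples memorizes them (training QE -> 0), which starves
    the Bayes threshold fitted on training QE; 9 prototypes keep the map a
    genuine quantizer at this sample size.
    """
    return SOMConfig(grid=(3, 3), schedule=SOMSchedule(seed=seed))


def classification_study(
    study: BandStudy, k: int = 5, seed: int = 0, som: SOMConfig | None = None
) -> CVResult:
    """Stratified-CV SOM-QE classification on a cohort's band features."""
    return run_cv(
        study.features, study.labels, k=k, seed=seed,
        som=som or default_som_config(seed), band=study.band,
    )


def qe_group_means(study: BandStudy, som: SOMConfig | None = None) -> dict:
    """Train on all controls, score everyone; mean QE per group."""
    som = som or default_som_config(study.spec.seed)
    ctrl = study.features[study.labels == 0]
    model = train_som(init_som_pca(ctrl, som.grid), ctrl, som.schedule)
    groups = np.where(study.labels == 0, "control", "case")
    qs = quantization_errors(model, study.features, groups=groups, band=study.band)
    return {
        "model": model,
        "qe": qs,
        "mean_qe_control": float(qs.for_group("control").mean()),
        "mean_qe_case": float(qs.for_group("case").mean()),
    }
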