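"""End-to-end pipeline driver: bands -> connectivity -> evaluation artifacts."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .connectivity import connectivity_matrix, vectorize
from .evaluation import SOMConfig, edge_tests, permutation_test, run_cv
from .io import read_matrix, write_connectivity
from .preprocess import band_decompose, segment
from .recording import Recording
from .som import SOMSchedule
from .synthetic import generate_cohort

log = logging.getLogger("phasesom")


def _load_recordings(cfg: PipelineConfig) -> tuple[list[Recording], dict | None]:
    if cfg.simulate is not None:
        spec = cfg.cohort_spec()
        recs, truth = generate_cohort(spec)
        log.info("simulated cohort: %d recordings, master seed %d", len(recs), spec.seed)
        return recs, {
            band: {f"{i}-{j}": list(w) for (i, j), w in per.items()}
            for band, per in truth.planted.items()
        }
    in_dir = Path(cfg.input_dir)
    paths = sorted(in_dir.glob("*.tsv")) + sorted(in_dir.glob("*.txt"))
    if not paths:
        raise FileNotFoundError(f"no recording matrices found under {in_dir}")
    return [read_matrix(p) for p in paths], None


def run_all(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline and write every artifact plus a manifest.

    Per band: one connectivity matrix per subject, the FDR-corrected edge
    map, stratified-CV classification metrics and (optionally) the label
    permutation test.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recs, truth = _load_recordings(cfg)
    labels = np.array([0 if r.group == "control" else 1 for r in recs])
    subject_ids = np.array([r.subject_id for r in recs])

    summary: dict = {"bands": {}}
    for band in cfg.band_specs():
        log.info("band %s: filtering and connectivity", band.name)
        feats, mats, samp_labels, samp_subjects = [], [], [], []
        for rec, y in zip(recs, labels):
            band_rec = band_decompose(rec, [band])[band.name]
            pieces = [band_rec]
            if cfg.window_s is not None:
                trimmed = band_rec.copy_with(data=band_rec.interior(), edge_margin=0)
                pieces = segment(trimmed, cfg.window_s, cfg.overlap_s)
            for piece in pieces:
                cm = connectivity_matrix(piece, method=cfg.method)
                cm.band = band
                mats.append(cm)
                feats.append(vectorize(cm).values)
                samp_labels.append(y)
                samp_subjects.append(rec.subject_id)
        feats = np.asarray(feats)
        samp_labels = np.asarray(samp_labels)
        samp_subjects = np.asarray(samp_subjects)

        band_dir = out / band.name
        band_dir.mkdir(exist_ok=True)
        for cm, sid in zip(mats, samp_subjects):
            write_connectivity(cm, band_dir / f"connectivity_{sid}.csv")

        band_summary: dict = {}
        if len(np.unique(samp_labels)) == 2:
            ctrl = feats[samp_labels == 0]
            case = feats[samp_labels == 1]
            et = edge_tests(ctrl, case, alpha=cfg.fdr_alpha,
                            display_alpha=cfg.display_alpha)
            et.table.to_csv(band_dir / "edge_tests.csv", index=False)
            band_summary["n_significant_edges"] = int(et.table["significant"].sum())

            if cfg.cv_k:
                som = SOMConfig(
                    grid=cfg.som_grid,
                    schedule=SOMSchedule(
                        seed=cfg.som_seed, n_iter_per_sample=cfg.som_iter_per_sample
                    ),
                )
                cv = run_cv(feats, samp_labels, k=cfg.cv_k, seed=cfg.cv_seed,
                            som=som, subject_ids=samp_subjects, band=band.name)
                cv.summary().to_csv(band_dir / "cv_metrics.csv", index=False)
                band_summary["cv"] = {
                    m: [cv.mean(m), cv.sd(m)]
                    for m in ("accuracy", "sensitivity", "specificity", "auc")
                }
                if cfg.permutation_B:
                    pr = permutation_test(
                        feats, samp_labels, B=cfg.permutation_B, k=cfg.cv_k,
                        seed=cfg.cv_seed, som=som, subject_ids=samp_subjects,
                    )
                    band_summary["permutation"] = {
                        "observed_accuracy": pr.observed_accuracy,
                        "p_value": pr.p_value,
                        "p_value_smoothed": pr.p_value_smoothed,
                        "B": pr.B,
                    }
                    pd.DataFrame({"null_accuracy": pr.null_accuracies}).to_csv(
                        band_dir / "permutation_null.csv", index=False
                    )
        summary["bands"][band.name] = band_summary

    if truth is not None:
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    manifest = {
        "config_hash": cfg.manifest_hash(),
        "version": __version__,
        "seeds": {"som": cfg.som_seed, "cv": cfg.cv_seed},
        "n_recordings": len(recs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
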