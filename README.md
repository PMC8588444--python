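# phasesom

EEG phase-synchrony connectivity and self-organizing-map anomaly detection
for two-group studies.

`phasesom` is aimed at researchers who want to ask, from multichannel EEG,
whether a clinical group (the running example is developmental dyslexia in
children listening to amplitude-modulated noise) differs from controls in
*how synchronized* pairs of channels are within the classical frequency
bands — and whether that difference is strong enough to detect individual
subjects as anomalies.

## What it computes

1. **Zero-phase band decomposition.** Channels are re-referenced (e.g. to
   Cz), notch-filtered at 50 Hz, low-passed at 80 Hz and split into the five
   EEG bands (Delta 1.5–4, Theta 4–8, Alpha 8–13, Beta 13–30, Gamma
   30–80 Hz) using linear-phase least-squares FIR filters applied forward
   and backward — phase estimates tolerate no phase distortion, so IIR
   filters are never used.
2. **Phase synchrony.** Each band-limited channel's instantaneous phase
   φ(t) comes from its analytic signal x(t) + j·H{x(t)}. Two measures are
   offered for every channel pair:
   - phase locking value, PLV = |⟨e^{j(φ_x−φ_y)}⟩|, and
   - circular correlation,
     r = Σ sin(φ_x−φ̄_x) sin(φ_y−φ̄_y) / √(Σ sin²(φ_x−φ̄_x) · Σ sin²(φ_y−φ̄_y)),
     the circular analogue of Pearson's r (φ̄ is the circular mean).
   The C×C matrices per band are flattened (upper triangle, row-major) into
   feature vectors.
3. **One-class anomaly detection.** A self-organizing map is trained on
   control subjects only. The quantization error (QE) — a sample's distance
   to its best matching unit — is the anomaly score: patterns the map never
   saw quantize poorly. A two-Gaussian Bayes model of QE yields the decision
   threshold, and the symmetrized Kullback–Leibler divergence between the
   groups' QE histograms ranks bands by separability.
4. **Evaluation.** Subject-stratified k-fold cross-validation (accuracy,
   sensitivity, specificity, rank-based AUC), label-permutation significance
   of the CV accuracy, and per-connection two-sided Mann–Whitney tests with
   Benjamini–Hochberg FDR control.
5. **Synthetic cohorts with ground truth.** A generator plants band-limited
   shared sources on chosen channel pairs with tunable coupling weights, so
   every stage can be validated against known answers.

## Worked example

A synthetic study: 12 controls with Beta-band coupling 0.8 on eight channel
pairs, 6 cases where that coupling drops to 0.3.

```python
from phasesom.studies import (planted_beta_spec, band_connectivity_study,
                              edge_recovery, classification_study, qe_group_means)
from phasesom.som import band_relevance

spec = planted_beta_spec(seed=42, n_control=12, n_case=6, duration=40.0)
study = band_connectivity_study(spec)          # Beta band, 5 s epoch-averaged
er = edge_recovery(study)
print(f"planted edges recovered: {er['recovered_fraction']:.0%} "
      f"({er['n_false']} false positives)")
cv = classification_study(study, k=5, seed=42)
print(f"CV accuracy {cv.mean('accuracy'):.2f} +/- {cv.sd('accuracy'):.2f}, "
      f"AUC {cv.mean('auc'):.2f}")
qg = qe_group_means(study)
print(f"mean QE control {qg['mean_qe_control']:.3f}, case {qg['mean_qe_case']:.3f}")
qe = qg["qe"]
print(f"Beta band relevance (symmetrized KL): "
      f"{band_relevance(qe.for_group('control'), qe.for_group('case')):.2f} nats")
```

prints

```
planted edges recovered: 100% (0 false positives)
CV accuracy 0.90 +/- 0.22, AUC 1.00
mean QE control 0.162, case 0.713
Beta band relevance (symmetrized KL): 22.86 nats
```

All eight weakened connections survive FDR correction with no false edges;
cases quantize ~4× worse than controls on a map trained only on controls,
which is what makes the one-class classifier work.

## Command line

`phasesom simulate|bands|connectivity|evaluate|permtest|edges|run-all` wrap
the same functions; `run-all --config cfg.yaml --out dir/` executes the whole
pipeline (per-band connectivity, edge maps, CV, permutations) and writes a
manifest with the config hash and seeds so runs are bit-reproducible.

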