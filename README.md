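# trustwsi

Uncertainty-aware, conformalized tile-to-patient classification for
whole-slide images (WSIs).

Weakly supervised WSI pipelines classify gigapixel slides by scoring
thousands of tiles and averaging: tiles inherit the slide's diagnosis as a
weak label, many of them (stroma, necrosis, normal tissue) carry no subtype
signal, and deployment streams contain slides the model has never seen
(other tissue types, other scanners).  `trustwsi` implements a
trustworthiness layer for this setting, aimed at researchers building or
auditing computational-pathology classifiers:

* **SNGP** — a spectral-normalized feature extractor (residual blocks with
  every dense layer's spectral norm clipped at *c*) with a
  random-Fourier-feature Gaussian-process head.  The fixed projection
  Φ(h) = √(2/D) cos(−W_L h + b_L) approximates an RBF kernel, the MAP
  coefficients β̂ give logits μ_k = Φ*ᵀβ̂_k, and the ridge form
  τ·Φ*ᵀ(ΦᵀΦ + τI)⁻¹Φ* is a single-pass distance-aware uncertainty (≈1 far
  from the training data).  An MC-dropout baseline and an attention-based
  multiple-instance (ABMIL) bag classifier are included.
* **Conformal prediction** — split CP with nonconformity s(x,y) = 1 − p̂(x)_y
  and threshold q̂ = the ⌈(R+1)(1−α)⌉-th smallest calibration score, giving
  prediction sets with marginal coverage in [1−α, 1−α+1/(R+1)].  For binary
  labels a size-2 set is an abstention; the definitive-answer (DA) error
  rate is the fraction of singleton calls that are wrong.
* **Conformal risk control (CRC)** — sets Γ_ρ(x) = {k : p̂(x)_k ≥ 1−ρ} with
  ρ̂ chosen by bisection so the (finite-sample-corrected) calibration
  coverage meets the target even when undetected out-of-distribution (OOD)
  units contaminate the stream.
* **EAT** — elimination of ambiguous tiles, scored by
  s(x, M) = 1 − |p(y=0|x) − p(y=1|x)|, via k-means latent clusters
  (silhouette-selected k), score thresholding with a proxy tile classifier,
  or the random-elimination control.
* **OOD detection and distribution-shift control** — probability-based
  (1 − mean max-class probability) and uncertainty-based (mean of the δ=200
  lowest tile uncertainties) unit scores, FPR/TPR-based thresholds, and
  OOD-guarded conformal inference.
* **Metrics** — two-stage tile→slide→patient aggregation, accuracy/AUROC,
  demographic fairness gaps (max−min across subgroups, small groups merged
  into "Others"), and attention efficiency.

Everything runs end-to-end on a seeded synthetic cohort generator that
reproduces the statistical structure of real WSI cohorts — class-dominant
and ambiguous embedding clusters, multi-slide patients, subgroup labels and
well-separated OOD cohorts — so the statistical guarantees are testable on
a laptop without any data download.

## Worked example

```python
import numpy as np
from trustwsi import CohortConfig, generate_cohort, generate_ood_cohort, conformal
from trustwsi.sngp import SNGPConfig, train_tile_classifier
from trustwsi.metrics import aggregate, classification_metrics
from trustwsi.ood import unit_scores, evaluate_detection

cfg = CohortConfig(n_patients_per_class=60, tiles_per_slide=(15, 25), seed=7)
cohort = generate_cohort(cfg)
ood = generate_ood_cohort(cfg, 30)

model = train_tile_classifier(
    cohort, SNGPConfig(hidden_sizes=(32, 32), D_L=128, epochs=10, seed=7))
out = model.predict(cohort.embeddings)

patients = aggregate(out.probs, cohort.manifest)["patient"]
print(classification_metrics(patients.probs, patients.labels))

rng = np.random.default_rng(0)
order = rng.permutation(len(patients.labels))
cal, test = order[:60], order[60:]
scores = conformal.nonconformity(patients.probs[cal], patients.labels[cal])
calib = conformal.calibrate(scores, alpha=0.05)
sets = conformal.predict_set(patients.probs[test], calib)
print("q_hat:", round(calib.q_hat, 4))
print(conformal.evaluate(sets, patients.labels[test]))

o_ood = model.predict(ood.embeddings)
_, s_in = unit_scores(cohort.manifest, out.probs, out.uncertainty)
_, s_out = unit_scores(ood.manifest, o_ood.probs, o_ood.uncertainty)
print("OOD AUROC:", evaluate_detection(s_in, s_out)["auroc"])
```

Output:

```
{'accuracy': 1.0, 'auroc': 1.0, 'n': 120}
q_hat: 0.2766
{'n': 60, 'coverage': 0.9666666666666667, 'mean_set_size': 0.9666666666666667,
 'breakdown': {'single_correct': 58, 'single_incorrect': 0, 'abstention': 0,
 'empty': 2}, 'da_error': 0.0}
OOD AUROC: 1.0
```

Reading: the 120 held-in patients are classified perfectly; with 60
calibration patients at α = 0.05 the conformal threshold is q̂ ≈ 0.277, the
58 singleton predictions are all correct (DA error 0), two units get empty
sets (flagged, not silently coerced), and coverage 0.967 sits inside the
guaranteed band [0.95, 0.95 + 1/61].  The uncertainty-based OOD score
separates the shifted cohort perfectly.

## Command line

`trustwsi simulate | train | predict | eat | calibrate | evaluate | ood |
reproduce-protocol` — see `trustwsi --help`.  `reproduce-protocol` runs the
replicated study design (patient-level 65/15/20 split, repeated models, many
conformal calibration/test splits) at a configurable scale and writes a
summary JSON with coverage, set sizes, the
single-correct/single-incorrect/abstention/empty breakdown, DA error and
fairness gaps.

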