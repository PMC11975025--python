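# Methods

This note records the models, the synthetic study conditions, the numerical
choices, and what the test suite does and does not establish.

## Problem setting

A whole-slide image (WSI) is processed as a bag of tiles with a single
slide-level binary diagnosis (e.g. the two non-small-cell lung cancer
subtypes).  Every tile inherits the slide label ("weak" supervision), so the
tile-level training signal is noisy by construction; slide calls are means
of tile outputs and patient calls means of slide outputs.  The package adds
three safeguards to this pipeline: distance-aware uncertainty, prediction
sets with coverage guarantees, and explicit handling of ambiguous tiles and
out-of-distribution (OOD) inputs.

## Spectral-normalized neural Gaussian process

**Extractor.** The tile extractor is an entry dense layer followed by
residual blocks `h ← h + relu(W h + b)`, all dense weights re-projected to
spectral norm ≤ c after every optimizer step (`W ← cW/λ̂` when `λ̂ > c`,
with λ̂ from power iteration — one iteration per step against a persistent
vector during training, 50 iterations for standalone calls).  The residual
form matters: bounding each block's gain keeps the whole map approximately
bi-Lipschitz, so latent distances track input distances; a plain
feedforward stack with clipped norms is merely contractive and has no lower
Lipschitz bound.  The tests therefore quantify "distance preservation" as
the width of the empirical ratio interval [L1, L2] on sampled pairs, the
quantity spectral normalization directly controls.

**GP head.** The output layer is a random-Fourier-feature approximation of
an RBF-kernel GP: Φ(h) = √(2/D_L)·cos(−W_L h + b_L) with W_L ~ N(0,1) and
b_L ~ U(0, 2π) fixed at construction, so ΦᵢᵀΦⱼ → exp(−‖hᵢ−hⱼ‖²/2) at rate
O(1/√D_L).  The only learned output parameters are the coefficients β with
a standard-normal prior.  Training is end-to-end (Adam on cross-entropy,
β's prior entering as weight decay 1 on the summed loss); after the best
validation epoch is selected, β is re-solved to its exact MAP on the frozen
features by L-BFGS and the precision ΦᵀΦ + τI is accumulated over the
training tiles.  Predictions use μ = Φ*ᵀβ̂ and the ridge-form uncertainty
τ·Φ*ᵀ(ΦᵀΦ+τI)⁻¹Φ* (applied through a Cholesky factorization, never an
explicit inverse); it equals Φ*ᵀΦ* ≈ 1 with no training data and shrinks as
training data accumulates near the query.

**Probabilities.** The softmax is integrated over the Gaussian logit
distribution by Monte Carlo with `n_mc_softmax = 100` draws by default;
`n_mc_softmax = 0` selects the mean-field approximation
softmax(μ/√(1 + π/8·σ²)).  The integral's estimator is a free choice; both
routes agree within a few hundredths on the tests' problems.

**Defaults.** c = 1, D_L = 1024 (128–256 in the desk-scale experiment
configurations), τ = 1, hidden widths 64, Adam lr 1e-3, ≤30 epochs,
patient-level validation split.  These follow common practice for
spectral-normalized GP heads and keep the precision matrix well
conditioned; they were fixed once for the study conditions.

**Baselines.**  MC dropout: a plain dropout MLP with a dense softmax head,
predictions averaged over 5 stochastic passes (uncertainty = across-pass
standard deviation of the predicted probability).  ABMIL: tile transform
512→384 (ReLU), dropout 0.1 on inputs and 0.25 after each intermediate
layer, tanh attention (dim 256) with softmax weights summing to 1 per bag,
spectral normalization on the dense layers, a GP head on the pooled bag
representation, ≤20 epochs of Adam at lr 1e-4 under a cosine schedule.
The attention logit vector `w` itself is left unnormalized (it sets the
attention temperature, not a representation distance).

## Conformal prediction and risk control

Split CP uses s(x,y) = 1 − p̂(x)_y, q̂ = the ⌈(R+1)(1−α)⌉-th smallest of R
calibration scores (+∞ when the index exceeds R, giving all-label sets),
and Γ(x) = {k : s(x,k) ≤ q̂} with ties included.  No tie-breaking
randomization is used.  Empty sets are representable and reported as their
own category; for binary problems set size 2 is an abstention and the
definitive-answer (DA) error rate is single-incorrect /
(single-correct + single-incorrect), reported as missing when there are no
singletons.

CRC controls expected miscoverage under contamination: Γ_ρ(x) =
{k : p̂(x)_k ≥ 1−ρ}, with ρ̂ the smallest threshold (bisection, tolerance
1e-4 on ρ, ≤64 iterations) whose calibration coverage reaches the
finite-sample-corrected target 1 − ((R+1)α − 1)/R.  The correction is the
upper-confidence form of the risk bound for a loss bounded by 1; without
it, small calibration streams systematically under-cover on new data.
Units marked "never covered" (true OOD) charge their miscoverage at every
ρ, which is what inflates ρ̂ — and set sizes — under contamination.  When
even ρ = 1 cannot reach the target (OOD fraction above α) the controller
returns ρ̂ = 1 with an explicit infeasibility flag.

Patient-level conformal scores use the aggregated (post-integration)
probabilities, i.e. the two-stage mean of final tile probabilities.

## Ambiguity and elimination (EAT)

The ambiguity of a tile under binary classifier M is
s(x, M) = 1 − |p₀ − p₁|.  Three elimination modes:

* **cluster** — k-means (k by maximal mean silhouette over 2–6, subsampled
  above 20 000 tiles) on tile representations; a cluster is ambiguous when
  its largest weak-label fraction is below the dominance threshold (default
  0.7); new tiles are assigned to the nearest Euclidean center.  The tile
  classifier is retrained on the survivors.
* **threshold** — keep the lowest-ambiguity fraction (`retain_rate`) using
  any proxy tile classifier's probabilities (here: logistic regression on
  embeddings); the bag model is reused without retraining.
* **random** — the seeded uniform control at the same rate.

In the elimination-effect experiment the clusters are fit on the raw
embeddings: with a distance-preserving extractor, input and latent
structure coincide on this generator, and the rule then does not depend on
one particular trained representation.  The experiment removes exactly the
least label-dominated cluster, matching the one-ambiguous-cluster structure
the procedure assumes.  The retention sweep applies rates per slide (each
slide keeps at least its single least ambiguous tile), so the comparison is
not confounded by slides emptying out.

## OOD scoring and guarded inference

Unit scores (slides or patients, all tiles pooled): probability-based
1 − (1/N)Σ max_k p̂(ŷ_k|x_i), and uncertainty-based — the mean of the
δ = 200 lowest tile uncertainties (the *most confident* tiles of a truly
OOD unit are still uncertain; the mean over the δ lowest reduces variance).
OOD is the positive class in all detection metrics.  Decision thresholds
come from the empirical (1−FPR)-quantile of in-distribution reference
scores (reference = the calibration split) or from a target TPR on an OOD
reference pool.  Guarded inference rejects units above threshold and gives
CRC sets to survivors; CRC is calibrated on the post-filter survivors of a
contaminated calibration stream, so that OOD units escaping detection are
priced in.

## Synthetic study conditions

The generator emulates the hierarchy and geometry such pipelines assume,
with one splittable RNG stream per sub-generator (structure, embeddings,
subgroups) from a single integer seed:

* three isotropic Gaussian clusters in 8-D: class centroids 6 scales apart,
  the ambiguous cluster equidistant between them (offset 0.75×separation);
  at this separation class-dominant tiles are nearly perfectly classifiable
  and the three clusters are crisply recoverable by k-means/silhouette —
  the structure the elimination procedure assumes.  Overlapping regimes are
  studied explicitly via `cluster_means` (the elimination-effect experiment
  uses separation 3 with 12 tiles per slide, so tile noise genuinely
  reaches patient calls);
* ambiguous tiles are drawn per tile with probability `ambiguous_fraction`
  (default 1/3; 2/3 in the elimination studies) and inherit the slide's
  weak label — label noise arises exactly as in real weak supervision;
* one slide per patient in the TCGA-like configuration, 2–4 (mean ≈ 3) in
  the CPTAC-like one; tiles per slide uniform in a configurable range
  (default 20–40);
* OOD cohorts are displaced by `ood_mean_shift` (default 8) cluster scales
  from *every* in-distribution centroid (guaranteed via the triangle
  inequality, whatever the in-distribution geometry);
* per-patient sex (0.55/0.45) and race (0.72/0.10/0.18) labels assigned
  independently of difficulty, so fairness gaps are ~0 by construction.

What the generator does **not** emulate: real embedding geometry
(anisotropy, manifold curvature, batch effects), within-slide spatial
correlation of tiles, class imbalance, label errors at the slide level,
and gradual (rather than well-separated) distribution shift.  Passing
tests therefore establish the correctness and calibration of the
*machinery* under its stated assumptions, not performance claims about any
real cohort.

## Experiment scales and numerical choices

The replicated protocol is a 65/15/20 patient-level split (never
tile-level, to avoid leakage), with the full design at 20 model replicates
× 500 conformal splits and 100 calibration patients; the bundled
experiments and the acceptance script run desk-scale versions (5 generator
seeds, 500 splits, cohorts of 60–160 patients per class, D_L 128–256,
~10 training epochs), chosen so the whole suite runs in well under a
minute while Monte-Carlo standard errors stay below half a percentage
point.  Ties in attention rankings and ambiguity orderings are broken by
stable tile order.  Degenerate inputs (zero-weight matrices, empty bags,
single-class labels, empty calibration sets, all-identical cluster data)
raise explicit errors or warnings rather than propagating silently.

## Known limitations

* Binary labels only; the ambiguity score is defined for two classes and
  multi-class generalizations are out of scope.
* The GP head's kernel bandwidth is fixed at 1; inputs are not rescaled
  before the head.
* The predictive variance is the shared ridge form per logit, not a
  per-class Laplace covariance.
* CRC instantiates only the miscoverage loss.
* The NumPy training loop is single-threaded desk-scale by design; it is
  not a GPU training framework.
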