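# Methods

This note documents the models, procedures, defaults and numerical choices
behind `quarg`, and what the synthetic study conditions do and do not show
about real radiogenomic data.

## Synthetic cohorts

`quarg.synthetic` generates paired imaging/expression feature tables with
planted ground truth. The generative model is deliberately the simplest one
whose informative set is recoverable both by correlation screening and by
the selection QUBO:

* **Labels** are Bernoulli(`class_balance`), default 0.5.
* **Informative features** are N(0, 1) for class 0 and N(`effect_size`, 1)
  for class 1 — an additive mean shift, default `effect_size = 2` (a
  "strong" signal: per-feature point-biserial correlation ≈ 0.71).
* **Redundant features** are a noisy copy of an informative parent
  (parent + N(0, 0.25)); at n ≥ 200 their correlation with the parent
  exceeds 0.9, giving the redundancy penalty something real to act on.
* **Site effects** are a single additive offset per acquisition site,
  N(0, `site_shift_sd`²) with default 0.3, applied to every feature of that
  site's patients. This makes the site-held-out protocol strictly harder
  than the patient-level one without confounding the label.
* **Missingness** is MCAR at `missing_rate` (default 0.05), genomic
  modality only, mirroring an unconditional imputation setting.
* **Image patches** contain one elliptical blob on Gaussian background;
  label 1 blobs are brighter (peak 1.0 vs 0.5) and larger (radius 0.28 vs
  0.20 of the patch side). An optional multiplicative quadratic bias field
  with range ≈ [0.7, 1.3] is planted for the correction stage.
* **Counts** for the normalization fixtures are gamma-Poisson
  (negative-binomial-like, dispersion 0.3) with log-uniform library-size
  factors spanning 4x and gene lengths uniform on [0.2, 20] kb.

What this emulates: paired records, planted relevance/redundancy structure,
batch offsets, missing values, intensity inhomogeneity. What it does not:
realistic mammographic texture, read-level sequencing noise, label noise,
covariate shift beyond an additive site offset, or any real biological
correlation structure. Tests passing here show the machinery is correct and
recoverable signal is recovered; they do not certify performance on real
screening-mammography archives or tumor expression cohorts.

## Imaging preprocessing

* **Bias-field correction** fits a 2D polynomial (default order 2) to
  log-intensity by least squares and removes it, re-centering so mean
  brightness is preserved: `exp(log I − field + mean(field))`. A polynomial
  log-domain model was chosen because it is directly testable against the
  planted quadratic field (the suite requires a ≥ 5x reduction of the
  refitted low-frequency component).
* **ROI extraction** crops the mask's bounding box dilated by `margin`
  pixels; all coordinates are 0-based with half-open boxes.
* **Harmonization** resamples bilinearly to a common pixel spacing and
  z-scores each patch; a constant patch maps to zeros. In the pipeline the
  variable-size ROI crops are then resampled onto a fixed `roi_size` grid
  (default 16×16) so they can be batched through the conv encoder.
* **Radiomic descriptors** are a fixed 10-vector: masked intensity mean,
  sd, skewness, excess kurtosis; area (pixel count × spacing²), perimeter,
  circularity `4πA/P²`; and contrast/homogeneity/energy from an 8-level,
  distance-1, 0° co-occurrence matrix restricted to pixel pairs inside the
  mask. Perimeter uses the standard weighted boundary-length estimator
  (`skimage.measure.perimeter`): a raw count of boundary pixel edges is a
  city-block length that overshoots curved outlines by up to 8/(2π), which
  would put a disc's circularity near 0.62 instead of ≈ 1.

## Genomics preprocessing

Stage tags (`raw → normalized → imputed → standardized`) are enforced so
the steps can only run in order.

* **Normalization**: TPM (length-normalized rates rescaled to sum 10⁶ per
  sample) or FPKM (`counts · 10⁹ / (length_bp · library_size)`), each
  followed by log2(1+x).
* **Imputation**: k-nearest-neighbour over samples (default k = 5), with
  plain Euclidean distance over co-observed genes and sample-order
  tie-breaks — fully deterministic, unlike EM-style alternatives.
* **Filtering/standardization**: genes below the `var_quantile` quantile
  of variances (default 0.05) and all zero-variance genes are dropped;
  remaining genes are z-scored. The threshold, kept-gene set and moments
  are fitted on the training split and reused on validation/test via an
  explicit statistics object, which is what makes the leakage guard
  assertable.

## Feature selection

Relevance is `|point-biserial correlation|` with the label and redundancy is
`|Pearson correlation|` between features (0 for constant features). The
QUBO is

    C(z) = − Σ r_i z_i + α Σ_{i<j} ρ_ij z_i z_j + β (Σ z_i − k)²

expanded exactly into linear/pairwise coefficients using z² = z.

**Choice of α (default 0.25).** Under an additive mean-shift effect, any two
informative features are themselves correlated through the label (ρ ≈
d²/4 / (1 + d²/4), i.e. 0.5 at d = 2), so a redundancy weight of 1 penalizes
a subset of four planted features by ≈ 6 × 0.5α while a subset of
uncorrelated noise features pays almost nothing — at α = 1 the verified
brute-force optimum prefers noise. α = 0.25 keeps the mRMR balance: planted
subsets beat both noise subsets and parent+copy subsets (the copy still
loses because its ≈ 0.9 correlation with the parent outweighs its relevance).
β defaults to `2·max(r)` so no single relevance gain can break the soft
cardinality constraint; k defaults to the encoder width Q.

**QAOA simulation** is exact: the cost Hamiltonian is diagonal, so a γ layer
is an elementwise phase and a β layer is RX(2β) on every qubit; no gate
decomposition is needed and unitarity holds to 1e-9 by construction. Angles
are optimized by Nelder–Mead with seeded random restarts drawn from
[0, 2π)²ᵖ plus the all-zero start (so the result can never be worse than the
uniform-state cost mean). The returned angles are *not* wrapped mod 2π: the
cost phase is only 2π-periodic when all costs are integers. Subsets are
extracted either by seeded sampling or, in exact mode, as the best-cost
basis state with probability ≥ 1/2^{n+2}; ties break toward the smallest
basis index. `brute_force_select` (n ≤ 20) is the oracle for everything.

When the QAOA subset size differs from Q, the pipeline pins it to exactly Q
by dropping the least relevant selected features or adding the most relevant
unselected ones, so the encoder width never varies between runs.

## Quantum encoding

Selected features are min–max scaled to [0, π] with training-split bounds
(out-of-range values clip; a constant feature maps to π/2), angle-encoded as
a product state, and passed through L layers of RY·RZ rotations plus a CNOT
entangler (ring by default, line optional; a single qubit skips
entanglement). Observables are single-qubit Pauli-Z, giving exactly Q
features in [−1, 1]; at L = 0 the embedding reduces to cos(x), which the
suite checks in closed form. θ initializes as N(0, 0.1²) from the config
seed — small angles keep the initial circuit near identity. Gradients use
the parameter-shift rule (exact for RY/RZ generators), with the per-layer
input states cached so a shift at layer ℓ only re-simulates layers ℓ..L.
Defaults L = 6, Q = 10, p = 3 follow the ablation optimum the pipeline is
configured around; the test and example configurations use smaller circuits
(Q ≤ 6, L ≤ 2) purely to keep CPU runtimes in seconds.

## Encoders, fusion and training

The imaging encoder is a conv stem plus `n_res_blocks` residual blocks (two
3×3 convolutions with an identity skip; stride-2 3×3 downsampling between
blocks), global average pooling and a linear map to `d_img`. The genomic
encoder chunks the standardized vector into `token_size` tokens (zero-padded),
embeds them, adds sinusoidal positional encodings, applies `n_layers` of
multi-head self-attention (`softmax(QKᵀ/√d_k)V`) with feed-forward,
residual connections and layer normalization, mean-pools and maps to
`d_gen`. The head concatenates `[z_img ‖ z_gen ‖ z_q]` in that fixed order
and applies one hidden ReLU layer and a logistic output. Compact defaults
(2 residual blocks / 6 channels, d_model 16 / 2 layers) are desk-scale
choices, all configurable.

Everything runs on a small tape-based reverse-mode autodiff engine written
on numpy (float64, CPU-only), which keeps runs bit-reproducible for a fixed
seed; gradients are verified against central finite differences in the test
suite.

**Loss.** Natural-log cross-entropy (probabilities clamped to
[1e-7, 1−1e-7] with a warning) plus `λ` times a soft-binned ECE surrogate:
confidence `c = max(ŷ, 1−ŷ)`, triangular kernel memberships over M
equal-width bins on [0.5, 1] (the kernels form a partition of unity away
from the interval ends), and the weighted sum of |soft-accuracy −
soft-confidence| over bins. Hard binning has zero gradient almost
everywhere, hence the surrogate; the hard ECE is what evaluation reports.
Defaults λ = 0.1, M = 10. The surrogate agrees with hard ECE within 0.02 on
1000-sample prediction sets and its gradient is finite-difference verified.

**Optimization.** Minibatch Adam (lr 0.01) for classical parameters and a
separate Adam (lr 0.05) driven by parameter-shift gradients for θ. After
each epoch the validation AUC and hard ECE are computed; the checkpoint
maximizing `AUC − w·ECE` (default w = 1) is kept, with early stopping after
`patience` stale epochs. Training is deterministic given the config seed.

**A caution on the composite early-stop score.** With w = 1 the score can
peak in early underfit epochs, where a model that is uncertain (hence
trivially calibrated) beats a better-discriminating but less calibrated
one; with aggressive patience this restores underfit checkpoints. The
controlled calibration experiment below therefore checkpoints on AUC alone
(w = 0); pipeline defaults keep patience ≥ 4 and moderate epoch counts.

**What the calibration penalty does and does not achieve here.** The
package ships a designed paired experiment
(`quarg.experiments.calibration_comparison`): λ = 0.1 vs λ = 0 on the same
seeds and data, cohorts with irreducible class overlap (effect size 1), a
small 120-patient training split the encoders can overfit, a 400-patient
test split so hard-ECE differences are measurable, 25 epochs, AUC-only
checkpointing. The test suite asserts the directional claim (penalty wins
on a majority of 10 seeds) and currently *fails*: on these synthetic
cohorts a converged cross-entropy model is already well calibrated (test
ECE typically 0.02–0.10), and the surrogate's bin-membership gradients can
push borderline probabilities away from 0.5, occasionally producing high-AUC
models with displaced thresholds. The experiment is reported as computed —
the acceptance script writes the measured win fraction and both mean ECEs —
rather than tuned until the direction flips. Conditions under which such
penalties are reported to help (large miscalibrated networks, large-batch
bin estimates) are outside this package's desk scale.

## Evaluation

Confusion-matrix metrics use threshold 0.5 by default; zero-denominator
precision/recall are defined as 0 and flagged. AUC is the Mann–Whitney
pair-counting estimator (ties credited 1/2), identical to trapezoidal
integration of the exported ROC curve to 1e-9. ECE bins confidence
`max(ŷ, 1−ŷ)` into M right-closed equal-width bins on [0.5, 1] (M = 10
default; the bin count is a documented choice), skipping empty bins.

The patient-level split is stratified 70/15/15 with largest-remainder
rounding per stratum plus a repair pass that moves single patients between
splits so the global sizes match the largest-remainder rounding of
n·fractions exactly. The site-held-out split reserves every patient of one
site for testing and splits the rest train/val stratified (val share
defaults to 15/85, matching the patient-level validation share). Split
indices, seeds and the split kind are cached as JSON.

## Pipeline and reproducibility

`run_pipeline` executes simulate → preprocess → split → select → encode →
train → evaluate for both protocols. Each stage directory stores a hash of
its config slice and its parents' hashes; a rerun with an unchanged config
reloads from disk, making reruns idempotent and individual stages
re-runnable. The run directory contains the resolved config, a JSONL log
with config hashes and all derived seeds, split indices, the selected-
feature JSON and QUBO CSV, training history, the best checkpoint (a single
npz archive of every parameter array plus config and seed), metrics JSON
and ROC/reliability CSVs. Identical config and seed give bit-identical
metrics JSON (asserted in the suite). The ablation harness sweeps one
factor (L, Q or p) at a time over seeds and writes a CSV keyed by
(factor, value, seed).

Problem sizes used by the shipped experiments — 400-patient cohorts for
selection/recovery and the strong-signal training run, 600-patient cohorts
(120 train / 400 test) for the calibration comparison, 50 random 8-feature
QUBOs for the QAOA-vs-brute-force rate, Q ≤ 6 and L ≤ 2 circuits in
training runs — are the package's chosen desk-scale study conditions; the
full Q = 10 / L = 6 configuration is the pipeline default and is exercised
by the acceptance script.

## Known limitations

* Statevector simulation is exact but exponential: n ≤ 20 features for the
  QUBO path, Q ≤ 14 qubits for the encoder.
* The brute-force oracle, not hardware or shot noise, is the reference:
  no noise models, no sampling error on expectations.
* The synthetic generator's additive effects make feature relevance
  essentially linear; nonlinear interaction signal would need a different
  planted model and possibly a different relevance proxy.
* The calibration penalty's directional benefit does not replicate at this
  scale (see above); λ > 0 should be treated as an option to study, not a
  recommended default for small well-specified models.
* kNN imputation is O(genes · samples²) — fine for cohorts of hundreds,
  not for tens of thousands of samples.
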