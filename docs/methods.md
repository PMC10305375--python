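# Methods

This note documents the models, the synthetic data they are verified
on, and the numerical and design choices behind `lipocomplex`.

## Data model

A `DescriptorTable` holds an n×p matrix of numeric molecular
descriptors (units vary per column: Da for molecular weight, °C for
temperatures, hours for reaction time, dimensionless for logP, TPSA,
counts), a binary label per row (1 = complexation rate ≥ 80%), ordered
feature names, and an optional grouping of each descriptor into the
four blocks it comes from: the drug (`api`), the phospholipid
(`lipid`), the solvent (`solvent`) and experimental conditions
(`condition`). The number of features is data-driven rather than
hard-coded; 46 is the generator default. Labels are mapped so that
"success" (complex formed) is the positive class, which makes
sensitivity the fraction of viable formulations recovered — the metric
that matters most in screening.

## Synthetic descriptor generator

The generator emulates the statistical structure of the formulation
dataset the pipeline targets, so that every stage is testable offline:

- **Split sizes and imbalance.** 272 training rows (179 success / 93
  failure) and 69 test rows. The test composition defaults to 40/29:
  the reference test split's published sensitivity (39/40), specificity
  (26/29), accuracy (65/69) and F1 (0.9512) are simultaneously
  consistent only with that composition, so it is treated as a known
  study condition rather than assumed proportional to the training
  prior. The distinction matters: class balancing shifts the operating
  point toward neutral priors, which is only beneficial when the test
  population is itself closer to balanced.
- **Generative family.** Class-conditional Gaussians on
  `n_informative = 10` features with a shared covariance; the remaining
  features are pure Gaussian noise except for `n_constant = 1` column
  fixed at 52 (a lipid heavy-atom-count analog — real tables contain
  such degenerate descriptors because one phospholipid dominates the
  literature). The informative block is equicorrelated (ρ = 0.6 by
  default) and the class-mean difference lies along its leading
  variance direction, scaled so the Mahalanobis distance between class
  means equals `class_separation` (default 4). Molecular descriptors
  are strongly collinear in families (molecular weight, heavy-atom
  count and complexity move together), and this correlation is what
  lets a low-dimensional principal subspace carry the discriminant;
  with an isotropic informative block, min–max normalization equalizes
  all column variances and a 10-component projection of 46
  near-isotropic columns would discard most of the class signal — a
  property of the isotropic model, not of descriptor tables.
- **Scales.** Each feature is affinely mapped into a configured
  (offset, offset+range) interval: feature 0 to [200, 1100] (molecular
  weight analog), feature 1 to [−2, 8] (logP analog), the rest cycling
  through unit/tens/hundreds ranges. Raw values are clipped to a ±(d/2
  + 6σ) reference interval before mapping, so configured intervals are
  hard bounds; at six standard deviations the clipping is immaterial.
- **Bayes oracle.** With shared covariance the optimal rule thresholds
  the projection onto the mean difference, giving the closed form
  acc = π₁Φ(d/2 − c) + π₀Φ(d/2 + c), c = log(π₀/π₁)/d, computed under
  the test priors (`separability_oracle`). This bounds any classifier's
  achievable test accuracy and is the yardstick the end-to-end tests
  use. At the defaults it equals 0.9776 ≈ Φ(2).

What the generator does **not** emulate: real descriptor correlations
across blocks, non-Gaussian marginals (real descriptors are skewed and
multimodal), label noise in the 80% complexation-rate cutoff, and any
train/test distribution shift from distance-based splitting. Passing
tests therefore demonstrate correctness and learnability of the
implementation under a controlled, analytically tractable distribution
— not performance on real formulation data.

A structural consequence of the Gaussian family worth stating: any
shared-covariance two-class Gaussian problem has a one-dimensional
discriminant, so of the 10 retained principal components exactly one
carries class signal and nine are noise by construction. The CNN
trained to the reference schedule overfits those nine directions to a
measurable degree: a control experiment that zeroes them recovers
near-Bayes accuracy (~0.97), while the full 10-component input settles
around 0.91–0.93 true accuracy. On a 69-row test set this puts
individual-seed accuracies in the 0.85–0.99 range, which the
learnability test reports over ten seeds.

## Min–max normalization

Fitted on the training split only; the identical affine map is applied
to any other split, and test values outside [0, 1] are legitimate and
never clipped. Zero-range (constant) columns map to 0 rather than NaN,
keeping them inert. Parameters serialize to JSON/YAML so the exact
transform can be reused at deployment time.

## Variational autoencoder

Architecture: input → 50 → 25 → (μ, log σ²) ∈ ℝ², decoder 2 → 25 → 50 →
input, ReLU hidden activations, logistic output, He-normal weights
(variance 2/fan_in), zero biases. Loss per sample:

    L = w · recon(x, x̂) + KL(q(z|x) ‖ N(0, I)),   w = 1000
    KL = −½ Σⱼ (1 + log σ²ⱼ − μ²ⱼ − σ²ⱼ)

The reconstruction term is element-summed binary cross-entropy: inputs
are min–max normalized to [0, 1] and the decoder output is logistic, so
BCE is the consistent Bernoulli-parameter likelihood; squared error is
available via `recon_loss="mse"`. The large reconstruction weight makes
posteriors nearly deterministic (posterior σ ≈ 0.01 after training),
which is intended: generation then resembles denoised resampling of
observed minority rows rather than free sampling from the prior.

Minority generation samples the posteriors of uniformly drawn minority
rows rather than the latent prior. The VAE itself is trained on the
full training split (both classes share the latent space); posterior
sampling of minority rows guarantees the generated rows carry the
minority label and land inside the minority cluster, which the tests
check via nearest-neighbor label fidelity (≥ 80% of pool rows have a
minority nearest neighbor) and latent silhouette (> 0 by true class).
Generated labels are fixed, never re-inferred. Balancing draws the
class gap (86 rows at the default counts) from a 500-row pool uniformly
without replacement and never modifies original rows.

## Training schedule and batching

Both networks use Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) at learning
rate 0.001: 5000 iterations for the VAE, 2500 for the CNN. An
*iteration* is one optimizer step on a shuffled mini-batch of 32 (the
convention of the mainstream deep-learning frameworks, whose default
batch size is 32); `batch_size=None` switches to full-batch steps. The
mini-batch default is deliberate: full-batch Adam drives the 2081-
parameter CNN to interpolation (train accuracy 1.000) on ~350-row
training sets, whereas batch-32 training settles at train accuracies of
0.93–0.97 — the regime the reference results for this pipeline report —
and generalizes measurably better; gradient noise is the standard
implicit regularizer for small tabular networks. All shuffling and
latent noise derive from the config seed, so training histories are
bit-reproducible.

## PCA

Explicit eigendecomposition of the training covariance with the
unbiased (n−1) denominator. Eigenvalues are clipped at 0 (they are
non-negative up to round-off), sorted descending; each eigenvector's
largest-magnitude entry is made positive, fixing the sign ambiguity so
projections are reproducible. Component selection implements the
cumulative-explained-variance ≥ 85% rule with a fixed-k override;
k = 10 is the pipeline default. PCA is fitted on the augmented
(post-balancing) training set, matching the pipeline order normalize →
augment → reduce; fitting on the pre-augmentation split was measured to
give indistinguishable end-to-end accuracy, so the order is a
convention here, not a tuning choice.

## CNN classifier

Topology (input length 10, kernel 1, stride 1): conv(8) → conv(16) →
conv(32) → concat(conv-1 out, conv-3 out → 40 channels) → max-pool(2)
→ conv(32) → max-pool(2) → flatten(64) → dense(1) → logistic. ReLU
after every convolution; He-normal init, zero biases. The skip merge is
channel concatenation — the 8- vs 32-channel mismatch rules out
addition — and it constrains conv-1 and conv-3 outputs to equal length,
which with this topology requires kernel = stride = 1 (validated at
construction). Pooling is max by default (average is available) with
floor-division output lengths (10 → 5 → 2). Parameter count of the
default model:

    (1·8+8) + (8·16+16) + (16·32+32) + (40·32+32) + (64·1+1) = 2081

A published description of this architecture reports 3105 parameters;
no completion of the stated topology (kernel 1, channels 8/16/32,
concatenating skip, pool 2, single dense output) reproduces that
number, so the model likely contained an unreported layer or width.
This implementation reports its own count and documents the
discrepancy rather than forcing a match. The classification threshold
is 0.5 on the logistic output, with label 1 on ties.

## Resampling baselines

From-definition implementations, with sklearn's `NearestNeighbors`
handling Euclidean neighbor queries in the normalized feature space:

- **SMOTE** (k = 5): each synthetic row is x + u(x′ − x) with x a
  uniform minority row, x′ one of its k nearest minority neighbors
  (self excluded), u ~ U(0, 1); exactly (majority − minority) rows are
  generated, so output classes balance.
- **ENN** (k = 3): a row is dropped only when strictly more than half
  of its k nearest neighbors (self excluded) carry the other label, so
  exact vote ties keep the row.
- **SMOTE-ENN**: sequential composition.

The k defaults are the classic values from the original formulations of
these methods. All methods leave original rows intact (ENN excepted, by
definition) and are deterministic under a fixed seed.

## Metrics

Accuracy, sensitivity, specificity, precision and F1 follow their
confusion-count definitions exactly; any zero-denominator case returns
an explicit `None` marker, never a silent 0 — a library must behave
sensibly on degenerate inputs the original study never hits. AUC uses
the Mann–Whitney rank statistic (average ranks), which equals
trapezoidal ROC integration over thresholds but is tie-robust; it is
cross-checked against an O(n²) pairwise oracle and sklearn in the
tests.

## Permutation importance

Computed on the no-PCA pipeline variant, because component mixing would
spread each descriptor's contribution across all inputs. Within each
repeat a single shared permutation is applied column-by-column; the
score is the mean accuracy drop, floored at 0 (a chance increase is
noise, not negative importance) and normalized to sum to 1. With the
shared schedule, a column the model provably ignores scores exactly 0
before normalization. If no column moves the accuracy the report is
flat (1/p each) rather than undefined. Ranking ties break by original
column order for determinism. The attribution method is a
model-agnostic choice of this package; importance rankings on real
data would additionally depend on descriptor collinearity, which
permutation importance splits across correlated columns.

## Numerical choices

- BCE probabilities clipped at 1e-12 for loss evaluation; gradients use
  the exact (unclipped) logistic-BCE form x̂ − x.
- `reparameterize` at log σ² = −50 returns μ to within 1e-9, covering
  the degenerate-variance limit without special-casing.
- PCA orthonormality and variance conservation are asserted to 1e-8;
  score decorrelation to 1e-6 (the (n−1) convention makes per-component
  score variance equal its eigenvalue).
- Seeds are split with `numpy.random.SeedSequence` so the generator,
  VAE init, latent noise, pool selection and CNN init never share
  streams; every derived seed stays below 2³¹.

## Known limitations

- The synthetic world is Gaussian with a rank-1 class-mean difference;
  its one-dimensional discriminant makes most retained principal
  components uninformative, which caps end-to-end accuracy below the
  Bayes bound at these sample sizes (see the generator section). Real
  descriptor tables distribute signal differently.
- VAE-generated rows are near-deterministic decodings and lie close to
  a 2-D manifold; with ample class signal the augmentation arms do not
  beat the no-augmentation arm on this generator, and the comparison
  harness asserts only that they stay within a small margin of it.
- ENN's edit counts on real data depend on local label noise that the
  clean generator does not produce; its data-dependent behavior is
  exercised only through constructed enclave/cluster cases.
- Descriptor computation from chemical structures, and the
  distance-based train/test splitting procedure used by the original
  data providers, are out of scope; the generator draws test rows
  i.i.d. from the training distributions.
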