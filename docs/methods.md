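# Methods

## Problem and model

Resting-state fMRI dynamics are usually summarized by windowed functional
network connectivity (wFNC): the Pearson correlation matrix of ICA
component timecourses inside a sliding window. Correlation is linear and
invariant to common temporal permutations, so it discards much of what
happens *within* a window. This package implements an alternative
summary: a disentangled sequential variational autoencoder that factorizes
each window of a multivariate timeseries `x_{1:W} ∈ R^{N×W}` into

* a **context embedding** `z_c` — one latent vector per window, intended to
  capture slowly varying, window-level structure, and
* **local embeddings** `z_{1:W}` — one latent vector per timestep, capturing
  fast within-window dynamics.

Two variants differ only in how the channels interact:

* **DSVAE** (dependent): a sampled `z_c` is broadcast-concatenated to every
  timestep's input of the local encoder, and the local prior — a learnable
  GRU rolled out over the sampled latent path — is initialized from `z_c`.
* **IDSVAE** (independent): the local encoder sees only the window, and the
  GRU prior is initialized from a learnable vector.

Both share the same context encoder (bidirectional tanh RNN over the
window, final states of both directions concatenated; a 1-D convolutional
stack with global average pooling is available as a config option) and the
same decoder (a per-timestep MLP on `[z_c; z_t]`, with the window's `z_c`
reused at every timestep). Two baselines complete the comparison set:
**LVAE** (local-only; its "context embedding" is the time-average of the
local posterior means) and **CVAE** (context-only; 1-D convolutional
encoder/decoder over the whole window).

The training objective per window is the negative ELBO

    L = recon + β · (1/W) Σ_t KL(q(z_t|·) ‖ p(z_t|z_{<t}, ·))
              + γ · KL(q(z_c|x_w) ‖ N(0, I))

with a unit-variance Gaussian likelihood (so `recon` is the mean over
timesteps of `½‖x_t − x̂_t‖²` plus the Gaussian constant), the local KL
averaged over the W timesteps, and no `1/W` on the context term. All
posteriors and priors are diagonal Gaussians; log-variances are clamped to
[−10, 10] to keep early-training KLs finite. The KL against the
autoregressive GRU prior is computed analytically per timestep along a
single sampled latent path (the exact marginal KL of an autoregressive
prior is intractable; a one-sample path estimate is the standard choice
for sequential VAEs). One reparameterized sample per window is drawn per
loss evaluation.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `width`, `stride` | 32, 4 timesteps | 64 s windows every 8 s at TR = 2 s |
| `local_size` (LS) | 4 | local latent dimension |
| `context_size` (CS) | 2 | context latent dimension (2 keeps the space directly visualizable) |
| `beta` | 2.0 | local KL weight; deliberately large so that routing window-level information through the local channel is expensive |
| `gamma` | 0.01 | context KL weight; small, so the context channel is the cheap place to store window-level structure |
| `hidden_size` | 32 | encoder RNN state size |
| `learning_rate` | 3e-3 | Adam step size, sized for the few hundred updates of a short CPU run |
| `batch_size` | 128 | larger batches amortize per-step costs of the CPU autodiff backend |
| `max_epochs`, `patience` | 20, 10 | early stopping on validation total; best-epoch weights restored |
| `input_noise_std` | 0 | optional training-time corruption of inputs only |

The β ≫ γ asymmetry is the disentanglement mechanism: both channels could
in principle reconstruct slow structure, but the local channel pays β per
window for deviating from its prior while the context channel pays only γ.
With β small the local channel absorbs everything and the context
posterior collapses to its prior; the defaults were chosen (and are
demonstrated by the collapsed-γ ablation test) so that the context channel
is the carrier of window-level signal.

Training is deterministic given the config seed: initialization, batch
shuffling, reparameterization draws and input noise each use a named
substream of the seed, so two runs with identical inputs produce identical
weights on the same backend. The compute backend is plain numpy
differentiated with HIPS autograd; recurrences are written so that
per-step slicing happens on untraced data arrays and both RNN directions
share one batched matrix product per step, which keeps the autodiff graph
small enough for CPU-only training.

Model selection follows the grid protocol: every configuration is trained
with the seed list (42, 1337, 1212, 9999 by default), and the
configuration with the best *mean validation total loss* across seeds is
selected (ties break to the lowest config index). "Best validation
performance" is read as validation loss rather than downstream accuracy,
since loss is the selection quantity available without labels.

## Synthetic cohort

No public windowed-fMRI cohort with known ground truth exists at this
scale (the motivating clinical dataset is access-restricted), so the
generator plants exactly the structure the model assumes, with defaults
acting as the study conditions:

* **Context factor** (2-D): a stationary Ornstein–Uhlenbeck walk with unit
  marginal variance and autocorrelation timescale 40 timesteps (80 s at
  TR = 2 s); group means differ by an offset of norm 2 (patients vs
  controls), so diagnosis is decodable from slow structure only.
* **Local factor** (4-D): an AR(1) with coefficient 0.6 and unit innovation
  variance — fast dynamics, identical across groups.
* **Mixing**: a fixed Gaussian matrix with unit-norm rows maps the 6
  latent dimensions to N = 10 observed channels, through a tanh
  nonlinearity by default, plus Gaussian observation noise (σ = 0.2).
* **Cohort**: 2 × 50 subjects, 160 timesteps each. Ages and cognitive
  scores are drawn from group-dependent normals matching published
  multi-site schizophrenia cohort demographics, *independently* of the
  latent trajectories (the generator plants no covariate–dynamics link).

The context factor evolves continuously rather than piecewise-constant per
window, so synthetic block boundaries never align with window boundaries.
All randomness flows from one seed through counter-based per-subject
streams, making generation order-independent and bitwise reproducible.

What the generator does *not* emulate: hemodynamic response, scanner noise
spectra, head motion, site effects, or any coupling between symptoms and
dynamics. Passing tests on this cohort show that the implementation
recovers planted slow/fast structure under its own assumptions — not that
the model finds such structure in real fMRI.

### Normalization and the synthetic group signal

`normalize_components` z-scores each component over a subject's full
timeseries (population variance convention). That is the right default for
real acquisitions with heterogeneous channel scales, but per-subject
centering removes the subject-level mean — and in the synthetic cohort the
between-group signal *is* a mean offset of the context factor. The
synthetic pipelines therefore run with `normalization: none` (the
generator's unit-norm mixing rows already give comparable channel scales);
with z-scoring enabled the synthetic group contrast is erased by
construction, which is a useful reminder that subject-level normalization
choices interact with between-subject questions.

## Evaluation suite

* **Window classification**: linear SVM (squared hinge, C = 1, nothing
  tuned) fit on train+val context embeddings, scored on test windows.
  Splits are by subject — windows of one subject never cross splits — and
  are stratified by diagnosis with largest-remainder rounding.
* **Cross-seed reliability**: for every ordered seed pair, OLS from one
  seed's embeddings to another's, fit on train+val rows, R² (uniform
  average over output dimensions) on held-out test rows; the mean over
  pairs is reported. Held-out evaluation is the conservative reading where
  the protocol names only the fitting set.
* **Manifold comparison**: Euclidean distances between the same windows in
  two spaces (model embeddings vs vectorized wFNC), each distance vector
  z-scored, simple linear regression of one on the other, R² reported.
  Above ~10⁶ pairs a seeded uniform subsample (without replacement) is
  used.
* **Clustering**: k-means (k-means++ init, 10 restarts) on patient windows
  in context space, k = 3 by default (configurable; 3 matches the
  motivating analysis). Dwell statistics per cluster: Welch two-sided
  t-test on a covariate between patients with ≥1 window in the cluster and
  those with none, and Pearson correlation between per-patient window
  counts (raw and normalized by the subject's window total — both are
  reported, since the convention is ambiguous) and the covariate. Raw
  p-values are reported alongside a Bonferroni column; no correction is
  applied by default. Cluster wFNC maps subtract the all-patient mean wFNC
  from each cluster's mean wFNC; their size-weighted sum is the zero matrix
  (up to float accumulation, ~1e-15).

## Numerical choices and degenerate inputs

* wFNC requires nonzero within-window variance per component; violations
  are hard errors naming the component and window, never silent NaNs.
* PCA for the wFNC baseline is fit on train+val only and centers but does
  not standardize by default (flag available); component signs follow the
  largest-|loading|-positive convention.
* Largest-remainder split rounding breaks ties toward the earlier split
  (train before val before test). k-means ties and restarts follow
  scikit-learn semantics with a fixed seed.
* Degenerate dwell statistics (constant covariate, a t-test side with < 2
  subjects) return 0/1 or NaN rather than raising.
* Embedding tables round-trip losslessly through TSV (floats written with
  shortest-round-trip repr and parsed with the exact reader).

## Scale of the shipped experiments

The test suite and the acceptance script run the full pipeline at the
default study conditions (100 subjects, 160 timesteps, ~3300 windows,
20-epoch training runs) — sizes chosen so a complete run takes minutes on
a single CPU core while leaving the measured effects (classification
accuracy near the oracle ceiling, recovery R² near 1) far from their
decision thresholds. The end-to-end determinism check uses a deliberately
small cohort (2 × 6 subjects), since determinism is size-independent.

## Known limitations

* The classification ceiling on the synthetic cohort is set by the overlap
  of the two groups' context distributions (the oracle on true
  window-averaged factors reaches ≈0.83 at offset norm 2); reported
  accuracies should be read against that ceiling, not against 1.0.
* One posterior sample per window makes the recorded per-epoch loss values
  stochastic (though seeded); they are selection quantities, not precise
  likelihood bounds.
* The one-sample path KL for the autoregressive prior is an upper-noise
  estimate of the marginal KL; β therefore regularizes a surrogate.
* CPU-only backend: wall-clock scales linearly in windows × epochs; the
  architecture is sized for tens of channels, not voxel-level data.
* How the original analysis combined `z_c` with the window sequence in the
  local encoder is underdetermined in its description; broadcast
  concatenation per timestep is this package's reading, and the LS/CS
  labeling of the visualized model is treated as configuration, not fact.
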