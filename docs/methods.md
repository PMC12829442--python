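# Methods

This note records the models, the defaults and the design decisions behind
`edal`, in the package's own words. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic data generator

The generator (`edal.datasets`) emulates the structure of an
out-of-distribution active-learning study on solvation free energy without
any chemistry: molecules are rows with a fixed-length descriptor vector, an
optional SMILES slot (left empty by synthetic data), a target in
kcal·mol⁻¹, a source tag and a small-integer "element palette" category.

**Feature model.** Both sources are Gaussian mixtures with unit within-
cluster covariance. The `k_in` in-distribution clusters sit at graded radii
`(0.5 … 3.0) × cluster_spread` from the origin along random directions —
molecular families ranging from typical to exotic. The graded placement is
deliberate: with isotropic cluster placement in `d = 10`, distances from the
centroid concentrate sharply (an interquartile spread of only ~1.5× in
σ², by direct computation during design), which would make the
heteroscedastic noise statistically unrecoverable from a few thousand
points; graded radii give the noise model a recoverable signal. Each of the
`k_ood` OOD clusters reuses an in-distribution base mean displaced by
`shift_scale` along a direction that mixes a library-wide drift
(`drift_coherence = 0.7`, the systematic difference between two libraries)
with a cluster-specific component. OOD cluster weights equalize the total
mass per base mean, so at `shift_scale = 0` the two feature distributions
are *exactly* equal — the exchangeability limit is by construction, not by
approximation.

**Target model.** Labels follow `y = f(x) + offset_c + ε(x)` with
`f(x) = w·x + 1.5 sin(x_i x_j / 4)` — a linear term plus one smooth
sinusoidal interaction whose length scale (4 descriptor units²) keeps it
learnable at the data scale; coefficients are fixed by the config seed. The
per-cluster offsets are parameterized through *levels*: the stored offset
cancels the linear term's cluster-mean contribution, so each cluster's
typical target is an independent N(0, 1) level. This keeps the
in-distribution target distribution symmetric regardless of the geometry. A
`tail_weight` fraction of OOD clusters instead receives strongly negative
levels `−(tail_shift + |N(0, 1.5)|)`; these tail levels are assigned to the
OOD clusters *farthest from the in-distribution centroid*, coupling extreme
targets with exotic chemistry the way outlier molecules couple extreme
solvation energies with unusual structures. This coupling is what makes
uncertainty-guided selection informative rather than merely noise-seeking.

**Noise model.** `ε(x) ~ N(0, σ²(x))` with
`σ(x) = noise_base + noise_slope·‖x − c_in‖`, where `c_in` is the
in-distribution centroid: labels get noisier for molecules farther from the
training distribution, emulating the larger solvation-free-energy
calculation error for large or flexible molecules.

**Defaults** (the desk-scale study conditions): `d = 10`, `n_in = 1000`,
`n_pool = 2000`, `n_test = 300`, `k_in = 5`, `k_ood = 24`,
`shift_scale = 3`, `tail_weight = 0.2`, `noise_base = 0.1`,
`noise_slope = 0.3`, `palette_fraction = 0.2`, `cluster_spread = 3`,
`tail_shift = 6`. The pool is deliberately more diverse than the source
(24 vs 5 clusters): 250 acquisitions spread over 24 clusters leave the pool
under-covered, which is the regime in which prioritized selection can beat
uniform coverage — with a handful of OOD clusters, random sampling covers
everything within a few rounds and the comparison degenerates.
`paper_scale_config()` switches to the published sizes (8795 / 22573 / 331).

**What the generator does not emulate.** Real descriptor correlations and
discreteness, scaffold structure, label noise that depends on conformer
search failures, and any actual chemistry. Passing tests show that the AL
machinery, the uncertainty model and the statistics behave correctly under a
controlled shift with known ground truth — not that any particular chemical
dataset will show the same effect sizes.

## Evidential regression model

`EvidentialRegressor` is a scikit-learn-style estimator: two dense hidden
layers with ReLU and dropout, and a four-output NIG head with transforms
`γ` unconstrained, `ν = softplus(·)`, `α = 1 + softplus(·)`,
`β = softplus(·)` (all shifted by 1e−6), trained with Adam on
`mean(NLL + λ·|y − γ|(2ν + α))` in minibatches. Features are z-scored with
training-set statistics refit at every AL iteration (pool and test are
transformed with the training statistics, never refit on them); the target
is standardized internally and predictions are mapped back, with β scaled by
the squared target scale so all reported quantities are in kcal·mol⁻¹.
Early stopping monitors the validation loss on a random `val_split` fraction
and restores the best-validation weights. Gradients of the loss with respect
to all four NIG parameters are analytic (digamma terms included) and are
finite-difference-checked in the test suite.

**Global ν.** Algebraically, the evidential NLL depends on (ν, α, β) only
through the Student-t predictive scale `σ_t² = β(1 + ν)/(να)` and the
degrees of freedom 2α: substituting β = σ_t²να/(1 + ν) cancels ν from the
loss entirely. A per-input ν is therefore not identified by the data; its
spatial pattern is set by optimizer dynamics and the evidence penalty, and
during design it was observed to corrupt the aleatoric readout β/(α − 1)
with arbitrary sign. `edal` consequently learns ν as a single global scalar
(a trainable bias; the corresponding weight column is held at zero), while
γ, α and β remain input-dependent. All formulas and the four-parameter
output are unchanged; the known consequence is that the three uncertainty
modes (aleatoric, epistemic, total) rank candidates identically and differ
only in scale.

**Hyper-parameters.** The published training configuration is the default:
hidden dims (128, 576), dropout (0.11, 0.60), learning rate 5e−4, batch 64,
up to 1000 epochs, patience 25, validation split 0.1. The evidence-penalty
coefficient λ is not a published value; the default is 0.01 (the scale used
in the evidential-regression literature) and it is exposed in the config.
Unpublished details decided here: ReLU activations, He initialization for
the trunk, zero-initialized evidence head, Adam with library defaults beyond
the learning rate, dropout disabled at inference, validation split drawn
with the run seed.

`desk_scale_model_params()` is the configuration used by the experiments
and tests in this repository: hidden dims (16, 16), dropout (0.05, 0.10),
learning rate 1e−3, max 400 epochs, patience 30. The small trunk is a
deliberate capacity control: with ~2000 training points, larger networks
memorize the training noise before the variance field is learned (validation
loss bottoms out within ~15 epochs and the heteroscedastic signal never
develops), whereas the small trunk trains in about a second and recovers the
noise ranking reliably.

**Checkpoint format.** A single JSON file (versioned) holding the estimator
parameters, weights, feature/target standardization statistics and the best
validation loss.

## Active-learning loop

One iteration: rank the pool (by predicted variance for the EDL arm, or
uniformly at random), move the top `N` — ties broken by ascending molecule
id for determinism — into the training set, label them through the oracle
(called exactly once per molecule, before any state mutation, so an oracle
failure leaves the state untouched), retrain from scratch, evaluate on the
fixed test set. Retraining is cold-started with a per-(run, iteration) seed:
warm starts would entangle the arms' optimization histories with the
acquisition policy. Pool exhaustion stops the loop early and is logged, not
an error.

Within a run the two arms are paired: identical initial split, identical
initial model (trained once and shared), identical per-iteration model
seeds. Pairing removes the split-to-split variance from the comparison; the
statistics module defaults to the paired t test accordingly, with Welch
available for unpaired use. Whether the original study paired its arms is
not documented; the choice is logged in every comparison.

The synthetic oracle is a lookup of the generator's own labels; the
interface is a plain `id -> float` callable so an external labeling workflow
can be plugged in unchanged.

## Distribution-shift and calibration metrics

**Fréchet distance.** The squared Fréchet (Wasserstein-2) distance between
Gaussian summaries, `‖μ_a − μ_b‖² + Tr(Σ_a + Σ_b − 2(Σ_a Σ_b)^{1/2})`,
reported on the squared scale as is conventional for FCD. The cross term is
computed as the trace of the PSD square root of `Σ_a^{1/2} Σ_b Σ_a^{1/2}`
via symmetric eigendecomposition with eigenvalues clamped at zero — robust
for near-singular covariances; degenerate covariances get 1e−6 diagonal
jitter (logged). The embedder is injected; the default embeds a pair of sets
by z-scoring with their pooled statistics (scale-free, symmetric, exactly
zero for identical sets). A pretrained chemical-network embedder can be
passed as a plain function; none is bundled. `bootstrap_internal_fcd`
implements the internal baseline: random disjoint half-sample splits,
FCD between halves, mean ± sd over (default) 20 iterations.

**ENCE.** Predictions sorted by predicted variance into equal-count bins
(remainder to the last bin; the bin count defaults to 10), per-bin
RMV = √(mean variance) and RMSE = √(mean squared error), and
`ENCE = mean_k |RMV_k − RMSE_k| / RMV_k`. Equal-count binning follows the
metric's source literature; the per-bin table is exported for calibration
plots.

**Diversity entropy.** Plug-in Shannon entropy (natural log) over category
frequencies. Scaffold/functional-group categorizers are out of scope; any
hashable labels work.

## Comparison statistics

One-tailed tests oriented so the alternative is "EDL better" (lower RMSE,
higher R²): paired t by default, Welch otherwise, p-values floored at
1e−300 before the −log₁₀ transform. Cohen's d uses the pooled-SD formula
`(m₁ − m₂)/s_pooled` exactly as printed in the source literature even in the
paired design, signed so positive favors EDL, and classed at |d| = 0.2 /
0.5 / 0.8. Degenerate inputs (zero pooled variance) map to d = ±∞ and the
p-value floor, or to p = 0.5, d = 0 for identical arms. R² may be negative
for predictors worse than the mean; the implementation allows this and the
"ranges from 0 to 1" description found in textbooks is treated as the usual
case, not a constraint.

## Problem sizes

The experiments shipped in the tests and the acceptance script use the
desk-scale conditions: 10 paired runs × 10 iterations × batch 25 on the
1000/2000/300 bundle, the uncertainty-recovery experiment at 2000 training
and 1000 held-out molecules, and 20-fold bootstrap baselines. These sizes
are the package's chosen study conditions; paper-scale sizes are available
through `paper_scale_config()` and the same code paths.

## Known limitations

- The EDL-vs-random outcome depends on the coupling between uncertainty and
  learnable structure. In this generator, predicted variance tracks
  feature-space extremity; uncertainty-selected batches therefore
  concentrate in extreme clusters, and the FCD between the EDL arm's
  training set and the pool *rises* over iterations at desk scale (the
  acquisitions are ~20 % of the training set), even though the same arm wins
  on RMSE. Larger-scale studies, where additions perturb the training
  distribution far less, report the FCD falling for both arms while still
  observing that uncertainty selection diverges more than random selection.
- With ν global, epistemic and aleatoric uncertainty rank candidates
  identically; the decomposition's scales remain meaningful but acquisition
  cannot distinguish the two sources of uncertainty.
- The evidential network is plain NumPy on one CPU; it is sized for
  thousands of molecules and tens of descriptors, not for deep chemistry
  models.
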