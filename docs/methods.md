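# Methods

This note documents the model and procedures implemented in
`pharmadapt`, the assumptions behind the synthetic-data generator, and
the numerically consequential choices, in enough detail that every
reported number can be traced to a decision made here.

## Model

The network is deliberately shallow: encoder L (d→k, one fully
connected layer + ReLU), task layer S (k→T), decoder A (T→k, no bias),
a learnable per-task log noise scale, and a single-layer logistic domain
discriminator on the latent features. All arithmetic is numpy float64;
gradients are hand-derived reverse-mode (validated entry-by-entry
against central finite differences in `tests/test_gradients.py`).

**Heteroscedastic task loss.** ℓ_t = mse_t/(2σ_t²) + log σ_t with
σ_t = exp(log_sigma_t) learnable. The per-task mse uses one stochastic
(dropout) pass per minibatch — standard MC-dropout training; the P-pass
machinery is reserved for prediction and uncertainty. For a fixed mse
the minimizer is σ_t = √mse_t, so σ_t converges to each drug's
irreducible error scale and attenuates its gradient accordingly.

**Epistemic uncertainty.** Dropout (inverted, rate p) is applied to the
encoder input and — switchable, on by default — to Z before the task
layer, at train and test time. U_t(x) is the variance over P passes
with the population 1/P normalization, exactly as specified (not the
1/(P−1) sample form); with dropout off the passes are bit-identical and
the variance is hard-zeroed rather than left to float cancellation. The
per-task scalar U_t averages the per-sample variances over the drug's
observed training samples and is refreshed once per epoch. U_t is a
constant during backpropagation: it gates the loss, it is not a target,
and letting gradients flow through it would reward variance shrinkage
for the wrong reason.

**Transfer gate.** The printed form of the weighting
(1 + (U_t + ‖a_t‖₁)) and the surrounding prose ("U_t weights a_t")
conflict; both are implemented. The default "product" mode
w_t = 1 + U_t‖a_t‖₁ follows the prose — the uncertainty scales the
pressure on the decoder row, so an uncertain drug is pushed toward a
sparse a_t and transfers less into the shared space. The "sum" mode is
the literal print. The loss-weighted baseline has the same ambiguity
(α multiplying the loss vs. the printed (1+α‖a_t‖₁)ℓ factor); both
readings are implemented, with the loss treated as a detached scalar
inside the gate in the prose reading. Experiments must state the mode;
every protocol here uses the defaults (product / prose).

**Reconstruction.** γ‖Z − Ω(ZSA)‖²_F computed on the same
(post-dropout) Z as the prediction path of that step, since the source
formulation leaves this unstated and reusing the stochastic Z keeps one
forward pass per step.

**Initialization.** Fan-in-scaled Gaussians for L and the
discriminator; log_sigma starts at 0 (σ_t = 1, attenuation weight 0.5).
The task columns of S and rows of A start *identical* (one shared
random vector each): every drug begins from the same prior predictor,
which makes training exactly equivariant to the ordering of drug
columns — a property the test suite asserts. Per-drug gradients break
the symmetry at the first step.

## Optimization

Supervised training uses Adam (fixed learning rate from the config) on
minibatches, single-threaded and bit-deterministic given the seed.
Early stopping monitors MSE on a held-out source validation split
(default 10%) and returns the best-epoch parameters; `patience` can cut
training short, otherwise all epochs run.

The adversarial min-max deliberately does **not** use Adam. With
adaptive per-parameter step normalization the encoder overshoots the
discriminator and learns to *flip* the domains across the decision
boundary instead of aligning them (observable as the adversarial
cross-entropy collapsing to 0 while a fresh probe still separates the
domains perfectly). The game is therefore played with plain SGD: the
discriminator descends its cross-entropy with step `disc_lr` and an ℓ2
decay `disc_l2` that bounds its logits — without the decay a saturated
discriminator emits vanishing gradients and the reversed signal dies —
while the encoder takes the lam_adv-scaled, sign-reversed gradient with
step `adv_lr`. Several adversarial sub-steps (`adv_steps`) may run per
supervised step so the equilibrium holds against the larger supervised
updates. At the confusion equilibrium the adversarial loss sits at
2·log 2 ≈ 1.386. With lam_adv = 0 the domain-adaptation loop reduces
bit-exactly to supervised training (no adversarial code runs, no RNG is
consumed).

For the domain-adaptation protocol the validation snapshot is disabled
(val_fraction = 0, i.e. the final epoch is returned): a source-MSE
snapshot can predate encoder alignment, which source-only validation
cannot detect.

## Synthetic data

The generator emulates the structure the method exploits, nothing more:

- Expression is iid standard normal per gene — already "standardized";
  no transcriptomic covariance, batch structure or tissue identity.
- Per-drug weights w*_t = L*s*_t share a rank-k* subspace; designated
  outlier drugs draw dense weights independent of the bases
  (conditionally unrelated tasks, the generative picture of an
  unreliable predictor). Every weight vector is rescaled to a fixed
  signal SD (default 3.0), mirroring response matrices whose per-drug
  scale is comparable after preprocessing; without this the per-drug
  signal-scale spread dominates the MC-dropout variance and noise-scale
  recovery is confounded.
- Responses add iid Gaussian noise with per-drug SD σ*_t. Gaussianity
  is an assumption of convenience, not evidence.
- Missingness is block-structured (drug t observed on the first N_t
  samples), mirroring per-drug cohort sizes; a uniform-random mask is
  available for robustness tests.
- The target domain redraws from the same latent process and applies a
  per-gene affine transform x → scale·x + shift, modeling a
  measurement/platform distortion. The biological response rule is
  defined on the undistorted draws; drugs in `violated_tasks`
  additionally change their weight vector (negated by default), so no
  marginal alignment can rescue them. Hidden target responses and
  median-split responder labels are returned only as evaluation truth.

What passing tests on this generator do **not** show: behavior under
correlated expression, non-Gaussian or heavy-tailed response noise,
nonlinear response rules, or real batch structure.

## Study conditions (the protocols in `pharmadapt.experiments`)

Problem sizes are desk-scale — 50 genes, 10–15 drugs, cohorts of
20–700 — chosen so each protocol runs in seconds while preserving the
regime under study.

- **Noise-scale recovery.** 10 drugs, N_t = 400, true σ*_t spanning
  0.1–2.0; model latent width 32 (≈4× the true rank, enough for ±ReLU
  pairs to represent the linear truth), dropout 0.1, 200 epochs.
  Measured: Spearman(σ_t, σ*_t).
- **Epistemic vs cohort size.** Matched noise σ* = 5.0 for all drugs —
  set so the population R² ≈ 0.26 matches the predictive-accuracy
  regime reported for in vitro panels (Pearson ≈ 0.5) — with three
  drugs at each of N_t ∈ {20, 50, 100, 400, 700}. Latent width 16, at
  the scale of the true rank: prediction variance under fixed-rate
  dropout tracks the fitted function norm, whose estimation inflation
  peaks near the model capacity; keeping capacity at or below the
  smallest cohort puts every drug in the classical regime where the
  inflation — and hence U_t — decreases with N_t. Measured: Spearman
  between cohort size and the per-size mean U_t.
- **Negative transfer.** 10 drugs (σ = 2), two outliers, two cohorts of
  30, base cohorts of 100 (a scaled-down panel where joint training has
  real room to help or hurt), 75/25 train/test split, ridge penalty 20
  (≈ σ²d/‖w‖², the oracle-optimal scale). NT per drug is the strict
  sign of MSE_model − MSE_ridge. The clean-task comparison against the
  shared-latent baseline is read one-sidedly (the uncertainty machinery
  must not cost more than 5% clean-task MSE; being better is
  compliant).
- **Domain adaptation.** Per-gene shift drawn N(0, 1.5²) — far larger
  than the within-domain spread, so a linear probe on random-encoder
  features separates domains at >0.9. The two violated drugs are also
  the unreliable ones in the source (N = 100, σ = 5): uncertainty is
  estimated on source data only, so the premise under test is that
  source-side unreliability flags the drugs that fail to translate —
  the method's own modeling assumption, made explicit here. Measured:
  held-out accuracy of a fresh logistic probe on frozen features before
  and after training, target MSE on transferable drugs vs the
  lam_adv = 0 ablation, and the violated/transferable transfer-weight
  ratio.

## Evaluation conventions

- Nested CV partitions *samples* (cell lines), never per-drug rows;
  the inner loop scores hyperparameter candidates by inner-validation
  MSE (random search; the search strategy is pluggable).
- The responder test is one-sided with the alternative "responders have
  lower predicted response" (lower = sensitive). The effect size is the
  common-language U/(n₁·n₂) — the probability that a random responder's
  prediction is below a random non-responder's — matching bracketed
  effect values in [0, 1] with 1.00 attainable. scipy selects the exact
  null for small tie-free samples, the tie-corrected normal
  approximation otherwise.
- Spearman on constant input is undefined and returned as NaN with a
  warning rather than silently as 0.
- Integrated gradients use the midpoint Riemann rule on the straight
  path from an all-zeros baseline (= population mean on the
  standardized scale; configurable), with dropout disabled. Cohort
  attributions average per-sample attributions. Exact for effectively
  linear models; on trained ReLU networks the completeness gap at 256
  steps is ~0.1–0.3% of F(x) − F(baseline).

## Numerical details and limitations

- Checkpoints are a custom container (JSON manifest + raw float64
  segments) because zip-based formats embed timestamps and break
  byte-level reproducibility.
- Probabilities are clamped to [1e-7, 1−1e-7] before logs in the
  adversarial loss; ‖L‖²_F penalizes weights only, not biases; ℓ1
  subgradients use sign(0) = 0.
- TSV floats are written with `repr` (17 significant digits) and read
  with round-trip float parsing, so write→read is exact.
- Divergence (non-finite loss) aborts training with a diagnostic rather
  than returning garbage.
- The discriminator is binary (one source, one target domain);
  multi-domain studies train one model per source–target pair. No
  multi-layer encoders, no per-sample aleatoric heads, no alternative
  alignment divergences (MMD, Wasserstein) — all out of scope.
- The adversarial equilibrium is monitored, not guaranteed: probe
  accuracies land near but not always inside [0.4, 0.6] for an
  occasional seed; the protocols report per-seed values for that
  reason.
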