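# Methods

## The adaptive momentum schedule

The optimizer augments classical momentum backpropagation with an
epoch-varying coefficient

    α(n) = β / (1 + exp(−1/√(E(n)·E(n−1)))),   β ∈ (0, 1),

driven by the epoch error sequence E(n). Because the logistic argument
1/√(E(n)E(n−1)) is positive, α(n) is confined to (β/2, β]; it is
non-increasing in the geometric mean of the last two errors, with
analytic limits α → β as errors vanish and α → β/2 as they diverge.
The forgetting factor β (default 0.9, the schedule's only tunable,
dimensionless) is the supremum of the momentum actually applied.

Interpretation choices the schedule leaves open, and how this package
resolves them:

* **What E(n) is.** E(n) is the mean training cross-entropy of epoch n
  — the quantity the loss (categorical or summed binary cross-entropy)
  defines and the training loop already tracks. A misclassification-rate
  alternative is available via `RunConfig(error_kind="error_rate")` but
  is not the default.
* **Update cadence.** α is refreshed once per epoch and held fixed for
  every minibatch update of the following epoch. Per-step adaptation is
  deliberately not implemented: the schedule is defined on epoch errors.
* **Scope.** One global α for all parameter groups. A per-hidden-unit
  coefficient would be a different algorithm and is not implemented.
* **Bootstrap.** α needs two errors before the first epoch has run. The
  harness evaluates the initial loss E(0) with one eval-mode pass over
  the training set and self-pairs it (E(−1) := E(0)). This makes the
  first epoch's momentum well defined and consistent with the schedule.
* **Zero-error guard.** When E(n)·E(n−1) ≤ 10⁻³⁰ the exponent
  diverges; the implementation returns the analytic limit β, keeping
  the schedule continuous instead of dividing by zero.
* **No bias correction.** The schedule is applied literally; no
  (1 − βⁿ)-style correction factor is introduced.

The momentum update per parameter group is Δw ← αΔw − η(∇E + 2λw),
w ← w + Δw, with learning rate η (default 0.01) and L2 coefficient λ
(default 5·10⁻⁴) entering as the gradient of λ‖w‖²; biases and
batch-norm scale/offset are exempt from decay, matching common
practice. Baselines (plain SGD, fixed momentum, Adam, RMSprop) share
the same functional update-step contract and the same weight-decay
handling; Adam and RMSprop run at learning rate 0.001, β₁ = 0.9,
β₂ = 0.999, ε = 10⁻⁷, the comparison protocol's standard settings.

## The network engine

The network is a plain-NumPy layered model with manual gradients:
conv2d (cross-correlation orientation, no kernel flip, 0-based
indexing, floor division for strided output sizes, same/valid padding),
dense, batch normalization, inverted dropout, max pooling, flatten,
ReLU, and softmax/sigmoid heads fused with the cross-entropy loss
(output pre-activation gradient (q − p)/N). Correctness is pinned by
central finite-difference oracles (step 10⁻⁵, relative tolerance 10⁻⁴)
over every layer kind, with dropout masks frozen by seed.

Numerical choices: softmax is computed shift-invariantly; probabilities
are clipped at 10⁻¹² before logs; batch-norm uses ε = 10⁻⁵ and running
statistics with EMA weight 0.9 (train mode uses batch statistics, eval
mode running statistics); dropout uses inverted scaling so eval needs
no rescaling; weights are initialized with seeded He-style fan-in
uniform scaling, BN scale 1 / offset 0. Forward passes are pure
functions; BN running-statistic updates are returned in the cache and
applied explicitly by the training loop, which is what makes every run
bit-replayable.

The reference architecture is conv(32, 3×3, same) → BN → ReLU →
dropout 0.3 → conv(64, 3×3, valid) → BN → ReLU → maxpool(4×4, stride 4)
→ conv(128, 3×3, same) → BN → ReLU → flatten → dense(512) → BN → ReLU →
dropout 0.5 → dense(n_outputs) head. For a 64×64×3 input the stage
shapes are 64×64×32 → 62×62×64 → 15×15×64 → 15×15×128 → 28 800 → 512,
with parameter counts 896 / 18 496 / 73 856 / 14 746 112 and 4 per
batch-norm channel (scale, offset, running mean, running variance).
The head on 512 inputs has the standard units·513 parameters. ReLU
follows each batch-norm stage; activations add no parameters and leave
the shape chain unchanged. The pooling stage requires spatial input of
at least 16×16.

## Synthetic tasks

The generators emulate the *statistical shape* of three clinical
classification settings — multiclass (tumor-type-like), multilabel
(co-occurring findings), binary (lesion/no lesion) — not their imagery:

* multiclass: one elliptical blob per image; each class has a distinct
  radius, eccentricity and intensity; blob position and orientation are
  random; labels drawn from a configurable simplex of proportions.
* multilabel: each label has a fixed pattern location on a ring; labels
  are independently present with configurable prevalences; patterns add.
* binary: lesion blob present vs. plain background — linearly separable
  when noiseless, which the tests exploit with a logistic-regression
  probe.

Pixel noise is additive Gaussian (default SD 0.1 on the unit intensity
scale) with clipping to [0, 1]; noise controls task difficulty. All
generators are pure functions of their `TaskSpec` (seed included).
What passing tests on these tasks show is that the training engine and
optimizers behave as specified under controlled conditions; they say
nothing about performance on real medical images, which differ in
resolution, texture, label noise and class structure.

Class imbalance is handled by inverse-frequency class weights
w_c = n/(K·n_c) (mean ≈ 1, invariant to dataset duplication) applied
multiplicatively inside the loss. Stratified train/test splitting
preserves class proportions.

## Convergence diagnostics and benchmarks

`convergence_report` turns the schedule's qualitative convergence
claims into measurements on any loss history: the fraction of steps
with E(n+1) ≤ E(n) + tolerance, the spread of the last k losses (limit
detection), and the final gradient norm. `convergence_speedup` reports
the ratio of first epochs at which two histories reach a target loss.

The quadratic benchmark minimizes E(w) = ½ wᵀHw with H = diag(0.25,
0.2), η = 0.01, full-batch steps (each step treated as an epoch). The
curvatures were chosen once so that the heavy-ball recursion stays
overdamped for every α ≤ 0.9 (ηλᵢ ≤ (1 − √α)² ≈ 0.00263): both modes
then decay monotonically with real contraction factors, so the loss
decreases at every step and the gradient norm passes below 10⁻⁶ within
500 steps while still exercising the full α range of the schedule.
With an under-damped choice the loss would spiral and the monotonicity
diagnostic would read noise rather than the schedule's behavior.

The scaled-down optimizer comparison fixes its study conditions once:
4 classes with proportions 0.4/0.3/0.2/0.1 (imbalance comparable to
the motivating datasets), 16×16 images (the smallest input the
reference architecture admits), 400 samples, noise SD 0.1, test
fraction 0.25, class weights on, batch 32, 5 epochs, learning rate
0.01 for both SGD and adaptive momentum, β = 0.9, λ = 5·10⁻⁴, five
seeds. These sizes keep a full two-optimizer, five-seed comparison in
the low minutes on one CPU while leaving the task unsaturated within
five epochs. At this scale the adaptive optimizer consistently reaches
a lower training loss than plain SGD; final test accuracy on a 100-item
test set carries sampling noise of a few points, so the comparison is
evaluated directionally (mean over seeds), not as a fixed margin.

## Degenerate inputs and failure policy

Zero-denominator metrics raise `UndefinedMetricError` instead of
returning 0; non-finite training loss raises `DivergenceError` naming
the epoch (RMSprop-style instability is surfaced, never masked);
shape-incongruent gradients raise `CongruenceError`; impossible
architecture chains raise `SpecError` at spec construction, never a
silent mismatch. Constant images min-max-normalize to all zeros;
foreground cropping returns all-dark images unchanged.

## Known limitations

* The engine is CPU-bound NumPy intended for desk-scale experiments;
  no accelerator execution, no autodiff.
* No Nesterov momentum, learning-rate schedules, or per-parameter
  adaptive momentum variants.
* Multilabel accuracy is reported micro label-wise; exact-match
  accuracy would be stricter.
* The synthetic renderer makes no claim to anatomical realism; Bayes
  error is controlled only through pixel noise and class geometry.
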