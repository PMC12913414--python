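# Methods

This note documents the models, the synthetic data generator, the training
protocols and the numerical choices behind `alignnet`. The package couples a
spiking (SNN) autoencoder for multi-channel spike counts with an artificial
(ANN) autoencoder for 2-D movement trajectories, aligns their latent spaces
with a symmetric contrastive objective, and evaluates spike→behavior
decoding and behavior→spike simulation under single-day and cross-day
protocols.

## Data model

A *trial* is a pair: a spike-count matrix `S ∈ ℕ^{64×100}` (64 electrode
channels, 100 bins at 50 Hz, i.e. 2 s) and a cursor trajectory
`B ∈ ℝ^{2×100}`. Trials carry a recording-day index; a *session* is one
day's trials and is the unit of the train/test protocols.

## Preprocessing chain

From a continuous recording (multi-channel voltage at a high rate plus a
lower-rate 2-D joystick trace) to aligned trials:

1. **Spike detection.** Per channel, the noise scale is the median absolute
   deviation divided by 0.6745; the threshold is −4.5× that scale.
   Sub-threshold samples separated by less than one refractory window
   (default 1 ms) are merged into a single excursion; the event is timed at
   the excursion minimum, and events closer than the refractory window to
   the previous event are suppressed. Merging before timing matters: noise
   can push a sample inside a spike trough back above threshold, and
   without merging one action potential splits into two events.
2. **Spike-matrix reconstruction.** Events are counted into half-open bins
   `[t/r, (t+1)/r)`; total count is conserved.
3. **Behavior interpolation.** Linear interpolation maps a length-`m`
   sequence to length `n` via `y[j] = (1−α)x[⌊p_j⌋] + αx[⌈p_j⌉]` with
   `p_j = j(m−1)/(n−1)`; endpoints are exact, and affine sequences are
   reproduced exactly.
4. **Downsampling.** Spike counts are summed over consecutive windows of
   `I` bins (count-conserving when the length divides; a trailing partial
   window is dropped with a warning, because a short last bin would have a
   biased rate). Behavior is downsampled with the same interpolation
   operator.
5. **Gaussian smoothing** (behavior only, default σ = 2 bins, half-width
   3σ). The printed Gaussian weights do not sum to one at finite width, so
   they are renormalized; the filter is then a convex combination that
   preserves constants and the input range. Edges are handled by
   replication.
6. **Segmentation** into fixed 100-point trials; short trailing segments
   are discarded.

Conventions: 0-based indexing, half-open bins throughout, float64 in the
whole chain.

## Synthetic center-out cortex

The generator stands in for primate motor-cortex recordings that cannot be
redistributed, emulating their shape: an 8-direction center-out joystick
task with 64-channel motor-cortical spiking at 50 Hz.

* **Behavior:** minimum-jerk reaches from the origin to unit-radius
  targets, position profile `10s³ − 15s⁴ + 6s⁵`, plus Gaussian position
  noise (sd 0.02 of the reach radius). Directions cycle deterministically
  through the 8 targets so small sessions stay class-balanced. The stored
  behavior is the Gaussian-smoothed noisy trajectory — what the
  preprocessing chain would deliver.
* **Spiking:** rectified cosine tuning on instantaneous velocity
  (the standard M1 encoding model):
  `rate_c(t) = b_c + g_c · speed(t) · max(0, cos(θ(t) − pd_c))`, with
  Poisson counts per 20 ms bin. Channels 1–32 are behavior-relevant
  (gain U(20, 40) Hz·s/unit, baseline U(2, 8) Hz, preferred directions
  tiling the circle with jitter); channels 33–64 are behavior-irrelevant
  (gain 0, baseline U(0.5, 2) Hz), mirroring recordings where the upper
  channel groups carry little movement information.
* **Cross-day drift:** per day, preferred directions rotate (default
  0.1 rad/day), gains scale (×0.95/day), baselines jitter (sd 0.5 Hz,
  cumulative), and channels drop out permanently (p = 0.02/day). Day 0 is
  always the undrifted reference; everything is deterministic given the
  drift seed.
* **Raw fidelity:** each count expands into a fixed negative-deflection
  template placed at jittered, evenly spaced offsets inside its 20 ms bin
  over Gaussian noise (default template amplitude 5× the noise sd);
  behavior is resampled to a joystick rate. The default emulation rate is
  3 kHz rather than a full acquisition rate — desk-scale, configurable —
  and the template's support is therefore defined in **samples** (a
  4-sample flat trough with raised-cosine shoulders), preserving the
  multi-sample trough a real trace would give the detector. Ground-truth
  event times are retained so the detection→binning round trip can be
  scored; at the default SNR the chain recovers ≈97% of per-bin counts.

What the generator does **not** emulate: non-Poisson count statistics
(refractory-induced underdispersion, bursting), correlated noise across
channels, waveform diversity and overlapping units, behavioral variability
beyond additive noise (reaction times, curved or corrected reaches), and
slow within-day nonstationarity. Passing benchmarks on this generator
therefore demonstrates that the pipeline and models behave as designed
under a known ground truth — not that the same R²/PCC values would be
reached on cortical recordings.

## LIF dynamics and surrogate gradient

The spike autoencoder's activation stage is a leaky integrate-and-fire
unit iterated along the trial's own time axis:

    V_t = H_{t−1} + (1/τ)(I_t − (H_{t−1} − V_reset))
    S_t = Θ(V_t − v_th)
    H_t = V_reset·S_t + V_t·(1 − S_t)

with τ = 2, v_th = 0.3, V_reset = 0. The update integrates the current
step's input against the previous step's post-reset potential (the two
index conventions found in the literature differ here; this one is
implemented and tested against hand-iterated traces). State is reset at
every trial — trials are
independent samples — and each activation layer keeps its own state. After
each 2×2 pooling stage the temporal axis is halved, so deeper LIF layers
simply run on the shorter axis.

Training through Θ uses an arctan surrogate: the backward pass substitutes
`w / (2(1 + (πwx/2)²))` (width w = 2.0) for Θ′, the derivative of the
scaled-arctan sigmoid. The reset pathway is kept in the gradient rather
than detached, so when the spike is replaced by its smooth companion the
hand-rolled backpropagation-through-time is the *exact* gradient of that
smoothed model — which is how the BPTT code is verified by finite
differences.

## Architecture

Both autoencoders are U-Nets over the one-plane (time × channel) image of
a trial; they share shapes but not weights.

* A per-time-point MLP first lifts behavior (2 dims) into the 64-channel
  space so both modalities enter identical trunks; its inverse maps the
  behavior decoder's output plane back to 2 dims. This shape-matching is
  what makes the cross-modal paths (spike encoder → behavior decoder and
  vice versa) well-formed, skip maps included.
* Encoder: k stages of [3×3 conv → BatchNorm → activation] ×2 followed by
  2×2 max pooling; the pre-pool feature map of each stage is kept as a
  skip. The bottleneck is a formal 1×1 average pool of stride 1 (an
  identity, kept so the stage structure reads uniformly), then a 1×1 conv
  to the latent width and a final activation. Activations are LIF in the spike trunk and ReLU in the
  behavior trunk.
* Decoder: k stages of [2×2 transposed conv (stride 2) → concatenate the
  matching skip → two conv-BN-activation blocks], then a 1×1 conv head to
  one plane. The simulate path adds a softplus so predicted counts are
  non-negative.
* When the 100-point time axis is not divisible by 2^k it is zero-padded
  symmetrically (k = 3: 100 → 104) and cropped on output.
* The latent is kept as the reduced-resolution map
  (D, S/2^k, C/2^k) — with the printed full-temporal-length latent the k
  downsamplings could not produce it — and is flattened for the
  contrastive term.

Defaults: depth k = 3, base width 32, latent D = 128. The benchmarks use a
reduced geometry (k = 2, base 4, D = 16; base 8/D = 32 for the memorization
probe) so that every experiment runs in minutes on one CPU; all sizes are
configuration fields.

## Objectives

Pretraining minimizes

    L = MSE(spike reconstruction) + MSE(behavior reconstruction) + λ·L_CL

with λ = 0.5. `L_CL` is the symmetric InfoNCE loss over a batch of N
matched pairs: flattened bottleneck embeddings are L2-normalized (chosen so
the temperature has its usual cosine-similarity interpretation; can be
disabled), inner products are scaled by temperature τ_CL = 0.07, and both
softmax directions (spike anchors over behavior candidates, and the
transpose) are averaged. Closed forms used as tests: N = 1 gives exactly
zero; embedding collapse gives ln N.

Reconstruction targets: spike reconstruction is computed on per-channel
z-scored counts (statistics from the training split); behavior on the raw
trajectories. Fine-tuning is plain supervised MSE on the cross-modal path —
decoding: spike encoder → behavior decoder against trajectories;
simulation: behavior encoder → spike decoder (softplus head) against raw
counts. Scope is "all" parameters by default, or "decoder-only" (encoders
and projections frozen). The contrastive term is off during fine-tuning by
default (a flag enables it).

## Protocols and benchmarks

* **Single-day:** a seeded shuffle of one session; the first ⌊0.8n⌋ trials
  train, the rest test.
* **Cross-day:** all trials of the two days preceding a held-out test day
  train; the held-out day tests.

The standard benchmarks (in `alignnet.benchmarks`, shared by the test
suite and `scripts/acceptance.py`) fix the following desk-scale
conditions, chosen once as realistic small-lab sizes:

* memorization probe: 8 trials, 500 full-batch steps, lr 4e-3;
* alignment probe: 200 one-day trials, 6 pretraining epochs;
* single-day decode: 160 trials (80/20), 8 pretrain + 20 fine-tune epochs,
  against a Wiener filter (5 lags ≈ 100 ms, ridge 10) fit on the same
  split;
* cross-day decode: 3 drifted days × 48 trials, pretrain 10 + fine-tune 20
  epochs versus from-scratch supervised training with the same total
  budget (30 epochs);
* round trip: 12 trials through the raw emulation and the full
  preprocessing chain.

Adam (lr 2e-3, batch 16) is used throughout the benchmarks; training is
deterministic given (seed, config, data) on a single device.

On these conditions the hybrid model decodes with R² ≈ 0.5–0.7 versus
≈ 0.3 for the Wiener filter, and pretraining improves the held-out-day
median R² over from-scratch training. Simulation PCC on synthetic data is
low (≈ 0.05–0.15 per channel) *by construction*: per-bin Poisson counts at
≈ 0.1–0.4 expected spikes per bin are mostly noise, and even the true
generating rate correlates with single-bin counts only at ≈ 0.14. The
simulate-path machinery is therefore validated by loss descent, head
contracts and metric correctness rather than by a PCC ordering.

## Baselines

* **Wiener filter:** ridge-penalized least squares from a causal window of
  L = 5 lagged input vectors (intercept unpenalized), solved by the normal
  equations; lags zero-pad at trial starts and never cross trial
  boundaries. `ridge = 0` on a singular system raises with advice.
* **MLP:** two hidden ReLU layers (default 256) on flattened trials.
* **GRU:** single-layer gated recurrent regressor over the 100-step axis
  with a per-step linear readout.

All baselines consume the same `SplitPlan` as the hybrid model, so no test
trial ever enters a fit.

## Evaluation

R² (`1 − Σ(y−ŷ)²/Σ(y−ȳ)²`) is reported per behavior dimension
with test trials concatenated along time, plus the dimension mean; this
pooled-concatenation convention is the package default (per-trial averaging
is available in the underlying functions). PCC is the standard centered
cross-correlation. Simulation reports per-channel PCC averaged over
channels with nonzero truth variance — the correlation is undefined on
silent channels, so they are excluded and counted. The binary firing rate
`FR[i] = (1/N)Σ_t 1{S[i,t] ≥ 1}` (fraction of active bins, per trial,
averaged across trials) feeds an 8-channels-per-group comparison table of
truth versus prediction.

Constant-truth R² and zero-variance PCC return NaN with a warning rather
than raising: evaluation of a batch should not abort on one degenerate
channel.

## Numerical engine

All trainable components run on a compact reverse-mode automatic
differentiation engine (`alignnet.nn`) over numpy arrays: broadcasting
elementwise ops, 2-D matmul, shape ops, reductions, 2-D convolution /
transposed convolution / 2×2 max pooling, and batch normalization (batch
statistics in training, running statistics — momentum 0.1 — in evaluation,
which makes evaluation deterministic). Convolution inner loops and the LIF
forward/backward recursions are JIT-compiled with numba (fastmath); the
convolution adjoint with respect to the input uses the flipped-kernel
identity for stride-1 kernels. Gradients accumulate, so weight sharing and
tensor reuse are handled. Every op's backward pass is tested against
finite differences; Adam (β = 0.9/0.999, ε = 1e-8) is the only optimizer.

Parameters are float32 (He-initialized from a seeded generator); the
preprocessing chain, metrics and closed-form tests run in float64.

## Known limitations

* Simulation quality on the synthetic task is bounded by Poisson bin noise
  (see above); smoothed-rate targets would raise PCC but change the task.
* The spike autoencoder reconstructs z-scored counts through binary LIF
  features; very narrow widths cannot express per-channel count scales
  precisely (the memorization probe uses base width 8 for this reason).
* BatchNorm uses batch statistics during training, so training-time
  forward passes are batch-composition-dependent (evaluation is not).
* The engine targets clarity and desk-scale sizes, not large-scale
  throughput; there is no GPU path.
* Cross-day results use parametric drift; real recordings drift in ways
  the generator does not model (electrode migration, unit turnover with
  replacement, behavioral adaptation).
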