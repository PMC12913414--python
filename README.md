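# alignnet

Bidirectional spike–behavior alignment with hybrid SNN–ANN autoencoders,
for cross-day neural decoding and simulation.

Intracortical brain–computer interfaces must map multi-channel spiking
activity to movement (decoding) and, increasingly, movement back to
realistic spiking (simulation). Both mappings degrade across recording
days: the relationship between neural activity and behavior drifts from
session to session. `alignnet` addresses this with a pair of U-shaped
autoencoders — a spiking (leaky integrate-and-fire) network for spike-count
matrices and a conventional network for 2-D trajectories — whose bottleneck
embeddings are pulled into a shared latent space by a symmetric contrastive
objective. After multi-day pretraining, either encoder can feed either
decoder: spike encoder → behavior decoder performs decoding, behavior
encoder → spike decoder performs simulation, and each path is fine-tuned
supervised for its task.

The package is aimed at computational-neuroscience practitioners who want a
self-contained, CPU-scale reference implementation: a synthetic
center-out motor-cortex simulator with controllable day-to-day drift, the
full preprocessing chain from raw voltage to aligned 50 Hz trials, the
hybrid model and training protocols, classical baselines (Wiener filter,
MLP, GRU), and the evaluation metrics.

## Model sketch

A trial is a spike matrix `S ∈ ℕ^{64×100}` (64 channels, 2 s at 50 Hz)
paired with a trajectory `B ∈ ℝ^{2×100}`. Each LIF activation iterates

    V_t = H_{t−1} + (1/τ)(I_t − (H_{t−1} − V_reset)),   S_t = Θ(V_t − v_th),
    H_t = V_reset S_t + V_t (1 − S_t),       τ = 2, v_th = 0.3, V_reset = 0,

along the trial's time axis, trained with an arctan surrogate gradient.
Pretraining minimizes

    L = MSE(Ŝ, S) + MSE(B̂, B) + λ · L_CL,

where `L_CL` is the symmetric InfoNCE loss over matched spike/behavior
embedding pairs at temperature τ_CL = 0.07. Decoding quality is reported as
R²; simulation as per-channel Pearson correlation (PCC) plus binary
firing-rate tables. Details, defaults and design rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

Generate three synthetic days with drift, pretrain, fine-tune the decoding
path, and evaluate on a held-out day — all from Python:

```python
import numpy as np
from alignnet import (AlignNet, ModelConfig, TrainConfig, DriftSpec,
                      default_tuning, make_session, pretrain, finetune_decode,
                      predict_decode, split_cross_day)
from alignnet.training import gather
from alignnet.metrics import decode_metrics

tuning = default_tuning(seed=0)
days = [make_session(48, day=d, tuning=tuning, drift=DriftSpec(seed=0), seed=0)
        for d in range(3)]
plan = split_cross_day(days, test_day=2)        # train days 0-1, test day 2

model = AlignNet(ModelConfig(depth=2, base_width=4, latent_dim=16,
                             proj_hidden=32), seed=0)
std, hist = pretrain(days[:2], model,
                     TrainConfig(epochs=10, batch_size=16, lr=2e-3, seed=0))
finetune_decode(model, plan, days,
                TrainConfig(epochs=20, batch_size=16, lr=2e-3, seed=0), std)

spikes, behavior = gather(days, plan.test_indices)
per_dim, r2 = decode_metrics(behavior, predict_decode(model, std, spikes))
print(f"held-out day R2 = {r2:.3f} (x: {per_dim[0]:.3f}, y: {per_dim[1]:.3f})")
```

```
held-out day R2 = 0.510 (x: 0.510, y: 0.511)
```

An R² of ~0.5 on a day the model never saw means about half the variance of
the held-out trajectories is explained; the same split fit from scratch
with the same total epoch budget reaches a lower median across seeds, which
is the point of the contrastive pretraining.

The same pipeline is available as a shell tool:

```bash
alignnet simulate --days 3 --trials-per-day 48 --seed 0 --raw --out raw.h5
alignnet preprocess --in raw.h5 --out trials.h5
alignnet pretrain  --data trials.h5 --days 0:2 --seed 0 --out ckpt.npz
alignnet finetune  --data trials.h5 --ckpt ckpt.npz --task decode \
                   --protocol cross-day --test-day 2 --out ckpt_ft.npz
alignnet evaluate  --data trials.h5 --ckpt ckpt_ft.npz --task decode \
                   --protocol cross-day --test-day 2 --report report.json
alignnet baseline  --data trials.h5 --model wiener --task decode \
                   --protocol cross-day --test-day 2 --report wiener.json
```

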