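"""Standard desk-scale synthetic benchmarks.

These functions define the package's reference evaluation conditions — the
trial counts, drift settings, model geometry and training budgets used by
the test suite and the results-reproduction script.  They are deliberately
small: a reduced U-Net (depth 2, base width 4, latent 16; width 8/latent 32
for the memorization probe) and minutes-scale training on one CPU.  The
synthetic task keeps the full trial format (64 channels x 100 bins at
50 Hz, 8-direction center-out reaches).
"""

from __future__ import annotations

import numpy as np

from .baselines import wiener_fit, wiener_predict
from .metrics import decode_metrics, simulate_metrics
from .model import AlignNet, ModelConfig
from .preprocessing import PreprocessConfig, preprocess_recording
from .synthetic import DriftSpec, SessionSet, default_tuning, make_raw_session, make_session
from .training import (Standardizer, TrainConfig, finetune_decode,
                       finetune_simulate, gather, predict_decode,
                       predict_simulate, pretrain, split_cross_day,
                       split_single_day)

# reduced geometry used by all decode/alignment benchmarks
BENCH_CFG = ModelConfig(depth=2, base_width=4, latent_dim=16, proj_hidden=32)
# wider variant for the memorization probe (binary LIF features need width
# to reconstruct per-channel count scales)
OVERFIT_CFG = ModelConfig(depth=2, base_width=8, latent_dim=32, proj_hidden=32)

LR = 2e-3
BATCH = 16


def tiny_overfit(seed: int = 1, steps: int = 500) -> dict:
    """Memorization probe: 8 fixed trials, `steps` full-batch updates.

    Returns the spike/behavior reconstruction losses relative to their
    first-step values; a trainable model drives both well below 1.
    """
    sess = make_session(8, day=0, seed=seed)
    model = AlignNet(OVERFIT_CFG, seed=seed)
    tc = TrainConfig(epochs=steps, batch_size=8, lr=4e-3, seed=seed)
    _, hist = pretrain([sess], model, tc)
    return {
        "spike_ratio": hist[-1]["mse_spike"] / hist[0]["mse_spike"],
        "behavior_ratio": hist[-1]["mse_behavior"] / hist[0]["mse_behavior"],
        "n": 8,
    }


def alignment_probe(seed: int = 0, n_trials: int = 200, epochs: int = 6) -> dict:
    """Contrastive pretraining on one day, then matched vs mismatched
    cosine similarity of spike/behavior embedding pairs."""
    sess = make_session(n_trials, day=0, seed=seed)
    model = AlignNet(BENCH_CFG, seed=seed)
    std, _ = pretrain([sess], model,
                      TrainConfig(epochs=epochs, batch_size=BATCH, lr=LR, seed=seed))
    model.eval()
    zs = model.embed(model.encode_spike(std.transform(sess.spikes().astype(float)))).data
    zb = model.embed(model.encode_behavior(sess.behavior().astype(np.float32))).data
    zs = zs / np.linalg.norm(zs, axis=1, keepdims=True)
    zb = zb / np.linalg.norm(zb, axis=1, keepdims=True)
    sim = zs @ zb.T
    matched = float(np.mean(np.diag(sim)))
    mismatched = float((sim.sum() - np.trace(sim)) / (sim.size - len(sim)))
    return {"matched": matched, "mismatched": mismatched,
            "gap": matched - mismatched, "n": n_trials}


def _train_single_day(sess: SessionSet, plan, seed: int, task: str,
                      pre_epochs: int = 8, ft_epochs: int = 20):
    model = AlignNet(BENCH_CFG, seed=seed)
    train_sess = SessionSet(
        trials=[sess.trials[i] for i in plan.train_indices[sess.day]], day=sess.day)
    std, _ = pretrain([train_sess], model,
                      TrainConfig(epochs=pre_epochs, batch_size=BATCH, lr=LR, seed=seed))
    ft = finetune_decode if task == "decode" else finetune_simulate
    ft(model, plan, [sess], TrainConfig(epochs=ft_epochs, batch_size=BATCH,
                                        lr=LR, seed=seed), std)
    return model, std


def single_day_benchmark(seed: int = 0, n_trials: int = 160) -> dict:
    """80/20 single-day decoding: pretrain + fine-tune vs the Wiener filter
    on the identical split."""
    sess = make_session(n_trials, day=0, seed=seed)
    plan = split_single_day(sess, 0.8, seed=seed)
    te_spk, te_beh = gather([sess], plan.test_indices)
    model, std = _train_single_day(sess, plan, seed, "decode")
    r2_align = decode_metrics(te_beh, predict_decode(model, std, te_spk))[1]
    tr_spk, tr_beh = gather([sess], plan.train_indices)
    wm = wiener_fit(list(tr_spk), list(tr_beh), lags=5, ridge=10.0)
    r2_wiener = decode_metrics(te_beh, np.stack(wiener_predict(wm, list(te_spk))))[1]
    return {"alignnet_r2": float(r2_align), "wiener_r2": float(r2_wiener),
            "n": n_trials}


def single_day_simulate_benchmark(seed: int = 0, n_trials: int = 160) -> dict:
    """80/20 single-day behavior -> spike simulation, per-channel PCC.

    Per-bin Poisson counts put a hard ceiling on attainable PCC; the true
    underlying rate itself correlates only modestly with single-bin counts.
    """
    sess = make_session(n_trials, day=0, seed=seed)
    plan = split_single_day(sess, 0.8, seed=seed)
    te_spk, te_beh = gather([sess], plan.test_indices)
    model, std = _train_single_day(sess, plan, seed, "simulate",
                                   pre_epochs=8, ft_epochs=25)
    pred = predict_simulate(model, te_beh)
    _, mean_pcc, _ = simulate_metrics(te_spk, pred)
    tr_spk, tr_beh = gather([sess], plan.train_indices)
    wm = wiener_fit(list(tr_beh), list(tr_spk), lags=5, ridge=10.0)
    _, wiener_pcc, _ = simulate_metrics(
        te_spk, np.stack(wiener_predict(wm, list(te_beh))))
    return {"alignnet_pcc": float(mean_pcc), "wiener_pcc": float(wiener_pcc),
            "n": n_trials}


def cross_day_benchmark(seed: int = 0, trials_per_day: int = 48,
                        pre_epochs: int = 10, ft_epochs: int = 20) -> dict:
    """Three drifted days; train on days 0-1, test on day 2.

    Compares contrastive pretraining + fine-tuning against from-scratch
    supervised training with the same total number of epochs.
    """
    drift = DriftSpec(seed=seed)
    tuning = default_tuning(seed=seed)
    sessions = [make_session(trials_per_day, day=d, tuning=tuning, drift=drift,
                             seed=seed) for d in range(3)]
    plan = split_cross_day(sessions, test_day=2)
    train_sessions = [s for s in sessions if s.day in plan.train_days]
    te_spk, te_beh = gather(sessions, plan.test_indices)

    model = AlignNet(BENCH_CFG, seed=seed)
    std, _ = pretrain(train_sessions, model,
                      TrainConfig(epochs=pre_epochs, batch_size=BATCH, lr=LR, seed=seed))
    finetune_decode(model, plan, sessions,
                    TrainConfig(epochs=ft_epochs, batch_size=BATCH, lr=LR, seed=seed),
                    std)
    r2_pre = decode_metrics(te_beh, predict_decode(model, std, te_spk))[1]

    scratch = AlignNet(BENCH_CFG, seed=seed + 100)
    std2 = Standardizer.fit(gather(sessions, plan.train_indices)[0])
    finetune_decode(scratch, plan, sessions,
                    TrainConfig(epochs=pre_epochs + ft_epochs, batch_size=BATCH,
                                lr=LR, seed=seed), std2)
    r2_scr = decode_metrics(te_beh, predict_decode(scratch, std2, te_spk))[1]
    return {"pretrained_r2": float(r2_pre), "scratch_r2": float(r2_scr),
            "n": 3 * trials_per_day}


def roundtrip_recovery(seed: int = 0, n_trials: int = 12) -> dict:
    """Raw-emulation -> detection -> binning round trip; fraction of
    ground-truth per-bin counts recovered (1 - |error| / total)."""
    sess = make_session(n_trials, day=0, seed=seed)
    rec = make_raw_session(sess, seed=seed + 50)
    trials = preprocess_recording(rec, PreprocessConfig(), day=0)
    true = sess.spikes()
    det = np.stack([t.spikes for t in trials])
    recovery = 1.0 - np.abs(true - det).sum() / true.sum()
    return {"recovery": float(recovery), "n": n_trials}
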