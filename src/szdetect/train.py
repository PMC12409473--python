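"""Training loop: Adam on cross-entropy with best-validation-accuracy
checkpoint selection over a fixed epoch budget (no early stopping).

The published run used lr = 1e-5, 100 epochs, batch 2048; those are the
defaults here. ``desk_hyperparams`` is the CPU-scale preset used by the
test suite and the end-to-end pipeline (batch 64, <= 20 epochs).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .augment import WindowSet
from .model import ChannelTransformer, ModelConfig, TrainedModel
from .nn import Adam, softmax_cross_entropy


@dataclass(frozen=True)
class HyperParams:
    learning_rate: float = 1e-5
    epochs: int = 100
    batch_size: int = 2048
    val_fraction: float = 0.1
    #: fraction of batches trained on a random channel subset; exercises the
    #: channel-agnostic property so detection stays calibrated when fewer
    #: electrodes are available at inference time
    channel_subsample_prob: float = 0.0
    channel_subsample_counts: tuple[int, ...] = (1, 2, 4, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")


def desk_hyperparams(epochs: int = 12, seed: int = 0, learning_rate: float = 3e-4) -> HyperParams:
    """Small-batch CPU preset; the higher learning rate suits the tiny model."""
    return HyperParams(learning_rate=learning_rate, epochs=epochs, batch_size=64, seed=seed)


class StratificationError(ValueError):
    pass


def split_dataset(
    windows: WindowSet, val_fraction: float, seed: int
) -> tuple[WindowSet, WindowSet]:
    """Disjoint, exhaustive, label-stratified train/validation split."""
    if len(windows) < 2:
        raise ValueError("need at least 2 windows to split")
    labels = windows.labels
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise StratificationError("both classes must be present to stratify")
    groups = []
    for lab in classes:
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            raise StratificationError(f"label {lab} has {len(idx)} window(s); cannot stratify")
        groups.append(rng.permutation(idx))
    # largest-remainder allocation so the overall split size is
    # round(val_fraction * n) while staying stratified
    ideal = [val_fraction * len(g) for g in groups]
    n_vals = [int(np.floor(v)) for v in ideal]
    target = int(round(val_fraction * len(labels)))
    order = np.argsort([n - v for n, v in zip(n_vals, ideal)])  # largest remainder first
    for j in order:
        if sum(n_vals) >= target:
            break
        n_vals[j] += 1
    n_vals = [min(max(v, 1), len(g) - 1) for v, g in zip(n_vals, groups)]
    train_idx = [g[v:] for g, v in zip(groups, n_vals)]
    val_idx = [g[:v] for g, v in zip(groups, n_vals)]
    return (
        windows.subset(np.sort(np.concatenate(train_idx))),
        windows.subset(np.sort(np.concatenate(val_idx))),
    )


def _accuracy(net: ChannelTransformer, ws: WindowSet, batch_size: int) -> float:
    pred = np.argmax(net.predict_proba(ws.data, batch_size=batch_size), axis=1)
    return float(np.mean(pred == ws.labels))


def train_model(
    cfg: ModelConfig,
    hyper: HyperParams,
    train: WindowSet,
    val: WindowSet,
    verbose: bool = False,
) -> TrainedModel:
    """Fit the classifier; return the epoch with the best validation accuracy.

    Fully seeded: parameter init and per-epoch shuffling both derive from
    ``hyper.seed``, so reruns reproduce the same record bit-for-bit.
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    if train.data.shape[2] != cfg.window_len:
        raise ValueError(
            f"windows have L={train.data.shape[2]} but the model expects {cfg.window_len}"
        )
    ss = np.random.SeedSequence(hyper.seed)
    init_seed, shuffle_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    net = ChannelTransformer(cfg, seed=init_seed)
    opt = Adam(net.parameters(), lr=hyper.learning_rate)
    shuffle_rng = np.random.default_rng(shuffle_seed)

    x = train.data.astype(np.float64)
    y = train.labels.astype(np.int64)
    losses, val_accs = [], []
    best = (-1.0, None)
    for epoch in range(hyper.epochs):
        order = shuffle_rng.permutation(len(x))
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(x), hyper.batch_size):
            idx = order[i : i + hyper.batch_size]
            xb = x[idx]
            if hyper.channel_subsample_prob and shuffle_rng.random() < hyper.channel_subsample_prob:
                counts = [k for k in hyper.channel_subsample_counts if k <= xb.shape[1]]
                if counts:
                    k = int(shuffle_rng.choice(counts))
                    xb = xb[:, np.sort(shuffle_rng.choice(xb.shape[1], size=k, replace=False))]
            net.zero_grad()
            logits = net.forward(xb)
            loss, g = softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {n_batches}; "
                    "lower the learning rate"
                )
            net.backward(g)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)
        acc = _accuracy(net, val, hyper.batch_size) if len(val) else float("nan")
        val_accs.append(acc)
        # ties go to the later (more converged) epoch
        if len(val) and acc >= best[0]:
            best = (acc, copy.deepcopy(net.state_arrays()))
        if verbose:
            print(f"epoch {epoch + 1:3d}/{hyper.epochs}  loss {losses[-1]:.4f}  val acc {acc:.4f}")

    if best[1] is not None:
        net.load_state_arrays(best[1])
    selected = (
        int(len(val_accs) - 1 - np.argmax(val_accs[::-1])) if len(val) else hyper.epochs - 1
    )
    record = {
        "train_loss": losses,
        "val_accuracy": val_accs,
        "selected_epoch": selected,
        "best_val_accuracy": best[0] if len(val) else None,
        "hyperparams": {
            "learning_rate": hyper.learning_rate,
            "epochs": hyper.epochs,
            "batch_size": hyper.batch_size,
            "channel_subsample_prob": hyper.channel_subsample_prob,
            "val_fraction": hyper.val_fraction,
            "seed": hyper.seed,
        },
    }
    return TrainedModel(config=cfg, network=net, record=record)
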