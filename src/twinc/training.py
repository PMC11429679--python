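"""Training loops with dynamic pair sampling and best-on-validation checkpointing.

Labeled trans pairs are sampled on the fly (class-balanced by default;
uniform over labeled pairs retained for fidelity), windows are fetched from
the genome store at batch time, and the classifier minimizes binary
cross-entropy under Adam (lr 1e-2, betas (0.9, 0.999), no weight decay,
batch 16).  Validation average precision is evaluated every 200 batches on
a fixed seeded subsample and the best state is kept.  The regression
variant minimizes mean squared error over 5x5 log o/e blocks (lr 9e-4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labels import LabelSet
from .metrics import binary_metrics
from .model import TwinCNet

EPS = 1e-7  # score clip inside the cross-entropy


@dataclass
class TrainConfig:
    lr: float = 1e-2
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.0
    batch_size: int = 16
    max_epochs: int = 10
    eval_interval: int = 200
    seed: int = 0
    sampler: str = "balanced"  # or "uniform"
    val_subsample: int = 512
    pairs_per_epoch: int | None = None  # default: number of labeled pairs
    max_batches: int | None = None

    def __post_init__(self):
        if self.batch_size <= 0 or self.max_epochs <= 0 or self.eval_interval <= 0:
            raise ValueError("batch size, epochs and eval interval must be positive")
        if self.sampler not in ("balanced", "uniform"):
            raise ValueError(f"unknown sampler {self.sampler!r}")


def _pair_arrays(label_set: LabelSet):
    # cached: sampling happens every batch and the sets are large
    cache = getattr(label_set, "_pair_cache", None)
    if cache is not None and cache[0] == (len(label_set.positives),
                                          len(label_set.negatives)):
        return cache[1], cache[2]
    pos = np.array(sorted(label_set.positives), dtype=np.int64).reshape(-1, 2)
    neg = np.array(sorted(label_set.negatives), dtype=np.int64).reshape(-1, 2)
    label_set._pair_cache = ((len(pos), len(neg)), pos, neg)
    return pos, neg


def _fetch_windows(store, grid, gidx: np.ndarray, window_bp: int) -> np.ndarray:
    wins = np.empty((gidx.size, window_bp, 4), dtype=np.uint8)
    for k, g in enumerate(gidx):
        chrom, start = grid.bin_location(int(g))
        wins[k] = store.fetch_window(chrom, start, window_bp).seq
    return wins


def sample_batch(label_set: LabelSet, store, batch: int,
                 rng: np.random.Generator, window_bp: int,
                 sampler: str = "balanced", swap: bool = False):
    """Draw a labeled batch; returns (windowsA, windowsB, targets).

    With ``swap=True`` each pair's orientation is randomized (contact is
    symmetric in window order; training should not key on storage order).
    """
    pos, neg = _pair_arrays(label_set)
    if sampler == "balanced":
        if len(pos) == 0 or len(neg) == 0:
            raise ValueError("balanced sampling requires both classes")
        npos = batch // 2
        ip = rng.integers(0, len(pos), npos)
        ineg = rng.integers(0, len(neg), batch - npos)
        pairs = np.concatenate([pos[ip], neg[ineg]])
        y = np.concatenate([np.ones(npos), np.zeros(batch - npos)])
    else:
        allp = np.concatenate([pos, neg])
        ally = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        if len(allp) == 0:
            raise ValueError("empty label set")
        idx = rng.integers(0, len(allp), batch)
        pairs, y = allp[idx], ally[idx]
    if swap:
        flip = rng.random(len(pairs)) < 0.5
        pairs = pairs.copy()
        pairs[flip] = pairs[flip][:, ::-1]
    wa = _fetch_windows(store, label_set.grid, pairs[:, 0], window_bp)
    wb = _fetch_windows(store, label_set.grid, pairs[:, 1], window_bp)
    return wa, wb, y


def bce_loss(y: np.ndarray, scores: np.ndarray) -> float:
    s = np.clip(scores, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(s) + (1.0 - y) * np.log(1.0 - s)))


def _bce_score_grad(y: np.ndarray, scores: np.ndarray) -> np.ndarray:
    s = np.clip(scores, EPS, 1.0 - EPS)
    return ((s - y) / (s * (1.0 - s)) / y.size).astype(np.float32)


def _val_pairs(labels_val: LabelSet, size: int, seed: int):
    pos, neg = _pair_arrays(labels_val)
    rng = np.random.default_rng(seed)
    take_p = min(len(pos), max(1, size // 2))
    take_n = min(len(neg), max(1, size - take_p))
    ip = rng.choice(len(pos), take_p, replace=False)
    ineg = rng.choice(len(neg), take_n, replace=False)
    pairs = np.concatenate([pos[ip], neg[ineg]])
    y = np.concatenate([np.ones(take_p), np.zeros(take_n)])
    return pairs, y


def _score_pairs(net: TwinCNet, store, grid, pairs, window_bp, batch=64):
    out = np.empty(len(pairs))
    for s in range(0, len(pairs), batch):
        sl = slice(s, s + batch)
        wa = _fetch_windows(store, grid, pairs[sl, 0], window_bp)
        wb = _fetch_windows(store, grid, pairs[sl, 1], window_bp)
        out[sl] = net.forward_pairs(wa, wb, train=False)
    return out


def train_classifier(net: TwinCNet, store, labels_train: LabelSet,
                     labels_val: LabelSet, config: TrainConfig):
    """Minimize binary cross-entropy; returns (best_state, history frame)."""
    window_bp = net.config.window_bp
    rng = np.random.default_rng(config.seed)
    opt = net.make_optimizer(lr=config.lr, betas=config.betas)
    opt.weight_decay = config.weight_decay
    vpairs, vy = _val_pairs(labels_val, config.val_subsample, config.seed + 1)

    if config.max_batches is not None:
        total = config.max_batches
    else:
        n_pairs = config.pairs_per_epoch or (
            len(labels_train.positives) + len(labels_train.negatives)
        )
        total = config.max_epochs * max(1, n_pairs // config.batch_size)

    best_ap, best_state = -np.inf, None
    history = []

    def evaluate(step):
        nonlocal best_ap, best_state
        vs = _score_pairs(net, store, labels_train.grid, vpairs, window_bp)
        rep = binary_metrics(vy, vs)
        history.append(
            {"batch": step, "loss": float(loss), "val_ap": rep.average_precision,
             "val_auroc": rep.auroc}
        )
        if rep.average_precision > best_ap:
            best_ap = rep.average_precision
            best_state = net.state()

    loss = np.nan
    for step in range(1, total + 1):
        wa, wb, y = sample_batch(labels_train, store, config.batch_size, rng,
                                 window_bp, config.sampler, swap=True)
        scores = net.forward_pairs(wa, wb, train=True)
        loss = bce_loss(y, scores)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at batch {step}: scores "
                f"[{scores.min():.3g}, {scores.max():.3g}]"
            )
        opt.zero_grad()
        net.backward(_bce_score_grad(y, scores))
        opt.step()
        if step % config.eval_interval == 0 or step == total:
            evaluate(step)

    if best_state is not None:
        net.load_state(best_state)
    return best_state, pd.DataFrame(history)


def mse_loss(targets: np.ndarray, preds: np.ndarray) -> float:
    return float(np.mean((targets - preds) ** 2))


def train_regressor(net: TwinCNet, windowsA: np.ndarray, windowsB: np.ndarray,
                    targets: np.ndarray, config: TrainConfig):
    """Minimize MSE over (N, P, P) target blocks; returns (state, history)."""
    if net.config.head != "regression":
        raise ValueError("train_regressor requires a regression-head network")
    rng = np.random.default_rng(config.seed)
    opt = net.make_optimizer(lr=config.lr, betas=config.betas)
    n = len(targets)
    if config.max_batches is not None:
        total = config.max_batches
    else:
        total = config.max_epochs * max(1, n // config.batch_size)
    history = []
    for step in range(1, total + 1):
        idx = rng.integers(0, n, min(config.batch_size, n))
        preds = net.forward_pairs(windowsA[idx], windowsB[idx], train=True)
        t = targets[idx]
        loss = mse_loss(t, preds)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at batch {step}")
        opt.zero_grad()
        net.backward((2.0 * (preds - t) / t.size).astype(np.float32))
        opt.step()
        history.append({"batch": step, "loss": loss})
    return net.state(), pd.DataFrame(history)
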