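"""Sample partitioning and the fast / nonstop training modes.

Training uses Adam (default betas) under a global learning rate that only
caps the adaptive per-node rates.  The *fast* mode decays the global rate
by 10x when the validation cost plateaus or oscillates for five rounds and
stops after the plateau that follows the second decay.  The *nonstop* mode
runs a fixed (epoch bound, learning rate) schedule, emitting a checkpoint
at every boundary.  The L2 regularisation strength lambda always tracks
the current learning rate, and dropout (p=0.5 on FC4) is active only
during training.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import network as nw
from .network import Network


@dataclass
class TrainPolicy:
    """Knobs of the fast (adaptive-decay) training mode."""

    initial_learning_rate: float = 1e-3
    decay_factor: float = 0.1
    plateau_rounds: int = 5
    min_rel_improvement: float = 0.01
    max_decays: int = 2
    batch_size: int = 500
    max_epochs: int = 200
    l2_tracks_learning_rate: bool = True


@dataclass
class EpochRecord:
    epoch: int
    learning_rate: float
    train_cost: float
    val_cost: float
    wall_time: float
    event: str = ""


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)
    decay_events: int = 0
    stopped_reason: str = ""

    @property
    def val_costs(self) -> list[float]:
        return [r.val_cost for r in self.records]

    @property
    def train_costs(self) -> list[float]:
        return [r.train_cost for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def split_samples(samples: Sequence, fraction: float = 0.9,
                  seed: int = 0) -> tuple[list, list]:
    """Random 90/10 partition of samples into training and validation."""
    tr, va = split_indices(len(samples), fraction, seed)
    lst = list(samples)
    return [lst[i] for i in tr], [lst[i] for i in va]


def split_indices(n: int, fraction: float = 0.9,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Index form of :func:`split_samples`; disjoint and exhaustive."""
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = int(round(fraction * n))
    return np.sort(perm[:k]), np.sort(perm[k:])


def should_decay(val_history: Sequence[float], plateau_rounds: int = 5,
                 min_rel_improvement: float = 0.01) -> bool:
    """Detect a validation cost that has stopped improving.

    ``val_history`` is the per-epoch validation cost since the last decay.
    True when each of the last ``plateau_rounds`` epochs failed to improve
    on the best cost seen before it by more than ``min_rel_improvement``
    relative -- i.e. the cost only went up and down (or crept) for five
    rounds.  Fewer than ``plateau_rounds + 1`` epochs never trigger.
    """
    h = list(val_history)
    if len(h) < plateau_rounds + 1:
        return False
    for i in range(len(h) - plateau_rounds, len(h)):
        if h[i] < min(h[:i]) * (1.0 - min_rel_improvement):
            return False
    return True


class AdamState:
    """Adam optimiser with default betas (0.9, 0.999) and eps 1e-8."""

    def __init__(self, model: Network, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in model.params.items()}

    def step(self, model: Network, grads: dict[str, np.ndarray],
             lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            model.params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _run_epoch(model, X, Y, lr, l2, batch_size, adam, rng):
    n = len(X)
    order = rng.permutation(n)
    total, seen = 0.0, 0
    for s in range(0, n, batch_size):
        idx = order[s:s + batch_size]
        c, _, grads = nw.loss_and_grads(model, X[idx], Y[idx], l2=l2,
                                        train=True, rng=rng)
        adam.step(model, grads, lr)
        total += c * len(idx)
        seen += len(idx)
    return total / seen


def _val_cost(model, X, Y, batch_size=2000):
    total = 0.0
    for s in range(0, len(X), batch_size):
        out = nw.forward(model, X[s:s + batch_size])
        total += nw.cost(out, Y[s:s + batch_size]) * len(X[s:s + batch_size])
    return total / len(X)


def train_fast(model: Network, train_data: tuple[np.ndarray, np.ndarray],
               val_data: tuple[np.ndarray, np.ndarray],
               policy: TrainPolicy | None = None,
               seed: int = 0) -> tuple[Network, TrainHistory]:
    """Adaptive-decay training: 1e-3 start, two 10x decays, then stop."""
    policy = policy or TrainPolicy()
    Xtr, Ytr = train_data
    Xva, Yva = val_data
    rng = np.random.default_rng(seed)
    adam = AdamState(model)
    history = TrainHistory()
    lr = policy.initial_learning_rate
    decays = 0
    since_decay: list[float] = []
    t0 = time.monotonic()
    for epoch in range(policy.max_epochs):
        l2 = lr if policy.l2_tracks_learning_rate else 0.0
        epoch_rng = np.random.default_rng(rng.integers(2 ** 31))
        tc = _run_epoch(model, Xtr, Ytr, lr, l2, policy.batch_size, adam,
                        epoch_rng)
        vc = _val_cost(model, Xva, Yva)
        rec = EpochRecord(epoch, lr, tc, vc, time.monotonic() - t0)
        history.records.append(rec)
        if not np.isfinite(tc) or not np.isfinite(vc):
            history.stopped_reason = "diverged"
            rec.event = "diverged"
            break
        since_decay.append(vc)
        if should_decay(since_decay, policy.plateau_rounds,
                        policy.min_rel_improvement):
            if decays >= policy.max_decays:
                rec.event = "stop"
                history.stopped_reason = "plateau after final decay"
                break
            lr *= policy.decay_factor
            decays += 1
            history.decay_events += 1
            rec.event = f"decay->{lr:g}"
            since_decay = []
    else:
        history.stopped_reason = "max epochs"
    return model, history


DEFAULT_NONSTOP_SCHEDULE = ((1000, 1e-3), (1500, 1e-4), (2000, 1e-5))


def train_nonstop(model: Network, train_data, val_data,
                  schedule: Sequence[tuple[int, float]] =
                  DEFAULT_NONSTOP_SCHEDULE,
                  seed: int = 0, batch_size: int = 500,
                  start_epoch: int = 0
                  ) -> tuple[Network, TrainHistory, list[Network]]:
    """Fixed-schedule training; a checkpoint at every epoch bound.

    ``schedule`` is a list of (exclusive epoch bound, learning rate); the
    learning rate switches exactly at the bounds.  ``start_epoch`` allows
    resuming from a checkpoint.
    """
    bounds = [b for b, _ in schedule]
    if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
        raise ValueError("schedule epochs must be strictly increasing")
    Xtr, Ytr = train_data
    Xva, Yva = val_data
    rng = np.random.default_rng(seed)
    # burn the per-epoch seeds of already-completed epochs so a resumed run
    # reproduces the same learning-rate and shuffle trace
    for _ in range(start_epoch):
        rng.integers(2 ** 31)
    adam = AdamState(model)
    history = TrainHistory()
    checkpoints: list[Network] = []
    t0 = time.monotonic()
    for epoch in range(start_epoch, bounds[-1]):
        lr = next(r for b, r in schedule if epoch < b)
        epoch_rng = np.random.default_rng(rng.integers(2 ** 31))
        tc = _run_epoch(model, Xtr, Ytr, lr, lr, batch_size, adam, epoch_rng)
        vc = _val_cost(model, Xva, Yva)
        event = ""
        if epoch + 1 in bounds:
            checkpoints.append(model.copy())
            event = "checkpoint"
        history.records.append(
            EpochRecord(epoch, lr, tc, vc, time.monotonic() - t0, event))
    history.stopped_reason = "schedule complete"
    return model, history, checkpoints
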