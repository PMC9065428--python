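"""Training protocol: Adam with plateau LR decay, early stopping, gradient
accumulation, and the cross-validation fold harness.

The learning-rate schedule divides the LR by a fixed factor whenever the
best validation loss has not improved for ``plateau_patience`` consecutive
epochs; training stops early after ``early_stop_patience`` epochs without
a new best, or at ``max_epochs``.  "Improvement" means a strictly lower
best validation loss by at least ``min_improvement`` (guards float noise).
The plateau counter resets both on a new best and on a decay; the
early-stop counter resets only on a new best.

The physical batch size is one volume; gradient accumulation averages the
gradients of ``accumulation_steps`` consecutive samples before each
parameter update, simulating a larger batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augmentation import AugmentationPolicy, augment_pair
from .losses import DEFAULT_ALPHA, deep_supervision_aggregate, inverse_frequency_weights, make_loss, one_hot
from .network import SegmentationNetwork
from .nn import Adam
from .windowing import WindowSpec, stack_windows

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 1e-2
    lr_decay_factor: float = 10.0
    plateau_patience_epochs: int = 100
    max_epochs: int = 1000
    early_stop_patience_epochs: int = 250
    accumulation_steps: int = 4
    batch_size: int = 1  # fixed; one volume per forward pass
    min_improvement: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plateau_patience_epochs <= 0 or self.early_stop_patience_epochs <= 0:
            raise ValueError("patience values must be positive")
        if self.early_stop_patience_epochs < self.plateau_patience_epochs:
            raise ValueError("early-stop patience must be >= plateau patience")
        if self.accumulation_steps < 1:
            raise ValueError("accumulation_steps must be >= 1")
        if self.batch_size != 1:
            raise ValueError("the physical batch size is fixed at one volume")


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    termination: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.val_loss)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.n_epochs + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "learning_rate": self.learning_rate,
            }
        )


class PlateauSchedule:
    """Stateful LR / stopping rule driven by the validation-loss trace."""

    def __init__(self, config: TrainConfig):
        self.config = config
        self.lr = config.initial_lr
        self.best = float("inf")
        self.best_epoch = 0
        self.epoch = 0
        self._plateau = 0
        self._stagnant = 0

    def update(self, val_loss: float) -> tuple[float, bool, str]:
        """Record one epoch; returns ``(lr_for_next_epoch, stop, reason)``."""
        c = self.config
        self.epoch += 1
        if val_loss < self.best - c.min_improvement:
            self.best = val_loss
            self.best_epoch = self.epoch
            self._plateau = 0
            self._stagnant = 0
        else:
            self._plateau += 1
            self._stagnant += 1
        if self._plateau >= c.plateau_patience_epochs:
            self.lr /= c.lr_decay_factor
            self._plateau = 0
        if self.epoch >= c.max_epochs:
            return self.lr, True, "max_epochs"
        if self._stagnant >= c.early_stop_patience_epochs:
            return self.lr, True, "early_stop"
        return self.lr, False, ""


def _replay(val_losses, config: TrainConfig) -> PlateauSchedule:
    sched = PlateauSchedule(config)
    for v in val_losses:
        sched.update(float(v))
    return sched


def lr_step(history: TrainingHistory, config: TrainConfig) -> float:
    """Learning rate for the next epoch given the validation trace so far."""
    if history.n_epochs < 1:
        raise ValueError("need at least one recorded epoch")
    return _replay(history.val_loss, config).lr


def should_stop(history: TrainingHistory, config: TrainConfig) -> tuple[bool, str]:
    """Stopping decision from the validation trace alone."""
    sched = PlateauSchedule(config)
    stop, reason = False, ""
    for v in history.val_loss:
        _, stop, reason = sched.update(float(v))
        if stop:
            break
    return stop, reason


# -- cross-validation folds ------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Per-fold train / validation / test index lists."""

    folds: tuple  # of dicts with keys "train", "val", "test"

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


def make_folds(
    n_items: int,
    n_folds: int = 5,
    n_val: int = 3,
    rng_seed: int = 0,
    allow_overlap: bool = False,
    test_size: int | None = None,
) -> FoldPlan:
    """Deterministic cross-validation plan.

    By default the items are partitioned into ``n_folds`` test sets as
    evenly as possible (34 items over 5 folds gives four test sets of 7 and
    one of 6) so every item is tested exactly once.  With
    ``allow_overlap=True`` each test fold has exactly ``test_size`` items
    taken from a wrapped-around shuffled sequence, so a few items may recur.
    Within each fold the remaining items split into ``n_val`` validation
    items and the rest for training.
    """
    if n_folds < 2 or n_items < n_folds:
        raise ValueError(f"cannot make {n_folds} folds from {n_items} items")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n_items)

    test_sets: list[np.ndarray] = []
    if allow_overlap:
        if test_size is None:
            raise ValueError("allow_overlap requires an explicit test_size")
        wrapped = np.concatenate([order, order])
        for k in range(n_folds):
            test_sets.append(wrapped[k * test_size : (k + 1) * test_size])
    else:
        base, extra = divmod(n_items, n_folds)
        start = 0
        for k in range(n_folds):
            size = base + (1 if k < extra else 0)
            test_sets.append(order[start : start + size])
            start += size

    folds = []
    for k, test in enumerate(test_sets):
        rest = np.array([i for i in order if i not in set(test.tolist())])
        rest = rng.permutation(rest)
        if n_val >= rest.size:
            raise ValueError("validation size leaves no training items")
        folds.append(
            {
                "train": tuple(int(i) for i in rest[n_val:]),
                "val": tuple(int(i) for i in rest[:n_val]),
                "test": tuple(int(i) for i in test),
            }
        )
    return FoldPlan(folds=tuple(folds))


# -- the training loop -----------------------------------------------------------

def _forward_loss(net, x, target_1h, weights, loss_fn, ds_weights=None):
    out = net(x)
    if isinstance(out, tuple):
        main, aux = out
        lv = deep_supervision_aggregate(
            loss_fn(main, target_1h, weights),
            [loss_fn(a, target_1h, weights) for a in aux],
            ds_weights,
        )
    else:
        lv = loss_fn(out, target_1h, weights)
    return lv


def accumulate_and_update(net, samples, loss_fn, optimizer, steps: int) -> float:
    """One accumulated update: mean gradient over ``steps`` samples, then step.

    ``samples`` yields ``(x, target_one_hot, weights)`` triples.  Returns the
    mean loss over the group.  The update is delayed, not interleaved: all
    gradients are evaluated at the same parameter state.
    """
    net.zero_grad()
    total = 0.0
    count = 0
    for x, t, w in samples:
        lv = _forward_loss(net, x, t, w, loss_fn)
        (lv.total * (1.0 / steps)).backward()
        total += lv.value
        count += 1
        if count == steps:
            break
    optimizer.step()
    net.zero_grad()
    return total / max(count, 1)


def train(
    network: SegmentationNetwork,
    train_set,
    val_set,
    window_specs: list[WindowSpec],
    loss_kind: str = "explog",
    augmentation: AugmentationPolicy | None = None,
    config: TrainConfig | None = None,
    class_weights=None,
    ds_weights=None,
) -> tuple[SegmentationNetwork, TrainingHistory]:
    """Run the full training loop and return the best-validation network.

    ``train_set`` / ``val_set`` are sequences of ``(CTVolume, LabelMap)``
    pairs.  Class weights default to the inverse-frequency weights of the
    training labels at the loss kind's exponent.  Validation uses the same
    loss without augmentation or deep-supervision auxiliaries.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    loss_fn = make_loss(loss_kind)
    nc = network.config.num_classes
    if class_weights is None:
        class_weights = inverse_frequency_weights(
            [lab for _, lab in train_set], alpha=DEFAULT_ALPHA[loss_kind], num_classes=nc
        )

    val_onehots = [one_hot(lab, nc) for _, lab in val_set]
    val_inputs = [stack_windows(ct, window_specs).channels for ct, _ in val_set]

    optimizer = Adam(network.parameters(), lr=config.initial_lr)
    sched = PlateauSchedule(config)
    history = TrainingHistory()
    best_state = [a.copy() for a in network.state_arrays()]

    steps = config.accumulation_steps
    for epoch in range(1, config.max_epochs + 1):
        network.train_mode()
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        network.zero_grad()
        in_group = 0
        for idx in order:
            ct, lab = train_set[idx]
            if augmentation is not None:
                ct, lab, _ = augment_pair(ct, lab, augmentation, int(rng.integers(2**31 - 1)))
            x = stack_windows(ct, window_specs).channels
            lv = _forward_loss(
                network, x, one_hot(lab, nc), class_weights, loss_fn, ds_weights
            )
            if not np.isfinite(lv.value):
                history.termination = "diverged"
                log.error("non-finite training loss at epoch %d; aborting", epoch)
                network.load_state_arrays(best_state)
                return network, history
            (lv.total * (1.0 / steps)).backward()
            epoch_loss += lv.value
            in_group += 1
            if in_group == steps:
                optimizer.step()
                network.zero_grad()
                in_group = 0
        if in_group:  # trailing partial accumulation group
            optimizer.step()
            network.zero_grad()

        network.eval_mode()
        val_loss = 0.0
        for x, t in zip(val_inputs, val_onehots):
            val_loss += loss_fn(network(x), t, class_weights).value
        val_loss /= len(val_set)

        history.train_loss.append(epoch_loss / len(train_set))
        history.val_loss.append(val_loss)
        history.learning_rate.append(optimizer.lr)

        prev_best = sched.best_epoch
        new_lr, stop, reason = sched.update(val_loss)
        if sched.best_epoch != prev_best or epoch == 1:
            best_state = [a.copy() for a in network.state_arrays()]
            history.best_epoch = epoch
            history.best_val_loss = sched.best
        optimizer.lr = new_lr
        log.info(
            "epoch %d train %.5f val %.5f lr %.1e", epoch,
            history.train_loss[-1], val_loss, optimizer.lr,
        )
        if stop:
            history.termination = reason
            break
    else:
        history.termination = "max_epochs"

    network.load_state_arrays(best_state)
    network.eval_mode()
    return network, history
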