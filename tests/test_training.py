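"""Schedule rules, fold plans, gradient accumulation, and a short train run."""

import numpy as np
import pytest

from oarseg.losses import exp_log_loss, inverse_frequency_weights, one_hot
from oarseg.network import NetworkConfig, build_network
from oarseg.nn import Adam
from oarseg.phantom import PhantomSpec, phantom_dataset
from oarseg.training import (
    FoldPlan,
    PlateauSchedule,
    TrainConfig,
    TrainingHistory,
    accumulate_and_update,
    lr_step,
    make_folds,
    should_stop,
    train,
)
from oarseg.windowing import get_preset


def history_from(vals):
    h = TrainingHistory()
    h.val_loss = list(vals)
    return h


# -- learning-rate plateau schedule ----------------------------------------------

def test_lr_decays_after_exactly_100_stagnant_epochs():
    cfg = TrainConfig()
    trace = [1.0] + [1.0] * 99  # best at epoch 1, then 99 stagnant
    assert lr_step(history_from(trace), cfg) == pytest.approx(1e-2)
    trace.append(1.0)  # 100th stagnant epoch
    assert lr_step(history_from(trace), cfg) == pytest.approx(1e-3)


def test_improvement_at_epoch_99_resets_the_counter():
    cfg = TrainConfig()
    trace = [1.0] + [1.0] * 97 + [0.5]  # improvement on the 99th epoch
    assert lr_step(history_from(trace + [0.5]), cfg) == pytest.approx(1e-2)


def test_two_consecutive_plateaus_decay_twice():
    cfg = TrainConfig()
    trace = [1.0] + [1.0] * 200
    assert lr_step(history_from(trace), cfg) == pytest.approx(1e-4)


def test_early_stop_after_exactly_250_stagnant_epochs():
    cfg = TrainConfig()
    stop, reason = should_stop(history_from([1.0] + [1.0] * 249), cfg)
    assert not stop
    stop, reason = should_stop(history_from([1.0] + [1.0] * 250), cfg)
    assert stop and reason == "early_stop"


def test_stop_at_max_epochs_with_steady_improvement():
    cfg = TrainConfig(max_epochs=1000)
    trace = list(np.linspace(1.0, 0.1, 1000))
    stop, reason = should_stop(history_from(trace), cfg)
    assert stop and reason == "max_epochs"
    stop, _ = should_stop(history_from(trace[:999]), cfg)
    assert not stop


def test_tiny_improvements_do_not_reset_counters():
    cfg = TrainConfig()
    # decreasing by less than min_improvement each epoch: still a plateau
    trace = [1.0 - 1e-9 * k for k in range(101)]
    assert lr_step(history_from(trace), cfg) == pytest.approx(1e-3)


def test_lr_trace_values_are_powers_of_the_decay_factor():
    cfg = TrainConfig(plateau_patience_epochs=3, early_stop_patience_epochs=10, max_epochs=50)
    sched = PlateauSchedule(cfg)
    lrs = []
    for v in [1.0, 0.9, 0.9, 0.9, 0.9, 0.8, 0.8, 0.8, 0.8]:
        lr, _, _ = sched.update(v)
        lrs.append(lr)
    allowed = {1e-2 / 10**k for k in range(5)}
    assert set(np.round(lrs, 12)) <= {round(a, 12) for a in allowed}
    assert all(a >= b for a, b in zip(lrs, lrs[1:]))  # non-increasing


def test_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(plateau_patience_epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(early_stop_patience_epochs=50, plateau_patience_epochs=100)
    with pytest.raises(ValueError):
        TrainConfig(accumulation_steps=0)
    with pytest.raises(ValueError):
        TrainConfig(batch_size=2)


# -- cross-validation folds ------------------------------------------------------

def test_folds_partition_each_item_tested_once():
    plan = make_folds(10, n_folds=5, n_val=2, rng_seed=1)
    tested = [i for fold in plan for i in fold["test"]]
    assert sorted(tested) == list(range(10))
    for fold in plan:
        all_idx = set(fold["train"]) | set(fold["val"]) | set(fold["test"])
        assert len(fold["train"]) + len(fold["val"]) + len(fold["test"]) == 10
        assert all_idx == set(range(10))


def test_34_items_give_4x7_plus_6_pattern():
    plan = make_folds(34, n_folds=5, n_val=3, rng_seed=0)
    sizes = sorted(len(f["test"]) for f in plan)
    assert sizes == [6, 7, 7, 7, 7]
    full = [f for f in plan if len(f["test"]) == 7][0]
    assert len(full["train"]) == 24 and len(full["val"]) == 3
    tested = sorted(i for f in plan for i in f["test"])
    assert tested == list(range(34))


def test_overlapping_variant_covers_all_items():
    plan = make_folds(34, n_folds=5, n_val=3, rng_seed=0, allow_overlap=True, test_size=7)
    tested = [i for f in plan for i in f["test"]]
    assert len(tested) == 35  # one repeat
    assert set(tested) == set(range(34))
    for f in plan:
        assert len(f["test"]) == 7


def test_fold_plan_is_deterministic():
    a = make_folds(20, n_folds=4, n_val=2, rng_seed=9)
    b = make_folds(20, n_folds=4, n_val=2, rng_seed=9)
    assert a == b
    assert make_folds(20, n_folds=4, n_val=2, rng_seed=10) != a
    with pytest.raises(ValueError):
        make_folds(3, n_folds=5)


# -- gradient accumulation -------------------------------------------------------

@pytest.fixture(scope="module")
def toy_samples():
    rng = np.random.default_rng(0)
    cfg = NetworkConfig(in_channels=1, num_classes=3, channel_scheme=(4, 8),
                        norm_kind="instance", deep_supervision=False, dtype="float64")
    samples = []
    for _ in range(4):
        x = rng.normal(size=(1, 8, 8, 8))
        labels = rng.integers(0, 3, size=(8, 8, 8))
        labels.ravel()[:3] = [0, 1, 2]
        t = one_hot(labels, 3).astype(np.float64)
        w = inverse_frequency_weights(labels, alpha=0.5, num_classes=3)
        samples.append((x, t, w))
    return cfg, samples


def test_accumulated_gradient_equals_mean_of_per_sample_gradients(toy_samples):
    cfg, samples = toy_samples
    net = build_network(cfg, seed=3)
    state = [a.copy() for a in net.state_arrays()]

    # per-sample gradients, each computed independently at the same state
    per_sample = []
    for x, t, w in samples:
        net.load_state_arrays(state)
        net.zero_grad()
        exp_log_loss(net(x), t, w).total.backward()
        per_sample.append([p.grad.copy() for p in net.parameters()])
    mean_grads = [np.mean([g[i] for g in per_sample], axis=0)
                  for i in range(len(per_sample[0]))]

    # accumulated gradients before the delayed update
    net.load_state_arrays(state)
    net.zero_grad()
    for x, t, w in samples:
        lv = exp_log_loss(net(x), t, w)
        (lv.total * 0.25).backward()
    for acc, mean in zip([p.grad for p in net.parameters()], mean_grads):
        np.testing.assert_allclose(acc, mean, atol=1e-6)


def test_accumulate_steps_one_equals_plain_update(toy_samples):
    cfg, samples = toy_samples
    net_a = build_network(cfg, seed=4)
    net_b = build_network(cfg, seed=4)
    opt_a = Adam(net_a.parameters(), lr=1e-3)
    opt_b = Adam(net_b.parameters(), lr=1e-3)
    x, t, w = samples[0]
    accumulate_and_update(net_a, [(x, t, w)], exp_log_loss, opt_a, steps=1)
    net_b.zero_grad()
    exp_log_loss(net_b(x), t, w).total.backward()
    opt_b.step()
    for pa, pb in zip(net_a.state_arrays(), net_b.state_arrays()):
        np.testing.assert_allclose(pa, pb, atol=1e-12)


def test_four_identical_samples_equal_single_sample_update(toy_samples):
    cfg, samples = toy_samples
    x, t, w = samples[0]
    net_a = build_network(cfg, seed=5)
    net_b = build_network(cfg, seed=5)
    opt_a = Adam(net_a.parameters(), lr=1e-3)
    opt_b = Adam(net_b.parameters(), lr=1e-3)
    accumulate_and_update(net_a, [(x, t, w)] * 4, exp_log_loss, opt_a, steps=4)
    accumulate_and_update(net_b, [(x, t, w)], exp_log_loss, opt_b, steps=1)
    for pa, pb in zip(net_a.state_arrays(), net_b.state_arrays()):
        np.testing.assert_allclose(pa, pb, atol=1e-9)


# -- a short end-to-end run ------------------------------------------------------

def test_short_training_run_contracts():
    spec = PhantomSpec(shape=(32, 32, 16), jitter_voxels=(1.0, 1.0, 0.5))
    cases = phantom_dataset(3, base_seed=11, spec=spec)
    pairs = [(c.ct, c.gold) for c in cases]
    cfg = NetworkConfig(in_channels=1, num_classes=6, channel_scheme=(4, 8),
                        norm_kind="instance")
    net = build_network(cfg, seed=1)
    tc = TrainConfig(max_epochs=3, plateau_patience_epochs=2,
                     early_stop_patience_epochs=2, accumulation_steps=2, seed=5)
    net, history = train(
        net, pairs[:2], pairs[2:], [get_preset("baseline")],
        loss_kind="explog", augmentation=None, config=tc,
    )
    assert history.n_epochs <= 3
    assert history.termination in ("max_epochs", "early_stop")
    assert all(np.isfinite(v) for v in history.val_loss)
    assert history.best_val_loss == min(history.val_loss)  # checkpointed best
    assert all(a >= b for a, b in zip(history.learning_rate, history.learning_rate[1:]))
    df = history.to_dataframe()
    assert list(df.columns) == ["epoch", "train_loss", "val_loss", "learning_rate"]
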