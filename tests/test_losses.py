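"""Loss functions: closed forms, scalar-loop oracle equivalence, gradients."""

import math

import numpy as np
import pytest

from oarseg.losses import (
    EPSILON,
    ClassWeights,
    WeightError,
    deep_supervision_aggregate,
    exp_log_loss,
    inverse_frequency_weights,
    one_hot,
    weighted_cross_entropy,
    weighted_soft_dice_loss,
    wsd_plus_xe_loss,
)
from oarseg.nn import Tensor
from oarseg.nn import functional as F
from oarseg.volume import GeometryError


# -- independent scalar-loop reference implementations ---------------------------

def oracle_wsd(pred, target, w):
    total = 0.0
    for l in range(pred.shape[0]):
        inter = s_t = s_p = 0.0
        for v in range(pred[l].size):
            y = target[l].ravel()[v]
            p = pred[l].ravel()[v]
            inter += y * p
            s_t += y
            s_p += p
        dice = (2 * inter + 1) / (s_t + s_p + 1)
        total += w[l] * (1 - dice)
    return total


def oracle_xe(pred, target, w):
    n = pred[0].size
    total = 0.0
    for v in range(n):
        for l in range(pred.shape[0]):
            if target[l].ravel()[v] == 1:
                p = min(max(pred[l].ravel()[v], EPSILON), 1.0)
                total += w[l] * (-math.log(p))
    return total / n


def oracle_explog(pred, target, w, gamma=0.3):
    c = pred.shape[0]
    dice_term = 0.0
    for l in range(c):
        inter = s_t = s_p = 0.0
        for v in range(pred[l].size):
            y = target[l].ravel()[v]
            p = pred[l].ravel()[v]
            inter += y * p
            s_t += y
            s_p += p
        dice = min(max((2 * inter + 1) / (s_t + s_p + 1), EPSILON), 1.0)
        dice_term += (-math.log(dice)) ** gamma
    dice_term /= c
    n = pred[0].size
    xe_term = 0.0
    for v in range(n):
        for l in range(c):
            if target[l].ravel()[v] == 1:
                p = min(max(pred[l].ravel()[v], EPSILON), 1.0)
                xe_term += w[l] * (-math.log(p)) ** gamma
    return dice_term + xe_term / n


def random_case(rng, shape=(3, 4, 3, 2)):
    """Random simplex prediction and one-hot target on a tiny volume."""
    c = shape[0]
    logits = rng.normal(size=shape)
    e = np.exp(logits - logits.max(axis=0))
    pred = e / e.sum(axis=0)
    labels = rng.integers(0, c, size=shape[1:])
    # ensure every class occurs
    labels.ravel()[:c] = np.arange(c)
    target = one_hot(labels, c).astype(np.float64)
    w = inverse_frequency_weights(labels, alpha=1 / 3, num_classes=c)
    return pred, target, w


# -- inverse-frequency weights ---------------------------------------------------

def test_weights_exact_two_class_case():
    # frequencies 1/9 and 8/9 at alpha=1/3 give exactly (2/3, 1/3)
    labels = np.array([0] * 1 + [1] * 8).reshape(1, 3, 3)
    w = inverse_frequency_weights(labels, alpha=1 / 3)
    np.testing.assert_allclose(w.weights, [2 / 3, 1 / 3], atol=1e-12)


def test_weights_uniform_cases():
    labels = np.arange(4).repeat(5).reshape(4, 5, 1)
    for alpha in (0.0, 1 / 3, 0.5, 2.0):
        w = inverse_frequency_weights(labels, alpha=alpha)
        np.testing.assert_allclose(w.weights, 0.25, atol=1e-12)
    skewed = np.array([0] * 17 + [1] * 2 + [2] * 1).reshape(4, 5, 1)
    np.testing.assert_allclose(
        inverse_frequency_weights(skewed, alpha=0.0).weights, 1 / 3, atol=1e-12
    )


def test_weights_sum_to_one_and_absent_class_error(rng):
    labels = rng.integers(0, 5, size=(6, 6, 3))
    labels.ravel()[:5] = np.arange(5)
    w = inverse_frequency_weights(labels, alpha=0.5)
    assert abs(w.weights.sum() - 1.0) < 1e-12
    with pytest.raises(WeightError, match="3"):
        inverse_frequency_weights(np.zeros((2, 2, 2), dtype=int), alpha=1 / 3, num_classes=4)


# -- weighted soft dice ----------------------------------------------------------

def test_wsd_zero_at_perfect_binary_prediction():
    labels = np.array([[[0, 1], [2, 0]], [[1, 2], [0, 0]]])
    target = one_hot(labels, 3)
    w = ClassWeights.uniform(3)
    lv = weighted_soft_dice_loss(target.copy(), target, w)
    assert lv.value == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("n", range(1, 11))
def test_wsd_disjoint_masks_closed_form(n):
    # two disjoint single-class foregrounds of n voxels each:
    # per-class term w_l * (1 - 1/(2n+1))
    size = 2 * n + 2
    pred = np.zeros((2, size, 1, 1))
    target = np.zeros((2, size, 1, 1))
    pred[1, :n] = 1.0
    target[1, n : 2 * n] = 1.0
    pred[0] = 1.0 - pred[1]
    target[0] = 1.0 - target[1]
    w = ClassWeights(np.array([0.25, 0.75]), alpha=0.0)
    lv = weighted_soft_dice_loss(pred, target, w)
    fg = 0.75 * (1 - 1 / (2 * n + 1))
    # background masks overlap in size-2n voxels out of n..? compute directly
    bg_inter = size - 2 * n
    bg = 0.25 * (1 - (2 * bg_inter + 1) / (2 * (size - n) + 1))
    assert lv.per_class[1] == pytest.approx(fg, abs=1e-12)
    assert lv.value == pytest.approx(fg + bg, abs=1e-12)


def test_wsd_empty_class_contributes_zero():
    pred = np.zeros((2, 3, 1, 1))
    target = np.zeros((2, 3, 1, 1))
    pred[0] = target[0] = 1.0  # class 1 empty in both
    lv = weighted_soft_dice_loss(pred, target, ClassWeights.uniform(2))
    assert lv.per_class[1] == pytest.approx(0.0, abs=1e-12)


# -- cross-entropy ---------------------------------------------------------------

def test_xe_perfect_prediction_is_zero_and_uniform_closed_form():
    labels = np.arange(6).reshape(6, 1, 1)
    target = one_hot(labels, 6)
    w = inverse_frequency_weights(labels, alpha=1 / 3, num_classes=6)
    assert weighted_cross_entropy(target.copy(), target, w).value == pytest.approx(0.0)
    uniform = np.full((6, 6, 1, 1), 1 / 6)
    lv = weighted_cross_entropy(uniform, target, w)
    # every class equally frequent -> mean weight = 1/6; loss = ln(6)/6
    assert lv.value == pytest.approx(math.log(6) / 6, rel=1e-9)


def test_xe_strictly_increases_as_true_probability_drops():
    target = one_hot(np.zeros((1, 1, 1), dtype=int), 2)
    w = ClassWeights.uniform(2)
    losses = [
        weighted_cross_entropy(np.array([[[[p]]], [[[1 - p]]]]), target, w).value
        for p in (0.9, 0.7, 0.5, 0.3, 0.1)
    ]
    assert np.all(np.diff(losses) > 0)


# -- combination -----------------------------------------------------------------

def test_wsd_plus_xe_components_sum_and_degenerate_cases(rng):
    pred, target, w = random_case(rng)
    lv = wsd_plus_xe_loss(pred, target, w)
    assert lv.value == pytest.approx(lv.components["wsd"] + lv.components["xe"], abs=1e-9)
    only_wsd = wsd_plus_xe_loss(pred, target, w, xe_coefficient=0.0)
    assert only_wsd.value == pytest.approx(
        weighted_soft_dice_loss(pred, target, w).value, abs=1e-12
    )
    perfect = wsd_plus_xe_loss(target.copy(), target, w)
    assert perfect.value == pytest.approx(0.0, abs=1e-9)


# -- exponential logarithmic loss ------------------------------------------------

def test_explog_zero_at_perfect_binary_prediction():
    labels = np.array([[[0, 1], [1, 0]]])
    target = one_hot(labels, 2)
    lv = exp_log_loss(target.copy(), target, ClassWeights.uniform(2))
    assert lv.value == pytest.approx(0.0, abs=1e-12)


def test_explog_dice_term_unit_contribution_at_exp_minus_one():
    # a class with smoothed Dice e^-1 contributes (-ln e^-1)^0.3 = 1 exactly
    dice = Tensor(np.array([math.exp(-1.0)]))
    contribution = (-(dice.log())).data ** 0.3
    assert contribution[0] == pytest.approx(1.0, abs=1e-12)
    # end-to-end: construct a 2-class case whose foreground Dice is e^-1
    # via soft predictions: inter=0, sums chosen so (2*0+1)/(s+1)=e^-1
    s = math.exp(1.0) - 1.0  # total mass on the empty-overlap class
    pred = np.zeros((2, 5, 1, 1))
    target = np.zeros((2, 5, 1, 1))
    target[1, 0] = 1.0  # one foreground voxel
    pred[1, 1] = s - 1.0  # soft mass elsewhere, no overlap
    pred[0] = 1.0 - pred[1]
    target[0] = 1.0 - target[1]
    lv = exp_log_loss(pred, target, ClassWeights.uniform(2))
    assert lv.components["dice_term"] * 2 >= 1.0  # class-1 term is exactly 1
    fg_dice = (2 * 0 + 1) / (1 + (s - 1) + 1)
    assert fg_dice == pytest.approx(math.exp(-1.0), abs=1e-12)


def test_explog_decreases_as_mass_moves_to_true_class():
    target = one_hot(np.array([[[0, 1, 1]]]), 2)
    w = ClassWeights.uniform(2)
    vals = []
    for good in (0.4, 0.6, 0.8, 0.95):
        pred = np.empty((2, 1, 1, 3))
        pred[1] = [[[good, good, good]]]
        pred[0] = 1 - pred[1]
        pred[0, 0, 0, 0], pred[1, 0, 0, 0] = good, 1 - good
        vals.append(exp_log_loss(pred, target, w).value)
    assert np.all(np.diff(vals) < 0)


# -- oracle equivalence and shared properties ------------------------------------

@pytest.mark.parametrize("case_seed", range(8))
def test_losses_match_scalar_loop_oracle(case_seed):
    rng = np.random.default_rng(case_seed)
    shape = (rng.integers(2, 4), rng.integers(3, 6), rng.integers(1, 6), rng.integers(1, 5))
    pred, target, w = random_case(rng, shape=tuple(int(s) for s in shape))
    assert weighted_soft_dice_loss(pred, target, w).value == pytest.approx(
        oracle_wsd(pred, target, w.weights), abs=1e-9
    )
    assert weighted_cross_entropy(pred, target, w).value == pytest.approx(
        oracle_xe(pred, target, w.weights), abs=1e-9
    )
    assert exp_log_loss(pred, target, w).value == pytest.approx(
        oracle_explog(pred, target, w.weights), abs=1e-9
    )


def test_permutation_equivariance(rng):
    pred, target, w = random_case(rng)
    perm = np.array([2, 0, 1])
    wp = ClassWeights(w.weights[perm], alpha=w.alpha)
    for fn in (weighted_soft_dice_loss, weighted_cross_entropy, exp_log_loss):
        orig = fn(pred, target, w).value
        permuted = fn(pred[perm], target[perm], wp).value
        assert permuted == pytest.approx(orig, abs=1e-9)


def test_nonnegativity_on_random_inputs():
    for seed in range(5):
        pred, target, w = random_case(np.random.default_rng(seed + 100))
        for fn in (weighted_soft_dice_loss, weighted_cross_entropy, exp_log_loss):
            assert fn(pred, target, w).value >= 0.0


def test_geometry_mismatch_raises(rng):
    pred, target, w = random_case(rng)
    with pytest.raises(GeometryError):
        weighted_soft_dice_loss(pred[:, :2], target, w)
    with pytest.raises(GeometryError):
        exp_log_loss(pred, target, ClassWeights.uniform(4))


# -- deep-supervision aggregation ------------------------------------------------

def test_deep_supervision_aggregation_rules(rng):
    pred, target, w = random_case(rng)
    main = weighted_soft_dice_loss(pred, target, w)
    assert deep_supervision_aggregate(main, []) is main
    same = deep_supervision_aggregate(main, [main, main])
    assert same.value == pytest.approx(main.value, abs=1e-12)
    zero_aux = deep_supervision_aggregate(main, [main], level_weights=[1.0, 0.0])
    assert zero_aux.value == pytest.approx(main.value, abs=1e-12)
    with pytest.raises(ValueError):
        deep_supervision_aggregate(main, [main], level_weights=[1.0, 0.5, 0.5])


# -- gradient sanity -------------------------------------------------------------

@pytest.mark.parametrize(
    "loss_fn", [weighted_soft_dice_loss, weighted_cross_entropy, exp_log_loss, wsd_plus_xe_loss]
)
def test_analytic_gradient_matches_finite_difference(loss_fn):
    rng = np.random.default_rng(5)
    logits_np = rng.normal(size=(3, 2, 2, 1))
    labels = rng.integers(0, 3, size=(2, 2, 1))
    labels.ravel()[:3] = [0, 1, 2]
    target = one_hot(labels, 3).astype(np.float64)
    w = inverse_frequency_weights(labels, alpha=1 / 3, num_classes=3)

    logits = Tensor(logits_np, requires_grad=True)
    loss = loss_fn(F.softmax_channels(logits), target, w)
    loss.total.backward()

    def value_at(arr):
        return loss_fn(F.softmax_channels(Tensor(arr)), target, w).value

    eps = 1e-6
    for idx in [(0, 0, 0, 0), (1, 1, 0, 0), (2, 0, 1, 0)]:
        hi = logits_np.copy()
        hi[idx] += eps
        lo = logits_np.copy()
        lo[idx] -= eps
        numeric = (value_at(hi) - value_at(lo)) / (2 * eps)
        assert logits.grad[idx] == pytest.approx(numeric, abs=1e-4)
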