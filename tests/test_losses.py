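"""Loss-function oracles: every formula is checked against an independent
scalar-loop reference implementation and against hand-computed values."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scintibsi.losses import (class_weights, dsv_loss,
                              generalized_dice_grad_logits,
                              generalized_dice_loss, softmax,
                              weighted_softmax_cross_entropy,
                              weighted_softmax_cross_entropy_grad_logits)

PHI = (1 + np.sqrt(5)) / 2


# --- scalar-loop references -------------------------------------------------

def softmax_ref(y):
    C, N = y.shape
    p = np.zeros_like(y, dtype=float)
    for n in range(N):
        exps = [np.exp(y[c, n]) for c in range(C)]
        for c in range(C):
            p[c, n] = exps[c] / sum(exps)
    return p


def gdl_ref(p, t, eps):
    C, N = p.shape
    acc = 0.0
    for c in range(C):
        num = sum(p[c, n] * t[c, n] for n in range(N)) + eps
        den = sum(p[c, n] for n in range(N)) + sum(t[c, n] for n in range(N)) + eps
        acc += num / den
    return 1.0 - (2.0 / C) * acc


def weights_ref(t):
    C, N = t.shape
    return np.array([(N - sum(t[c, n] for n in range(N))) / N for c in range(C)])


def wsce_ref(p, t, w):
    C, N = p.shape
    acc = 0.0
    for n in range(N):
        for c in range(C):
            if t[c, n]:
                acc += w[c] * np.log(max(p[c, n], 1e-12))
    return -acc / N


def random_field(rng, C, N):
    y = rng.normal(size=(C, N))
    labels = rng.integers(C, size=N)
    t = np.zeros((C, N))
    t[labels, np.arange(N)] = 1.0
    return y, t


# --- softmax ----------------------------------------------------------------

def test_softmax_worked_values():
    p = softmax(np.array([[np.log(3.0)], [0.0]]), axis=0)
    np.testing.assert_allclose(p[:, 0], [0.75, 0.25], atol=1e-12)
    p = softmax(np.array([[0.0], [0.0]]), axis=0)
    np.testing.assert_allclose(p[:, 0], [0.5, 0.5])


def test_softmax_shift_invariance(rng):
    y, _ = random_field(rng, 3, 10)
    np.testing.assert_allclose(softmax(y, axis=0), softmax(y + 7.3, axis=0),
                               atol=1e-12)


def test_softmax_matches_scalar_reference(rng):
    y, _ = random_field(rng, 4, 12)
    np.testing.assert_allclose(softmax(y, axis=0), softmax_ref(y), atol=1e-10)


# --- generalized Dice loss ---------------------------------------------------

def test_gdl_perfect_match_is_near_zero(rng):
    _, t = random_field(rng, 3, 20)
    loss = generalized_dice_loss(t, t, eps=0.001)
    assert abs(loss) <= 0.001  # bounded by eps-driven slack


def test_gdl_disjoint_limit():
    t = np.array([[1.0, 1.0], [0.0, 0.0]])
    p = 1.0 - t
    assert generalized_dice_loss(p, t, eps=1e-12) == pytest.approx(1.0, abs=1e-9)


def test_gdl_two_pixel_hand_case():
    # two pixels, one per class, uniform probabilities, eps = 0.001
    t = np.array([[1.0, 0.0], [0.0, 1.0]])
    p = np.full((2, 2), 0.5)
    expected = 1.0 - (2.0 / 2) * 2 * (0.5 + 0.001) / (2.0 + 0.001)
    assert generalized_dice_loss(p, t, eps=0.001) == pytest.approx(expected,
                                                                   abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(C=st.integers(2, 4), N=st.integers(1, 16), seed=st.integers(0, 1000))
def test_gdl_matches_scalar_reference(C, N, seed):
    rng = np.random.default_rng(seed)
    y, t = random_field(rng, C, N)
    p = softmax(y, axis=0)
    assert generalized_dice_loss(p, t, 0.001) == pytest.approx(
        gdl_ref(p, t, 0.001), abs=1e-10)


def test_gdl_decreasing_in_correct_probability():
    t = np.array([[1.0, 0.0], [0.0, 1.0]])
    losses = []
    for q in (0.3, 0.5, 0.7, 0.9):
        p = np.array([[q, 1 - q], [1 - q, q]])
        losses.append(generalized_dice_loss(p, t, 0.001))
    assert all(a > b for a, b in zip(losses, losses[1:]))


def test_gdl_rejects_bad_eps_and_shapes():
    t = np.array([[1.0], [0.0]])
    with pytest.raises(ValueError):
        generalized_dice_loss(t, t, eps=0.0)
    with pytest.raises(ValueError):
        generalized_dice_loss(t, np.ones((3, 1)))


def test_gdl_gradient_matches_finite_differences(rng):
    y, t = random_field(rng, 3, 8)
    g = generalized_dice_grad_logits(y, t, 0.001)
    eps = 1e-6
    for _ in range(12):
        c, n = rng.integers(3), rng.integers(8)
        y[c, n] += eps
        up = generalized_dice_loss(softmax(y, axis=0), t, 0.001)
        y[c, n] -= 2 * eps
        dn = generalized_dice_loss(softmax(y, axis=0), t, 0.001)
        y[c, n] += eps
        assert g[c, n] == pytest.approx((up - dn) / (2 * eps), abs=1e-7)


# --- class weights -----------------------------------------------------------

@pytest.mark.parametrize("count,expected", [(0, 1.0), (100, 0.0), (10, 0.9)])
def test_class_weight_values(count, expected):
    t = np.zeros((2, 100))
    t[0, :count] = 1.0
    t[1, count:] = 1.0
    assert class_weights(t)[0] == pytest.approx(expected)


def test_class_weights_sum_when_partitioned(rng):
    _, t = random_field(rng, 5, 40)
    assert class_weights(t).sum() == pytest.approx(5 - 1)


# --- weighted softmax cross entropy ------------------------------------------

def test_wsce_zero_at_perfect_prediction():
    t = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert weighted_softmax_cross_entropy(t, t) == pytest.approx(0.0, abs=1e-9)


def test_wsce_two_pixel_hand_case():
    t = np.array([[1.0, 0.0], [0.0, 1.0]])
    p = np.full((2, 2), 0.5)
    # both class weights are 0.5, so L = -(1/2)(0.5 ln 0.5 + 0.5 ln 0.5)
    assert weighted_softmax_cross_entropy(p, t) == pytest.approx(
        0.5 * np.log(2.0), abs=1e-12)


def test_wsce_linear_in_weights(rng):
    y, t = random_field(rng, 3, 11)
    p = softmax(y, axis=0)
    w = class_weights(t)
    assert weighted_softmax_cross_entropy(p, t, 2 * w) == pytest.approx(
        2 * weighted_softmax_cross_entropy(p, t, w), rel=1e-12)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(C=st.integers(2, 4), N=st.integers(1, 16), seed=st.integers(0, 1000))
def test_wsce_matches_scalar_reference(C, N, seed):
    rng = np.random.default_rng(seed)
    y, t = random_field(rng, C, N)
    p = softmax(y, axis=0)
    w = class_weights(t)
    assert weighted_softmax_cross_entropy(p, t, w) == pytest.approx(
        wsce_ref(p, t, weights_ref(t)), abs=1e-10)


def test_wsce_warns_and_stays_finite_at_floor():
    t = np.array([[1.0], [0.0]])
    p = np.array([[0.0], [1.0]])
    with pytest.warns(RuntimeWarning):
        loss = weighted_softmax_cross_entropy(p, t)
    assert np.isfinite(loss)


def test_wsce_gradient_matches_finite_differences(rng):
    y, t = random_field(rng, 3, 9)
    g = weighted_softmax_cross_entropy_grad_logits(y, t)
    eps = 1e-6
    for _ in range(12):
        c, n = rng.integers(3), rng.integers(9)
        y[c, n] += eps
        up = weighted_softmax_cross_entropy(softmax(y, axis=0), t)
        y[c, n] -= 2 * eps
        dn = weighted_softmax_cross_entropy(softmax(y, axis=0), t)
        y[c, n] += eps
        assert g[c, n] == pytest.approx((up - dn) / (2 * eps), abs=1e-7)


# --- deep-supervision sum ----------------------------------------------------

def test_dsv_is_sum_of_six_dice_terms(rng):
    ys = [random_field(rng, 3, 10)[0] for _ in range(6)]
    _, t = random_field(rng, 3, 10)
    expected = sum(gdl_ref(softmax(y, axis=0), t, 0.001) for y in ys)
    assert dsv_loss(ys, t, 0.001) == pytest.approx(expected, abs=1e-10)


def test_dsv_six_identical_outputs(rng):
    y, t = random_field(rng, 3, 10)
    single = generalized_dice_loss(softmax(y, axis=0), t, 0.001)
    assert dsv_loss([y] * 6, t, 0.001) == pytest.approx(6 * single, rel=1e-12)


def test_dsv_requires_exactly_six_outputs(rng):
    y, t = random_field(rng, 3, 10)
    with pytest.raises(ValueError):
        dsv_loss([y] * 5, t)
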