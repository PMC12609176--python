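"""Closed-form identities and oracle checks for the compound loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hyp

from polysite import objective as ob
from polysite._autodiff import Tensor
from polysite.errors import ConsistencyError


# ---------------------------------------------------------------------------
# cross entropy
# ---------------------------------------------------------------------------

def test_ce_zero_for_certain_correct_predictions():
    labels = np.array([0, 3, 6])
    logits = np.full((3, 7), -1000.0)
    logits[np.arange(3), labels] = 1000.0
    assert float(ob.weighted_cross_entropy(logits, labels).data) < 1e-12


def test_ce_uniform_logits_single_residue_is_ln_K():
    # weighted-mean normalization cancels the lone weight
    for k, w in ((0, 0.01), (4, 0.5), (5, 2.5)):
        loss = ob.weighted_cross_entropy(
            np.zeros((1, 7)), np.array([k]),
            weights=np.array([0.01, 1.0, 0.7, 1.0, 0.5, 2.5, 2.0]))
        assert abs(float(loss.data) - np.log(7.0)) < 1e-12


def test_ce_masking_equals_row_removal():
    rng = np.random.default_rng(0)
    logits = rng.standard_normal((5, 7))
    labels = rng.integers(0, 7, 5)
    w = np.array([0.01, 1.0, 0.7, 1.0, 0.5, 2.5, 2.0])
    mask = np.array([True, True, False, True, True])
    masked = ob.weighted_cross_entropy(logits, labels, w, mask)
    removed = ob.weighted_cross_entropy(logits[mask], labels[mask], w)
    assert abs(float(masked.data) - float(removed.data)) < 1e-12


def test_ce_all_masked_raises():
    with pytest.raises(ConsistencyError):
        ob.weighted_cross_entropy(np.zeros((2, 7)), np.zeros(2, dtype=int),
                                  mask=np.zeros(2, dtype=bool))


# ---------------------------------------------------------------------------
# center loss and center updates
# ---------------------------------------------------------------------------

def test_center_loss_zero_at_centers_and_half_square_distance():
    centers = np.zeros((7, 4))
    feats = np.zeros((3, 4))
    labels = np.array([1, 2, 3])
    assert float(ob.center_loss(feats, labels, centers).data) == 0.0
    feats = np.array([[2.0, 0.0, 0.0, 0.0]])  # distance 2 from center
    assert abs(float(ob.center_loss(feats, np.array([0]), centers).data) - 2.0) < 1e-12


def test_center_loss_invariant_under_batch_duplication():
    rng = np.random.default_rng(1)
    feats = rng.standard_normal((6, 4))
    labels = rng.integers(0, 7, 6)
    centers = rng.standard_normal((7, 4))
    once = float(ob.center_loss(feats, labels, centers).data)
    twice = float(ob.center_loss(np.vstack([feats, feats]),
                                 np.tile(labels, 2), centers).data)
    assert abs(once - twice) < 1e-12


def test_update_centers_alpha_limits_and_absent_classes():
    rng = np.random.default_rng(2)
    feats = rng.standard_normal((8, 4))
    labels = np.array([0, 0, 1, 1, 1, 2, 2, 2])
    init = ob.CenterState(rng.standard_normal((7, 4)), alpha=0.0)
    assert np.array_equal(ob.update_centers(init, feats, labels).centers,
                          init.centers)
    full = ob.CenterState(init.centers.copy(), alpha=1.0)
    updated = ob.update_centers(full, feats, labels)
    for k in (0, 1, 2):
        assert np.allclose(updated.centers[k], feats[labels == k].mean(axis=0))
    for k in range(3, 7):  # absent classes bit-identical
        assert np.array_equal(updated.centers[k], init.centers[k])


def test_repeated_center_updates_contract_geometrically():
    rng = np.random.default_rng(3)
    feats = rng.standard_normal((10, 3))
    labels = rng.integers(0, 2, 10)
    state = ob.CenterState(rng.standard_normal((2, 3)), alpha=0.5)
    means = np.stack([feats[labels == k].mean(axis=0) for k in (0, 1)])
    err = [np.abs(state.centers - means).max()]
    for _ in range(6):
        state = ob.update_centers(state, feats, labels)
        err.append(np.abs(state.centers - means).max())
    ratios = [err[i + 1] / err[i] for i in range(6)]
    assert all(abs(r - 0.5) < 1e-9 for r in ratios)


# ---------------------------------------------------------------------------
# inter loss
# ---------------------------------------------------------------------------

def test_inter_loss_zero_when_separated_and_double_counts_pairs():
    centers = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
    assert ob.inter_loss(centers, margin=0.1) == 0.0
    coincident = np.array([[1.0, 1.0], [1.0, 1.0]])
    assert abs(ob.inter_loss(coincident, margin=0.1) - 0.2) < 1e-15
    assert abs(ob.inter_loss(coincident, margin=0.1, pairs="unordered") - 0.1) < 1e-15


def test_inter_loss_matches_bruteforce_double_loop():
    rng = np.random.default_rng(4)
    centers = 0.05 * rng.standard_normal((7, 6))
    brute = 0.0
    for i in range(7):
        for j in range(7):
            if i != j:
                brute += max(0.0, 0.1 - np.linalg.norm(centers[i] - centers[j]))
    assert abs(ob.inter_loss(centers, 0.1) - brute) < 1e-9


def test_inter_loss_rigid_transform_invariant():
    rng = np.random.default_rng(5)
    centers = 0.05 * rng.standard_normal((5, 3))
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    moved = centers @ q.T + rng.standard_normal(3)
    assert abs(ob.inter_loss(centers, 0.1) - ob.inter_loss(moved, 0.1)) < 1e-12


# ---------------------------------------------------------------------------
# total
# ---------------------------------------------------------------------------

def test_total_loss_identities():
    cfg = ob.LossConfig(lambda1=0.0, lambda2=0.0)
    assert ob.total_loss(1.7, 9.9, 3.3, cfg).total == 1.7
    default = ob.LossConfig()
    assert default.lambda1 == 0.1 and default.lambda2 == 0.001
    assert default.margin == 0.1
    assert ob.CenterState.initialize(7, 4).alpha == 0.5
    bd = ob.total_loss(1.0, 2.0, 3.0, default)
    assert abs(bd.total - 1.203) < 1e-12


@settings(deadline=None, max_examples=30)
@given(hyp.floats(0, 5), hyp.floats(0, 5), hyp.floats(0, 5))
def test_total_loss_decomposition_identity(ce, center, inter):
    bd = ob.total_loss(ce, center, inter, ob.LossConfig())
    assert abs(bd.total - (bd.ce + 0.1 * bd.center + 0.001 * bd.inter)) < 1e-9


def test_compound_loss_gradient_matches_finite_difference():
    rng = np.random.default_rng(6)
    feats = rng.standard_normal((4, 5))
    logits = rng.standard_normal((4, 7))
    labels = rng.integers(0, 7, 4)
    centers = ob.CenterState(rng.standard_normal((7, 5)), 0.5)
    cfg = ob.LossConfig()

    def value(f, lo):
        t, _ = ob.compound_loss(Tensor(f), Tensor(lo), labels, centers, cfg)
        return float(t.data)

    ft = Tensor(feats, requires_grad=True)
    lt = Tensor(logits, requires_grad=True)
    total, _ = ob.compound_loss(ft, lt, labels, centers, cfg)
    total.backward()
    eps = 1e-6
    for arr, tensor in ((feats, ft), (logits, lt)):
        num = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            p, m = arr.copy(), arr.copy()
            p[i] += eps
            m[i] -= eps
            if arr is feats:
                num[i] = (value(p, logits) - value(m, logits)) / (2 * eps)
            else:
                num[i] = (value(feats, p) - value(feats, m)) / (2 * eps)
        assert np.abs(num - tensor.grad).max() < 1e-6
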