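import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiercls.losses import (
    MarginConfig,
    QuadrupletEmbeddings,
    combined_loss,
    combined_loss_grads,
    constraint_satisfied,
    euclidean_distance,
    hinge_constraint_loss,
    hinge_constraint_loss_grad,
    l2_normalize,
    softmax_loss,
    softmax_loss_grad,
    softmax_probabilities,
)
from tests.conftest import random_unit_vectors

M = MarginConfig(m1=0.2, m2=0.4, lam=0.5)


# --- independent oracles (literal formula evaluation, scalar loops) --------

def oracle_softmax(logits):
    es = [math.exp(z) for z in logits]
    s = sum(es)
    return [e / s for e in es]


def oracle_softmax_loss(logits, labels):
    total = 0.0
    for row, y in zip(logits, labels):
        total += -math.log(oracle_softmax(row)[y])
    return total / len(labels)


def oracle_hinge(quads, m1, m2):
    t1 = t2 = 0.0
    for x, pp, pm, n in quads:
        dpp = math.sqrt(sum((a - b) ** 2 for a, b in zip(x, pp)))
        dpm = math.sqrt(sum((a - b) ** 2 for a, b in zip(x, pm)))
        dn = math.sqrt(sum((a - b) ** 2 for a, b in zip(x, n)))
        t1 += max(0.0, dpp - dpm + m1 - m2)
        t2 += max(0.0, dpm - dn + m2)
    return (t1 + t2) / (2 * len(quads))


def unit_at_distance(dist, d=8):
    """Unit vector at a prescribed Euclidean distance from e1 (dist <= 2)."""
    cos = 1 - dist**2 / 2
    v = np.zeros(d)
    v[0], v[1] = cos, math.sqrt(max(0.0, 1 - cos**2))
    return v


def quad_with_distances(dpp, dpm, dn, d=8):
    x = np.zeros(d)
    x[0] = 1.0
    return QuadrupletEmbeddings(
        x, unit_at_distance(dpp, d), unit_at_distance(dpm, d), unit_at_distance(dn, d)
    )


# --- margin config ---------------------------------------------------------

class TestMarginConfig:
    def test_defaults(self):
        m = MarginConfig()
        assert (m.m1, m.m2, m.lam) == (0.2, 0.4, 0.5)

    def test_m1_ge_m2_rejected(self):
        with pytest.raises(ValueError, match="m1 must be <"):
            MarginConfig(m1=0.4, m2=0.4)

    @pytest.mark.parametrize("lam", [0.0, 1.0, -0.1, 1.5])
    def test_lam_open_interval(self, lam):
        with pytest.raises(ValueError, match="lam"):
            MarginConfig(lam=lam)

    def test_boundary_allowed_for_diagnostics(self):
        assert MarginConfig(lam=1.0, allow_boundary=True).lam == 1.0


# --- softmax ---------------------------------------------------------------

class TestSoftmax:
    def test_uniform_logits(self):
        p = softmax_probabilities(np.zeros(8))
        np.testing.assert_allclose(p, np.full(8, 0.125), rtol=1e-15)

    def test_closed_form_two_class(self):
        p = softmax_probabilities(np.log([1.0, 3.0]))
        np.testing.assert_allclose(p, [0.25, 0.75], rtol=1e-12)

    def test_matches_oracle(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=8)
        np.testing.assert_allclose(softmax_probabilities(z), oracle_softmax(z), rtol=1e-12)

    def test_sums_to_one_large_logits(self):
        p = softmax_probabilities(np.array([1000.0, 1001.0, 999.0]))
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p > 0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            softmax_probabilities(np.array([np.nan, 0.0]))


class TestSoftmaxLoss:
    def test_uniform_is_log_k(self):
        assert softmax_loss(np.zeros((1, 8)), np.array([3])) == pytest.approx(math.log(8), rel=1e-12)

    def test_confident_correct_near_zero(self):
        logits = np.zeros((2, 4))
        logits[0, 1] = logits[1, 2] = 50.0
        assert softmax_loss(logits, np.array([1, 2])) < 1e-12

    def test_matches_oracle_batch(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(4, 8))
        labels = rng.integers(0, 8, size=4)
        assert softmax_loss(logits, labels) == pytest.approx(
            oracle_softmax_loss(logits, labels), rel=1e-12
        )

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            softmax_loss(np.empty((0, 8)), np.empty(0, dtype=int))

    def test_nonnegative_property(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            logits = rng.normal(size=(3, 5)) * rng.uniform(0.1, 10)
            assert softmax_loss(logits, rng.integers(0, 5, size=3)) >= 0.0


# --- distances and constraint ----------------------------------------------

class TestEuclideanDistance:
    def test_zero_on_equal(self):
        v = np.ones(5)
        assert euclidean_distance(v, v) == 0.0

    def test_basis_vectors(self):
        e1, e2 = np.eye(2)
        assert euclidean_distance(e1, e2) == pytest.approx(math.sqrt(2), rel=1e-12)

    def test_matches_oracle(self):
        rng = np.random.default_rng(3)
        a, b = random_unit_vectors(rng, 2, 16)
        want = math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
        assert euclidean_distance(a, b) == pytest.approx(want, rel=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            euclidean_distance(np.ones(3), np.ones(4))


class TestConstraintSatisfied:
    def test_hand_case_satisfied(self):
        assert constraint_satisfied(quad_with_distances(0.2, 0.5, 1.0), M)

    def test_degenerate_equal_embeddings(self):
        assert not constraint_satisfied(quad_with_distances(0.0, 0.0, 0.0), M)

    def test_hand_case_violated(self):
        assert not constraint_satisfied(quad_with_distances(0.9, 0.3, 0.4), M)


class TestHingeLoss:
    def test_satisfied_quadruplet_is_zero(self):
        assert hinge_constraint_loss([quad_with_distances(0.2, 0.5, 1.0)], M) == 0.0

    def test_hand_evaluated_value(self):
        # term1 = max(0, 0.9-0.3+0.2-0.4)=0.4; term2 = max(0, 0.3-0.4+0.4)=0.3
        got = hinge_constraint_loss([quad_with_distances(0.9, 0.3, 0.4)], M)
        assert got == pytest.approx(0.35, abs=1e-12)

    def test_matches_oracle_random(self):
        rng = np.random.default_rng(4)
        arr = random_unit_vectors(rng, 50 * 4, 8).reshape(50, 4, 8)
        want = oracle_hinge([(q[0], q[1], q[2], q[3]) for q in arr], M.m1, M.m2)
        assert hinge_constraint_loss(arr, M) == pytest.approx(want, abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hinge_constraint_loss([], M)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        arr = random_unit_vectors(rng, 10 * 4, 8).reshape(10, 4, 8)
        q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        rotated = arr @ q.T
        assert hinge_constraint_loss(rotated, M) == pytest.approx(
            hinge_constraint_loss(arr, M), rel=1e-10
        )

    def test_monotone_in_m1(self):
        rng = np.random.default_rng(6)
        arr = random_unit_vectors(rng, 20 * 4, 8).reshape(20, 4, 8)
        vals = [
            hinge_constraint_loss(arr, MarginConfig(m1=m1, m2=0.5))
            for m1 in (0.0, 0.1, 0.2, 0.3, 0.4)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


# --- combined --------------------------------------------------------------

class TestCombinedLoss:
    def test_paper_default_arithmetic(self):
        # lam=0.5, J=ln 8 via uniform logits, E_t=0 via satisfied quadruplet
        logits = np.zeros((1, 8))
        quads = [quad_with_distances(0.2, 0.5, 1.0)]
        got = combined_loss(logits, np.array([0]), quads, M)
        assert got == pytest.approx(0.5 * math.log(8), rel=1e-12)

    def test_lam_near_one_is_softmax(self):
        rng = np.random.default_rng(7)
        logits = rng.normal(size=(4, 8))
        labels = rng.integers(0, 8, size=4)
        arr = random_unit_vectors(rng, 8, 8).reshape(2, 4, 8)
        m = MarginConfig(lam=1 - 1e-9)
        got = combined_loss(logits, labels, arr, m)
        assert got == pytest.approx(softmax_loss(logits, labels), rel=1e-6)

    def test_component_oracle_lam_03(self):
        rng = np.random.default_rng(8)
        logits = rng.normal(size=(5, 8))
        labels = rng.integers(0, 8, size=5)
        arr = random_unit_vectors(rng, 3 * 4, 8).reshape(3, 4, 8)
        m = MarginConfig(lam=0.3)
        want = 0.3 * oracle_softmax_loss(logits, labels) + 0.7 * oracle_hinge(
            [(q[0], q[1], q[2], q[3]) for q in arr], m.m1, m.m2
        )
        assert combined_loss(logits, labels, arr, m) == pytest.approx(want, rel=1e-10)

    def test_degenerate_batch_falls_back_to_softmax(self):
        logits = np.zeros((2, 8))
        got = combined_loss(logits, np.array([0, 1]), None, M)
        assert got == pytest.approx(0.5 * math.log(8), rel=1e-12)


# --- gradients -------------------------------------------------------------

def _away_from_kinks(arr, m, eps=1e-3):
    x, pp, pm, n = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    dpp = np.linalg.norm(x - pp, axis=1)
    dpm = np.linalg.norm(x - pm, axis=1)
    dn = np.linalg.norm(x - n, axis=1)
    return np.all(np.abs(dpp - dpm + m.m1 - m.m2) > eps) and np.all(
        np.abs(dpm - dn + m.m2) > eps
    )


class TestGradients:
    def test_softmax_grad_finite_difference(self):
        rng = np.random.default_rng(9)
        logits = rng.normal(size=(3, 8))
        labels = rng.integers(0, 8, size=3)
        g = softmax_loss_grad(logits, labels)
        h = 1e-5
        for i in range(3):
            for j in range(8):
                zp, zm = logits.copy(), logits.copy()
                zp[i, j] += h
                zm[i, j] -= h
                fd = (softmax_loss(zp, labels) - softmax_loss(zm, labels)) / (2 * h)
                assert g[i, j] == pytest.approx(fd, abs=1e-7)

    def test_hinge_grad_finite_difference(self):
        rng = np.random.default_rng(10)
        while True:
            arr = random_unit_vectors(rng, 2 * 4, 6).reshape(2, 4, 6)
            if _away_from_kinks(arr, M):
                break
        g = hinge_constraint_loss_grad(arr, M)
        h = 1e-5
        for idx in np.ndindex(arr.shape):
            ap, am = arr.copy(), arr.copy()
            ap[idx] += h
            am[idx] -= h
            fd = (hinge_constraint_loss(ap, M) - hinge_constraint_loss(am, M)) / (2 * h)
            assert g[idx] == pytest.approx(fd, abs=1e-6)

    def test_combined_grads_match_components(self):
        rng = np.random.default_rng(11)
        logits = rng.normal(size=(4, 8))
        labels = rng.integers(0, 8, size=4)
        arr = random_unit_vectors(rng, 2 * 4, 6).reshape(2, 4, 6)
        gl, ge = combined_loss_grads(logits, labels, arr, M)
        np.testing.assert_allclose(gl, 0.5 * softmax_loss_grad(logits, labels))
        np.testing.assert_allclose(ge, 0.5 * hinge_constraint_loss_grad(arr, M))


# --- type validation --------------------------------------------------------

class TestQuadrupletEmbeddings:
    def test_non_unit_rejected(self):
        v = np.zeros(4)
        v[0] = 2.0
        u = np.zeros(4)
        u[0] = 1.0
        with pytest.raises(ValueError, match="unit-norm"):
            QuadrupletEmbeddings(v, u, u, u)

    def test_dimension_mismatch_rejected(self):
        u3, u4 = np.zeros(3), np.zeros(4)
        u3[0] = u4[0] = 1.0
        with pytest.raises(ValueError, match="shape"):
            QuadrupletEmbeddings(u3, u4, u3, u3)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_l2_normalize_is_unit(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(3, 7)) * rng.uniform(0.1, 100)
        nrm = np.linalg.norm(l2_normalize(v), axis=1)
        np.testing.assert_allclose(nrm, 1.0, atol=1e-9)
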