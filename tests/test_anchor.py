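"""Anchor-space alignment: Gram algebra, Fisher weighting, subspace projection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitdistill.anchor import (
    AnchorWeights,
    FisherWeights,
    align_loss,
    default_subspace_rank,
    estimate_fisher_diag,
    fisher_align_loss,
    gram,
    principal_projector,
    subspace_loss,
)
from gaitdistill.autodiff import Tensor


def random_gram(rng, n=4):
    w = rng.standard_normal((6, n))
    return w.T @ w


class TestGram:
    def test_identity_weights_give_identity_gram(self):
        g = gram(AnchorWeights(np.eye(2), "teacher"))
        assert np.allclose(g.matrix, np.eye(2))

    def test_hand_computed_product(self):
        g = gram(AnchorWeights(np.array([[1.0, 2.0], [3.0, 4.0]]), "student"))
        assert np.allclose(g.matrix, [[10.0, 14.0], [14.0, 20.0]])

    def test_zero_column_annihilates_row_and_column(self):
        w = np.random.default_rng(0).standard_normal((5, 3))
        w[:, 1] = 0.0
        g = gram(AnchorWeights(w, "teacher")).matrix
        assert np.allclose(g[1, :], 0.0) and np.allclose(g[:, 1], 0.0)

    def test_nonfinite_input_names_origin(self):
        w = np.ones((3, 2))
        w[0, 0] = np.nan
        with pytest.raises(ValueError, match="teacher"):
            AnchorWeights(w, "teacher")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_gram_symmetric_psd_on_random_weights(self, seed):
        w = np.random.default_rng(seed).standard_normal((7, 5))
        g = gram(AnchorWeights(w, "student")).matrix
        assert np.allclose(g, g.T, atol=1e-10)
        assert np.linalg.eigvalsh(g).min() >= -1e-8 * np.abs(g).max()


class TestAlignLosses:
    def test_zero_iff_equal(self, rng):
        g = random_gram(rng)
        assert align_loss(g, g) == 0.0
        assert align_loss(np.eye(2), np.zeros((2, 2))) == pytest.approx(2.0)

    def test_matches_elementwise_double_loop(self, rng):
        gs, gt = random_gram(rng), random_gram(rng)
        expected = sum(
            (gs[i, j] - gt[i, j]) ** 2 for i in range(4) for j in range(4)
        )
        assert align_loss(gs, gt) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_reports_both_shapes(self):
        with pytest.raises(ValueError, match=r"\(2, 2\).*\(3, 3\)"):
            align_loss(np.eye(2), np.eye(3))

    def test_unit_fisher_weights_recover_unweighted_loss(self, rng):
        gs, gt = random_gram(rng), random_gram(rng)
        f = FisherWeights(np.ones(4), 1)
        assert fisher_align_loss(gs, gt, f) == pytest.approx(
            align_loss(gs, gt), rel=1e-10
        )

    def test_zero_fisher_weights_give_zero(self, rng):
        gs, gt = random_gram(rng), random_gram(rng)
        assert fisher_align_loss(gs, gt, FisherWeights(np.zeros(4), 1)) == 0.0

    def test_one_hot_fisher_selects_single_row(self, rng):
        gs, gt = random_gram(rng, 3), random_gram(rng, 3)
        f = np.array([0.0, 2.5, 0.0])
        expected = 2.5 * ((gs[1] - gt[1]) ** 2).sum()
        assert fisher_align_loss(gs, gt, FisherWeights(f, 1)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_fisher_length_mismatch_raises(self, rng):
        g = random_gram(rng)
        with pytest.raises(ValueError, match="length"):
            fisher_align_loss(g, g, FisherWeights(np.ones(3), 1))


class TestSubspace:
    def test_dominant_axis_of_diagonal_matrix(self):
        p = principal_projector(np.diag([3.0, 1.0]), 1)
        assert np.allclose(p.projector, np.diag([1.0, 0.0]))

    def test_full_rank_gives_identity(self, rng):
        g = random_gram(rng)
        p = principal_projector(g, 4)
        assert np.allclose(p.projector, np.eye(4), atol=1e-10)

    def test_projector_properties_match_eigendecomposition(self, rng):
        g = random_gram(rng, 8)
        k = 3
        p = principal_projector(g, k)
        assert np.allclose(p.projector, p.projector.T, atol=1e-10)
        assert np.allclose(p.projector @ p.projector, p.projector, atol=1e-8)
        assert np.trace(p.projector) == pytest.approx(k, abs=1e-6)
        # oracle: dense eigendecomposition, top-k eigenspace
        evals, evecs = np.linalg.eigh(g)
        u = evecs[:, np.argsort(-evals)[:k]]
        assert np.allclose(p.projector, u @ u.T, atol=1e-8)

    def test_rank_out_of_range(self, rng):
        with pytest.raises(ValueError, match="out of range"):
            principal_projector(random_gram(rng), 0)
        with pytest.raises(ValueError, match="out of range"):
            principal_projector(random_gram(rng), 5)

    def test_subspace_loss_zero_at_equality_and_identity_projector(self, rng):
        gs, gt = random_gram(rng), random_gram(rng)
        p_full = principal_projector(gt, 4)
        assert subspace_loss(gs, gs, p_full) == 0.0
        assert subspace_loss(gs, gt, p_full) == pytest.approx(
            align_loss(gs, gt), rel=1e-10
        )

    def test_projection_is_nonexpansive_on_100_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            gs, gt = random_gram(rng, 5), random_gram(rng, 5)
            k = int(rng.integers(1, 6))
            p = principal_projector(gt, k)
            assert subspace_loss(gs, gt, p) <= align_loss(gs, gt) + 1e-12

    def test_default_rank_captures_energy_and_respects_cap(self, rng):
        g = np.diag([100.0, 1.0, 0.5, 0.1, 0.05, 0.01])
        k = default_subspace_rank(g)
        assert 1 <= k <= 3  # capped at D_anchor / 2
        evals = np.sort(np.linalg.eigvalsh(g))[::-1]
        assert evals[:k].sum() / evals.sum() >= 0.95 or k == 3


class _QuadraticAnchorModel:
    """Toy model whose loss is 1/2 sum z_k^2 at a fixed anchor activation."""

    def __init__(self, c):
        self.c = np.asarray(c, dtype=np.float64)

    def forward_with_anchor(self, x):
        z = Tensor(self.c, requires_grad=True)
        tau = z  # prediction IS the anchor activation
        return tau, z, Tensor(np.eye(len(self.c)))


class TestFisherEstimation:
    def test_analytic_gradient_squares(self):
        # L = 1/2 sum z_k^2  =>  dL/dz_k = z_k  =>  diag = c_k^2
        c = np.array([1.0, -2.0, 0.5])
        model = _QuadraticAnchorModel(c)
        f = estimate_fisher_diag(
            model, [(None, np.zeros(3))], loss_fn=lambda tau, y: (tau * tau).sum() * 0.5
        )
        assert np.allclose(f.diag, c**2)

    def test_loss_independent_dimension_gets_zero_weight(self):
        c = np.array([1.0, 3.0])
        model = _QuadraticAnchorModel(c)
        f = estimate_fisher_diag(
            model,
            [(None, np.zeros(2))],
            loss_fn=lambda tau, y: (tau[0:1] * tau[0:1]).sum(),
        )
        assert f.diag[1] == 0.0 and f.diag[0] > 0.0

    def test_entries_nonnegative_and_deterministic(self, teacher_run, clean_dataset):
        from gaitdistill.trainer import _build_caches, _prepare_split

        tc = teacher_run.train_config
        train = _prepare_split(
            clean_dataset, "hip", "train", teacher_run.stats, tc.sg, True,
            teacher_run.config,
        )
        f1 = _build_caches(teacher_run.model, train)["fisher"]
        f2 = _build_caches(teacher_run.model, train)["fisher"]
        assert np.all(f1.diag >= 0.0)
        assert np.array_equal(f1.diag, f2.diag)

    def test_empty_batch_stream_raises(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_fisher_diag(_QuadraticAnchorModel([1.0]), [])

    def test_model_without_anchor_head_raises(self):
        with pytest.raises(TypeError, match="anchor"):
            estimate_fisher_diag(object(), [(None, None)])

    def test_unit_mean_normalization(self):
        f = FisherWeights(np.array([1.0, 3.0]), 1).normalized()
        assert f.diag.mean() == pytest.approx(1.0)


class TestDifferentiability:
    """All three alignment losses backpropagate into the student adapter."""

    @pytest.mark.parametrize("which", ["align", "fisher", "subspace"])
    def test_finite_difference_gradient_wrt_student_weights(self, which, rng):
        wt = rng.standard_normal((6, 4))
        gt = wt.T @ wt
        fisher = FisherWeights(np.abs(rng.standard_normal(4)), 1)
        proj = principal_projector(gt, 2)
        ws = rng.standard_normal((5, 4))

        def loss_of(w):
            gs = gram(w)  # ndarray stays ndarray; Tensor stays on the graph
            if which == "align":
                return align_loss(gs, gt)
            if which == "fisher":
                return fisher_align_loss(gs, gt, fisher)
            return subspace_loss(gs, gt, proj)

        t = Tensor(ws, requires_grad=True)
        loss_of(t).backward()
        eps = 1e-6
        num = np.zeros_like(ws)
        for i in range(ws.shape[0]):
            for j in range(ws.shape[1]):
                wp, wm = ws.copy(), ws.copy()
                wp[i, j] += eps
                wm[i, j] -= eps
                num[i, j] = (float(loss_of(wp)) - float(loss_of(wm))) / (2 * eps)
        assert np.allclose(t.grad, num, rtol=1e-4, atol=1e-8)
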