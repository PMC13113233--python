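"""Parameter-manifold alignment in a shared anchor space.

Heterogeneous teacher and student networks cannot be compared weight-by-weight
(their feature widths differ), but both end in a linear map into a common
``D_anchor``-dimensional anchor space: the teacher's projection layer W_T
(D_T x D_anchor) and the student's adapter W_S (D_S x D_anchor).  The Gram
matrix G = W^T W of each map lives in (D_anchor x D_anchor) regardless of the
input width, so structural discrepancy between the two maps can be measured
there:

* ``align_loss``        — plain squared Frobenius distance ||G_S - G_T||_F^2
  (diagnostic; not part of the training objective).
* ``fisher_align_loss`` — rows of the Gram difference weighted by the diagonal
  Fisher information of the teacher's anchor activations, F_kk = E[(dL/dz_k)^2],
  so alignment concentrates on task-sensitive anchor directions.
* ``subspace_loss``     — Frobenius distance after projecting both Grams onto
  the span of the top-k eigenvectors of G_T, restricting alignment to the
  teacher's dominant correlation structure.

All three losses accept either NumPy arrays or autodiff ``Tensor`` objects, so
the same code path is used for cached teacher-side quantities and for the
differentiable student side during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .autodiff import Tensor

__all__ = [
    "AnchorWeights",
    "GramMatrix",
    "FisherWeights",
    "SubspaceProjector",
    "gram",
    "align_loss",
    "estimate_fisher_diag",
    "fisher_align_loss",
    "principal_projector",
    "default_subspace_rank",
    "subspace_loss",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnchorWeights:
    """A projection/adapter weight matrix of shape (D_in, D_anchor)."""

    matrix: np.ndarray
    origin: Literal["teacher", "student"]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2:
            raise ValueError(f"{self.origin} anchor weights must be 2-D, got {m.ndim}-D")
        if not np.all(np.isfinite(m)):
            raise ValueError(f"non-finite entries in {self.origin} anchor weights")
        object.__setattr__(self, "matrix", m)

    @property
    def d_in(self) -> int:
        return self.matrix.shape[0]

    @property
    def d_anchor(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class GramMatrix:
    """Symmetric PSD matrix W^T W in anchor coordinates."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"Gram matrix must be square, got shape {m.shape}")
        scale = max(np.abs(m).max(), 1.0)
        if np.abs(m - m.T).max() > 1e-10 * scale:
            raise ValueError("Gram matrix is not symmetric")
        object.__setattr__(self, "matrix", m)

    @property
    def d_anchor(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class FisherWeights:
    """Diagonal Fisher information of the teacher's anchor activations.

    Estimated once from the frozen teacher and held fixed for the whole
    student run.
    """

    diag: np.ndarray
    n_samples: int

    def __post_init__(self):
        d = np.asarray(self.diag, dtype=np.float64)
        if d.ndim != 1:
            raise ValueError("Fisher diagonal must be a vector")
        if np.any(d < 0):
            raise ValueError("Fisher diagonal has negative entries")
        d.setflags(write=False)
        object.__setattr__(self, "diag", d)

    def normalized(self) -> "FisherWeights":
        """Rescale to unit mean (optional; raw values are the default)."""
        mean = self.diag.mean()
        if mean == 0.0:
            return self
        return FisherWeights(self.diag / mean, self.n_samples)


@dataclass(frozen=True)
class SubspaceProjector:
    """Orthogonal projector P = U_k U_k^T onto the teacher's principal subspace."""

    basis: np.ndarray
    rank: int
    projector: np.ndarray = field(init=False)

    def __post_init__(self):
        u = np.asarray(self.basis, dtype=np.float64)
        if u.ndim != 2 or u.shape[1] != self.rank:
            raise ValueError(f"basis shape {u.shape} inconsistent with rank {self.rank}")
        if np.abs(u.T @ u - np.eye(self.rank)).max() > 1e-8:
            raise ValueError("basis columns are not orthonormal")
        object.__setattr__(self, "basis", u)
        object.__setattr__(self, "projector", u @ u.T)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _mat(x):
    """Unwrap domain types; pass ndarrays and Tensors through."""
    if isinstance(x, AnchorWeights):
        return x.matrix
    if isinstance(x, GramMatrix):
        return x.matrix
    if isinstance(x, SubspaceProjector):
        return x.projector
    return x


def gram(w):
    """Gram image W^T W of an anchor weight matrix.

    Accepts :class:`AnchorWeights` (returns :class:`GramMatrix`), a plain
    ndarray (returns ndarray) or a ``Tensor`` (returns ``Tensor``, keeping the
    result differentiable with respect to W).
    """
    m = _mat(w)
    if isinstance(m, np.ndarray) and not np.all(np.isfinite(m)):
        origin = w.origin if isinstance(w, AnchorWeights) else "input"
        raise ValueError(f"non-finite entries in {origin} weight matrix")
    g = m.T @ m
    if isinstance(w, AnchorWeights):
        g = 0.5 * (g + g.T)  # kill round-off asymmetry before validation
        return GramMatrix(g)
    return g


def _check_same_shape(a, b) -> None:
    sa = _mat(a).shape
    sb = _mat(b).shape
    if sa != sb:
        raise ValueError(f"Gram shape mismatch: {sa} vs {sb}")


def align_loss(gs, gt):
    """Squared Frobenius distance ||G_S - G_T||_F^2."""
    _check_same_shape(gs, gt)
    d = _mat(gs) - _mat(gt)
    return (d * d).sum()


def fisher_align_loss(gs, gt, fisher):
    """Fisher-weighted row distance sum_k F_kk ||G_S[k,:] - G_T[k,:]||^2.

    The Gram matrices are symmetric, so weighting rows or columns is
    equivalent; rows are used.
    """
    _check_same_shape(gs, gt)
    f = fisher.diag if isinstance(fisher, FisherWeights) else np.asarray(fisher)
    n = _mat(gs).shape[0]
    if f.shape != (n,):
        raise ValueError(f"Fisher length {f.shape} does not match D_anchor {n}")
    d = _mat(gs) - _mat(gt)
    row_sq = (d * d).sum(axis=1)
    return (row_sq * f).sum() if isinstance(row_sq, Tensor) else float(row_sq @ f)


def estimate_fisher_diag(teacher, batches: Iterable, loss_fn=None) -> FisherWeights:
    """Diagonal Fisher information of the teacher's anchor activation.

    For each sample the teacher is run forward, the task loss is evaluated
    against the sample's torque label, and the squared gradient of the loss
    with respect to each anchor coordinate z_k is accumulated:
    F_kk = mean over samples of (dL/dz_k)^2.

    Parameters
    ----------
    teacher:
        Model exposing ``forward_with_anchor(x) -> (tau, z, W)`` where ``z``
        is a ``Tensor`` on the autodiff graph.
    batches:
        Iterable of ``(x, y)`` pairs (single samples or mini-batches whose
        leading axis is the batch).
    loss_fn:
        Scalar task loss ``loss_fn(tau, y)``; defaults to mean squared error.
    """
    if not hasattr(teacher, "forward_with_anchor"):
        raise TypeError("teacher does not expose an anchor head (forward_with_anchor)")
    if loss_fn is None:

        def loss_fn(tau, y):
            d = tau - y
            return (d * d).mean()

    total = None
    n = 0
    for x, y in batches:
        tau, z, _ = teacher.forward_with_anchor(x)
        loss = loss_fn(tau, np.asarray(y))
        loss.backward()
        # prefer the anchor node the prediction actually flows through (e.g.
        # per-timestep activations); fall back to z itself
        node = getattr(teacher, "_fisher_node", None)
        g = node.grad if node is not None else z.grad
        if g is None:
            g = z.grad
        if g is None:
            raise RuntimeError("anchor activation received no gradient")
        g2 = g.reshape(-1, g.shape[-1]) ** 2  # one row per activation draw
        total = g2.sum(axis=0) if total is None else total + g2.sum(axis=0)
        n += g2.shape[0]
    if total is None or n == 0:
        raise ValueError("empty batch stream for Fisher estimation")
    return FisherWeights(total / n, n)


def default_subspace_rank(gt, energy: float = 0.95) -> int:
    """Smallest k capturing >= ``energy`` of G_T's eigenvalue mass, capped at
    D_anchor / 2 (and at least 1)."""
    g = _mat(gt)
    evals = np.linalg.eigvalsh(g)[::-1]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    if total <= 0.0:
        return 1
    cum = np.cumsum(evals) / total
    k = int(np.searchsorted(cum, energy) + 1)
    return max(1, min(k, max(1, g.shape[0] // 2)))


def principal_projector(gt, k: int) -> SubspaceProjector:
    """Projector onto the span of the top-k eigenvectors of G_T.

    Deterministic: eigenvalues sorted descending, degenerate blocks broken by
    index order, and each eigenvector's sign fixed so its largest-magnitude
    component is positive.
    """
    g = _mat(gt)
    n = g.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"rank k={k} out of range [1, {n}]")
    evals, evecs = np.linalg.eigh(g)  # ascending
    order = np.argsort(-evals, kind="stable")
    u = evecs[:, order[:k]]
    for j in range(k):
        i = int(np.argmax(np.abs(u[:, j])))
        if u[i, j] < 0:
            u[:, j] = -u[:, j]
    return SubspaceProjector(u, k)


def subspace_loss(gs, gt, projector: SubspaceProjector):
    """Structural distance after projection: ||P_T G_S - P_T G_T||_F^2."""
    _check_same_shape(gs, gt)
    p = projector.projector if isinstance(projector, SubspaceProjector) else _mat(projector)
    d = _mat(gs) - _mat(gt)
    if isinstance(d, Tensor):
        p = Tensor(p) if not isinstance(p, Tensor) else p
    pd = p @ d
    return (pd * pd).sum()
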