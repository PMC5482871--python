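"""Classification and hierarchy-constraint losses, with analytic gradients.

Three pieces compose the training objective:

* a softmax cross-entropy loss ``J`` over subclass logits,
* a quadruplet hinge loss ``E_t`` that pushes embedding distances into the
  tiered ordering ``D(x, p+) + m1 < D(x, p-) + m2 < D(x, n)`` where ``p+``
  is a same-subclass positive, ``p-`` a same-superclass positive, and ``n``
  a different-superclass negative,
* their convex combination ``E = lam * J + (1 - lam) * E_t``.

All functions operate on plain :mod:`numpy` arrays; analytic gradients are
provided for every differentiable quantity so the training loop needs no
autodiff framework.

Notes
-----
``D`` is the plain (non-squared) Euclidean distance; a squared variant is
available behind the ``squared`` flag for ablation.  Embeddings are assumed
l2-normalized by the model before they reach these functions (distances are
computed on the vectors as given).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MarginConfig",
    "QuadrupletEmbeddings",
    "l2_normalize",
    "softmax_probabilities",
    "softmax_loss",
    "softmax_loss_grad",
    "euclidean_distance",
    "constraint_satisfied",
    "hinge_constraint_loss",
    "hinge_constraint_loss_grad",
    "combined_loss",
    "combined_loss_grads",
]

_NORM_EPS = 1e-12


@dataclass(frozen=True)
class MarginConfig:
    """Margins and loss weight for the combined objective.

    ``m1`` is the inner margin (same-subclass vs same-superclass), ``m2``
    the outer margin (same-superclass vs different-superclass); ``m1 < m2``
    is required.  ``lam`` weights the softmax term; it must lie in the open
    interval (0, 1) unless ``allow_boundary`` is set (diagnostic runs at
    exactly 0 or 1).
    """

    m1: float = 0.2
    m2: float = 0.4
    lam: float = 0.5
    allow_boundary: bool = False

    def __post_init__(self) -> None:
        if not (self.m1 >= 0 and self.m2 >= 0):
            raise ValueError("margins must be nonnegative")
        if not self.m1 < self.m2:
            raise ValueError(f"m1 must be < m2 (got m1={self.m1}, m2={self.m2})")
        lo, hi = (0.0, 1.0)
        ok = lo < self.lam < hi or (self.allow_boundary and lo <= self.lam <= hi)
        if not ok:
            raise ValueError(f"lam must be in (0, 1), got {self.lam}")


@dataclass(frozen=True)
class QuadrupletEmbeddings:
    """One (anchor, same-subclass, same-superclass, cross-superclass) tuple
    of unit-norm embedding vectors."""

    x: np.ndarray
    p_plus: np.ndarray
    p_minus: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        vecs = [np.asarray(v, dtype=float) for v in (self.x, self.p_plus, self.p_minus, self.n)]
        d = vecs[0].shape
        for name, v in zip(("x", "p_plus", "p_minus", "n"), vecs):
            if v.ndim != 1 or v.shape != d:
                raise ValueError(f"embedding {name} has shape {v.shape}, expected {d}")
            nrm = float(np.linalg.norm(v))
            if abs(nrm - 1.0) > 1e-6:
                raise ValueError(f"embedding {name} is not unit-norm (|v|={nrm:.8f})")
        object.__setattr__(self, "x", vecs[0])
        object.__setattr__(self, "p_plus", vecs[1])
        object.__setattr__(self, "p_minus", vecs[2])
        object.__setattr__(self, "n", vecs[3])

    def stacked(self) -> np.ndarray:
        return np.stack([self.x, self.p_plus, self.p_minus, self.n])


def l2_normalize(v: np.ndarray, axis: int = -1, eps: float = _NORM_EPS) -> np.ndarray:
    """Project vectors onto the unit sphere (safe at the origin)."""
    v = np.asarray(v, dtype=float)
    nrm = np.sqrt(np.sum(v * v, axis=axis, keepdims=True))
    return v / np.maximum(nrm, eps)


def _as_quad_arrays(
    quads: "list[QuadrupletEmbeddings] | np.ndarray",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Accept a list of quadruplets or an (N, 4, d) array; return four (N, d)
    arrays x, p+, p-, n."""
    if isinstance(quads, np.ndarray):
        arr = np.asarray(quads, dtype=float)
        if arr.ndim != 3 or arr.shape[1] != 4:
            raise ValueError(f"quadruplet array must be (N, 4, d), got {arr.shape}")
    else:
        if len(quads) == 0:
            raise ValueError("empty quadruplet list")
        arr = np.stack([q.stacked() for q in quads])
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]


# ---------------------------------------------------------------------------
# softmax classification loss
# ---------------------------------------------------------------------------

def softmax_probabilities(logits: np.ndarray) -> np.ndarray:
    """Class-membership probabilities from logits (max-subtracted for
    stability).  Works on a single k-vector or an (N, k) batch."""
    z = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite logits")
    z = z - np.max(z, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


def _check_logits_batch(logits: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if logits.ndim != 2:
        raise ValueError(f"logits must be (N, k), got shape {logits.shape}")
    n, k = logits.shape
    if n < 1:
        raise ValueError("empty logits batch")
    if labels.shape != (n,):
        raise ValueError(f"labels shape {labels.shape} does not match N={n}")
    if np.any(labels < 0) or np.any(labels >= k):
        raise ValueError("label index out of range for k classes")
    return logits, labels


def softmax_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class.

    ``J = -(1/N) sum_i log p(y_i | x_i)`` with 0-based integer labels.
    """
    logits, labels = _check_logits_batch(logits, labels)
    z = logits - np.max(logits, axis=1, keepdims=True)
    logp = z - np.log(np.sum(np.exp(z), axis=1, keepdims=True))
    return float(-np.mean(logp[np.arange(len(labels)), labels]))


def softmax_loss_grad(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Gradient of :func:`softmax_loss` w.r.t. the logits: (p - onehot)/N."""
    logits, labels = _check_logits_batch(logits, labels)
    p = softmax_probabilities(logits)
    p[np.arange(len(labels)), labels] -= 1.0
    return p / len(labels)


# ---------------------------------------------------------------------------
# distance-constraint hinge loss
# ---------------------------------------------------------------------------

def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (non-squared) Euclidean distance between two vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def _pair_distances(x, pp, pm, n, squared: bool):
    d_pp = np.sqrt(np.sum((x - pp) ** 2, axis=1))
    d_pm = np.sqrt(np.sum((x - pm) ** 2, axis=1))
    d_n = np.sqrt(np.sum((x - n) ** 2, axis=1))
    if squared:
        return d_pp**2, d_pm**2, d_n**2
    return d_pp, d_pm, d_n


def constraint_satisfied(q: QuadrupletEmbeddings, m: MarginConfig) -> bool:
    """Whether a quadruplet strictly satisfies the tiered distance ordering
    ``D(x,p+)+m1 < D(x,p-)+m2 < D(x,n)``."""
    d_pp = euclidean_distance(q.x, q.p_plus)
    d_pm = euclidean_distance(q.x, q.p_minus)
    d_n = euclidean_distance(q.x, q.n)
    return (d_pp + m.m1 < d_pm + m.m2) and (d_pm + m.m2 < d_n)


def hinge_constraint_loss(
    quads: "list[QuadrupletEmbeddings] | np.ndarray",
    m: MarginConfig,
    squared: bool = False,
) -> float:
    """Hinge relaxation of the tiered distance constraint.

    ``E_t = (1/2N) sum max{0, D(x,p+) - D(x,p-) + m1 - m2}
          + (1/2N) sum max{0, D(x,p-) - D(x,n) + m2}``

    Zero iff every quadruplet satisfies the non-strict version of both
    margins.
    """
    x, pp, pm, n = _as_quad_arrays(quads)
    d_pp, d_pm, d_n = _pair_distances(x, pp, pm, n, squared)
    t1 = np.maximum(0.0, d_pp - d_pm + m.m1 - m.m2)
    t2 = np.maximum(0.0, d_pm - d_n + m.m2)
    return float((t1.sum() + t2.sum()) / (2 * len(d_pp)))


def hinge_constraint_loss_grad(
    quads: "list[QuadrupletEmbeddings] | np.ndarray",
    m: MarginConfig,
    squared: bool = False,
) -> np.ndarray:
    """Gradient of :func:`hinge_constraint_loss` w.r.t. the embeddings.

    Returns an (N, 4, d) array ordered (x, p+, p-, n).  At a hinge kink or a
    zero distance the subgradient 0 is used.
    """
    x, pp, pm, n = _as_quad_arrays(quads)
    nq = x.shape[0]
    d_pp, d_pm, d_n = _pair_distances(x, pp, pm, n, squared=False)

    # unit difference vectors; zero where the distance vanishes
    def _unit(diff, d):
        out = np.zeros_like(diff)
        nz = d > 0
        out[nz] = diff[nz] / d[nz, None]
        return out

    if squared:
        g_pp = 2 * (x - pp)
        g_pm = 2 * (x - pm)
        g_n = 2 * (x - n)
        a1 = (d_pp**2 - d_pm**2 + m.m1 - m.m2) > 0
        a2 = (d_pm**2 - d_n**2 + m.m2) > 0
    else:
        g_pp = _unit(x - pp, d_pp)
        g_pm = _unit(x - pm, d_pm)
        g_n = _unit(x - n, d_n)
        a1 = (d_pp - d_pm + m.m1 - m.m2) > 0
        a2 = (d_pm - d_n + m.m2) > 0

    grad = np.zeros((nq, 4) + x.shape[1:])
    w = 1.0 / (2 * nq)
    # term 1: +D(x,p+) - D(x,p-)
    grad[a1, 0] += w * (g_pp[a1] - g_pm[a1])
    grad[a1, 1] += -w * g_pp[a1]
    grad[a1, 2] += w * g_pm[a1]
    # term 2: +D(x,p-) - D(x,n)
    grad[a2, 0] += w * (g_pm[a2] - g_n[a2])
    grad[a2, 2] += -w * g_pm[a2]
    grad[a2, 3] += w * g_n[a2]
    return grad


# ---------------------------------------------------------------------------
# combined objective
# ---------------------------------------------------------------------------

def combined_loss(
    logits: np.ndarray,
    labels: np.ndarray,
    quads: "list[QuadrupletEmbeddings] | np.ndarray | None",
    m: MarginConfig,
    squared: bool = False,
) -> float:
    """Weighted combination ``E = lam * J + (1 - lam) * E_t``.

    ``quads`` may be ``None`` or empty (degenerate batch): the hinge term is
    then taken as zero and the loss reduces to ``lam * J``.
    """
    j = softmax_loss(logits, labels)
    if quads is None or (not isinstance(quads, np.ndarray) and len(quads) == 0):
        et = 0.0
    else:
        et = hinge_constraint_loss(quads, m, squared=squared)
    return float(m.lam * j + (1.0 - m.lam) * et)


def combined_loss_grads(
    logits: np.ndarray,
    labels: np.ndarray,
    quads: "list[QuadrupletEmbeddings] | np.ndarray | None",
    m: MarginConfig,
    squared: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Gradients of :func:`combined_loss` w.r.t. logits and quadruplet
    embeddings; the second element is ``None`` when no quadruplets were
    given."""
    g_logits = m.lam * softmax_loss_grad(logits, labels)
    if quads is None or (not isinstance(quads, np.ndarray) and len(quads) == 0):
        return g_logits, None
    g_emb = (1.0 - m.lam) * hinge_constraint_loss_grad(quads, m, squared=squared)
    return g_logits, g_emb
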