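"""Capsule-layer mathematics: squash, routing by agreement, margin loss.

A *capsule* is a group of neurons whose activity is a vector: its length
encodes the probability that an entity is present, its orientation encodes
the entity's attributes.  A lower capsule ``i`` predicts each higher capsule
``j`` through an affine transform ``u_hat[j|i] = W[i,j] @ u[i]``; the higher
capsule's input is the coupling-weighted sum ``s[j] = sum_i c[i,j] u_hat``
with the couplings produced by a softmax over routing logits ``b[i,j]``,
which dynamic routing updates by the agreement ``u_hat . v[j]``.  The squash
nonlinearity compresses ``s[j]`` so output lengths live in [0, 1) and can be
read as class probabilities; training minimises a per-class hinge-squared
margin loss.

All functions accept either plain ``ndarray`` inputs (returning arrays —
this is the contract the unit tests and reference oracles exercise) or
:class:`~tonguecaps.autograd.Tensor` inputs (recording gradients for
training).  Shapes may carry an optional leading batch axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag

__all__ = [
    "CapsuleBank",
    "TransformWeights",
    "PredictionTensor",
    "RoutingState",
    "MarginLossParams",
    "squash",
    "predict_vectors",
    "coupling_from_logits",
    "dynamic_routing",
    "capsule_lengths",
    "classify",
    "margin_loss",
]

#: numerical floor inside the squash norm; keeps the zero vector a fixed
#: point with a finite gradient.
SQUASH_EPS = 1e-16


@dataclass
class CapsuleBank:
    """A set of capsule vectors, shape (count N, dimension D).

    ``role`` distinguishes lower-layer inputs (``"input"``, the u_i) from
    routed outputs (``"output"``, the V_j, whose lengths lie in [0, 1)).
    """

    vectors: np.ndarray
    role: str = "input"

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors)
        if self.vectors.ndim != 2 or min(self.vectors.shape) < 1:
            raise ValueError("CapsuleBank requires an N×D array with N, D >= 1")
        if self.role not in ("input", "output"):
            raise ValueError(f"unknown capsule role {self.role!r}")
        if self.role == "output":
            norms = np.linalg.norm(self.vectors, axis=-1)
            if np.any(norms >= 1.0):
                raise ValueError("output-role capsule lengths must lie in [0, 1)")

    @property
    def count(self) -> int:
        return self.vectors.shape[0]

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]


@dataclass
class TransformWeights:
    """Per-pair affine capsule transforms: W[i, j] is the D_in×D_out
    matrix mapping input capsule i's vector to its prediction for output
    capsule j (one matrix per pair; no sharing across input capsules)."""

    W: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W)
        if self.W.ndim != 4:
            raise ValueError("weights must be N_in × N_out × D_in × D_out")
        if not np.isfinite(self.W).all():
            raise ValueError("transform weights must be finite")


@dataclass
class PredictionTensor:
    """The prediction vectors u_hat[j|i], shape N_in × N_out × D_out."""

    u_hat: np.ndarray

    def __post_init__(self):
        self.u_hat = np.asarray(self.u_hat)
        if self.u_hat.ndim != 3:
            raise ValueError("predictions must be N_in × N_out × D_out")


@dataclass
class RoutingState:
    """Final routing quantities: logits b, couplings c, weighted sums s."""

    b: np.ndarray
    c: np.ndarray
    s: np.ndarray
    iterations: int = 0


@dataclass(frozen=True)
class MarginLossParams:
    """Margin-loss constants: the positive margin m+, negative margin m-,
    and the down-weight lambda on absent-class terms."""

    m_plus: float = 0.9
    m_minus: float = 0.1
    lam: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.m_minus < self.m_plus < 1.0):
            raise ValueError("margins must satisfy 0 < m- < m+ < 1")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


def squash(s, axis: int = -1):
    """Squash nonlinearity: ``v = (|s|^2 / (1 + |s|^2)) * s / |s|``.

    Preserves direction; maps length monotonically into [0, 1); the zero
    vector maps to the zero vector.
    """
    n2 = ag.sum(ag.mul(s, s), axis=axis, keepdims=True)
    scale = ag.mul(ag.power(ag.add(n2, 1.0), -1.0), ag.power(ag.add(n2, SQUASH_EPS), -0.5))
    # scale = |s| / (1+|s|^2) up to the eps floor; times s gives the squash
    return ag.mul(ag.mul(s, n2), scale)


def predict_vectors(u, W):
    """Prediction vectors ``u_hat[j|i] = W[i,j] @ u[i]``.

    u: (..., N_in, D_in) array or CapsuleBank; W: (N_in, N_out, D_in, D_out).
    Returns (..., N_in, N_out, D_out).
    """
    if isinstance(u, CapsuleBank):
        u = u.vectors
    if isinstance(W, TransformWeights):
        W = W.W
    u_arr, W_arr = ag.asarray(u), ag.asarray(W)
    if W_arr.ndim != 4:
        raise ValueError("W must be N_in × N_out × D_in × D_out")
    if u_arr.shape[-1] != W_arr.shape[2] or u_arr.shape[-2] != W_arr.shape[0]:
        raise ValueError(
            f"shape mismatch: u {u_arr.shape} vs W {W_arr.shape} "
            "(expected u (..., N_in, D_in))"
        )
    if u_arr.ndim == 2 and not ag.is_tensor(u):
        return np.einsum("id,ijde->ije", u_arr, W_arr)
    return ag.einsum("bid,ijde->bije", u, W)


def coupling_from_logits(b, axis: int = -1):
    """Couplings ``c[i,j] = exp(b[i,j]) / sum_j exp(b[i,j])`` (softmax over
    the output-capsule axis, for each input capsule)."""
    return ag.softmax(b, axis=axis)


def dynamic_routing(u_hat, iterations: int = 3):
    """Routing by agreement over prediction vectors.

    u_hat: (N_in, N_out, D_out) or batched (B, N_in, N_out, D_out); plain
    array or Tensor.  Logits start at zero; each round computes couplings
    c = softmax(b), weighted sums ``s[j] = sum_i c[i,j] u_hat[j|i]`` and
    outputs ``v[j] = squash(s[j])``; all rounds but the last add the
    agreement ``u_hat . v[j]`` to the logits (a final update could not
    change the returned outputs).

    Returns ``(v, RoutingState)`` with v of shape (..., N_out, D_out).
    """
    if iterations < 1:
        raise ValueError("routing needs at least one iteration")
    if isinstance(u_hat, PredictionTensor):
        u_hat = u_hat.u_hat
    batched = ag.asarray(u_hat).ndim == 4
    if not batched:
        u_hat = ag.reshape(u_hat, (1,) + tuple(ag.asarray(u_hat).shape))
    shape = ag.asarray(u_hat).shape  # (B, N_in, N_out, D)
    b = np.zeros(shape[:3], dtype=ag.asarray(u_hat).dtype)
    v = c = s = None
    for r in range(iterations):
        c = coupling_from_logits(b, axis=-1)
        s = ag.einsum("bij,bijd->bjd", c, u_hat)
        v = squash(s, axis=-1)
        if r < iterations - 1:
            agreement = ag.einsum("bijd,bjd->bij", u_hat, v)
            b = ag.add(b, agreement)
    state = RoutingState(
        b=ag.asarray(b).copy() if batched else ag.asarray(b)[0].copy(),
        c=ag.asarray(c).copy() if batched else ag.asarray(c)[0].copy(),
        s=ag.asarray(s).copy() if batched else ag.asarray(s)[0].copy(),
        iterations=iterations,
    )
    if not batched:
        v = ag.reshape(v, tuple(ag.asarray(v).shape[1:]))
    return v, state


def capsule_lengths(v, axis: int = -1):
    """Euclidean norm of each capsule vector (the class score)."""
    if isinstance(v, CapsuleBank):
        v = v.vectors
    n2 = ag.sum(ag.mul(v, v), axis=axis)
    return ag.power(ag.add(n2, SQUASH_EPS), 0.5) if ag.is_tensor(v) else np.sqrt(ag.asarray(n2))


def classify(lengths) -> np.ndarray | int:
    """Predicted class = index of the longest capsule; ties -> lowest index."""
    arr = ag.asarray(lengths)
    if arr.size == 0:
        raise ValueError("classify requires at least one capsule length")
    if arr.ndim == 1:
        return int(np.argmax(arr))
    return np.argmax(arr, axis=-1)


def margin_loss(lengths, target_one_hot, params: MarginLossParams | None = None):
    """Hinge-squared margin loss.

    Per sample: ``sum_k T_k max(0, m+ - |v_k|)^2
    + lambda (1 - T_k) max(0, |v_k| - m-)^2``; a batched input returns the
    mean over samples of the per-sample class sum.
    """
    params = params or MarginLossParams()
    t = ag.asarray(target_one_hot)
    if ag.asarray(lengths).shape != t.shape:
        raise ValueError(
            f"lengths {ag.asarray(lengths).shape} and target {t.shape} differ"
        )
    present = ag.mul(t, ag.power(ag.relu(ag.add(-lengths, params.m_plus)), 2.0))
    absent = ag.mul(
        ag.mul(1.0 - t, params.lam),
        ag.power(ag.relu(ag.add(lengths, -params.m_minus)), 2.0),
    )
    per_class = ag.add(present, absent)
    per_sample = ag.sum(per_class, axis=-1)
    if ag.asarray(per_sample).ndim == 0:
        return per_sample
    return ag.mean(per_sample)
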