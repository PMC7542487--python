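"""Per-group style transformations in feature space, via the kernel trick.

Samples that share a "style" (a writer, a recording session, an EEG set)
are modelled as a common affine distortion of a standard-style distribution.
Each style group j gets a feature-space matrix A_j that normalizes the group
toward the standard style; A_j is regularized toward the identity by a
Frobenius penalty gamma * ||A_j' - I||_F^2, so gamma -> infinity recovers
the untransformed model.

The stationarity condition of the per-group subproblem gives the rank-one
structure

    A_j' = I + 1/(2 lam gamma) * w v_j',

where w = sum_m alpha_w[m] Phi(x_m) is the classifier weight vector in the
combined feature space and v_j = sum_{k in group j} alpha_s[k] Phi(x_k) is a
group-local coefficient vector.  Nothing is ever materialized: every
transformed kernel value

    khat(x_a, x_b) = <A_{g(a)}' Phi(x_a), A_{g(b)}' Phi(x_b)>

expands into original kernel values only,

    khat = K + c (q s' + s q') + c^2 W q q',     c = 1/(2 lam gamma),

with s = K alpha_w, W = alpha_w' K alpha_w and q_a the group-masked sum
sum_{m in g(a)} alpha_s[m] K[a, m].  A rank-two correction of the combined
Gram therefore carries the whole style adaptation.

``update_style`` solves the per-group subproblem exactly: with the classifier
(w, b) fixed, minimizing the residual-plus-penalty objective over A_j reduces
to a t_j x t_j ridge system per group,

    (I + (W / 2 gamma) K_jj) e_j = rho_j,    alpha_s = lam * e_j,

where rho are the residuals at A = I.  This keeps the outer alternation a
genuine block-coordinate descent, and the resulting A_j coincides with an
explicit quadratic-programming solve over the d x d entries in the
linear-kernel case (a test oracle).

For the linear kernel the feature map is the identity, so the A_j can be
materialized explicitly (``materialize_A_linear``); this is the arbiter for
the kernel-trick algebra, not a user-facing feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve

from .errors import InputError
from .lssvm_core import DualSolution


@dataclass
class StyleGroupedDataset:
    """Samples with binary labels and per-sample style-group ids.

    Fields
    ------
    X : (n, d) features
    y : (n,) labels in {+1, -1}
    group : (n,) positive integer style-group ids
    """

    X: np.ndarray
    y: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.group = np.asarray(self.group, dtype=int).ravel()
        if self.X.ndim != 2 or self.X.shape[0] == 0 or self.X.shape[1] == 0:
            raise InputError(f"X must be a nonempty 2-D matrix, got shape {self.X.shape}")
        n = self.X.shape[0]
        if self.y.size != n or self.group.size != n:
            raise InputError("X, y and group must agree in length")
        if not np.all(np.isin(self.y, (-1.0, 1.0))):
            raise InputError("labels must be +1/-1")
        if np.any(self.group < 1):
            raise InputError("group ids must be positive integers")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def group_ids(self) -> np.ndarray:
        return np.unique(self.group)

    @property
    def group_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.group, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def subset(self, idx: np.ndarray) -> "StyleGroupedDataset":
        return StyleGroupedDataset(self.X[idx], self.y[idx], self.group[idx])


@dataclass
class StyleModel:
    """Implicit per-group style matrices A_j' = I + scale * w v_j'.

    ``alpha_style`` holds the subproblem multipliers defining the v_j (each
    entry contributes only to its own group's matrix); ``alpha_w`` is the
    classifier dual snapshot defining w.  ``scale`` = 1/(2 lam gamma).
    All zeros means every A_j is the identity.
    """

    alpha_style: np.ndarray
    alpha_w: np.ndarray
    lam: float
    gamma: float
    group: np.ndarray

    def __post_init__(self) -> None:
        self.alpha_style = np.asarray(self.alpha_style, dtype=float).ravel()
        self.alpha_w = np.asarray(self.alpha_w, dtype=float).ravel()
        self.group = np.asarray(self.group, dtype=int).ravel()
        if not (self.gamma > 0 and self.lam > 0):
            raise InputError(f"lam and gamma must be > 0, got lam={self.lam}, gamma={self.gamma}")
        if not (self.alpha_style.size == self.alpha_w.size == self.group.size):
            raise InputError("alpha_style, alpha_w and group must agree in length")

    @property
    def scale(self) -> float:
        return 1.0 / (2.0 * self.lam * self.gamma)

    @property
    def is_identity(self) -> bool:
        return not np.any(self.alpha_style) or not np.any(self.alpha_w)


def init_style(dataset: StyleGroupedDataset, lam: float, gamma: float) -> StyleModel:
    """Identity initialization: zero coefficients, every A_j = I."""
    n = dataset.n
    return StyleModel(np.zeros(n), np.zeros(n), float(lam), float(gamma), dataset.group)


def _group_masked_matvec(K_block: np.ndarray, coeff: np.ndarray,
                         col_group: np.ndarray, row_group: np.ndarray) -> np.ndarray:
    """q[a] = sum_{m : col_group[m] == row_group[a]} coeff[m] * K_block[a, m]."""
    q = np.zeros(K_block.shape[0])
    for g in np.unique(row_group):
        rows = np.flatnonzero(row_group == g)
        cols = np.flatnonzero(col_group == g)
        if cols.size:
            q[rows] = K_block[np.ix_(rows, cols)] @ coeff[cols]
    return q


def update_style(base_gram: np.ndarray, y: np.ndarray, current_dual: DualSolution,
                 group: np.ndarray, gamma: float) -> StyleModel:
    """Exact closed-form update of all A_j for a fixed classifier.

    Per group j the subproblem (squared residuals + Frobenius penalty) has
    the kernelized solution (I + (W / 2 gamma) K_jj) e_j = rho_j with
    rho = y - (K alpha_w + b) the residuals at A = I and W = alpha_w' K alpha_w;
    the stored multipliers are alpha_style = lam * e.
    """
    if not gamma > 0:
        raise InputError(f"gamma must be > 0, got {gamma}")
    K = np.asarray(base_gram, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    group = np.asarray(group, dtype=int).ravel()
    aw = current_dual.alpha
    if not (K.shape[0] == K.shape[1] == y.size == group.size == aw.size):
        raise InputError("gram, labels, groups and dual coefficients must agree in size")
    s = K @ aw
    rho = y - (s + current_dual.bias)
    W = float(aw @ s)
    e = np.zeros_like(rho)
    for g in np.unique(group):
        idx = np.flatnonzero(group == g)
        Kjj = K[np.ix_(idx, idx)]
        A = np.eye(idx.size) + (W / (2.0 * gamma)) * Kjj
        e[idx] = solve(A, rho[idx], assume_a="sym")
    lam = current_dual.lam
    return StyleModel(lam * e, aw.copy(), lam, float(gamma), group)


def _train_vectors(model: StyleModel, K_tt: np.ndarray):
    """(s, q, W) of the training block: s = K alpha_w, q group-masked, W = |w|^2."""
    s = K_tt @ model.alpha_w
    q = _group_masked_matvec(K_tt, model.alpha_style, model.group, model.group)
    W = float(model.alpha_w @ s)
    return s, q, W


def transform_delta(model: StyleModel, base_gram: np.ndarray) -> np.ndarray:
    """The rank-two style correction Delta with khat = base_gram + Delta."""
    K = np.asarray(base_gram, dtype=float)
    if K.shape != (model.group.size, model.group.size):
        raise InputError(f"base gram shape {K.shape} does not match {model.group.size} samples")
    if model.is_identity:
        return np.zeros_like(K)
    s, q, W = _train_vectors(model, K)
    c = model.scale
    return c * (np.outer(q, s) + np.outer(s, q)) + (c * c * W) * np.outer(q, q)


def transformed_gram(model: StyleModel, base_gram: np.ndarray) -> np.ndarray:
    """Style-transformed combined Gram on the training set (kernel trick only)."""
    return np.asarray(base_gram, dtype=float) + transform_delta(model, base_gram)


def transformed_cross(model: StyleModel, K_tt: np.ndarray, K_tn: np.ndarray,
                      new_group: int) -> np.ndarray:
    """Transformed cross-kernel block khat(x_train, x_new).

    The new samples (columns of ``K_tn``, an n_train x m block of combined
    kernel values) inherit the style matrix of ``new_group``; training rows
    use their own A_j.
    """
    K_tt = np.asarray(K_tt, dtype=float)
    K_tn = np.atleast_2d(np.asarray(K_tn, dtype=float))
    if K_tn.shape[0] != model.group.size:
        raise InputError("cross block rows must index the training samples")
    if model.is_identity:
        return K_tn.copy()
    if new_group not in model.group:
        raise InputError(f"group {new_group} was not seen during training")
    s_tr, q_tr, W = _train_vectors(model, K_tt)
    s_new = K_tn.T @ model.alpha_w
    cols = np.flatnonzero(model.group == new_group)
    q_new = K_tn[cols].T @ model.alpha_style[cols]
    c = model.scale
    return (K_tn + c * (np.outer(q_tr, s_new) + np.outer(s_tr, q_new))
            + (c * c * W) * np.outer(q_tr, q_new))


def style_penalty(model: StyleModel, base_gram: np.ndarray) -> float:
    """sum_j ||A_j' - I||_F^2 in kernel form: scale^2 * |w|^2 * sum_j v_j' v_j."""
    if model.is_identity:
        return 0.0
    K = np.asarray(base_gram, dtype=float)
    s, q, W = _train_vectors(model, K)
    val = model.scale**2 * W * float(model.alpha_style @ q)
    return max(val, 0.0)


def materialize_A_linear(model: StyleModel, X: np.ndarray) -> dict[int, np.ndarray]:
    """Explicit d x d style matrices A_j for the linear kernel (test oracle).

    Only valid when the combined kernel is the plain inner product, so the
    feature map is the identity: w = X' alpha_w, v_j = X_j' alpha_style_j and
    A_j = I + scale * v_j w'.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] != model.group.size:
        raise InputError("X rows must match the training samples")
    w = X.T @ model.alpha_w
    d = X.shape[1]
    out = {}
    for g in np.unique(model.group):
        idx = np.flatnonzero(model.group == g)
        v = X[idx].T @ model.alpha_style[idx]
        out[int(g)] = np.eye(d) + model.scale * np.outer(v, w)
    return out
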