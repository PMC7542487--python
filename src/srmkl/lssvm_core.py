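"""Least-squares SVM trained in the dual by one symmetric linear solve.

The LSSVM replaces the hinge loss with a squared error under equality
constraints, so for a fixed Gram matrix K the dual variables come from a
linear system instead of a QP.  With Ktilde = K + I/lam:

    b     = (1' Ktilde^-1 y) / (1' Ktilde^-1 1)
    alpha = Ktilde^-1 (y - b 1)

The multipliers satisfy sum_j alpha_j = 0 and the KKT identity
alpha_j = lam * e_j, where e_j = y_j - (K alpha + b)_j is the training
residual — both are used as self-checks throughout the package.

Ktilde is factorized once (Cholesky) with two right-hand sides; the inverse
is never formed.  A diagonal jitter of 1e-10 * trace(K)/n is added only if
the factorization fails, which can happen for numerically semidefinite Grams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve, solve

from .errors import InputError, NumericalError


@dataclass
class DualSolution:
    """Dual variables of one LSSVM solve: multipliers alpha, bias b, ridge lam."""

    alpha: np.ndarray
    bias: float
    lam: float


def hard_sign(values: np.ndarray) -> np.ndarray:
    """Decision sign with the fixed convention sign(0) = +1."""
    return np.where(np.asarray(values) >= 0, 1.0, -1.0)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise InputError("labels must be +1/-1")
    if np.unique(y).size < 2:
        raise InputError("both classes must be present")
    return y


def solve_lssvm_dual(K: np.ndarray, y: np.ndarray, lam: float) -> DualSolution:
    """Solve the LSSVM dual for a fixed (combined) Gram matrix.

    Parameters
    ----------
    K : (n, n) symmetric positive semidefinite Gram matrix.
    y : (n,) labels in {+1, -1}; both classes required.
    lam : float
        Regularization lam > 0; larger lam fits the residuals harder.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise InputError(f"K must be square, got shape {K.shape}")
    y = _check_labels(y)
    n = K.shape[0]
    if y.size != n:
        raise InputError(f"{y.size} labels for an {n} x {n} Gram")
    if not lam > 0:
        raise InputError(f"lam must be > 0, got {lam}")

    Kt = K + np.eye(n) / lam
    rhs = np.column_stack([y, np.ones(n)])
    try:
        cf = cho_factor(Kt, lower=True, check_finite=False)
        sol = cho_solve(cf, rhs, check_finite=False)
    except LinAlgError:
        jitter = 1e-10 * max(np.trace(K) / n, 1.0)
        try:
            cf = cho_factor(Kt + jitter * np.eye(n), lower=True, check_finite=False)
            sol = cho_solve(cf, rhs, check_finite=False)
        except LinAlgError:
            try:
                sol = solve(Kt, rhs, assume_a="sym", check_finite=False)
            except LinAlgError as exc:  # pragma: no cover - pathological input
                raise NumericalError("Ktilde = K + I/lam could not be solved") from exc
    u_y, u_1 = sol[:, 0], sol[:, 1]
    denom = float(u_1.sum())
    if denom == 0.0:  # pragma: no cover - impossible for PD Ktilde
        raise NumericalError("degenerate bias system: 1' Ktilde^-1 1 = 0")
    b = float(u_y.sum()) / denom
    alpha = u_y - b * u_1
    return DualSolution(alpha=alpha, bias=b, lam=float(lam))


def decision_values(K_cross: np.ndarray, sol: DualSolution) -> np.ndarray:
    """Decision values K_cross @ alpha + b for rows of cross-kernel values.

    ``K_cross`` has one row per evaluation point and one column per training
    sample (m x n); passing the training Gram itself yields the training
    decision values.
    """
    K_cross = np.atleast_2d(np.asarray(K_cross, dtype=float))
    if K_cross.shape[1] != sol.alpha.size:
        raise InputError(
            f"cross-kernel has {K_cross.shape[1]} columns but the model has "
            f"{sol.alpha.size} training samples")
    return K_cross @ sol.alpha + sol.bias
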