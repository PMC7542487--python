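"""Multiple-kernel LSSVM trained by semi-infinite linear programming.

The min-max problem over simplex weights mu and dual variables alpha,

    min_mu max_alpha  -1/2 sum_i mu_i alpha' K_i alpha - alpha'alpha/(2 lam)
                      + alpha' y      s.t. alpha' 1 = 0,

is a semi-infinite LP once the inner maximum is replaced by an epigraph
variable t: every fixed alpha contributes one linear cut in (mu, t).  The
standard column-generation scheme alternates (a) an exact inner LSSVM dual
solve at the current mu, which both evaluates the objective S(mu) and yields
a new cut, and (b) a finite LP over the accumulated cuts whose value is a
lower bound on the optimum.  The loop stops when the gap between the
incumbent objective and the LP lower bound drops below ``tol``.

The reported objective trace is the incumbent (best visited mu) value, which
is non-increasing by construction; the returned model is the best iterate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .errors import InputError
from .kernel_bank import GramStack, KernelWeights, combine_gram
from .lssvm_core import DualSolution, decision_values, hard_sign, solve_lssvm_dual


@dataclass
class MKLModel:
    """Fitted MK-LSSVM: simplex weights, dual solution and the SILP trace."""

    weights: KernelWeights
    dual: DualSolution
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    stack_ref: GramStack | None = field(default=None, repr=False)


def _as_gram_list(grams: GramStack | Sequence[np.ndarray]) -> list[np.ndarray]:
    return grams.grams if isinstance(grams, GramStack) else list(grams)


def silp_objective(grams: GramStack | Sequence[np.ndarray], y: np.ndarray, lam: float,
                   mu: np.ndarray) -> float:
    """S(mu): the inner-maximum value of the min-max objective at fixed mu.

    Used by the cutting-plane loop and, independently, by grid-scan oracles.
    """
    mats = _as_gram_list(grams)
    K = combine_gram(mats, KernelWeights(np.asarray(mu, dtype=float)))
    sol = solve_lssvm_dual(K, y, lam)
    a = sol.alpha
    return float(-0.5 * a @ (K @ a) - (a @ a) / (2.0 * lam) + a @ y)


def fit_mkl(grams: GramStack | Sequence[np.ndarray], y: np.ndarray, lam: float,
            tol: float = 1e-4, max_iter: int = 100) -> MKLModel:
    """Fit MK-LSSVM over a bank of base Grams by the SILP cutting-plane loop.

    Parameters
    ----------
    grams : GramStack or sequence of (n, n) arrays
        The base Gram matrices K_i.
    y : (n,) labels in {+1, -1}.
    lam : float
        LSSVM regularization, > 0.
    tol : float
        Relative tolerance on the LP bound gap / incumbent change.
    max_iter : int
        Cutting-plane iteration budget; exhaustion sets ``converged=False``
        on the model rather than raising.
    """
    mats = _as_gram_list(grams)
    stack_ref = grams if isinstance(grams, GramStack) else None
    if not tol > 0:
        raise InputError(f"tol must be > 0, got {tol}")
    M = len(mats)
    y = np.asarray(y, dtype=float).ravel()

    if M == 1:
        sol = solve_lssvm_dual(mats[0], y, lam)
        a = sol.alpha
        S = float(-0.5 * a @ (mats[0] @ a) - (a @ a) / (2.0 * lam) + a @ y)
        return MKLModel(KernelWeights(np.ones(1)), sol, np.array([S]), True, 1, stack_ref)

    mu = np.full(M, 1.0 / M)
    cut_c: list[np.ndarray] = []   # per-cut coefficients of mu
    cut_k: list[float] = []        # per-cut constants
    trace: list[float] = []
    best_S = np.inf
    best_mu = mu
    best_sol: DualSolution | None = None
    converged = False
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        K = combine_gram(mats, KernelWeights(mu))
        sol = solve_lssvm_dual(K, y, lam)
        a = sol.alpha
        c = np.array([-0.5 * a @ (Ki @ a) for Ki in mats])
        k0 = float(-(a @ a) / (2.0 * lam) + a @ y)
        S = float(c @ mu + k0)
        if S < best_S:
            best_S, best_mu, best_sol = S, mu.copy(), sol
        trace.append(best_S)
        cut_c.append(c)
        cut_k.append(k0)

        # LP over (mu, t): min t  s.t.  c_r . mu - t <= -k0_r,  mu on the simplex.
        A_ub = np.column_stack([np.array(cut_c), -np.ones(len(cut_c))])
        b_ub = -np.array(cut_k)
        A_eq = np.concatenate([np.ones(M), [0.0]])[None, :]
        res = linprog(c=np.concatenate([np.zeros(M), [1.0]]), A_ub=A_ub, b_ub=b_ub,
                      A_eq=A_eq, b_eq=[1.0],
                      bounds=[(0.0, 1.0)] * M + [(None, None)], method="highs")
        if not res.success:  # pragma: no cover - simplex-constrained LP is feasible
            raise RuntimeError(f"SILP restricted master LP failed: {res.message}")
        t_lp = float(res.x[-1])
        mu_new = np.clip(res.x[:M], 0.0, None)
        mu_new /= mu_new.sum()

        scale = max(1.0, abs(best_S))
        if best_S - t_lp <= tol * scale:
            converged = True
            break
        mu = mu_new

    assert best_sol is not None
    return MKLModel(weights=KernelWeights(best_mu), dual=best_sol,
                    objective_trace=np.array(trace), converged=converged,
                    n_iter=n_iter, stack_ref=stack_ref)


def predict_mkl(model: MKLModel, X_new: np.ndarray, stack: GramStack | None = None) -> np.ndarray:
    """Labels sign(sum_j alpha_j sum_i mu_i k_i(x_j, x_new) + b), sign(0) = +1."""
    stack = stack if stack is not None else model.stack_ref
    if stack is None:
        raise InputError("prediction needs the training GramStack (with stored samples)")
    crosses = stack.cross(np.atleast_2d(np.asarray(X_new, dtype=float)))
    Kc = combine_gram(crosses, model.weights)  # n_train x m
    return hard_sign(decision_values(Kc.T, model.dual))
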