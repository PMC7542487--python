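"""Style-regularized multiple-kernel LSSVM: alternating trainer and Rules 1-3.

Training alternates two blocks until the regularized objective

    J = 1/2 |w|^2 + 1/(2 lam) alpha'alpha + lam gamma sum_j ||A_j' - I||_F^2

stops improving: (a) an MK-LSSVM fit (SILP weights + LSSVM dual) on the
style-transformed Grams with the A_j fixed, and (b) the closed-form style
update with the classifier fixed.  Iteration 1 starts from A_j = I, so its
classifier coincides exactly with plain MK-LSSVM on the untransformed Grams.

Within one outer iteration the style correction is a fixed rank-two matrix
Delta added to every base Gram; since the simplex weights sum to one, any
recombination sum mu_i (K_i + Delta) = sum mu_i K_i + Delta, which lets the
SILP relearn mu while the A_j stay fixed.  Delta is defined against the
combined Gram of the weights in force when the style was last updated
(``mu_style``), which the model records alongside the final weights.

Prediction follows three rules:

* Rule 1 — ignore style: decision on untransformed cross-kernel values.
* Rule 2 — known style: the new samples inherit the trained A of their
  group; cross-kernel values are style-transformed before the decision.
* Rule 3 — unseen style: label the group by Rule 1, refit with the group
  appended as a new style, then predict it by Rule 2 (direct extrapolation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InputError, UnknownStyleError
from .kernel_bank import (BaseKernelSpec, GramStack, KernelWeights, combine_gram,
                          default_bank)
from .lssvm_core import decision_values, hard_sign
from .mk_lssvm import MKLModel, fit_mkl
from .style_transform import (StyleGroupedDataset, StyleModel, init_style,
                              style_penalty, transform_delta, transformed_cross,
                              update_style)

#: relative slack allowed before an objective increase aborts the outer loop
_MONOTONE_SLACK = 1e-6


@dataclass
class SRModel:
    """Fitted SR-MKL-SVM: classifier, style model and the training reference."""

    mkl: MKLModel
    style: StyleModel
    mu_style: KernelWeights | None
    train: StyleGroupedDataset
    specs: list[BaseKernelSpec]
    normalize: bool
    lam: float
    gamma: float
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    _stack: GramStack | None = field(default=None, repr=False)

    @property
    def stack(self) -> GramStack:
        if self._stack is None:
            self._stack = GramStack.from_data(self.train.X, self.specs, self.normalize)
        return self._stack


def fit_sr(dataset: StyleGroupedDataset, specs: Sequence[BaseKernelSpec] | None = None,
           lam: float = 1.0, gamma: float = 1.0, max_outer: int = 20, tol: float = 1e-4,
           inner_tol: float = 1e-4, inner_max_iter: int = 100,
           normalize: bool = True) -> SRModel:
    """Train SR-MKL-SVM by alternating MKL fits with style updates.

    Parameters
    ----------
    dataset : StyleGroupedDataset
        Training samples with labels and style-group ids.
    specs : sequence of BaseKernelSpec, optional
        Kernel bank; defaults to the 10-kernel median-heuristic bank.
    lam : float
        LSSVM regularization (> 0).
    gamma : float
        Style-penalty strength (> 0); large gamma pins every A_j at I.
    max_outer : int
        Outer alternation budget; ``max_outer=1`` is plain MK-LSSVM.
    tol : float
        Relative tolerance on the objective J for outer convergence.
    """
    if not (lam > 0 and gamma > 0):
        raise InputError(f"lam and gamma must be > 0, got lam={lam}, gamma={gamma}")
    if max_outer < 1:
        raise InputError("max_outer must be >= 1")
    if specs is None:
        specs = default_bank(dataset.X)
    stack = GramStack.from_data(dataset.X, specs, normalize)
    grams = stack.grams
    y = dataset.y

    style = init_style(dataset, lam, gamma)
    mu_style: KernelWeights | None = None
    trace: list[float] = []
    best: tuple[float, MKLModel, StyleModel, KernelWeights | None] | None = None
    converged = False
    J_prev: float | None = None
    n_iter = 0

    for n_iter in range(1, max_outer + 1):
        if style.is_identity:
            hat = grams
            K_base_style = None
        else:
            assert mu_style is not None
            K_base_style = combine_gram(grams, mu_style)
            delta = transform_delta(style, K_base_style)
            hat = [K + delta for K in grams]

        mkl = fit_mkl(hat, y, lam, tol=inner_tol, max_iter=inner_max_iter)
        a = mkl.dual.alpha
        K_hat = combine_gram(hat, mkl.weights)
        penalty = 0.0 if K_base_style is None else style_penalty(style, K_base_style)
        J = float(0.5 * a @ (K_hat @ a) + (a @ a) / (2.0 * lam) + lam * gamma * penalty)
        trace.append(J)

        if best is None or J <= best[0]:
            best = (J, mkl, style, mu_style)
        if J_prev is not None:
            scale = max(1.0, abs(J_prev))
            if J > J_prev + _MONOTONE_SLACK * scale:
                break  # alternation lost descent; keep the best iterate
            if abs(J_prev - J) <= tol * scale:
                converged = True
                break
        J_prev = J
        if n_iter == max_outer:
            break

        K_base_new = combine_gram(grams, mkl.weights)
        style = update_style(K_base_new, y, mkl.dual, dataset.group, gamma)
        mu_style = mkl.weights

    assert best is not None
    _, mkl_b, style_b, mu_style_b = best
    model = SRModel(mkl=mkl_b, style=style_b, mu_style=mu_style_b, train=dataset,
                    specs=list(specs), normalize=normalize, lam=float(lam),
                    gamma=float(gamma), objective_trace=np.array(trace),
                    converged=converged, n_iter=n_iter)
    model._stack = stack
    return model


def _cross_grams(model: SRModel, X_new: np.ndarray) -> list[np.ndarray]:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.train.d:
        raise InputError(f"expected {model.train.d} features, got {X_new.shape[1]}")
    return model.stack.cross(X_new)


def decision_rule1(model: SRModel, X_new: np.ndarray) -> np.ndarray:
    """Decision values on untransformed cross-kernel entries."""
    Kc = combine_gram(_cross_grams(model, X_new), model.mkl.weights)
    return decision_values(Kc.T, model.mkl.dual)


def predict_rule1(model: SRModel, X_new: np.ndarray) -> np.ndarray:
    """Rule 1: style-agnostic prediction, sign(0) = +1."""
    return hard_sign(decision_rule1(model, X_new))


def decision_rule2(model: SRModel, X_new: np.ndarray, known_group: int) -> np.ndarray:
    if model.style.is_identity:
        return decision_rule1(model, X_new)
    if known_group not in model.train.group_ids:
        raise UnknownStyleError(
            f"style group {known_group} was not present at training time; "
            "use Rule 3 for unseen styles")
    crosses = _cross_grams(model, X_new)
    assert model.mu_style is not None
    K_tn_style = combine_gram(crosses, model.mu_style)
    K_tt_style = combine_gram(model.stack.grams, model.mu_style)
    delta_cross = transformed_cross(model.style, K_tt_style, K_tn_style,
                                    int(known_group)) - K_tn_style
    K_hat = combine_gram(crosses, model.mkl.weights) + delta_cross
    return decision_values(K_hat.T, model.mkl.dual)


def predict_rule2(model: SRModel, X_new: np.ndarray, known_group: int) -> np.ndarray:
    """Rule 2: the new samples inherit the trained style matrix of their group."""
    return hard_sign(decision_rule2(model, X_new, known_group))


def predict_rule3(model: SRModel, X_new_group: np.ndarray, lam: float | None = None,
                  gamma: float | None = None, max_outer: int | None = None,
                  tol: float = 1e-4) -> np.ndarray:
    """Rule 3: direct extrapolation for a style-homogeneous unseen group.

    Step 1 labels the group by Rule 1; Step 2 refits SR-MKL-SVM with the
    group appended as a new style under those temporary labels (one pass,
    no label re-estimation); Step 3 predicts the group by Rule 2 of the
    refit model.
    """
    X_new_group = np.atleast_2d(np.asarray(X_new_group, dtype=float))
    if X_new_group.shape[0] == 0:
        raise InputError("Rule 3 needs a nonempty sample group")
    temp = predict_rule1(model, X_new_group)
    new_gid = int(model.train.group.max()) + 1
    aug = StyleGroupedDataset(
        np.vstack([model.train.X, X_new_group]),
        np.concatenate([model.train.y, temp]),
        np.concatenate([model.train.group, np.full(X_new_group.shape[0], new_gid)]))
    refit = fit_sr(aug, specs=model.specs,
                   lam=model.lam if lam is None else lam,
                   gamma=model.gamma if gamma is None else gamma,
                   max_outer=model.n_iter if max_outer is None else max_outer,
                   tol=tol, normalize=model.normalize)
    return predict_rule2(refit, X_new_group, new_gid)


def evaluate(model: SRModel, test: StyleGroupedDataset, rule: int = 1, **rule3_kwargs) -> float:
    """Fraction of correctly signed predictions on a labeled test set.

    Rules 2 and 3 are applied group by group (the test set is assumed
    style-grouped); Rule 3 treats every test group as an unseen style.
    """
    if test.n == 0:
        raise InputError("empty test set")
    if rule == 1:
        pred = predict_rule1(model, test.X)
    elif rule in (2, 3):
        pred = np.empty(test.n)
        for g in test.group_ids:
            idx = np.flatnonzero(test.group == g)
            if rule == 2:
                pred[idx] = predict_rule2(model, test.X[idx], int(g))
            else:
                pred[idx] = predict_rule3(model, test.X[idx], **rule3_kwargs)
    else:
        raise InputError(f"rule must be 1, 2 or 3, got {rule}")
    return float(np.mean(pred == test.y))


# ---------------------------------------------------------------------------
# Serialization: structured-text header + one binary container of raw .npy
# records (concatenated with np.lib.format, so the bytes are deterministic).
# ---------------------------------------------------------------------------

_ARRAY_FIELDS = ("alpha", "alpha_style", "alpha_w", "mu", "mu_style",
                 "objective_trace", "mkl_trace", "X", "y", "group")


def save_model(model: SRModel, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.json`` (header) and ``<prefix>.bin`` (arrays)."""
    prefix = Path(prefix)
    header = {
        "format": "srmkl-model",
        "version": 1,
        "lam": model.lam,
        "gamma": model.gamma,
        "normalize": model.normalize,
        "bias": model.mkl.dual.bias,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "mkl_converged": model.mkl.converged,
        "mkl_n_iter": model.mkl.n_iter,
        "has_mu_style": model.mu_style is not None,
        "kernels": [s.to_dict() for s in model.specs],
        "group_sizes": {str(k): v for k, v in model.train.group_sizes.items()},
        "arrays": list(_ARRAY_FIELDS),
    }
    arrays = {
        "alpha": model.mkl.dual.alpha,
        "alpha_style": model.style.alpha_style,
        "alpha_w": model.style.alpha_w,
        "mu": model.mkl.weights.mu,
        "mu_style": (model.mu_style.mu if model.mu_style is not None else np.zeros(0)),
        "objective_trace": model.objective_trace,
        "mkl_trace": model.mkl.objective_trace,
        "X": model.train.X,
        "y": model.train.y,
        "group": model.train.group.astype(np.int64),
    }
    header_path = prefix.with_suffix(".json")
    bin_path = prefix.with_suffix(".bin")
    header_path.write_text(json.dumps(header, indent=2, sort_keys=True) + "\n")
    with open(bin_path, "wb") as fh:
        for name in _ARRAY_FIELDS:
            np.lib.format.write_array(fh, np.ascontiguousarray(arrays[name]))
    return header_path, bin_path


def load_model(prefix: str | Path) -> SRModel:
    """Reload a saved model; predictions reproduce the original bit-exactly."""
    prefix = Path(prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    if header.get("format") != "srmkl-model":
        raise InputError(f"{prefix}: not an srmkl model artifact")
    arrays = {}
    with open(prefix.with_suffix(".bin"), "rb") as fh:
        for name in header["arrays"]:
            arrays[name] = np.lib.format.read_array(fh)
    train = StyleGroupedDataset(arrays["X"], arrays["y"], arrays["group"])
    lam, gamma = header["lam"], header["gamma"]
    from .lssvm_core import DualSolution  # local import to avoid cycle noise

    dual = DualSolution(alpha=arrays["alpha"], bias=header["bias"], lam=lam)
    mkl = MKLModel(weights=KernelWeights(arrays["mu"]), dual=dual,
                   objective_trace=arrays["mkl_trace"],
                   converged=header["mkl_converged"], n_iter=header["mkl_n_iter"])
    style = StyleModel(arrays["alpha_style"], arrays["alpha_w"], lam, gamma, train.group)
    mu_style = KernelWeights(arrays["mu_style"]) if header["has_mu_style"] else None
    specs = [BaseKernelSpec.from_dict(d) for d in header["kernels"]]
    return SRModel(mkl=mkl, style=style, mu_style=mu_style, train=train, specs=specs,
                   normalize=header["normalize"], lam=lam, gamma=gamma,
                   objective_trace=arrays["objective_trace"],
                   converged=header["converged"], n_iter=header["n_iter"])
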