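"""Base kernels, Gram matrices and their simplex-weighted convex combination.

A multiple-kernel model works with a bank of M base kernels k_i(.,.) whose
Gram matrices K_i are combined as K = sum_i mu_i K_i with mu on the
probability simplex.  By Mercer's theorem any such convex combination of
positive semidefinite Grams is again a valid kernel matrix.

Three base families are supported:

``linear``        k(x, z) = <x, z>
``polynomial``    k(x, z) = (<x, z> + coef0)^degree
``gaussian``      k(x, z) = exp(-||x - z||^2 / (2 width^2))

Heterogeneous base kernels live on very different scales, so Grams are
cosine-normalized to unit diagonal by default before entering the weight
optimization (toggleable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .errors import DegenerateKernelError, InputError

FAMILIES = ("linear", "polynomial", "gaussian")


@dataclass(frozen=True)
class BaseKernelSpec:
    """One base kernel of the bank.

    Parameters
    ----------
    family : {"linear", "polynomial", "gaussian"}
    degree : int
        Polynomial degree (polynomial family only), >= 1.
    width : float
        Gaussian bandwidth, the ``sigma`` in exp(-||x-z||^2 / (2 sigma^2)); > 0.
    coef0 : float
        Additive constant of the polynomial kernel.
    """

    family: str
    degree: int = 3
    width: float = 1.0
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InputError(f"unknown kernel family {self.family!r}; expected one of {FAMILIES}")
        if self.family == "polynomial" and (int(self.degree) != self.degree or self.degree < 1):
            raise InputError(f"polynomial degree must be a positive integer, got {self.degree}")
        if self.family == "gaussian" and not self.width > 0:
            raise InputError(f"gaussian width must be > 0, got {self.width}")

    def to_dict(self) -> dict:
        return {"family": self.family, "degree": int(self.degree),
                "width": float(self.width), "coef0": float(self.coef0)}

    @classmethod
    def from_dict(cls, d: dict) -> "BaseKernelSpec":
        return cls(**d)


def _check_features(X: np.ndarray, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InputError(f"{name} must be a 2-D sample matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InputError(f"{name} contains non-finite features")
    return X


def compute_gram(spec: BaseKernelSpec, X: np.ndarray, Z: np.ndarray | None = None) -> np.ndarray:
    """Gram matrix K[p, q] = k(X[p], Z[q]) for one base kernel.

    With ``Z`` omitted the symmetric n x n training Gram is returned.
    """
    X = _check_features(X, "X")
    Z = X if Z is None else _check_features(Z, "Z")
    if X.shape[1] != Z.shape[1]:
        raise InputError(f"feature dimension mismatch: {X.shape[1]} vs {Z.shape[1]}")
    if spec.family == "linear":
        return X @ Z.T
    if spec.family == "polynomial":
        return (X @ Z.T + spec.coef0) ** spec.degree
    sq = cdist(X, Z, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * spec.width**2))


def self_kernel(spec: BaseKernelSpec, X: np.ndarray) -> np.ndarray:
    """The diagonal values k(x, x), one per row of X."""
    X = _check_features(X, "X")
    if spec.family == "linear":
        return np.einsum("ij,ij->i", X, X)
    if spec.family == "polynomial":
        return (np.einsum("ij,ij->i", X, X) + spec.coef0) ** spec.degree
    return np.ones(X.shape[0])


def normalize_gram(K: np.ndarray, diag_rows: np.ndarray | None = None,
                   diag_cols: np.ndarray | None = None) -> np.ndarray:
    """Cosine normalization K[p,q] / sqrt(k(p,p) k(q,q)) to unit diagonal.

    For a square training Gram the self-similarities are read off the
    diagonal; for a cross Gram they must be supplied for both sides.
    """
    K = np.asarray(K, dtype=float)
    if diag_rows is None:
        if K.shape[0] != K.shape[1]:
            raise InputError("cross-gram normalization needs explicit self-kernel values")
        diag_rows = np.diag(K)
        diag_cols = diag_rows
    if diag_cols is None:
        diag_cols = diag_rows
    if np.any(diag_rows <= 0) or np.any(diag_cols <= 0):
        raise DegenerateKernelError("zero or negative self-similarity on the kernel diagonal")
    return K / np.sqrt(np.outer(diag_rows, diag_cols))


@dataclass(frozen=True)
class KernelWeights:
    """Simplex weights mu of the combined kernel: mu_i >= 0, sum mu_i = 1."""

    mu: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float).ravel()
        object.__setattr__(self, "mu", mu)
        if mu.size == 0:
            raise InputError("empty weight vector")
        if np.any(mu < -1e-10):
            raise InputError(f"negative kernel weight: min = {mu.min()}")
        if abs(mu.sum() - 1.0) > 1e-10:
            raise InputError(f"kernel weights must sum to 1, got {mu.sum()}")

    def __len__(self) -> int:
        return self.mu.size

    @classmethod
    def uniform(cls, m: int) -> "KernelWeights":
        return cls(np.full(m, 1.0 / m))


@dataclass
class GramStack:
    """A bank of M precomputed base Gram matrices sharing one sample set."""

    grams: list[np.ndarray]
    specs: list[BaseKernelSpec]
    X: np.ndarray | None = None
    normalized: bool = True
    _self_kernels: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len(self.grams) != len(self.specs):
            raise InputError("one spec per Gram matrix is required")
        n = self.grams[0].shape[0]
        for K in self.grams:
            if K.shape != (n, n):
                raise InputError("all Gram matrices must share the same n x n shape")

    @property
    def n(self) -> int:
        return self.grams[0].shape[0]

    @property
    def M(self) -> int:
        return len(self.grams)

    @classmethod
    def from_data(cls, X: np.ndarray, specs: Sequence[BaseKernelSpec],
                  normalize: bool = True) -> "GramStack":
        X = _check_features(X, "X")
        grams, diags = [], []
        for spec in specs:
            K = compute_gram(spec, X)
            d = self_kernel(spec, X)
            if normalize:
                K = normalize_gram(K, d, d)
            grams.append(K)
            diags.append(d)
        stack = cls(grams=grams, specs=list(specs), X=X, normalized=normalize)
        stack._self_kernels = diags
        return stack

    def cross(self, Z: np.ndarray) -> list[np.ndarray]:
        """Cross Grams k_i(X[p], Z[q]) (n x m), normalized like the training Grams."""
        if self.X is None:
            raise InputError("this GramStack stores no sample matrix; cannot extend")
        out = []
        for i, spec in enumerate(self.specs):
            K = compute_gram(spec, self.X, Z)
            if self.normalized:
                K = normalize_gram(K, self._self_kernels[i], self_kernel(spec, Z))
            out.append(K)
        return out

    def validate(self, sym_tol: float = 1e-10, psd_slack: float = 1e-8) -> None:
        """Assert symmetry and (numerical) positive semidefiniteness."""
        for spec, K in zip(self.specs, self.grams):
            if np.max(np.abs(K - K.T)) > sym_tol * max(1.0, np.max(np.abs(K))):
                raise InputError(f"Gram for {spec} is not symmetric")
            w = np.linalg.eigvalsh(K)
            if w[0] < -psd_slack * max(np.trace(K) / K.shape[0], 1e-30):
                raise InputError(f"Gram for {spec} is not positive semidefinite (eigmin={w[0]:.3e})")


def combine_gram(grams: GramStack | Sequence[np.ndarray], weights: KernelWeights) -> np.ndarray:
    """The combined Gram sum_i mu_i K_i."""
    mats = grams.grams if isinstance(grams, GramStack) else list(grams)
    if len(mats) != len(weights):
        raise InputError(f"{len(weights)} weights for {len(mats)} Gram matrices")
    out = np.zeros_like(mats[0], dtype=float)
    for w, K in zip(weights.mu, mats):
        if w != 0.0:
            out += w * K
    return out


def default_bank(X: np.ndarray, width_powers: Sequence[int] = (-3, -2, -1, 0, 1, 2, 3),
                 poly_degrees: Sequence[int] = (2, 3), coef0: float = 1.0) -> list[BaseKernelSpec]:
    """The conventional MKL bank: gaussians at scaled median pairwise distance,
    plus a linear kernel and low-degree polynomials (M = 10 by default)."""
    X = _check_features(X, "X")
    if X.shape[0] > 1:
        med = float(np.median(pdist(X)))
    else:
        med = 0.0
    if med <= 0:
        med = 1.0
    specs = [BaseKernelSpec("gaussian", width=med * 2.0**p) for p in width_powers]
    specs.append(BaseKernelSpec("linear"))
    specs.extend(BaseKernelSpec("polynomial", degree=d, coef0=coef0) for d in poly_degrees)
    return specs
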