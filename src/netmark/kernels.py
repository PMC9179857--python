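"""The eight SVM kernel functions and Gram-matrix utilities.

All kernels operate on real feature rows and follow the parameterizations
customary in kernel-machine toolkits:

- linear:      k(x, y) = x·y
- polynomial:  k(x, y) = (scale·x·y + offset)^degree
- rbf:         k(x, y) = exp(-sigma·‖x-y‖²)
- laplacian:   k(x, y) = exp(-sigma·‖x-y‖)
- tanh:        k(x, y) = tanh(scale·x·y + offset)
- anova_rbf:   k(x, y) = (Σ_d exp(-sigma·(x_d - y_d)²))^degree
- spline:      k(x, y) = Π_d [1 + x_d y_d + x_d y_d m - ((x_d + y_d)/2) m²
                               + m³/3],   m = min(x_d, y_d)
- bessel:      k(x, y) = [J_ν(sigma·r) / ((sigma·r)^ν · L)]^degree with
               r = ‖x-y‖ and L = lim_{r→0} J_ν(r)/r^ν = 1 / (Γ(ν+1)·2^ν),
               so k(x, x) = 1 exactly; the removable singularity at
               sigma·r < 1e-5 is evaluated as 1.

tanh, bessel and spline are indefinite in general; :func:`psd_clip` provides
the standard workaround of clipping negative Gram eigenvalues to zero before
handing the matrix to a convex QP solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import gamma as gamma_fn
from scipy.special import jv

from .errors import ValidationError

__all__ = ["KERNEL_NAMES", "KernelSpec", "kernel_matrix", "psd_clip"]

KERNEL_NAMES: tuple[str, ...] = (
    "linear",
    "polynomial",
    "rbf",
    "laplacian",
    "tanh",
    "bessel",
    "anova_rbf",
    "spline",
)

_NEEDS_SIGMA = {"rbf", "laplacian", "bessel", "anova_rbf"}
_BESSEL_R_EPS = 1e-5


@dataclass(frozen=True)
class KernelSpec:
    """A named kernel with its parameters (defaults: sigma=1, degree=1, nu=1,
    scale=1, offset=1; none of these were dictated by any benchmark — they are
    the library defaults and all are exposed in configuration)."""

    name: str
    sigma: float = 1.0
    degree: int = 1
    nu: float = 1.0
    scale: float = 1.0
    offset: float = 1.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in KERNEL_NAMES:
            raise ValidationError(
                f"unknown kernel {self.name!r}; choose from {KERNEL_NAMES}"
            )
        if self.name in _NEEDS_SIGMA and not self.sigma > 0:
            raise ValidationError(f"kernel {self.name!r} requires sigma > 0")
        if self.degree < 1:
            raise ValidationError("degree must be a positive integer")


def _spline_gram(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    G = np.ones((X.shape[0], Y.shape[0]))
    for d in range(X.shape[1]):
        x = X[:, d][:, None]
        y = Y[:, d][None, :]
        m = np.minimum(x, y)
        xy = x * y
        G *= 1.0 + xy + xy * m - ((x + y) / 2.0) * m**2 + m**3 / 3.0
    return G


def _bessel_gram(r: np.ndarray, spec: KernelSpec) -> np.ndarray:
    s = spec.sigma * r
    limit = 1.0 / (gamma_fn(spec.nu + 1.0) * 2.0**spec.nu)
    small = s < _BESSEL_R_EPS
    safe = np.where(small, 1.0, s)
    vals = jv(spec.nu, safe) / (safe**spec.nu * limit)
    vals = np.where(small, 1.0, vals)
    return vals**spec.degree


def kernel_matrix(X: np.ndarray, Y: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix G[i, j] = k(x_i, y_j) for feature rows X, Y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValidationError("X and Y must share the same feature columns")
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValidationError("kernel inputs must be finite")

    name = spec.name
    if name == "linear":
        return X @ Y.T
    if name == "polynomial":
        return (spec.scale * (X @ Y.T) + spec.offset) ** spec.degree
    if name == "tanh":
        return np.tanh(spec.scale * (X @ Y.T) + spec.offset)
    if name == "rbf":
        return np.exp(-spec.sigma * cdist(X, Y, "sqeuclidean"))
    if name == "laplacian":
        return np.exp(-spec.sigma * cdist(X, Y, "euclidean"))
    if name == "anova_rbf":
        diff2 = (X[:, None, :] - Y[None, :, :]) ** 2
        return np.exp(-spec.sigma * diff2).sum(axis=2) ** spec.degree
    if name == "spline":
        return _spline_gram(X, Y)
    if name == "bessel":
        return _bessel_gram(cdist(X, Y, "euclidean"), spec)
    raise ValidationError(f"unknown kernel {name!r}")  # pragma: no cover


def psd_clip(gram: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Symmetrize and clip negative eigenvalues so the matrix is PSD."""
    G = np.asarray(gram, dtype=float)
    if G.shape[0] != G.shape[1]:
        raise ValidationError("Gram matrix must be square")
    G = (G + G.T) / 2.0
    w, V = np.linalg.eigh(G)
    if w.min() >= -abs(tol):
        return G
    w = np.clip(w, 0.0, None)
    G2 = (V * w) @ V.T
    return (G2 + G2.T) / 2.0
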