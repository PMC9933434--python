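"""Covariance functions for the Gaussian-process site-energy models.

Three kernels are provided:

* :class:`MaternKernel` — stationary Matérn covariance on Euclidean
  distance between descriptor vectors.  Smoothness is fixed at ν = 5/2
  (twice-differentiable sample paths, the usual default for smooth
  molecular-descriptor regression).

* :class:`LinearKernel` — homogeneous linear (dot-product) covariance on
  MM-potential vectors.  A GP with this kernel is equivalent to Bayesian
  linear regression through the origin in the potential features: its
  posterior mean is ⟨Φ*, C⟩ for effective QM charges C, so the model's
  zero-environment prediction is exactly zero.

* :class:`CompositeShiftKernel` — the physics-constrained shift kernel
      κ = σ₁² ⟨Φ, Φ′⟩ + σ₂² ⟨Φ, Φ′⟩ · matérn(|χ_CM − χ_CM′|; 1, ℓ).
  The first term is the direct (linear) QM–MM electrostatic response; the
  second lets the response depend nonlinearly on the internal geometry,
  weighted by the magnitude of the QM–MM interaction so that the whole
  kernel — and hence every prediction of a zero-mean GP built on it —
  vanishes identically when either potential is zero.

Hyperparameters are exposed both in natural units and as a log-space
vector ``theta`` for optimization.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .descriptors import ShiftFeatures

MATERN_NU = 2.5  # fixed smoothness of the build

_SQRT5 = np.sqrt(5.0)


def matern52(d: np.ndarray, sigma: float, lengthscale: float) -> np.ndarray:
    """Matérn ν=5/2 covariance at distance ``d`` (elementwise)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if sigma <= 0 or lengthscale <= 0:
        raise ValueError("sigma and lengthscale must be positive")
    u = _SQRT5 * d / lengthscale
    return sigma**2 * (1.0 + u + u**2 / 3.0) * np.exp(-u)


def matern_kernel(d, sigma: float, lengthscale: float):
    """Scalar/elementwise Matérn ν=5/2 kernel value."""
    return matern52(d, sigma, lengthscale)


def linear_kernel(phi, phi2, sigma1: float = 1.0) -> float:
    """σ₁² ⟨φ, φ′⟩ on two potential vectors."""
    a = np.asarray(getattr(phi, "values", phi), dtype=float)
    b = np.asarray(getattr(phi2, "values", phi2), dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return float(sigma1**2 * (a @ b))


class Kernel:
    """Base class: positive hyperparameters, log-space optimization view."""

    param_names: tuple[str, ...] = ()

    def params(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.param_names}

    @property
    def theta(self) -> np.ndarray:
        return np.log([getattr(self, n) for n in self.param_names])

    def with_theta(self, theta: np.ndarray) -> "Kernel":
        vals = np.exp(np.asarray(theta, dtype=float))
        return type(self)(**dict(zip(self.param_names, vals)))

    def __call__(self, X, X2=None) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def diag(self, X) -> np.ndarray:
        return np.diag(self(X))

    def __repr__(self) -> str:
        args = ", ".join(f"{n}={getattr(self, n):.6g}" for n in self.param_names)
        return f"{type(self).__name__}({args})"


class MaternKernel(Kernel):
    """Matérn ν=5/2 on Euclidean distance between descriptor rows."""

    kind = "matern"
    param_names = ("sigma", "lengthscale")

    def __init__(self, sigma: float = 1.0, lengthscale: float = 1.0):
        if sigma <= 0 or lengthscale <= 0:
            raise ValueError("hyperparameters must be positive")
        self.sigma = float(sigma)
        self.lengthscale = float(lengthscale)

    def __call__(self, X, X2=None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        X2 = X if X2 is None else np.atleast_2d(np.asarray(X2, dtype=float))
        d = cdist(X, X2)
        return matern52(d, self.sigma, self.lengthscale)

    def diag(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.full(X.shape[0], self.sigma**2)


class LinearKernel(Kernel):
    """Homogeneous dot-product kernel σ₁² X X′ᵀ on potential rows."""

    kind = "linear"
    param_names = ("sigma1",)

    def __init__(self, sigma1: float = 1.0):
        if sigma1 <= 0:
            raise ValueError("sigma1 must be positive")
        self.sigma1 = float(sigma1)

    @staticmethod
    def _pot(X) -> np.ndarray:
        if isinstance(X, ShiftFeatures):
            return X.pot
        return np.atleast_2d(np.asarray(X, dtype=float))

    def __call__(self, X, X2=None) -> np.ndarray:
        A = self._pot(X)
        B = A if X2 is None else self._pot(X2)
        return self.sigma1**2 * (A @ B.T)

    def diag(self, X) -> np.ndarray:
        A = self._pot(X)
        return self.sigma1**2 * np.einsum("ij,ij->i", A, A)


class CompositeShiftKernel(Kernel):
    """Linear + interaction-weighted nonlinear-geometry shift kernel."""

    kind = "composite_shift"
    param_names = ("sigma1", "sigma2", "lengthscale")

    def __init__(
        self,
        sigma1: float = 1.0,
        sigma2: float = 1.0,
        lengthscale: float = 1.0,
    ):
        if min(sigma1, sigma2, lengthscale) <= 0:
            raise ValueError("hyperparameters must be positive")
        self.sigma1 = float(sigma1)
        self.sigma2 = float(sigma2)
        self.lengthscale = float(lengthscale)

    @staticmethod
    def _bundle(X) -> ShiftFeatures:
        if not isinstance(X, ShiftFeatures):
            raise TypeError(
                "composite shift kernel requires ShiftFeatures with both "
                "Coulomb-matrix and potential descriptors"
            )
        return X

    def __call__(self, X, X2=None) -> np.ndarray:
        A = self._bundle(X)
        B = A if X2 is None else self._bundle(X2)
        P = A.pot @ B.pot.T
        d = cdist(A.cm, B.cm)
        return self.sigma1**2 * P + self.sigma2**2 * P * matern52(
            d, 1.0, self.lengthscale
        )

    def diag(self, X) -> np.ndarray:
        A = self._bundle(X)
        p2 = np.einsum("ij,ij->i", A.pot, A.pot)
        return (self.sigma1**2 + self.sigma2**2) * p2


def composite_shift_kernel(x, x2, sigma1, sigma2, lengthscale) -> float:
    """Scalar composite shift kernel between two (CM, Φ) descriptor bundles."""
    cm1, pot1 = x
    cm2, pot2 = x2
    X = ShiftFeatures(cm=np.atleast_2d(cm1), pot=np.atleast_2d(pot1))
    X2 = ShiftFeatures(cm=np.atleast_2d(cm2), pot=np.atleast_2d(pot2))
    k = CompositeShiftKernel(sigma1, sigma2, lengthscale)
    return float(k(X, X2)[0, 0])


KERNEL_KINDS = {
    "matern": MaternKernel,
    "linear": LinearKernel,
    "composite_shift": CompositeShiftKernel,
}


def make_kernel(kind: str, **params) -> Kernel:
    try:
        cls = KERNEL_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown kernel kind {kind!r}") from None
    return cls(**params)
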