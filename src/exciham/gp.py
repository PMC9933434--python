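"""Exact Gaussian-process regression.

The model/results split follows the statsmodels idiom:
:class:`GaussianProcess` holds the data and prior (kernel, prior-mean mode,
noise), ``fit()`` maximizes the log marginal likelihood (unless asked not
to) and returns a :class:`GPResults` carrying the trained state — expansion
coefficients α, Cholesky factor, optimized hyperparameters — plus
``predict``, ``loglike``, ``summary`` and single-file (de)serialization.

The posterior is the textbook exact-GP form.  With training inputs χ and
mean-free targets ε = y − μ, the coefficients solve

    (K + σ²I) α = ε,        K_ij = κ(χ_i, χ_j),

and a new point χ* gets posterior mean μ + k*ᵀα and variance
κ(χ*,χ*) − k*ᵀ(K + σ²I)⁻¹k* (clipped at zero).  A fixed jitter of 1e−10
is added to the diagonal before the Cholesky factorization.

Hyperparameters (kernel parameters and, optionally, the noise variance σ²)
are optimized in log space with L-BFGS-B from multiple seeded restarts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import linalg, optimize

from .descriptors import ShiftFeatures
from .kernels import Kernel, make_kernel

JITTER = 1e-10
SCHEMA_VERSION = 1

PRIOR_MEAN_MODES = ("zero", "mean_of_targets")


class SingularKernelError(np.linalg.LinAlgError):
    pass


def _as_dataset(X):
    if isinstance(X, ShiftFeatures):
        return X
    return np.atleast_2d(np.asarray(X, dtype=float))


def _n_samples(X) -> int:
    return len(X) if isinstance(X, ShiftFeatures) else X.shape[0]


def _median_heuristic(D: np.ndarray) -> float:
    pos = D[D > 0]
    return float(np.median(pos)) if pos.size else 1.0


class GaussianProcess:
    """Exact GP regression model over descriptor inputs.

    Parameters
    ----------
    X : array (n, p) or ShiftFeatures
        Training descriptors.
    y : array (n,)
        Training targets (eV for the site-energy models).
    kernel : Kernel
        Prior covariance; its current parameters seed the optimization.
    noise_variance : float
        Observation noise σ² (same units as y², i.e. eV²).
    prior_mean : {"zero", "mean_of_targets"}
        Zero prior mean (shift model) or the average of the training
        targets (vacuum model).
    """

    def __init__(
        self,
        X,
        y,
        kernel: Kernel,
        noise_variance: float = 1e-6,
        prior_mean: str = "mean_of_targets",
    ):
        self.X = _as_dataset(X)
        self.y = np.asarray(y, dtype=float).ravel()
        n = _n_samples(self.X)
        if n < 1 or self.y.shape[0] != n:
            raise ValueError("X and y must contain the same (>=1) number of samples")
        if noise_variance < 0:
            raise ValueError("noise variance must be >= 0")
        if prior_mean not in PRIOR_MEAN_MODES:
            raise ValueError(f"prior_mean must be one of {PRIOR_MEAN_MODES}")
        self.kernel = kernel
        self.noise_variance = float(noise_variance)
        self.prior_mean = prior_mean

    @property
    def nobs(self) -> int:
        return self.y.shape[0]

    @property
    def mu(self) -> float:
        return float(self.y.mean()) if self.prior_mean == "mean_of_targets" else 0.0

    # -- likelihood ----------------------------------------------------

    def _factorize(self, kernel: Kernel, noise_variance: float):
        K = kernel(self.X)
        Ky = K + (noise_variance + JITTER) * np.eye(self.nobs)
        try:
            cho = linalg.cho_factor(Ky, lower=True)
        except np.linalg.LinAlgError as exc:
            raise SingularKernelError(
                "kernel matrix is singular; duplicated inputs with zero "
                "noise — add jitter or a small noise variance"
            ) from exc
        return cho

    def loglike(self, kernel: Kernel | None = None, noise_variance: float | None = None) -> float:
        """Log marginal likelihood at the given (or current) hyperparameters."""
        kernel = self.kernel if kernel is None else kernel
        nv = self.noise_variance if noise_variance is None else noise_variance
        cho = self._factorize(kernel, nv)
        eps = self.y - self.mu
        alpha = linalg.cho_solve(cho, eps)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        return float(
            -0.5 * eps @ alpha - 0.5 * logdet - 0.5 * self.nobs * np.log(2.0 * np.pi)
        )

    # -- fitting -------------------------------------------------------

    def _initial_guess(self):
        """Data-scale heuristics for kernel parameters and noise."""
        y_sd = float(np.std(self.y - self.mu))
        y_sd = y_sd if y_sd > 0 else 1.0
        params = dict(self.kernel.params())
        kind = getattr(self.kernel, "kind", "")
        if kind == "matern":
            from scipy.spatial.distance import pdist

            params["sigma"] = y_sd
            params["lengthscale"] = _median_heuristic(pdist(np.asarray(self.X)))
        elif kind == "linear":
            p2 = float(np.mean(self.kernel.diag(self.X))) / self.kernel.sigma1**2
            params["sigma1"] = y_sd / np.sqrt(max(p2, 1e-12))
        elif kind == "composite_shift":
            from scipy.spatial.distance import pdist

            p2 = float(np.mean(np.einsum("ij,ij->i", self.X.pot, self.X.pot)))
            s = y_sd / np.sqrt(max(2.0 * p2, 1e-12))
            params["sigma1"] = s
            params["sigma2"] = s
            params["lengthscale"] = _median_heuristic(pdist(self.X.cm))
        init_kernel = type(self.kernel)(**params)
        init_noise = max(1e-4 * y_sd**2, 1e-10)
        return init_kernel, init_noise

    def fit(
        self,
        optimize_hyperparameters: bool = True,
        optimize_noise: bool = True,
        restarts: int = 5,
        seed: int = 0,
        bounds: dict[str, tuple[float, float]] | None = None,
    ) -> "GPResults":
        """Train the GP, optionally maximizing the log marginal likelihood.

        ``bounds`` maps hyperparameter names (and optionally ``"noise"``)
        to (low, high) in natural units; unspecified parameters get a wide
        window (factor 10³) around a data-scale initial guess.  Restarts
        draw log-uniform starting points from the bounds with a seeded
        generator, so the fit is deterministic given ``seed``.
        """
        kernel = self.kernel
        noise = self.noise_variance
        if optimize_hyperparameters:
            if restarts < 1:
                raise ValueError("restarts must be >= 1")
            kernel, noise = self._optimize(
                optimize_noise=optimize_noise,
                restarts=restarts,
                seed=seed,
                bounds=bounds or {},
            )
        cho = self._factorize(kernel, noise)
        alpha = linalg.cho_solve(cho, self.y - self.mu)
        return GPResults(self, kernel, noise, alpha)

    def _optimize(self, optimize_noise, restarts, seed, bounds):
        init_kernel, init_noise = self._initial_guess()
        names = list(init_kernel.param_names)
        x0 = list(np.log([getattr(init_kernel, n) for n in names]))
        lo, hi = [], []
        for n in names:
            b = bounds.get(n)
            if b is None:
                b = (getattr(init_kernel, n) / 1e3, getattr(init_kernel, n) * 1e3)
            lo.append(np.log(b[0]))
            hi.append(np.log(b[1]))
        if optimize_noise:
            nb = bounds.get("noise")
            if nb is None:
                y_var = float(np.var(self.y - self.mu)) or 1.0
                nb = (1e-10, 10.0 * y_var)
            x0.append(np.log(np.clip(init_noise if self.noise_variance == 0
                                     else self.noise_variance, *nb)))
            lo.append(np.log(nb[0]))
            hi.append(np.log(nb[1]))
        x0 = np.clip(np.asarray(x0), lo, hi)

        def objective(logx):
            k = init_kernel.with_theta(logx[: len(names)])
            nv = float(np.exp(logx[len(names)])) if optimize_noise else self.noise_variance
            try:
                ll = self.loglike(k, nv)
            except (np.linalg.LinAlgError, FloatingPointError):
                return np.inf
            return np.inf if not np.isfinite(ll) else -ll

        rng = np.random.default_rng(seed)
        starts = [x0] + [
            rng.uniform(lo, hi) for _ in range(restarts - 1)
        ]
        best_x, best_f = None, np.inf
        for s in starts:
            res = optimize.minimize(
                objective, s, method="L-BFGS-B", bounds=list(zip(lo, hi))
            )
            if np.isfinite(res.fun) and res.fun < best_f:
                best_x, best_f = res.x, res.fun
        if best_x is None:
            raise RuntimeError("hyperparameter optimization failed at every restart")
        kernel = init_kernel.with_theta(best_x[: len(names)])
        noise = float(np.exp(best_x[len(names)])) if optimize_noise else self.noise_variance
        return kernel, noise


class GPResults:
    """Trained GP state: kernel, noise, expansion coefficients, factors."""

    def __init__(self, model: GaussianProcess, kernel: Kernel, noise_variance: float, alpha: np.ndarray, metadata: dict | None = None):
        self.model = model
        self.kernel_ = kernel
        self.noise_variance_ = float(noise_variance)
        self.alpha_ = np.asarray(alpha, dtype=float)
        self.mu_ = model.mu
        self.metadata = dict(metadata or {})
        self._cho = model._factorize(kernel, noise_variance)

    # -- inference -----------------------------------------------------

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def loglike(self) -> float:
        return self.model.loglike(self.kernel_, self.noise_variance_)

    def predict(self, Xnew, return_var: bool = False):
        """Posterior mean (and, optionally, clipped posterior variance)."""
        Xnew = _as_dataset(Xnew)
        Ks = self.kernel_(Xnew, self.model.X)  # (n*, n)
        mean = self.mu_ + Ks @ self.alpha_
        if not return_var:
            return mean
        v = linalg.cho_solve(self._cho, Ks.T)
        var = self.kernel_.diag(Xnew) - np.einsum("ij,ji->i", Ks, v)
        return mean, np.clip(var, 0.0, None)

    def summary(self) -> str:
        lines = [
            "Gaussian Process Regression Results",
            "=" * 46,
            f"No. observations: {self.nobs}",
            f"Kernel:           {self.kernel_!r}",
            f"Noise variance:   {self.noise_variance_:.6g}",
            f"Prior mean:       {self.model.prior_mean} (mu = {self.mu_:.6f})",
            f"Log marginal lik: {self.loglike():.4f}",
        ]
        for k, v in self.metadata.items():
            lines.append(f"{k}: {v}")
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------

    def _payload(self) -> dict:
        X = self.model.X
        if isinstance(X, ShiftFeatures):
            xdata = {"type": "shift_features", "cm": X.cm.tolist(), "pot": X.pot.tolist()}
        else:
            xdata = {"type": "array", "values": X.tolist()}
        return {
            "schema_version": SCHEMA_VERSION,
            "kernel": {"kind": self.kernel_.kind, "params": self.kernel_.params()},
            "noise_variance": self.noise_variance_,
            "prior_mean": self.model.prior_mean,
            "mu": self.mu_,
            "X": xdata,
            "y": self.model.y.tolist(),
            "alpha": self.alpha_.tolist(),
            "metadata": self.metadata,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self._payload()))

    @classmethod
    def load(cls, path) -> "GPResults":
        data = json.loads(Path(path).read_text())
        if data.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"model file schema version {data.get('schema_version')} is "
                f"incompatible with this build (expects {SCHEMA_VERSION})"
            )
        xdata = data["X"]
        if xdata["type"] == "shift_features":
            X = ShiftFeatures(cm=np.asarray(xdata["cm"]), pot=np.asarray(xdata["pot"]))
        else:
            X = np.asarray(xdata["values"])
        kernel = make_kernel(data["kernel"]["kind"], **data["kernel"]["params"])
        model = GaussianProcess(
            X,
            np.asarray(data["y"]),
            kernel,
            noise_variance=data["noise_variance"],
            prior_mean=data["prior_mean"],
        )
        return cls(model, kernel, data["noise_variance"], np.asarray(data["alpha"]), metadata=data.get("metadata"))


# -- spec-level functional surface -------------------------------------


def fit_gp(X, y, kernel: Kernel, noise_variance: float = 0.0, prior_mean_mode: str = "mean_of_targets") -> GPResults:
    """Solve (K + σ²I)α = y − μ at fixed hyperparameters."""
    return GaussianProcess(
        X, y, kernel, noise_variance=noise_variance, prior_mean=prior_mean_mode
    ).fit(optimize_hyperparameters=False)


def predict_gp(results: GPResults, Xnew):
    """Posterior mean and variance at new inputs."""
    return results.predict(Xnew, return_var=True)


def log_marginal_likelihood(results: GPResults) -> float:
    return results.loglike()


def optimize_hyperparameters(
    X,
    y,
    kernel_kind: str = "matern",
    bounds: dict | None = None,
    restarts: int = 5,
    seed: int = 0,
    prior_mean_mode: str = "mean_of_targets",
    optimize_noise: bool = True,
) -> GPResults:
    """Multi-start LML maximization; returns the fitted results object."""
    model = GaussianProcess(X, y, make_kernel(kernel_kind), prior_mean=prior_mean_mode)
    return model.fit(
        optimize_hyperparameters=True,
        optimize_noise=optimize_noise,
        restarts=restarts,
        seed=seed,
        bounds=bounds,
    )
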