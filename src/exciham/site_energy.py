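"""Sequential site-energy models.

The excitation energy of an embedded pigment is decomposed as

    ε̂ = ε̂_vac + ε̂_shift + ε̂_pol

where ε̂_vac is predicted by a Matérn-kernel GP on the heavy-atom Coulomb
matrix (prior mean = average of the training energies), ε̂_shift — the
electrochromic shift ε_QM/MM − ε_vac — by a zero-mean GP with the
composite linear+interaction-weighted kernel on (Coulomb matrix, MM
potential) pairs, and ε̂_pol is an analytic induced-dipole term computed
from TrEsp transition charges (see :mod:`exciham.tresp`).  The zero prior
mean together with the potential-linear factor of the shift kernel makes
the predicted shift *exactly* zero for an empty environment.

One model is trained per pigment type (mirroring the separate chlorophyll
a / b models); mixing types in one training set is an error.

The charge-density-coupling (CDC) baseline is also provided: the
electrochromic shift estimated from fixed excitation difference-density
charges Δq interacting with the environment charges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .constants import K_E
from .descriptors import (
    SingularityError,
    ShiftFeatures,
    coulomb_matrix,
    mm_potential,
    residue_cutoff_mask,
    shift_features,
)
from .gp import GaussianProcess, GPResults
from .kernels import CompositeShiftKernel, LinearKernel, MaternKernel
from .systems import ChromophoreGeometry, EnvironmentModel


@dataclass(frozen=True)
class SiteEnergyPrediction:
    """A predicted site energy and its decomposition (all in eV)."""

    value: float
    variance: float
    eps_vac: float
    eps_shift: float
    eps_pol: float
    pigment_id: str = ""

    @property
    def components(self) -> tuple[float, float, float]:
        return (self.eps_vac, self.eps_shift, self.eps_pol)


@dataclass(frozen=True)
class CDCChargeSet:
    """Fixed difference-density charges Δq (e), one per QM atom."""

    delta_charges: np.ndarray

    def __post_init__(self):
        dq = np.asarray(self.delta_charges, dtype=float).ravel()
        if not np.all(np.isfinite(dq)):
            raise ValueError("difference charges must be finite")
        object.__setattr__(self, "delta_charges", dq)


def _check_single_type(geoms) -> str:
    types = {g.pigment_type for g in geoms}
    if len(types) != 1:
        raise ValueError(
            f"training set mixes pigment types {sorted(types)}; train one "
            "model per pigment type"
        )
    return types.pop()


class VacuumModel:
    """GP model of vacuum site energies on Coulomb-matrix descriptors."""

    def __init__(self, geometries, energies_ev, min_samples: int = 10):
        geometries = list(geometries)
        if len(geometries) < min_samples:
            raise ValueError(f"need at least {min_samples} training samples")
        self.pigment_type = _check_single_type(geometries)
        self.X = np.stack([coulomb_matrix(g).values for g in geometries])
        self.y = np.asarray(energies_ev, dtype=float)

    def fit(self, restarts: int = 5, seed: int = 0, bounds=None,
            optimize_hyperparameters: bool = True) -> "VacuumResults":
        gp = GaussianProcess(
            self.X, self.y, MaternKernel(), prior_mean="mean_of_targets"
        )
        res = gp.fit(
            optimize_hyperparameters=optimize_hyperparameters,
            restarts=restarts,
            seed=seed,
            bounds=bounds,
        )
        res.metadata.update(
            {"model": "vacuum", "target": "eps_vac_ev", "pigment_type": self.pigment_type}
        )
        return VacuumResults(res)


class VacuumResults:
    """Vacuum-model results: predicts ε̂_vac (eV) from geometries."""

    def __init__(self, gp_results: GPResults):
        self.gp = gp_results

    @property
    def pigment_type(self) -> str:
        return self.gp.metadata.get("pigment_type", "")

    def predict(self, geometries, return_var: bool = False):
        X = np.stack([coulomb_matrix(g).values for g in geometries])
        return self.gp.predict(X, return_var=return_var)

    def summary(self) -> str:
        return self.gp.summary()

    def save(self, path) -> None:
        self.gp.save(path)

    @classmethod
    def load(cls, path) -> "VacuumResults":
        return cls(GPResults.load(path))


class ShiftModel:
    """Zero-mean GP of the electrochromic shift on (CM, Φ) descriptors."""

    def __init__(self, geometries, environments, shifts_ev, cutoff_A: float = 30.0,
                 kernel: str = "composite_shift"):
        geometries = list(geometries)
        environments = list(environments)
        if len(geometries) != len(environments):
            raise ValueError("geometry/environment count mismatch")
        self.pigment_type = _check_single_type(geometries)
        self.cutoff_A = float(cutoff_A)
        self.X = shift_features(geometries, environments, cutoff_A)
        self.y = np.asarray(shifts_ev, dtype=float)
        if kernel not in ("composite_shift", "linear"):
            raise ValueError("shift kernel must be 'composite_shift' or 'linear'")
        self.kernel_kind = kernel

    def fit(self, restarts: int = 5, seed: int = 0, bounds=None,
            optimize_hyperparameters: bool = True) -> "ShiftResults":
        kernel = (
            CompositeShiftKernel() if self.kernel_kind == "composite_shift" else LinearKernel()
        )
        gp = GaussianProcess(self.X, self.y, kernel, prior_mean="zero")
        res = gp.fit(
            optimize_hyperparameters=optimize_hyperparameters,
            restarts=restarts,
            seed=seed,
            bounds=bounds,
        )
        res.metadata.update(
            {
                "model": "shift",
                "target": "eps_shift_ev",
                "pigment_type": self.pigment_type,
                "cutoff_A": self.cutoff_A,
            }
        )
        return ShiftResults(res)


class ShiftResults:
    """Shift-model results: predicts ε̂_shift (eV) from (geometry, env)."""

    def __init__(self, gp_results: GPResults):
        self.gp = gp_results

    @property
    def pigment_type(self) -> str:
        return self.gp.metadata.get("pigment_type", "")

    @property
    def cutoff_A(self) -> float:
        return float(self.gp.metadata.get("cutoff_A", 30.0))

    def features(self, geometries, environments) -> ShiftFeatures:
        return shift_features(geometries, environments, self.cutoff_A)

    def predict(self, geometries, environments, return_var: bool = False):
        return self.gp.predict(
            self.features(geometries, environments), return_var=return_var
        )

    def predict_features(self, X: ShiftFeatures, return_var: bool = False):
        return self.gp.predict(X, return_var=return_var)

    def effective_charges(self) -> np.ndarray:
        """Effective QM response charges of the linear kernel part.

        For a pure linear kernel the posterior mean is ⟨Φ*, C⟩ with
        C = σ₁² Φ_trainᵀ α — the ridge-type regression coefficients of the
        shift on the potential features (up to the Coulomb constant).
        """
        k = self.gp.kernel_
        sigma1 = getattr(k, "sigma1")
        return sigma1**2 * (self.gp.model.X.pot.T @ self.gp.alpha_)

    def summary(self) -> str:
        return self.gp.summary()

    def save(self, path) -> None:
        self.gp.save(path)

    @classmethod
    def load(cls, path) -> "ShiftResults":
        return cls(GPResults.load(path))


# -- spec-level functional surface -------------------------------------


def train_vacuum_model(geometries, eps_vac_targets, restarts: int = 5,
                       seed: int = 0, bounds=None) -> VacuumResults:
    return VacuumModel(geometries, eps_vac_targets).fit(
        restarts=restarts, seed=seed, bounds=bounds
    )


def train_shift_model(geometries, environments, eps_shift_targets,
                      cutoff_A: float = 30.0, restarts: int = 5, seed: int = 0,
                      bounds=None, kernel: str = "composite_shift") -> ShiftResults:
    return ShiftModel(
        geometries, environments, eps_shift_targets, cutoff_A=cutoff_A, kernel=kernel
    ).fit(restarts=restarts, seed=seed, bounds=bounds)


def predict_site_energy(
    vacuum: VacuumResults,
    shift: ShiftResults,
    geom: ChromophoreGeometry,
    env: EnvironmentModel,
    polarization_context=None,
    pigment_id: str = "",
) -> SiteEnergyPrediction:
    """Sequential site-energy prediction ε̂ = ε̂_vac + ε̂_shift + ε̂_pol.

    The polarization term is zero unless a
    :class:`~exciham.tresp.PolarizationContext` is supplied.  The variance
    is the sum of the two GP posterior variances (the models are treated
    as independent).
    """
    vac_mean, vac_var = vacuum.predict([geom], return_var=True)
    shift_mean, shift_var = shift.predict([geom], [env], return_var=True)
    eps_pol = 0.0
    if polarization_context is not None:
        eps_pol = polarization_context.site_contribution(geom, env)
    value = float(vac_mean[0] + shift_mean[0] + eps_pol)
    return SiteEnergyPrediction(
        value=value,
        variance=float(vac_var[0] + shift_var[0]),
        eps_vac=float(vac_mean[0]),
        eps_shift=float(shift_mean[0]),
        eps_pol=float(eps_pol),
        pigment_id=pigment_id,
    )


def cdc_shift(
    delta_q: CDCChargeSet,
    geom: ChromophoreGeometry,
    env: EnvironmentModel,
    cutoff_A: float = 30.0,
) -> float:
    """Charge-density-coupling electrochromic shift (eV).

    k_e Σ_i Σ_m Δq_i q_m / r_im over the environment residues within the
    cutoff; the bare charge–charge form with no dielectric screening.
    """
    dq = delta_q.delta_charges
    if dq.shape[0] != geom.n_atoms:
        raise ValueError("one difference charge per QM atom required")
    if env.n_atoms == 0:
        return 0.0
    sub = env.subset(residue_cutoff_mask(geom, env, cutoff_A))
    if sub.n_atoms == 0:
        return 0.0
    r = cdist(geom.coordinates, sub.positions)
    if r.min() < 0.1:
        raise SingularityError("environment atom within 0.1 Å of a QM atom")
    return float(K_E * (dq @ (sub.charges[None, :] / r).sum(axis=1)))
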