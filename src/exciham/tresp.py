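"""Transition charges, excitonic couplings and polarizable corrections.

The transition density of a pigment's bright excitation is represented by
atom-centered **TrEsp** transition charges {q^tr}.  With two such sets the
Coulomb part of the excitonic coupling is

    V_coul = k_e Σ_i Σ_j q_i^tr,I q_j^tr,J / r_ij .

The environment enters twice.  First, embedding rescales the vacuum
transition charges by a per-pigment factor γ.  Second, a *polarizable*
environment carries induced dipoles responding to the transition density.
Solving the mutual-polarization linear system

    μ_m = α_m ( E_m^ext + Σ_{m'≠m} T_mm' μ_m' )

with the point-dipole interaction tensor T gives:

* the polarization contribution to the site energy,
  ε_pol = −(1/2) k_e Σ_m μ_m({q^tr}) · E_m({q^tr})  ≤ 0,
  the self-energy of the linear response to the transition field
  (the prefactor is configurable; −1/2 is the linear-response value);

* the screening correction to the coupling,
  V_screen = −k_e Σ_m μ_m({q^tr}_J) · E_m({q^tr}_I),
  the dipoles induced by pigment J interacting with the transition field
  of pigment I — symmetric under I↔J because the polarization response
  matrix is symmetric.

Vacuum transition charges are estimated from the Coulomb-matrix descriptor
with a per-atom Ridge regression, optionally neutralized to zero total
charge.

No Thole damping is applied: the bare dipole tensor is used with a hard
minimum-distance guard that raises on close contacts instead of damping
them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.linear_model import Ridge

from .constants import K_E
from .descriptors import coulomb_matrix
from .systems import ChromophoreGeometry, EnvironmentModel

MIN_CONTACT = 1.0  # Å; closer charge/dipole pairs raise instead of damping
POL_PREFACTOR = -0.5  # linear-response self-energy prefactor for eps_pol


class PolarizationError(ValueError):
    """Singular or unphysically close polarization configuration."""


@dataclass(frozen=True)
class TransitionChargeSet:
    """Per-atom transition charges (e) with environment scaling γ."""

    charges: np.ndarray
    gamma: float = 1.0
    state_label: str = "Qy"

    def __post_init__(self):
        q = np.asarray(self.charges, dtype=float).ravel()
        if not np.all(np.isfinite(q)):
            raise ValueError("transition charges must be finite")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        object.__setattr__(self, "charges", q)


@dataclass(frozen=True)
class InducedDipoleSet:
    """Induced dipoles (e·Å) on the polarizable sites of one environment."""

    dipoles: np.ndarray  # (n_pol_sites, 3) for the full environment
    source_label: str = ""

    def __post_init__(self):
        mu = np.atleast_2d(np.asarray(self.dipoles, dtype=float))
        if mu.size == 0:
            mu = mu.reshape(0, 3)
        object.__setattr__(self, "dipoles", mu)


def scale_charges(q: TransitionChargeSet, gamma: float) -> TransitionChargeSet:
    """Multiply every transition charge by γ (environment scaling)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return replace(q, charges=q.charges * gamma, gamma=gamma)


def neutralize(charges: np.ndarray) -> np.ndarray:
    """Uniform shift to zero total charge."""
    charges = np.asarray(charges, dtype=float)
    return charges - charges.mean(axis=-1, keepdims=True)


class TrespModel:
    """Per-atom Ridge regression of transition charges on the Coulomb matrix."""

    def __init__(self, geometries, target_charge_sets, ridge_lambda: float = 1e-6,
                 neutralize_predictions: bool = True):
        geometries = list(geometries)
        Q = np.stack(
            [np.asarray(getattr(t, "charges", t), dtype=float) for t in target_charge_sets]
        )
        counts = {g.n_atoms for g in geometries}
        if len(counts) != 1 or Q.shape != (len(geometries), counts.pop()):
            raise ValueError("all samples must share atom count and order")
        self.X = np.stack([coulomb_matrix(g).values for g in geometries])
        self.Q = Q
        self.ridge_lambda = float(ridge_lambda)
        self.neutralize = bool(neutralize_predictions)

    def fit(self) -> "TrespResults":
        reg = Ridge(alpha=self.ridge_lambda, fit_intercept=True)
        reg.fit(self.X, self.Q)
        return TrespResults(reg, self.neutralize)


class TrespResults:
    def __init__(self, regressor, neutralize_predictions: bool):
        self._reg = regressor
        self.neutralize = neutralize_predictions

    def predict(self, geometries, gamma: float = 1.0, state_label: str = "Qy"):
        X = np.stack([coulomb_matrix(g).values for g in geometries])
        Q = self._reg.predict(X)
        if self.neutralize:
            Q = neutralize(Q)
        return [
            TransitionChargeSet(charges=gamma * q, gamma=gamma, state_label=state_label)
            for q in Q
        ]


def fit_tresp_model(geometries, target_charge_sets, ridge_lambda: float = 1e-6,
                    neutralize_predictions: bool = True) -> TrespResults:
    """Fit the linear CM → transition-charge map (Ridge, per atom)."""
    return TrespModel(
        geometries, target_charge_sets, ridge_lambda, neutralize_predictions
    ).fit()


# -- electrostatics ----------------------------------------------------


def _charges_of(q) -> np.ndarray:
    return np.asarray(getattr(q, "charges", q), dtype=float).ravel()


def transition_dipole(qtr, positions) -> np.ndarray:
    """Transition dipole Σ q_i r_i (e·Å) of a transition-charge set."""
    q = _charges_of(qtr)
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    return q @ pos


def coulomb_coupling(qI, posI, qJ, posJ) -> float:
    """TrEsp Coulomb coupling k_e ΣΣ q_i q_j / r_ij (eV)."""
    qi, qj = _charges_of(qI), _charges_of(qJ)
    ri = np.atleast_2d(np.asarray(posI, dtype=float))
    rj = np.atleast_2d(np.asarray(posJ, dtype=float))
    r = cdist(ri, rj)
    if r.min() <= MIN_CONTACT:
        raise PolarizationError(
            f"chromophores overlap: min distance {r.min():.3f} Å <= {MIN_CONTACT} Å"
        )
    return float(K_E * qi @ (1.0 / r) @ qj)


def charge_field(charges, charge_positions, site_positions) -> np.ndarray:
    """Electric field (e/Å²) of point charges at the given sites."""
    q = _charges_of(charges)
    rq = np.atleast_2d(np.asarray(charge_positions, dtype=float))
    rs = np.atleast_2d(np.asarray(site_positions, dtype=float))
    if rs.size == 0:
        return np.zeros((0, 3))
    dr = rs[:, None, :] - rq[None, :, :]  # site - charge
    dist = np.linalg.norm(dr, axis=-1)
    if dist.size and dist.min() <= MIN_CONTACT:
        raise PolarizationError(
            f"charge within {MIN_CONTACT} Å of a polarizable site"
        )
    return np.einsum("smk,m,sm->sk", dr, q, dist**-3)


def _dipole_interaction_matrix(pos: np.ndarray) -> np.ndarray:
    """Block matrix of point-dipole tensors T = (3 r̂r̂ᵀ − I)/r³; zero blocks on the diagonal."""
    n = pos.shape[0]
    T = np.zeros((3 * n, 3 * n))
    if n < 2:
        return T
    dr = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(dr, axis=-1)
    np.fill_diagonal(dist, np.inf)
    if dist.min() <= MIN_CONTACT:
        raise PolarizationError(
            f"polarizable sites within {MIN_CONTACT} Å of each other "
            "(polarization catastrophe risk)"
        )
    blocks = (
        3.0 * np.einsum("abi,abj->abij", dr, dr) / dist[..., None, None] ** 5
        - np.eye(3)[None, None] / dist[..., None, None] ** 3
    )
    for a in range(n):
        blocks[a, a] = 0.0
    T = blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    return T


def solve_induced_dipoles(
    env: EnvironmentModel,
    source_charges,
    source_positions,
    source_label: str = "",
) -> InducedDipoleSet:
    """Mutually consistent induced dipoles for the external charge field.

    Solves (I − α T) μ = α E_ext over the sites with α > 0 by a direct
    dense solve; sites with zero polarizability carry zero dipole.  The
    returned dipoles are ordered like ``env`` atoms.
    """
    if not env.is_polarizable:
        raise PolarizationError("environment carries no polarizabilities")
    alpha = env.polarizabilities
    mu = np.zeros((env.n_atoms, 3))
    active = alpha > 0
    n = int(active.sum())
    if n == 0:
        return InducedDipoleSet(dipoles=mu, source_label=source_label)
    pos = env.positions[active]
    a = np.repeat(alpha[active], 3)
    E = charge_field(source_charges, source_positions, pos).ravel()
    T = _dipole_interaction_matrix(pos)
    A = np.eye(3 * n) - a[:, None] * T
    try:
        sol = np.linalg.solve(A, a * E)
    except np.linalg.LinAlgError as exc:
        raise PolarizationError("singular mutual-polarization system") from exc
    mu[active] = sol.reshape(n, 3)
    return InducedDipoleSet(dipoles=mu, source_label=source_label)


def _dipole_field_energy(charges, charge_positions, env: EnvironmentModel,
                         dipoles: InducedDipoleSet) -> float:
    """k_e Σ_m μ_m · E_m(charges), the dipole/field contraction in eV."""
    alpha = env.polarizabilities
    active = alpha > 0
    if not active.any():
        return 0.0
    E = charge_field(charges, charge_positions, env.positions[active])
    return float(K_E * np.sum(dipoles.dipoles[active] * E))


def polarization_site_contribution(
    qtr: TransitionChargeSet,
    geom: ChromophoreGeometry,
    env: EnvironmentModel,
    prefactor: float = POL_PREFACTOR,
) -> float:
    """Polarization contribution ε_pol (eV) of the environment response.

    ε_pol = prefactor · k_e Σ_m μ_m({q^tr}) · E_m({q^tr}); with the default
    prefactor −1/2 this is the (non-positive) self-energy of the induced
    dipoles in the transition-charge field.
    """
    q = qtr.charges
    if q.shape[0] != geom.n_atoms:
        raise ValueError("one transition charge per QM atom required")
    if env.n_atoms == 0 or not np.any(q):
        return 0.0
    mu = solve_induced_dipoles(env, qtr, geom.coordinates, source_label=qtr.state_label)
    return prefactor * _dipole_field_energy(qtr, geom.coordinates, env, mu)


def screening_term(qI, posI, qJ, posJ, env: EnvironmentModel) -> float:
    """Environment screening of the coupling (eV).

    −k_e Σ_m μ_m({q^tr}_J) · E_m({q^tr}_I): dipoles induced by the
    transition density of chromophore J interacting with the field of the
    transition charges of chromophore I.
    """
    if env.n_atoms == 0:
        return 0.0
    if not env.is_polarizable or not np.any(env.polarizabilities > 0):
        return 0.0
    muJ = solve_induced_dipoles(env, qJ, posJ, source_label="J")
    return -_dipole_field_energy(qI, posI, env, muJ)


@dataclass(frozen=True)
class PolarizationContext:
    """Bundle needed to add ε_pol to a sequential site-energy prediction."""

    tresp: TransitionChargeSet
    prefactor: float = POL_PREFACTOR

    def site_contribution(self, geom: ChromophoreGeometry, env: EnvironmentModel) -> float:
        if env.n_atoms == 0 or not env.is_polarizable:
            return 0.0
        return polarization_site_contribution(
            self.tresp, geom, env, prefactor=self.prefactor
        )


def total_coupling(qI, posI, qJ, posJ, env: EnvironmentModel | None = None) -> float:
    """Coulomb coupling plus (if the environment is polarizable) screening."""
    v = coulomb_coupling(qI, posI, qJ, posJ)
    if env is not None and env.is_polarizable:
        v += screening_term(qI, posI, qJ, posJ, env)
    return v
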