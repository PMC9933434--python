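"""Frenkel exciton Hamiltonians: assembly, diagonalization and analysis.

The exciton Hamiltonian of an aggregate of N pigments (one bright state
each) is the symmetric N×N matrix with site energies ε_I on the diagonal
and excitonic couplings V_IJ off it.  Diagonalizing it yields the exciton
energies and the coefficient matrix that mixes localized transitions; the
exciton transition dipoles are the same linear combinations of the site
dipoles, so total dipole strength is conserved (sum rule).

The residue-influence analysis quantifies how single environment residues
tune a pigment's site energy: ε_{P:R} is the difference between the
predicted electrochromic shift with the full environment and with residue
R's charges turned off (atoms kept in place, charges zeroed, no
re-selection of the cutoff set).

A Gaussian-broadened stick spectrum over an ensemble of Hamiltonians is
provided as a lightweight stand-in for a full lineshape theory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .site_energy import ShiftResults, SiteEnergyPrediction
from .systems import ChromophoreGeometry, EnvironmentModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExcitonHamiltonian:
    """Symmetric site-basis Hamiltonian (eV) with pigment labels."""

    matrix: np.ndarray
    site_labels: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        H = np.asarray(self.matrix, dtype=float)
        n = len(self.site_labels)
        if H.shape != (n, n):
            raise ValueError("matrix shape inconsistent with site labels")
        if not np.allclose(H, H.T, atol=1e-12, rtol=0.0):
            raise ValueError("Hamiltonian must be symmetric to 1e-12")
        object.__setattr__(self, "matrix", 0.5 * (H + H.T))
        object.__setattr__(self, "site_labels", tuple(self.site_labels))

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    @property
    def site_energies(self) -> np.ndarray:
        return np.diag(self.matrix)


def build_hamiltonian(site_energies, couplings, provenance: dict | None = None) -> ExcitonHamiltonian:
    """Assemble a Hamiltonian from site energies and a pair-coupling table.

    ``site_energies`` maps label → energy (eV) or is a list of
    :class:`~exciham.site_energy.SiteEnergyPrediction`; ``couplings`` maps
    (label_I, label_J) → V_IJ (eV).  Missing pairs default to zero with a
    logged warning; a pair listed twice with inconsistent values is an
    error.
    """
    if isinstance(site_energies, dict):
        labels = list(site_energies)
        energies = [float(site_energies[k]) for k in labels]
    else:
        preds = list(site_energies)
        if preds and isinstance(preds[0], SiteEnergyPrediction):
            labels = [p.pigment_id or f"site{i}" for i, p in enumerate(preds)]
            energies = [p.value for p in preds]
        else:
            energies = [float(v) for v in preds]
            labels = [f"site{i}" for i in range(len(energies))]
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    H = np.diag(np.asarray(energies, dtype=float))
    seen: dict[tuple[int, int], float] = {}
    for (a, b), v in couplings.items():
        i, j = idx[a], idx[b]
        if i == j:
            raise ValueError(f"coupling given for a site with itself: {a}")
        key = (min(i, j), max(i, j))
        if key in seen and not np.isclose(seen[key], v, rtol=0.0, atol=1e-12):
            raise ValueError(f"inconsistent duplicate coupling for pair {a},{b}")
        seen[key] = float(v)
        H[i, j] = H[j, i] = float(v)
    n_missing = n * (n - 1) // 2 - len(seen)
    if n_missing:
        logger.warning("%d pigment pairs lack couplings; set to 0", n_missing)
    return ExcitonHamiltonian(matrix=H, site_labels=labels, provenance=provenance or {})


def diagonalize(H: ExcitonHamiltonian):
    """Exciton energies (ascending, eV) and orthonormal coefficient matrix.

    Column k of the coefficient matrix holds the site amplitudes of
    exciton k.
    """
    energies, coeff = np.linalg.eigh(H.matrix)
    return energies, coeff


def residue_influence(
    shift_model: ShiftResults,
    geom: ChromophoreGeometry,
    env: EnvironmentModel,
    residue_id: int,
) -> float:
    """Influence ε_{P:R} (eV) of one residue on the predicted shift.

    Predicted shift with the full environment minus the shift with residue
    R's charges zeroed (its atoms remain, so the cutoff residue selection
    is unchanged).
    """
    env_off = env.with_residue_off(residue_id)
    on = shift_model.predict([geom], [env])[0]
    off = shift_model.predict([geom], [env_off])[0]
    return float(on - off)


@dataclass(frozen=True)
class ResidueInfluenceRecord:
    """Per-frame influence samples of one residue on one pigment (eV)."""

    pigment_id: str
    residue_id: int
    residue_name: str
    samples: np.ndarray
    mean: float
    std: float

    @classmethod
    def from_samples(cls, pigment_id, residue_id, residue_name, samples):
        s = np.asarray(samples, dtype=float)
        return cls(
            pigment_id=pigment_id,
            residue_id=int(residue_id),
            residue_name=str(residue_name),
            samples=s,
            mean=float(s.mean()),
            std=float(s.std()),
        )


def residue_influence_scan(
    shift_model: ShiftResults,
    frames,
    pigment_id: str = "",
    radius_A: float = 6.0,
) -> list[ResidueInfluenceRecord]:
    """Mean and spread of ε_{P:R} over frames for residues near the pigment.

    ``frames`` is a sequence of (geometry, environment) pairs for the same
    pigment.  A residue is scanned if any of its atoms comes within
    ``radius_A`` of the pigment in at least one frame (atom-minimum
    distance criterion).
    """
    frames = list(frames)
    selected: dict[int, str] = {}
    for geom, env in frames:
        if env.n_atoms == 0:
            continue
        dmin = cdist(env.positions, geom.coordinates).min(axis=1)
        for rid in env.unique_residues():
            sel = env.residue_ids == rid
            if dmin[sel].min() <= radius_A and rid not in selected:
                names = env.residue_names
                selected[int(rid)] = (
                    str(np.asarray(names, dtype=object)[sel][0]) if names else ""
                )
    records = []
    for rid in sorted(selected):
        samples = [
            residue_influence(shift_model, geom, env, rid)
            for geom, env in frames
            if (env.residue_ids == rid).any()
        ]
        records.append(
            ResidueInfluenceRecord.from_samples(pigment_id, rid, selected[rid], samples)
        )
    return records


@dataclass(frozen=True)
class Spectrum:
    """Absorption stick spectrum broadened on an energy grid."""

    energies_ev: np.ndarray
    intensity: np.ndarray

    def integrated_intensity(self) -> float:
        return float(np.trapezoid(self.intensity, self.energies_ev))


def exciton_dipoles(H: ExcitonHamiltonian, site_dipoles: np.ndarray):
    """Exciton energies, transition dipoles and dipole strengths."""
    mu_site = np.atleast_2d(np.asarray(site_dipoles, dtype=float))
    if mu_site.shape != (H.n_sites, 3):
        raise ValueError("site_dipoles must have shape (n_sites, 3)")
    energies, coeff = diagonalize(H)
    mu_ex = coeff.T @ mu_site  # (n_excitons, 3)
    strengths = np.einsum("ij,ij->i", mu_ex, mu_ex)
    return energies, mu_ex, strengths


def broadened_spectrum(
    hamiltonians,
    site_dipoles,
    fwhm_ev: float = 0.05,
    grid_ev: np.ndarray | None = None,
    grid_spacing_ev: float = 0.001,
    grid_pad_sigma: float = 8.0,
) -> Spectrum:
    """Ensemble-averaged Gaussian-broadened absorption spectrum.

    Stick intensities are exciton dipole strengths |μ_ex|²; each stick is
    broadened with a unit-area Gaussian of the given FWHM, so the
    integrated intensity equals the ensemble-mean total dipole strength.
    ``site_dipoles`` is one (n_sites, 3) array shared by all frames or a
    list with one per frame.
    """
    hams = list(hamiltonians)
    if not hams:
        raise ValueError("need at least one Hamiltonian")
    if fwhm_ev <= 0:
        raise ValueError("fwhm must be positive")
    dip_list = (
        site_dipoles
        if isinstance(site_dipoles, (list, tuple))
        else [site_dipoles] * len(hams)
    )
    sigma = fwhm_ev / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    all_e, all_s = [], []
    for H, mu in zip(hams, dip_list):
        e, _, s = exciton_dipoles(H, mu)
        all_e.append(e)
        all_s.append(s)
    e_all = np.concatenate(all_e)
    if grid_ev is None:
        lo = e_all.min() - grid_pad_sigma * sigma
        hi = e_all.max() + grid_pad_sigma * sigma
        grid_ev = np.arange(lo, hi + grid_spacing_ev, grid_spacing_ev)
    intensity = np.zeros_like(grid_ev, dtype=float)
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    for e, s in zip(all_e, all_s):
        g = np.exp(-0.5 * ((grid_ev[:, None] - e[None, :]) / sigma) ** 2)
        intensity += g @ s * norm
    intensity /= len(hams)
    return Spectrum(energies_ev=np.asarray(grid_ev), intensity=intensity)


def difference_spectrum(spec_a: Spectrum, spec_b: Spectrum) -> Spectrum:
    """a − b on spec_a's grid (b is interpolated onto it)."""
    b = np.interp(spec_a.energies_ev, spec_b.energies_ev, spec_b.intensity)
    return Spectrum(energies_ev=spec_a.energies_ev, intensity=spec_a.intensity - b)
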