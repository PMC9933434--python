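"""Descriptors for the site-energy models.

Two featurizations are used:

* the **Coulomb matrix** of the heavy atoms of the chromophore — the
  flattened upper triangle of Z_i Z_j / r_ij — which encodes the internal
  geometry (bonds, angles, torsions, and long-range deformations) in a
  rotation/translation-invariant way.  Hydrogens are excluded: they add
  permutationally ambiguous, nearly redundant entries and encourage
  memorization of the training set.  The constant diagonal is dropped.

* the **MM potential descriptor** — the electrostatic potential generated
  by the environment point charges on every QM atom (hydrogens included),
  a fixed-length encoding of the environment whose size is independent of
  the number of MM atoms.  Residues are included whole when their minimum
  distance from the QM subsystem is within a cutoff (30 Å by default at
  the workflow level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .systems import ChromophoreGeometry, EnvironmentModel, GeometryError

MIN_QM_MM_DISTANCE = 0.1  # Å; a closer MM charge is a singular configuration


class SingularityError(ValueError):
    """An environment charge (nearly) coincides with a QM atom."""


@dataclass(frozen=True)
class CoulombMatrixDescriptor:
    """Flattened upper triangle of the heavy-atom Coulomb matrix."""

    values: np.ndarray
    n_heavy: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        expected = self.n_heavy * (self.n_heavy - 1) // 2
        if v.shape != (expected,):
            raise ValueError(
                f"Coulomb matrix length {v.shape} inconsistent with "
                f"n_heavy={self.n_heavy}"
            )
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PotentialDescriptor:
    """MM electrostatic potential (e/Å) on each QM atom."""

    values: np.ndarray
    cutoff_A: float

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def coulomb_matrix(geom: ChromophoreGeometry) -> CoulombMatrixDescriptor:
    """Heavy-atom Coulomb matrix descriptor of a chromophore geometry.

    Entries are Z_i Z_j / r_ij over heavy-atom pairs, flattened in the
    canonical atom order (upper triangle, row-major); the diagonal is
    omitted.  Raises :class:`~exciham.systems.AtomOrderError` if the
    geometry's atoms deviate from the registered canonical order for its
    pigment type, and :class:`~exciham.systems.GeometryError` on
    overlapping atoms.
    """
    geom.check_canonical()
    mask = geom.heavy_mask
    z = geom.atomic_numbers[mask].astype(float)
    xyz = geom.coordinates[mask]
    n = int(mask.sum())
    if n < 2:
        return CoulombMatrixDescriptor(values=np.empty(0), n_heavy=n)
    d = cdist(xyz, xyz)
    iu = np.triu_indices(n, k=1)
    r = d[iu]
    if r.min() < 0.5:
        raise GeometryError("heavy atoms closer than 0.5 Å")
    vals = z[iu[0]] * z[iu[1]] / r
    return CoulombMatrixDescriptor(values=vals, n_heavy=n)


def residue_cutoff_mask(
    geom: ChromophoreGeometry, env: EnvironmentModel, cutoff_A: float
) -> np.ndarray:
    """Boolean mask of environment atoms whose residue is within the cutoff.

    A residue is retained iff the minimum distance between any of its atoms
    and any QM atom is <= ``cutoff_A``; residues are kept or dropped whole.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff_A must be positive")
    if env.n_atoms == 0:
        return np.zeros(0, dtype=bool)
    dmin = cdist(env.positions, geom.coordinates).min(axis=1)
    keep = np.zeros(env.n_atoms, dtype=bool)
    for rid in env.unique_residues():
        sel = env.residue_ids == rid
        if dmin[sel].min() <= cutoff_A:
            keep[sel] = True
    return keep


def mm_potential(
    geom: ChromophoreGeometry, env: EnvironmentModel, cutoff_A: float = 30.0
) -> PotentialDescriptor:
    """Electrostatic potential of the MM charges on every QM atom (e/Å)."""
    if env.n_atoms == 0:
        return PotentialDescriptor(values=np.zeros(geom.n_atoms), cutoff_A=cutoff_A)
    keep = residue_cutoff_mask(geom, env, cutoff_A)
    sub = env.subset(keep)
    if sub.n_atoms == 0:
        return PotentialDescriptor(values=np.zeros(geom.n_atoms), cutoff_A=cutoff_A)
    r = cdist(geom.coordinates, sub.positions)  # (n_qm, n_mm)
    if r.min() < MIN_QM_MM_DISTANCE:
        raise SingularityError(
            f"environment atom within {MIN_QM_MM_DISTANCE} Å of a QM atom"
        )
    phi = (sub.charges[None, :] / r).sum(axis=1)
    return PotentialDescriptor(values=phi, cutoff_A=cutoff_A)


@dataclass(frozen=True)
class ShiftFeatures:
    """Paired descriptor matrices for the electrochromic-shift model.

    ``cm`` holds one Coulomb-matrix row per sample, ``pot`` one MM-potential
    row per sample; both are required by the composite shift kernel.
    """

    cm: np.ndarray   # (n_samples, n_cm)
    pot: np.ndarray  # (n_samples, n_qm_atoms)

    def __post_init__(self):
        cm = np.atleast_2d(np.asarray(self.cm, dtype=float))
        pot = np.atleast_2d(np.asarray(self.pot, dtype=float))
        if cm.shape[0] != pot.shape[0]:
            raise ValueError("cm and pot must have the same number of rows")
        object.__setattr__(self, "cm", cm)
        object.__setattr__(self, "pot", pot)

    def __len__(self) -> int:
        return self.cm.shape[0]

    def take(self, idx) -> "ShiftFeatures":
        idx = np.asarray(idx)
        return ShiftFeatures(cm=self.cm[idx], pot=self.pot[idx])


def shift_features(geoms, envs, cutoff_A: float = 30.0) -> ShiftFeatures:
    """Stack Coulomb-matrix and MM-potential descriptors for paired samples."""
    if len(geoms) != len(envs):
        raise ValueError("geometry/environment count mismatch")
    cm = np.stack([coulomb_matrix(g).values for g in geoms])
    pot = np.stack(
        [mm_potential(g, e, cutoff_A).values for g, e in zip(geoms, envs)]
    )
    return ShiftFeatures(cm=cm, pot=pot)


def interaction_weight(phi, phi2) -> float:
    """Inner product of two potential descriptors.

    This is the similarity the shift kernel uses: proportional to the
    magnitude of the QM–MM interaction energy the two environments would
    share through a common set of effective QM charges.
    """
    a = np.asarray(getattr(phi, "values", phi), dtype=float)
    b = np.asarray(getattr(phi2, "values", phi2), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(a @ b)
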