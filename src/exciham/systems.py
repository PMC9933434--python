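"""Domain containers: the QM chromophore and the classical (MM) environment.

A :class:`ChromophoreGeometry` is the quantum subsystem — the labeled atoms
of one pigment (e.g. a chlorophyll macrocycle with the phytyl tail already
truncated upstream).  An :class:`EnvironmentModel` is the molecular-mechanics
subsystem: point charges grouped into residues, optionally carrying isotropic
polarizabilities for a polarizable-embedding treatment.

Units throughout the package: distances in Å, charges in elementary charges
(e), polarizabilities in Å³, energies in eV.  Electrostatic potentials are
kept in e/Å and converted to eV only at energy-forming steps via
:data:`exciham.constants.K_E`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Atomic numbers for the elements that occur in pigment macrocycles and
# typical MM environments; extended as needed.
ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "K": 19, "Ca": 20, "Mn": 25, "Fe": 26, "Zn": 30,
    "Br": 35, "I": 53,
}

MIN_PAIR_DISTANCE = 0.5  # Å; closer atoms indicate a broken geometry

# Registry of canonical atom orders, one per pigment type.  The Coulomb
# matrix is not permutation invariant, so every instance of a pigment type
# must present its atoms in the same order before descriptors are built.
_CANONICAL_ORDERS: dict[str, tuple[str, ...]] = {}


class GeometryError(ValueError):
    """Invalid chromophore geometry (overlapping atoms, bad coordinates)."""


class AtomOrderError(ValueError):
    """Atom names do not match the canonical order for the pigment type."""


def register_pigment_type(pigment_type: str, atom_names) -> None:
    """Register (or re-assert) the canonical atom-name order for a type."""
    names = tuple(atom_names)
    existing = _CANONICAL_ORDERS.get(pigment_type)
    if existing is not None and existing != names:
        raise AtomOrderError(
            f"pigment type {pigment_type!r} already registered with a "
            "different atom order"
        )
    _CANONICAL_ORDERS[pigment_type] = names


def canonical_order(pigment_type: str):
    """Return the registered atom-name order, or None if unregistered."""
    return _CANONICAL_ORDERS.get(pigment_type)


@dataclass(frozen=True)
class ChromophoreGeometry:
    """One pigment's atoms: elements, canonical names and coordinates (Å)."""

    elements: tuple[str, ...]
    atom_names: tuple[str, ...]
    coordinates: np.ndarray  # (n_atoms, 3), Å
    pigment_type: str = "GEN"

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError("coordinates must have shape (n_atoms, 3)")
        if len(self.elements) != coords.shape[0] or len(self.atom_names) != coords.shape[0]:
            raise GeometryError("elements/atom_names/coordinates length mismatch")
        if not np.all(np.isfinite(coords)):
            raise GeometryError("non-finite coordinates")
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "atom_names", tuple(self.atom_names))
        object.__setattr__(self, "coordinates", coords)
        if self.n_atoms > 1:
            d = np.linalg.norm(
                coords[:, None, :] - coords[None, :, :], axis=-1
            )
            np.fill_diagonal(d, np.inf)
            if d.min() < MIN_PAIR_DISTANCE:
                raise GeometryError(
                    f"overlapping atoms: min pair distance {d.min():.3f} Å "
                    f"< {MIN_PAIR_DISTANCE} Å"
                )

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    @property
    def atomic_numbers(self) -> np.ndarray:
        try:
            return np.array([ATOMIC_NUMBERS[e] for e in self.elements])
        except KeyError as exc:  # pragma: no cover - defensive
            raise GeometryError(f"unknown element {exc.args[0]!r}") from exc

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.atomic_numbers > 1

    def check_canonical(self) -> None:
        """Raise AtomOrderError if atoms deviate from the registered order."""
        order = canonical_order(self.pigment_type)
        if order is not None and self.atom_names != order:
            raise AtomOrderError(
                f"atoms of pigment type {self.pigment_type!r} are not in "
                "canonical order; call canonicalized() first"
            )

    def canonicalized(self) -> "ChromophoreGeometry":
        """Reorder atoms by name into the registered canonical order."""
        order = canonical_order(self.pigment_type)
        if order is None:
            return self
        name_to_idx = {n: i for i, n in enumerate(self.atom_names)}
        if set(order) != set(self.atom_names):
            raise AtomOrderError(
                f"atom names do not match template for {self.pigment_type!r}"
            )
        idx = [name_to_idx[n] for n in order]
        return ChromophoreGeometry(
            elements=tuple(self.elements[i] for i in idx),
            atom_names=order,
            coordinates=self.coordinates[idx],
            pigment_type=self.pigment_type,
        )

    def transformed(self, rotation=None, translation=None) -> "ChromophoreGeometry":
        coords = self.coordinates
        if rotation is not None:
            coords = coords @ np.asarray(rotation).T
        if translation is not None:
            coords = coords + np.asarray(translation)
        return replace(self, coordinates=coords)


@dataclass(frozen=True)
class EnvironmentModel:
    """MM point charges grouped into residues, optionally polarizable."""

    positions: np.ndarray       # (n, 3), Å
    charges: np.ndarray         # (n,), e
    residue_ids: np.ndarray     # (n,), int grouping key
    residue_names: tuple[str, ...] = ()
    polarizabilities: np.ndarray | None = None  # (n,), Å³, all present or None

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.size == 0:
            pos = pos.reshape(0, 3)
        q = np.atleast_1d(np.asarray(self.charges, dtype=float))
        rid = np.atleast_1d(np.asarray(self.residue_ids, dtype=int))
        if pos.shape != (q.shape[0], 3) or rid.shape[0] != q.shape[0]:
            raise ValueError("positions/charges/residue_ids length mismatch")
        names = tuple(self.residue_names)
        if names and len(names) != q.shape[0]:
            raise ValueError("residue_names length mismatch")
        alpha = self.polarizabilities
        if alpha is not None:
            alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
            if alpha.shape[0] != q.shape[0]:
                raise ValueError("polarizabilities length mismatch")
            if np.any(alpha < 0):
                raise ValueError("polarizabilities must be >= 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", q)
        object.__setattr__(self, "residue_ids", rid)
        object.__setattr__(self, "residue_names", names)
        object.__setattr__(self, "polarizabilities", alpha)

    @property
    def n_atoms(self) -> int:
        return self.charges.shape[0]

    @property
    def is_polarizable(self) -> bool:
        return self.polarizabilities is not None

    def unique_residues(self) -> np.ndarray:
        return np.unique(self.residue_ids)

    def subset(self, mask) -> "EnvironmentModel":
        mask = np.asarray(mask)
        names = (
            tuple(np.asarray(self.residue_names, dtype=object)[mask])
            if self.residue_names
            else ()
        )
        return EnvironmentModel(
            positions=self.positions[mask],
            charges=self.charges[mask],
            residue_ids=self.residue_ids[mask],
            residue_names=names,
            polarizabilities=(
                None if self.polarizabilities is None else self.polarizabilities[mask]
            ),
        )

    def residue(self, residue_id: int) -> "EnvironmentModel":
        mask = self.residue_ids == residue_id
        if not mask.any():
            raise KeyError(f"residue id {residue_id} not present")
        return self.subset(mask)

    def with_residue_off(self, residue_id: int) -> "EnvironmentModel":
        """Copy with the residue's charges zeroed; atoms kept in place."""
        mask = self.residue_ids == residue_id
        if not mask.any():
            raise KeyError(f"residue id {residue_id} not present")
        q = self.charges.copy()
        q[mask] = 0.0
        return replace(self, charges=q)

    @staticmethod
    def empty() -> "EnvironmentModel":
        return EnvironmentModel(
            positions=np.empty((0, 3)),
            charges=np.empty(0),
            residue_ids=np.empty(0, dtype=int),
        )
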