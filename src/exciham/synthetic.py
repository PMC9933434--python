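"""Synthetic chromophore/environment ensembles with analytic oracle targets.

Real training data for the site-energy models comes from excited-state QM
calculations on MD frames.  This module generates a statistical stand-in:

* distorted macrocycle-like heavy-atom geometries (a central metal-like
  atom in a 16-membered C/N ring) with bond/angle jitter plus a collective
  "improper" mode that pushes the central-adjacent nitrogen out of plane,
  emulating the strongly distorted geometries a dihedral scan produces;

* heterogeneous charge environments: spatial residue clusters in a shell
  around the pigment, with optional isotropic polarizabilities;

* analytic targets: a "vacuum excitation energy" that is a smooth
  (linear + saturating-nonlinear) function of the Coulomb-matrix entries
  around 2.1 eV, and an "electrochromic shift" that is an exactly linear
  response to the MM potential through geometry-dependent effective
  charges — zero for an empty environment by construction, exactly the
  constraint the shift model builds into its kernel.

The oracle's realism is statistical (energy ranges, smoothness, response
magnitudes), not chemical.  With the geometry coupling switched off the
shift oracle lies *inside* the linear-kernel model class, so recovery
tests separate "the model can represent the target" from "the optimizer
can find it".  All randomness flows through seeded generators keyed by
(seed, sample index), so targets are reproducible sample-by-sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import K_E
from .descriptors import coulomb_matrix, mm_potential
from .systems import ChromophoreGeometry, EnvironmentModel, register_pigment_type

# Default study conditions (chosen once; see docs/methods.md)
DEFAULT_N_HEAVY = 17
DEFAULT_DISTORTION_SD = 0.05     # Å per-coordinate jitter
IMPROPER_SCALE = 6.0             # out-of-plane mode amplitude = scale * sd
DEFAULT_BASE_ENERGY = 2.10       # eV, center of the vacuum-energy range
DEFAULT_LINEAR_WEIGHT_SD = 4.5e-2  # eV per CM unit
DEFAULT_NONLINEARITY = 0.02      # eV
DEFAULT_VACUUM_NOISE_SD = 2e-3   # eV
DEFAULT_RESPONSE_CHARGE_SD = 5e-3   # e
DEFAULT_GEOMETRY_COUPLING_SD = 4e-4  # e per CM unit
RING_BOND = 1.4                  # Å nominal ring bond length
MIN_PAIR = 0.95                  # Å regeneration guard


def _scaffold(n_heavy: int = DEFAULT_N_HEAVY):
    """Reference geometry: central Mg-like atom plus a planar C/N ring."""
    n_ring = n_heavy - 1
    if n_ring < 3:
        raise ValueError("need at least 4 heavy atoms")
    radius = RING_BOND / (2.0 * np.sin(np.pi / n_ring))
    angles = 2.0 * np.pi * np.arange(n_ring) / n_ring
    ring = np.stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n_ring)], axis=1
    )
    coords = np.vstack([[0.0, 0.0, 0.0], ring])
    elements = ["Mg"] + ["N" if i % 2 == 0 else "C" for i in range(n_ring)]
    names = ["MG"] + [f"{e}{i+1}" for i, e in enumerate(elements[1:])]
    ptype = f"SYN{n_heavy}"
    register_pigment_type(ptype, names)
    return elements, names, coords, ptype


def reference_geometry(n_heavy: int = DEFAULT_N_HEAVY) -> ChromophoreGeometry:
    elements, names, coords, ptype = _scaffold(n_heavy)
    return ChromophoreGeometry(
        elements=elements, atom_names=names, coordinates=coords, pigment_type=ptype
    )


def generate_chromophore_ensemble(
    n: int,
    n_heavy: int = DEFAULT_N_HEAVY,
    distortion_sd: float = DEFAULT_DISTORTION_SD,
    seed: int = 0,
    start_index: int = 0,
) -> list[ChromophoreGeometry]:
    """Distorted copies of the macrocycle scaffold.

    Per-sample: isotropic Gaussian jitter of every coordinate
    (``distortion_sd``) plus an out-of-plane displacement of the first
    ring nitrogen with amplitude uniform in ±IMPROPER_SCALE·sd — the
    improper-like mode.  Geometries with any pair closer than 0.95 Å are
    redrawn.  Deterministic given (seed, sample index).
    """
    elements, names, ref, ptype = _scaffold(n_heavy)
    geoms = []
    for i in range(start_index, start_index + n):
        rng = np.random.default_rng([seed, i, 0])
        for _ in range(200):
            coords = ref + rng.normal(0.0, distortion_sd, ref.shape)
            t = rng.uniform(-1.0, 1.0)
            coords[1, 2] += t * IMPROPER_SCALE * distortion_sd
            d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() > MIN_PAIR:
                break
        else:  # pragma: no cover - only at extreme distortion
            raise RuntimeError("could not generate a non-overlapping geometry")
        geoms.append(
            ChromophoreGeometry(
                elements=elements, atom_names=names, coordinates=coords,
                pigment_type=ptype,
            )
        )
    return geoms


def generate_environment(
    n_residues: int = 40,
    atoms_per_residue: int = 4,
    box_A: float = 25.0,
    charge_sd: float = 0.25,
    alpha_range: tuple[float, float] | None = None,
    seed: int = 0,
    sample_index: int = 0,
    shell_min_A: float = 7.0,
    min_origin_distance_A: float = 5.5,
) -> EnvironmentModel:
    """Residue-clustered point charges in a shell around the pigment.

    Residue centers are drawn in a spherical shell [shell_min_A, box_A];
    atoms scatter around their center (sd 0.8 Å) and are redrawn if they
    come within ``min_origin_distance_A`` of the origin, where the
    chromophore sits.  Each residue receives a net charge ~N(0, charge_sd)
    distributed over its atoms plus a zero-sum intra-residue spread.  With
    ``alpha_range`` set, per-atom polarizabilities are drawn uniformly.
    """
    rng = np.random.default_rng([seed, sample_index, 1])
    min_spacing = 1.2  # Å; keeps polarizable sites clear of the dipole-tensor guard
    positions, charges, rids, rnames = [], [], [], []
    for rid in range(n_residues):
        for _ in range(500):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            center = u * rng.uniform(shell_min_A, box_A)
            atoms = center + rng.normal(0.0, 0.8, (atoms_per_residue, 3))
            if np.linalg.norm(atoms, axis=1).min() <= min_origin_distance_A:
                continue
            d = np.linalg.norm(atoms[:, None] - atoms[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() <= min_spacing:
                continue
            if positions:
                placed = np.vstack(positions)
                from scipy.spatial.distance import cdist

                if cdist(atoms, placed).min() <= min_spacing:
                    continue
            break
        else:  # pragma: no cover
            raise RuntimeError("could not place residue outside the pigment")
        net = rng.normal(0.0, charge_sd)
        eta = rng.normal(0.0, charge_sd, atoms_per_residue)
        eta -= eta.mean()
        q = net / atoms_per_residue + eta
        positions.append(atoms)
        charges.append(q)
        rids.extend([rid] * atoms_per_residue)
        rnames.extend([f"R{rid}"] * atoms_per_residue)
    alpha = None
    if alpha_range is not None:
        alpha = rng.uniform(alpha_range[0], alpha_range[1], n_residues * atoms_per_residue)
    return EnvironmentModel(
        positions=np.vstack(positions),
        charges=np.concatenate(charges),
        residue_ids=np.asarray(rids),
        residue_names=tuple(rnames),
        polarizabilities=alpha,
    )


@dataclass(frozen=True)
class OracleSpec:
    """Parameters of the analytic target functions."""

    cm_ref: np.ndarray
    geometry_weights: np.ndarray        # eV per CM unit, length p
    nonlinearity_weights: np.ndarray    # unit direction in CM space
    response_charges: np.ndarray        # e, per QM atom
    geometry_coupling: np.ndarray       # e per CM unit, (n_atoms, p)
    base_energy: float = DEFAULT_BASE_ENERGY
    nonlinearity_scale: float = DEFAULT_NONLINEARITY
    vacuum_noise_sd: float = DEFAULT_VACUUM_NOISE_SD
    shift_noise_sd: float = 0.0
    cutoff_A: float = 30.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = {}
        for k in (
            "base_energy", "nonlinearity_scale", "vacuum_noise_sd",
            "shift_noise_sd", "cutoff_A", "seed",
        ):
            d[k] = getattr(self, k)
        for k in (
            "cm_ref", "geometry_weights", "nonlinearity_weights",
            "response_charges", "geometry_coupling",
        ):
            d[k] = np.asarray(getattr(self, k)).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OracleSpec":
        kw = dict(d)
        for k in (
            "cm_ref", "geometry_weights", "nonlinearity_weights",
            "response_charges", "geometry_coupling",
        ):
            kw[k] = np.asarray(kw[k], dtype=float)
        return cls(**kw)


def default_oracle_spec(
    n_heavy: int = DEFAULT_N_HEAVY,
    seed: int = 0,
    geometry_coupling_sd: float = DEFAULT_GEOMETRY_COUPLING_SD,
    shift_noise_sd: float = 0.0,
    vacuum_noise_sd: float = DEFAULT_VACUUM_NOISE_SD,
) -> OracleSpec:
    """Draw oracle parameters at the default study scales."""
    ref = reference_geometry(n_heavy)
    cm_ref = coulomb_matrix(ref).values
    p = cm_ref.shape[0]
    n_atoms = ref.n_atoms
    rng = np.random.default_rng([seed, 2])
    w = rng.normal(0.0, DEFAULT_LINEAR_WEIGHT_SD, p) / np.sqrt(p)
    v = rng.normal(size=p)
    v /= np.linalg.norm(v)
    c = rng.normal(0.0, DEFAULT_RESPONSE_CHARGE_SD, n_atoms)
    G = rng.normal(0.0, geometry_coupling_sd, (n_atoms, p)) / np.sqrt(p)
    return OracleSpec(
        cm_ref=cm_ref,
        geometry_weights=w,
        nonlinearity_weights=v,
        response_charges=c,
        geometry_coupling=G,
        vacuum_noise_sd=vacuum_noise_sd,
        shift_noise_sd=shift_noise_sd,
        seed=seed,
    )


def oracle_vacuum_energy(geom: ChromophoreGeometry, spec: OracleSpec,
                         sample_index: int = 0) -> float:
    """Analytic vacuum excitation energy (eV) for one geometry.

    base + ⟨w, ΔCM⟩ + s·tanh(u²) with u the projection of ΔCM on a fixed
    direction, plus Gaussian noise keyed by (seed, sample index).
    """
    dcm = coulomb_matrix(geom).values - spec.cm_ref
    u = float(dcm @ spec.nonlinearity_weights) / np.sqrt(dcm.shape[0])
    e = (
        spec.base_energy
        + float(spec.geometry_weights @ dcm)
        + spec.nonlinearity_scale * np.tanh(u * u)
    )
    if spec.vacuum_noise_sd > 0:
        rng = np.random.default_rng([spec.seed, sample_index, 3])
        e += rng.normal(0.0, spec.vacuum_noise_sd)
    return float(e)


def oracle_shift(geom: ChromophoreGeometry, env: EnvironmentModel,
                 spec: OracleSpec, sample_index: int = 0) -> float:
    """Analytic electrochromic shift (eV): k_e ⟨Φ, c(geom)⟩ (+ noise).

    Effective charges c(geom) = response_charges + G·ΔCM; exactly zero for
    an empty environment (no noise is added in that case either, so the
    zero-at-zero-potential constraint holds for the targets too).
    """
    phi = mm_potential(geom, env, spec.cutoff_A).values
    if not np.any(phi):
        return 0.0
    dcm = coulomb_matrix(geom).values - spec.cm_ref
    c = spec.response_charges + spec.geometry_coupling @ dcm
    s = K_E * float(phi @ c)
    if spec.shift_noise_sd > 0:
        rng = np.random.default_rng([spec.seed, sample_index, 4])
        s += rng.normal(0.0, spec.shift_noise_sd)
    return float(s)


@dataclass
class Bundle:
    """In-memory train/test bundle of geometries, environments and targets."""

    geoms_train: list
    envs_train: list
    geoms_test: list
    envs_test: list
    eps_vac_train: np.ndarray
    eps_vac_test: np.ndarray
    eps_shift_train: np.ndarray
    eps_shift_test: np.ndarray
    spec: OracleSpec
    config: dict = field(default_factory=dict)


def make_bundle(
    n_train: int = 600,
    n_test: int = 200,
    n_heavy: int = DEFAULT_N_HEAVY,
    distortion_sd: float = DEFAULT_DISTORTION_SD,
    n_residues: int = 40,
    atoms_per_residue: int = 4,
    box_A: float = 25.0,
    charge_sd: float = 0.25,
    alpha_range: tuple[float, float] | None = None,
    geometry_coupling_sd: float = DEFAULT_GEOMETRY_COUPLING_SD,
    shift_noise_sd: float = 0.0,
    vacuum_noise_sd: float = DEFAULT_VACUUM_NOISE_SD,
    seed: int = 0,
) -> Bundle:
    """Generate a full synthetic training/test bundle in memory."""
    spec = default_oracle_spec(
        n_heavy=n_heavy,
        seed=seed,
        geometry_coupling_sd=geometry_coupling_sd,
        shift_noise_sd=shift_noise_sd,
        vacuum_noise_sd=vacuum_noise_sd,
    )
    n = n_train + n_test
    geoms = generate_chromophore_ensemble(
        n, n_heavy=n_heavy, distortion_sd=distortion_sd, seed=seed
    )
    envs = [
        generate_environment(
            n_residues=n_residues,
            atoms_per_residue=atoms_per_residue,
            box_A=box_A,
            charge_sd=charge_sd,
            alpha_range=alpha_range,
            seed=seed,
            sample_index=i,
        )
        for i in range(n)
    ]
    eps_vac = np.array(
        [oracle_vacuum_energy(g, spec, i) for i, g in enumerate(geoms)]
    )
    eps_shift = np.array(
        [oracle_shift(g, e, spec, i) for i, (g, e) in enumerate(zip(geoms, envs))]
    )
    config = {
        "n_train": n_train, "n_test": n_test, "n_heavy": n_heavy,
        "distortion_sd": distortion_sd, "n_residues": n_residues,
        "atoms_per_residue": atoms_per_residue, "box_A": box_A,
        "charge_sd": charge_sd, "alpha_range": alpha_range,
        "geometry_coupling_sd": geometry_coupling_sd,
        "shift_noise_sd": shift_noise_sd, "vacuum_noise_sd": vacuum_noise_sd,
        "seed": seed,
    }
    return Bundle(
        geoms_train=geoms[:n_train],
        envs_train=envs[:n_train],
        geoms_test=geoms[n_train:],
        envs_test=envs[n_train:],
        eps_vac_train=eps_vac[:n_train],
        eps_vac_test=eps_vac[n_train:],
        eps_shift_train=eps_shift[:n_train],
        eps_shift_test=eps_shift[n_train:],
        spec=spec,
        config=config,
    )


SCHEMA_VERSION = 1


def make_benchmark_bundle(out_dir, seed: int = 0, **kwargs) -> Bundle:
    """Generate a bundle and write it to disk with a JSON manifest.

    Layout: ``geometries/{split}_{i:05d}.xyz``,
    ``environments/{split}_{i:05d}.csv``, ``targets.csv`` and
    ``manifest.json`` (schema version, generator config, oracle spec and
    file list).  Regeneration with the same seed is bit-identical.
    """
    from . import io as eio

    bundle = make_bundle(seed=seed, **kwargs)
    out = Path(out_dir)
    (out / "geometries").mkdir(parents=True, exist_ok=True)
    (out / "environments").mkdir(parents=True, exist_ok=True)
    rows = []
    files = []
    for split, geoms, envs, yv, ys in (
        ("train", bundle.geoms_train, bundle.envs_train,
         bundle.eps_vac_train, bundle.eps_shift_train),
        ("test", bundle.geoms_test, bundle.envs_test,
         bundle.eps_vac_test, bundle.eps_shift_test),
    ):
        for i, (g, e) in enumerate(zip(geoms, envs)):
            gpath = f"geometries/{split}_{i:05d}.xyz"
            epath = f"environments/{split}_{i:05d}.csv"
            eio.write_geometry(out / gpath, g)
            eio.write_environment(out / epath, e)
            files.extend([gpath, epath])
            rows.append(
                {
                    "sample_id": f"{split}_{i:05d}",
                    "split": split,
                    "eps_vac_ev": repr(float(yv[i])),
                    "eps_shift_ev": repr(float(ys[i])),
                }
            )
    import pandas as pd

    targets = pd.DataFrame(rows)
    targets.to_csv(out / "targets.csv", index=False)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": bundle.config,
        "oracle_spec": bundle.spec.to_dict(),
        "files": files + ["targets.csv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return bundle


def load_bundle(bundle_dir) -> Bundle:
    """Read a bundle written by :func:`make_benchmark_bundle`."""
    from . import io as eio
    import pandas as pd

    out = Path(bundle_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise ValueError("incompatible bundle schema version")
    spec = OracleSpec.from_dict(manifest["oracle_spec"])
    targets = pd.read_csv(out / "targets.csv", float_precision="round_trip")
    data = {"train": ([], [], [], []), "test": ([], [], [], [])}
    for _, row in targets.iterrows():
        split = row["split"]
        geoms, envs, yv, ys = data[split]
        geoms.append(eio.read_geometry(out / f"geometries/{row['sample_id']}.xyz"))
        envs.append(eio.read_environment(out / f"environments/{row['sample_id']}.csv"))
        yv.append(float(row["eps_vac_ev"]))
        ys.append(float(row["eps_shift_ev"]))
    (gt, et, yvt, yst) = data["train"]
    (gs, es, yvs, yss) = data["test"]
    return Bundle(
        geoms_train=gt, envs_train=et, geoms_test=gs, envs_test=es,
        eps_vac_train=np.asarray(yvt), eps_vac_test=np.asarray(yvs),
        eps_shift_train=np.asarray(yst), eps_shift_test=np.asarray(yss),
        spec=spec, config=manifest["config"],
    )
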