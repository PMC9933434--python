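"""File formats: geometries (XYZ/PDB), environment tables, sidecars.

Geometries are stored as XYZ with two extensions that keep descriptors
reproducible: the comment line carries ``pigment_type=...`` and a fifth
column carries the canonical atom name.  Coordinates are written with
full ``repr`` precision, so write → read round-trips are exact.
Environment tables are CSV with columns
``residue_id,residue_name,atom_name,x,y,z,q[,alpha]``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .systems import ChromophoreGeometry, EnvironmentModel


class FormatError(ValueError):
    pass


def write_geometry(path, geom: ChromophoreGeometry) -> None:
    lines = [str(geom.n_atoms), f"pigment_type={geom.pigment_type}"]
    for el, name, (x, y, z) in zip(geom.elements, geom.atom_names, geom.coordinates):
        lines.append(f"{el} {float(x)!r} {float(y)!r} {float(z)!r} {name}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_xyz(path) -> ChromophoreGeometry:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise FormatError(f"{path}: truncated XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(f"{path}: malformed atom-count line") from None
    ptype = "GEN"
    for tok in lines[1].split():
        if tok.startswith("pigment_type="):
            ptype = tok.split("=", 1)[1]
    if len(lines) < 2 + n:
        raise FormatError(f"{path}: expected {n} atom records")
    elements, names, coords = [], [], []
    for i, line in enumerate(lines[2 : 2 + n]):
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: malformed atom record {i}")
        elements.append(parts[0])
        try:
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        except ValueError:
            raise FormatError(f"{path}: non-numeric coordinate in record {i}") from None
        names.append(parts[4] if len(parts) > 4 else f"{parts[0]}{i+1}")
    return ChromophoreGeometry(
        elements=elements, atom_names=names, coordinates=np.asarray(coords),
        pigment_type=ptype,
    )


def _read_pdb(path, pigment_type: str | None = None) -> ChromophoreGeometry:
    """Read one residue's atoms from a PDB file (first residue by default)."""
    import gemmi

    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    for model in st:
        for chain in model:
            for res in chain:
                elements = [a.element.name for a in res]
                names = [a.name for a in res]
                coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res])
                geom = ChromophoreGeometry(
                    elements=elements,
                    atom_names=names,
                    coordinates=coords,
                    pigment_type=pigment_type or res.name,
                )
                return geom.canonicalized()
    raise FormatError(f"{path}: no atoms found")


def read_geometry(path, format: str | None = None, pigment_type: str | None = None) -> ChromophoreGeometry:
    """Read a chromophore geometry from XYZ or PDB (by extension)."""
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "pdb":
        return _read_pdb(path, pigment_type)
    raise FormatError(f"unknown geometry format {fmt!r}")


def write_environment(path, env: EnvironmentModel) -> None:
    names = env.residue_names or tuple(f"R{r}" for r in env.residue_ids)
    data = {
        "residue_id": env.residue_ids,
        "residue_name": list(names),
        "atom_name": [f"A{i}" for i in range(env.n_atoms)],
        "x": [repr(float(v)) for v in env.positions[:, 0]],
        "y": [repr(float(v)) for v in env.positions[:, 1]],
        "z": [repr(float(v)) for v in env.positions[:, 2]],
        "q": [repr(float(v)) for v in env.charges],
    }
    if env.polarizabilities is not None:
        data["alpha"] = [repr(float(v)) for v in env.polarizabilities]
    pd.DataFrame(data).to_csv(path, index=False)


def read_environment(path) -> EnvironmentModel:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"residue_id", "x", "y", "z", "q"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    return EnvironmentModel(
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        charges=df["q"].to_numpy(dtype=float),
        residue_ids=df["residue_id"].to_numpy(dtype=int),
        residue_names=tuple(df["residue_name"].astype(str))
        if "residue_name" in df
        else (),
        polarizabilities=df["alpha"].to_numpy(dtype=float) if "alpha" in df else None,
    )


def read_transition_charges(path) -> np.ndarray:
    """CSV (atom_name, q_tr) → charge vector in file order."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "q_tr" not in df.columns:
        raise FormatError(f"{path}: expected a q_tr column")
    return df["q_tr"].to_numpy(dtype=float)


def write_transition_charges(path, atom_names, charges) -> None:
    pd.DataFrame(
        {"atom_name": list(atom_names), "q_tr": [repr(float(q)) for q in charges]}
    ).to_csv(path, index=False)


def write_hamiltonian(path, ham) -> None:
    """Plain-text matrix (eV) plus a JSON sidecar with labels/provenance."""
    import json

    path = Path(path)
    np.savetxt(path, ham.matrix, fmt="%.12e", header="exciton Hamiltonian (eV)")
    sidecar = {
        "site_labels": list(ham.site_labels),
        "units": "eV",
        "provenance": ham.provenance,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_hamiltonian(path):
    import json

    from .exciton import ExcitonHamiltonian

    path = Path(path)
    matrix = np.atleast_2d(np.loadtxt(path))
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ExcitonHamiltonian(
        matrix=matrix,
        site_labels=tuple(sidecar["site_labels"]),
        provenance=sidecar.get("provenance", {}),
    )
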