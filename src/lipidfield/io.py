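"""Readers and writers for the package's on-disk formats.

Formats are deliberately plain: PDB for structures (with a tab-separated
sidecar for partial charges, since the PDB format has no full-precision
charge column), TSV for density grids, profile parameter tables, scales,
landscapes and per-atom reports, FASTA for sequences, and JSON/YAML for
configuration and reports.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .chemistry import assign_atom_params
from .constants import DEFAULT_REFERENCE_DEPTH, THREE_TO_ONE, ONE_TO_THREE
from .potential import ChargeDensityGrid, LipidProfileParams
from .structure import Structure

_PROFILE_COLUMNS = ["lipid_name", "A1", "A2", "A3", "A4",
                    "C1", "C2", "C3", "C4", "C5",
                    "z_c", "has_salt", "reference_depth"]


# ---------------------------------------------------------------- structures

def read_structure(path, charge_table=None, center: bool = False) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Coordinates are interpreted in the membrane frame (z = membrane normal,
    bilayer center at z = 0), i.e. the file is assumed pre-oriented as in
    the OPM database; pass ``center=True`` to re-center the centroid at the
    origin.  Charges and transfer types come from ``charge_table`` (a TSV
    sidecar written by :func:`write_structure`) or, failing that, from the
    embedded per-residue parameter table.

    Non-standard residues are rejected with a clear message.
    """
    st = gemmi.read_pdb(str(path))
    names, elements, res_index, coords, charges, ttypes = [], [], [], [], [], []
    sequence = []
    sidecar = None
    if charge_table is not None:
        sidecar = pd.read_csv(charge_table, sep="\t", comment="#")
        sidecar = sidecar.set_index("atom_index")
    atom_i = 0
    for model in st:
        for chain in model:
            for res in chain:
                if res.name not in THREE_TO_ONE:
                    raise ValueError(
                        f"non-standard residue {res.name!r}; only the 20 "
                        "canonical amino acids are supported"
                    )
                code = THREE_TO_ONE[res.name]
                ri = len(sequence)
                sequence.append(code)
                for atom in res:
                    if atom.element.name == "H":
                        continue
                    names.append(atom.name)
                    elements.append(atom.element.name)
                    res_index.append(ri)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    if sidecar is not None and atom_i in sidecar.index:
                        row = sidecar.loc[atom_i]
                        charges.append(float(row["charge"]))
                        ttypes.append(str(row["ttype"]))
                    else:
                        q, tt = assign_atom_params(code, atom.name)
                        charges.append(q)
                        ttypes.append(tt)
                    atom_i += 1
        break  # first model only
    coords = np.asarray(coords, dtype=float)
    if center:
        coords = coords - coords.mean(axis=0)
    return Structure(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        res_index=np.array(res_index),
        sequence="".join(sequence),
        coords=coords,
        charges=np.array(charges),
        atom_types=np.array(ttypes, dtype=object),
    )


def write_structure(structure: Structure, path, charge_table=None) -> None:
    """Write a Structure as PDB, optionally with a charge sidecar TSV."""
    st = gemmi.Structure()
    st.name = "lipidfield"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for ri in range(structure.n_residues):
        res = gemmi.Residue()
        res.name = ONE_TO_THREE[structure.sequence[ri]]
        res.seqid = gemmi.SeqId(ri + 1, " ")
        for ai in structure.residue_atom_indices(ri):
            atom = gemmi.Atom()
            atom.name = str(structure.atom_names[ai])
            atom.element = gemmi.Element(str(structure.elements[ai]))
            x, y, z = structure.coords[ai]
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    if charge_table is not None:
        rows = [
            {"atom_index": i,
             "residue": int(structure.res_index[i]),
             "atom": structure.atom_names[i],
             "charge": structure.charges[i],
             "ttype": structure.atom_types[i]}
            for i in range(structure.n_atoms)
        ]
        pd.DataFrame(rows).to_csv(charge_table, sep="\t", index=False)


# -------------------------------------------------------------- density grids

def write_density_grid_tsv(grid: ChargeDensityGrid, path) -> None:
    """Voxel-list TSV: a small header then one row per voxel."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# dims\t{grid.dims[0]}\t{grid.dims[1]}\t{grid.dims[2]}\n")
        fh.write(f"# spacing\t{grid.spacing[0]:.6g}\t{grid.spacing[1]:.6g}"
                 f"\t{grid.spacing[2]:.6g}\n")
        fh.write("ix\tiy\tiz\trho_lipid\trho_water\trho_salt\n")
        nx, ny, nz = grid.dims
        ix, iy, iz = np.unravel_index(np.arange(nx * ny * nz), grid.dims)
        cols = np.column_stack([
            ix, iy, iz,
            grid.density_lipid.ravel(),
            grid.density_water.ravel(),
            grid.density_salt.ravel(),
        ])
        np.savetxt(fh, cols, fmt=["%d", "%d", "%d", "%.10e", "%.10e", "%.10e"],
                   delimiter="\t")


def read_density_grid_tsv(path) -> ChargeDensityGrid:
    path = Path(path)
    with path.open() as fh:
        dims = tuple(int(v) for v in fh.readline().split("\t")[1:4])
        spacing = tuple(float(v) for v in fh.readline().split("\t")[1:4])
    tab = pd.read_csv(path, sep="\t", skiprows=2)
    arrays = {}
    for col in ("rho_lipid", "rho_water", "rho_salt"):
        arr = np.zeros(dims)
        arr[tab["ix"], tab["iy"], tab["iz"]] = tab[col]
        arrays[col] = arr
    return ChargeDensityGrid(dims, spacing, arrays["rho_lipid"],
                             arrays["rho_water"], arrays["rho_salt"])


_GRID_MAGIC = "LIPIDFIELD-GRID v1"


def write_density_grid_binary(grid: ChargeDensityGrid, path) -> None:
    """Compact grid format: a 4-line text header, then the three density
    arrays as consecutive little-endian float64 blocks in C order
    (lipid, water, salt)."""
    path = Path(path)
    header = (
        f"{_GRID_MAGIC}\n"
        f"dims {grid.dims[0]} {grid.dims[1]} {grid.dims[2]}\n"
        f"spacing {grid.spacing[0]:.17g} {grid.spacing[1]:.17g} "
        f"{grid.spacing[2]:.17g}\n"
        "arrays rho_lipid rho_water rho_salt float64 little-endian\n"
    )
    with path.open("wb") as fh:
        fh.write(header.encode())
        for arr in (grid.density_lipid, grid.density_water, grid.density_salt):
            fh.write(np.ascontiguousarray(arr, dtype="<f8").tobytes())


def read_density_grid_binary(path) -> ChargeDensityGrid:
    with Path(path).open("rb") as fh:
        lines = [fh.readline().decode().rstrip("\n") for _ in range(4)]
        if lines[0] != _GRID_MAGIC:
            raise ValueError(f"not a {_GRID_MAGIC} file")
        dims = tuple(int(v) for v in lines[1].split()[1:4])
        spacing = tuple(float(v) for v in lines[2].split()[1:4])
        n = int(np.prod(dims))
        arrays = []
        for _ in range(3):
            buf = fh.read(8 * n)
            if len(buf) != 8 * n:
                raise ValueError("truncated grid file")
            arrays.append(np.frombuffer(buf, dtype="<f8").reshape(dims).copy())
    return ChargeDensityGrid(dims, spacing, *arrays)


# ------------------------------------------------------------ profile tables

def write_profile_table(params_list, path, header_comment: str = "") -> None:
    rows = [{c: getattr(p, c) for c in _PROFILE_COLUMNS} for p in params_list]
    path = Path(path)
    with path.open("w") as fh:
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(
            fh, sep="\t", index=False)


def read_profile_table(path) -> dict[str, LipidProfileParams]:
    tab = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_PROFILE_COLUMNS) - set(tab.columns)
    if missing:
        raise ValueError(f"profile table lacks columns {sorted(missing)}")
    out = {}
    for row in tab.itertuples():
        out[row.lipid_name] = LipidProfileParams(
            lipid_name=row.lipid_name,
            A1=row.A1, A2=row.A2, A3=row.A3, A4=row.A4,
            C1=row.C1, C2=row.C2, C3=row.C3, C4=row.C4, C5=row.C5,
            z_c=row.z_c, has_salt=bool(row.has_salt),
            reference_depth=float(row.reference_depth),
        )
    return out


def load_default_profiles() -> dict[str, LipidProfileParams]:
    """The shipped lipid profile table (synthetic placeholder parameters;
    replace with production fit values where available)."""
    from importlib import resources

    with resources.as_file(
        resources.files("lipidfield.data").joinpath("lipid_profiles.tsv")
    ) as p:
        return read_profile_table(p)


# ----------------------------------------------------------------- landscapes

def write_landscape(landscape, path, argmin_json=None) -> None:
    recs = landscape.to_records()
    with Path(path).open("w") as fh:
        fh.write("depth\ttilt\trotation\tenergy\n")
        np.savetxt(fh, recs, fmt="%.6g", delimiter="\t")
    if argmin_json is not None:
        d, t, r, e = landscape.argmin()
        Path(argmin_json).write_text(json.dumps(
            {"depth": d, "tilt": t, "rotation": r, "energy": e}, indent=2))


# ------------------------------------------------------------- atom reports

def write_hydration_report(structure: Structure, path, geometry=None) -> None:
    """Per-atom hydration table: index, residue, z, f_hyd, f_pore, region."""
    from .frame import MembraneGeometry, classify_region, hydration_fraction

    geometry = geometry or MembraneGeometry()
    z = structure.coords[:, 2]
    f_hyd = hydration_fraction(z, geometry, structure.f_pore)
    rows = [
        {"atom_index": i,
         "residue": structure.sequence[structure.res_index[i]],
         "z": z[i],
         "f_hyd": f_hyd[i],
         "f_pore": structure.f_pore[i],
         "region": classify_region(float(f_hyd[i]), float(structure.f_pore[i]))}
        for i in range(structure.n_atoms)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4f")


# -------------------------------------------------------------------- fasta

def read_fasta(path) -> dict[str, str]:
    from biotite.sequence.io.fasta import FastaFile

    return dict(FastaFile.read(str(path)).items())


def write_fasta(records: dict[str, str], path) -> None:
    from biotite.sequence.io.fasta import FastaFile

    ff = FastaFile()
    for name, seq in records.items():
        ff[name] = seq
    ff.write(str(path))


def read_sequence_pairs(native_path, designed_path):
    """Pair FASTA records by order (or by matching _nat/_des ID stems)."""
    nat = read_fasta(native_path)
    des = read_fasta(designed_path)
    nat_keys, des_keys = list(nat), list(des)
    stems_nat = {k.removesuffix("_nat"): k for k in nat_keys}
    stems_des = {k.removesuffix("_des"): k for k in des_keys}
    if set(stems_nat) == set(stems_des):
        return [(nat[stems_nat[s]], des[stems_des[s]]) for s in stems_nat]
    if len(nat_keys) != len(des_keys):
        raise ValueError("native and designed FASTA differ in record count")
    return [(nat[a], des[b]) for a, b in zip(nat_keys, des_keys)]


# -------------------------------------------------------------------- config

@dataclasses.dataclass
class Config:
    """Run configuration with the printed model constants as defaults."""

    lipid: str = "DLPC"
    half_thickness: float = 15.0
    steepness: float = 10.0
    w_wl: float = 1.0
    w_lipid: float = 0.128
    w_dielec: float = 0.01
    eps_core_sol: float = 6.0
    eps_surf_sol: float = 80.0
    eps_core_mem: float = 3.0
    eps_surf_mem: float = 10.0
    sigmoid_steepness: float = 1.2
    r_max: float = 5.5
    depth_step: float = 2.0
    tilt_step: float = 5.0
    rot_step: float = 15.0
    reference_depth: float = DEFAULT_REFERENCE_DEPTH
    charge_table: str | None = None
    log_level: str = "INFO"

    @classmethod
    def load(cls, path) -> "Config":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text)) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def dump(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
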