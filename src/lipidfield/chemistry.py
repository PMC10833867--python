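"""Embedded chemical parameter tables and atom-parameter assignment.

The package ships a compact fixed-charge set (hydrogens collapsed onto
heavy atoms) and a transfer-type vocabulary for the 20 canonical amino
acids, plus the side-chain hydrophobicity scale table.  Both are plain TSV
files under ``lipidfield/data`` and can be overridden by user-supplied
tables of the same schema.
"""

from __future__ import annotations

import functools
import warnings
from importlib import resources

import numpy as np
import pandas as pd

from .constants import AA20, ASP_DEPROT, GLU_DEPROT
from .transfer import AAScale, StoichiometryMatrix, stoichiometry_from_atom_types


def _data_path(name: str):
    return resources.files("lipidfield.data").joinpath(name)


@functools.lru_cache(maxsize=None)
def load_atom_params(path=None) -> pd.DataFrame:
    """Atom parameter table: columns aa, atom, ttype, charge."""
    src = path if path is not None else _data_path("atom_params.tsv")
    with resources.as_file(src) if path is None else _nullcontext(src) as p:
        tab = pd.read_csv(p, sep="\t", comment="#")
    expected = {"aa", "atom", "ttype", "charge"}
    if set(tab.columns) != expected:
        raise ValueError(f"atom parameter table must have columns {sorted(expected)}")
    return tab


class _nullcontext:
    def __init__(self, v):
        self.v = v

    def __enter__(self):
        return self.v

    def __exit__(self, *a):
        return False


@functools.lru_cache(maxsize=None)
def _atom_param_index(path=None) -> dict[tuple[str, str], tuple[float, str]]:
    tab = load_atom_params(path)
    return {
        (row.aa, row.atom): (float(row.charge), str(row.ttype))
        for row in tab.itertuples()
    }


def assign_atom_params(aa_code: str, atom_name: str, path=None) -> tuple[float, str]:
    """Charge and transfer type for one atom; best-effort for unknown atoms.

    Unknown atoms get charge 0 and an element-based generic type, with a
    warning, so slightly non-standard structures remain scorable.
    """
    idx = _atom_param_index(path)
    key = (aa_code, atom_name)
    if key in idx:
        return idx[key]
    if atom_name == "OXT":  # C-terminal carboxylate oxygen
        return 0.0, "OOC"
    warnings.warn(
        f"no parameters for atom {atom_name!r} in residue {aa_code!r}; "
        "assigning zero charge and a generic type",
        stacklevel=2,
    )
    element = atom_name.strip("0123456789")[:1] or "C"
    return 0.0, {"C": "CH2", "N": "Namide", "O": "Oamide", "S": "S"}.get(element, "CH2")


def atom_types_by_aa(path=None) -> dict[str, list[str]]:
    tab = load_atom_params(path)
    return {aa: grp["ttype"].tolist() for aa, grp in tab.groupby("aa")}


def default_stoichiometry(include_deprotonated: bool = False) -> StoichiometryMatrix:
    """Stoichiometry matrix counted from the embedded atom-type table.

    With ``include_deprotonated`` the deprotonated Asp/Glu codes are
    appended as extra rows with the same atom stoichiometry as Asp/Glu
    (the chemistry is identical; only the target transfer energy differs).
    """
    types = atom_types_by_aa()
    A = stoichiometry_from_atom_types({aa: types[aa] for aa in AA20})
    if include_deprotonated:
        extra = A.table.loc[["D", "E"]].copy()
        extra.index = [ASP_DEPROT, GLU_DEPROT]
        A = A.appended(extra)
    return A


@functools.lru_cache(maxsize=None)
def load_reference_scales() -> tuple[AAScale, AAScale, dict[str, float]]:
    """(MF scale, WW scale, WW values for the deprotonated Asp/Glu codes)."""
    with resources.as_file(_data_path("aa_scales.tsv")) as p:
        tab = pd.read_csv(p, sep="\t", comment="#").set_index("code")
    canon = tab.loc[list(AA20)]
    mf = AAScale(canon["mf"].astype(float).to_dict(), label="MF")
    ww = AAScale(canon["ww"].astype(float).to_dict(), label="WW")
    charged = {
        code: float(tab.loc[code, "ww"])
        for code in (ASP_DEPROT, GLU_DEPROT)
        if code in tab.index and np.isfinite(float(tab.loc[code, "ww"]))
    }
    return mf, ww, charged
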