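"""Water-to-bilayer transfer-energy scales.

Holds side-chain hydrophobicity scales (kcal/mol), the linear fit between a
bilayer-context scale (Moon–Fleming type, "MF") and a water-to-octanol scale
(Wimley–White type, "WW"), extrapolation of the deprotonated neutral-pH
Asp/Glu transfer energies from that fit, and the stoichiometry regression
that distributes per-amino-acid energies onto per-atom-type energies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import AA20, ASP_DEPROT, GLU_DEPROT


@dataclass
class AAScale:
    """Per-amino-acid transfer energies ΔG_w,l in kcal/mol.

    ``values`` maps one-letter codes (20 canonical, plus optionally the
    deprotonated-carboxylate codes 'D1'/'E1') to energies.  ``label`` names
    the provenance of the scale ('MF', 'WW', or 'derived').
    """

    values: dict[str, float]
    label: str = "derived"

    def __post_init__(self):
        self.values = {str(k): float(v) for k, v in self.values.items()}
        if self.label not in ("MF", "WW", "derived"):
            raise ValueError(f"unknown scale label {self.label!r}")
        if self.label in ("MF", "WW"):
            extra = {ASP_DEPROT, GLU_DEPROT} & set(self.values)
            if extra:
                raise ValueError(
                    f"{sorted(extra)} belong only to derived/extended scales, "
                    f"not a measured {self.label} scale"
                )

    def __getitem__(self, code: str) -> float:
        return self.values[code]

    def __contains__(self, code: str) -> bool:
        return code in self.values

    def codes(self) -> list[str]:
        return list(self.values)

    def extended(self, extra: dict[str, float]) -> "AAScale":
        """Return a derived copy with extra codes (e.g. D1/E1) added."""
        merged = dict(self.values)
        merged.update(extra)
        return AAScale(merged, label="derived")


@dataclass
class LinearFit:
    """Ordinary least-squares line y = slope·x + intercept with r²."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r² must lie in [0, 1], got {self.r_squared}")

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class StoichiometryMatrix:
    """Counts of each atom type per amino acid.

    Wraps a DataFrame whose index is amino-acid codes and whose columns are
    atom-type labels; entries are non-negative integer counts.
    """

    table: pd.DataFrame

    def __post_init__(self):
        tab = pd.DataFrame(self.table).fillna(0).astype(int)
        if tab.empty:
            raise ValueError("stoichiometry matrix is empty")
        if (tab.to_numpy() < 0).any():
            raise ValueError("stoichiometry counts must be non-negative")
        if (tab.sum(axis=1) == 0).any():
            empty = tab.index[tab.sum(axis=1) == 0].tolist()
            raise ValueError(f"amino acids with no atoms: {empty}")
        self.table = tab

    @property
    def aa_codes(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def atom_types(self) -> list[str]:
        return self.table.columns.tolist()

    def appended(self, rows: pd.DataFrame) -> "StoichiometryMatrix":
        """Append extra amino-acid rows (e.g. D1/E1) with aligned columns."""
        rows = pd.DataFrame(rows).reindex(columns=self.table.columns, fill_value=0)
        return StoichiometryMatrix(pd.concat([self.table, rows]))


@dataclass
class AtomScale:
    """Per-atom-type transfer energies ΔG_w,l in kcal/mol."""

    values: dict[str, float]
    provenance: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.values = {str(k): float(v) for k, v in self.values.items()}

    def __getitem__(self, atom_type: str) -> float:
        return self.values[atom_type]

    def __contains__(self, atom_type: str) -> bool:
        return atom_type in self.values


def fit_mf_vs_ww(mf: AAScale, ww: AAScale, excluded: set[str] = frozenset()) -> LinearFit:
    """OLS fit of the bilayer-context (MF) scale on the octanol (WW) scale.

    Only codes present in both scales and not in ``excluded`` enter the fit.
    Typical exclusions are the host residue of the mutagenesis experiment
    and residues measured at a non-physiological pH (Asp, Glu).
    """
    shared = [c for c in mf.codes() if c in ww and c not in excluded]
    if len(shared) < 3:
        raise ValueError(
            f"need at least 3 shared non-excluded codes, have {len(shared)}"
        )
    x = np.array([ww[c] for c in shared])
    y = np.array([mf[c] for c in shared])
    res = stats.linregress(x, y)
    return LinearFit(float(res.slope), float(res.intercept), float(res.rvalue**2))


def extrapolate_charged(fit: LinearFit, ww_value: float) -> float:
    """Map a WW transfer energy onto the MF scale through the fitted line.

    Used for the deprotonated Asp/Glu side chains, whose bilayer-context
    energies cannot be measured directly near their pKa.
    """
    return float(fit.predict(ww_value))


def solve_atom_transfer(A: StoichiometryMatrix, g_aa: AAScale) -> AtomScale:
    """Least-squares solve of  A · ΔG_atom = ΔG_aa  for per-atom-type energies.

    Rows of ``A`` are matched to ``g_aa`` by amino-acid code; every row code
    must be present in the scale.  For a rank-deficient system the
    minimum-norm solution is returned with a warning.
    """
    codes = A.aa_codes
    missing = [c for c in codes if c not in g_aa]
    if missing:
        raise KeyError(f"scale lacks values for stoichiometry rows: {missing}")
    mat = A.table.to_numpy(dtype=float)
    g = np.array([g_aa[c] for c in codes])
    x, _, rank, _ = np.linalg.lstsq(mat, g, rcond=None)
    if rank < mat.shape[1]:
        warnings.warn(
            f"stoichiometry matrix has column rank {rank} < {mat.shape[1]}; "
            "returning the minimum-norm least-squares solution",
            stacklevel=2,
        )
    residual = g - mat @ x
    return AtomScale(
        dict(zip(A.atom_types, x)),
        provenance={
            "aa_codes": codes,
            "residual": residual,
            "residual_norm": float(np.linalg.norm(residual)),
            "rank": int(rank),
        },
    )


def compose_aa_energy(A: StoichiometryMatrix, atom: AtomScale) -> AAScale:
    """Recompose per-amino-acid energies as the matrix–vector product A·x."""
    missing = [t for t in A.atom_types if t not in atom]
    if missing:
        raise KeyError(f"atom scale lacks types: {missing}")
    x = np.array([atom[t] for t in A.atom_types])
    vals = A.table.to_numpy(dtype=float) @ x
    return AAScale(dict(zip(A.aa_codes, vals)), label="derived")


def extend_scale_neutral_ph(
    mf: AAScale,
    ww: AAScale,
    ww_charged: dict[str, float],
    excluded: set[str] = frozenset({"A", "P", "D", "E"}),
) -> tuple[AAScale, LinearFit]:
    """Derive the neutral-pH extended scale.

    Fits MF on WW over the non-excluded canonical residues, extrapolates the
    deprotonated Asp/Glu codes from their WW octanol values, and returns the
    extended scale together with the fit.  The default exclusions drop the
    Ala host residue, Pro, and the low-pH Asp/Glu measurements.
    """
    fit = fit_mf_vs_ww(mf, ww, excluded=excluded)
    extra = {code: extrapolate_charged(fit, wwv) for code, wwv in ww_charged.items()}
    return mf.extended(extra), fit


def stoichiometry_from_atom_types(atom_types_by_aa: dict[str, list[str]]) -> StoichiometryMatrix:
    """Build the stoichiometry matrix by counting atom-type labels per residue."""
    counts = {aa: pd.Series(types).value_counts()
              for aa, types in atom_types_by_aa.items()}
    tab = pd.DataFrame(counts).T.fillna(0).astype(int)
    order = [c for c in AA20 if c in tab.index] + \
        [c for c in tab.index if c not in AA20]
    return StoichiometryMatrix(tab.loc[order].sort_index(axis=1))
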