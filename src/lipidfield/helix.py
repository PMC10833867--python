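"""Ideal α-helix construction from sequence.

Backbones are generated atom-by-atom (natural extension reference frame)
with the helical dihedrals φ = −57°, ψ = −47°, ω = 180° and standard bond
lengths/angles.  Side chains are grafted from ideal residue templates
(biotite's chemical-component dictionary coordinates, default conformer),
superimposed on each residue's N/CA/C frame — a fixed-rotamer
simplification, with no packing.  The finished helix is placed in canonical
membrane coordinates: principal axis along +z, centroid at the origin.
"""

from __future__ import annotations

import functools

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info

from .chemistry import assign_atom_params
from .constants import ONE_TO_THREE
from .structure import Structure

# Engh–Huber-style backbone geometry (Å, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
ANG_N_CA_C, ANG_CA_C_N, ANG_C_N_CA, ANG_CA_C_O = 111.2, 116.2, 121.7, 120.5
PHI_HELIX, PSI_HELIX, OMEGA = -57.0, -47.0, 180.0


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """Place atom D given three predecessors and internal coordinates."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _kabsch(mobile, target):
    """Rotation + translation mapping ``mobile`` onto ``target`` (3 points)."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, tc - R @ mc


@functools.lru_cache(maxsize=32)
def _sidechain_template(three: str):
    """Heavy side-chain atoms of the ideal residue, with its N/CA/C frame."""
    res = struc_info.residue(three)
    res = res[res.element != "H"]
    frame = np.stack([res.coord[res.atom_name == a][0] for a in ("N", "CA", "C")])
    side = res[~np.isin(res.atom_name, ("N", "CA", "C", "O", "OXT"))]
    return frame, tuple(side.atom_name), tuple(side.element), side.coord.copy()


def build_ideal_helix(
    sequence: str,
    charged_ends: bool = True,
    phi: float = PHI_HELIX,
    psi: float = PSI_HELIX,
) -> Structure:
    """Build an ideal α-helix for a one-letter-code sequence.

    Parameters
    ----------
    sequence
        Canonical one-letter codes, length ≥ 3 (shorter peptides have no
        meaningful principal axis).
    charged_ends
        Add +1 e to the N-terminal backbone nitrogen and −1 e to the
        C-terminal carbonyl oxygen, emulating free charged termini.
    phi, psi
        Backbone dihedrals in degrees; defaults are the ideal helix values.

    Returns
    -------
    Structure in canonical membrane coordinates (axis = +z, centroid = 0).
    """
    sequence = str(sequence).upper()
    if len(sequence) < 3:
        raise ValueError("sequence must contain at least 3 residues")
    unknown = [c for c in sequence if c not in ONE_TO_THREE]
    if unknown:
        raise ValueError(f"unknown residue codes: {sorted(set(unknown))}")

    n_res = len(sequence)
    bb = np.zeros((n_res, 3, 3))  # (residue, [N, CA, C], xyz)
    ang = np.deg2rad(ANG_N_CA_C)
    bb[0, 0] = (0.0, 0.0, 0.0)
    bb[0, 1] = (B_N_CA, 0.0, 0.0)
    bb[0, 2] = bb[0, 1] + (
        -B_CA_C * np.cos(ang),
        B_CA_C * np.sin(ang),
        0.0,
    )
    for i in range(1, n_res):
        pN, pCA, pC = bb[i - 1]
        N = _place_atom(pN, pCA, pC, B_C_N, ANG_CA_C_N, psi)
        CA = _place_atom(pCA, pC, N, B_N_CA, ANG_C_N_CA, OMEGA)
        C = _place_atom(pC, N, CA, B_CA_C, ANG_N_CA_C, phi)
        bb[i] = (N, CA, C)

    names, elements, res_index, coords = [], [], [], []
    for i, code in enumerate(sequence):
        N, CA, C = bb[i]
        # carbonyl O trans to the following amide nitrogen
        o_dih = (psi + 180.0) if i < n_res - 1 else (psi + 180.0)
        O = _place_atom(N, CA, C, B_C_O, ANG_CA_C_O, o_dih)
        for nm, el, xyz in (("N", "N", N), ("CA", "C", CA), ("C", "C", C), ("O", "O", O)):
            names.append(nm)
            elements.append(el)
            res_index.append(i)
            coords.append(xyz)
        frame, s_names, s_elements, s_coords = _sidechain_template(ONE_TO_THREE[code])
        if len(s_names):
            R, t = _kabsch(frame, np.stack([N, CA, C]))
            placed = s_coords @ R.T + t
            for nm, el, xyz in zip(s_names, s_elements, placed):
                names.append(nm)
                elements.append(el)
                res_index.append(i)
                coords.append(xyz)

    charges, ttypes = [], []
    for nm, ri in zip(names, res_index):
        q, tt = assign_atom_params(sequence[ri], nm)
        charges.append(q)
        ttypes.append(tt)
    if charged_ends:
        idx_arr = np.asarray(res_index)
        names_arr = np.asarray(names, dtype=object)
        first_n = int(np.nonzero((idx_arr == 0) & (names_arr == "N"))[0][0])
        last_o = int(np.nonzero((idx_arr == n_res - 1) & (names_arr == "O"))[0][0])
        charges[first_n] += 1.0
        charges[last_o] -= 1.0

    st = Structure(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        res_index=np.array(res_index),
        sequence=sequence,
        coords=np.array(coords),
        charges=np.array(charges),
        atom_types=np.array(ttypes, dtype=object),
    )
    canonical = st.canonical_coords()
    st = st.with_coords(canonical, (0.0, 0.0, 0.0))
    st._canonical = canonical
    return st


def walp_sequence(n: int) -> str:
    """WALP pattern GWW(LA)ₙLWWA."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    return "GWW" + "LA" * n + "LWWA"


def polyalanine_sequence(x: int) -> str:
    if x < 3:
        raise ValueError("polyalanine length must be ≥ 3")
    return "A" * x


def polyleucine_sequence(x: int, flank_trp: bool = False) -> str:
    """Designed poly-Leu insertion peptides: G Lx R Lx G, optionally with a
    flanking Trp (G W L₆ R L₇ G pattern when ``flank_trp``)."""
    if flank_trp:
        return "GW" + "L" * x + "R" + "L" * (x + 1) + "G"
    if x < 1:
        raise ValueError("x must be ≥ 1")
    return "G" + "L" * x + "R" + "L" * x + "G"
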