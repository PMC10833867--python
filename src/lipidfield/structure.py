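"""Atomic structure container with a rigid membrane-frame transform.

Atoms are stored in flat numpy arrays, grouped contiguously by residue.
Coordinates are always expressed in the membrane frame (normal = +z,
bilayer center at z = 0).  A structure additionally remembers *canonical*
coordinates — principal axis aligned with +z, centroid at the origin —
from which any (depth, tilt, rotation) placement is generated as a pure
rigid motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Structure:
    """Ordered atoms with charges, transfer types and a rigid transform.

    Attributes
    ----------
    atom_names, elements : (n_atoms,) object arrays
    res_index : (n_atoms,) int array, 0-based residue index per atom
    sequence : one-letter amino-acid code per residue
    coords : (n_atoms, 3) float array, Å, membrane frame
    charges : (n_atoms,) partial charges in e
    atom_types : (n_atoms,) transfer-type labels
    f_pore : (n_atoms,) pore exposure fractions (default all zero)
    transform : (depth Å, tilt °, rotation °) realized by the current coords
    """

    atom_names: np.ndarray
    elements: np.ndarray
    res_index: np.ndarray
    sequence: str
    coords: np.ndarray
    charges: np.ndarray
    atom_types: np.ndarray
    f_pore: np.ndarray | None = None
    transform: tuple[float, float, float] = (0.0, 0.0, 0.0)
    _canonical: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.res_index = np.asarray(self.res_index, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        self.atom_types = np.asarray(self.atom_types, dtype=object)
        n = self.coords.shape[0]
        for name in ("atom_names", "elements", "res_index", "charges", "atom_types"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length mismatch with coords ({n} atoms)")
        if self.f_pore is None:
            self.f_pore = np.zeros(n)
        self.f_pore = np.clip(np.asarray(self.f_pore, dtype=float), 0.0, 1.0)
        if np.any(np.diff(self.res_index) < 0):
            raise ValueError("atoms must be grouped contiguously by residue")
        if self.n_residues != len(self.sequence):
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match "
                f"{self.n_residues} residues"
            )

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return int(self.res_index.max()) + 1 if self.n_atoms else 0

    @property
    def residue_codes_per_atom(self) -> np.ndarray:
        return np.array([self.sequence[i] for i in self.res_index], dtype=object)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def principal_axis(self) -> np.ndarray:
        """Unit principal axis of the CA trace (all atoms if no CA present).

        Oriented to point from the N- toward the C-terminus, so tilt angles
        are well defined.
        """
        mask = self.atom_names == "CA"
        pts = self.coords[mask] if mask.sum() >= 2 else self.coords
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        if (pts[-1] - pts[0]) @ axis < 0:
            axis = -axis
        return axis / np.linalg.norm(axis)

    def canonical_coords(self) -> np.ndarray:
        """Coordinates with the principal axis along +z, centroid at origin."""
        if self._canonical is not None:
            return self._canonical
        axis = self.principal_axis()
        R = _rotation_onto_z(axis)
        self._canonical = (self.coords - self.centroid()) @ R.T
        return self._canonical

    def with_coords(self, coords: np.ndarray,
                    transform: tuple[float, float, float]) -> "Structure":
        new = replace(self, coords=coords, transform=transform)
        new._canonical = self._canonical
        return new

    def residue_atom_indices(self, res: int) -> np.ndarray:
        return np.nonzero(self.res_index == res)[0]


def _rotation_onto_z(axis: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix R with R @ axis = +z."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(axis @ z)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def rotation_zyz(tilt_deg: float, rot_deg: float) -> np.ndarray:
    """Rotation placing a z-aligned helix at (tilt, rotation).

    First rotates by ``rot_deg`` about the helix axis (z), then tilts the
    axis away from +z by ``tilt_deg`` about the y axis.
    """
    t = np.deg2rad(tilt_deg)
    p = np.deg2rad(rot_deg)
    ct, st = np.cos(t), np.sin(t)
    cp, sp = np.cos(p), np.sin(p)
    tilt_m = np.array([[ct, 0, st], [0, 1, 0], [-st, 0, ct]])
    spin_m = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1]])
    return tilt_m @ spin_m
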