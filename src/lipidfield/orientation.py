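"""Rigid-body orientation sampling of peptides in the membrane frame.

A placement is (d, θ, φ): depth of the centroid along the membrane normal,
tilt of the helix principal axis away from +z, and rotation about the
helical axis.  The sampler exhaustively grids these variables, and the
global minimum over the grid is the predicted orientation.  Insertion and
mutation free-energy differences are energy differences between
membrane-embedded and fully aqueous placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_REFERENCE_DEPTH
from .helix import _kabsch, _sidechain_template  # shared rigid-fit helpers
from .chemistry import assign_atom_params
from .constants import ONE_TO_THREE
from .structure import Structure, rotation_zyz


@dataclass(frozen=True)
class OrientationGridSpec:
    """Sampling grid: depth ±60 Å, tilt ±180°, rotation 0–360°.

    Default steps (2 Å, 5°, 15°) keep an exhaustive scan desk-scale; pair
    with :func:`refine_around` for a finer local pass.
    """

    depth_min: float = -60.0
    depth_max: float = 60.0
    depth_step: float = 2.0
    tilt_min: float = -180.0
    tilt_max: float = 180.0
    tilt_step: float = 5.0
    rot_min: float = 0.0
    rot_max: float = 360.0
    rot_step: float = 15.0

    def __post_init__(self):
        if min(self.depth_step, self.tilt_step, self.rot_step) <= 0:
            raise ValueError("grid steps must be positive")

    def depths(self) -> np.ndarray:
        return np.arange(self.depth_min, self.depth_max + 1e-9, self.depth_step)

    def tilts(self) -> np.ndarray:
        return np.arange(self.tilt_min, self.tilt_max + 1e-9, self.tilt_step)

    def rotations(self) -> np.ndarray:
        # 360° aliases 0°; keep the half-open interval
        return np.arange(self.rot_min, self.rot_max - 1e-9, self.rot_step)


def fold_tilt(theta) -> np.ndarray | float:
    """Fold a tilt angle into [0°, 90°] (axis direction is ambiguous)."""
    t = np.abs(np.asarray(theta, dtype=float)) % 360.0
    t = np.where(t > 180.0, 360.0 - t, t)
    t = np.where(t > 90.0, 180.0 - t, t)
    return t if t.ndim else float(t)


@dataclass
class Landscape:
    """Energies over the (depth, tilt, rotation) grid."""

    depths: np.ndarray
    tilts: np.ndarray
    rotations: np.ndarray
    energies: np.ndarray  # (nd, nt, nr)
    argmin_: tuple[float, float, float, float] = field(default=None, repr=False)

    def argmin(self) -> tuple[float, float, float, float]:
        """(d*, θ*, φ*, E*) with a deterministic tie-break.

        Ties on energy resolve lexicographically by smallest |d|, smallest
        folded tilt, smallest φ, then smallest d and θ as printed.
        """
        if self.argmin_ is not None:
            return self.argmin_
        e_min = self.energies.min()
        cand = np.argwhere(self.energies == e_min)
        keys = [
            (abs(self.depths[i]), fold_tilt(self.tilts[j]), self.rotations[k],
             self.depths[i], self.tilts[j])
            for i, j, k in cand
        ]
        i, j, k = cand[min(range(len(keys)), key=keys.__getitem__)]
        self.argmin_ = (float(self.depths[i]), float(self.tilts[j]),
                        float(self.rotations[k]), float(e_min))
        return self.argmin_

    def min_over_rotation(self) -> np.ndarray:
        """(nd, nt) landscape minimized over φ, for contour plots."""
        return self.energies.min(axis=2)

    def to_records(self):
        d, t, r = np.meshgrid(self.depths, self.tilts, self.rotations,
                              indexing="ij")
        return np.column_stack([d.ravel(), t.ravel(), r.ravel(),
                                self.energies.ravel()])


def apply_orientation(structure: Structure, depth: float, tilt: float,
                      rotation: float) -> Structure:
    """Rigidly place a structure at (depth, tilt, rotation).

    Rotation by φ about the helical axis, then tilt of that axis from +z,
    then translation of the centroid to (0, 0, depth) — a pure rigid motion
    applied to the canonical coordinates.
    """
    R = rotation_zyz(tilt, rotation)
    coords = structure.canonical_coords() @ R.T
    coords = coords + np.array([0.0, 0.0, depth])
    return structure.with_coords(coords, (depth, tilt, rotation))


def scan_orientations(structure: Structure, grid: OrientationGridSpec,
                      scorer) -> Landscape:
    """Exhaustive energy evaluation over the orientation grid.

    ``scorer`` maps an oriented structure to an energy.  Scorers exposing
    the vectorized ``depth_batch`` fast path (see
    :class:`~lipidfield.energy.MembraneScorer`) are evaluated one rotation
    at a time over the whole depth stack.
    """
    depths, tilts, rots = grid.depths(), grid.tilts(), grid.rotations()
    if 0 in (depths.size, tilts.size, rots.size):
        raise ValueError("empty orientation grid")
    energies = np.empty((depths.size, tilts.size, rots.size))
    canonical = structure.canonical_coords()
    fast = (hasattr(scorer, "supports_depth_batch")
            and scorer.supports_depth_batch())
    for jt, tilt in enumerate(tilts):
        for kr, rot in enumerate(rots):
            if fast:
                rotated = canonical @ rotation_zyz(tilt, rot).T
                energies[:, jt, kr] = scorer.depth_batch(structure, rotated,
                                                         depths)
            else:
                for idp, d in enumerate(depths):
                    energies[idp, jt, kr] = scorer(
                        apply_orientation(structure, d, tilt, rot))
    return Landscape(depths, tilts, rots, energies)


def refine_around(structure: Structure, coarse: Landscape, scorer,
                  depth_step: float = 0.5, tilt_step: float = 1.0,
                  rot_step: float = 5.0) -> Landscape:
    """Finer local re-scan around the coarse argmin."""
    d0, t0, r0, _ = coarse.argmin()
    dd = np.diff(coarse.depths).max() if coarse.depths.size > 1 else depth_step
    dt = np.diff(coarse.tilts).max() if coarse.tilts.size > 1 else tilt_step
    dr = (np.diff(coarse.rotations).max() if coarse.rotations.size > 1
          else rot_step)
    grid = OrientationGridSpec(
        depth_min=d0 - dd, depth_max=d0 + dd, depth_step=depth_step,
        tilt_min=t0 - dt, tilt_max=t0 + dt, tilt_step=tilt_step,
        rot_min=r0 - dr, rot_max=r0 + dr + rot_step, rot_step=rot_step,
    )
    return scan_orientations(structure, grid, scorer)


def tilt_angle(structure: Structure) -> float:
    """Angle (degrees, folded to [0°, 90°]) between the helix principal
    axis and the membrane normal, from the current coordinates."""
    axis = structure.principal_axis()
    return float(np.degrees(np.arccos(np.clip(abs(axis[2]), -1.0, 1.0))))


def aqueous_depth(structure: Structure,
                  reference_depth: float = DEFAULT_REFERENCE_DEPTH) -> float:
    """Depth placing every atom beyond the bulk-water reference depth."""
    z_extent = np.abs(structure.canonical_coords()[:, 2]).max()
    return reference_depth + z_extent + 1.0


def ddg_insertion(structure: Structure, scorer,
                  grid: OrientationGridSpec = OrientationGridSpec(),
                  aqueous_threshold: float = DEFAULT_REFERENCE_DEPTH) -> float:
    """Insertion free energy: lowest membrane-placed energy minus lowest
    aqueous-placed energy.

    Membrane placements are grid points with |d| < ``aqueous_threshold``;
    aqueous placements are those with |d| ≥ ``aqueous_threshold``.  The
    unfolded-reference energy cancels in the difference and is reported as
    zero for membrane-only scorers.  Invariant to additive constants in the
    scorer.
    """
    landscape = scan_orientations(structure, grid, scorer)
    aqueous = np.abs(landscape.depths) >= aqueous_threshold
    if not aqueous.any():
        raise ValueError(
            f"grid has no aqueous placements (|d| ≥ {aqueous_threshold} Å)"
        )
    if aqueous.all():
        raise ValueError("grid has no membrane placements")
    e = landscape.energies
    g_lipid = e[~aqueous].min()
    g_water = e[aqueous].min()
    return float(g_lipid - g_water)


def mutate_residue(structure: Structure, position: int,
                   mutant_code: str) -> Structure:
    """Fixed-backbone point mutation: replace the side chain at ``position``
    (0-based) with the mutant template grafted onto the existing N/CA/C.

    Backbone atoms (and their charges, including any terminal charge) are
    untouched; mutating a residue to itself returns an identical structure.
    """
    mutant_code = mutant_code.upper()
    if mutant_code not in ONE_TO_THREE:
        raise ValueError(f"unknown mutant code {mutant_code!r}")
    if not 0 <= position < structure.n_residues:
        raise IndexError(f"position {position} outside sequence")
    if structure.sequence[position] == mutant_code:
        return structure

    res_mask = structure.res_index == position
    backbone = np.isin(structure.atom_names, ("N", "CA", "C", "O", "OXT"))
    keep = ~res_mask | backbone

    bb_idx = {n: int(np.nonzero(res_mask & (structure.atom_names == n))[0][0])
              for n in ("N", "CA", "C")}
    frame, s_names, s_elements, s_coords = _sidechain_template(
        ONE_TO_THREE[mutant_code])
    target = np.stack([structure.coords[bb_idx[n]] for n in ("N", "CA", "C")])
    R, t = _kabsch(frame, target)
    placed = s_coords @ R.T + t

    new_seq = (structure.sequence[:position] + mutant_code
               + structure.sequence[position + 1:])
    names, elements, res_index, coords, charges, ttypes, f_pore = \
        [], [], [], [], [], [], []
    for i in range(structure.n_atoms):
        if not keep[i]:
            continue
        names.append(structure.atom_names[i])
        elements.append(structure.elements[i])
        res_index.append(structure.res_index[i])
        coords.append(structure.coords[i])
        charges.append(structure.charges[i])
        ttypes.append(structure.atom_types[i])
        f_pore.append(structure.f_pore[i])
        # append the new side chain right after this residue's backbone O
        if (structure.res_index[i] == position
                and structure.atom_names[i] == "O"):
            for nm, el, xyz in zip(s_names, s_elements, placed):
                q, tt = assign_atom_params(mutant_code, nm)
                names.append(nm)
                elements.append(el)
                res_index.append(position)
                coords.append(xyz)
                charges.append(q)
                ttypes.append(tt)
                f_pore.append(structure.f_pore[res_mask].mean()
                              if res_mask.any() else 0.0)

    return Structure(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        res_index=np.array(res_index),
        sequence=new_seq,
        coords=np.array(coords),
        charges=np.array(charges),
        atom_types=np.array(ttypes, dtype=object),
        f_pore=np.array(f_pore),
        transform=structure.transform,
    )


def ddg_mutation(structure: Structure, position: int, mutant_code: str,
                 scorer,
                 reference_depth: float = DEFAULT_REFERENCE_DEPTH) -> float:
    """Mutational free-energy change in the membrane, fixed backbone and
    fixed orientation:

        ΔΔG = [G_bilayer(mut) − G_water(mut)] − [G_bilayer(nat) − G_water(nat)]

    Bilayer energies use the structure's current placement; water energies
    re-place the same coordinates at a fully aqueous depth.  Invariant to
    additive constants in the scorer; exactly zero for a self-mutation.
    """
    mutant = mutate_residue(structure, position, mutant_code)
    if mutant is structure:
        return 0.0
    d_aq = aqueous_depth(structure, reference_depth)
    d, tilt, rot = structure.transform
    g_bil_nat = scorer(structure)
    g_bil_mut = scorer(mutant)
    nat_water = apply_orientation(structure, d_aq, tilt, rot)
    mut_water = apply_orientation(mutant, d_aq, tilt, rot)
    g_wat_nat = scorer(nat_water)
    g_wat_mut = scorer(mut_water)
    return float((g_bil_mut - g_wat_mut) - (g_bil_nat - g_wat_nat))
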