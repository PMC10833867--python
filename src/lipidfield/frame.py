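"""Membrane coordinate frame, hydration fractions, and region labels.

Convention: the membrane normal is +z, the bilayer center is z = 0, and
coordinates are in Å (structures pre-oriented as in the OPM database).

Hydration ``f_hyd`` is a per-atom proxy in [0, 1] for water exposure: 0 for
a lipid-exposed atom at the bilayer center, 1 in bulk water.  ``f_pore``
measures exposure to a water-filled pore inside the membrane span; pore
water hydrates an atom regardless of its depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MembraneGeometry:
    """Slab geometry of the implicit bilayer.

    half_thickness : Å from the bilayer center to the hydrophobic boundary.
    steepness : exponent of the logistic depth-to-hydration transition;
        larger values sharpen the water/lipid interface.
    """

    half_thickness: float = 15.0
    steepness: float = 10.0

    def __post_init__(self):
        if self.half_thickness <= 0:
            raise ValueError("half_thickness must be positive")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")


@dataclass
class HydrationState:
    """Per-atom hydration and pore fractions, clamped to [0, 1]."""

    f_hyd: np.ndarray
    f_pore: np.ndarray

    def __post_init__(self):
        self.f_hyd = np.clip(np.asarray(self.f_hyd, dtype=float), 0.0, 1.0)
        self.f_pore = np.clip(np.asarray(self.f_pore, dtype=float), 0.0, 1.0)
        if self.f_hyd.shape != self.f_pore.shape:
            raise ValueError("f_hyd and f_pore must have the same shape")


def hydration_fraction(z, geometry: MembraneGeometry = MembraneGeometry(), f_pore=0.0):
    """Depth-dependent hydration fraction.

    Logistic in normalized depth u = |z|/half_thickness:
    f = uⁿ/(1 + uⁿ) with n = steepness, so f(0) = 0 and f → 1 in bulk
    water.  Pore water overrides burial: the result is
    max(depth term, f_pore).

    Accepts scalars or arrays (broadcast together).
    """
    z = np.asarray(z, dtype=float)
    f_pore = np.clip(np.asarray(f_pore, dtype=float), 0.0, 1.0)
    u = np.abs(z) / geometry.half_thickness
    with np.errstate(over="ignore"):
        un = u**geometry.steepness
        depth_term = np.where(np.isinf(un), 1.0, un / (1.0 + un))
    out = np.clip(np.maximum(depth_term, f_pore), 0.0, 1.0)
    return out if out.ndim else float(out)


def pair_hydration(f_i, f_j):
    """Pair hydration fraction: geometric mean √(f_i·f_j)."""
    f_i = np.asarray(f_i, dtype=float)
    f_j = np.asarray(f_j, dtype=float)
    out = np.sqrt(f_i * f_j)
    return out if out.ndim else float(out)


#: Region labels used for stratified design metrics.
REGIONS = ("lipid", "interface", "aqueous")


def classify_region(f_hyd: float, f_pore: float) -> str:
    """Classify an atom/residue environment from hydration and pore fractions.

    lipid:     f_hyd < 0.25 and f_pore < 0.5
    interface: 0.25 ≤ f_hyd < 0.75 and f_pore < 0.5
    aqueous:   everything else (high hydration, or pore-facing)

    Pore-facing positions (f_pore ≥ 0.5) count as aqueous regardless of
    depth, since they see water.
    """
    if not (0.0 <= f_hyd <= 1.0 and 0.0 <= f_pore <= 1.0):
        raise ValueError("f_hyd and f_pore must lie in [0, 1]")
    if f_pore < 0.5:
        if f_hyd < 0.25:
            return "lipid"
        if f_hyd < 0.75:
            return "interface"
    return "aqueous"


def classify_regions(f_hyd, f_pore) -> list[str]:
    """Vectorized :func:`classify_region` over arrays."""
    return [classify_region(float(h), float(p)) for h, p in
            zip(np.atleast_1d(f_hyd), np.atleast_1d(f_pore))]
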