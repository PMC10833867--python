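"""Membrane energy terms and their weighted combination.

Three terms describe the membrane environment:

* **transfer** — water-to-bilayer transfer energy: Σ_atoms ΔG_w,l(type) ·
  (1 − f_hyd), so a fully hydrated atom contributes nothing.
* **lipid field** — the interaction of protein partial charges with the
  depth-dependent electrostatic potential of the empty bilayer:
  Σ_atoms q · ΔΨ(z).
* **dielectric excess** — the change of truncated-Coulomb pair energies
  caused by the lower membrane dielectric, relative to the same pairs in
  solution: C0·q_i·q_j·(1/r − 1/r_max)·(1/ε(r, f_pair) − 1/ε_sol(r)).

The combined score is

    E = baseline + w_wl·ΔG_w,l + w_lipid·ΔG_lipid + w_dielec·ΣΔE_elec

where the baseline is an injected scorer for the non-membrane part of the
energy (defaults to zero).  Setting weights (0.5, 0, 0) recovers a
transfer-only membrane model whose score is independent of the lipid
profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .constants import COULOMB_CONSTANT_SCORE
from .frame import HydrationState, MembraneGeometry, hydration_fraction, pair_hydration
from .potential import LipidProfileParams
from .structure import Structure
from .transfer import AtomScale


@dataclass(frozen=True)
class DielectricParams:
    """Sigmoidal distance-dependent dielectric parameters.

    In solution the dielectric rises from the protein core value (6) to the
    surface value (80); inside the membrane the corresponding pair is
    (3, 10).  ``sigmoid_steepness`` (Å⁻¹) sets how fast the sigmoid
    saturates; ``r_max`` truncates the Coulomb term; ``C0`` is the Coulomb
    prefactor in Å·kcal·mol⁻¹·e⁻².
    """

    eps_core_sol: float = 6.0
    eps_surf_sol: float = 80.0
    eps_core_mem: float = 3.0
    eps_surf_mem: float = 10.0
    sigmoid_steepness: float = 1.2
    r_max: float = 5.5
    C0: float = COULOMB_CONSTANT_SCORE

    def __post_init__(self):
        for core, surf in ((self.eps_core_sol, self.eps_surf_sol),
                           (self.eps_core_mem, self.eps_surf_mem)):
            if not 0 < core <= surf:
                raise ValueError("need 0 < eps_core <= eps_surf")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")


@dataclass(frozen=True)
class WeightSet:
    """Combination weights, each bounded to [0, 1]."""

    w_wl: float = 1.0
    w_lipid: float = 0.128
    w_dielec: float = 0.01

    def __post_init__(self):
        for name in ("w_wl", "w_lipid", "w_dielec"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_wl, self.w_lipid, self.w_dielec])


#: Weights that reduce the combined score to the transfer-only predecessor
#: model (membrane electrostatics switched off).
TRANSFER_ONLY_WEIGHTS = WeightSet(0.5, 0.0, 0.0)


@dataclass
class EnergyBreakdown:
    """Per-residue and total energies of each term (kcal/mol ≡ REU).

    Pair energies are split half/half between the partner residues, so the
    per-residue columns sum exactly to the totals.
    """

    transfer: np.ndarray
    lipid_field: np.ndarray
    dielec_excess: np.ndarray
    baseline: np.ndarray
    weights: WeightSet

    @property
    def combined(self) -> np.ndarray:
        w = self.weights
        return (self.baseline + w.w_wl * self.transfer
                + w.w_lipid * self.lipid_field + w.w_dielec * self.dielec_excess)

    def total(self, term: str = "combined") -> float:
        return float(getattr(self, term).sum())

    def to_dict(self) -> dict:
        return {
            "totals": {t: self.total(t) for t in
                       ("transfer", "lipid_field", "dielec_excess",
                        "baseline", "combined")},
            "per_residue": {t: getattr(self, t).tolist() for t in
                            ("transfer", "lipid_field", "dielec_excess",
                             "baseline", "combined")},
            "weights": {"w_wl": self.weights.w_wl,
                        "w_lipid": self.weights.w_lipid,
                        "w_dielec": self.weights.w_dielec},
        }


def sigmoidal_dielectric(r, eps_core, eps_surf, steepness=1.2):
    """Distance-dependent dielectric rising from eps_core at contact to
    eps_surf at long range.

    Uses the standard screened form
    ε(r) = ε_s − (ε_s − ε_c)·((σr)² + 2σr + 2)·e^(−σr)/2.
    """
    sr = steepness * np.asarray(r, dtype=float)
    out = eps_surf - (eps_surf - eps_core) * (sr**2 + 2.0 * sr + 2.0) * np.exp(-sr) / 2.0
    return out if out.ndim else float(out)


def mixed_dielectric(r, f_pair, params: DielectricParams = DielectricParams()):
    """Hydration-weighted linear mixture of the solution and membrane
    dielectric sigmoids: f·ε_sol(r) + (1−f)·ε_memb(r)."""
    f_pair = np.asarray(f_pair, dtype=float)
    eps_sol = sigmoidal_dielectric(r, params.eps_core_sol, params.eps_surf_sol,
                                   params.sigmoid_steepness)
    eps_mem = sigmoidal_dielectric(r, params.eps_core_mem, params.eps_surf_mem,
                                   params.sigmoid_steepness)
    out = f_pair * eps_sol + (1.0 - f_pair) * eps_mem
    return out if out.ndim else float(out)


def _check_r(r):
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive (clash guard)")
    return r


def coulomb_pair(q_i, q_j, r, eps, params: DielectricParams = DielectricParams()):
    """Truncated Coulomb pair energy C0·q_i·q_j/ε·(1/r − 1/r_max).

    Zero at and beyond r_max; r = 0 raises.
    """
    r = _check_r(r)
    bracket = np.where(r < params.r_max, 1.0 / r - 1.0 / params.r_max, 0.0)
    out = params.C0 * np.asarray(q_i) * np.asarray(q_j) / np.asarray(eps) * bracket
    return out if out.ndim else float(out)


def excess_coulomb_pair(q_i, q_j, r, f_pair,
                        params: DielectricParams = DielectricParams()):
    """Membrane-induced excess pair energy.

    The same truncated Coulomb interaction evaluated with the mixed
    dielectric, minus its value with the solution dielectric — zero for a
    fully hydrated pair, and zero at or beyond r_max.
    """
    r = _check_r(r)
    eps_sol = sigmoidal_dielectric(r, params.eps_core_sol, params.eps_surf_sol,
                                   params.sigmoid_steepness)
    eps_mix = mixed_dielectric(r, f_pair, params)
    bracket = np.where(r < params.r_max, 1.0 / r - 1.0 / params.r_max, 0.0)
    out = (params.C0 * np.asarray(q_i) * np.asarray(q_j) * bracket
           * (1.0 / eps_mix - 1.0 / eps_sol))
    return out if out.ndim else float(out)


def hydration_state(structure: Structure,
                    geometry: MembraneGeometry = MembraneGeometry()) -> HydrationState:
    """Per-atom hydration from the current membrane-frame coordinates."""
    f = hydration_fraction(structure.coords[:, 2], geometry, structure.f_pore)
    return HydrationState(np.atleast_1d(f), structure.f_pore)


def transfer_energy(structure: Structure, atom_scale: AtomScale,
                    hydration: HydrationState) -> np.ndarray:
    """Per-residue water-to-bilayer transfer energy Σ ΔG·(1 − f_hyd)."""
    missing = sorted({t for t in structure.atom_types if t not in atom_scale})
    if missing:
        raise KeyError(f"atom scale lacks transfer types: {missing}")
    g = np.array([atom_scale[t] for t in structure.atom_types])
    per_atom = g * (1.0 - hydration.f_hyd)
    return np.bincount(structure.res_index, weights=per_atom,
                       minlength=structure.n_residues)


def lipid_field_energy(structure: Structure,
                       profile: LipidProfileParams) -> np.ndarray:
    """Per-residue lipid electrostatic field energy Σ q·ΔΨ(z)."""
    if not np.all(np.isfinite(structure.charges)):
        bad = np.nonzero(~np.isfinite(structure.charges))[0]
        raise ValueError(f"atoms with missing charges: {bad.tolist()}")
    per_atom = structure.charges * profile.evaluate(structure.coords[:, 2])
    return np.bincount(structure.res_index, weights=per_atom,
                       minlength=structure.n_residues)


@dataclass
class PairList:
    """Intra-structure atom pairs within the Coulomb cutoff.

    Built once per structure from canonical coordinates: pair identities,
    distances, charge products and the two dielectric sigmoids are all
    invariant under rigid-body placement, so only the pair hydration varies
    across orientations.  Pairs within the same or adjacent residues are
    excluded (a bonded-neighbor exclusion).
    """

    i: np.ndarray
    j: np.ndarray
    r: np.ndarray
    qq_bracket: np.ndarray  # C0·q_i·q_j·(1/r − 1/r_max)
    eps_sol: np.ndarray
    eps_mem: np.ndarray

    @classmethod
    def build(cls, structure: Structure,
              params: DielectricParams = DielectricParams()) -> "PairList":
        coords = structure.canonical_coords()
        tree = cKDTree(coords)
        pairs = tree.query_pairs(params.r_max, output_type="ndarray")
        if pairs.size:
            i, j = pairs[:, 0], pairs[:, 1]
            keep = np.abs(structure.res_index[i] - structure.res_index[j]) > 1
            i, j = i[keep], j[keep]
        else:
            i = j = np.empty(0, dtype=int)
        r = np.linalg.norm(coords[i] - coords[j], axis=1)
        if np.any(r <= 1e-9):
            raise ValueError("coincident atoms in pair list (clash)")
        qq_bracket = (params.C0 * structure.charges[i] * structure.charges[j]
                      * (1.0 / r - 1.0 / params.r_max))
        eps_sol = sigmoidal_dielectric(r, params.eps_core_sol, params.eps_surf_sol,
                                       params.sigmoid_steepness)
        eps_mem = sigmoidal_dielectric(r, params.eps_core_mem, params.eps_surf_mem,
                                       params.sigmoid_steepness)
        return cls(i, j, np.asarray(r), np.asarray(qq_bracket),
                   np.atleast_1d(eps_sol), np.atleast_1d(eps_mem))


def dielectric_excess_energy(structure: Structure,
                             hydration: HydrationState,
                             params: DielectricParams = DielectricParams(),
                             pairs: PairList | None = None) -> np.ndarray:
    """Per-residue membrane dielectric excess energy (pairs split half/half)."""
    if pairs is None:
        pairs = PairList.build(structure, params)
    out = np.zeros(structure.n_residues)
    if pairs.i.size == 0:
        return out
    f_pair = pair_hydration(hydration.f_hyd[pairs.i], hydration.f_hyd[pairs.j])
    eps_mix = f_pair * pairs.eps_sol + (1.0 - f_pair) * pairs.eps_mem
    e_pair = pairs.qq_bracket * (1.0 / eps_mix - 1.0 / pairs.eps_sol)
    np.add.at(out, structure.res_index[pairs.i], 0.5 * e_pair)
    np.add.at(out, structure.res_index[pairs.j], 0.5 * e_pair)
    return out


def total_score(
    structure: Structure,
    weights: WeightSet,
    profile: LipidProfileParams,
    atom_scale: AtomScale,
    params: DielectricParams = DielectricParams(),
    geometry: MembraneGeometry = MembraneGeometry(),
    baseline_scorer=None,
    pairs: PairList | None = None,
) -> EnergyBreakdown:
    """Full combined membrane score with per-residue ledger.

    ``baseline_scorer`` is any callable mapping the structure to either a
    total energy (spread uniformly over residues) or a per-residue array;
    by default it contributes zero.
    """
    hyd = hydration_state(structure, geometry)
    trans = transfer_energy(structure, atom_scale, hyd)
    lipid = lipid_field_energy(structure, profile)
    dielec = dielectric_excess_energy(structure, hyd, params, pairs)
    baseline = np.zeros(structure.n_residues)
    if baseline_scorer is not None:
        b = np.asarray(baseline_scorer(structure), dtype=float)
        baseline = (np.full(structure.n_residues, b / structure.n_residues)
                    if b.ndim == 0 else b)
    return EnergyBreakdown(trans, lipid, dielec, baseline, weights)


class MembraneScorer:
    """Callable scorer bundling profile, scales and parameters.

    Calling it on a structure returns the combined total energy.  The
    ``depth_batch`` fast path evaluates a whole stack of depths for one
    rotated pose in a single vectorized pass, exploiting that rigid motion
    leaves the pair list invariant.
    """

    def __init__(self, profile: LipidProfileParams, atom_scale: AtomScale,
                 weights: WeightSet = WeightSet(),
                 params: DielectricParams = DielectricParams(),
                 geometry: MembraneGeometry = MembraneGeometry(),
                 baseline_scorer=None):
        self.profile = profile
        self.atom_scale = atom_scale
        self.weights = weights
        self.params = params
        self.geometry = geometry
        self.baseline_scorer = baseline_scorer
        self._pair_cache: tuple[int, PairList] | None = None

    def _pairs(self, structure: Structure) -> PairList:
        key = id(structure.canonical_coords())
        if self._pair_cache is None or self._pair_cache[0] != key:
            self._pair_cache = (key, PairList.build(structure, self.params))
        return self._pair_cache[1]

    def breakdown(self, structure: Structure) -> EnergyBreakdown:
        return total_score(structure, self.weights, self.profile,
                           self.atom_scale, self.params, self.geometry,
                           self.baseline_scorer, pairs=self._pairs(structure))

    def __call__(self, structure: Structure) -> float:
        return self.breakdown(structure).total("combined")

    def supports_depth_batch(self) -> bool:
        return self.baseline_scorer is None

    def depth_batch(self, structure: Structure, rotated_xyz: np.ndarray,
                    depths: np.ndarray) -> np.ndarray:
        """Combined energies for one rotation over a stack of depths.

        ``rotated_xyz`` are canonical coordinates after the (tilt, rotation)
        rotation; depth d shifts every z by d.
        """
        depths = np.asarray(depths, dtype=float)
        z = rotated_xyz[:, 2][None, :] + depths[:, None]  # (nd, natoms)
        f = hydration_fraction(z, self.geometry, structure.f_pore[None, :])
        g = np.array([self.atom_scale[t] for t in structure.atom_types])
        e_trans = ((1.0 - f) * g[None, :]).sum(axis=1)
        e_lipid = (structure.charges[None, :] * self.profile.evaluate(z)).sum(axis=1)
        pairs = self._pairs(structure)
        if pairs.i.size:
            f_pair = np.sqrt(f[:, pairs.i] * f[:, pairs.j])
            eps_mix = (f_pair * pairs.eps_sol[None, :]
                       + (1.0 - f_pair) * pairs.eps_mem[None, :])
            e_dielec = (pairs.qq_bracket[None, :]
                        * (1.0 / eps_mix - 1.0 / pairs.eps_sol[None, :])).sum(axis=1)
        else:
            e_dielec = np.zeros(depths.size)
        w = self.weights
        return w.w_wl * e_trans + w.w_lipid * e_lipid + w.w_dielec * e_dielec


def fit_weights(
    terms: np.ndarray,
    experimental_ddg: np.ndarray,
    baseline: np.ndarray | None = None,
    bounds: tuple[float, float] = (0.0, 1.0),
    n_starts: int = 8,
    seed: int = 0,
) -> WeightSet:
    """Fit combination weights against experimental ΔΔG values.

    Maximizes the Pearson correlation between ``baseline + terms @ w`` and
    the experimental vector over w ∈ bounds³ with L-BFGS-B from ``n_starts``
    seeded random starting points.  Correlation only identifies the weights
    up to a positive scale, so the returned triple is one representative of
    the optimal ray within the bounds.

    ``terms`` has one row per measurement and columns
    (transfer, lipid_field, dielec_excess).
    """
    terms = np.asarray(terms, dtype=float)
    y = np.asarray(experimental_ddg, dtype=float)
    if terms.ndim != 2 or terms.shape[1] != 3:
        raise ValueError("terms must be (n_points, 3)")
    if terms.shape[0] != y.size:
        raise ValueError("terms and experimental_ddg length mismatch")
    if y.size < 4:
        raise ValueError("need at least 4 experimental points")
    if np.ptp(y) == 0:
        raise ValueError("experimental ΔΔG vector is constant; "
                         "correlation is undefined")
    base = np.zeros(y.size) if baseline is None else np.asarray(baseline, float)
    if np.allclose(terms, 0.0):
        raise ValueError("all term values are zero; weights are unidentifiable")
    lo, hi = bounds
    if lo == hi:
        return WeightSet(lo, lo, lo)

    def neg_corr(w):
        pred = base + terms @ w
        if np.ptp(pred) < 1e-14:
            return 1.0
        return -np.corrcoef(pred, y)[0, 1]

    rng = np.random.default_rng(seed)
    best_w, best_val = None, np.inf
    starts = [np.full(3, 0.5 * (lo + hi))] + [
        rng.uniform(lo, hi, size=3) for _ in range(max(0, n_starts - 1))
    ]
    for x0 in starts:
        res = minimize(neg_corr, x0, method="L-BFGS-B",
                       bounds=[(lo, hi)] * 3)
        if res.fun < best_val:
            best_val, best_w = res.fun, res.x
    return WeightSet(*np.clip(best_w, lo, hi))
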