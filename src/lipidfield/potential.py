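"""Bilayer electrostatic potential profiles.

A lipid bilayer patch simulated without protein leaves behind time-averaged
charge densities of lipid, water, and (optionally) salt on a periodic 3D
grid.  Solving Poisson's equation on that grid and averaging laterally gives
the membrane-depth-dependent electrostatic potential Ψ(z), which is then
condensed into a small analytical parameterization: a logistic (sigmoid)
tail for the head-group/water region and a quartic polynomial in |z| for the
bilayer core, joined at a crossover depth ``z_c``.

Units: densities in e/Å³, lengths in Å, potentials in kcal·mol⁻¹·e⁻¹.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import COULOMB_CONSTANT_FULL, DEFAULT_REFERENCE_DEPTH


class NonNeutralGridError(ValueError):
    """Raised for a periodic charge grid with non-zero net charge."""


class ProfileFitError(RuntimeError):
    """Raised when the piecewise profile fit fails to converge.

    Carries the last residual norm in ``residual``.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass
class ChargeDensityGrid:
    """Periodic grid of charge densities for an empty bilayer-water system.

    The z axis is the membrane normal; the bilayer center sits at the grid
    mid-plane, so voxel ``iz`` has depth ``(iz - nz//2) * spacing_z``.

    Parameters
    ----------
    dims : (3,) ints
        Grid counts (nx, ny, nz).
    spacing : (3,) floats
        Å per grid step along each axis.
    density_lipid, density_water, density_salt : (nx, ny, nz) arrays
        Charge density per voxel in e/Å³.
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    density_lipid: np.ndarray
    density_water: np.ndarray
    density_salt: np.ndarray

    def __post_init__(self):
        self.dims = tuple(int(d) for d in self.dims)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(d <= 0 for d in self.dims):
            raise ValueError(f"grid dims must be positive, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        for name in ("density_lipid", "density_water", "density_salt"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.dims:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {self.dims}"
                )
            setattr(self, name, arr)

    @property
    def box(self) -> tuple[float, float, float]:
        """Periodic box lengths in Å."""
        return tuple(d * s for d, s in zip(self.dims, self.spacing))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def total_density(self) -> np.ndarray:
        return self.density_lipid + self.density_water + self.density_salt

    def net_charge(self) -> float:
        """Total charge of the box in e."""
        return float(self.total_density.sum() * self.voxel_volume)

    def z_coords(self) -> np.ndarray:
        nz = self.dims[2]
        return (np.arange(nz) - nz // 2) * self.spacing[2]


@dataclass
class PotentialProfile1D:
    """Laterally averaged potential as a function of membrane depth."""

    depths: np.ndarray
    potential: np.ndarray
    reference_depth: float = DEFAULT_REFERENCE_DEPTH

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.potential = np.asarray(self.potential, dtype=float)
        if self.depths.shape != self.potential.shape:
            raise ValueError("depths and potential must have the same shape")
        if self.depths.size >= 2 and not np.all(np.diff(self.depths) > 0):
            raise ValueError("depths must be strictly increasing")

    def referenced(self) -> "PotentialProfile1D":
        """Pin the potential to zero at the grid point nearest the reference
        depth.  Idempotent."""
        idx = int(np.argmin(np.abs(self.depths - self.reference_depth)))
        return PotentialProfile1D(
            self.depths,
            self.potential - self.potential[idx],
            self.reference_depth,
        )


@dataclass
class LipidProfileParams:
    """Piecewise analytical bilayer potential for one lipid/salt condition.

    The profile is a function of |z| only:

        Ψ̃(z) = A1 + (A1 − A2) / (1 + exp((|z| − A3)/A4))   for |z| ≥ z_c
        Ψ̃(z) = C1|z|⁴ + C2|z|³ + C3|z|² + C4|z| + C5        for |z| < z_c

    evaluated relative to the sigmoid value at ``reference_depth`` so that
    Ψ̃(reference_depth) = 0 (bulk-water reference).  With A4 > 0 the |z|→∞
    asymptote of the sigmoid branch is A1.
    """

    lipid_name: str
    A1: float
    A2: float
    A3: float
    A4: float
    C1: float
    C2: float
    C3: float
    C4: float
    C5: float
    z_c: float
    has_salt: bool = False
    reference_depth: float = DEFAULT_REFERENCE_DEPTH
    fit_info: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.z_c <= 0:
            raise ValueError(f"z_c must be positive, got {self.z_c}")
        if self.A4 == 0:
            raise ValueError("A4 must be nonzero")

    def _sigmoid(self, t):
        with np.errstate(over="ignore"):  # exp overflow → fraction → 0
            return self.A1 + (self.A1 - self.A2) / (
                1.0 + np.exp((t - self.A3) / self.A4))

    def _quartic(self, t):
        return np.polyval([self.C1, self.C2, self.C3, self.C4, self.C5], t)

    def _raw(self, t):
        t = np.asarray(t, dtype=float)
        return np.where(t >= self.z_c, self._sigmoid(t), self._quartic(t))

    def evaluate(self, z):
        """Referenced potential difference ΔΨ(z) in kcal·mol⁻¹·e⁻¹.

        Even in z; exactly zero at and beyond |z| = reference_depth (the
        potential is *defined* as zero in bulk water, so the aqueous
        reference state carries no lipid-field energy).
        """
        z = np.abs(np.asarray(z, dtype=float))
        offset = self._sigmoid(np.asarray(self.reference_depth))
        out = np.where(z >= self.reference_depth, 0.0, self._raw(z) - offset)
        return out if out.ndim else float(out)

    __call__ = evaluate


def solve_poisson(
    grid: ChargeDensityGrid,
    neutralizing_background: bool = False,
    charge_atol: float = 1e-6,
) -> np.ndarray:
    """Solve the periodic Poisson equation on the density grid.

    Solves the discrete 7-point-stencil Laplacian equation
    ``∇²Ψ = −4π k_e ρ`` spectrally (FFT), with vacuum permittivity and the
    charge density taken as the sum of the lipid, water, and salt
    contributions.  The k = 0 Fourier mode is set to zero (gauge choice);
    downstream referencing pins the potential in bulk water.

    Parameters
    ----------
    grid
        Periodic charge density grid.
    neutralizing_background
        If True, a uniform background charge is subtracted so a slightly
        non-neutral grid becomes solvable; otherwise a non-neutral grid
        raises :class:`NonNeutralGridError`.
    charge_atol
        Net-charge tolerance in e.

    Returns
    -------
    (nx, ny, nz) array of Ψ in kcal·mol⁻¹·e⁻¹.
    """
    rho = grid.total_density.copy()
    net = grid.net_charge()
    if abs(net) > charge_atol:
        if not neutralizing_background:
            raise NonNeutralGridError(
                f"grid carries net charge {net:.3g} e; pass "
                "neutralizing_background=True to subtract a uniform background"
            )
        rho -= rho.mean()

    nx, ny, nz = grid.dims
    hx, hy, hz = grid.spacing
    # Eigenvalues of the discrete periodic Laplacian, one axis at a time.
    lam = (
        (2.0 * np.cos(2.0 * np.pi * np.fft.fftfreq(nx)) - 2.0) / hx**2
    )[:, None, None]
    lam = lam + (
        (2.0 * np.cos(2.0 * np.pi * np.fft.fftfreq(ny)) - 2.0) / hy**2
    )[None, :, None]
    lam = lam + (
        (2.0 * np.cos(2.0 * np.pi * np.fft.fftfreq(nz)) - 2.0) / hz**2
    )[None, None, :]

    rhs_hat = np.fft.fftn(-4.0 * np.pi * COULOMB_CONSTANT_FULL * rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        psi_hat = rhs_hat / lam
    psi_hat[0, 0, 0] = 0.0
    psi = np.fft.ifftn(psi_hat).real
    return psi


def lateral_average(
    volume: np.ndarray,
    spacing,
    reference_depth: float = DEFAULT_REFERENCE_DEPTH,
) -> PotentialProfile1D:
    """Average Ψ(x, y, z) over x and y and re-reference.

    The depth axis is the last array axis, with the bilayer center at the
    mid-plane voxel.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={volume.ndim}")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float).ravel(), (3,))
    nz = volume.shape[2]
    depths = (np.arange(nz) - nz // 2) * spacing[2]
    profile = PotentialProfile1D(depths, volume.mean(axis=(0, 1)), reference_depth)
    return profile.referenced()


def _symmetrize(profile: PotentialProfile1D):
    """Fold a profile onto |z|: average Ψ(t) and Ψ(−t) on a positive grid."""
    z, psi = profile.depths, profile.potential
    t_max = min(z.max(), -z.min()) if z.min() < 0 else z.max()
    t = np.unique(np.abs(z))
    t = t[t <= t_max + 1e-9]
    psi_pos = np.interp(t, z, psi)
    psi_neg = np.interp(-t[::-1], z, psi)[::-1]
    return t, 0.5 * (psi_pos + psi_neg)


def _quartic_critical_zc(coeffs, t_max):
    """Largest positive critical point of the quartic core polynomial."""
    deriv = np.polyder(np.poly1d(coeffs))
    roots = deriv.roots
    real = roots[np.abs(roots.imag) < 1e-8].real
    real = real[(real > 1e-6) & (real < t_max)]
    if real.size == 0:
        return None
    return float(real.max())


def _piecewise_fit_once(t, psi, z_c, sig_init, continuity_weight):
    """One pass of the coupled piecewise fit at a fixed crossover depth.

    Fits the quartic on the core window (soft continuity pseudo-observation
    at z_c against the current sigmoid), then refits the sigmoid on the
    tail (continuity against the new quartic).  Returns
    (quartic coeffs, sigmoid params, residual norm).
    """
    core = t < z_c
    tc, pc = t[core], psi[core]
    # tail-only sigmoid bootstrap when no sigmoid estimate exists yet
    sig = sig_init
    if sig is None:
        tt0, pt0 = t[~core], psi[~core]
        p0 = _sigmoid_guess(tt0, pt0, z_c)
        try:
            sig, _ = curve_fit(
                _sigmoid_eval_vec, tt0, pt0, p0=p0,
                bounds=([-np.inf, -np.inf, -np.inf, 1e-3], [np.inf] * 4),
                maxfev=20000,
            )
        except (RuntimeError, TypeError):
            sig = np.asarray(p0, dtype=float)

    quartic = np.zeros(5)
    if tc.size >= 5:
        V = np.vstack([np.vander(tc, 5), np.vander([z_c], 5)])
        rhs = np.append(pc, _sigmoid_eval(sig, z_c))
        w = np.append(np.ones(tc.size), continuity_weight)
        sw = np.sqrt(w)
        quartic, *_ = np.linalg.lstsq(V * sw[:, None], rhs * sw, rcond=None)

    tail = t >= z_c
    tt, pt = t[tail], psi[tail]
    tt_fit = np.append(tt, z_c)
    pt_fit = np.append(pt, np.polyval(quartic, z_c))
    sigma = np.append(np.ones(tt.size), 1.0 / math.sqrt(continuity_weight))
    try:
        sig, _ = curve_fit(
            _sigmoid_eval_vec, tt_fit, pt_fit, p0=sig, sigma=sigma,
            bounds=([-np.inf, -np.inf, -np.inf, 1e-3], [np.inf] * 4),
            maxfev=20000,
        )
    except RuntimeError:
        pass
    model = np.where(t >= z_c, _sigmoid_eval_vec(t, *sig),
                     np.polyval(quartic, t))
    residual = float(np.linalg.norm(model - psi))
    return quartic, np.asarray(sig, dtype=float), residual


def fit_profile(
    profile: PotentialProfile1D,
    initial_zc: float | None = None,
    lipid_name: str = "fit",
    has_salt: bool = False,
    max_iter: int = 50,
    zc_tol: float = 0.01,
    continuity_weight: float = 100.0,
) -> LipidProfileParams:
    """Fit the two-piece analytical form to a depth profile.

    The crossover depth is first located by scanning candidate values and
    keeping the one with the lowest piecewise-fit residual (or starting
    from ``initial_zc`` if given), then polished by self-consistency:
    alternately (a) fit the quartic on the current core window with a soft
    continuity pseudo-observation at z_c, (b) recompute z_c as the largest
    critical point of the fitted quartic, (c) refit the sigmoid tail, until
    z_c is stable to ``zc_tol`` Å.

    Raises :class:`ProfileFitError` (carrying the last residual norm) if z_c
    has not stabilized after ``max_iter`` iterations.
    """
    ref = profile.reference_depth
    profile = profile.referenced()
    t, psi = _symmetrize(profile)
    if t.max() < ref:
        raise ValueError(
            f"profile reaches only |z| = {t.max():.1f} Å; must cover the "
            f"reference depth {ref:.1f} Å"
        )

    if initial_zc is None:
        best = (math.inf, 4.0, None, None)
        for zc_try in np.arange(4.0, 0.75 * t.max(), 0.5):
            q, s, r = _piecewise_fit_once(t, psi, zc_try, None,
                                          continuity_weight)
            if r < best[0]:
                best = (r, zc_try, q, s)
        # fine local pass around the coarse winner
        for zc_try in best[1] + np.arange(-0.45, 0.46, 0.05):
            if zc_try <= 0:
                continue
            q, s, r = _piecewise_fit_once(t, psi, zc_try, None,
                                          continuity_weight)
            if r < best[0]:
                best = (r, zc_try, q, s)
        _, z_c, quartic, sig = best
    else:
        z_c = float(initial_zc)
        quartic, sig, _ = _piecewise_fit_once(t, psi, z_c, None,
                                              continuity_weight)

    quartic, sig, residual = _piecewise_fit_once(
        t, psi, z_c, sig, continuity_weight)
    converged = False
    for _ in range(max_iter):
        zc_prop = _quartic_critical_zc(quartic, 0.75 * t.max()) or z_c
        if abs(zc_prop - z_c) < zc_tol:
            converged = True
            break
        q2, s2, r2 = _piecewise_fit_once(
            t, psi, zc_prop, sig, continuity_weight)
        if r2 > residual:
            # a critical-point update that worsens the fit is noise-driven;
            # keep the current crossover (residual-guarded self-consistency)
            converged = True
            break
        z_c, quartic, sig, residual = zc_prop, q2, s2, r2
    if not converged:
        raise ProfileFitError(
            f"crossover depth did not stabilize after {max_iter} iterations "
            f"(last residual norm {residual:.3g})",
            residual=residual,
        )
    if np.allclose(quartic, 0.0) and np.allclose(psi, 0.0):
        warnings.warn(
            "degenerate flat profile: returning zero-amplitude parameters",
            stacklevel=2,
        )
    A1, A2, A3, A4 = (float(v) for v in sig)
    return LipidProfileParams(
        lipid_name=lipid_name,
        A1=A1, A2=A2, A3=A3, A4=A4,
        C1=float(quartic[0]), C2=float(quartic[1]), C3=float(quartic[2]),
        C4=float(quartic[3]), C5=float(quartic[4]),
        z_c=z_c,
        has_salt=has_salt,
        reference_depth=ref,
        fit_info={"residual_norm": residual},
    )


def _sigmoid_eval_vec(t, A1, A2, A3, A4):
    with np.errstate(over="ignore"):  # exp overflow → fraction → 0
        return A1 + (A1 - A2) / (
            1.0 + np.exp((np.asarray(t, dtype=float) - A3) / A4))


def _sigmoid_eval(params, t):
    return float(_sigmoid_eval_vec(np.asarray([t]), *params)[0])


def _sigmoid_guess(tt, pt, z_c):
    a1 = float(pt[-1]) if pt.size else 0.0
    near = float(np.interp(z_c, tt, pt)) if tt.size else 0.0
    # S(A3=z_c) = (3·A1 − A2)/2  →  A2 from the value at the crossover
    return [a1, 3.0 * a1 - 2.0 * near, z_c, 2.0]


def eval_profile(params: LipidProfileParams, z):
    """Referenced ΔΨ(z); thin functional wrapper over ``params.evaluate``."""
    return params.evaluate(z)
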