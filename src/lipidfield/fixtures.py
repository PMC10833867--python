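"""Synthetic fixtures emulating every external input the model consumes.

Nothing here is downloaded: bilayer charge-density grids are built as
charge-neutral Gaussian slab systems (zwitterionic head-group dipoles, with
an optional adsorbed counter-ion layer to exercise salt screening), peptide
sequences follow the standard model-peptide patterns (polyalanine, WALP,
designed poly-Leu), and design/ΔΔG tables are drawn from seeded random
generators.  All generators are deterministic for a given seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import io as lio
from .helix import polyalanine_sequence, polyleucine_sequence, walp_sequence
from .potential import ChargeDensityGrid, LipidProfileParams


def bilayer_density_grid(
    dims=(4, 4, 96),
    spacing=(2.0, 2.0, 1.0),
    head_charge_density: float = 2.0e-3,
    head_outer: float = 19.0,
    head_inner: float = 14.0,
    head_width: float = 2.0,
    with_salt: bool = False,
    salt_fraction: float = 0.5,
    noise: float = 0.0,
    seed: int = 0,
) -> ChargeDensityGrid:
    """Charge-neutral two-slab Gaussian bilayer density fixture.

    The lipid head-group region of each leaflet is a dipole of Gaussian
    charge sheets: positive charge (choline-like) centered at ±``head_outer``
    Å and the matching negative charge (phosphate-like) at ±``head_inner``
    Å, each integrating to the same total so the system is neutral.  With
    ``with_salt``, a counter-ion layer cancels ``salt_fraction`` of the
    outer sheet and redistributes it uniformly through the water region,
    mimicking adsorbed counter-ions screening the head groups.

    ``head_charge_density`` is the peak charge density in e/Å³.
    """
    dims = tuple(int(d) for d in dims)
    spacing = tuple(float(s) for s in spacing)
    nz = dims[2]
    z = (np.arange(nz) - nz // 2) * spacing[2]

    def sheet(center, sign):
        g = np.exp(-0.5 * ((z - center) / head_width) ** 2)
        g += np.exp(-0.5 * ((z + center) / head_width) ** 2)
        return sign * g / g.sum()  # unit total charge per unit area, signed

    # equal and opposite integrated charge: dipole per leaflet
    profile = head_charge_density * (
        sheet(head_outer, +1.0) + sheet(head_inner, -1.0)
    )
    lipid = np.broadcast_to(profile, dims).copy()

    salt = np.zeros(dims)
    if with_salt:
        # adsorbed counter-ion layers partially cancel each head-group
        # sheet (cations at the phosphate-like plane, anions at the
        # choline-like plane), screening the head-group dipole while
        # keeping the box exactly neutral
        screen = salt_fraction * head_charge_density * (
            sheet(head_inner, +1.0) + sheet(head_outer, -1.0)
        )
        salt = np.broadcast_to(screen, dims).copy()

    water = np.zeros(dims)
    if noise > 0:
        rng = np.random.default_rng(seed)
        w = rng.normal(0.0, noise * head_charge_density, size=dims)
        water = w - w.mean()  # keep exact neutrality

    return ChargeDensityGrid(dims, spacing, lipid, water, salt)


def make_profile_params(
    lipid_name: str = "FIXTURE",
    psi_core: float = 10.0,
    psi_head: float = 1.0,
    z_c: float = 17.0,
    a4: float = 2.0,
    has_salt: bool = False,
    reference_depth: float = 40.0,
) -> LipidProfileParams:
    """Self-consistent piecewise profile parameters for testing.

    Builds a quartic core whose largest critical point is exactly ``z_c``
    (C2 = C4 = 0, C3 = −2·C1·z_c²) and a sigmoid tail continuous with it at
    z_c, with core potential ``psi_core`` and head-region potential
    ``psi_head`` (both relative to bulk water).
    """
    c1 = (psi_core - psi_head) / z_c**4
    c3 = -2.0 * c1 * z_c**2
    c5 = psi_core
    q_zc = c1 * z_c**4 + c3 * z_c**2 + c5  # = psi_head
    a1 = 0.0  # tail decays to the water reference
    a2 = 3.0 * a1 - 2.0 * q_zc  # sigmoid passes through Q(z_c) at A3 = z_c
    return LipidProfileParams(
        lipid_name=lipid_name,
        A1=a1, A2=a2, A3=z_c, A4=a4,
        C1=c1, C2=0.0, C3=c3, C4=0.0, C5=c5,
        z_c=z_c, has_salt=has_salt, reference_depth=reference_depth,
    )


def synthetic_profile(params: LipidProfileParams, z_max: float = 48.0,
                      dz: float = 0.5, noise: float = 0.0, seed: int = 0):
    """Sampled (and optionally noisy) profile from analytical parameters."""
    from .potential import PotentialProfile1D

    z = np.arange(-z_max, z_max + 1e-9, dz)
    psi = params.evaluate(z)
    if noise > 0:
        rng = np.random.default_rng(seed)
        psi = psi + rng.normal(0.0, noise * np.ptp(psi), size=z.size)
    return PotentialProfile1D(z, psi, params.reference_depth)


def design_pair_set(n_pairs: int = 30, length: int = 60, seed: int = 0,
                    recovery: float = 0.4):
    """Seeded native/designed sequence pairs with region labels.

    Natives are uniform over the 20 canonical residues; each designed
    position keeps the native with probability ``recovery`` and otherwise
    mutates uniformly.  Region labels are drawn to mimic a membrane-spanning
    segment flanked by interface and aqueous stretches.
    """
    from .constants import AA20
    from .metrics import SequencePairSet

    rng = np.random.default_rng(seed)
    aas = np.array(list(AA20))
    pairs, regions = [], []
    for _ in range(n_pairs):
        nat = rng.choice(aas, size=length)
        keep = rng.random(length) < recovery
        mut = rng.choice(aas, size=length)
        des = np.where(keep, nat, mut)
        third = length // 3
        region = (["aqueous"] * third + ["interface"] * (third // 2)
                  + ["lipid"] * (length - third - third // 2 - third // 2)
                  + ["interface"] * (third // 2))
        region = region[:length] + ["aqueous"] * max(0, length - len(region))
        pairs.append(("".join(nat), "".join(des)))
        regions.append(region)
    return SequencePairSet(pairs, region_labels=regions)


def synthetic_ddg_table(n_points: int = 19, seed: int = 0,
                        weights=(1.0, 0.128, 0.01), noise: float = 0.0):
    """Per-mutation term matrix and ΔΔG values generated from known weights.

    Term columns are independent random draws with magnitudes typical of
    the three energy terms; the experimental column is their weighted sum
    (plus optional Gaussian noise).  Used for weight-fitting recovery.
    """
    rng = np.random.default_rng(seed)
    terms = np.column_stack([
        rng.normal(0.0, 3.0, n_points),     # transfer
        rng.normal(0.0, 5.0, n_points),     # lipid field
        rng.normal(0.0, 40.0, n_points),    # dielectric excess
    ])
    ddg = terms @ np.asarray(weights, dtype=float)
    if noise > 0:
        ddg = ddg + rng.normal(0.0, noise, n_points)
    return terms, ddg


def make_fixture(kind: str, out_dir, seed: int = 0, **params) -> list[Path]:
    """Write fixture files to ``out_dir``; deterministic per seed.

    kinds: polyala, walp, polyleu (FASTA); density-grid (TSV grid, one
    salt-free and one with counter-ions); design-pairs (two FASTA files and
    a region-label TSV); ddg-table (terms + experimental ΔΔG TSV).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _w(path):
        written.append(path)
        return path

    if kind == "polyala":
        x = int(params.get("length", 25))
        seq = polyalanine_sequence(x)
        lio.write_fasta({f"polyala_{x}": seq}, _w(out_dir / f"polyala_{x}.fasta"))
    elif kind == "walp":
        n = int(params.get("n", 8))
        seq = walp_sequence(n)
        lio.write_fasta({f"walp_{len(seq)}": seq},
                        _w(out_dir / f"walp_{len(seq)}.fasta"))
    elif kind == "polyleu":
        x = int(params.get("x", 5))
        flank = bool(params.get("flank_trp", False))
        seq = polyleucine_sequence(x, flank_trp=flank)
        lio.write_fasta({f"polyleu_{x}": seq},
                        _w(out_dir / f"polyleu_{x}.fasta"))
    elif kind == "density-grid":
        for tag, with_salt in (("nosalt", False), ("salt", True)):
            grid = bilayer_density_grid(with_salt=with_salt, seed=seed,
                                        **{k: v for k, v in params.items()
                                           if k != "with_salt"})
            lio.write_density_grid_tsv(grid, _w(out_dir / f"bilayer_{tag}.tsv"))
    elif kind == "design-pairs":
        pairs = design_pair_set(seed=seed, **params)
        lio.write_fasta({f"p{i}_nat": nat for i, (nat, _) in
                         enumerate(pairs.pairs)}, _w(out_dir / "native.fasta"))
        lio.write_fasta({f"p{i}_des": des for i, (_, des) in
                         enumerate(pairs.pairs)}, _w(out_dir / "designed.fasta"))
        with (_w(out_dir / "regions.tsv")).open("w") as fh:
            fh.write("pair\tposition\tregion\n")
            for i, labels in enumerate(pairs.region_labels):
                for j, lab in enumerate(labels):
                    fh.write(f"{i}\t{j}\t{lab}\n")
    elif kind == "ddg-table":
        terms, ddg = synthetic_ddg_table(seed=seed, **params)
        with (_w(out_dir / "ddg.tsv")).open("w") as fh:
            fh.write("transfer\tlipid_field\tdielec_excess\texperimental\n")
            np.savetxt(fh, np.column_stack([terms, ddg]), fmt="%.10g",
                       delimiter="\t")
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    manifest = out_dir / f"{kind}.manifest.json"
    manifest.write_text(json.dumps(
        {"kind": kind, "seed": seed,
         "params": {k: repr(v) for k, v in params.items()},
         "files": [p.name for p in written]}, indent=2))
    return written
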