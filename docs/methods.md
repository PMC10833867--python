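# Methods

This note records the model as implemented, the defaults and why they were
chosen, the numerical decisions that were genuinely open, and what the
synthetic fixtures do and do not establish.

## Bilayer potential profiles

**Poisson solve.** The electrostatic potential of an empty bilayer–water
system is obtained from per-voxel charge densities (lipid, water, salt; in
e/Å³) on a periodic 3D grid by solving `∇²Ψ = −4π·k_e·ρ` with the vacuum
permittivity and explicit charges — no Boltzmann/ionic-strength response;
salt enters only through its explicit charge density. The solver inverts
the *discrete* 7-point Laplacian in Fourier space (eigenvalues
`(2cos(2πn/N) − 2)/h²` per axis), so it agrees with a direct linear solve
of the discretized operator to machine precision rather than only to
discretization order. `k_e = 332.0637 Å·kcal·mol⁻¹·e⁻²` is the single
unit-conversion constant; potentials are kcal·mol⁻¹·e⁻¹ throughout
(1 V = 23.061 kcal·mol⁻¹·e⁻¹). Gauge: the k = 0 mode is set to zero, and
profiles are subsequently re-referenced. A uniform neutralizing background
for slightly non-neutral grids is available but opt-in; by default a
non-neutral grid is an error.

Sign convention: the Poisson equation is implemented with the standard
minus sign (charge density as a source). Referencing to bulk water makes
all scored quantities differences, so only the global sign of Ψ depends on
this choice.

**Lateral averaging and referencing.** Ψ(z) is the x,y-mean of the volume;
the profile is pinned to zero at the grid point nearest the reference depth
(default 40 Å, bulk water). Referencing is idempotent.

**Piecewise analytical form.** The depth profile is condensed to

```
Ψ̃(z) = A1 + (A1 − A2)/(1 + exp((|z| − A3)/A4))    |z| ≥ z_c
Ψ̃(z) = C1|z|⁴ + C2|z|³ + C3|z|² + C4|z| + C5       |z| < z_c
```

a function of |z| only (bilayers are treated as symmetric; profiles are
symmetrized by averaging Ψ(z) and Ψ(−z) before fitting). With A4 > 0 the
|z| → ∞ asymptote of the sigmoid branch is A1. Evaluation subtracts the
sigmoid value at the reference depth and clamps to exactly zero for
|z| ≥ reference depth: bulk water is the model's zero of lipid-field
energy by definition, which makes aqueous reference states exact at the
cost of a discontinuity of order (A1 − A2)·e^(−(ref−A3)/A4) (≈10⁻⁵ of the
amplitude for typical parameters).

**Fitting.** z_c is defined as the largest positive critical point of the
quartic core. The fit first scans candidate crossover depths (0.5 Å grid,
then a 0.05 Å local pass) keeping the candidate with the lowest piecewise
residual, then polishes by self-consistency: fit the quartic on the core
window with a soft continuity pseudo-observation at z_c (weight 100× a
data point), recompute z_c from the quartic's critical points, refit the
sigmoid tail, and repeat until z_c is stable to 0.01 Å (≤50 iterations).
Critical-point updates that *worsen* the residual are rejected — on noisy
data the largest critical point of a refitted quartic occasionally jumps
to a spurious root far outside the head-group region, and the residual
guard suppresses exactly those excursions. A flat profile degenerates to
zero-amplitude parameters with a warning; failure of z_c to stabilize
raises an error carrying the last residual norm.

*Limitation:* under additive noise the crossover depth is weakly
identified — the residual valley around z_c is shallow, and at 1% noise
the recovered z_c is typically within ~0.3 Å of truth but can deviate by
1–2 Å for unlucky noise realizations. Exact (noise-free) profiles are
recovered essentially exactly.

**Shipped profile table.** `data/lipid_profiles.tsv` holds *synthetic
placeholder* parameters for DLPC/DLPE/DLPG/DPPC/DOPC/POPC (labeled as such
in the header) with qualitatively reasonable trends: PE above PC (smaller
head group, higher local charge density), PG screened by counter-ions,
longer tails shifting the crossover outward. Users supply their own fitted
table for quantitative work; the file format is the exchange contract.

## Membrane frame and hydration

The membrane normal is +z with the bilayer center at z = 0 (structures are
assumed pre-oriented, OPM-style; an optional re-centering flag exists in
the reader). Hydration uses a logistic in normalized depth,
`f = uⁿ/(1+uⁿ)` with `u = |z|/half_thickness` (default 15 Å) and
`n = steepness` (default 10), chosen because it is smooth, monotone, hits
f(0) = 0 and f → 1 in bulk water, and puts f = 0.5 at the hydrophobic
boundary. This is a stand-in for surface-based hydration measures: it has
no cavity or neighbor-burial term, so every atom at the same depth is
equally hydrated. Pore exposure f_pore is an input (default 0 — single
helices have no pore) and acts through `f_hyd = max(f_depth, f_pore)`.
Pair hydration is the geometric mean √(f_i·f_j).

Region labels for design metrics: lipid (f_hyd < 0.25 ∧ f_pore < 0.5),
interface (0.25 ≤ f_hyd < 0.75 ∧ f_pore < 0.5), aqueous otherwise. The
boundary and gap cases (f_hyd = 0.75 exactly; pore-facing but weakly
hydrated) are resolved toward aqueous, because pore-facing residues see
water regardless of depth; with this resolution the classification is
total on [0,1]².

## Transfer-energy scales

Per-amino-acid water-to-bilayer energies are distributed onto atom types by
least squares on `A·x = g`, where A counts atom types per residue. The
default typing distinguishes backbone N/CA/C/O, aliphatic CH₃/CH₂/CH₁,
aromatic carbon, hydroxyl/amide/ring nitrogens and oxygens, sulfur,
amine/guanidinium nitrogens, and the carboxylate carbon (COO) and oxygen
(OOC) as separate types. This vocabulary is deliberately coarse and
rank-deficient (amide N/O co-occur in fixed ratios), so the minimum-norm
solution is returned with a warning; recomposed per-residue energies are
unaffected by the null-space ambiguity.

Neutral-pH Asp/Glu: the bilayer-context (MF-type) scale cannot measure the
deprotonated side chains near their pKa, so their values are extrapolated
through the ordinary least-squares line of MF on WW (octanol) values over
shared residues — by default excluding the Ala host, Pro, and the low-pH
Asp/Glu points, all caller-overridable — applied to the octanol values of
the charged forms. Appending the two extra stoichiometry rows and
re-solving renews the carboxylate types while consistent rows keep their
exact solutions.

The shipped scale table is an editable convenience transcription; every
test and derived quantity uses synthetic scales or recomputes from the
table at run time, so nothing in the package's correctness rests on the
transcription.

## Energy terms

**Dielectric.** Distance dependence uses the standard screened sigmoid
`ε(r) = ε_s − (ε_s − ε_c)·((σr)² + 2σr + 2)·e^(−σr)/2` with σ = 1.2 Å⁻¹
(configurable); any monotone sigmoid with the same endpoints satisfies the
model contract. Solution endpoints (6, 80), membrane endpoints (3, 10).
The pair dielectric is the hydration-weighted linear mixture, and the
excess term subtracts the same truncated Coulomb form evaluated with the
*solution* sigmoid ε_sol(r) — interpreted this way rather than a constant
80, so that the term is exactly zero for any fully hydrated pair at any
distance. C0 = 322 Å·kcal·mol⁻¹·e⁻², truncation r_max = 5.5 Å, r = 0 is a
clash error.

**Pair list.** Pairs within r_max are found once per structure with a k-d
tree on canonical coordinates and reused across all rigid placements
(distances, charge products, and both dielectric sigmoids are
placement-invariant; only pair hydration varies). Pairs within the same or
adjacent residues are excluded as bonded neighbors; the model has no bond
graph, and at r_max = 5.5 Å this residue-level exclusion is the coarse
equivalent of the usual 1-4 exclusions. Pair energies are attributed half
to each partner residue in the per-residue ledger, so ledger columns sum
exactly to totals. Energies are reported in kcal/mol, treated as
numerically interchangeable with Rosetta energy units.

**Charges.** The embedded fixed-charge set collapses hydrogen charges onto
their bound heavy atoms (CHARMM36-like grouping; every residue sums to its
formal charge; Asp/Glu deprotonated). Charged termini add +1 e to the
N-terminal nitrogen and −1 e to the C-terminal carbonyl oxygen (default
for built helices; a neutral-cap option exists). A user table of the same
schema overrides all of this.

**Weight fitting.** Weights are constrained to [0, 1] and fitted by
maximizing the Pearson correlation between predicted combined scores and
experimental ΔΔG with L-BFGS-B from 8 seeded multi-starts. Correlation is
scale-free, so the optimum is a ray: the returned triple is one
representative within the bounds, and correlation — not the weight values —
is the recovery contract. Degenerate inputs (constant experimental vector,
all-zero terms, <4 points) are errors.

## Orientation sampling

Ideal helices are built atom-by-atom (NeRF) with φ = −57°, ψ = −47°,
ω = 180° and Engh–Huber-style bond geometry; side chains are grafted from
ideal-coordinate residue templates superimposed on each N/CA/C frame — a
fixed default conformer with no packing, a stated simplification relative
to rotamer optimization. The finished helix is stored in canonical
coordinates (principal axis of the CA trace along +z, oriented N→C,
centroid at origin); a placement (d, θ, φ) is spin about the axis, tilt
about y, then translation to depth d — a pure rigid motion regenerated
from canonical coordinates each time, so transforms never accumulate
error.

The default grid is ±60 Å depth / ±180° tilt / 0–360° rotation at
(2 Å, 5°, 15°) steps — 106,872 poses, which the vectorized depth-batch
scorer path evaluates in a few seconds for a 23-residue helix — with an
optional refinement pass at (0.5 Å, 1°, 5°) around the coarse argmin. The
argmin tie-break is lexicographic on (|d|, folded tilt, rotation, then the
signed values) and deterministic; tilt angles are reported folded to
[0°, 90°] to match experimental conventions. The fast path is only engaged
when no baseline scorer is attached; with a baseline, every pose is scored
through the generic callable.

ΔΔG protocols: the "aqueous phase" of both the insertion and the mutation
protocol is operationalized as placements with every membrane term zero —
|d| ≥ 40 Å grid points for insertion (the unfolded-reference energy
cancels in the double difference and is reported as zero), and a
dynamically chosen depth placing all atoms beyond 40 Å for mutation. The
water state is thus folded-in-water, not an unfolded chain; for
membrane-only scorers the distinction is immaterial because both water
energies vanish. Mutations are fixed-backbone and fixed-orientation:
the mutant side chain is template-grafted onto the existing backbone
frame, and a self-mutation returns the identical structure (ΔΔG exactly
zero).

## Design metrics

Sequence recovery, amino-acid distributions, K-L divergence, confusion
matrices p(designed s | native r), and per-residue perplexity
`2^(−Σ p log₂ p)` are computed over position sets optionally filtered by
region or burial labels. Perplexity uses base-2 logs (so the value reads
as an effective number of residue choices, 1–20); the divergence uses
natural logs by default (configurable — printed divergence values in the
literature rarely pin the base). Zero-probability handling: 0·log 0 = 0
inside D_KL; per-residue D_s is undefined (NaN, excluded from the sum D
with a warning) where either distribution has no mass, rather than
pseudo-counted; designed mass where the native distribution has none makes
D_KL infinite (reported as missing in the JSON report). Confusion rows for
never-occurring native residues are flagged undefined rather than fatal.

## Synthetic fixtures: what they establish

The density fixture is a charge-neutral two-sheet Gaussian dipole per
leaflet (choline-like positive sheet outside a phosphate-like negative
sheet); the salt variant adds adsorbed counter-ion layers canceling a
fraction f of *both* sheets, giving |ΔΨ(0)| exactly (1−f) of the salt-free
value. This exercises the solver, referencing, fitting, and the
salt-screening property, but it is not an MD-derived density: it has no
carbonyl/water dipole structure, no ionic diffuse layer, and no thermal
roughness, so passing tests demonstrate correctness of the machinery, not
realism of any particular ΔΨ amplitude. Likewise the design-pair fixture
draws natives uniformly over residue types with a fixed per-position
recovery probability — it validates the counting and the identities, not
any claim about real design output. Sequence fixtures follow the standard
model-peptide patterns: AAₓ polyalanine, GWW(LA)ₙLWWA, and G Lₓ R Lₓ G
poly-Leu (with an optional flanking-Trp variant).

All generators are deterministic given a seed; fixture directories include
a manifest recording kind, seed, and parameters.

## Problem sizes used in the checks

Solver-oracle equivalence uses dense solves on ≤12³ grids (the dense
operator is the memory bound, not the FFT); profile recovery uses a
±48 Å, 0.5 Å profile; the sampler checks use a 23-residue WALP helix with
the full default grid for the cost check and small grids for the oracle
comparisons; weight recovery uses 19 synthetic measurements (one per
non-host mutation in a typical host-guest scan) and 8 multi-starts.
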