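"""Physical constants and unit conventions.

Internal unit system: lengths in Å, charges in elementary charges (e),
energies in kcal/mol, electrostatic potentials in kcal·mol⁻¹·e⁻¹.
"""

#: Coulomb constant 1/(4π ε0) in Å·kcal·mol⁻¹·e⁻², used once to convert the
#: Poisson-solver output from (e/Å) Gaussian units into kcal·mol⁻¹·e⁻¹.
#: Equivalent to the statement 1 V = 23.061 kcal·mol⁻¹·e⁻¹.
COULOMB_CONSTANT_FULL = 332.0637

#: Truncated-Coulomb prefactor used by the pairwise dielectric score term,
#: in Å·kcal·mol⁻¹·e⁻² (the rounded value conventional in Rosetta-style
#: score functions, distinct from the exact constant above).
COULOMB_CONSTANT_SCORE = 322.0

#: Volts to kcal·mol⁻¹·e⁻¹.
VOLT_TO_KCAL_PER_MOL_E = 23.061

#: Default depth (Å) at which the bilayer potential is pinned to zero
#: (bulk water reference).
DEFAULT_REFERENCE_DEPTH = 40.0

#: The 20 canonical amino acids, one-letter codes, alphabetical.
AA20 = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Extended codes for deprotonated (neutral-pH) aspartate and glutamate,
#: whose water-to-bilayer transfer energies are extrapolated, not measured.
ASP_DEPROT = "D1"
GLU_DEPROT = "E1"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
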