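"""Nuclear and molecular constants used across the toolkit.

Coherent neutron scattering lengths are the bound-atom values from the
standard Sears compilation, in femtometres.  Displaced (excluded) atomic
volumes follow the Fraser--MacRae--Suzuki convention used by solution
scattering codes.  Scattering-length densities (SLD) are expressed in
A^-2 throughout; 1 fm / A^3 = 1e-5 A^-2.
"""

from __future__ import annotations

# fm; 1 fm = 1e-5 A
COHERENT_B_FM: dict[str, float] = {
    "H": -3.7390,
    "D": 6.671,
    "C": 6.6460,
    "N": 9.36,
    "O": 5.803,
    "S": 2.847,
    "P": 5.13,
}

#: conversion factor fm/A^3 -> A^-2
FM_PER_A3_TO_SLD = 1.0e-5

#: displaced volume per atom, A^3 (heavy atoms carry their own volume;
#: bound hydrogens add V_H each)
DISPLACED_VOLUME_A3: dict[str, float] = {
    "H": 5.15,
    "D": 5.15,
    "C": 16.44,
    "N": 2.49,
    "O": 9.13,
    "S": 19.86,
    "P": 5.73,
}

#: van der Waals radii, A (surface construction)
VDW_RADIUS_A: dict[str, float] = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}

#: volume of one water molecule, A^3
WATER_VOLUME_A3 = 30.0

#: side-chain labile (exchangeable) hydrogens per residue, attached to the
#: named heavy atom; backbone amide N-H handled separately (1 per residue,
#: 0 for proline).
SIDECHAIN_LABILE_H: dict[str, dict[str, int]] = {
    "SER": {"OG": 1},
    "THR": {"OG1": 1},
    "TYR": {"OH": 1},
    "LYS": {"NZ": 3},
    "ARG": {"NE": 1, "NH1": 2, "NH2": 2},
    "ASN": {"ND2": 2},
    "GLN": {"NE2": 2},
    "HIS": {"NE2": 1},
    "TRP": {"NE1": 1},
    "CYS": {"SG": 1},
}

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# ---------------------------------------------------------------------------
# Reference monomer formulas for biomolecular classes.
#
# Each class is represented by a per-monomer elemental formula (heavy atoms
# and non-labile H), a labile-H count, and a monomer volume in A^3.  These
# are standard average compositions: the mean amino-acid residue, the mean
# ribonucleotide, a POPC-like phospholipid, an anhydroglucose unit, a small
# organic metabolite, and a phosphate-like inorganic unit.
# ---------------------------------------------------------------------------

CLASS_FORMULAS: dict[str, dict] = {
    "protein": {
        "heavy": {"C": 4.92, "N": 1.36, "O": 1.46, "S": 0.04},
        "h_nonlabile": 6.06,
        "h_labile": 1.70,
        "volume_a3": 133.0,   # v_bar ~ 0.73 cm3/g at 110 Da
    },
    "nucleic_acid": {
        "heavy": {"C": 9.5, "N": 3.75, "O": 6.75, "P": 1.0},
        "h_nonlabile": 9.75,
        "h_labile": 1.25,
        "volume_a3": 310.0,   # v_bar ~ 0.55 cm3/g at 340 Da
    },
    "lipid": {
        "heavy": {"C": 42.0, "N": 1.0, "O": 8.0, "P": 1.0},
        "h_nonlabile": 82.0,
        "h_labile": 0.0,
        "volume_a3": 1265.0,  # POPC molecular volume
    },
    "carbohydrate": {
        "heavy": {"C": 6.0, "O": 5.0},
        "h_nonlabile": 7.0,
        "h_labile": 3.0,
        "volume_a3": 164.0,   # anhydroglucose, v_bar ~ 0.61 cm3/g
    },
    "other_organic": {
        "heavy": {"C": 4.92, "N": 1.36, "O": 1.46, "S": 0.04},
        "h_nonlabile": 6.06,
        "h_labile": 1.70,
        "volume_a3": 133.0,   # treated as protein-like metabolites
    },
    "inorganic": {
        "heavy": {"P": 1.0, "O": 4.0},
        "h_nonlabile": 0.0,
        "h_labile": 0.0,
        "volume_a3": 55.0,    # phosphate-like ion
    },
}

#: E. coli dry-matter mass fractions (% w/w of whole cell); the remainder
#: is water.  Renormalised over non-water classes when used as a debris
#: composition.
ECOLI_MASS_PERCENT = {
    "protein": 15.0,
    "nucleic_acid": 7.0,
    "lipid": 2.0,
    "carbohydrate": 3.0,
    "other_organic": 1.0,
    "inorganic": 1.0,
}
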