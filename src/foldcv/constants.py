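"""Physical constants, stereochemistry defaults and the category reference table.

The secondary-structure category table holds survey statistics (mean and
sample s.d. of the residue folding degree and of the phi/psi angles) for the
nine DSSP 4 categories H, G, I, E, B, T, S, P, C.  These are used as
characteristic per-category reference values for the relative folding-degree
collective variable.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Molar gas constant, J mol^-1 K^-1 (CODATA 2018, exact).
GAS_CONSTANT = 8.31446261815324

#: Thermochemical calorie, J.
CALORIE = 4.184

#: The nine secondary-structure categories used throughout.
SS_CATEGORIES = ("H", "G", "I", "E", "B", "T", "S", "P", "C")

# Standard peptide backbone stereochemistry (Engh-Huber-like), used by the
# synthetic backbone builder.  Lengths in Angstrom, angles in degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7

#: Maximum C(i)-N(i+1) distance (Angstrom) for two residues to count as
#: covalently linked; beyond this the chain is treated as broken.
CHAIN_BREAK_CN = 2.5


def _load_category_table() -> pd.DataFrame:
    with resources.files("foldcv.data").joinpath("ss_category_rcs.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.set_index("category")


#: Per-category folding-degree and dihedral survey statistics (DSSP 4).
CATEGORY_TABLE: pd.DataFrame = _load_category_table()
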