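"""Packaged reference summary data.

`conservation_reference` returns the published class-level conservation
summary from a genome-scale survey of ligand-binding sites across 18
primate species (~4200 one-to-one orthogroups): the number of alignment
columns per site class and the percentage of them that are fully
conserved.  These summary counts let the class-comparison statistics be
recomputed exactly at desk scale without the underlying sequence
databases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_REFERENCE = [
    # class, n_sites, percent_conserved
    ("other", 2_588_980, 77.26),
    ("other_within_domain", 1_082_970, 84.63),
    ("ligand_binding", 67_823, 89.23),
    ("DNA", 20_105, 91.22),
    ("RNA", 4_668, 93.38),
    ("small_molecule", 14_134, 88.96),
    ("ion", 22_771, 87.95),
    ("peptide", 12_639, 88.96),
]


def conservation_reference() -> pd.DataFrame:
    """Class-level site counts and percent fully conserved (published survey).

    ``n_conserved`` is reconstructed from the printed percentage at the
    precision given (two decimals), rounded to the nearest integer.
    """
    frame = pd.DataFrame(
        _REFERENCE, columns=["class", "n_sites", "percent_conserved"]
    ).set_index("class")
    frame["n_conserved"] = np.rint(
        frame["n_sites"] * frame["percent_conserved"] / 100.0
    ).astype(np.int64)
    return frame


def percent_variable_by_ligand(ndigits: int = 2) -> pd.Series:
    """Percent of sites per ligand class with variation across primates.

    The complement of the conserved percentage, rounded to two
    significant figures as conventionally reported.
    """
    ref = conservation_reference()
    ligands = ["DNA", "RNA", "small_molecule", "ion", "peptide"]
    variable = 100.0 - ref.loc[ligands, "percent_conserved"]

    def _round_sig(x: float) -> float:
        if x == 0:
            return 0.0
        from math import floor, log10

        return round(x, ndigits - 1 - floor(log10(abs(x))))

    return variable.apply(_round_sig).rename("percent_variable")
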