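"""Published observed counts used as analysis inputs.

These are the printed summary data of the tongue-sole sex-reversal studies:
the two-locus validation cohort of 259 genetic females, and the ZW/ZZ
offspring counts of a pseudomale sire used in the W-sperm transmission test.
"""

from __future__ import annotations

import pandas as pd

#: Validation-cohort cell counts: (g1 allele at the first causal locus,
#: g2 genotype at the second, observed phenotype) -> number of fish.
VALIDATION_COHORT_CELLS: dict[tuple[str, str, str], int] = {
    ("A", "GG", "female"): 91,
    ("T", "GG", "female"): 123,
    ("A", "AA", "female"): 0,
    ("T", "AA", "pseudomale"): 39,
    ("A", "AG", "female"): 1,
    ("T", "AG", "pseudomale"): 5,
}

#: Offspring of a pseudomale (ZW) sire: 24 genetic females (ZW) and
#: 22 genetic males (ZZ).
PSEUDOMALE_OFFSPRING: dict[str, int] = {"ZW": 24, "ZZ": 22}


def validation_cohort() -> pd.DataFrame:
    """Expand the validation-cohort cells into one record per fish.

    Returns a DataFrame with columns ``g1``, ``g2``, ``phenotype``
    (259 rows).
    """
    rows = []
    for (g1, g2, phenotype), n in VALIDATION_COHORT_CELLS.items():
        rows.extend({"g1": g1, "g2": g2, "phenotype": phenotype} for _ in range(n))
    return pd.DataFrame(rows, columns=["g1", "g2", "phenotype"])
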