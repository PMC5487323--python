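"""Small bundled reference tables.

``hpo_dmc_counts`` carries the published per-feature site and DMC
tallies from the porcine hypothalamus-pituitary-ovary (HPO) RRBS
methylome comparison: the number of detected CpGs per genomic feature
and the number of differentially methylated CpGs per feature for each
pairwise tissue comparison. These marginal counts are inputs for the
desk-scale enrichment arithmetic (the full per-site data lives in a
public sequence archive and is not needed for it).
"""

from __future__ import annotations

import pandas as pd

#: total detected CpGs (covered >= 5x in all nine libraries, all tissues)
HPO_TOTAL_DETECTED_CPGS = 1_403_700

#: total DMCs per pairwise comparison
HPO_TOTAL_DMCS = {
    "hypothalamus_vs_pituitary": 14_744,
    "hypothalamus_vs_ovary": 33_809,
    "pituitary_vs_ovary": 29_759,
}

_ROWS = [
    # feature, detected CpGs, DMCs H-vs-P, DMCs H-vs-O, DMCs P-vs-O
    ("cgi", 556_039, 3_509, 7_313, 7_612),
    ("shore", 294_560, 3_452, 8_044, 7_391),
    ("shelf", 98_913, 1_262, 3_383, 2_493),
    ("upstream", 175_419, 1_189, 2_308, 2_529),
    ("exon", 228_324, 1_340, 2_848, 2_661),
    ("intron", 369_473, 4_359, 9_303, 7_838),
    ("downstream", 89_868, 919, 2_114, 1_706),
    ("intergenic", 540_616, 6_937, 17_236, 15_025),
]


def hpo_dmc_counts() -> pd.DataFrame:
    """Per-feature detected-CpG and DMC counts of the HPO comparison."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "feature",
            "detected",
            "dmcs_hypothalamus_vs_pituitary",
            "dmcs_hypothalamus_vs_ovary",
            "dmcs_pituitary_vs_ovary",
        ],
    )
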