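"""Bundled example data: published overlap counts and screen p-values.

Two small tables from a published Drosophila study of the steroid
mifepristone are shipped as plain Python data so the statistics can be
exercised on real printed numbers without any download.

``stress_overlap_counts`` gives, for each of 34 comparisons, the size of a
mifepristone-regulated gene list ("Mf", 45 genes in virgin females, 100 in
mated), the size of a published stress-response gene list, and their overlap,
all on a shared background of 13,964 genes. These are inputs for the
two-set overlap statistics (expected overlap, over/under fold, hypergeometric
tail).

``tf_score_p_blocks`` gives the top score p-values printed for four query
lists of a 445-TF ChIP-seq target-enrichment screen. These are inputs for
the multiple-testing corrections with explicit family size m = 445 (the
supplied values are the smallest of the family).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "stress_overlap_counts",
    "tf_score_p_blocks",
    "TF_FAMILY_SIZE",
    "BACKGROUND_SIZE",
]

BACKGROUND_SIZE = 13_964
TF_FAMILY_SIZE = 445

# (group, stress label, n_mf, n_stress, overlap)
_STRESS_ROWS = [
    ("virgin", "Landis aging", 45, 1470, 15),
    ("virgin", "Landis O2", 45, 897, 12),
    ("virgin", "Landis H2O2", 45, 1641, 11),
    ("virgin", "Landis heat", 45, 1566, 16),
    ("virgin", "Landis IR 907 Gy", 45, 1388, 9),
    ("virgin", "Moskalev cold 4C", 45, 869, 10),
    ("virgin", "Moskalev IR 144 Gy", 45, 195, 3),
    ("virgin", "Moskalev starvation", 45, 79, 2),
    ("virgin", "Dobson DR", 45, 442, 17),
    ("virgin", "Dobson rapa", 45, 350, 14),
    ("virgin", "Gershman yeast feeding", 45, 631, 4),
    ("virgin", "Mack mating", 45, 545, 3),
    ("virgin", "Wang tubule expression", 45, 1315, 5),
    ("virgin", "King-Jones PB", 45, 828, 17),
    ("virgin", "King-Jones PB DHR96 mutant", 45, 503, 9),
    ("virgin", "Zimmerman sleep", 45, 44, 4),
    ("virgin", "Deng rox deficiency males", 45, 3464, 20),
    ("mated", "Landis aging", 100, 1470, 27),
    ("mated", "Landis O2", 100, 897, 27),
    ("mated", "Landis H2O2", 100, 1641, 29),
    ("mated", "Landis heat", 100, 1566, 31),
    ("mated", "Landis IR 907 Gy", 100, 1388, 21),
    ("mated", "Moskalev cold 4C", 100, 869, 34),
    ("mated", "Moskalev IR 144 Gy", 100, 195, 9),
    ("mated", "Moskalev starvation", 100, 79, 1),
    ("mated", "Dobson DR", 100, 442, 39),
    ("mated", "Dobson rapa", 100, 350, 34),
    ("mated", "Gershman yeast feeding", 100, 631, 7),
    ("mated", "Mack mating", 100, 545, 2),
    ("mated", "Wang tubule expression", 100, 1315, 15),
    ("mated", "King-Jones PB", 100, 828, 35),
    ("mated", "King-Jones PB DHR96 mutant", 100, 503, 17),
    ("mated", "Zimmerman sleep", 100, 44, 4),
    ("mated", "Deng rox deficiency", 100, 3464, 42),
]

# per query list: printed (tf, score_p) pairs, smallest first; family m = 445
_TF_SCORE_P = {
    "mated_plus_vs_minus": [
        ("prd", 0.0),
        ("exex", 0.000013),
    ],
    "mated_vs_virgin_down": [
        ("psq", 0.000001),
        ("Sin3A", 0.000002),
        ("Stat92E", 0.000002),
        ("YL-1", 0.000004),
        ("gfzf", 0.000008),
        ("Sry-delta", 0.00001),
        ("M1BP", 0.000017),
        ("HmgD", 0.000021),
        ("CG4617", 0.000024),
        ("Crg-1", 0.000034),
        ("Dif", 0.000042),
        ("Clamp", 0.000054),
        ("CG1620", 0.000058),
        ("ovo", 0.000067),
    ],
    "mated_vs_virgin_up": [
        ("exex", 0.0),
        ("prd", 0.0),
        ("grn", 0.000015),
    ],
    "virgin_plus_vs_minus": [
        ("prd", 0.012),
        ("exex", 0.07),
        ("cic", 0.447),
        ("cnc", 0.316),
    ],
}


def stress_overlap_counts() -> pd.DataFrame:
    """34 published overlap comparisons on a 13,964-gene background.

    Columns: group, label, total, n_a (mifepristone list), n_b (stress list),
    overlap.
    """
    return pd.DataFrame(
        _STRESS_ROWS, columns=["group", "label", "n_a", "n_b", "overlap"]
    ).assign(total=BACKGROUND_SIZE)[
        ["group", "label", "total", "n_a", "n_b", "overlap"]
    ]


def tf_score_p_blocks() -> dict[str, list[tuple[str, float]]]:
    """Printed top score p-values per query list of the 445-TF screen."""
    return {k: list(v) for k, v in _TF_SCORE_P.items()}
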