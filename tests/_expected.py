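"""Frozen published results used as expected values.

Each overlap row: (group, label, direction, fold printed to 2 dp,
printed p, how to compare the p-value). Comparison modes:
  "rel"      — printed at >=3 significant figures; 1% relative tolerance
  "abs4"     — printed rounded to 4 decimals; absolute tolerance 5e-5
  "mantissa" — the printed exponent is a known typo; compare the mantissa
               to 3 significant figures and require p below the printed
               mantissa's plausible range ceiling
The expected folds/p's were verified against independent exact arithmetic
(fractions + scipy.stats.hypergeom) before freezing.
"""

OVERLAP_EXPECTED = [
    ("virgin", "Landis aging", "over", 3.17, 3.25e-5, "rel"),
    ("virgin", "Landis O2", "over", 4.15, 1.83e-5, "rel"),
    ("virgin", "Landis H2O2", "over", 2.08, 0.0132, "rel"),
    ("virgin", "Landis heat", "over", 3.17, 1.56e-5, "rel"),
    ("virgin", "Landis IR 907 Gy", "over", 2.01, 0.0306, "rel"),
    ("virgin", "Moskalev cold 4C", "over", 3.57, 0.0004, "abs4"),
    ("virgin", "Moskalev IR 144 Gy", "over", 4.77, 0.0248, "rel"),
    ("virgin", "Moskalev starvation", "over", 7.86, 0.0267, "rel"),
    ("virgin", "Dobson DR", "over", 11.94, 1.16e-14, "rel"),
    ("virgin", "Dobson rapa", "over", 12.41, 2.46e-12, "rel"),
    ("virgin", "Gershman yeast feeding", "over", 1.97, 0.1445, "rel"),
    ("virgin", "Mack mating", "over", 1.71, 0.2562, "rel"),
    ("virgin", "Wang tubule expression", "over", 1.18, 0.4197, "rel"),
    ("virgin", "King-Jones PB", "over", 6.37, 2.70e-10, "rel"),
    ("virgin", "King-Jones PB DHR96 mutant", "over", 5.55, 2.65e-5, "rel"),
    ("virgin", "Zimmerman sleep", "over", 28.21, 1.16e-5, "rel"),
    ("virgin", "Deng rox deficiency males", "over", 1.79, 0.0031, "rel"),
    ("mated", "Landis aging", "over", 2.56, 2.95e-6, "rel"),
    ("mated", "Landis O2", "over", 4.20, 9.24e-11, "rel"),
    ("mated", "Landis H2O2", "over", 2.47, 2.452e-6, "rel"),
    ("mated", "Landis heat", "over", 2.76, 7.52e-8, "rel"),
    ("mated", "Landis IR 907 Gy", "over", 2.11, 0.0007, "abs4"),
    ("mated", "Moskalev cold 4C", "over", 5.46, 5.93e-17, "rel"),
    ("mated", "Moskalev IR 144 Gy", "over", 6.44, 1.07e-5, "rel"),
    ("mated", "Moskalev starvation", "over", 1.77, 0.4341, "rel"),
    ("mated", "Dobson DR", "over", 12.32, 9.65e-33, "rel"),
    ("mated", "Dobson rapa", "over", 13.57, 9.78e-30, "rel"),
    ("mated", "Gershman yeast feeding", "over", 1.55, 0.1662, "rel"),
    ("mated", "Mack mating", "under", 1.95, 0.2458, "rel"),
    ("mated", "Wang tubule expression", "over", 1.59, 0.0471, "rel"),
    ("mated", "King-Jones PB", "over", 5.90, 1.54, "mantissa"),
    ("mated", "King-Jones PB DHR96 mutant", "over", 4.72, 9.25e-8, "rel"),
    ("mated", "Zimmerman sleep", "over", 12.69, 0.0003, "abs4"),
    ("mated", "Deng rox deficiency", "over", 1.69, 0.0001, "abs4"),
]

# published adjusted score p-values per screen block (family m = 445),
# aligned with tfenrich.datasets.tf_score_p_blocks ordering:
# tf -> (bh printed, bonferroni printed) as printed strings
ADJUSTED_EXPECTED = {
    "mated_plus_vs_minus": {
        "prd": ("0", "0"),
        "exex": ("0.0028925", "0.005785"),
    },
    "mated_vs_virgin_down": {
        "psq": ("0.000297", "0.000445"),
        "Sin3A": ("0.000297", "0.00089"),
        "Stat92E": ("0.000297", "0.00089"),
        "YL-1": ("0.000445", "0.00178"),
        "gfzf": ("0.000712", "0.00356"),
        "Sry-delta": ("0.000742", "0.00445"),
        "M1BP": ("0.001081", "0.007565"),
        "HmgD": ("0.001168", "0.009345"),
        "CG4617": ("0.001187", "0.01068"),
        "Crg-1": ("0.001513", "0.01513"),
        "Dif": ("0.001699", "0.01869"),
        "Clamp": ("0.001985", "0.02403"),
        "CG1620": ("0.001985", "0.02581"),
        "ovo": ("0.00213", "0.029815"),
    },
    "mated_vs_virgin_up": {
        "exex": ("0", "0"),
        "prd": ("0", "0"),
        "grn": ("0.002225", "0.006675"),
    },
}


def matches_printed(value: float, printed: str) -> bool:
    """True when `value` rounds to the printed decimal string."""
    if "." not in printed:
        return value == float(printed)
    decimals = len(printed.split(".")[1])
    return abs(value - float(printed)) <= 0.5 * 10 ** (-decimals) + 1e-15
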