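"""Published per-cohort diplotype frequency tables, shipped as data.

These are the star-allele diplotype block (with CPIC-style phenotype
assignments) and the combined CYP2C19-CYP2C diplotype block (with the
combined-scheme assignments) for the four study cohorts.  They serve as
printed inputs for phenotype-translation checks and as regression
fixtures; they are not computed by this package.
"""

from __future__ import annotations

from .naming import MERGED_CG_TA

COHORT_SIZES = {"1kg_nat": 68, "hgdp": 61, "kaingang": 54, "guarani": 33}

# Star-allele diplotype frequencies (CPIC-scheme input).
STAR_DIPLOTYPE_FREQS: dict[str, dict[tuple[str, str], float]] = {
    "1kg_nat": {
        ("*1", "*1"): 0.838,
        ("*1", "*2"): 0.118,
        ("*2", "*17"): 0.015,
        ("*1", "*17"): 0.029,
    },
    "hgdp": {
        ("*1", "*1"): 0.885,
        ("*1", "*2"): 0.115,
        ("*2", "*17"): 0.0,
        ("*1", "*17"): 0.0,
    },
    "kaingang": {
        ("*1", "*1"): 1.0,
        ("*1", "*2"): 0.0,
        ("*2", "*17"): 0.0,
        ("*1", "*17"): 0.0,
    },
    "guarani": {
        ("*1", "*1"): 0.758,
        ("*1", "*2"): 0.212,
        ("*2", "*17"): 0.0,
        ("*1", "*17"): 0.030,
    },
}

# Combined CYP2C19-CYP2C diplotype frequencies over merged classes
# (combined-scheme input).  Row order follows the published table.
_CGTA = MERGED_CG_TA

COMBINED_DIPLOTYPE_FREQS: dict[str, dict[tuple[str, str], float]] = {
    "1kg_nat": {
        (_CGTA, _CGTA): 0.162,
        (_CGTA, "*1TG"): 0.426,
        ("*1TG", "*1TG"): 0.250,
        (_CGTA, "*2CG"): 0.088,
        ("*1TG", "*2CG"): 0.029,
        (_CGTA, "*17CG"): 0.0,
        ("*1TG", "*17CG"): 0.029,
        ("*2CG", "*17CG"): 0.015,
    },
    "hgdp": {
        (_CGTA, _CGTA): 0.180,
        (_CGTA, "*1TG"): 0.279,
        ("*1TG", "*1TG"): 0.426,
        (_CGTA, "*2CG"): 0.049,
        ("*1TG", "*2CG"): 0.066,
        (_CGTA, "*17CG"): 0.0,
        ("*1TG", "*17CG"): 0.0,
        ("*2CG", "*17CG"): 0.0,
    },
    "kaingang": {
        (_CGTA, _CGTA): 0.241,
        (_CGTA, "*1TG"): 0.556,
        ("*1TG", "*1TG"): 0.204,
        (_CGTA, "*2CG"): 0.0,
        ("*1TG", "*2CG"): 0.0,
        (_CGTA, "*17CG"): 0.0,
        ("*1TG", "*17CG"): 0.0,
        ("*2CG", "*17CG"): 0.0,
    },
    "guarani": {
        (_CGTA, _CGTA): 0.182,
        (_CGTA, "*1TG"): 0.394,
        ("*1TG", "*1TG"): 0.182,
        (_CGTA, "*2CG"): 0.030,
        ("*1TG", "*2CG"): 0.182,
        (_CGTA, "*17CG"): 0.030,
        ("*1TG", "*17CG"): 0.0,
        ("*2CG", "*17CG"): 0.0,
    },
}

# Published phenotype labels for the combined diplotype rows, kept as a
# regression fixture for the activity-class ladder.
COMBINED_ROW_PHENOTYPES: dict[tuple[str, str], str] = {
    (_CGTA, _CGTA): "NM",
    (_CGTA, "*1TG"): "RM",
    ("*1TG", "*1TG"): "UM",
    (_CGTA, "*2CG"): "IM",
    ("*1TG", "*2CG"): "IM",
    (_CGTA, "*17CG"): "RM",
    ("*1TG", "*17CG"): "UM",
    ("*2CG", "*17CG"): "IM",
}

# Published phenotype labels for the star-allele diplotype rows.
STAR_ROW_PHENOTYPES: dict[tuple[str, str], str] = {
    ("*1", "*1"): "NM",
    ("*1", "*2"): "IM",
    ("*2", "*17"): "IM",
    ("*1", "*17"): "RM",
}
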