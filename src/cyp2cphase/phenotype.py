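"""Diplotype-to-phenotype translation for CYP2C19.

Two schemes are implemented:

* ``cpic`` — the conventional translation from star-allele diplotypes
  (*1, *2, *3, *9, *17) to the five metabolizer phenotypes.
* ``combined`` — the translation from combined CYP2C19-CYP2C labels,
  where *1TG (the wild-type star allele on the CYP2C:TG background) is
  treated as an increased-activity haplotype on a par with *17.

Both schemes share one activity-class ladder: each haplotype label maps
to an activity class (no function, decreased, normal, increased) and an
unordered pair of classes maps to a phenotype:

    no_function + no_function            -> PM
    no_function + anything else          -> IM
    decreased   + (normal | decreased)   -> IM
    decreased   + increased              -> NM   (extrapolated; see note)
    normal      + normal                 -> NM
    normal      + increased              -> RM
    increased   + increased              -> UM

The decreased x increased cell is not covered by any published table
for this panel (*9 never appears in an observed diplotype here); the
ladder's NM assignment is flagged as extrapolated.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .naming import MERGED_CG_TA, CombinedLabel, merge_class


class ActivityClass(str, Enum):
    NO_FUNCTION = "no_function"
    DECREASED = "decreased"
    NORMAL = "normal"
    INCREASED = "increased"


class Phenotype(str, Enum):
    PM = "PM"
    IM = "IM"
    NM = "NM"
    RM = "RM"
    UM = "UM"


PHENOTYPE_ORDER = (Phenotype.PM, Phenotype.IM, Phenotype.NM, Phenotype.RM, Phenotype.UM)

# Star-allele activity classes used by the cpic scheme.
CPIC_CLASSES: dict[str, ActivityClass] = {
    "*1": ActivityClass.NORMAL,
    "*2": ActivityClass.NO_FUNCTION,
    "*3": ActivityClass.NO_FUNCTION,
    "*9": ActivityClass.DECREASED,
    "*17": ActivityClass.INCREASED,
}

# Combined-label activity classes: the wild-type star allele on the
# CYP2C:TG background behaves as an increased-activity haplotype.
COMBINED_CLASSES: dict[str, ActivityClass] = {
    "*1TG": ActivityClass.INCREASED,
    "*17CG": ActivityClass.INCREASED,
    "*1CG": ActivityClass.NORMAL,
    "*1TA": ActivityClass.NORMAL,
    MERGED_CG_TA: ActivityClass.NORMAL,
    "*2CG": ActivityClass.NO_FUNCTION,
    "*3CG": ActivityClass.NO_FUNCTION,
    "*9CG": ActivityClass.DECREASED,
}

# Ladder cells flagged as extrapolated (no published diplotype row).
_EXTRAPOLATED = frozenset(
    {frozenset({ActivityClass.DECREASED, ActivityClass.INCREASED})}
)


class UnknownLabelError(KeyError):
    pass


def activity_ladder(a: ActivityClass, b: ActivityClass) -> Phenotype:
    """Phenotype for an unordered pair of activity classes."""
    pair = Counter((a, b))
    if pair[ActivityClass.NO_FUNCTION] == 2:
        return Phenotype.PM
    if pair[ActivityClass.NO_FUNCTION] == 1:
        return Phenotype.IM
    if pair[ActivityClass.DECREASED] >= 1:
        if pair[ActivityClass.INCREASED] == 1:
            return Phenotype.NM
        return Phenotype.IM
    if pair[ActivityClass.INCREASED] == 2:
        return Phenotype.UM
    if pair[ActivityClass.INCREASED] == 1:
        return Phenotype.RM
    return Phenotype.NM


def is_extrapolated(a: ActivityClass, b: ActivityClass) -> bool:
    """True if the ladder cell has no published diplotype row behind it."""
    return frozenset({a, b}) in _EXTRAPOLATED


@dataclass(frozen=True)
class PhenotypeScheme:
    """A named haplotype-label -> activity-class map plus the shared ladder."""

    name: str
    allele_classes: Mapping[str, ActivityClass]

    def activity(self, label: str) -> ActivityClass:
        try:
            return self.allele_classes[label]
        except KeyError:
            raise UnknownLabelError(
                f"label {label!r} has no activity class in scheme {self.name!r}"
            ) from None

    def assign(self, label_a: str, label_b: str) -> Phenotype:
        return activity_ladder(self.activity(label_a), self.activity(label_b))


CPIC_SCHEME = PhenotypeScheme("cpic", CPIC_CLASSES)
COMBINED_SCHEME = PhenotypeScheme("combined", COMBINED_CLASSES)

SCHEMES = {"cpic": CPIC_SCHEME, "combined": COMBINED_SCHEME}


def assign_cpic(pair: Sequence[str]) -> Phenotype:
    """Phenotype for an unordered star-allele pair, e.g. ("*1", "*2") -> IM."""
    a, b = pair
    return CPIC_SCHEME.assign(a, b)


def assign_combined(pair: Sequence[str | CombinedLabel]) -> Phenotype:
    """Phenotype for an unordered combined-label pair, e.g. ("*1TG", "*2CG") -> IM.

    Accepts raw combined labels or merged-class strings; raw *1CG/*1TA
    labels are first collapsed to their merged class.
    """
    a, b = (merge_class(x) for x in pair)
    return COMBINED_SCHEME.assign(a, b)


def round_percent(fraction: float) -> int:
    """Whole-percent rounding, half away from zero (0.556 -> 56)."""
    x = fraction * 100.0
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def phenotype_distribution(phenotypes: Iterable[Phenotype]) -> pd.DataFrame:
    """Counts and frequencies per phenotype over included individuals."""
    phen = list(phenotypes)
    if not phen:
        raise ValueError("empty phenotype list")
    counts = Counter(phen)
    total = len(phen)
    rows = [
        (p.value, counts.get(p, 0), counts.get(p, 0) / total,
         round_percent(counts.get(p, 0) / total))
        for p in PHENOTYPE_ORDER
    ]
    return pd.DataFrame(rows, columns=["phenotype", "count", "frequency", "percent"])


def distribution_from_frequencies(
    diplotype_freqs: Mapping[tuple[str, str], float],
    scheme: PhenotypeScheme,
) -> pd.DataFrame:
    """Phenotype totals from a printed diplotype-frequency table.

    Each diplotype row (an unordered label pair) contributes its
    frequency to the phenotype the scheme assigns it; totals are also
    reported as whole percents (half away from zero).
    """
    totals: dict[Phenotype, float] = {p: 0.0 for p in PHENOTYPE_ORDER}
    for (a, b), freq in diplotype_freqs.items():
        totals[scheme.assign(a, b)] += freq
    rows = [
        (p.value, totals[p], round_percent(totals[p]))
        for p in PHENOTYPE_ORDER
    ]
    return pd.DataFrame(rows, columns=["phenotype", "frequency", "percent"])
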