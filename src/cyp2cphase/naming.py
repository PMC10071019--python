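"""Haplotype nomenclature: CYP2C 2-SNP labels, CYP2C19 star alleles,
combined labels, and the merged classes used for analysis.

The CYP2C label is the pair of allele letters at rs2860840 and
rs11188059 (TG, TA, CG or CA).  Star alleles are defined by single tag
SNPs (*2 = rs4244285 A, *3 = rs4986893 A, *9 = rs17884712 A,
*17 = rs12248560 T); *1 is the default when no variant allele is seen
at any star site.  A haplotype bearing two or more star variants is
flagged as a conflict rather than silently labelled, since single-SNP
tags cannot name it.

In the cohorts this package models, the CYP2C:TG haplotype is never
linked to the *2 or *17 variant alleles; a combined label that violates
this pattern is marked (and warned about) but still returned.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .panel import VariantPanel

CYP2C_LABELS = ("TG", "TA", "CG", "CA")
MERGED_CG_TA = "*1CG-or-TA"


class LinkageViolationWarning(UserWarning):
    """A CYP2C:TG haplotype carrying a non-*1 star variant."""


@dataclass(frozen=True)
class StarDef:
    rsid: str
    variant_allele: str
    star_tag: str


def default_star_defs(panel: VariantPanel) -> tuple[StarDef, ...]:
    """Star definitions implied by the panel's star-site tags (ALT = variant)."""
    return tuple(
        StarDef(s.rsid, s.alt_allele, s.star_tag) for s in panel.star_sites
    )


def load_star_defs(path: str | Path) -> tuple[StarDef, ...]:
    """Load star definitions from TSV or JSON (rsid, variant_allele, star_tag)."""
    p = Path(path)
    if p.suffix.lower() == ".json":
        records = json.loads(p.read_text())
    else:
        records = pd.read_csv(p, sep="\t", dtype=str).to_dict("records")
    return tuple(
        StarDef(str(r["rsid"]), str(r["variant_allele"]).upper(), str(r["star_tag"]))
        for r in records
    )


@dataclass(frozen=True)
class StarAllele:
    value: str                      # "*1", "*2", ... or "conflict"
    defining_rsids: frozenset[str] = frozenset()
    conflict: bool = False


@dataclass(frozen=True)
class CombinedLabel:
    star: StarAllele
    cyp2c: str
    linkage_violation: bool = False

    @property
    def value(self) -> str:
        return f"{self.star.value}{self.cyp2c}"

    def __str__(self) -> str:
        return self.value


def name_cyp2c(hap: Sequence[int], panel: VariantPanel) -> str:
    """Two-letter CYP2C label: rs2860840 allele then rs11188059 allele."""
    i1, i2 = panel.cyp2c_indices
    s1, s2 = panel.cyp2c_sites
    return s1.allele(hap[i1]) + s2.allele(hap[i2])


def call_star(
    hap: Sequence[int],
    panel: VariantPanel,
    star_defs: Optional[tuple[StarDef, ...]] = None,
) -> StarAllele:
    """Star allele of a haplotype; *1 when no star-site variant is present."""
    if star_defs is None:
        star_defs = default_star_defs(panel)
    by_rsid = {d.rsid: d for d in star_defs}
    hits: list[StarDef] = []
    for idx, snp in zip(panel.star_indices, panel.star_sites):
        d = by_rsid.get(snp.rsid)
        if d is None:
            continue
        if snp.allele(hap[idx]) == d.variant_allele:
            hits.append(d)
    if not hits:
        return StarAllele("*1")
    if len(hits) == 1:
        return StarAllele(hits[0].star_tag, frozenset({hits[0].rsid}))
    return StarAllele(
        "conflict", frozenset(d.rsid for d in hits), conflict=True
    )


def combined_label(
    hap: Sequence[int],
    panel: VariantPanel,
    star_defs: Optional[tuple[StarDef, ...]] = None,
) -> CombinedLabel:
    """Star allele + CYP2C label, e.g. '*1TG'; warns on TG-linked variants."""
    star = call_star(hap, panel, star_defs)
    cyp2c = name_cyp2c(hap, panel)
    violation = cyp2c == "TG" and star.value != "*1"
    if violation and not star.conflict:
        warnings.warn(
            f"haplotype {panel.hap_str(hap)}: CYP2C:TG linked to {star.value} "
            "variant, violating the expected linkage pattern",
            LinkageViolationWarning,
            stacklevel=2,
        )
    return CombinedLabel(star, cyp2c, linkage_violation=violation)


def merge_class(label: CombinedLabel | str) -> str:
    """Merged analysis class: *1CG and *1TA collapse to one class."""
    value = label if isinstance(label, str) else label.value
    if value in ("*1CG", "*1TA"):
        return MERGED_CG_TA
    return value


def label_table(
    haps: Sequence[Sequence[int]],
    panel: VariantPanel,
    star_defs: Optional[tuple[StarDef, ...]] = None,
) -> pd.DataFrame:
    """Per-haplotype naming table: alleles, CYP2C label, star, combined, merged."""
    rows = []
    for hap in haps:
        lab = combined_label(hap, panel, star_defs)
        rows.append(
            (
                panel.hap_str(hap),
                lab.cyp2c,
                lab.star.value,
                lab.value,
                merge_class(lab),
                lab.star.conflict,
                lab.linkage_violation,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "haplotype", "cyp2c_label", "star", "combined", "merged",
            "conflict", "linkage_violation",
        ],
    )
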