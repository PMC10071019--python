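"""SNP panel definitions for the CYP2C cluster.

The panel ties together the two CYP2C18 sites that define the CYP2C
two-letter haplotype labels (TG/TA/CG/CA) and the CYP2C19 star-allele
tag SNPs (*2, *3, *9, *17).  Panel order is the canonical coordinate
order for every haplotype vector downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

VALID_BASES = frozenset("ACGT")

CYP2C_SITE = "CYP2C_site"
STAR_SITE = "star_site"

# Fixed order of the CYP2C18 sites: first letter of the two-letter label
# is the rs2860840 allele, second is the rs11188059 allele.
CYP2C_SITE_ORDER = ("rs2860840", "rs11188059")


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel configurations."""


@dataclass(frozen=True)
class SNPDef:
    """One biallelic SNP of the panel.

    GRCh38, 1-based VCF-convention coordinates.  ``star_tag`` names the
    CYP2C19 star allele defined by the ALT allele (e.g. ``"*2"``) and is
    required for ``star_site`` roles, forbidden for ``CYP2C_site``.
    """

    rsid: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str
    role: str
    star_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise PanelError(f"{self.rsid}: position must be positive, got {self.pos}")
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise PanelError(f"{self.rsid}: alleles must be single bases A/C/G/T")
        if self.ref_allele == self.alt_allele:
            raise PanelError(f"{self.rsid}: ref and alt alleles are identical")
        if self.role == STAR_SITE:
            if not self.star_tag:
                raise PanelError(f"{self.rsid}: star_site requires a star_tag")
        elif self.role == CYP2C_SITE:
            if self.star_tag:
                raise PanelError(f"{self.rsid}: CYP2C_site must not carry a star_tag")
        else:
            raise PanelError(f"{self.rsid}: unknown role {self.role!r}")

    def allele(self, code: int) -> str:
        """Base letter for a 0 (ref) / 1 (alt) haplotype code."""
        return self.ref_allele if code == 0 else self.alt_allele


@dataclass(frozen=True)
class VariantPanel:
    """Ordered SNP panel; order defines haplotype vector coordinates."""

    snps: tuple[SNPDef, ...]

    def __post_init__(self) -> None:
        rsids = [s.rsid for s in self.snps]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise PanelError(f"duplicate rsid(s) in panel: {', '.join(dupes)}")
        cyp2c = [s for s in self.snps if s.role == CYP2C_SITE]
        if len(cyp2c) != 2:
            raise PanelError(f"panel must contain exactly 2 CYP2C sites, found {len(cyp2c)}")
        found = tuple(s.rsid for s in cyp2c)
        if set(found) != set(CYP2C_SITE_ORDER):
            raise PanelError(
                f"CYP2C sites must be {CYP2C_SITE_ORDER}, found {found}"
            )

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self.snps)

    @property
    def cyp2c_sites(self) -> tuple[SNPDef, SNPDef]:
        by_rsid = {s.rsid: s for s in self.snps}
        return (by_rsid[CYP2C_SITE_ORDER[0]], by_rsid[CYP2C_SITE_ORDER[1]])

    @property
    def cyp2c_indices(self) -> tuple[int, int]:
        idx = {s.rsid: i for i, s in enumerate(self.snps)}
        return (idx[CYP2C_SITE_ORDER[0]], idx[CYP2C_SITE_ORDER[1]])

    @property
    def star_sites(self) -> tuple[SNPDef, ...]:
        return tuple(s for s in self.snps if s.role == STAR_SITE)

    @property
    def star_indices(self) -> tuple[int, ...]:
        return tuple(i for i, s in enumerate(self.snps) if s.role == STAR_SITE)

    def index_of(self, rsid: str) -> int:
        for i, s in enumerate(self.snps):
            if s.rsid == rsid:
                return i
        raise KeyError(rsid)

    def subset(self, rsids: Iterable[str]) -> "VariantPanel":
        """New panel restricted to the given rsids, preserving order."""
        keep = set(rsids)
        return VariantPanel(tuple(s for s in self.snps if s.rsid in keep))

    def hap_str(self, hap: Sequence[int]) -> str:
        """Render a 0/1 haplotype vector as allele letters in panel order."""
        if len(hap) != len(self.snps):
            raise ValueError("haplotype length does not match panel size")
        return "".join(s.allele(int(a)) for s, a in zip(self.snps, hap))


# The six-SNP panel of the study: two CYP2C18 sites plus the CYP2C19
# star-allele tag SNPs.  Positions are GRCh38.
_DEFAULT_ROWS = (
    ("rs2860840", "chr10", 94735475, "C", "T", "CYP2C18", CYP2C_SITE, None),
    ("rs11188059", "chr10", 94709142, "G", "A", "CYP2C18", CYP2C_SITE, None),
    ("rs4244285", "chr10", 94781859, "G", "A", "CYP2C19", STAR_SITE, "*2"),
    ("rs4986893", "chr10", 94780653, "G", "A", "CYP2C19", STAR_SITE, "*3"),
    ("rs17884712", "chr10", 94775489, "G", "A", "CYP2C19", STAR_SITE, "*9"),
    ("rs12248560", "chr10", 94761900, "C", "T", "CYP2C19", STAR_SITE, "*17"),
)


def default_panel() -> VariantPanel:
    """The built-in six-SNP CYP2C-cluster panel."""
    return VariantPanel(tuple(SNPDef(*row) for row in _DEFAULT_ROWS))


def four_snp_panel() -> VariantPanel:
    """Panel without rs4986893 (*3) and rs17884712 (*9).

    Matches cohorts genotyped only at rs2860840, rs11188059, rs4244285
    and rs12248560.
    """
    return default_panel().subset(
        ["rs2860840", "rs11188059", "rs4244285", "rs12248560"]
    )


def cyp2c_only_panel() -> VariantPanel:
    """Two-SNP panel with just the CYP2C18 label-defining sites."""
    return default_panel().subset(list(CYP2C_SITE_ORDER))


_CONFIG_COLS = ["rsid", "chrom", "pos", "ref", "alt", "gene", "role", "star_tag"]


def load_panel(config_path: str | Path) -> VariantPanel:
    """Load a panel from a JSON (list of objects) or TSV config file.

    Columns/keys: rsid, chrom, pos, ref, alt, gene, role, star_tag
    (star_tag empty or absent for CYP2C sites).
    """
    path = Path(config_path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise PanelError("panel JSON must be a list of SNP objects")
        df = pd.DataFrame.from_records(records)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _CONFIG_COLS[:-1] if c not in df.columns]
    if missing:
        raise PanelError(f"panel config missing column(s): {', '.join(missing)}")
    if "star_tag" not in df.columns:
        df["star_tag"] = None
    snps = []
    for rec in df.to_dict("records"):
        tag = rec.get("star_tag")
        if tag is None or (isinstance(tag, float) and pd.isna(tag)) or tag == "":
            tag = None
        try:
            pos = int(rec["pos"])
        except (TypeError, ValueError) as exc:
            raise PanelError(f"{rec.get('rsid')}: malformed position {rec['pos']!r}") from exc
        snps.append(
            SNPDef(
                rsid=str(rec["rsid"]),
                chrom=str(rec["chrom"]),
                pos=pos,
                ref_allele=str(rec["ref"]).upper(),
                alt_allele=str(rec["alt"]).upper(),
                gene=str(rec["gene"]),
                role=str(rec["role"]),
                star_tag=tag,
            )
        )
    return VariantPanel(tuple(snps))


def write_panel(panel: VariantPanel, path: str | Path) -> None:
    """Write a panel config as TSV (inverse of load_panel)."""
    df = pd.DataFrame(
        [
            (s.rsid, s.chrom, s.pos, s.ref_allele, s.alt_allele, s.gene, s.role,
             s.star_tag or "")
            for s in panel
        ],
        columns=_CONFIG_COLS,
    )
    df.to_csv(path, sep="\t", index=False)
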