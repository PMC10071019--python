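"""Unphased genotype containers and VCF/TSV input-output.

Genotypes are biallelic and unordered; per sample per SNP we store the
ALT-allele dosage (0, 1, 2) or -1 for missing.  Phase separators in
input VCFs are deliberately ignored — inferring phase is the job of the
EM model downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .panel import SNPDef, VariantPanel

MISSING = -1


class GenotypeError(ValueError):
    """Raised for malformed genotype input."""


@dataclass
class GenotypeMatrix:
    """Unphased calls for a cohort over a variant panel.

    ``dosages`` is (n_samples, n_snps) int8: number of ALT alleles, or
    -1 for a missing call.
    """

    sample_ids: list[str]
    dosages: np.ndarray
    panel: VariantPanel

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeError("duplicate sample ids")
        if self.dosages.shape != (len(self.sample_ids), len(self.panel)):
            raise GenotypeError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.panel)} SNPs"
            )
        bad = ~np.isin(self.dosages, [MISSING, 0, 1, 2])
        if bad.any():
            raise GenotypeError("dosages must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def complete_mask(self) -> np.ndarray:
        """True for samples with no missing call at any panel locus."""
        return (self.dosages != MISSING).all(axis=1)

    def call_str(self, sample_idx: int, snp_idx: int) -> str:
        """Render one call as 'X/Y' (ref allele first) or '.'."""
        d = int(self.dosages[sample_idx, snp_idx])
        snp = self.panel.snps[snp_idx]
        if d == MISSING:
            return "."
        a = [snp.ref_allele] * (2 - d) + [snp.alt_allele] * d
        return f"{a[0]}/{a[1]}"

    def to_dataframe(self) -> pd.DataFrame:
        """Sample x rsid table of 'X/Y' call strings."""
        data = {
            snp.rsid: [self.call_str(i, j) for i in range(self.n_samples)]
            for j, snp in enumerate(self.panel)
        }
        return pd.DataFrame(data, index=pd.Index(self.sample_ids, name="sample"))


def _parse_call(call: str, snp: SNPDef) -> int:
    call = call.strip()
    if call in (".", "./.", ""):
        return MISSING
    sep = "/" if "/" in call else "|"
    parts = call.split(sep)
    if len(parts) != 2:
        raise GenotypeError(f"{snp.rsid}: malformed call {call!r}")
    dosage = 0
    for base in parts:
        base = base.strip().upper()
        if base == snp.alt_allele:
            dosage += 1
        elif base != snp.ref_allele:
            raise GenotypeError(
                f"{snp.rsid}: allele {base!r} is neither ref "
                f"{snp.ref_allele!r} nor alt {snp.alt_allele!r}"
            )
    return dosage


def read_genotypes_tsv(path: str | Path, panel: VariantPanel) -> GenotypeMatrix:
    """Read a sample x rsid TSV of 'X/Y' calls ('.' for missing).

    Panel SNPs absent from the file become missing for all samples;
    file columns not in the panel are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise GenotypeError(f"no samples in genotype file {path}")
    sample_col = df.columns[0]
    samples = df[sample_col].astype(str).tolist()
    if len(set(samples)) != len(samples):
        raise GenotypeError("sample parsed twice in genotype TSV")
    n, L = len(samples), len(panel)
    dosages = np.full((n, L), MISSING, dtype=np.int8)
    for j, snp in enumerate(panel):
        if snp.rsid not in df.columns:
            continue
        for i, call in enumerate(df[snp.rsid].fillna(".")):
            dosages[i, j] = _parse_call(call, snp)
    return GenotypeMatrix(samples, dosages, panel)


def write_genotypes_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t")


def read_genotypes_vcf(path: str | Path, panel: VariantPanel) -> GenotypeMatrix:
    """Read panel genotypes from a (possibly uncompressed) VCF.

    Records are matched to panel SNPs by (chrom, pos, ref, alt), with
    rsid as fallback when coordinates match but the ID line carries the
    rsid.  Phase separators are ignored.  A matched position with
    different alleles is an error; unmatched panel SNPs are missing.
    """
    by_coord = {(s.chrom, s.pos): (j, s) for j, s in enumerate(panel)}
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if len(set(samples)) != len(samples):
        raise GenotypeError("sample parsed twice in VCF header")
    if not samples:
        raise GenotypeError(f"no samples in VCF {path}")
    n, L = len(samples), len(panel)
    dosages = np.full((n, L), MISSING, dtype=np.int8)
    for rec in vf.fetch() if vf.index is not None else vf:
        chrom = rec.chrom if rec.chrom.startswith("chr") else f"chr{rec.chrom}"
        key = (chrom, rec.pos)
        if key not in by_coord:
            continue
        j, snp = by_coord[key]
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            raise GenotypeError(f"{snp.rsid}: only biallelic SNVs are supported")
        if rec.ref != snp.ref_allele or alts[0] != snp.alt_allele:
            raise GenotypeError(
                f"allele mismatch at {chrom}:{rec.pos}: VCF {rec.ref}/{alts[0]}, "
                f"panel {snp.ref_allele}/{snp.alt_allele}"
            )
        for i, sample in enumerate(samples):
            gt = rec.samples[sample].get("GT")
            if gt is None or any(a is None for a in gt):
                dosages[i, j] = MISSING
            else:
                dosages[i, j] = sum(int(a) for a in gt)
    return GenotypeMatrix(samples, dosages, panel)


def write_genotypes_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as an uncompressed VCF 4.2 file (unphased GTs)."""
    panel = matrix.panel
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"), ("Description", "Genotype")])
    for chrom in dict.fromkeys(s.chrom for s in panel):
        header.contigs.add(chrom)
    for sid in matrix.sample_ids:
        header.add_sample(sid)
    # VCF requires coordinate-sorted records; panel order is restored on read.
    order = sorted(range(len(panel)), key=lambda j: (panel.snps[j].chrom, panel.snps[j].pos))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in order:
            snp = panel.snps[j]
            rec = out.new_record(
                contig=snp.chrom, start=snp.pos - 1, stop=snp.pos,
                alleles=(snp.ref_allele, snp.alt_allele), id=snp.rsid,
            )
            for i, sid in enumerate(matrix.sample_ids):
                d = int(matrix.dosages[i, j])
                if d == MISSING:
                    rec.samples[sid]["GT"] = (None, None)
                else:
                    rec.samples[sid]["GT"] = (0, 0) if d == 0 else ((0, 1) if d == 1 else (1, 1))
                rec.samples[sid].phased = False
            out.write(rec)


def read_genotypes(path: str | Path, format: str, panel: VariantPanel) -> GenotypeMatrix:
    """Dispatch on format: 'vcf' or 'tsv'."""
    if format == "vcf":
        return read_genotypes_vcf(path, panel)
    if format == "tsv":
        return read_genotypes_tsv(path, panel)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(matrix: GenotypeMatrix, path: str | Path, format: str) -> None:
    if format == "vcf":
        write_genotypes_vcf(matrix, path)
    elif format == "tsv":
        write_genotypes_tsv(matrix, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
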