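"""Pipeline orchestration: genotypes (read or simulated) -> EM phasing
-> diplotype calls -> haplotype naming -> phenotype assignment (both
schemes) -> population statistics, rendered as stable TSV/JSON reports.

Exclusion accounting is part of the method: individuals are dropped
either for missing calls (before EM) or for a best-diplotype posterior
below the inclusion threshold (after EM), and both counts are logged
and reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import em as em_mod
from .em import DEFAULT_MAX_ITER, DEFAULT_THRESHOLD, DEFAULT_TOL, HaplotypeFrequencyModel
from .genotypes import GenotypeMatrix, read_genotypes
from .naming import combined_label, merge_class
from .panel import VariantPanel, default_panel, load_panel
from .phenotype import (
    COMBINED_SCHEME,
    CPIC_SCHEME,
    Phenotype,
    UnknownLabelError,
    phenotype_distribution,
)
from .popstats import (
    allele_frequency,
    compare_phenotype_distributions,
    genotype_counts_from_dosages,
    hwe_test,
)
from .simulate import CohortConfig, generate_cohort, get_preset

logger = logging.getLogger("cyp2cphase")


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """One of ``genotypes_path``/``preset``/``cohort`` supplies the input."""

    genotypes_path: Optional[str] = None
    genotypes_format: str = "tsv"
    preset: Optional[str] = None
    cohort: Optional[CohortConfig] = None
    panel_path: Optional[str] = None
    panel: Optional[VariantPanel] = None
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER
    threshold: float = DEFAULT_THRESHOLD
    seed: Optional[int] = None
    restrict_to_included: bool = False
    schemes: tuple[str, ...] = ("cpic", "combined")

    def __post_init__(self) -> None:
        sources = [
            s for s in (self.genotypes_path, self.preset, self.cohort) if s is not None
        ]
        if len(sources) != 1:
            raise PipelineError(
                "config", "exactly one of genotypes_path / preset / cohort is required"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict):
            raise PipelineError("config", f"config file {path} must be a mapping")
        known = {f for f in cls.__dataclass_fields__ if f not in ("cohort", "panel")}
        unknown = set(doc) - known
        if unknown:
            raise PipelineError("config", f"unknown config key(s): {sorted(unknown)}")
        if "schemes" in doc:
            doc["schemes"] = tuple(doc["schemes"])
        return cls(**doc)


@dataclass
class CohortReport:
    allele_table: pd.DataFrame
    haplotype_table: pd.DataFrame
    diplotype_table: pd.DataFrame
    phenotype_distributions: dict[str, pd.DataFrame]
    excluded: pd.DataFrame
    tests: pd.DataFrame
    n_samples: int
    n_excluded_missing: int
    n_excluded_posterior: int
    truth: Optional[object] = None  # TruthCohort when simulated


def _load_matrix(config: PipelineConfig) -> tuple[GenotypeMatrix, Optional[object]]:
    if config.cohort is not None or config.preset is not None:
        cohort_cfg = config.cohort or get_preset(config.preset)
        truth = generate_cohort(cohort_cfg, seed=config.seed)
        return truth.matrix, truth
    panel = config.panel
    if panel is None:
        panel = load_panel(config.panel_path) if config.panel_path else default_panel()
    try:
        matrix = read_genotypes(config.genotypes_path, config.genotypes_format, panel)
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc
    return matrix, None


def run_pipeline(config: PipelineConfig) -> CohortReport:
    matrix, truth = _load_matrix(config)
    panel = matrix.panel
    logger.info("input: %d samples, %d panel SNPs", matrix.n_samples, len(panel))

    # --- EM phasing ---
    try:
        model = HaplotypeFrequencyModel(matrix)
        res = model.fit(
            tol=config.tol,
            max_iter=config.max_iter,
            seed=config.seed,
            restrict_to_included=config.restrict_to_included,
            threshold=config.threshold,
        )
    except em_mod.PhasingError as exc:
        raise PipelineError("em_phasing", str(exc)) from exc
    logger.info(
        "em: %d samples used, %d excluded for missing calls, %d iterations, loglik %.4f",
        res.n_samples_used, res.n_excluded_missing, res.n_iter, res.loglik,
    )

    # --- diplotype calls + threshold ---
    calls = res.call_diplotypes(config.threshold)
    n_below = sum(not c.included for c in calls)
    logger.info(
        "calls: %d/%d individuals pass posterior >= %.2f",
        len(calls) - n_below, len(calls), config.threshold,
    )

    # --- haplotype naming ---
    freqs = res.frequencies
    reported = res.reported_haplotypes(em_mod.DROP_FREQ_THRESHOLD)
    hap_rows = []
    for hap_str, f in reported.items():
        hap = em_mod._hap_from_str(hap_str, panel)
        lab = combined_label(hap, panel)
        hap_rows.append(
            (hap_str, lab.cyp2c, lab.star.value, lab.value, merge_class(lab),
             float(f), lab.star.conflict, lab.linkage_violation)
        )
    haplotype_table = pd.DataFrame(
        hap_rows,
        columns=["haplotype", "cyp2c_label", "star", "combined", "merged",
                 "frequency", "conflict", "linkage_violation"],
    )

    # --- per-sample labels and phenotypes ---
    dip_rows = []
    for c in calls:
        lab_a = combined_label(c.hap_a, panel)
        lab_b = combined_label(c.hap_b, panel)
        conflict = lab_a.star.conflict or lab_b.star.conflict
        row = {
            "sample": c.sample_id,
            "hap_a": panel.hap_str(c.hap_a),
            "hap_b": panel.hap_str(c.hap_b),
            "star_a": lab_a.star.value,
            "star_b": lab_b.star.value,
            "combined_a": lab_a.value,
            "combined_b": lab_b.value,
            "posterior": c.posterior,
            "included": c.included,
            "ambiguous": c.ambiguous,
            "conflict": conflict,
        }
        for scheme_name in config.schemes:
            phen = None
            if not conflict:
                try:
                    if scheme_name == "cpic":
                        phen = CPIC_SCHEME.assign(lab_a.star.value, lab_b.star.value)
                    else:
                        phen = COMBINED_SCHEME.assign(
                            merge_class(lab_a), merge_class(lab_b)
                        )
                except UnknownLabelError:
                    phen = None
            row[f"phenotype_{scheme_name}"] = phen.value if phen else ""
        dip_rows.append(row)
    diplotype_table = pd.DataFrame(dip_rows)

    # --- phenotype distributions over included, conflict-free samples ---
    distributions: dict[str, pd.DataFrame] = {}
    for scheme_name in config.schemes:
        col = f"phenotype_{scheme_name}"
        usable = diplotype_table[
            diplotype_table["included"]
            & ~diplotype_table["conflict"]
            & (diplotype_table[col] != "")
        ]
        if len(usable) == 0:
            raise PipelineError(
                "phenotype", f"no usable individuals for scheme {scheme_name!r}"
            )
        distributions[scheme_name] = phenotype_distribution(
            [Phenotype(v) for v in usable[col]]
        )

    # --- allele frequencies + HWE per SNP ---
    allele_rows = []
    for j, snp in enumerate(panel):
        if (matrix.dosages[:, j] >= 0).sum() == 0:
            continue  # locus entirely missing
        counts = genotype_counts_from_dosages(matrix.dosages, j)
        hwe = hwe_test(counts)
        allele_rows.append(
            (snp.rsid, f"{snp.ref_allele}>{snp.alt_allele}",
             allele_frequency(counts), hwe.statistic, hwe.p_value)
        )
    allele_table = pd.DataFrame(
        allele_rows, columns=["rsid", "alleles", "variant_freq", "hwe_chi2", "hwe_p"]
    )

    # --- scheme comparison (the published figure's chi-square) ---
    test_rows = []
    if len(config.schemes) == 2:
        a, b = config.schemes
        da = dict(zip(distributions[a]["phenotype"], distributions[a]["count"]))
        db = dict(zip(distributions[b]["phenotype"], distributions[b]["count"]))
        try:
            t = compare_phenotype_distributions(da, db)
            test_rows.append(
                (f"phenotype:{a}-vs-{b}", t.statistic, t.df, t.p_value, t.significant)
            )
        except ValueError as exc:
            logger.info("scheme comparison skipped: %s", exc)
    tests = pd.DataFrame(
        test_rows, columns=["test", "statistic", "df", "p_value", "significant"]
    )

    # --- exclusion accounting ---
    complete = set(matrix.sample_ids[i] for i in model._complete_idx)
    excluded_rows = [
        (sid, "missing_calls") for sid in matrix.sample_ids if sid not in complete
    ] + [
        (c.sample_id, "posterior_below_threshold") for c in calls if not c.included
    ]
    excluded = pd.DataFrame(excluded_rows, columns=["sample", "reason"])
    logger.info(
        "excluded: %d for missingness, %d below posterior threshold",
        res.n_excluded_missing, n_below,
    )

    return CohortReport(
        allele_table=allele_table,
        haplotype_table=haplotype_table,
        diplotype_table=diplotype_table,
        phenotype_distributions=distributions,
        excluded=excluded,
        tests=tests,
        n_samples=matrix.n_samples,
        n_excluded_missing=res.n_excluded_missing,
        n_excluded_posterior=n_below,
        truth=truth,
    )


def _round_freq_cols(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == float:
            out[col] = out[col].map(lambda x: f"{x:.3f}" if pd.notna(x) else "")
    return out


def render_report(report: CohortReport, outdir: str | Path, format: str = "tsv") -> list[Path]:
    """Write report files with deterministic order and rounding.

    Frequencies are rendered at 3 decimals, percentages as whole
    numbers, so repeated runs under the same seed diff clean.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown report format {format!r}")
    if format == "tsv":
        frames = {
            "alleles.tsv": report.allele_table,
            "haplotypes.tsv": report.haplotype_table.sort_values(
                "frequency", ascending=False, kind="stable"
            ),
            "diplotypes.tsv": report.diplotype_table,
            "excluded.tsv": report.excluded,
            "tests.tsv": report.tests,
        }
        for scheme, dist in report.phenotype_distributions.items():
            frames[f"phenotypes_{scheme}.tsv"] = dist
        for name, df in frames.items():
            path = outdir / name
            _round_freq_cols(df).to_csv(path, sep="\t", index=False)
            written.append(path)
    else:
        doc = {
            "n_samples": report.n_samples,
            "n_excluded_missing": report.n_excluded_missing,
            "n_excluded_posterior": report.n_excluded_posterior,
            "haplotype_frequencies": {
                row.combined: round(float(row.frequency), 3)
                for row in report.haplotype_table.itertuples()
            },
            "phenotype_distributions": {
                scheme: {
                    rec["phenotype"]: {
                        "count": int(rec["count"]),
                        "frequency": round(float(rec["frequency"]), 3),
                        "percent": int(rec["percent"]),
                    }
                    for rec in dist.to_dict("records")
                }
                for scheme, dist in report.phenotype_distributions.items()
            },
        }
        path = outdir / "report.json"
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
        written.append(path)
    return written
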