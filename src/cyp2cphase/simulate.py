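"""Seeded synthetic diploid cohorts drawn from haplotype frequency tables.

Individuals are formed by two independent haplotype draws (random
mating, i.e. Hardy-Weinberg at the haplotype level), then unphased into
genotype dosages, with optional per-call missingness.  Truth diplotypes
are kept alongside the genotype matrix so phasing accuracy can be
scored exactly.

Presets transcribe the four study cohorts' frequency columns: the
two-SNP CYP2C haplotype tables and the combined CYP2C19-CYP2C label
tables.  Printed columns do not always sum to exactly 1 (3-decimal
rounding; one column sums to 0.839): presets off by rounding only are
shipped with auto-renormalization flagged (a warning is emitted at
generation), while the badly non-normalized column ships verbatim
(refusing generation) plus a clearly named renormalized variant.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .genotypes import MISSING, GenotypeMatrix
from .naming import CYP2C_LABELS, StarDef, default_star_defs
from .panel import VariantPanel, cyp2c_only_panel, default_panel, four_snp_panel

FREQ_SUM_TOL = 1e-6


class CohortConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Recipe for one synthetic cohort.

    ``hap_freqs`` maps haplotype labels to frequencies; labels are
    either two-letter CYP2C labels (TG/TA/CG/CA) or combined labels
    like ``*1TG``/``*2CG``.  ``renormalize=True`` permits (with a
    warning) frequencies whose sum deviates from 1.
    """

    name: str
    n: int
    hap_freqs: dict[str, float]
    seed: Optional[int] = None
    missing_rate: float = 0.0
    renormalize: bool = False
    panel: Optional[VariantPanel] = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise CohortConfigError("cohort size must be positive")
        if not self.hap_freqs:
            raise CohortConfigError("hap_freqs must be non-empty")
        if any(f < 0 for f in self.hap_freqs.values()):
            raise CohortConfigError("haplotype frequencies must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise CohortConfigError("missing_rate must be in [0, 1)")

    @property
    def freq_sum(self) -> float:
        return float(sum(self.hap_freqs.values()))

    @property
    def normalized(self) -> bool:
        return abs(self.freq_sum - 1.0) <= FREQ_SUM_TOL


@dataclass
class TruthCohort:
    """Synthetic cohort with generating truth attached."""

    matrix: GenotypeMatrix
    truth_diplotypes: list[tuple[tuple[int, ...], tuple[int, ...]]]
    config: CohortConfig

    def truth_hap_counts(self) -> dict[tuple[int, ...], int]:
        counts: dict[tuple[int, ...], int] = {}
        for a, b in self.truth_diplotypes:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        return counts


_COMBINED_RE = re.compile(r"^(\*\w+)([CT][GA])$")


def expand_label(
    label: str,
    panel: VariantPanel,
    star_defs: Optional[tuple[StarDef, ...]] = None,
) -> tuple[int, ...]:
    """Expand a haplotype label to a full 0/1 vector over the panel.

    Two-letter labels set only the CYP2C sites; combined labels also set
    the tag SNP of their star allele (``*1`` sets none).  Labels like
    ``*2TG`` are accepted — they produce the linkage pattern the study
    cohorts never show, which exists to exercise the warning path.
    """
    hap = [0] * len(panel)
    if label in CYP2C_LABELS:
        star, cyp2c = "*1", label
    else:
        m = _COMBINED_RE.match(label)
        if not m:
            raise CohortConfigError(f"unparseable haplotype label {label!r}")
        star, cyp2c = m.group(1), m.group(2)
    i1, i2 = panel.cyp2c_indices
    s1, s2 = panel.cyp2c_sites
    for idx, snp, base in ((i1, s1, cyp2c[0]), (i2, s2, cyp2c[1])):
        if base == snp.alt_allele:
            hap[idx] = 1
        elif base != snp.ref_allele:
            raise CohortConfigError(f"{label!r}: {base} not an allele of {snp.rsid}")
    if star != "*1":
        if star_defs is None:
            star_defs = default_star_defs(panel)
        tagged = [d for d in star_defs if d.star_tag == star]
        if not tagged:
            raise CohortConfigError(f"{label!r}: no star definition for {star}")
        for d in tagged:
            idx = panel.index_of(d.rsid)
            snp = panel.snps[idx]
            if snp.allele(1) != d.variant_allele:
                raise CohortConfigError(
                    f"{star} variant allele {d.variant_allele} is not the ALT of {d.rsid}"
                )
            hap[idx] = 1
    return tuple(hap)


def _infer_panel(config: CohortConfig) -> VariantPanel:
    if config.panel is not None:
        return config.panel
    if all(lbl in CYP2C_LABELS for lbl in config.hap_freqs):
        return cyp2c_only_panel()
    return default_panel()


def generate_cohort(
    config: CohortConfig,
    seed: Optional[int] = None,
    star_defs: Optional[tuple[StarDef, ...]] = None,
) -> TruthCohort:
    """Draw a cohort: two independent haplotypes per individual.

    ``seed`` overrides ``config.seed``.  Deterministic for a fixed
    seed.  Raises unless frequencies sum to 1 (within 1e-6) or the
    config carries ``renormalize=True`` (warning emitted).
    """
    panel = _infer_panel(config)
    labels = list(config.hap_freqs)
    freqs = np.array([config.hap_freqs[k] for k in labels], dtype=float)
    total = freqs.sum()
    if abs(total - 1.0) > FREQ_SUM_TOL:
        if not config.renormalize:
            raise CohortConfigError(
                f"{config.name}: haplotype frequencies sum to {total:.3f}, not 1 "
                "(pass renormalize=True to rescale)"
            )
        warnings.warn(
            f"{config.name}: renormalizing haplotype frequencies (sum {total:.3f})",
            UserWarning,
            stacklevel=2,
        )
    freqs = freqs / total
    haps = [expand_label(lbl, panel, star_defs) for lbl in labels]
    use_seed = seed if seed is not None else config.seed
    rng = np.random.default_rng(use_seed)
    draws = rng.choice(len(labels), size=(config.n, 2), p=freqs)
    truth = []
    dosages = np.empty((config.n, len(panel)), dtype=np.int8)
    for i, (ia, ib) in enumerate(draws):
        a, b = haps[ia], haps[ib]
        truth.append((min(a, b), max(a, b)))
        dosages[i] = np.asarray(a) + np.asarray(b)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = MISSING
    sample_ids = [f"{config.name}_{i + 1:04d}" for i in range(config.n)]
    matrix = GenotypeMatrix(sample_ids, dosages, panel)
    return TruthCohort(matrix, truth, replace(config, seed=use_seed))


# ---------------------------------------------------------------------------
# Presets: the four study cohorts' printed frequency columns.
# Columns off by <= 0.005 from 1 (3-decimal rounding) carry
# renormalize=True; the 0.839 column ships verbatim + renormalized.

_TABLE1 = {
    "1kg_nat": (68, {"TG": 0.493, "TA": 0.265, "CG": 0.243, "CA": 0.0}),
    "hgdp": (61, {"TG": 0.598, "TA": 0.107, "CG": 0.295, "CA": 0.0}),
    "kaingang": (54, {"TG": 0.490, "TA": 0.471, "CG": 0.038, "CA": 0.0}),
    "guarani": (33, {"TG": 0.469, "TA": 0.250, "CG": 0.281, "CA": 0.0}),
}

_TABLE3 = {
    "1kg_nat": (68, {"*1CG": 0.154, "*1TA": 0.265, "*1TG": 0.493,
                     "*2CG": 0.066, "*17CG": 0.022}),
    "hgdp": (61, {"*1CG": 0.238, "*1TA": 0.107, "*1TG": 0.598, "*2CG": 0.057}),
    "kaingang": (54, {"*1CG": 0.037, "*1TA": 0.481, "*1TG": 0.481}),
    "guarani": (33, {"*1CG": 0.081, "*1TA": 0.167, "*1TG": 0.470,
                     "*2CG": 0.106, "*17CG": 0.015}),
}

# Kaingang and Guarani were genotyped at four of the six loci.
_COHORT_PANELS = {
    "1kg_nat": default_panel,
    "hgdp": default_panel,
    "kaingang": four_snp_panel,
    "guarani": four_snp_panel,
}


def _preset(name: str, cohort: str, n: int, freqs: dict[str, float],
            two_snp: bool) -> list[CohortConfig]:
    panel = cyp2c_only_panel() if two_snp else _COHORT_PANELS[cohort]()
    total = sum(freqs.values())
    off = abs(total - 1.0)
    if off <= FREQ_SUM_TOL:
        return [CohortConfig(name, n, dict(freqs), panel=panel)]
    if off <= 0.005:  # printing/rounding slack
        return [CohortConfig(name, n, dict(freqs), renormalize=True, panel=panel)]
    renorm = {k: v / total for k, v in freqs.items()}
    return [
        CohortConfig(f"{name}_verbatim", n, dict(freqs), panel=panel),
        CohortConfig(f"{name}_renormalized", n, renorm, panel=panel),
    ]


def cohort_presets() -> dict[str, CohortConfig]:
    """Named presets for the study cohorts, in both label modes."""
    presets: dict[str, CohortConfig] = {}
    for cohort, (n, freqs) in _TABLE1.items():
        for cfg in _preset(f"{cohort}_table1", cohort, n, freqs, two_snp=True):
            presets[cfg.name] = cfg
    for cohort, (n, freqs) in _TABLE3.items():
        for cfg in _preset(f"{cohort}_table3", cohort, n, freqs, two_snp=False):
            presets[cfg.name] = cfg
    return presets


def get_preset(name: str) -> CohortConfig:
    presets = cohort_presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(presets))}"
        ) from None
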