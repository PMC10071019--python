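# Methods

## The problem

CYP2C19 metabolizes a broad range of drugs (escitalopram, clopidogrel,
voriconazole, omeprazole, ...), and clinical guidelines predict a
person's metabolizer phenotype — poor (PM), intermediate (IM), normal
(NM), rapid (RM) or ultrarapid (UM) — from their *CYP2C19* star-allele
diplotype. In several Native American populations the increased-function
*CYP2C19\*17* allele is rare or absent, yet pharmacokinetic studies find
individuals with higher-than-NM activity among \*1/\*1 carriers. A
two-SNP haplotype in neighbouring *CYP2C18* — rs2860840 T with
rs11188059 G, written CYP2C:TG — has been associated with increased
CYP2C19 activity comparable to \*17, and it is common precisely where
\*17 is absent. This package implements the inference chain needed to
study that question on genotype data: EM haplotype phasing of the
six-SNP CYP2C-cluster panel, star-allele and CYP2C-label naming,
diplotype-to-phenotype translation under both the conventional
(star-allele-only) scheme and the combined CYP2C19-CYP2C scheme, and
the accompanying population statistics — exercised end to end on
synthetic cohorts drawn from published frequency tables.

## Variant panel

Six biallelic SNPs (GRCh38, chromosome 10):

| rsid | position | alleles | role |
|---|---|---|---|
| rs2860840 | 94735475 | C>T | CYP2C18 3'UTR; first letter of the CYP2C label |
| rs11188059 | 94709142 | G>A | CYP2C18 intron 5; second letter |
| rs4244285 | 94781859 | G>A | tags CYP2C19\*2 (no function) |
| rs4986893 | 94780653 | G>A | tags \*3 (no function) |
| rs17884712 | 94775489 | G>A | tags \*9 (decreased function) |
| rs12248560 | 94761900 | C>T | tags \*17 (increased function) |

Panel order (as listed) is the canonical coordinate order for every
haplotype vector. Star-allele definitions are configuration data, not
code: the built-in table maps each tag SNP's ALT allele to its star
name, and users can swap in alternative definitions (sources disagree
on the \*9 tag SNP, so this must not be hard-wired). \*1 is assigned by
default when no star-site variant allele is present. A haplotype
carrying two or more star variants cannot be named by single-SNP tags
and is flagged as a conflict rather than silently labelled; conflicted
haplotypes are excluded from phenotype assignment and surfaced in QC
columns. A 4-SNP panel variant (without \*3/\*9) matches cohorts
genotyped at only four loci, and a 2-SNP panel supports pure
CYP2C-label analyses.

Genotypes are stored as unordered ALT-dosage calls (0/1/2, −1
missing); phase separators in input VCFs are ignored, because inferring
phase is this package's job. Matching is by (chrom, pos, ref, alt); no
strand flipping, liftover, indel or multiallelic support.

## EM haplotype phasing

The model is the standard multilocus haplotype-frequency likelihood for
unphased genotypes under random mating. For individual *i* with
genotype *g<sub>i</sub>*, the likelihood sums over all phase
configurations {h<sub>a</sub>, h<sub>b</sub>} compatible with
*g<sub>i</sub>* (2^(h−1) unordered configurations for h heterozygous
loci):

P(g<sub>i</sub>) = Σ c(h<sub>a</sub>,h<sub>b</sub>) · p(h<sub>a</sub>) · p(h<sub>b</sub>),  c = 2 if h<sub>a</sub> ≠ h<sub>b</sub>, else 1.

The E-step weights each configuration by its posterior under the
current frequencies; the M-step sets each haplotype frequency to its
expected share of the 2n chromosomes. The posterior of a specific
diplotype configuration given the fitted frequencies is the same E-step
quantity, and an individual enters downstream diplotype/phenotype
tables only if their best configuration reaches a posterior threshold,
0.95 by default, with an **inclusive** boundary (posterior = 0.95 is
in).

Numerical choices:

* Initialization is uniform over the haplotypes compatible with at
  least one sample (never all 2^L); a seed-controlled random-restart
  option guards against the rare local optimum. For two-locus panels we
  have verified EM against a direct numerical maximizer of the same
  likelihood and found agreement to 1e-6 log-likelihood.
* Convergence: |Δ log-likelihood| < 1e-10 or 500 iterations, whichever
  comes first — conservative for panels of ≤ 6 SNPs. The trace is
  retained and is non-decreasing (an EM guarantee we assert in tests).
* Argmax ties in diplotype calling are broken lexicographically on the
  haplotype allele strings and flagged `ambiguous`.
* Samples with any missing call at a panel locus are excluded from the
  likelihood and from calling (exclusion, not marginalization: the
  panel is small, so the cost is low and the bookkeeping transparent).
  Excluded counts are reported and logged.
* Frequencies below 1e-6 are dropped from reports; a haplotype counts
  as "identified" in a cohort when its estimated frequency exceeds
  0.01. These two thresholds turn a continuous estimate into the
  discrete haplotype lists of a cohort report.
* Frequency estimation uses **all** complete samples by default; the
  0.95 rule governs only who enters diplotype/phenotype tables. A
  `restrict_to_included=True` mode re-estimates frequencies on the
  included subset, for comparing the two conventions.

## Naming and phenotype translation

The CYP2C label of a haplotype is its rs2860840 allele followed by its
rs11188059 allele (TG, TA, CG, CA); the combined label appends it to
the star allele (e.g. \*1TG, \*2CG). For analyses, \*1CG and \*1TA are
merged into one class, \*1CG-or-TA, reflecting that only the TG
background is associated with increased activity. In the study cohorts
the TG background never carries a \*2 or \*17 variant; a combined label
violating that pattern is returned with a warning and a
`linkage_violation` flag (report-only — no published behaviour exists
to match).

Both phenotype schemes are encoded as an activity class per haplotype
label plus one shared ladder, rather than a literal lookup table, so
that unobserved diplotypes get principled assignments while every
published diplotype row is reproduced exactly (the published rows are
kept as a regression fixture):

* classes — cpic: \*1 normal, \*2/\*3 no function, \*9 decreased, \*17
  increased; combined: \*1TG and \*17CG increased, \*1CG-or-TA normal,
  \*2CG no function (\*3CG/\*9CG carry their star's class).
* ladder — two no-function → PM; one no-function + anything → IM;
  decreased + (normal or decreased) → IM; decreased + increased → NM
  (this cell has no published row anywhere; it is flagged
  extrapolated); normal + normal → NM; normal + increased → RM; two
  increased → UM.

Under this encoding reassignment from star-allele to combined
diplotypes can move individuals from NM to RM/UM but never changes who
is IM or PM — a structural invariant we test over all label pairs.

Percentages are rounded half away from zero to whole percent
(0.556 → 56%); frequencies are rendered at 3 decimals.

## Population statistics

Allele frequencies are counted from genotypes ((het + 2·hom)/2n).
Hardy-Weinberg is a goodness-of-fit chi-square (df = 1) against
p², 2pq, q² at the counted frequency; monomorphic loci return statistic
0, p 1. Cohort contrasts are plain contingency chi-squares without
continuity correction (switchable): 2×2 on chromosome counts for one
haplotype versus all others, r×2 on individual counts for phenotype
distributions (categories empty in both cohorts dropped; df = r−1).
Counts reconstructed from printed frequencies use round(f · 2n). The
comparison between the two assignment procedures applied to the same
cohort is treated, as published, as an independent-samples contingency
test rather than a marginal-homogeneity test — fidelity over
orthodoxy, noted here deliberately. No multiple-testing correction; α
= 0.05.

## Synthetic cohorts

`generate_cohort` draws, per individual, two independent haplotypes
from a frequency table (random mating, hence HWE at the haplotype
level — exactly the assumption the HWE tests presume), unphases them
into dosages, and optionally masks calls independently at a missing
rate (default 0). Truth diplotypes are retained so phasing accuracy is
scorable. Generation is deterministic given a seed. Combined-label
generation expands labels over the full panel, so star-site/CYP2C-site
linkage is respected by construction; deliberately linkage-violating
labels (e.g. \*2TG) are accepted solely to exercise the warning path.

Presets transcribe the published cohort columns verbatim: the four
cohorts (n = 68, 61, 54, 33) in two-SNP CYP2C-label mode and in
combined-label mode, with the 4-SNP panel for the two cohorts genotyped
at four loci. Printed columns summing to 0.999–1.001 (3-decimal
rounding) are shipped with auto-renormalization flagged and warned
about; the one badly non-normalized column (sum 0.839) ships verbatim
— refusing generation — alongside a clearly named `_renormalized`
variant. Tests and the acceptance script use only normalized or
renormalizable presets. Two cohorts' two-SNP and combined columns
disagree slightly in the published source (TA 0.471 vs \*1TA 0.481);
both are shipped unreconciled.

What the generator does **not** emulate: genotyping error, linkage to
unmodelled variants, population substructure or admixture within a
cohort, inbreeding (no F parameter), and missingness that correlates
with genotype. Passing tests therefore demonstrate the inference
machinery is correct under idealized random-mating sampling from the
stated frequencies — not robustness to real-data artefacts.

## Problem sizes and expected behaviour

The replicate studies use 200 seeded cohorts at the published cohort
sizes (n = 61 or 54) for mean-recovery checks, 100 replicates for the
consistency (RMSE) contrast at n = 50 vs 500, and 2000 simulated
cohorts of n = 100 for the HWE type-I-error calibration — sizes chosen
so each study is a statistically meaningful Monte-Carlo estimate of
the property it checks.

One finite-sample behaviour deserves note: in a cohort of ~54–61 from
the printed frequencies, the rarest CYP2C haplotype (frequency ~0.04)
occasionally drifts below the 0.01 "identified" threshold, and the CA
haplotype — absent from the generator — occasionally receives a small
positive frequency because that genuinely is the MLE for the realized
genotype counts (verified against the independent likelihood
maximizer). The three-haplotype discovery result is therefore a
property of the replicate majority and of mean frequencies, and the
tests state it that way.

## Known limitations

* Panels are small by design (≤ ~10 SNPs); diplotype enumeration is
  exponential in heterozygous loci and no partition-ligation or
  Bayesian phasing is attempted.
* Missing data are excluded, not marginalized; cohorts with heavy
  missingness lose samples rather than information-weighted precision.
* The \*9-involving phenotype assignments beyond published rows are
  ladder extrapolations and flagged as such.
* The full PharmVar star nomenclature (39 alleles, sub-alleles such as
  \*1.002) is out of scope; star calling is single-tag-SNP based.
* Chi-square approximations are used throughout (no exact tests); with
  very small expected counts the p-values inherit the usual
  approximation error.
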