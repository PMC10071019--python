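# cyp2cphase

Haplotype phasing and metabolizer-phenotype translation for the human
*CYP2C* cluster, built for pharmacogenetic analyses of *CYP2C19* in
populations where the conventional star-allele panel under-predicts
metabolic activity.

The package is aimed at population pharmacogeneticists who have
unphased genotypes at six CYP2C-cluster SNPs — the two *CYP2C18* sites
rs2860840 and rs11188059 that define the CYP2C:TG/TA/CG/CA haplotype
labels, plus the *CYP2C19* star-allele tag SNPs rs4244285 (\*2),
rs4986893 (\*3), rs17884712 (\*9) and rs12248560 (\*17) — and want to go
from genotypes to phenotype distributions with full control of each
step. The CYP2C:TG haplotype is associated with increased CYP2C19
activity comparable to \*17, and is common in Native American
populations where \*17 is rare; translating diplotypes with it included
can reclassify most of a cohort from normal to rapid/ultrarapid
metabolizer status.

## What it computes

Given unphased genotypes (VCF or TSV) over a configurable SNP panel:

1. **EM haplotype frequencies.** The classic multilocus EM for the
   likelihood P(gᵢ) = Σ c·p(hₐ)p(h_b) over the phase configurations
   compatible with each genotype (c = 2 for heterozygous
   configurations), with per-individual diplotype posteriors and a
   0.95 posterior inclusion threshold for downstream tables.
2. **Naming.** CYP2C two-letter labels, star alleles (\*1 by default in
   the absence of tag variants), combined labels such as \*1TG and
   \*2CG, and the merged \*1CG-or-TA analysis class.
3. **Phenotypes.** Diplotype → {PM, IM, NM, RM, UM} under two schemes:
   the conventional star-allele translation and the combined
   CYP2C19-CYP2C translation in which \*1TG acts as an
   increased-activity allele.
4. **Statistics.** Counted allele frequencies, Hardy-Weinberg
   goodness-of-fit chi-squares, and contingency chi-squares comparing
   haplotype frequencies (chromosome counts) or phenotype
   distributions (individual counts) between cohorts.
5. **Simulation.** Seeded synthetic cohorts drawn by random mating
   from haplotype frequency tables, with truth diplotypes retained;
   presets transcribe the published frequency columns of four Native
   American cohorts (1KG_NAT n=68, HGDP n=61, Kaingang n=54, Guarani
   n=33).

See `docs/methods.md` for the model, parameter defaults and
limitations.

## Worked example

```python
from cyp2cphase import (
    HaplotypeFrequencyModel, generate_cohort, get_preset,
    PipelineConfig, run_pipeline,
)

cohort = generate_cohort(get_preset("hgdp_table3"), seed=42)
res = HaplotypeFrequencyModel(cohort.matrix).fit()
print(res.summary())
```

```
Haplotype frequency estimate (EM)
  samples used: 61 (excluded for missing calls: 0)
  iterations: 25  converged: True
  log-likelihood: -93.864257

  haplotype  frequency
  TGGGGC     0.6430
  CGGGGC     0.2377
  TAGGGC     0.0783
  CGAGGC     0.0373
  CAAGGC     0.0036
```

Each haplotype is rendered as its allele string in panel order; here
`TGGGGC` is \*1TG (T and G at the two CYP2C18 sites, reference at all
four star sites) at frequency 0.643, `CGAGGC` is \*2CG at 0.037, and
the trace amount of `CAAGGC` is finite-sample EM mass on a phase
configuration the generator never drew. The full pipeline adds naming,
phenotypes and statistics:

```python
report = run_pipeline(PipelineConfig(preset="hgdp_table3", seed=42))
print(report.phenotype_distributions["combined"].to_string(index=False))
```

```
phenotype  count  frequency  percent
       PM      0   0.000000        0
       IM      4   0.066667        7
       NM      4   0.066667        7
       RM     28   0.466667       47
       UM     24   0.400000       40
```

Under the star-allele-only scheme the same 60 included individuals are
93% NM and 7% IM; translating with the CYP2C:TG background reclassifies
nearly all NMs to RM or UM while leaving the IM group untouched — the
package's central phenomenon. (One of the 61 simulated individuals
falls below the 0.95 diplotype-posterior threshold and is excluded,
which the report's exclusion table accounts for.)

The same steps are scriptable from the shell:

```
cyp2c-phase simulate --preset hgdp_table3 --seed 42 --out-prefix sim
cyp2c-phase phase --genotypes sim.genotypes.tsv --out-dir phased
cyp2c-phase phenotype --diplotypes phased/diplotypes.tsv --scheme both --out-dir phen
cyp2c-phase stats --compare-haplotypes 53 108 14 1000
```

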