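# polytrans

Tools for asking how much of the parent–child correlation in educational
attainment is genetic: polygenic-score construction, GREML SNP-heritability
estimation, family-clustered regression suites with gene–environment and
gene–gene interactions, within-/between-family decomposition, and the
mediation-scaling statistic that converts score-conditional attenuation of
the parental-education coefficient into a genetic share of the
intergenerational association. A calibrated forward simulator (assortative
mating with burn-in to equilibrium, Mendelian transmission, 1–3 children per
family) generates cohorts whose moments match published survey values, so
the whole pipeline is testable without restricted survey microdata.

## Modules

| module | contents |
|---|---|
| `polytrans.genio` | TSV/VCF genotype, FAM-like pedigree, phenotype and weight-table IO; GCTA-style text GRM reader/writer |
| `polytrans.synthetic_data` | `SimConfig`, founder draws, effect/noisy-weight generation, calibrated couple matching, Mendelian transmission, phenotype simulation, `simulate_cohort` |
| `polytrans.grs` | weighted-allele-sum scores, allele harmonization, within-generation standardization |
| `polytrans.grm_greml` | centered-scaled GRM, greedy relatedness pruning, EM-warm-started AI-REML, boundary (0.5·χ²₁) likelihood-ratio p-values |
| `polytrans.regress` | OLS with CR1 family-cluster sandwich SEs, published-table model suites, interaction-advantage prediction |
| `polytrans.family_decomp` | within/between-family regression decomposition, one-way ANOVA ICC(1) |
| `polytrans.mediation` | attenuation, genetic-share scaling (attenuation × h²/R² × relatedness), cluster-bootstrap coefficient-difference test |
| `polytrans.cli` | `polytrans` command: simulate / score / grm / reml / models / decompose / mediate / run |

## CLI

```bash
# simulate a cohort calibrated to the default survey moments
polytrans simulate --out cohort/ --seed 7

# individual stages
polytrans score --geno cohort/genotypes.tsv --weights cohort/weights.tsv --out scores.tsv
polytrans grm --geno cohort/genotypes.tsv --out mygrm
polytrans reml --grm mygrm --pheno cohort/phenotypes.tsv --covar age,sex --out reml.json
polytrans models --data cohort/ --suite table4 --out models.json
polytrans decompose --data cohort/ --out decomp.json
polytrans mediate --data cohort/ --h2 0.20 --relatedness 0.5 --out mediation.json

# or the whole pipeline from one JSON config
polytrans run --config run.json --out run_dir/ --seed 7
```

`run` writes a `manifest.json` (config hash, seed, version), per-stage JSON
outputs, and a `report.json` whose every numeric is read back from a stage
file. Fixed seeds reproduce byte-identical reports.

## Simulator calibration

With the default `SimConfig` (5,000 families, 8 burn-in generations of
assortative mating) the realized moments are: spousal education correlation
≈ 0.61, spousal score correlation ≈ 0.22, sibling score ICC ≈ 0.59
(equilibrium value (1+r)/2 ≈ 0.61), score-alone R² on offspring education
≈ 0.024, and parent-generation h² ≈ 0.20. Structural coefficients
(`b_mother`, `gamma_within`, `gamma_between`, `theta_gxg`) act on the
standardized polygenic score by default so that fitted table analogues
recover them directly; set `genetic_regressor="true_g"` to inject the latent
genetic value instead.
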