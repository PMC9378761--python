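# facegrowth

Phenotyping and genetic association of early facial growth patterns from
longitudinal photograph landmarks.

The pipeline:

1. **Landmark phenotyping** (`facegrowth.landmarks`) — reads per-photo
   tables of 19 named facial landmark points plus the two iris centers and
   computes 21 distance phenotypes (10 horizontal H1–H10, 11 vertical
   V1–V11), each normalized by the interocular distance so every photo's
   iris-center distance maps to exactly 1. The landmark-pair table is
   configurable.
2. **Measurement QC** (`facegrowth.measurement_qc`) — per phenotype, pooled
   over all photos, trims values strictly below the 2nd / above the 98th
   percentile (percentages configurable; boxplot 1.5×IQR mode available).
3. **Trajectory classification** (`facegrowth.trajectories`) — builds
   per-(person, phenotype) series on relative age (current photo at 0),
   fits an OLS quadratic, and classifies the endpoint-slope signs into five
   growth patterns: DD=1 (continued decrease), DI=2 (decrease→increase),
   CC=3 (constant), ID=4 (increase→decrease), II=5 (continued increase).
4. **Genotype QC** (`facegrowth.genotype_qc`) — per-SNP call rate, MAF and
   a from-scratch exact Hardy–Weinberg test; retains SNPs with
   call rate ≥ 0.98, MAF ≥ 0.10 and HWE p > 1e-4. Reads VCF (via cyvcf2)
   and PLINK-style text .ped/.map.
5. **Association** (`facegrowth.association`) — single-SNP linear
   regression of the 1–5 pattern code on allele dosage (no covariates):
   Wald t-test (n−2 df) and Gaussian likelihood-ratio test, uncapped
   Bonferroni adjustment (default M = 800,000), significance tiers
   (p < 5e-8 significant; 5e-8 ≤ p < 1e-5 suggestive), 500 kb locus
   clustering (clustered = some member has > 3 co-segregating tiered
   neighbors), and replication selection (combined p < 1e-5 plus both
   population p < 0.05). Plain Manhattan/QQ plots optional; an
   ordinal-logit sensitivity test is available as `ordinal_qtl`.
6. **Cohort replication** (`facegrowth.replication`) — modal-pattern
   concordance between two cohorts' pattern frequency tables.
7. **Synthetic cohorts** (`facegrowth.simulate`) — genotypes drawn in HWE,
   ordinal pattern codes from a latent-propensity threshold model with
   planted SNP effects, quadratic trajectory templates realizing each
   pattern, and landmark fixtures with independently computed ground
   truth. Writers for landmark CSV, VCF and .ped/.map text.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked
Bonferroni examples, structural constants, filter boundaries, oracle
equivalence of the HWE and Wald implementations, type-I calibration,
pattern/parameter recovery, cohort concordance).

## CLI

```sh
facegrowth run-all --seed 1 --out runs/demo        # full synthetic run
facegrowth init-config cfg.yaml                    # write default config
facegrowth run-all --config cfg.yaml               # run from config
facegrowth phenotype landmarks.csv --out pheno.tsv # landmark CSV -> phenotypes
facegrowth qc pheno.tsv --trim-pct 2 --out mask.tsv
facegrowth classify pheno.tsv --out patterns.tsv
facegrowth geno-qc genotypes.vcf --out stats.tsv
facegrowth assoc patterns.tsv genotypes.vcf --out assoc.tsv
facegrowth replicate table_pop1.tsv table_pop2.tsv --out concordance.tsv
```

`run-all` writes every stage's TSV plus `manifest.json` (config hash,
seed, versions, per-stage record counts); identical config + seed gives
byte-identical outputs.

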