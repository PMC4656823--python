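# transfermap

Tools for testing whether GWAS susceptibility loci discovered in one
population transfer to a case-control cohort from another, and for
fine-mapping transferable loci by exploiting shorter haplotype blocks.

The pipeline stages:

1. **Cohort QC** — sample cascade (call rate, duplicate detection at
   PiHat ≥ 0.95, X-heterozygosity sex check, greedy relatedness pruning
   at PiHat > 0.125) and variant filters (missingness > 0.05, exact HWE
   p < 1e-6 on genotyped variants, MAF < 0.01, and for imputed dosages
   folded frequency < 0.01 or imputation r² < 0.3).
2. **Association** — per-variant logistic regression on allelic dosages
   with age, sex, BMI and the top genotype PCs as covariates; Wald
   tests; genomic-control lambda.
3. **LD structure** — two-locus EM haplotype frequencies from unphased
   genotypes, 90% profile-likelihood intervals on |D′|,
   confidence-interval haplotype blocks (strong pair CI ≥ 0.70/0.98,
   recombination CI < 0.90, ≥ 95% informative pairs strong), and the
   spectral effective number of tests Neff = (Σλ)²/Σλ².
4. **Transferability** — exact calls (index SNP p < 0.05 with
   harmonized direction consistent with the reported OR), local calls
   (best block SNP with p·Neff < 0.05 and r² ≥ 0.3 to the index), a
   one-sided exact binomial sign-consistency test, and block-span
   fine-mapping verdicts against a reference panel.
5. **Power** — analytic one-sided allelic Wald power for replicating a
   reported per-allele OR, with a simulation cross-check.

A first-class synthetic-cohort module (`transfermap.synth`) generates
block-structured haplotype panels, genotypes, logistic phenotypes under
case-control ascertainment, imputation-style dosage noise, and planted
QC flaws with a truth ledger, so the whole pipeline is testable without
external data.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences, planted-structure recovery, statistical calibration); the
rest are per-module unit and property tests.

## CLI

```sh
transfermap simulate --out demo --seed 1          # synthetic scenario
transfermap qc --vcf demo/cohort.vcf --samples demo/samples.tsv --out demo/qc
transfermap assoc --vcf demo/cohort.vcf --samples demo/samples.tsv --out demo/assoc
transfermap blocks --vcf demo/ref_eur.vcf --out demo/blocks
transfermap power --out demo/power.tsv
transfermap run --config demo/config.yaml         # full pipeline
```

Inputs are a dosage VCF (per-sample `DS`, `GT` fallback), a tab-separated
sample table (`sample_id`, `status`, `age`, `sex`, `bmi`, optional
`xhet`), and an index-locus catalog
(`SNP CHR BP RISK_ALLELE REPORTED_OR PANEL GENE`). Outputs are TSVs
mirroring the association/transfer tables, a BED-like block file, and a
JSON run summary.

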