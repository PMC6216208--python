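# gwascreen

Case-control SNP association statistics and a network-based *in silico*
drug-repurposing screen, built around the workflow that connects a GWAS
risk locus to candidate approved drugs.

The package is written for statistical geneticists and computational drug-
discovery researchers who have (a) per-SNP genotype counts from a
case-control study and (b) gene-level resources — a protein–protein
interaction (PPI) edge list and a drug→target table — and want a tested,
reproducible implementation of both halves of that pipeline.

## What it computes

**Association statistics** (`gwascreen.assoc`), for each SNP with genotype
counts ordered (hom-minor, het, hom-major):

- minor allele frequency, MAF = (2·n_aa + n_aA) / 2n, and the genotyping
  call rate;
- the Cochran–Armitage trend test (1 d.f., additive weights 0/1/2, no
  continuity correction), χ² = U²/Var(U) with
  U = Σᵢ wᵢ (S·rᵢ − R·sᵢ)/N;
- the 2×3 genotypic Pearson chi-square (2 d.f.);
- the exact Hardy–Weinberg equilibrium test: full enumeration of
  heterozygote counts conditional on the observed allele counts, summing
  the probability of every configuration no more probable than the
  observed one;
- the allelic odds ratio from the collapsed 2×2 allele table with a Wald
  CI on the log scale (Haldane–Anscombe 0.5 correction on zero cells);
- two-locus LD, r² = D²/(p_A(1−p_A)p_B(1−p_B)), from phased haplotype
  counts;
- inverse-variance fixed-effects meta-analysis of per-study log odds
  ratios.

**Drug screen** (`gwascreen.screen`): expand a risk-gene list by its direct
PPI neighbors (neighbors exclude the seeds, so |disease set| = |seeds| +
|neighbors|), intersect the combined disease gene set with the targets of
approved drugs, and report candidate drugs grouped into families, with
per-gene provenance (seed vs neighbor) and the full count cascade.

**Synthetic data** (`gwascreen.simulate`): genotype counts under a
per-allele multiplicative odds model (controls at HWE, case probabilities
∝ HWE × OR^dose), type-I-error and power calibration of the trend test,
and planted screening instances whose cascade counts are known by
construction.

## Worked example

`examples/rit2_counts.tsv` holds published genotype counts for five SNPs
in the *RIT2* Parkinson's-disease locus (988 cases / 2521 controls):

```sh
gwascreen assoc --in examples/rit2_counts.tsv --out assoc.tsv --plot-data plot.tsv
```

`assoc.tsv` (columns abridged):

```text
snp_id     maf_case  maf_control  p_trend   p_hwe_control  or_allelic  ci_low  ci_high  call_rate_control
rs879215   0.1240    0.1626       4.59e-05  0.2146         0.7287      0.6252  0.8495   1.0000
rs4130047  0.4195    0.3635       1.37e-05  0.8296         1.2656      1.1381  1.4074   0.9996
```

rs4130047 is the most significant SNP of the locus: trend P = 1.37×10⁻⁵,
an allelic odds ratio of 1.27 (95% CI 1.14–1.41) for the C allele, and no
HWE deviation in controls (P = 0.83). `plot.tsv` contains the
position-sorted −log₁₀ P values for regional plotting.

The screen side runs off three TSVs (gene list, PPI edges, drug targets):

```sh
gwascreen simulate --kind screen --seed 1 --out-dir demo/
gwascreen screen --genes demo/risk_genes.txt --ppi demo/ppi.tsv \
    --drugs demo/drug_targets.tsv --out report.tsv
```

The report header carries the cascade counts
(`n_seed`, `n_neighbor`, `n_disease_genes`, `n_hit_genes`,
`n_candidate_drug_families`) followed by one row per candidate drug with
its hit genes and their provenance.

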