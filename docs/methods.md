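# Methods

## Statistical model and procedures

### Genotype-count conventions

All genotype triples are ordered (hom-minor, het, hom-major); readers and
writers enforce this ordering and it is documented on every public
signature. The minor allele, when a table must infer it, is the allele
with the lower pooled case+control frequency, ties broken alphabetically.
Positions are 1-based; the genome build is carried as a free-text label
(default `hg19`) and no strand flipping or allele harmonization is
performed — inputs are assumed pre-harmonized.

### Cochran–Armitage trend test

For a 2×3 table with case counts r_i, control counts s_i, column totals
n_i, R = Σr_i, S = Σs_i, N = R + S and scores w = (0, 1, 2):

    U   = Σ w_i (S·r_i − R·s_i) / N
    Var = (RS/N³) · (N Σ w_i² n_i − (Σ w_i n_i)²)
    χ²  = U²/Var  on 1 d.f.

No continuity correction is applied. The additive scores are the GWAS
standard and are the package default; other weightings can be passed
explicitly. The statistic is invariant to simultaneously reversing the
genotype ordering in both groups (i.e. to which allele is labelled
minor). A pooled-monomorphic table has Var = 0; the test then returns
statistic 0, p = 1 and a warning flag rather than raising, since such
SNPs routinely appear in genome-wide input and should not abort a run.
Equivalently χ² = N·r², r the Pearson correlation between allele dose and
case status over individuals; the test suite uses that identity as an
independent oracle, and a margin-conditional permutation oracle as a
second one. Because the permutation distribution is discrete, the
permutation comparison uses its mid-p value (half weight on the atom at
the observed statistic), which is the quantity the continuous χ² tail
approximates.

### Genotypic test

Pearson chi-square on the full 2×3 table, 2 d.f., no correction
(`scipy.stats.chi2_contingency` behind the module surface). Genotype
columns with zero pooled count are dropped and the degrees of freedom
reduced; fewer than two non-empty columns is an error because no
association test exists on a single column.

### Exact Hardy–Weinberg test

With n samples and n_a copies of the rarer allele, the conditional null
distribution over heterozygote counts h (same parity as n_a) is

    P(h | n, n_a) ∝ n! · 2^h / (n_aa! · h! · n_AA!)

normalized over all feasible h. The returned p-value is the sum of P(h)
over configurations with P(h) ≤ P(h_obs) — the standard exact test, not
the mid-p variant. The choice matters: on the example control triple
(330, 1172, 1018) the exact test gives 0.8296 while the 1-d.f. asymptotic
chi-square gives a different value, and published locus reports of this
kind print the exact value. Implementation is log-space (lgamma) with
max-subtraction, stable for cohort-scale counts; ties are detected with a
1e-12 relative tolerance. An exact rational-arithmetic enumeration
(`fractions.Fraction`) serves as the test-suite oracle, exhaustively for
all triples with n ≤ 50.

### Allelic odds ratio

Genotypes collapse to allele counts (minor = 2·hom-minor + het); OR =
(case_minor·control_major)/(case_major·control_minor), CI Wald on the log
scale at the requested level. If any of the four allele cells is zero,
0.5 is added to all four (Haldane–Anscombe) and the result flags the
correction; the flag lets table writers annotate the row rather than
silently blending corrected and uncorrected estimates.

### LD r² and meta-analysis

r² is computed directly from phased haplotype frequencies (D = p_AB −
p_A·p_B; r² = D²/(p_A(1−p_A)p_B(1−p_B))) and requires both loci
polymorphic; haplotype phasing itself (EM or otherwise) is out of scope —
the function takes phased counts as input. Meta-analysis is fixed-effects
inverse-variance pooling on the log-OR scale: w_i = 1/se_i², pooled se =
(Σw_i)^(−1/2), two-sided normal p. Heterogeneity statistics (Q, I²) are
not computed; with the package's intended use (pooling a new cohort with
one published estimate) a random-effects layer would be spurious
precision.

## The screen

The cascade is purely set-based: seeds → direct PPI neighbors (seed genes
excluded from the neighbor set, so the disease-set size is exactly
|seeds| + |neighbors|) → intersection with targets of drugs passing the
approval-status whitelist (default `{"approved"}`) → candidates grouped
into families. Gene identity is the uppercase symbol string; identifier
mapping (Entrez/UniProt) is the caller's responsibility. "Family" is
deliberately an input: records may carry a family id, a drug→family map
may be supplied, and an unassigned drug is its own family — no grouping
heuristic is hard-coded because none is canonical. The approval filter is
applied before intersection by default. Everything is deterministic
(candidates sorted by drug id), so identical inputs give byte-identical
reports.

## Synthetic data

`simulate_genotype_counts` draws controls multinomially from HWE
proportions (p², 2pq, q²) at the population MAF and cases from the same
proportions tilted by OR^dose and renormalized — the multiplicative
per-allele odds model, the natural generator when the target of inference
is a single allelic OR. Under it the case allele frequency has closed
form p·OR/(1 − p + p·OR), which the tests verify both algebraically
against the tilted probabilities and by simulation. Defaults mirror the
motivating study design: 988 cases, 2521 controls, MAF 0.3635, OR 1.27.

What the generator does *not* emulate: LD between SNPs, genotyping error,
population stratification, covariates, or genotypic (non-multiplicative)
risk. Passing calibration tests therefore show the statistics behave
correctly under a clean additive model, not robustness to those
real-data complications.

`make_planted_screen` builds instances with known cascade counts: seeds,
exactly the planted number of neighbor genes wired to ≥ 1 seed, and
background edges drawn uniformly (Erdős–Rényi style) from pairs that
cannot enlarge the neighbor set (seed–background edges are excluded;
everything else is allowed). Approved drugs are spread surjectively over
the requested number of families and target exactly the planted hit
genes; decoy drugs (approved ones targeting background genes, unapproved
ones targeting disease genes) are added and must leave every count
unchanged. The uniform background graph is a documented simplification —
the screen is set-based, so degree-distribution realism would not change
any tested quantity. The planted instance's `truth` is filled from the
construction, never by running the screen, which keeps it a genuine
oracle.

## Numerical and design choices

- P-values print in scientific notation with 3 significant digits
  (lower-case `e` in machine output); MAFs, call rates and HWE p-values
  print to 4 decimals. These match the precision at which locus reports
  are conventionally printed and make golden-file tests exact.
- Monte-Carlo acceptance bands are ±5 binomial standard deviations, wide
  enough to keep false failures rare while still detecting calibration
  bugs.
- Simulation sizes in the test suite (10,000 null replicates at 500/500
  for type-I error; 2,000 replicates at 988/2521 for OR recovery; 100
  planted screen instances) were chosen as the smallest sizes at which
  the ±5-SD bands are informative about the properties being checked.
- All generators are pure functions of (parameters, seed), via
  `numpy.random.default_rng`; the CLI routes every random stream through
  `--seed`.

## Known limitations

- The screen stops at first neighbors: no network propagation, random
  walks or diffusion scoring, and no drug ranking — candidates are
  reported, not prioritized.
- Reproducing literal published candidate counts requires the specific
  PPI and drug-database versions a given study used; with planted
  instances the package demonstrates correctness of the cascade, not of
  any external database snapshot.
- The exact HWE test enumerates one SNP at a time; for genome-wide use a
  vectorized batch implementation would be preferable.
- `annotate_literature` does arithmetic on a curated evidence list; the
  curation itself (which families have reported neuroprotective effects)
  is an input, not a computation.
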