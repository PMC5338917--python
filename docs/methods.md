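# Methods

## The procedure

The pipeline identifies candidate regulatory SNPs by requiring convergent
evidence along the causal chain *enhancer → TF binding → cis expression →
outcome*:

- **Regulatory regions.** Open-chromatin (DHS) and active-enhancer
  (H3K27ac) peaks are unioned into an "active" set; the five TF ChIP-seq
  peak sets are unioned with per-region support counts; the regulatory set
  is the exact base-pair intersection of the two. All interval arithmetic
  is on 0-based half-open coordinates, abutting intervals merge (a
  non-redundant region collection means maximal runs), and a region's
  TF support is the number of distinct TF peak sets overlapping it by
  ≥ 1 bp anywhere — binding is a per-region property, not per-base.
  Chromosome names are compared by exact string equality; mixed
  `chr1`/`1` naming raises instead of being silently normalized, because
  silent normalization hides upstream data errors.
- **SNP membership.** Array manifests store 1-based positions; the overlap
  test converts with `pos − 1`. A SNP on a chromosome absent from the
  region set is dropped without error.
- **cis-eQTL.** Genes qualify when |TSS − SNP| ≤ 25 kb, boundary
  inclusive, distance measured to the TSS (the interaction-relevant
  anchor) rather than the gene body. Samples are grouped by observed
  genotype class; classes with < 3 samples are dropped (an F statistic on
  a 1–2 sample group is noise), and < 2 remaining classes makes the pair
  untestable rather than an error. The ANOVA is computed from explicit
  sums of squares so degenerate inputs have defined outcomes: zero
  between- and within-group variance → F = 0, p = 1; zero within-group
  variance with unequal means → F = ∞, p = 0. Multiplicity is controlled
  by Benjamini–Hochberg FDR at 0.05 across all tested pairs (a raw-p
  override exists); expression enters as provided, with an optional
  log2(x+1) flag default-off.
- **Motif scoring.** Log-odds base 2 against a uniform background with a
  probability floor of 10⁻³ (matrix dialects contain near-zero entries; an
  explicit floor keeps scores finite and documented). The reverse strand
  is scored by reverse-complementing the window and applying the unmodified
  PWM. `N` scores as the worst base at its position — conservative, never
  creating a spurious gain. All L placements covering the SNP must fit in
  the ±F flank (F = 20 by default), else the scorer instructs a larger
  flank. When both alleles pass the detection threshold, a direction is
  only called at |Δ| ≥ 2 bits (≈ a strong single-base preference);
  otherwise the SNP is neutral for that motif.
- **Candidate rule.** Region membership ∧ significant eQTL ∧
  disrupt/create call. Differential expression and recurrence risk are
  annotations, not filters — a regulatory SNP can act without changing
  average tumor expression. Candidates are labeled promoter/distal by
  TSS ± 2 kb.
- **Differential expression.** Fold change on the linear normalized scale
  with a +1 offset guarding zero means (tumor-high means FC > 1); the
  p-value from Welch's t on log2(x+1), with a Wilcoxon rank-sum option.
  The combined call is |FC| > 1.5 and p < 0.01.
- **Risk stratification.** z-scores use the normal-sample mean and n−1
  standard deviation (stated to pin the convention); σ = 0 excludes the
  gene with a warning. The extreme-75% rule uses floor with a minimum
  stratum size of 1; ties at the retention boundary resolve by stable
  sample-id order, making assignments permutation-invariant. Kaplan–Meier
  estimation and the two-sided log-rank test (standard aggregated
  risk-set treatment of ties) come from lifelines; both-groups-censored
  data is untestable, not an error.

## Synthetic cohort

The generator emulates the *processed* forms of a tumor-profiling study:
peak intervals, allele-count genotype calls, RSEM-like positive normalized
expression, and months-to-recurrence clinical records. Default
conditions: 2 chromosomes × 1 Mb, 200 tumors / 50 normals, 500 array SNPs
(5 planted regulatory, 50 in-region decoys, the rest outside regions),
300 genes, MAF uniform on (0.1, 0.5) with planted SNPs on (0.25, 0.45) so
all three genotype classes are populated at n = 200 (genotyping arrays
target common variants), additive eQTL effect of 1.0 noise-SD per allele
copy on the log scale with noise σ = 0.5, planted DE shifts of 3-fold,
hazard ratio 3 for the high-expression tail of one designated risk gene
(which deliberately carries no DE shift, so both z-score strata stay
populated), 30% censoring, and length-8 PWMs of ~14 bits information with
the detection threshold midway between the consensus score and the score
after one worst-case core substitution — a single core change crosses the
threshold by construction, which the generator asserts at build time.

Genotypes follow Hardy–Weinberg proportions; expression is Gaussian on the
log scale then exponentiated; event times are exponential with the hazard
doubled-plus for high-risk tumors; censored samples (a `censor_rate`
fraction, chosen exactly) get a uniform time before their event. All
randomness descends from one seed through named child streams, one per
artifact, so adding artifacts never perturbs existing ones and emitted
files are byte-identical across runs.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, gene–gene expression correlation, population structure, tumor
purity, batch effects, or realistic genome composition. Passing tests
therefore demonstrate that the machinery is correct and well-calibrated
under its stated model — not that the pipeline's discoveries on real
cohort data would be free of the confounders those features introduce.

## Numerical and design choices

- Problem sizes throughout (1 Mb chromosomes, 500 SNPs, 2,000-replicate
  calibrations, 100-replicate power runs) are chosen so the full suite and
  the acceptance script complete in well under a minute each on one core
  while leaving the Monte-Carlo tolerances meaningful.
- The interval algebra is implemented directly (sorted sweep, two-pointer
  intersection, binary-search membership) and validated against literal
  per-base oracles; the per-region distinct-source support count the
  pipeline needs is not expressible as a single call in generic
  genomic-ranges libraries.
- Where both a heterozygous and a rare-homozygous class are observed with
  ≥ 3 samples each, the ANOVA keeps them separate (3 groups); pooling is
  not performed.
- The risk module reports direction-neutral log-rank statistics plus the
  stratum assignments; the sign of the high-vs-low effect is left to the
  caller, since either direction is biologically interpretable.
- Re-running the pipeline recomputes every stage deterministically rather
  than caching; byte-identical outputs make re-runs idempotent without
  cache-invalidation machinery.

## Known limitations

- No covariate adjustment (ancestry, purity) in the eQTL scan; no LD
  pruning — associated SNPs may tag rather than cause.
- Motif calls are threshold-based, not p-value calibrated; indels are out
  of scope.
- DE uses two-sample tests on normalized values, not count models with
  dispersion shrinkage.
- Survival analysis is single-variable Kaplan–Meier/log-rank; no Cox
  modeling or competing risks.
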