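# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the design decisions behind `gagwas`, in the
spirit of a package's model documentation: what is computed, under which
assumptions, and what the tests do and do not demonstrate.

## Phenotype and study design

The phenotype is gestational age at delivery in integer days (registry
dating granularity). Analyses are stratified six ways: maternal or fetal
genome × delivery onset (labor, PROM, or both), because the two onsets
plausibly represent different aetiologies and mixing them dilutes signal.
No covariate adjustment is performed; permutation testing is relied upon to
protect against the strongly skewed, bimodal phenotype distribution that a
case-oversampled design produces.

## Association model

For each SNP the minor allele is the effect allele (sample frequency;
lexicographically greater token on a 0.5 tie). Three codings of the
genotype g ∈ {0,1,2} are tested: additive (g), recessive (1{g=2}) and
dominant (1{g≥1}). The statistic is |t| from the simple linear regression
of phenotype on coded dosage with pairwise deletion of missing calls. A
coding with zero dosage variance (e.g. no minor homozygote) is
*skipped-degenerate* and excluded from the per-SNP summary.

Empirical significance uses label permutation of the phenotype vector. One
permutation per replicate is shared by every SNP × model test active in
that replicate — the semantics of the standard GWAS permutation engines,
and essential for speed. Exceedances count ties (|t*| ≥ |t|), and the
estimator is p = (R+1)/(N+1), which is valid (never anti-conservative)
under exchangeability. Permutations are generated in fixed-size blocks of
256 from a seeded PCG64 stream, so results are bit-reproducible and
independent of pruning decisions.

**Adaptive stopping.** Checkpoints start at `min_perms` (10) and then recur
every `max(1, ceil(a + b·N))` replicates with a = 1 (initial interval) and
b = 0.001 (slope). At a checkpoint the two-sided normal-approximation
interval around R/N at confidence 1−β is computed; when its lower bound
exceeds α the test stops with status *pruned*. With α = β = 5×10⁻⁸ this is
one-sided in effect: only clearly non-significant tests stop early, and in
practice a test prunes once R exceeds ≈ z²(1−R/N) ≈ 30 exceedances.
`max_perms` defaults to 10⁵ at desk scale (p-floor 10⁻⁵); the full-scale
10⁹ is a configuration value. A fixed-N mode (`adaptive=False`) uses the
identical replicate stream, so tests that reach the cap under both modes
have identical R — a tested invariant.

Each SNP reports the most extreme empirical p across its non-skipped
models, with the deterministic tie-break additive > dominant > recessive.
This combined minimum is deliberately uncorrected for the three-model
multiplicity, mirroring the exploratory reporting convention; an optional
second-stage family-wise correction exists in the enrichment module where
it matters most. X-chromosome SNPs are tested additively only.

## Quality control

Order: sample missingness → SNP missingness → heterozygosity → relatedness
→ Hardy-Weinberg → PCA ancestry. Entity-level filters run before
statistics that assume clean data; each stage logs removed entities, and
the report reconciles counts exactly.

* **Missingness**: strict 3% on samples first, then on SNPs recomputed over
  the remaining samples.
* **Heterozygosity**: autosomal het rate per sample; beyond 3 SD of the
  genome-type group mean removed (population SD; a zero-SD group removes
  nobody).
* **Hardy-Weinberg**: the exact conditional test — given the allele
  counts, the probability of all heterozygote configurations no more
  probable than the one observed (log-gamma arithmetic; a 1+10⁻¹²
  relative tolerance guards float ties). Threshold p < 10⁻⁶ on autosomes;
  monomorphic SNPs give p = 1. The implementation is verified against an
  exact rational-arithmetic enumeration over every genotype table with
  n ≤ 50 (agreement < 10⁻¹⁰).
* **Relatedness**: method-of-moments genome-wide IBD (PI_HAT = P(IBD=2) +
  P(IBD=1)/2) from IBS counts on an LD-thinned SNP set (greedy 50-SNP
  windows, r² > 0.2). Conditional IBS probabilities use *unbiased
  factorial-moment* estimates of p²q², p³q, pq — plug-in sample
  frequencies systematically overstate relatedness at small SNP counts.
  Because the estimator's sampling noise scales as 1/√M, a pair is flagged
  only when PI_HAT exceeds both the configured threshold (default 0.05,
  "closer than second cousins") and a data-driven noise floor (median + 5
  robust SDs of all pairwise values); with realistic SNP counts the floor
  is negligible and the threshold alone governs. One random (seeded)
  member of each flagged within-group pair is removed.
* **PCA ancestry**: study and reference panels are merged on shared,
  LD-thinned SNPs, standardised by reference allele frequencies
  ((g−2p)/√(2p(1−p)), missing mean-imputed for the decomposition only) and
  decomposed together; fitting on the merged matrix is necessary — a
  divergent study cluster is invisible when projected onto
  reference-only components. Samples beyond 10 SD of the reference
  distance distribution (first 3 PCs) are removed. Absent reference panel
  skips the stage with a warning.
* **Genomic inflation**: λ = median(χ²)/0.45494 over additive-model 1-df
  Wald χ² (t²) at MAF > 0.06, reported to three decimals.

## Clumping

Candidates with p < 5×10⁻⁴ are processed in ascending p (ties by
chromosome, then position). A new index claims every still-unassigned SNP
on its chromosome strictly within 250 kb, with r² > 0.25 to the index and
own p < 0.05. Each SNP joins at most one clump (first-processed index
wins), distances are index-to-member, and the inequalities are strict.

r² defaults to the EM maximum-likelihood haplotype-frequency estimate on
founders: the only latent quantity is the double-heterozygote phase, the
EM update preserves the observed allele frequencies exactly, and iteration
stops at 50 rounds or frequency change < 10⁻¹⁰. The estimate is verified
against an exhaustive grid search over the one free haplotype frequency
(|Δr²| < 10⁻³). A squared-Pearson dosage correlation is available as a
fast, assumption-light alternative. Monomorphic pairs yield NaN, treated
as below any threshold.

## Gene-set mining

An abstract enters a keyword's pool when it contains ≥1 keyword term
(case-insensitive exact token) AND ≥1 genetics term (text or MeSH), and no
non-human or condition indicator token. Condition indicators can be mined
from any vocabulary by suffix (-osis, -itis, -emia, -oma; ≥5 letters;
minus an allowlist of non-conditions such as "diagnosis"). Gene mentions
are tokens equal to a known symbol case-sensitively, or all-uppercase
tokens (≥2 characters) matching case-insensitively; a blacklisted symbol
is suppressed when any of its forbidden phrases co-occurs. Genes need more
than one supporting abstract per keyword. Non-exempt keywords exclude
abstracts that also match another non-exempt keyword; the "very common"
exemption is an explicit per-keyword flag (the ubiquity criterion is a
judgement call, so it is configuration, not heuristic), and control
keywords are exempt by design. The shipped 12 candidate + 16 control
keyword configs, the indicator lists and the acronym blacklist are curated
editable defaults, not authoritative vocabularies. There is no network
path: the corpus is a local JSON-lines snapshot, which is what makes the
procedure reproducible.

## Enrichment

The top `top_k_clumps` (300) clump spans — singletons widened by a ±1 kb
flank so degenerate intervals stay usable — are filtered to those with ≥1
gene within the 25 kb offset, then overlap-merged into non-overlapping
target intervals. Interval SNP counts are (re)computed as the number of
analyzed map SNPs inside the span, which avoids double counting in merges.
The statistic per gene-set is T = number of target intervals within the
offset of ≥1 set gene (boundary-touching counts); the number of distinct
genes hit is reported alongside, since both views of "hits" are useful.

The null redraws, per replicate, one random interval per target interval:
a uniformly random map SNP anchors the interval, which extends rightward
over m map SNPs with m/m_template in [0.90, 1.10] (hard criterion), stays
on one chromosome, and keeps span/template_span within a soft band
([0.5, 2.0]; widened stepwise with a logged warning if sampling starves;
skipped for single-SNP templates). One shared replicate serves all sets;
p = (1+#{T* ≥ T})/(1+N). Random intervals may be gene-less by default —
only *observed* gene-less intervals are dropped, and a conservative
"resample until gene-containing" mode is one flag away. The optional
second stage converts per-replicate minima across sets into family-wise
corrected p-values. On a toy genome where every admissible placement can
be enumerated, the permutation p agrees with the exact placement
probability within Monte-Carlo error (a tested oracle).

## Synthetic data

The generator's defaults are the package's study conditions.

* **Genotypes** — haplotype-pool block model: each block (10 SNPs, 5 kb
  spacing) holds K founder haplotypes (default 8) drawn at a per-SNP MAF ~
  U(0.1, 0.5); an individual's two copies choose a pool member per block
  and redraw it with probability 0.5 at each boundary. This produces
  elevated within-block r² (mean ≈ 0.15 at K = 8, up to ≈ 1 at K = 2) and
  near-independent blocks (adjacent-block mean r² ≈ 0.035) — block-local
  LD, which is what greedy clumping assumes. A coalescent simulator would
  be more realistic but is unnecessary for these contracts.
* **Phenotype** — GA = 270 + Σ model-coded causal effects + N(0, 15²),
  rounded to days. The cohort is assembled by individual-level rejection:
  keep simulated individuals while the preterm (154–258 d) or term
  (273–286 d) window still needs members (default quota 40:60), capped at
  100× the target before a simulation error. Selection acts on the
  phenotype, so genotype–phenotype association survives — the mechanism
  of extreme-phenotype oversampling. The baseline/noise values put ≈20%
  and ≈30% of latent mass in the two windows, keeping rejection cheap.
  Onset (labor 0.807) and genome (mother 0.616) labels follow the cohort
  proportions of the motivating study and are drawn independently of
  genotype. `auto_causal_spec` sizes each causal effect from the
  variance-fraction prescription β = √(f·σ²_tot / var(coding)) using
  founder-pool frequencies.
* **Annotation** — genes of 10 kb tile each chromosome with 2.5 kb gaps;
  a causal SNP landing in a gap extends its upstream gene, so every causal
  SNP lies inside a gene by construction. The first candidate keyword's
  set is the truth set (default ≈1.5% of genes, min 5) containing the
  causal genes; the other 11 candidate-analog and 16 control-analog sets
  are random draws of 4–8% of genes — sized so a clump-scale interval
  (+offset) lands near a null set with mid-range probability, giving null
  hit counts wide support instead of degenerate 0/1 outcomes. Four genes
  are reserved out of every set as dedicated trap symbols.
* **Corpus** — two abstracts per (keyword, gene) pair (so true genes pass
  the >1-abstract filter) plus labelled traps: a non-human indicator
  ("bovine"), a condition indicator ("listeriosis"), an acronym collision
  (SPTB beside "spontaneous preterm birth"), a single-mention gene, and a
  multi-keyword abstract. Trap genes never belong to a set, so any filter
  failure is visible as a spurious gene. Mining the corpus reproduces the
  emitted sets exactly.

What the synthetic data does **not** emulate: realistic human allele
spectra and LD decay, genotype–stratum correlation, batch effects,
genuine literature language (templated abstracts), or population structure
beyond one optional frequency-shifted cluster for the PCA test. Passing
tests therefore demonstrate correctness of the algorithms under the
assumed structure, not field performance on real cohorts.

## Numerical and reproducibility choices

* Every stage seed derives from a global seed plus stage/stratum labels via
  SHA-256 (always < 2³¹), so strata are independent yet reproducible; a
  full pipeline rerun is byte-identical (hash-stamped manifest).
* Internal coordinates are 1-based inclusive; BED converts at the I/O
  boundary. Strand is ignored (allele-count coding).
* The PED/MAP reader canonicalises alleles (a2 = minor; lexicographically
  greater token on ties) and writes heterozygotes in lexicographic order,
  making write∘read the identity on files; a monomorphic SNP's absent
  allele is unrecoverable from PED and becomes the placeholder "0".
* The adaptive-permutation engine's pruning interval uses the named keys
  `prune_interval_init` / `prune_interval_slope` because the two symbols
  are order-ambiguous in common usage; both conventions are expressible.
* Permutation is within the analysed stratum (each stratified GWAS is a
  self-contained sample).

## Known limitations

* MoM PI_HAT needs ≳10⁴ informative SNPs before a 0.05 threshold is
  meaningful; below that the noise floor governs (logged).
* The desk-scale permutation cap (10⁵) floors empirical p at 10⁻⁵;
  clump ranking below that floor falls back to tie-break order.
* Gene-symbol recognition is exact-token; no synonym expansion or NER.
* Cross-chromosome clumping, conditional multi-signal analysis,
  mitochondrial/Y/pseudo-autosomal variants and sex checks are out of
  scope.
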