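# Methods

This note documents the models, parameter choices and numerical decisions
behind `cribsc`, and what the synthetic data do and do not establish about
real data.

## Study design being modelled

Each of 7 patients contributes a benign-enriched and an ICC/IDC-enriched
prostate specimen. Specimens are dissociated, sorted into immune (CD45⁺),
epithelial (EpCAM⁺) and other (CD45⁻EpCAM⁻) fractions, recombined at
30/25/45%, hash-tagged per specimen with two oligo antibodies, and pooled
30:70 benign:tumor for droplet sequencing. Downstream, cells are
demultiplexed from the hashtags, QC-filtered, clustered (cluster labels
are consumed as input here — the generator provides the truth), and
analysed per cluster with patient-paired statistics.

## Synthetic-data generator

The generator's defaults are the study conditions above. Choices:

- **Composition is exact, not expected.** Cells are allocated to
  conditions and fractions by largest-remainder rounding of the
  configured proportions (ties to the first-listed category), so a
  10,000-cell pool carries exactly 3,000/2,500/4,500 fraction labels and
  3,000 benign labels. Sampling proportions would only match in
  expectation.
- **Counts** are negative binomial per gene with fixed dispersion 0.5 and
  log-normal baseline means (scale `base_mean = 2.0`, giving a few
  thousand counts and several hundred detected genes per cell — deep
  enough that the QC gate's >500-count rule is a live filter rather than
  a wall). Clusters are dealt round-robin to the three fractions; each
  cluster elevates 10 marker genes 8-fold. DE is planted per
  (cluster, gene, log2FC) by scaling tumor-cell means.
- **Mitochondrial content**: a per-cell target fraction ~ Beta(2, 8) is
  imposed by scaling the mito-gene means; the NB draw adds noise around
  it, so a realistic tail of cells exceeds the 40% QC bound.
- **Hashtags**: on-target counts NB with mean 200, off-target mean 3
  (dispersion 0.5). The real count distributions are not published;
  these are stand-ins exposed in `SynthConfig`. Doublets receive
  on-target signal on both tags, negatives background on both; they are
  injected by corrupting the hashtag counts of a largest-remainder 3% /
  2% of cells while keeping the transcriptome and the truth condition
  label intact, so demultiplexing accuracy is measured over the
  uncorrupted singlets.
- **TCR repertoires**: each clonotype receives a fixed productive chain
  composition (1α+1β / 2α+1β / 1α+2β at 88/7/5%) and CDR3 sequences
  drawn once; cells sample clonotypes from configurable per-condition
  frequency vectors. A configurable fraction of cells get >4 productive
  chains to exercise the chain filter, and non-productive chains are
  sprinkled in to verify they are ignored.
- **Survival cohorts**: gene expression is standard normal; the true
  signature score (even mean) above the cohort median multiplies an
  exponential event rate by the configured hazard ratio; censoring times
  are exponential with rate set so roughly the requested fraction is
  censored. Default sizes in the dual-cohort stage are 492 and 131 —
  the sizes of the two public prostate cohorts the synthetic cohorts
  stand in for.
- **Stain tables**: intensity-bin percentages are 100 × Dirichlet over
  (weak, moderate, strong, unstained); zero concentrations yield exactly
  0%, so a degenerate "all strong" class scores exactly 300. Stromal
  counts are Poisson, positives binomial, intensity gamma-scaled.

What the generator does **not** emulate: ambient RNA, UMI collapsing,
realistic transcriptome covariance, batch/chemistry effects, V(D)J
segment structure. Passing tests therefore establish the correctness and
calibration of the *procedures* under the stated design, not performance
on real tissue.

## Pipeline decisions

- **Demultiplexing rule** (unpublished in the source protocol, exposed as
  parameters): a tag is positive at ≥ 10 counts; exactly one positive tag
  assigns the cell; a double positive is rescued as a singlet only when
  one tag is ≥ 3× the other, otherwise it is a doublet; double negatives
  are negative. Doublets and negatives are removed before QC. The
  pipeline order is fixed demux → QC and tested in that order.
- **QC bounds**: "between 200 and 8000 genes" is read inclusive; "more
  than 500 counts" strict; "maximum 40% mitochondrial" inclusive. A
  zero-count cell gets pct_mito = 0 and a flag.
- **Detection**: the TPM ≥ 1 rule is implemented as CPM ≥ 1 — 3′/5′ UMI
  counts carry no transcript-length term, so CPM is the equivalent
  quantity.
- **Paired DE** is a paired t-test on log2(CPM+1) of per-(patient,
  condition) pseudobulk, log2FC = mean paired difference, BH correction
  across the tested (official, >20%-detected) genes. The original
  protocol used edgeR's paired GLM; the stand-in is validated by
  simulation instead (null type-I rate 3–7% at p<0.05 over 2000 genes
  and 6 pairs; sensitivity ≥ 0.8 at q<0.05 for |log2FC| = 2 planted in
  expressed genes over 7 pairs). Power simulations plant effects in the
  better-expressed half of genes because the official detection rule
  would exclude near-zero genes before testing. Zero-variance difference
  genes get p = 1 and a flag. BH is the correction of choice where the
  original's correction is unstated.
- **Ranking**: score = sign(log2FC)·(−log10 p), descending; ties by
  |log2FC| then gene id; p = 0 clamps to the smallest positive float.
- **GSEA**: weighted-KS running sum with weight p = 1 (configurable;
  p = 0 reduces to the classical KS statistic). The null permutes gene
  labels — equivalently, hit positions — n_perm = 1000 by default,
  seeded (default 17). The nominal p counts null scores at least as
  extreme in magnitude, (1 + k)/(1 + n_perm), which is uniform for
  random sets and bounded below by 1/(1+n_perm). NES divides ES by the
  mean |null ES| of matching sign; FDR is the sign-stratified tail-ratio
  over pooled normalized nulls, clipped to [0, 1]. Set members absent
  from the ranked list are dropped (counted in the log); sets with fewer
  than 5 present members are skipped. Phenotype permutation is out of
  scope — a preranked list has no per-sample expression to permute.
- **Clonotypes** are exact multisets of productive (chain, CDR3-nt)
  pairs; no fuzzy matching. Cells with more than 4 productive chains are
  removed first (non-productive chains never count); 2α+2β cells survive
  that filter and are kept but flagged, since only 2+1 and 1+2
  compositions are canonical. Expansion/contraction boundaries (2-fold,
  ½-fold) are inclusive; condition-exclusive clonotypes need ≥ 2 cells,
  else unclassified. A shift exactly at the 2-fold boundary is recovered
  only ~half the time under sampling noise (the boundary is a coin flip
  by symmetry); recovery guarantees are therefore stated for ≥ 4-fold
  shifts, where the seeded recovery rate is ≥ 95% at 1000 cells per
  condition.
- **Ligand–receptor**: no receptor-expression threshold is imposed by
  default (a `min_fraction` filter is available); receptors absent from
  the matrix report fraction 0 with a flag. The bundled pair table is a
  small synthetic structural stand-in, not a FANTOM5 reproduction; a
  full CSV can be supplied.
- **Signatures**: Z-scores are computed within each cohort (sample sd,
  ddof 1); the score is the unweighted mean; median ties go to the low
  group (deterministic and conservative for high-score claims). "High
  group worse" compares the KM curves at the end of *common* follow-up
  (the shorter group's last observed time) — each group's own final
  estimate is ~0 under exponential event times and carries no
  information. KM and log-rank delegate to lifelines and are
  cross-checked against hand-rolled product-limit and
  hypergeometric-variance oracles in the tests. Refinement keeps a gene
  iff its single-gene median split is significant (α = 0.05) with the
  high group worse in both cohorts.
- **Histology**: the Tukey pairwise table reports statsmodels'
  unrounded adjusted p-values (the printable summary rounds to 4
  decimals). The Tukey ≥ unadjusted-p invariant holds against the
  pooled-MSE pairwise t-test, which shares Tukey's variance estimator
  and degrees of freedom — not against the two-sample t-test, whose
  smaller df can produce larger p.

## Problem sizes

The shipped drivers and the acceptance script use 7 patients × 600 cells
× 1000 genes (≈ 4,200 cells), TCR repertoires of 60 clonotypes × 800
cells per condition, survival cohorts of 492 + 131 samples, and 12 stain
regions per class; calibration suites use 2,000 genes × 6–7 pairs, 100–200
replicates. These sizes give stable estimates for every reported quantity
while keeping a full run in the seconds-to-minutes range.

## Known limitations

- The paired t on pseudobulk is less powerful than a dispersion-sharing
  NB GLM at small pair counts and is not a drop-in for edgeR's estimates.
- Gene-label permutation GSEA ignores inter-gene correlation; its p-values
  are calibrated under the permutation null only.
- The survival generator induces a step hazard at the median of the true
  score, not a proportional-hazards relation per gene; per-gene
  refinement power on a 4-gene-driven hazard is modest by construction.
- Two-tag demultiplexing only; CLR-based multi-HTO demultiplexing and
  transcriptome doublet detection are out of scope.
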