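# Methods

msapkit implements the band-based MSAP (methylation-sensitive amplified
polymorphism) workflow for quantifying global DNA-methylation
differentiation between experimental groups, and the efficiency-corrected
2^-ΔΔCq workflow for relative gene expression. This note documents the
models, the defaults and why they were chosen, the numerical decisions,
and what the synthetic-data generators do and do not emulate.

## MSAP methylation typing

MSAP digests genomic DNA in parallel with two isoschizomers sharing the
CCGG recognition site but with different methylation sensitivity
(HpaII vs MspI, each paired with EcoRI). Per sample and anonymous locus,
the pair of band-presence calls encodes a methylation state:

| HpaII | MspI | Type | state |
|-------|------|------|-------|
| 1 | 1 | I   | unmethylated |
| 0 | 1 | II  | internal cytosine methylation |
| 1 | 0 | III | hemi-methylated outer cytosine |
| 0 | 0 | IV  | hypermethylated (or target absent) |

A cell is missing iff either enzyme call is missing. Type IV is scored as
"methylated" in the downstream binary matrix, following the standard
full-methylation convention; this is a known caveat because
(absent, absent) can also reflect a restriction-site polymorphism rather
than methylation.

**Locus classification.** A locus is *methylation-susceptible* (MSL) when
the proportion of non-missing samples with Type II/III/IV strictly exceeds
`error_threshold`; otherwise it is non-methylated (NML) and excluded. The
default threshold of 0.05 is of the order of typical replicate-based
genotyping error rates for dominant markers (a few percent), which is also
why the package estimates that rate from technical replicate pairs
(discordant calls / compared calls, missing excluded pairwise). Within the
MSL, only *polymorphic* loci are analysed; we require each binary state to
occur in strictly more than `error_threshold` of the non-missing samples,
rather than "at least one discordant sample", so that loci whose apparent
polymorphism is compatible with pure scoring error do not enter the
differentiation analyses. Lowering the threshold can only grow the MSL
set (monotonicity, tested).

**Global methylation ratio.** Per sample, (Type II + III) / (Type I + II
+ III). Type IV is excluded from both numerator and denominator because
its interpretation is ambiguous; a sample with no Type I–III loci has no
defined ratio and raises an error rather than returning a silent NaN.

## Distances and AMOVA

Between two samples' binary profiles, the squared distance is the number
of loci with opposite states among the L_ij loci non-missing in both,
rescaled by L / L_ij (L = total loci) so that incomplete pairs live on the
same scale as complete ones. With no missing data this is exactly the
squared Euclidean distance on 0/1 vectors — the convention under which the
AMOVA sums of squares decompose cleanly, and the choice that reproduces
the internal arithmetic of published AMOVA tables for this kind of data.

The analysis of molecular variance partitions squared distances into
among- and within-group components:

    SSD_total  = (1/N) Σ_{i<j} d²_ij
    SSD_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij,   SSD_among = SSD_total − SSD_within
    MSD = SSD/df,  df_among = G−1,  df_within = N−G
    n0 = (N − Σ n_g²/N)/(G−1)
    σ²_within = MSD_within,  σ²_among = (MSD_among − MSD_within)/n0
    Φ_ST = σ²_among / (σ²_among + σ²_within)

Negative variance components are retained, not truncated at zero: a
slightly negative Φ_ST is a legitimate "no differentiation" outcome and
truncation would bias permutation nulls. Significance comes from
permuting the sample-to-group assignment (group sizes preserved), with
the positively biased estimator p = (1 + b)/(1 + B) so that p is never
exactly zero; B defaults to 10,000 and is configurable to millions (the
permutation engine is vectorised over permutation blocks, so 10⁶
permutations on ~50 samples take seconds). Pairwise group AMOVAs rerun
the full machinery on each pair's sample subset with raw p-values; each
pair's stream derives from the run seed and the pair index so results do
not depend on evaluation order.

**PCoA.** Classical metric scaling on the squared-distance matrix:
double-center −d²/2, eigendecompose, keep positive eigenvalues, scale
eigenvectors by √λ. Negative eigenvalues (possible when missing-data
rescaling makes the matrix non-Euclidean) are dropped and logged, and
percent variance is reported over the positive spectrum only. Axes are
deterministic up to sign.

## Per-locus tests and clustering

Each polymorphic MSL yields a 2×G table of methylated/unmethylated counts
per group (missing cells excluded). G = 2 uses scipy's Fisher exact test.
For G > 2 the package enumerates every table with the observed margins
and sums the multivariate-hypergeometric probabilities of tables no more
probable than the observed one — the same two-sided rule as R's
`fisher.test`, against which the implementation was validated to 12
decimal places. Enumeration is exact at this study's scale (≤ ~60 samples
per locus); above a 2×10⁶-table budget a seeded Monte-Carlo estimate
(10⁵ margin-preserving draws, (1+hits)/(1+draws)) engages and is logged.
A table with an all-zero margin carries no information and scores p = 1
with a log note. Benjamini–Hochberg adjustment is applied jointly across
all polymorphic MSL of a comparison; `significant` means adjusted
p < alpha (default 0.05).

For heatmap ordering, significant loci are clustered on the categorical
four-state profiles (not the binary matrix): Gower's distance for pure
categoricals is the fraction of jointly non-missing samples whose types
differ. UPGMA merges the closest cluster pair with unweighted average
linkage (mean over all cross leaf pairs), node height = half the merge
distance (ultrametric). Ties are broken by the lexicographically smallest
leaf label in each cluster, making output independent of input order;
the Newick serialisation orders children canonically the same way. Only
the locus axis is clustered.

## qPCR relative quantification

1. Efficiency correction: Cq_E = Cq · log₂(1+E), E ∈ (0, 1] the per-gene
   amplification efficiency (E = 1 is perfect doubling; the correction is
   then the identity).
2. Normalisation: dCq = Cq_E(target) − mean(Cq_E of the two reference
   genes). The arithmetic mean of corrected Cq equals the geometric mean
   of the reference expression levels on the 2^−Cq scale, which is the
   quantity a two-reference normalisation intends.
3. ΔΔCq = mean dCq(treatment) − mean dCq(control); log₂FC = −ΔΔCq; fold
   change = 2^−ΔΔCq. Standard error propagation: SE = √(SE_t² + SE_c²).
4. Confidence interval on log₂FC: ±t_(df) · SE with df = n_t + n_c − 2.
   A Student-t quantile is used deliberately instead of a normal one:
   with the typical four replicates per group the SE is estimated with
   six degrees of freedom, and a z-based "95%" interval would actually
   cover ~90% (P(|t₆| < 1.96) ≈ 0.902). The t-interval achieves nominal
   coverage, which the acceptance suite verifies by simulation.
5. Group comparison: two-tailed Student t on dCq with pooled variance
   (Welch behind a flag), oriented on the expression scale so that
   positive t means upregulation. Shapiro–Wilk and Levene checks are run
   per comparison and logged as warnings; they never switch the test
   automatically, because silent test substitution makes reported
   statistics incomparable across genes.
6. FDR across all comparisons reported together: Storey q-values.
   π₀ is estimated by the smoother — π₀(λ) = #{p > λ}/(m(1−λ)) on
   λ = 0.05…0.95 (step 0.05), a cubic smoothing spline evaluated at
   λ = 0.95, clipped to (0, 1] — then q_i = min_{p_j ≥ p_i} π₀·m·p_j/rank.
   With π₀ fixed at 1 this reduces exactly to Benjamini–Hochberg
   (tested); with fewer than two p-values π₀ is fixed at 1 and logged.

Morphometric group tests (weight/length) use the Kruskal–Wallis rank sum
test (tie-corrected) for multi-group designs and the two-sided Wilcoxon
rank sum test for two groups, reporting the W statistic of the first
group.

## Synthetic-data generators

`simulate_msap` draws, per sample, a Type I–IV state per locus from its
group's state-probability 4-vector, maps it to the two-enzyme band
pattern, then flips each band call independently with `error_rate` and
masks it with `missing_rate` — errors enter per band, the way scoring
error arises in real fragment data, so a single state error can manifest
as any neighbouring type. Baseline per-locus probability vectors default
to Dirichlet(6, 2, 2, 2) draws (Type I most common at ~50%, the
methylated types sharing the rest), a shape typical of MSAP band-type
tallies; they can be supplied explicitly. A fraction `diff_fraction` of
loci is differentiated: in non-reference groups, `effect_size`
total-variation mass moves from Type I to Types II/III/IV proportionally
to their baseline shares, and the shift grows linearly with group index
(group g gets effect_size·g/(G−1)) so every non-reference group is
distinct. The default group sizes (23/15/12) and locus count (250) mirror
a realistic larval-pool design with 200–300 polymorphic loci; one sample
is one biological replicate, whether a pooled batch of larvae or an
individual fish.

What the generator does **not** emulate: electropherogram traces,
fragment-length binning artefacts, linkage between loci (loci are
independent), group-specific missingness, or batch effects between
primer combinations. Passing calibration tests therefore demonstrate the
statistical machinery is correct under the stated generative model, not
that real MSAP data meet that model.

`simulate_qpcr` produces Cq = base_cq − true_log₂FC (treatment groups
only) + N(0, noise_sd) per replicate, with per-gene efficiencies attached
and reference genes pinned at fold change 0. Because efficiencies are
attached but not inverted in the generator, exact downstream recovery of
the true log₂FC holds at E = 1 (one corrected cycle = one doubling);
with E < 1 the generator models primers whose printed Cq is already on
the assay's own scale. Both generators are byte-deterministic functions
of their seed.

## Calibration results the test suite computes

- Under the null generator (diff_fraction = 0, no scoring error), the
  permutation AMOVA at α = 0.05 rejects at the nominal rate (500
  replicates, 999 permutations each; count inside the exact binomial 99%
  band).
- Mean Φ_ST increases strictly across diff_fraction ∈ {0, 0.2, 0.5} at
  effect_size 0.4 (100 replicates per level).
- Noiseless qPCR at E = 1 returns true log₂ fold changes to 1e-12;
  the 95% t-interval attains nominal coverage (500 seeds, binomial 99%
  band).

Problem sizes throughout the suite (three groups of 23/15/12 samples,
250 loci; 500-replicate calibrations) were chosen as the smallest designs
that exercise every code path at the study's realistic scale while
keeping the whole suite in the order of a minute.

## Known limitations

- The exact 2×G Fisher test is feasible only while the margin-product
  budget holds; beyond it the Monte-Carlo p is an estimate with its own
  seed-dependent error (~1/√draws).
- The binary recoding of Type IV as methylated conflates hypermethylation
  with target absence; conclusions about individual loci scored mostly
  Type IV deserve caution.
- AMOVA here is single-level (no nested hierarchies).
- Gower/UPGMA clustering is presentational; merge order among tied
  distances follows the documented lexicographic rule, not biology.
- Reproducing the published statistics of the motivating study end-to-end
  requires its original supplementary input files, which are not
  redistributable with the package; the acceptance suite documents the
  expected values and runs whenever the files are placed under
  `data/supplementary/`.
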