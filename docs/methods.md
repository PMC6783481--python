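# Methods

This note documents the statistical model behind the pipeline and the
synthetic-data generator, the defaults that matter, and the numerical
conventions — the things a maintainer would need before trusting or
changing a threshold.

## Coordinates and the interval engine

All coordinates are BED-style 0-based half-open `[start, end)`; GTF-style
1-based input must be converted on read. Overlap always means sharing at
least one base, so `[2000, 8000)` and `[8000, 9000)` do not overlap. The
interval engine (union merge, multi-source consensus, exclusion masking,
read counting) is written against a per-base definition and the test suite
holds it to exact equivalence with per-base brute-force oracles on random
toy genomes — any future optimisation must keep that contract.

**Consensus.** "Annotated in at least k sources" is operationalised as:
take maximal contiguous runs of union coverage over all sources and keep
runs containing ≥1 base covered by ≥k *distinct* sources (duplicates
within one source count once). This is the most permissive defensible
reading of multi-source agreement; it lives in one function
(`consensus_enhancers`) so a stricter criterion is a local change.

**Regions and exclusions.** Region = midpoint ± `flank_bp` (3000),
midpoint = floor((start+end)/2), clamped (not dropped) at chromosome ends.
The exclusion mask is the merge of: gene/lncRNA spans extended
`gene_extension_bp` (1000) on both ends; a `uaRNA_window_bp` (500) window
immediately beyond the extended TSS side, strand-aware (upstream of the
TSS for `+` genes is lower coordinates); blacklist intervals verbatim.
A region overlapping the mask by one base is dropped entirely — never
trimmed — because the analysis counts eRNAs per enhancer, not surviving
basepairs. Overlapping surviving regions are kept separate by default
(one region per consensus enhancer); `merge_surviving_regions` collapses
them to union spans for users who prefer non-redundant regions.

## Statistics

*Spearman* is Pearson on mid-ranks (average ranks at ties) with the
two-sided large-sample t approximation, t = Rs·√((n−2)/(1−Rs²)) on n−2 df.
Missing values are removed pairwise; pairs with fewer than
`min_pairs_complete` (10) complete observations are skipped (below that a
rank test is degenerate), as are constant vectors. *BH-FDR* is the
standard step-up adjustment (statsmodels), oracle-tested against the
definition. *Fisher combination* weights atanh-transformed correlations by
n−3 (the inverse variance of z) and refers z̄·√Σ(n−3) to the standard
normal.

Screening conventions, applied uniformly: edges and links require
**positive** Rs ≥ `rs_min` (0.3) — the screen targets activating
relationships; `rs_absolute` switches to |Rs|. BH scope is all tests of
one screen within one cohort (TF×eRNA jointly; all candidate pairs
jointly; per drug source; per clinical feature). Master regulators use the
inclusive ≥25 % boundary and general masters the inclusive ≥10-cohort
boundary; `master_strict`/`general_master_strict` give the strict (>)
variants.

**Hi-C.** O/E values are consumed precomputed on `hic_bin_bp` (10 kb)
bins, keyed by unordered (chrom, bin, bin) pairs; "support" in a tissue is
O/E ≥ `hic_oe_min` (1.0 — observed exceeds expected), and a missing bin
pair counts as unsupported. The permutation null draws |links| random
region–gene pairs genome-wide (uniform over all region×gene combinations,
without replacement within a permutation); a distance-matched background
(≤1 Mb, same chromosome) is available via `distance_matched_background`
for sensitivity analysis. The empirical p uses the add-one estimator
(b+1)/(B+1), so p is never 0 and is exactly uniform on its grid under the
null (up to ties in the supported fraction).

**Clinical tests.** The paired tumor/normal t-test and the group tests run
on log₂(RPM + ε), ε = 0.1: expression noise is log-scale and the fold
change is a ratio, so the linear-scale t would be dominated by the heavy
right tail; ε avoids log 0 at a level well below the detectability
threshold. Fold change itself is reported on the ratio scale,
(mean_T+ε)/(mean_N+ε), with the inclusive boundary (FC ≥ 1.5 or ≤ 1/1.5;
`fc_boundary_inclusive` switches). Cohort detectability means use tumor
samples only; normals enter only the paired comparison. Survival defaults
to a univariate Cox fit (lifelines) on z-scored expression with the Wald
p; the top-vs-bottom-quartile log-rank test is the secondary mode. Cohorts
below 5 pairs (DE), groups below 5 samples, and survival cohorts below 20
subjects or 10 events are skipped and logged rather than tested.
Stage and grade are treated as unordered categories (ANOVA); no trend
tests. "Clinically relevant" = significant in ≥1 of
survival/subtype/stage/grade/smoking; differential-expression calls are
reported alongside but do not enter the flag.

## The synthetic cohort

The generator exists so every stage can be tested against known truth
without external downloads. It emulates the *statistical* structure the
pipeline assumes, not any particular dataset.

**Genome and annotations.** 4 chromosomes × 3 Mb; 120 non-overlapping
genes (2–5 exons each), 25 lncRNAs, 16 blacklist intervals, placed by
rejection sampling. 110 base enhancers; a fraction
`cross_source_overlap_frac` (0.6) is duplicated into a second (sometimes
third) source with ±200 bp jitter, so ≥2-source membership is known in
advance; 12 % are deliberately placed so their region hits the exclusion
mask. Base enhancers are spaced > 2·flank apart, so each yields exactly
one consensus run and the truth ledger predicts the surviving region set
exactly (this is asserted in tests).

**Expression.** Counts are negative binomial (gamma–Poisson) with
variance μ + φμ², φ = `nb_dispersion` = 0.05. Per-sample means are
μ = base·exp(σz − σ²/2) with a latent standard normal z per
(feature, sample) and σ = `latent_sigma` = 1.2 (log₂ SD ≈ 1.7, the sort of
sample-to-sample spread eRNAs show across tumors). Correlation structure
is planted through a Gaussian copula on the latents: target latent =
ρ·driver + √(1−ρ²)·noise, so the Spearman correlation of the *latents* is
exactly 6/π·asin(ρ/2), and the count Spearman approaches it as counts grow
(the attenuation from NB noise and low-count ties is real and is why
recovery tests quote the analytic value only for well-expressed features).
Tumor/normal pairing shares `pairing_weight` = 0.3 of latent variance
through a patient latent. Gene base expression is log-uniform 5–100 RPM
everywhere; each eRNA is active (base 3–30 RPM) in a random non-empty
cohort subset and near-silent (0.05 RPM) elsewhere — this produces the
specificity classes and the cohort-distinct expression programs behind the
sample-similarity check.

**Planted effects and their defaults** (identities are drawn from the seed
and written to the truth ledger): one master TF driving 40 % of eRNAs at
ρ = 0.6; 20 eRNA→gene links at ρ = 0.5 (chosen among ≤1 Mb, non-intronic
pairs); tumor/normal fold change 4 on 15 eRNAs; drug correlations |ρ| = 0.6
for 10 (eRNA, drug) pairs with alternating sign; survival log-hazard
log 2 per SD of expression on 3 eRNAs (exponential event times, baseline
median 24 months, independent exponential censoring tuned to ≈30 %); a
2-latent-SD subtype shift on 5 eRNAs. Hi-C: background O/E is log-normal
(median 1, σ = 0.5) recorded for a random 10 % of same-chromosome
(region-bin, TSS-bin, tissue) combinations; planted link pairs are
recorded in all 20 tissues with O/E ×10.

**What the generator does not emulate**, hence what green tests do not
show about real data: alignment and library-preparation artifacts
(read-length or depth batch effects), GC/mappability bias, copy-number
driven expression changes, cell-type composition, genome-version liftover,
inter-gene correlation beyond the planted structure, and informative
censoring. Passing recovery tests demonstrate the *inferential machinery*
is correct and calibrated, not that real cohorts carry signals this clean.

## Numerical and reproducibility conventions

One `numpy` `default_rng` seeded from the design drives all simulation;
the permutation test takes its own seed argument. Every table is sorted on
stable keys and written with the `%.10g` float format, and matrix readers
canonicalise row/column order, so reruns with the same config and seed are
byte-identical and outputs are invariant to input row ordering. Problem
sizes used by the test suite (3 cohorts × 60 tumors, 100 cell lines, ≤50
toy genomes per oracle sweep, 199–999 permutations in the fast paths) were
chosen so the whole suite exercises every stage at full statistical
fidelity while staying small; the shipped defaults
(`n_permutations` = 10,000) match the analysis scale.

Known limitations: the univariate Cox screen attenuates when several
hazard effects coexist (omitted-covariate bias — visible in the default
bundle, where three simultaneous planted hazards are each estimated below
their marginal value); the permutation p is conservative under heavy ties
in the supported fraction; `spearman_matrix` falls back to slower
pairwise-complete loops only for rows containing missing values; and the
reads-as-BED quantification path covers eRNA regions only (gene/TF
expression must come as a matrix).
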