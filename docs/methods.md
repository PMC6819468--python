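# Methods

`stemwall` implements the desk analysis of a developmental RNA-seq time
course of maize stem internode rind tissue: which members of the large
cell-wall gene families are expressed when, which track secondary cell-wall
deposition rather than elongation growth, how expression compares between two
inbred genotypes, and which promoter motifs mark the secondary-wall cohort.
This note records the models, the parameters that matter, and the design
choices made where the procedure was genuinely open.

## The time course and its coordinate system

A maize stem at five to nine weeks carries internodes at every developmental
age at once: internodes near the apex (high ordinals, e.g. 8–9) are still
elongating and building primary walls, internodes near the base (low
ordinals, e.g. 2–5) have ceased elongation and are depositing thick,
lignified secondary walls. Sampling rind tissue from internodes 9 down to 2
therefore yields a developmental series from a single plant. All matrices in
the package order internodes **youngest first** (highest ordinal to lowest);
which internodes count as "elongating" versus "secondary-wall-forming" is
always declared in configuration (`StageConfig`), never inferred from the
data.

## Normalization and gating (`expression`)

* Counts are scaled per sample to a 20-million-read reference depth
  (**reads per 20 M**, 1 CPM = 20 per-20M units), then replicates of the same
  internode are averaged. Scaling precedes averaging so replicates of unequal
  depth contribute equally.
* Replicate spread is recorded as the standard deviation for three or more
  replicates and the variance for exactly two, mirroring the reporting
  convention for two- versus three-collection samples; this is bookkeeping
  only and feeds no downstream decision.
* Library size defaults to the column sum but an explicit value always wins:
  a table restricted to a gene subset cannot recover true sequencing depth.
* Detection: a gene is "detected" when its maximum replicate-collapsed value
  across internodes reaches 1 CPM (20 per 20 M). This detected set is the
  universe for genome-wide pattern matching.
* Gene scaling for clustering and slope matching is a per-gene z-score
  (subtract the row mean, divide by the population-denominator row SD).
  Constant rows map to all-zero rows and are reported, not dropped silently.
  The z-score makes every later shape comparison scale-free; min–max scaling
  was considered and rejected because it makes the slope metric sensitive to
  single-internode spikes.
* Housekeeping QC: for each sample, the median over a housekeeping panel of
  the log2 deviation of the gene's depth-scaled level from its cross-sample
  median. Samples beyond |2| log2 units are flagged for exclusion — the rule
  that drops an internode whose panel expression collapses. The bound is
  configurable; 2 was chosen as the smallest round value that cannot be
  produced by depth mis-estimation alone.

## Stage classification (`stage`)

Each gene's profile is reduced to the ratio of its mean expression over the
secondary-wall internodes (default {3,4,5}) to its mean over the elongating
internodes (default {8,9}). Genes are gated at ≥95 ("expressed") and ≥500
("highly expressed") reads per 20 M using the maximum across internodes, and
only high-gate genes are classed:

* ratio ≤ 1.04 → **Elongation** (primary-wall associated),
* 1.05–1.94 → **Transitional**,
* ratio ≥ 1.95 → **Secondary**.

The printed-table boundaries (1.04/1.95) are used rather than the rounder
"2-fold / 1.0" phrasing because they reproduce the published 323/171/199
split of 693 high-gate genes; both gates and boundaries are configurable.
Genes whose elongation mean is exactly zero have an undefined ratio; when
their secondary mean clears the high gate they are classed Secondary, since
an infinite ratio exceeds any finite boundary. Reported fractions are rounded
half-up to two decimals, the printed-table convention.

## Templates and slope-metric matching (`patterns`)

Curated cell-wall genes are clustered on their z-scaled profiles by
average-linkage agglomerative clustering with correlation distance
(1 − Pearson; Euclidean available), cut into k = 13 clades, and the clades
are grouped into five named stage templates. "Auto" grouping assigns each
clade to the canonical archetype shape (see below) with which its mean
profile correlates best; the template profile is the mean z-scaled profile of
all member genes. Thirteen clades for five patterns is deliberate slack: the
cut only needs to be fine enough that no clade straddles two shapes.

The **slope metric** between a bait profile A and test profile X over n
internodes is

    score(A, X) = Σ_{i=1}^{n-1} | (A_{i+1} − A_i) − (X_{i+1} − X_i) |

— the L1 distance between the successive-slope vectors. It is a pseudometric
(symmetric, triangle inequality) that is zero exactly when the profiles
differ by a constant offset, so it compares shape, not level. Every detected
gene is scored against each template; genes scoring strictly below one
standard deviation of that template's score distribution over the universe
are flagged as matching, and all genes are rank-ordered ascending (ties
broken lexicographically by gene ID, since the procedure itself does not
order ties).

Two notes on the threshold. First, the SD could alternatively be computed
over the gene-scaled abundances themselves; the score-distribution SD is the
default and the abundance form is available via `sd_mode`. Second, the
threshold is only meaningful on a *heterogeneous* universe: scores are sums
of absolute terms, so on a universe consisting solely of genes matching the
bait the score mean is ~3.5× the score SD and nothing falls below one SD.
Matching is therefore always run against the full detected universe, where
non-matching genes spread the distribution.

Covariance PCA (genes as observations, internodes as variables,
eigendecomposition of the internode × internode covariance matrix) is
provided as the exploratory companion; on five-pattern synthetic data the
first three components carry ≥80 % of variance, matching the behaviour
expected of a time course dominated by a few shapes.

## Ortholog concordance (`orthology`)

Each maize gene carries at most one precomputed closest reference-species
homolog with a wall class (`primary` / `secondary` / `none`) taken from a
published reference stem study; sequence search and the reference classes are
inputs, not computations. A high-gate maize gene is a **putative ortholog**
when its stage class maps to the same side as its homolog: Elongation and
Transitional map to the primary-wall side, Secondary to the secondary-wall
side. The primary-side fraction is reported over the combined
Elongation + Transitional count, the secondary-side fraction over the
Secondary count. A stricter variant additionally requiring template-shape
concordance would be straightforward but is not the default, as the
class-concordance rule is the one the summary tables define.

## Two-genotype comparison (`inbred`)

Expression of each genotype is pooled (mean) over declared elongation-stage
and secondary-stage internode sets (defaults {6,7} and {4,5}, the
four-internode greenhouse design). Fold-change per gene and stage is
(max + p)/(min + p) over the union gene universe with absent genes at zero.
The pseudocount p = 10 reads per 20 M bounds the fold-change of
zero-expression genes (a true absence at typical abundance then lands in the
tens-to-hundreds-fold range rather than at infinity); it is half the
detection floor, so no detected value is dominated by it. Folds are binned
<2 / ≥2 / ≥5 / ≥100 (nested), and a gene's headline fold is its maximum over
stages — a difference "at any stage".

**PAV candidates**: genes below the 1-CPM detection floor in every internode
of one genotype whose other-genotype fold reaches 26 (the lower edge of the
published deleted-block range). Maximal runs of at least 5 consecutive
same-direction candidates along the chromosome's ordinal gene order are
emitted as candidate deletion blocks. Gene order is an ordinal index from the
annotation, not physical coordinates — the package carries no assembly — so
"consecutive" means adjacent ordinals. A transcript-length bias check
(mean length per fold direction) is included as a pipeline property.

## Promoter motifs (`motifs`)

Motifs are IUPAC consensus strings; degeneracy codes match their letter set
at zero cost, and an optional budget of ≤1 substitution (no indels) covers
near-misses such as a consensus missing only its last base. Scanning is
forward-strand over the trailing window (default 1 kb) of each promoter —
the sequence nearest the gene start — with 0-based offsets plus the
upstream-distance convention for reporting. Scanning is vectorized but
bit-exact against a window-by-window oracle, which the tests enforce.

**Enrichment** is gene-level presence (≥1 hit), tested against randomly
sampled background genes: one background sample (default 500 genes, recorded)
estimates the background proportion, and the p-value is a permutation test —
resampled gene sets of the *target's* size drawn from the non-target pool,
p = (1 + #{resample proportion ≥ target proportion}) / (n_resample + 1).
Drawing resamples at the target's size keeps the two proportions
exchangeable under the null; resampling at a fixed 500 regardless of target
size makes null p-values U-shaped. Because hits are binary per gene, each
resample's hit count is drawn exactly (hypergeometric), making thousands of
resamples cheap. Null calibration (KS < 0.1 against uniform over 1,000
replicates) is asserted in the tests.

**Genotype comparison** pairs each gene's promoters from two genotypes and
matches hit offsets within ±10 bases (motif instances rarely move further
under SNPs/small indels; the slack is configurable); unmatched instances
yield lost-in-A / lost-in-B verdicts, the signature of a promoter-element
knockout.

## The synthetic generator (`simulate`)

The generator emits every input the analysis reads — two genotypes' count
tables with sample metadata, an annotation with chromosome ordinals and
families, a homolog map, paired promoter FASTA sets — plus a ground-truth
table, all from one seeded RNG (identical seeds give byte-identical files).

What it emulates, and the defaults:

* **Shapes**: five piecewise-linear archetypes (Elongation, Transition I/II,
  Secondary, Early&Late) plus a Flat background, anchored over eight
  internodes and interpolated to other lengths. The two Transition anchors
  put the secondary:elongation ratio mid-band (~1.4); Elongation, Secondary
  and Early&Late sit far outside the band, so a planted class is never a
  coin-flip at a boundary. Flat genes sit exactly at ratio 1.0 — on a class
  boundary by construction — and therefore carry no stage label in the
  ground truth.
* **Abundance**: log-normal peak abundance (ln-mean 4, ln-SD 2 on the per-20M
  scale, median ≈ 55), spanning the 95/500 gates. Shaped-pattern genes model
  curated, *expressed* cell-wall genes, so their abundance is drawn from the
  same log-normal truncated at the expressed gate (95); background genes are
  unrestricted, leaving ~30 % of the genome undetected, as in a real rind
  library.
* **Noise**: negative-binomial counts per replicate, variance μ + φμ², with
  φ = 0.01 — a replicate biological CV of 0.1, the standard figure for
  technical-plus-pooled replicates of a genetically identical inbred line.
  φ = 0 gives Poisson; `noise=False` gives rounded means.
* **Genotype effects**: a mixture over {none, 2–5×, 5–100×, >100×} with
  proportions 0.35 / 0.35 / 0.285 / 0.015 (so 65 % of genes differ ≥2-fold,
  30 % ≥5-fold, 1.5 % >100-fold). Fold values are drawn log-uniformly from
  mid-class ranges ([3.2, 3.8], [9, 60], [250, 500]) rather than the full
  bins: count noise and the fold pseudocount shrink measured folds by up to
  ~25 % for low-abundance genes, and mid-class draws keep a gene's planted
  bin unambiguous under measurement. The mixture proportions, not the
  ranges, carry the planted fractions. The fold multiplies the favored
  genotype's mean so the measured fold is direction-symmetric.
* **PAV**: one contiguous block (default 53 genes on chr6) zeroed in the
  absent genotype; block genes are Flat with abundance in [600, 5000] per
  20 M so the presence genotype clears the 26-fold pseudocounted contrast
  with large margin, matching the 26–500-fold range of a real deletion.
* **Homologs**: one reference homolog per gene; concordance rates 0.56
  (primary side) and 0.20 (secondary side), the published table's fractions;
  discordant genes split between the wrong class and `none`.
* **Promoters**: uniform-random DNA (default 1 kb); the consensus motif
  (default PALBOXA, CCGTCC) is planted at a recorded offset in 80 % of
  Secondary-pattern genes and 5 % of others, and knocked out by a single
  out-of-consensus substitution in 20 % of planted genotype-B copies.
* Pattern and effect-class counts are assigned by largest remainder, so
  ground-truth tallies equal the configured proportions exactly.

What it does **not** emulate: GC/length biases, correlated gene modules
beyond the shared archetypes, isoform structure, genotype-specific shape
changes (only level changes), promoter background composition beyond uniform
base frequencies, and mapping artifacts from duplicated loci. Recovery tests
passing on this generator show the pipeline's inference is correct under its
stated statistical assumptions — not that real libraries satisfy them.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the generator at 2,000 genes
(pattern and stage recovery; 100 planted Secondary genes for the matching
check), 10,000 genes (fold-change bins and PAV), and 1,000 permutation
replicates at 199 resamples each for null calibration — sizes at which every
planted structure is comfortably identifiable and a full run takes seconds.
Fractions shown in summaries are rounded half-up to 2 decimals; rank ties
break lexicographically; the within-SD comparison is strict (<); all
randomness flows from explicit seeds.

## Known limitations

* The stage classifier is a two-group mean ratio; it has no dispersion model
  and is not a significance test (differential-expression fitting is out of
  scope by design).
* Clade grouping quality depends on k and on the curated set; k = 13 with a
  high-gate curated set is robust on the generator but real curated lists
  should be inspected (`derive_templates` accepts a manual clade→name map).
* PAV calling from expression alone cannot distinguish a deletion from
  silencing; blocks are candidates for sequence-level follow-up.
* The enrichment test conditions on the planted motif; it does not correct
  across many motifs (callers should apply their own multiplicity control).
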