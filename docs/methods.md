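# Methods

## Scoring model

The input is a loci × samples table of read depth and methylated fraction
for a two-condition, single-factor design with at least two samples per
group. After depth filtering (default: complete cases with depth ≥ 10 in
every sample — 10 is the conventional WGBS floor; the value is a parameter),
the samples × loci matrix of methylated fractions is centered per locus and
decomposed with a thin SVD. No variance scaling is applied: methylated
fractions already live on a common [0, 1] scale, and scaling would inflate
the loadings of near-invariant loci.

The *delineating component* is chosen by maximizing the standardized
group-mean difference of the per-sample projections, |mean(treat) −
mean(control)| / pooled SD, with the pooled SD floored at 1e−12 so a
perfectly separating component wins outright; ties break toward the lower
component index, and the user can override the choice with an explicit
component number. The locus scores are the entries of that component's
right singular vector — a unit vector, so score magnitudes are comparable
across datasets only in rank terms, which is all the pipeline uses. The
global sign is fixed so a positive score means hyper-methylation in
treatment. Ranks (1 = largest |score|) break ties by genomic position so
every downstream result is deterministic.

The premise being exploited: when the PCA separates the conditions, a
locus's loading magnitude reflects its contribution to the
between-condition variance, so true differential loci concentrate at the
top ranks. The test suite verifies this directly on simulated genomes (mean
rank of true DMLs far below that of background loci).

## DML rank cutoff

On the rank vs |score| curve, ordinary least squares lines are fitted to a
head window (ranks 1..max(100, ⌈0.005 n⌉) — the steep true-variation
regime) and a tail window (the bottom half of ranks — background). The
`intersect` cutoff is the rounded rank where the two lines cross, clamped
to [1, n]; parallel fits are an error (the curve has no knee). The `strict`
cutoff is the midpoint between the intersect cutoff and the last head-window
rank, capped at the intersect cutoff; it is meant for very-low-variation
datasets where the intersect estimate drifts into the background. The
window fractions are parameters; the defaults are pinned by a
piecewise-linear fixture with an analytically known crossing. "Bottom half
of ranks" means the last ⌊tail_frac·n⌋ ranks (501–1000 at n = 1000).

No locus-level p-values are produced by design; the cutoff is a ranking
device, not a significance statement.

## DMR calling

Parameters (defaults): `n_seeds` (2% of filtered loci), `compress_gap`
(1000 bp), `max_dmr_size` (5000 bp), `containment_frac` (0.9),
`trim_window` (3 loci), `n_boot` (1000), `bg_span` (1 Mb), `fdr_alpha`
(0.05), `gate_p` (0.25), `min_loci` (5), `stat` ("both"), `rng_seed`.

1. **Seeds** — the `n_seeds` best-ranked loci. 1–3% of loci is the
   recommended range; accuracy is flat across 0.5–5% in the benchmark
   suite.
2. **Compression** — per chromosome, consecutive seeds ≤ `compress_gap`
   apart form one cluster (single linkage); the cluster is represented by
   its median member (lower-middle for even counts, so the point is a real
   locus). Clusters spanning more than `max_dmr_size` are split greedily
   into sub-clusters within the span bound, and the number of such
   overcompression splits is reported — a rising count signals too many
   seeds for the data's cluster structure.
3. **Expansion** — within ± `max_dmr_size`/2 of the compressed seed, with
   k "variable sites" (loci ranked at or above the seed cutoff), the
   candidate is the shortest interval spanned by ⌈0.9 k⌉ consecutive
   variable sites (ties toward the smaller start).
4. **Gate** — a cheap permutation pre-filter (mean-rank statistic,
   `n_boot`/10 draws) discards candidates with p ≥ `gate_p` before the
   expensive steps.
5. **Trimming** — the threshold τ is the median |score| of the loci in the
   two flanking windows (`bg_span`/10 bp each; genome-wide median if the
   flanks are empty). From each end, terminal loci are removed while the
   mean |score| of the outermost `trim_window` loci is below τ. Candidates
   trimmed to nothing, or to fewer than `min_loci` loci, are dropped — a
   handful of loci is an isolated DML cluster, not a region (comparable
   callers impose the same kind of minimum CpG count).
6. **Merging** — overlapping survivors merge (union of loci) so one true
   region found from two compressed seeds is reported once. Merged
   intervals may exceed `max_dmr_size`; the size bound applies to
   individual expansions.
7. **Significance** — the observed statistics are the mean and the median
   rank of the region's loci. Each null draw takes a uniformly random
   contiguous run of the same locus count from the background territory
   (all loci within `bg_span`, region excluded); contiguous runs rather
   than i.i.d. loci preserve local rank autocorrelation. Each statistic
   yields `p = (1 + #{null ≤ observed}) / (n_boot + 1)`, and the reported
   p is the larger of the two — an intersection-union test. The mean
   catches diffuse enrichment; the median demands that the *body* of the
   region out-rank the background, which is what separates a genuine DMR
   from a couple of extreme loci padded with background. Either single
   statistic can be selected via `stat`.

   Scoring runs in two passes. Pass 1 uses the raw local background, which
   is calibrated because the null draws cross the same selected landscape
   as the candidates. But a genuinely differential neighbour is not
   background: null runs crossing it suppress every true region near it
   (at the simulated DMR density, enough to hold suppressed regions at
   p ≈ 0.003–0.02, which Benjamini–Hochberg then discards). Pass 2
   therefore re-scores with the unambiguous pass-1 regions — either
   statistic at the bootstrap floor — masked out of the null territory,
   and only regions already nominally significant (either pass-1 margin
   ≤ `fdr_alpha`) may be called. The screen prevents the mask from
   promoting deep-null noise, whose selection bias would otherwise grow as
   strong territory is removed; under a null genome the floor and screen
   events are rare and the procedure reduces to the calibrated single
   pass. Benjamini–Hochberg across all scored regions yields q; regions
   with q ≤ `fdr_alpha` are returned.

Every stage draws from child generators spawned deterministically from
`rng_seed`, so identical inputs and seed give byte-identical output.

## Region queries and metagenes

A user region is tested two-sided (its direction is unknown a priori,
unlike a DMR whose direction the seed sign fixes): observed = mean signed
score of member loci, null = contiguous equal-size runs from ± `bg_span`,
p = (1 + #{|null| ≥ |observed|}) / (n_draws + 1).

Metagene profiles map loci to region-relative coordinates (0 = start,
1 = end; flanks of `flank_frac` × region length on either side), average a
chosen value (score or methylation difference) in equal-width bins (body
bins plus proportional flank bins), and then average across regions,
ignoring empty bins rather than imputing zeros. Bins are half-open on the
left; a locus exactly at the region start falls in the first body bin and
one exactly at the end in the last. Minus-strand regions reverse the bin
order (not the raw coordinate), so profiles are 5′→3′ and the
strand-flipped profile is exactly the reversed profile.

## Simulated genomes

The generator emulates a two-condition WGBS comparison at three variation
levels on a 24 Mb genome (three 8 Mb chromosomes) with 1.2 million measured
loci and 3 + 3 samples:

| level  | true DMLs | stray | true DMRs |
|--------|-----------|-------|-----------|
| low    | 8 358     | 1 000 | 45        |
| medium | 18 774    | 3 000 | 106       |
| high   | 37 192    | 6 000 | 192       |

True DMR intervals get uniform random lengths of 100–4000 bp, are assigned
to chromosomes uniformly (equal lengths) and placed without overlap. The
in-DMR DML budget (total minus stray) is allocated across intervals
multinomially in proportion to length — realizing the printed totals
exactly, which purely uniform placement cannot do — and placed uniformly
without replacement inside each interval; each interval is wholly hyper- or
hypo-methylated (fair coin). All remaining loci fall uniformly outside the
intervals, and the stray budget is drawn uniformly from them with random
direction (strays are counted within the true-DML total, ≈ 12–16% of it).
Stray DMLs mimic the isolated differential cytosines real WGBS comparisons
contain and are the main false-positive hazard for any region caller.

Each locus draws one site-level seed fraction b from a truncated normal —
NS (μ 0.5, SD 0.1, [0.25, 0.75]), hyper (0.55, 0.1, [0.35, 0.85]), hypo
(0.45, 0.1, [0.15, 0.65]) — shared by all samples. True sites carry an
intensity modifier m ∈ {0.25, 0.5, 0.75} (uniform) moving the treatment
success probability a fraction m toward the extreme: hyper b + m(1−b),
hypo b − m·b; this keeps probabilities in range without clamping and gives
three cleanly separated effect tiers. Per sample and locus, depth ~
Poisson(30) floored at 1 and methylated reads ~ Binomial(depth, prob);
sample-level noise comes entirely from read sampling. Note the hyper/hypo
truncations are asymmetric (2 SD on one side, 3 on the other), so their
realized seed means sit ≈ 0.005 from μ — the exact truncated-normal mean.

Class counts are exact by construction for every seed; only positions and
read draws vary. `scaled(factor)` shrinks everything (one chromosome,
budgets / factor) at constant locus density, and `null_spec()` gives a
signal-free genome for calibration.

What the simulation does not model: sequence context and CpG clustering
(loci are uniform, real CpGs are islands/shores), depth heterogeneity
beyond Poisson, bisulfite conversion error, strand structure, covariates
and batch effects, and methylation autocorrelation *outside* true DMRs.
Passing benchmarks here therefore show the machinery is correct and
calibrated under the stated generative model, not that real genomes behave
this way — in real data background autocorrelation will make the local
background less exchangeable and the bootstrap somewhat less conservative.

## Benchmark scales and observed behaviour

The test suite exercises generator contracts at the published scale (one
full 1.2 M-locus genome per level, seconds each) and the calling pipeline
on reduced genomes — one chromosome, 100 000 loci, budgets divided by 12,
which preserves locus density, DMR density and all distributions. At that
scale, with defaults, region-level precision/recall against truth average
≈ 0.93/0.78 (medium) and 1.00/0.87 (high) over three generator seeds,
precision stays ≥ 0.8 for seed counts from 0.5% to 5% of loci, and on a
null genome no region is called with ~3% of candidates reaching nominal
p ≤ 0.05.

## Numerical and edge-case choices

- Coordinates are 1-based inclusive internally (Bismark convention); BED
  output converts to 0-based half-open.
- Methylated fractions are always recomputed from counts; printed percent
  columns are advisory (a > 1-point disagreement warns, counts win).
- Strand merging (off by default) pools a minus-strand call at p with the
  plus-strand call at p−1 and reports the plus position.
- Missing calls are explicit NaNs until the filter resolves them; nothing
  is imputed.
- A constant methylation matrix, a group with fewer than two samples, and
  an empty post-filter matrix are errors, not warnings.
- Bootstrap/permutation territories smaller than the region widen to the
  chromosome (with a warning); if even that is too small the region gets
  p = 1 and a flag rather than a fabricated value.
- All cutoffs round half away from the boundary rank only through ordinary
  rounding; ranks are unique so cutoff ties cannot occur.
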