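# Methods

`selfmix` re-implements, as a tested library plus analysis drivers, a
population-genomic workflow for a recently derived selfing species and its
outcrossing progenitor: windowed diversity and divergence, closed-form
timescale and selfing-rate estimators, a two-state local-ancestry HMM with
admixture-block dating, the four-population D test with a chromosome-level
block jackknife, a single-outlier introgression scan, and the
recombination-divergence correlation. Everything runs on synthetic panels
with known truth; nothing requires downloads.

## Data model

Panels are haploid: samples represent fully inbred lines whose residual
heterozygosity has been resolved to a single allele (`resolve_heterozygotes`
picks one of the two alleles uniformly at random, seeded). Panels list
every *assayable* site explicitly, including invariant ones, so that the
denominator of every diversity estimate — sites co-called in both samples of
a pair, optionally restricted to a codon-degeneracy class — is exact.
Coordinates are 0-based half-open internally; VCF I/O converts to and from
1-based.

Site filters follow the genotype-processing recipe: per-sample calls with
depth < 10 become missing; calls whose depth is more than 2 sample standard
deviations from the sample's mean depth are censored (mean/SD computed from
the depth matrix over entries passing the minimum-depth cut, a fixed
reference that makes the filter idempotent); sites with more than two
alleles among retained calls are dropped. Whether the ±2 SD rule should be
per sample or pooled across samples is not decidable from the source
material; per sample is implemented.

Degeneracy: each coding site is classed 0/2/3/4-fold by counting, against
the reference codon, how many of its three alternative nucleotides are
synonymous (strand-aware). Sites whose degeneracy depends on another
polymorphic position in the same codon are classified against the reference
codon.

## Closed-form estimators

With μ the per-bp per-generation mutation rate (default 1.5e-8) and an
annual generation time:

* split time τ = (π_between − π_ancestral) / 2μ, in generations;
* π/2μ doubles as an effective number of chromosomes (Ne\*) or a
  divergence time, depending on which π is supplied;
* non-coalescence: a lineage pair fails to coalesce by generation *t* with
  probability e^(−t/Ne*); inverting at p gives N = t / ln(1/p);
* selfing: the population-scaled recombination/mutation ratio of a selfer
  is reduced by 1−F; dividing the Ne fold-reduction by the LD-scale
  fold-expansion estimates 1−F, and s = 2F/(1+F).

LD decay is profiled as mean r² between biallelic site pairs binned by
physical distance. "Half decay" is operationalized as the left edge of the
smallest-distance bin at which mean r² reaches the midpoint between the
shortest-distance bin and the asymptote (mean of the last 10% of bins);
with n haplotypes the asymptote is the 1/(n−1) sampling floor, not zero.

## Ancestry HMM

Observations are per-1 kb non-overlapping windows of a focal recipient
genome: the mismatch count k to the genetically closest donor-panel sample,
out of n co-called sites (the minimum-divergence statistic). Hidden states
are donor vs recipient ancestry. Emission distributions are calibrated
empirically: the donor state from the genome-wide distribution of
min-divergence between each donor sample and its closest donor relative;
the recipient state from min-divergence between pure recipient samples and
the donor panel. Each reference set is binned into a 50-bin weighted
histogram over per-site mismatch probabilities (pseudo-count 0.5 per bin),
and the emission likelihood of (k, n) is the histogram-weighted binomial
mixture — conditioning on each window's own n absorbs heterogeneity in
informative-site density. Because minima over more comparisons are
stochastically smaller, reference minima taken over m′ < m comparisons are
resampled to m (10,000 seeded draws, each the minimum of ~m/m′ reference
values).

Transitions use the admixture proportion α and per-window switch rate r
(recombination probability per window × generations since admixture),
constant across windows: staying probabilities (1−r)+r(1−α) and (1−r)+rα,
switching rα and r(1−α). The initial distribution is the stationary
(1−α, α). Chromosomes are independent chains. Missing windows emit
likelihood 1 in both states but still advance one transition step,
preserving genome geometry. Decoding is scaled forward-backward; the
per-window scaling makes posteriors identical to exact arithmetic (verified
against brute-force path enumeration to 1e-10). (α, r) are fitted by
Nelder-Mead on the forward log-likelihood over logit-transformed
parameters, with spread restarts; the fitted likelihood is never allowed
below the supplied initial point's.

## Blocks and dating

Ancestry blocks are maximal runs of consecutive windows with posterior
donor probability > 0.95; healing optionally merges blocks separated by ≤
0/20/50/100 kb (transitively; the healed block spans the merged extent).
Under a single admixture pulse v generations ago, block lengths in Morgans
are exponential with mean 1/v, so T = 1/mean dates the pulse; bp lengths
convert linearly via map length / genome size (1,470 cM / 2.6e8 bp at full
scale). Two caveats are inherent to the estimator and documented rather
than corrected: adjacent donor segments merge invisibly, so the observable
tract mean targets 1/(v(1−α)); and threshold decoding shaves block edges
while missing the shortest blocks. The dispersion test bootstrap-resamples
blocks and reports the fraction of resamples whose variance does not
exceed the squared mean (small p = over-dispersion, rejecting one pulse);
it is computed on Morgan-scale lengths. The chunk count X = vL + C and the
per-ancestor expectation log2(X) − v are computed in log space (2^150
overflows any float).

## Introgression tests

D = Σ(y−z)(w−x) / Σ(y+z−2yz)(w+x−2wx) over aligned sample allele
frequencies, signed so that excess sharing between the sympatric recipient
Y and the donor taxon W is positive. Uncertainty comes from a
delete-one-chromosome weighted jackknife (weights = each chromosome's share
of the denominator); chromosomes contributing no denominator are dropped.
With 14 chromosomes the |Z| < 2 coverage under the null is ~93.5% (the
t₁₃ reference), which is what the calibration suite observes.

The outlier scan slides non-overlapping windows over the donor-taxon panel
and flags windows where exactly one sample exceeds a pairwise-π threshold
(default 1%) against all others while the others stay mutually below it;
consecutive same-outlier windows merge, and regions shorter than 20 kb are
dropped. Per region, the outlier's divergence to a candidate source sample
is compared with the mean across non-outliers (a strict all-must-be-farther
variant is provided); ties drop from n, and the exact one-sided binomial
tail at 50% tests the incomplete-lineage-sorting null.

## Recombination scan

Raw window rates are interpolated cM differences across 100 kb windows
(windows outside map coverage are excluded); smoothing is the mean raw
rate over the centered five-window (~500 kb) span, edge windows using the
neighbors that exist. The association with windowed divergence is
Spearman's rank correlation over windows with ≥ 100 pairwise comparisons.
Covariate controls (outgroup divergence as a mutation-rate proxy, mean
depth) are implemented two ways — Spearman correlation of rank-regression
residuals, and an n-weighted mean of per-quartile-stratum correlations —
because the original control procedure is not fully specified; both are
reported.

## Synthetic data

The mosaic generator is Markovian along a linear genetic map: breakpoints
fall as a Poisson process at rate v per Morgan (plus chromosome ends) and
each segment is independently donor with probability α — no
back-coalescence of segments. Truth segments are the raw Poisson segments,
so segment counts follow X = vL + C and lengths are exponential(1/v)
exactly. Mutations use an infinite-sites binary alphabet: the donor
consensus differs from the recipient consensus (the reference) at per-site
rate π_between, and each sample carries private noise at π_within/2, so
conspecific pairs differ at ~π_within. Defaults are the study conditions:
α = 0.15, v = 150, π_within = 0.003, π_between = 0.04, μ = 1.5e-8, a
14.7-Morgan map over 14 chromosomes at 2.6e8 bp; when genomes are scaled
down the per-bp recombination density (14.7/2.6e8 Morgan/bp) is preserved.
Panels store assayable sites at 600/kb, matching the ~60–70% callable-site
density of the real pipeline after filtering; thinner grids starve the HMM
windows of evidence and create a discretization artifact in block dating.

What the generator does *not* emulate: coalescent ancestry within taxa
(within-taxon sites are iid, so pure samples have no background LD and no
allele-frequency spectrum structure), back-migration, gene conversion, or
sequencing error. Tests that need genealogies (spectra, D-statistic
calibration, divergence build-up) use the msprime-backed
`simulate_unlinked_loci` instead, which simulates independent neutral loci
under a two-population split with optional bottleneck and migration pulse.
Coding fixtures plant single-exon open reading frames (ATG start, clean
interior, terminal stop) on alternating strands and mutate chosen codons
to stops; background synthetic sites inside genes are removed so the
planted sequence is authoritative.

Passing on these panels demonstrates estimator correctness under the
stated generative models; it does not certify behavior under real-data
pathologies (alignment error, paralogy, reference bias).

## Problem sizes

Simulation-based checks use 6 Mb two-chromosome genomes (50 replicates)
for HMM parameter recovery and block dating; 280 five-kb coalescent loci
on 14 pseudo-chromosomes (200 replicates) for null D calibration; 400
one-kb loci for divergence recovery. These sizes give per-replicate
sampling noise well inside the tolerances being tested while keeping the
whole suite in a few minutes on one CPU. Premature-stop calling is exact,
not statistical, so its fixtures are small.

## Premature stops

A stop codon (TAA/TAG/TGA on the coding strand, not already a stop in the
reference) is premature only if (1) all three codon positions have data in
the sample, (2) ≥ 25% of the gene's codons are available in that sample (a
codon is available when all three positions are non-missing; the fraction
is per gene per sample), and (3) the codon is not in the final 5% of
codons. The rules are conjunctive, so relaxing any one can only add
events. A codon reached by two substitutions counts once. π_N/π_S is the
ratio of mean pairwise diversity at 0-fold to 4-fold sites, with a
100 kb-block bootstrap CI computed on the ratio itself.

## Known limitations

* Two ancestry states only; no phasing, no diploid emissions.
* The emission calibration assumes reference panels free of unrecognized
  admixture; contaminated references flatten the state separation.
* Block dating inherits the single-pulse assumptions discussed above; the
  dispersion test flags, but does not deconvolve, multi-pulse histories.
* The covariate controls are a documented stand-in for a procedure whose
  original specification is unavailable in full.
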