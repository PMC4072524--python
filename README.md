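# selfmix

Population-genomic analysis of divergence, the selfing syndrome, and
bidirectional introgression between a highly selfing species and its
outcrossing progenitor, for haploid (inbred-line) genotype panels.

The package is aimed at population geneticists working with small panels of
resequenced inbred lines from recently diverged plant species pairs. From a
multi-sample VCF (or its built-in simulators) it computes:

* **Diversity and divergence** — pairwise π per degeneracy class (π_S at
  4-fold, π_N at 0-fold sites), sliding 5 kb windows, 100 kb block-bootstrap
  CIs, polarized allele-frequency spectra, and shared/private/fixed variant
  partitions.
* **Timescales** — the split-time estimator τ = (π_b − π_a)/2μ, effective
  chromosome numbers Ne\* = π/2μ, the non-coalescence probability
  e^(−t/Ne\*), and a selfing-rate estimate from the Nordborg relation
  1 − F = (ρ/θ)_selfer / (ρ/θ)_outcrosser with F = s/(2−s), plus r² LD-decay
  profiles.
* **Local ancestry** — a two-state HMM over 1 kb windows of
  minimum divergence to a donor panel, with empirically calibrated
  binomial-mixture emissions, transitions t_recipient,donor = rα etc.
  parameterized by the admixture proportion α and per-window rate r,
  scaled forward-backward decoding, and Nelder-Mead likelihood fitting.
* **Admixture blocks** — >95%-posterior block extraction, gap healing,
  bp→cM conversion, pulse dating T = 1/mean-length(Morgans), a bootstrap
  dispersion test of the single-pulse model (variance vs squared mean), and
  the chunk arithmetic X = vL + C.
* **Introgression tests** — the four-population D statistic
  D = Σ(y−z)(w−x)/Σ(y+z−2yz)(w+x−2wx) with a delete-one-chromosome
  jackknife, and a single-outlier region scan (>20 kb, pairwise π_S > 1%)
  with an exact one-sided binomial source test.
* **Recombination scan** — 100 kb window rates from a genetic map smoothed
  over 500 kb, and the Spearman correlation between local recombination and
  divergence, with covariate controls.

A seeded synthetic-data module generates two-taxon panels with planted
mosaic ancestry, gene models with plantable premature stops, and genetic
maps, so every stage is testable with known truth and no downloads.

## Worked example

Simulate an admixed genome and recover the planted history:

```bash
python analysis/01_simulate.py
python analysis/04_ancestry_hmm.py
python analysis/05_blocks.py
```

which prints (4 Mb genome, α = 0.15, v = 150 planted):

```
alpha_hat = 0.1629  (planted fraction 0.1564)
r_hat     = 0.012141 (v x Morgans/window = 0.008481)
posterior admixture fraction = 0.1558
per-window decoding accuracy = 100.0%

heal   0 kb: n =   7  mean = 0.503 cM  T =  198.7  P(exp) = 0.421
heal  20 kb: n =   6  mean = 0.597 cM  T =  167.4  P(exp) = 0.500
```

The HMM's admixture estimate matches the realized donor fraction of the
planted mosaic to about a point; block dating recovers the order of the
planted pulse age (the small replicate carries only ~7 blocks, so T is
noisy); and the dispersion test correctly fails to reject the single-pulse
model that actually generated the data. The closed-form calculators are
also exposed on the command line:

```bash
$ selfmix chunks --generations 150
X       2219
log2_chunks_per_ancestor        -138.9

$ selfmix timescales --pi-between 0.005875 --pi-ancestral 0
tau     195833 generations    (196 ky)
```

The other drivers (`02` diversity, `03` timescales, `06` D/outliers,
`07` recombination) follow the same pattern and write their tables under
`results/`. See `docs/methods.md` for the models, assumptions, and
numerical choices.

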