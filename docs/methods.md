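# Methods

## Scope and model

`admixscan` analyses the local-ancestry architecture of composite
(taurine × indicine) cattle breeds — populations founded at a designed
pedigree proportion such as ⅜ Brahman × ⅝ Angus (Brangus, Santa
Gertrudis) or ½ Brahman (Beefmaster) — from RFMix-style most-likely
window assignments. Because real composite-breed genotypes are held by
breed associations, the package ships a first-class synthetic-data
module: a forward-in-time, tract-based crossbreeding simulator whose
output feeds every downstream stage, so the whole pipeline is exercised
and tested end to end on data with known ground truth.

An individual is a diploid mosaic: per homolog and chromosome, an
ordered tiling by maximal same-ancestry tracts on 0-based half-open
integer coordinates. The bundled genome map has the 29 bovine autosomes
(ARS-UCD1.2 coordinates, 2,489.38 Mb total; chromosome 1 spans
158,532,931 bp).

## Recombination and crossing schemes

Meiosis draws the crossover count per chromosome from
Poisson(λ_c), λ_c = length(Mb) × rate, with the rate defaulting to 0.01
crossovers/Mb (so λ₁ = 1.58532931), uniform crossover positions, a fair
coin for the starting homolog, no interference and no obligate
chiasma. Two named schemes cover the standard designs:

* `BRANGUS_SG` (⅜ × ⅝): F1 = taurine × Brahman; BC1 = F1 × taurine
  purebred (¼ Brahman); generation 1 = BC1 × F1 (⅜ expected); then
  random mating.
* `BEEFMASTER` (½ × ½): generation 1 = F1 × F1; then random mating.

Populations are monoecious, one offspring per cross, N = 1,000 per
generation and 8 rounds of random mating by default — the study-scale
conditions used throughout the calibration targets.

## Three readings of "random mating", and drift

The phrase "randomly mated" under-determines the simulation, and the
choice matters quantitatively for the calibrated dispersion:

* `pair_equal` — parents paired without replacement, two offspring per
  pair (equal parental contributions). Drift comes only from Mendelian
  segregation, about p(1−p)/(4N) per generation.
* `resample` — each offspring draws two distinct parents with
  replacement; family-size variance roughly doubles the drift.
* `independent` — the infinite-population limit: every final-generation
  individual is an independent draw whose pedigree shares no ancestors
  with any other's. No drift at all.

After 8 rounds at N = 1,000, the across-loci SD of the cohort Brahman
proportion is ≈ 0.024 under `pair_equal` and ≈ 0.011 under
`independent` for the ⅜ design. The published calibration estimates
(θ̂ = 0.3722 ± 0.0013, SD(θᵢ) = 0.0106 ± 0.0002 for ⅜; 0.4976 ± 0.0013,
0.0111 ± 0.0002 for ½) agree with the drift-free values — both the
across-loci SD (√(2θ(1−θ)/4/1000) = 0.0108 / 0.0112) and the
between-replicate SD of θ̂ (SD of an individual's global fraction
divided by √1000 ≈ 0.0013) — and are irreconcilable with serial drift
in a closed population of 1,000. `calibrate()` therefore defaults to
`independent`, with the two finite-population modes implemented and
reported through the same interface so the comparison stays one
function call away.

`independent` is sampled exactly, not approximately: a final-generation
haplotype is generated by lazy pedigree recursion, simulating each
ancestral meiosis only on the chromosome intervals actually inherited.
Cost is polynomial in the generation count (≈15 ms per individual at
study scale) instead of the 2^g of naive independent pedigrees.

## Calibration and the divergence scan

Per replicate, the scheme runs to its final generation and the Brahman
frequency among the 2N haplotypes is evaluated at every locus of a
marker grid; θ_rep is the mean across loci and sd_rep the SD across
loci. Ten replicates are averaged. The grid defaults to uniform 3 kb
spacing (~830k loci, the density of a large imputed SNP panel); the
true evaluation-panel coordinates are not public, and the SD estimate
is insensitive to grid choice down to ~50k loci because tract
boundaries, not markers, carry the signal (frequencies are computed by
tract-interval accumulation, exact at any density).

Each window's cohort proportion p_i is then tested against the breed
expectation θ (0.375 or 0.5) with Z_i = (p_i − θ)/SD(θᵢ). The
"variance" in the published notation is defined as a square root and is
used here as the SD denominator; the published p_i ↔ −log₁₀p pairs
(e.g. 0.02 ↔ 240.08) are consistent only with that reading. Two-sided
p-values come from the normal tail computed in the log domain
(`scipy.special.log_ndtr`), exact to machine precision beyond |Z| = 50;
a naive `2·(1−Φ(|z|))` underflows near |Z| ≈ 38 while observed window
statistics reach |Z| > 33. Benjamini–Hochberg step-up control (via
statsmodels) at FDR q = 0.001 defines significance; the reported
nominal threshold is −log₁₀ of the largest rejected raw p, which obeys
threshold ≈ 3 − log₁₀(fraction rejected) at q = 0.001. Window ranks are
invariant to the SD, so localisation conclusions do not depend on the
calibration mode.

## Generation proxy and contrasts

With no pedigree data, animals are ranked by their total ancestry-tract
count: recombination adds tracts every generation. Purebred and F1
genomes carry 58 full-chromosome tracts; at one crossover per
chromosome per meiosis a BC1 genome averages 29 + 29·2 = 87 and an F2
genome 2·29·2 = 116 (every crossover in an F1 meiosis switches
ancestry). The lower/upper ~10% tails of the count distribution define
early-/advanced-generation groups; ties at the threshold are always
wholly included, reproducing slightly unequal group sizes
deterministically. Windows are compared between groups with the pooled
two-proportion Z-test (haplotype counts n = twice the sample sizes),
BH-corrected at q = 0.001; the same statistic applied to the groups'
length-weighted global Brahman fractions gives the genome-wide
contrast. Windows where the pooled proportion is exactly 0 or 1 are
degenerate (p = 1) rather than special-cased to ±∞.

## QTL-window enrichment

Under uniform placement, database entries fall in a 1 Mb window as
Poisson with λ = entries/Mb (64.98 for the full 161,781-entry
database over 2,489.39 Mb); a window is non-empty with probability
1 − e^(−λ), and the count of non-empty windows among n sampled windows
is Binomial. All tails are exact sums (n is 12–15; no normal
approximation); the probability that exactly k of n windows are empty
is computed in the log domain because e^(−65) per window underflows the
naive product. Chromosomes whose entries cluster (e.g. birth-weight
reports on chromosome 6) can be excluded; their lengths are taken from
the active genome map. Entries sharing source and trait are collapsed
into one spanning record when they co-localise within 1 Mb (the
analysis's window scale) — repeated mappings of one QTL otherwise
inflate counts; a strict-overlap mode (`max_gap_bp=0`) is available.

## Selection injection (synthetic signal)

To give the scans a recoverable ground truth the simulator supports
multiplicative viability selection: an offspring with dosage d of the
favored ancestry at each selected locus survives with probability
∏(1+s)^d/(1+s)². This is a signal generator for validation, not a model
of any particular breed's history. Under resampled mating a rejected
candidate redraws its parents (sampling the joint parent–offspring
distribution); under paired mating the pair retries, preserving equal
contributions. With one locus at s = 0.3, N = 500 and 8 generations,
the top-ranked scan window falls within 5 Mb of the locus in ≥ 90% of
seeded runs.

## What the synthetic data does and does not emulate

Emulated: diploid ancestry mosaics from the stated crossing designs,
Poisson recombination, msp-dialect window calls on a dense marker grid,
majority-rule window assignment (ties resolved at the window midpoint
marker), RFMix-style concatenation of windows with identical call
vectors. Not emulated: local-ancestry inference error (calls are exact,
so merging behaviour near breakpoints is cleaner than RFMix's),
non-uniform recombination, mutation, sex chromosomes, overlapping
generations, real selection histories. Passing tests therefore
demonstrate correctness of the statistics given correct ancestry calls,
not robustness to inference error.

## Numerical and design choices

* Coordinates: 0-based half-open integers internally; msp files are
  1-based inclusive and converted only at the IO boundary.
* Window tiling: emitted windows tile each chromosome exactly
  (boundaries at each window's first marker), so run lengths derived
  from calls are in bp and sum to the genome length.
* Problem sizes: calibration uses N = 1,000, 10 replicates, 3 kb grid
  (~4 min); tract-count expectations use 10,000 genomes (±0.05
  Monte Carlo SE); recovery and null-contrast properties use N = 500
  and N = 40 cohorts respectively.
* Reproducibility: a single seeded `numpy` generator drives each run;
  seeded runs are bit-reproducible, and CLI artifacts embed config,
  seed and version.
* Degenerate inputs: all-equal tract counts make tail groups undefined
  (error); zero-variance counts make the count correlation undefined
  (error); p_i ∈ {0,1} windows keep finite Z in the expectation scan.

## Known limitations

The independent-mode calibration reproduces the published dispersion
because the published values carry no drift; if a real breed's
effective size were small enough for drift to matter, the closed-
population modes bound the effect but the package does not estimate N_e.
The ≤5%-of-any-founder filter for three-way composites is applied
literally, which also removes two-breed F1s missing one founder
entirely. Genetic map heterogeneity (recombination hotspots) is not
modelled; λ scales only with physical length.
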