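# Methods

`soysweep` re-implements, as a tested pipeline over synthetic data, the
population-genetic analysis used to localise and characterise a crop
domestication sweep: windowed diversity and differentiation scans with
genome-wide empirical thresholds, cross-population extended haplotype
homozygosity, multi-statistic sweep calling, gene-region haplotyping with
a median-joining network, haplotype-frequency shifts between wild and
cultivated subpopulations, and haplotype-group trait association.  This
note records the models, the parameter choices that matter and the
reasoning behind them, and what the synthetic data do and do not show.

## The domestication simulator

### Demographic model

Forward-in-time Wright–Fisher simulation of diploids with partial
selfing.  One ancestral population (N = 500 diploids) evolves for
`t_split` = 200 generations, then splits into

* a **wild** lineage (S) that keeps the ancestral size, and
* a **domesticated** lineage that passes through a founding bottleneck
  (N = 200 for 10 generations) and then splits into **landrace** (L,
  N = 300) and **cultivar** (C, N = 500) subpopulations,

with sampling at `t_total` = 320 generations (120 generations after
domestication).  Default samples are 100/80/100 accessions (S/L/C), two
phased chromosomes each.

Reproduction each generation draws parents proportional to fitness,
selfs with probability 0.95 (soybean is a predominant selfer; selfing is
what makes accessions near-homozygous and haplotypes long), recombines
with probability `r` = 1e-3 per adjacent-site interval, and mutates by
flipping 0↔1 with probability `mu` = 5e-5 per site per generation, so
every site stays biallelic.  Crossover counts per gamete are
Binomial(n_sites − 1, r) with uniform breakpoints; double hits on one
interval cancel, which matches the parity of independent per-interval
crossovers.  The chromosome is 1 Mb with 3000 variant-site slots;
standing variation is initialised from a 1/x frequency spectrum at
linkage equilibrium, and the ancestral phase builds linkage
disequilibrium before anything else happens.

The post-split era is deliberately *mild* in drift units (about 0.25
coalescent units in the domesticated lineage, 0.23 in the wild one).
This is the single most important calibration in the package: with a
longer or more intense bottleneck era, drift fixes large tracts of the
cultivar genome, the genome-wide background of F_ST / π-ratio / XP-EHH
saturates, and a real sweep is no longer an outlier against it.  The
values above reproduce the qualitative regime of the real study system
(moderate genome-wide differentiation, cultivar diversity reduced but
present) at desk scale.

### Selection and the focal allele

Fitness at the focal site is 1, 1 + s/2, 1 + s (additive), with
`s` = 0.1, acting only in the domesticated lineage (artificial
selection).  Two origin modes exist:

* **de novo** (default): at the domestication onset the beneficial
  allele appears on a single founder chromosome whose lineage is
  propagated to 20 identical copies (5% of the founding chromosomes) —
  one farmer's plant, multiplied.  This produces the classic hard sweep.
  The domesticated phases are conditioned on non-loss of the allele
  (generations losing it are redrawn from the same stream): a
  domestication locus is observed *because* its allele succeeded, so the
  conditioning is part of the scenario, not a distortion of it.
* **standing**: the allele segregates in the ancestral population inside
  a frequency band around `focal_start_freq` (band-violating generations
  are redrawn).  Sweeps from common standing variation are soft — the
  allele rides on several haplotype backgrounds — and leave much weaker
  local signatures; this mode exists to study exactly that contrast.

The focal site is excluded from recurrent mutation; its trajectory is
fully defined by the origin scenario.  (Without this, new mutations at
the focal site re-soften every "hard" sweep — an effect worth knowing
about.)  With `s` = 0 no allele is injected and the site drifts like any
other, which is the neutral null used throughout the tests.

Determinism: all randomness derives from `SimulationConfig.seed` through
named `SeedSequence` substreams, so identical configs give bit-identical
cohorts, and the trait generator is reproducible independently of the
genotype simulation.

### Traits

Each accession carries a ground-truth group label (I/II/III from its
focal-allele dosage).  Trait values are `baseline + group effect +
Gaussian noise`, per trait: 100-seed weight (baseline 12 g, effects
0/+3/+6 g, sd 2 g), fatty-acid content (18% DW, 0/+1.5/+3, sd 1), and
protein content (45% DW, 0/−2/−4, sd 1.5).  Effects follow the
domestication syndrome — seed weight and oil rise from group I to III,
protein falls — and the adjacent-group effect/sd ratios (≥ 1.3) make
recovery comfortable at n = 50 per group without being trivial.  There
is no polygenic background, no G×E and no trait correlation beyond the
shared group labels: the association stage only needs group-separable
means, and anything beyond that would be decoration the tests cannot
validate.

## Scan statistics

* **π** per site is 2k(n−k)/(n(n−1)) over non-missing chromosomes; a
  window's value is the summed site contributions divided by the full
  window span in bp.  A window is NaN only when it contains fewer than
  `min_sites_per_window` = 3 genotyped variant sites — a *data-density*
  condition, deliberately not a population-segregation condition,
  because a swept window (many variant sites, all monomorphic in
  cultivars) must report π = 0 rather than disappear.
* **π-ratio** is π_S/π_C per window, NaN when π_C = 0 (guarded
  division).  High values flag diversity loss in cultivars.
* **F_ST** is the Hudson two-population estimator with Bhatia-style
  ratio-of-averages windowing (site numerators and denominators summed
  separately), clipped to [0, 1] for output with the raw value retained.
  Worth knowing: for a *young* local fixation the estimator tops out
  well below 1 (between-population diversity at a swept window is
  roughly the wild diversity, so F_ST ≈ 1 − π_S/2 ÷ π_S ≈ 0.5–0.8);
  complete fixation of *different* alleles is what gives 1.
* **EHH** at an extent is the probability that two chromosomes drawn
  from the population are identical over all sites strictly beyond the
  core up to that extent (all-chromosome form, core excluded so
  EHH(0) = 1 exactly).  Chromosomes hitting a missing allele leave the
  computation.  **iHH** integrates the decay curve (trapezoid, physical
  bp) on both flanks, truncating at EHH < 0.05 or at an inter-site gap
  over 200 kb; a flank reaching the chromosome edge is integrated as-is
  under the default `clip` policy (counted and reported) or discarded
  under `discard`.  **XP-EHH** is ln iHH_C − ln iHH_S per core site
  (cores: pooled MAF ≥ 0.05), z-normalised genome-wide with the
  population sd; windows take the max z of their core sites.  Physical
  distance is used throughout — the simulator has no genetic map.

Windows are 0-based half-open, sliding, 40 kb wide with a 2-kb step.
The 40-kb default is matched to the simulator's sweep footprint
(~±25 kb at the default r and sweep duration): windows must be wide
enough that the outlier runs of different statistics overlap (see
below) yet narrow enough to resolve the footprint.  Scans of data with
other LD scales should set `window_bp` accordingly; 20 kb is the
natural choice when the expected footprint exceeds ~100 kb.

## Sweep calling

Per statistic, the genome-wide threshold is the ⌈q·W⌉-th smallest
finite window value at `top_quantile` q = 0.95; a window is an outlier
iff strictly above it, so a tie-free track flags exactly the top 5%.

Two support modes combine the statistics:

* **window** support: a window is sweep-supporting when ≥ `min_support`
  statistics flag that same window; supporting windows merge into
  regions (bridging gaps up to `merge_gap_bp`).
* **region** support (pipeline default): each statistic's flagged
  windows are first merged into per-statistic outlier intervals, and
  sweep regions are the genomic segments covered by ≥ `min_support`
  intervals.

The region mode exists because of a reproducible observation on the
simulator's replicates: the three statistics peak on *staggered* parts
of one sweep — F_ST on the allele-frequency shoulder, the π-ratio at
the deepest diversity trough, XP-EHH where the swept haplotype extends
— tiling the region without necessarily sharing any single window.
Requiring per-window coincidence then rejects textbook sweeps.  Region
support reflects how coincident signals actually present in scans of
this kind.  `min_support` defaults to 3 (all statistics) for
conservative calling; power analyses use 2, reflecting XP-EHH's
volatility at desk scale (its background is set by drift-IBD tract
lengths, which at a compressed timescale rival the sweep tract itself).
Called regions are intersected (half-open) with gene/QTL annotation
intervals when a BED file is supplied.

## Haplotype analysis

Gene-region variants are those inside the 0-based half-open region with
MAF ≥ 0.01 over non-missing chromosomes — a site at exactly 1% is
retained (the filter removes *strictly rarer* polymorphisms).  SNPs and
In/Dels are treated identically as single mutational steps.
Chromosomes collapse into haplotype strings ("chromosome" mode; the
"accession" mode counts only accessions homozygous across the region,
twice, and tallies heterozygotes — in a 95% selfer the two modes almost
coincide).

The median-joining network starts from the ε-relaxed minimum-spanning
network under Hamming distance (ε = 0 keeps exactly the union of all
minimum spanning trees; an edge belongs to one iff its weight equals
the minimax path distance between its ends).  Median vectors
(coordinate-wise majority of node triplets) are added greedily while
they reduce the minimum-spanning cost, with lexicographic tie-breaking
for determinism, then dead-end medians (degree ≤ 1) are pruned.  The
network cost therefore never exceeds the MST cost over observed
haplotypes.

Major groups cut the network at an edge-weight cutoff (components after
removing edges ≥ cutoff); `target_k` picks the smallest cutoff yielding
exactly k groups of observed haplotypes and reports the achievable
counts when k is unreachable.  Groups are labelled H_I, H_II, … by
descending wild-chromosome count, so H_I reads as the wild-enriched
group and the cultivar-enriched group comes last, matching how such
panels are usually presented.  Note that with a *de novo* sweep the
swept haplotype is one mutational step from its wild sister lineage, so
the cultivar-dominant group need not be maximally distant from H_I in
the network; analyses that need "the swept group" should select it by
cultivar count, not by label order.

Per-subpopulation haplotype and group frequencies come with a pooled
two-proportion z-test (statsmodels) for each group's wild-vs-cultivar
shift.

## Trait association

Pairwise classical pooled-variance Student's t-tests (df = n₁+n₂−2;
Welch available behind a flag), no multiple-testing correction by
default (per-pair α = 0.05; Bonferroni behind a flag).  Zero pooled
variance degenerates to p = 1 (equal means) or p = 0 with a warning.
Letters: a letter is a clique of the not-significantly-different graph;
the display is the smallest set of maximal cliques covering every group
and every non-significant pair (found exactly — group counts are small
— rather than by the insert-and-absorb heuristic, which is not always
minimal), ordered so that 'a' marks the highest-mean cluster.
Accessions map to groups through their homozygous gene-region
haplotype; heterozygous or incomplete accessions are excluded and
tallied.  A subpopulation filter (e.g. cultivars only) guards against
wild/domesticated confounding.

## What the synthetic cohorts do and do not show

The generator produces the *structure* the pipeline is built to detect:
three subpopulations with realistic differentiation, a hard sweep with
a localized footprint, haplotype groups with strong frequency shifts,
and group-separable traits.  Passing tests therefore demonstrate that
the statistics, thresholds, network and association machinery are
implemented correctly and can recover a planted signal under honest
noise.  They do not demonstrate performance on real resequencing data:
the simulator has a single 1-Mb chromosome (no genome-wide threshold
over thousands of windows), no missing genotypes or genotyping error in
its default output, no population substructure within S/L/C, no gene
flow after the splits, uniform recombination and mutation, and a trait
model without polygenic background.  The compressed timescale also
makes sweep-tract and drift-IBD lengths comparable, which is why
XP-EHH — decisive on real data — is the weakest of the three statistics
here.

## Problem sizes

Default analyses and tests run replicates of ~560 sampled chromosomes ×
~1600 segregating sites; the recovery analyses use 20 selected plus 20
neutral replicates (seeds 1–20) and the acceptance script 8 + 8
derived from its seed.  These sizes keep a full replicate (simulation
plus scan) around ten seconds while leaving every stage's signal
clearly measurable.
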