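# soysweep

Selective-sweep scanning and haplotype analysis for domestication
cohorts — a tested re-implementation of the population-genetics pipeline
used to localise a crop domestication sweep and tie it to seed traits,
together with a Wright–Fisher simulator so every stage runs end to end
without external data.

The scientific setting: cultivated soybean (*Glycine max*) was
domesticated from wild *G. soja*, with parallel increases in seed size
and oil content and a decrease in protein content.  Resequencing panels
of wild accessions (S), landraces (L) and improved cultivars (C) let one
localise the loci responsible: a selective sweep shows up as a region
where cultivars have lost diversity (high π_S/π_C), diverged from the
wild pool (high Hudson F_ST) and carry unusually long haplotypes
(positive XP-EHH), all relative to genome-wide empirical thresholds
(top 5% of windows).  The gene region is then haplotyped, the haplotypes
are related in a median-joining network and cut into major groups
(H_I wild-enriched … cultivar-enriched), and the groups are compared for
100-seed weight, fatty-acid and protein content with Student's t-tests
and compact letter displays.

The statistics, in the field's standard notation:

* per-site diversity π = 2k(n−k)/(n(n−1)), windowed per bp;
* Hudson F_ST per window as Σ[(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)] / Σ[p₁(1−p₂) + p₂(1−p₁)];
* EHH(x) = Σ_g C(c_g,2)/C(n,2) over haplotype groups extended from a
  core site to x; iHH = ∫EHH (trapezoid, both flanks, truncated at
  EHH < 0.05); XP-EHH = ln iHH_C − ln iHH_S, z-normalised genome-wide.

## Worked example

The numbered scripts under `analysis/` run the whole study on a
simulated cohort (wild → bottleneck → landrace/cultivar with a hard
sweep at a focal site, 280 accessions, 1 Mb):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_selection_scan.py
python analysis/03_call_sweeps.py
python analysis/04_haplotype_network.py
python analysis/05_trait_association.py
python analysis/06_recovery_power.py    # optional, ~4 min
```

With seed 1 this prints, abridged:

```
cohort: 280 accessions, 1626 segregating sites
focal allele frequency  wild=0.00  landrace=1.00  cultivar=1.00

top-5% threshold fst: 0.6249
top-5% threshold pi_ratio: 3.1252
top-5% threshold xpehh_norm: 2.0849
1 region(s) called -> results/sweeps/sweep_regions.tsv
  chr15:470000-556000 (86 kb) supported by fst,pi_ratio  <-- contains the selected focal site

35 distinct haplotypes ...
major groups: ['H_I', 'H_II', 'H_III'] (cutoff 7)
       count_S  count_C  freq_S  freq_C     z  p_value
H_I        171        0   0.855       0  17.3 6.36e-67
H_II        27      174   0.135    0.87 -14.7 6.43e-49
H_III        2       26    0.01    0.13  -4.7 2.56e-06

          trait group   n  mean   sd letter
seed_weight_100  H_II 174 17.50 2.33      a
seed_weight_100 H_III  13 17.08 2.66      a
seed_weight_100   H_I  78 11.58 1.84      b
    protein_pct   H_I  78 44.75 1.63      a
    protein_pct  H_II 174 41.08 1.84      b
```

Reading the output: the selected allele fixed in the domesticated
lineages while staying absent from the wild sample; an 86-kb region
containing the true focal position exceeds the genome-wide top-5%
thresholds of two statistics; the haplotype network splits into a
wild-dominant group (H_I, 85.5% of wild chromosomes) and a
cultivar-dominant swept group (H_II, 87% of cultivar chromosomes,
frequency-shift p ≈ 6e-49); and accessions carrying the swept
haplotypes have ~6 g heavier seeds, higher oil and ~3.7 points lower
protein, with letter displays separating them from H_I at α = 0.05 —
the domestication-syndrome pattern the pipeline is designed to expose.

The same machinery is available as a CLI
(`soysweep simulate|scan|xpehh|callsweeps|haplotype|network|associate|run`)
and as a library (`import soysweep`); `soysweep run -c config.yaml`
executes all stages with a reproducibility manifest (config hash,
artifact checksums, per-stage wall clock).

## Layout

```
src/soysweep/      library: simulate, vcf_io, diversity, xpehh, sweeps,
                   haplotypes, traits, evaluation, pipeline, cli
analysis/          numbered drivers reproducing the study end to end
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    models, parameter choices, limitations
scripts/           acceptance script
```
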