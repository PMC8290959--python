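"""Forward-in-time Wright-Fisher simulator of a selfing domestication scenario.

The demographic model mirrors crop domestication from a wild relative: an
ancestral population evolves neutrally, then splits into (i) a wild lineage
that keeps the ancestral size and (ii) a domesticated lineage that passes
through a strong bottleneck under positive selection at one focal site,
and later splits into landrace and cultivar subpopulations.  Reproduction
is Wright-Fisher with partial selfing (soybean is a predominant selfer),
per-interval recombination and per-site 0<->1 flip mutation, so records
stay biallelic.

Selection acts only in the domesticated lineage (artificial selection):
genotype fitnesses at the focal site are 1, 1+s/2 and 1+s (additive).  By
default the beneficial allele arises at domestication onset on a single
founder chromosome whose lineage was propagated to a handful of identical
copies (a hard sweep, conditioned on the allele's survival -- a
domestication locus is observed because its allele succeeded); a standing-
variation mode keeps the allele instead at a configured ancestral
frequency band.  Under s=0 no allele is injected and the focal site drifts
like any other; realized frequencies per subpopulation are always reported.

Traits are group-additive: every accession carries a ground-truth haplotype
group (I/II/III from its focal-allele dosage) and each trait is
``baseline + group effect + Gaussian noise``.  Default effect directions
follow the domestication syndrome: seed weight and fatty-acid content rise
from group I to III while protein content falls.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from soysweep.vcf_io import TRAIT_COLUMNS, HaplotypeMatrix, write_vcf

GROUPS = ("I", "II", "III")

_DEFAULT_BASELINES = {
    "seed_weight_100": 12.0,  # g
    "fatty_acid_pct": 18.0,  # % DW
    "protein_pct": 45.0,  # % DW
}
# additive shift per haplotype group; seed weight and oil rise from group
# I to III, protein falls -- the domestication direction.
_DEFAULT_EFFECTS = {
    "seed_weight_100": {"I": 0.0, "II": 3.0, "III": 6.0},
    "fatty_acid_pct": {"I": 0.0, "II": 1.5, "III": 3.0},
    "protein_pct": {"I": 0.0, "II": -2.0, "III": -4.0},
}
_DEFAULT_NOISE = {
    "seed_weight_100": 2.0,
    "fatty_acid_pct": 1.0,
    "protein_pct": 1.5,
}


class SimulationConfigError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass
class SimulationConfig:
    """Parameters of the domestication scenario.

    Population sizes are diploid counts; times are generations since the
    start of the simulation: the wild/domesticated split happens at
    ``t_split``, the domesticated lineage spends ``t_bottleneck``
    generations at size ``n_bottleneck`` before splitting into landrace
    and cultivar, and sampling happens at ``t_total``.  ``mu`` is the
    per-site per-generation flip probability, ``r`` the
    per-adjacent-interval crossover probability, ``s`` the additive
    selection coefficient at ``focal_index`` (active only in the
    domesticated lineage).
    """

    n_ancestral: int = 500
    n_bottleneck: int = 200
    n_landrace: int = 300
    n_cultivar: int = 500
    t_split: int = 200
    t_bottleneck: int = 10
    t_total: int = 320
    mu: float = 5e-5
    r: float = 1e-3
    selfing_rate: float = 0.95
    s: float = 0.1
    focal_index: int | None = None  # default: middle site
    focal_origin: str = "de_novo"  # "de_novo" | "standing"
    focal_founder_copies: int = 20  # de novo mode: IBD copies of the founder
    focal_start_freq: float = 0.2  # standing mode only
    standing_variation: bool = True
    chrom: str = "chr15"
    chrom_length_bp: int = 1_000_000
    n_sites: int = 3000
    indel_fraction: float = 0.1
    sample_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"S": 100, "L": 80, "C": 100}
    )
    baseline_traits: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINES)
    )
    effect_sizes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {t: dict(g) for t, g in _DEFAULT_EFFECTS.items()}
    )
    trait_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NOISE)
    )
    seed: int = 0

    def __post_init__(self):
        if self.focal_index is None:
            self.focal_index = self.n_sites // 2
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_ancestral": self.n_ancestral,
            "n_bottleneck": self.n_bottleneck,
            "n_landrace": self.n_landrace,
            "n_cultivar": self.n_cultivar,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value < 2:
                raise SimulationConfigError(f"{name} must be an integer >= 2, got {value}")
        for name in ("mu", "r", "selfing_rate"):
            value = getattr(self, name)
            if not math.isfinite(value) or not 0.0 <= value <= 1.0:
                raise SimulationConfigError(f"{name} must be in [0, 1], got {value}")
        if not math.isfinite(self.s) or self.s < 0:
            raise SimulationConfigError(f"s must be finite and >= 0, got {self.s}")
        if not 0 <= self.focal_index < self.n_sites:
            raise SimulationConfigError(
                f"focal_index {self.focal_index} outside [0, {self.n_sites})"
            )
        if not 0.0 <= self.focal_start_freq <= 1.0:
            raise SimulationConfigError("focal_start_freq must be in [0, 1]")
        if self.focal_origin not in ("de_novo", "standing"):
            raise SimulationConfigError("focal_origin must be 'de_novo' or 'standing'")
        if self.t_split >= self.t_total:
            raise SimulationConfigError("t_split must be < t_total")
        if self.t_split < 0:
            raise SimulationConfigError("t_split must be >= 0")
        if self.t_bottleneck < 1 or self.t_split + self.t_bottleneck >= self.t_total:
            raise SimulationConfigError(
                "need 1 <= t_bottleneck and t_split + t_bottleneck < t_total"
            )
        if self.n_sites < 2 or self.n_sites > self.chrom_length_bp:
            raise SimulationConfigError("need 2 <= n_sites <= chrom_length_bp")
        for pop in ("S", "L", "C"):
            if pop not in self.sample_sizes or self.sample_sizes[pop] < 2:
                raise SimulationConfigError(f"sample_sizes[{pop!r}] must be >= 2")
        source = {"S": self.n_ancestral, "L": self.n_landrace, "C": self.n_cultivar}
        for pop, n in source.items():
            if self.sample_sizes[pop] > n:
                raise SimulationConfigError(
                    f"cannot sample {self.sample_sizes[pop]} accessions from "
                    f"{n} diploids in subpopulation {pop}"
                )
        for trait in TRAIT_COLUMNS:
            if trait not in self.baseline_traits:
                raise SimulationConfigError(f"baseline missing for trait {trait}")
            if trait not in self.trait_noise_sd or self.trait_noise_sd[trait] < 0:
                raise SimulationConfigError(f"non-negative noise sd required for {trait}")
            effects = self.effect_sizes.get(trait)
            if effects is None:
                raise SimulationConfigError(f"effect sizes missing for trait {trait}")

    def to_dict(self) -> dict:
        return {
            "n_ancestral": self.n_ancestral,
            "n_bottleneck": self.n_bottleneck,
            "n_landrace": self.n_landrace,
            "n_cultivar": self.n_cultivar,
            "t_split": self.t_split,
            "t_bottleneck": self.t_bottleneck,
            "t_total": self.t_total,
            "mu": self.mu,
            "r": self.r,
            "selfing_rate": self.selfing_rate,
            "s": self.s,
            "focal_index": self.focal_index,
            "focal_origin": self.focal_origin,
            "focal_founder_copies": self.focal_founder_copies,
            "focal_start_freq": self.focal_start_freq,
            "standing_variation": self.standing_variation,
            "chrom": self.chrom,
            "chrom_length_bp": self.chrom_length_bp,
            "n_sites": self.n_sites,
            "indel_fraction": self.indel_fraction,
            "sample_sizes": dict(self.sample_sizes),
            "baseline_traits": dict(self.baseline_traits),
            "effect_sizes": {t: dict(g) for t, g in self.effect_sizes.items()},
            "trait_noise_sd": dict(self.trait_noise_sd),
            "seed": self.seed,
        }


@dataclass
class SimulatedCohort:
    """Simulator output: genotypes, population map, traits and ground truth."""

    haplotypes: HaplotypeMatrix
    population_map: dict[str, str]
    traits: pd.DataFrame
    truth: dict


def _gametes(pop: np.ndarray, parents: np.ndarray, r: float, rng) -> np.ndarray:
    """One recombinant gamete per listed parent (diploid index).

    Crossover counts per gamete are Binomial(n_sites - 1, r) with uniform
    breakpoint positions; an even number of hits at one interval cancels,
    matching the parity of independent per-interval crossovers.
    """
    n_sites = pop.shape[1]
    m = parents.size
    h1 = pop[2 * parents]
    h2 = pop[2 * parents + 1]
    start = rng.integers(0, 2, size=m, dtype=np.int8)
    if r > 0 and n_sites > 1:
        n_cross = np.minimum(rng.binomial(n_sites - 1, r, size=m), 120)
        total = int(n_cross.sum())
    else:
        n_cross = None
        total = 0
    if total == 0:
        out = h1
        swap = start.astype(bool)
        out[swap] = h2[swap]
        return out
    breaks = np.zeros((m, n_sites), dtype=np.int8)
    breaks[:, 0] = start
    rows = np.repeat(np.arange(m), n_cross)
    cols = rng.integers(1, n_sites, size=total)
    np.add.at(breaks, (rows, cols), 1)
    np.cumsum(breaks, axis=1, out=breaks)
    breaks &= 1
    return np.where(breaks.view(np.bool_), h2, h1)


def _next_generation(
    pop: np.ndarray, n_offspring: int, cfg: SimulationConfig, selected: bool, rng
) -> np.ndarray:
    """One Wright-Fisher generation with selection, selfing and mutation."""
    n_parents = pop.shape[0] // 2
    if selected and cfg.s > 0:
        dosage = pop[0::2, cfg.focal_index].astype(np.float64) + pop[
            1::2, cfg.focal_index
        ].astype(np.float64)
        weights = 1.0 + cfg.s * dosage / 2.0
        cdf = np.cumsum(weights)
        cdf /= cdf[-1]
        mothers = np.searchsorted(cdf, rng.random(n_offspring), side="right")
        fathers = np.searchsorted(cdf, rng.random(n_offspring), side="right")
    else:
        mothers = rng.integers(0, n_parents, size=n_offspring)
        fathers = rng.integers(0, n_parents, size=n_offspring)
    selfed = rng.random(n_offspring) < cfg.selfing_rate
    fathers = np.where(selfed, mothers, fathers)

    gametes = _gametes(pop, np.concatenate([mothers, fathers]), cfg.r, rng)
    children = np.empty((2 * n_offspring, pop.shape[1]), dtype=np.int8)
    children[0::2] = gametes[:n_offspring]
    children[1::2] = gametes[n_offspring:]

    if cfg.mu > 0:
        n_mut = rng.binomial(children.size, cfg.mu)
        if n_mut:
            rows = rng.integers(0, children.shape[0], size=n_mut)
            cols = rng.integers(0, children.shape[1], size=n_mut)
            # the focal site's trajectory is governed by the origin
            # scenario (standing frequency or single de novo copy), not
            # by recurrent mutation
            keep = cols != cfg.focal_index
            children[rows[keep], cols[keep]] ^= 1
    return children


def _evolve_phase(
    pop: np.ndarray,
    n_generations: int,
    n_diploids: int,
    cfg: SimulationConfig,
    selected: bool,
    rng,
    band: tuple[float, float] | None = None,
    forbid_loss: bool = False,
) -> np.ndarray:
    """Evolve one population phase, optionally conditioning the focal site.

    ``band`` keeps the focal frequency inside [lo, hi] (ancestral standing
    variation); ``forbid_loss`` redraws generations that would lose the
    focal allele (the domesticated lineage is observed conditional on the
    selected allele's success).  Redraws consume further draws from the
    same stream, so the output is deterministic for a given rng state.
    """
    for _ in range(n_generations):
        for _attempt in range(500):
            cand = _next_generation(pop, n_diploids, cfg, selected=selected, rng=rng)
            k = int(cand[:, cfg.focal_index].sum())
            if band is not None:
                n_chrom = cand.shape[0]
                if band[0] * n_chrom <= k <= band[1] * n_chrom:
                    break
            elif forbid_loss:
                if k > 0:
                    break
            else:
                break
        pop = cand
    return pop


def _initial_population(cfg: SimulationConfig, rng) -> np.ndarray:
    n_chrom = 2 * cfg.n_ancestral
    pop = np.zeros((n_chrom, cfg.n_sites), dtype=np.int8)
    if cfg.standing_variation:
        # neutral-SFS-like standing variation: frequency density ~ 1/x on
        # (1/n_chrom, 1), sampled by inverse CDF, sites at linkage
        # equilibrium (the burn-in builds LD).
        x_min = 1.0 / n_chrom
        u = rng.random(cfg.n_sites)
        freq = x_min ** (1.0 - u)
        pop[:] = rng.random((n_chrom, cfg.n_sites)) < freq[None, :]
    # focal site: exact standing frequency of the beneficial allele
    # (absent until domestication onset in de novo mode)
    k = (
        int(round(cfg.focal_start_freq * n_chrom))
        if cfg.focal_origin == "standing"
        else 0
    )
    col = np.zeros(n_chrom, dtype=np.int8)
    col[:k] = 1
    pop[:, cfg.focal_index] = rng.permutation(col)
    return pop


def _site_metadata(cfg: SimulationConfig, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    positions = np.sort(rng.choice(cfg.chrom_length_bp, size=cfg.n_sites, replace=False)) + 1
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=cfg.n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=cfg.n_sites)) % 4
    ref = bases[ref_idx].astype(object)
    alt = bases[alt_idx].astype(object)
    is_indel = rng.random(cfg.n_sites) < cfg.indel_fraction
    insertion = rng.random(cfg.n_sites) < 0.5
    for j in np.nonzero(is_indel)[0]:
        if insertion[j]:
            alt[j] = str(ref[j]) + "T"
        else:
            ref[j] = str(ref[j]) + "T"
            alt[j] = str(ref[j])[0]
    return positions.astype(np.int64), ref, alt, is_indel


def simulate_domestication(config: SimulationConfig) -> SimulatedCohort:
    """Run the domestication scenario and sample a three-subpopulation cohort.

    Returns a :class:`SimulatedCohort` whose haplotype matrix contains the
    sites still segregating among the sampled chromosomes.  The ``truth``
    dict records the focal position, the realized focal-allele frequency in
    each subpopulation and the per-accession haplotype-group label (I/II/III
    from focal dosage) that drives the trait generator.  Identical configs
    (including the seed) give bit-identical cohorts.
    """
    config.validate()
    seq = np.random.SeedSequence([int(config.seed), 0x5357])
    meta_ss, init_ss, burn_ss, wild_ss, dom_ss, land_ss, cult_ss, samp_ss = seq.spawn(8)
    rng_meta = np.random.default_rng(meta_ss)
    positions, ref, alt, is_indel = _site_metadata(config, rng_meta)

    pop = _initial_population(config, np.random.default_rng(init_ss))

    # Ancestral phase.  In standing mode the focal allele is conditioned
    # to stay near its standing frequency (generations pushing it outside
    # [f0/2, min(2*f0, 0.6)] are redrawn from the same stream); in de novo
    # mode the beneficial allele does not exist yet and the phase is a
    # plain neutral burn-in that builds linkage disequilibrium.
    f0 = config.focal_start_freq
    band = None
    if config.focal_origin == "standing" and f0 > 0:
        band = (max(0.5 * f0, 0.02), min(max(2.0 * f0, 0.1), 0.6))
    pop = _evolve_phase(
        pop, config.t_split, config.n_ancestral, config, selected=False,
        rng=np.random.default_rng(burn_ss), band=band,
    )

    t_late = config.t_total - config.t_split
    t_bottleneck = config.t_bottleneck
    t_lc = t_late - t_bottleneck

    # The domesticated lineage is conditioned on keeping the selected
    # allele (a domestication locus is studied because its allele
    # succeeded); the wild lineage drifts freely.  In de novo mode the
    # beneficial allele arises on a single founding chromosome at the
    # domestication onset, giving the classic hard sweep.
    keep = config.s > 0
    wild = _evolve_phase(
        pop, t_late, config.n_ancestral, config, selected=False,
        rng=np.random.default_rng(wild_ss),
    )
    rng_dom = np.random.default_rng(dom_ss)
    if config.focal_origin == "de_novo" and config.s > 0:
        dom = _next_generation(pop, config.n_bottleneck, config, selected=False, rng=rng_dom)
        dom[:, config.focal_index] = 0  # single origin: clear any strays
        origin = int(rng_dom.integers(0, dom.shape[0]))
        # the selected lineage descends from one founder chromosome whose
        # line was propagated at domestication: clone it onto
        # focal_founder_copies chromosomes (identical by descent), then
        # mark the beneficial allele
        k0 = max(1, min(config.focal_founder_copies, dom.shape[0]))
        others = rng_dom.choice(
            [i for i in range(dom.shape[0]) if i != origin], size=k0 - 1, replace=False
        )
        for i in others:
            dom[i] = dom[origin]
        dom[origin, config.focal_index] = 1
        dom[others, config.focal_index] = 1
        dom = _evolve_phase(
            dom, t_bottleneck - 1, config.n_bottleneck, config, selected=True,
            rng=rng_dom, forbid_loss=keep,
        )
    else:
        dom = _evolve_phase(
            pop, t_bottleneck, config.n_bottleneck, config, selected=True,
            rng=rng_dom, forbid_loss=keep,
        )
    land = _evolve_phase(
        dom, t_lc, config.n_landrace, config, selected=True,
        rng=np.random.default_rng(land_ss), forbid_loss=keep,
    )
    cult = _evolve_phase(
        dom, t_lc, config.n_cultivar, config, selected=True,
        rng=np.random.default_rng(cult_ss), forbid_loss=keep,
    )

    rng = np.random.default_rng(samp_ss)
    blocks, accessions, pop_map = [], [], {}
    final = {"S": wild, "L": land, "C": cult}
    for pop_code in ("S", "L", "C"):
        source = final[pop_code]
        chosen = np.sort(rng.choice(source.shape[0] // 2, config.sample_sizes[pop_code], replace=False))
        rows = np.empty(2 * chosen.size, dtype=np.intp)
        rows[0::2] = 2 * chosen
        rows[1::2] = 2 * chosen + 1
        blocks.append(source[rows])
        for i in range(chosen.size):
            acc = f"{pop_code}{i + 1:03d}"
            accessions.append(acc)
            pop_map[acc] = pop_code
    alleles = np.concatenate(blocks, axis=0)

    # ground truth before dropping monomorphic sites
    focal_col = alleles[:, config.focal_index]
    realized = {}
    offset = 0
    for pop_code in ("S", "L", "C"):
        n = 2 * config.sample_sizes[pop_code]
        realized[pop_code] = float(focal_col[offset : offset + n].mean())
        offset += n
    dosage = focal_col[0::2] + focal_col[1::2]
    labels = {
        acc: GROUPS[int(d)] for acc, d in zip(accessions, dosage)
    }

    counts = alleles.sum(axis=0)
    segregating = (counts > 0) & (counts < alleles.shape[0])
    matrix = HaplotypeMatrix(
        chrom=config.chrom,
        positions=positions[segregating],
        ref=ref[segregating],
        alt=alt[segregating],
        is_indel=is_indel[segregating],
        alleles=alleles[:, segregating],
        accessions=accessions,
        phased=True,
    )
    truth = {
        "focal_position": int(positions[config.focal_index]),
        "focal_retained": bool(segregating[config.focal_index]),
        "realized_focal_frequency": realized,
        "group_labels": labels,
    }
    traits = simulate_traits(labels, config).loc[accessions]
    return SimulatedCohort(matrix, pop_map, traits, truth)


def simulate_traits(
    group_labels: Mapping[str, str], config: SimulationConfig
) -> pd.DataFrame:
    """Group-additive trait table: baseline + group effect + Gaussian noise.

    Deterministic for a fixed config seed and label mapping (accessions are
    processed in sorted order).  Every accession must carry a group label
    with an effect size defined for every trait.
    """
    accs = sorted(group_labels)
    for acc in accs:
        group = group_labels[acc]
        if group is None or group == "":
            raise ValueError(f"accession {acc!r} has no group label")
        for trait in TRAIT_COLUMNS:
            if group not in config.effect_sizes[trait]:
                raise ValueError(
                    f"no effect size for group {group!r} in trait {trait}"
                )
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x7261]))
    data = {}
    for trait in TRAIT_COLUMNS:
        base = config.baseline_traits[trait]
        sd = config.trait_noise_sd[trait]
        effect = np.array([config.effect_sizes[trait][group_labels[a]] for a in accs])
        noise = rng.normal(0.0, sd, size=len(accs)) if sd > 0 else np.zeros(len(accs))
        data[trait] = base + effect + noise
    df = pd.DataFrame(data, index=pd.Index(accs, name="sample"))
    return df


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF, population map, trait table and truth JSON to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "popmap": out / "population_map.tsv",
        "traits": out / "traits.tsv",
        "truth": out / "truth.json",
    }
    write_vcf(cohort.haplotypes, paths["vcf"])
    with open(paths["popmap"], "w") as fh:
        fh.write("sample\tsubpopulation\n")
        for acc in cohort.haplotypes.accessions:
            fh.write(f"{acc}\t{cohort.population_map[acc]}\n")
    tdf = cohort.traits.reset_index()
    tdf.to_csv(paths["traits"], sep="\t", index=False, float_format="%.6f")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
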