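"""End-to-end orchestration: simulate/ingest -> scan -> XP-EHH -> sweep
calling -> haplotypes -> network -> trait association, with a JSON manifest.

All randomness flows from a single master seed (stage substreams are
derived from it), every intermediate artifact is written to the output
directory, and the manifest records the config hash, per-artifact
checksums, warning counters and wall-clock time per stage, so a rerun
with the same config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from soysweep import haplotypes as hap
from soysweep import sweeps as sw
from soysweep.diversity import ScanConfig, pi_ratio, windowed_fst, windowed_pi
from soysweep.simulate import SimulationConfig, simulate_domestication, write_cohort
from soysweep.traits import associate_groups
from soysweep.vcf_io import (
    read_bed,
    read_population_map,
    read_trait_table,
    read_vcf,
    write_stat_track,
)
from soysweep.xpehh import normalize_xpehh, xpehh_scan, xpehh_window_track


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    When ``simulation`` is set the cohort is generated and written first;
    otherwise ``vcf``, ``popmap`` and (for the association stage)
    ``traits`` must point to existing files.  ``region`` is the 0-based
    half-open gene region used for haplotyping.
    """

    outdir: str = "soysweep_run"
    vcf: str | None = None
    popmap: str | None = None
    traits: str | None = None
    annotations: str | None = None
    simulation: SimulationConfig | None = None
    scan: ScanConfig = field(default_factory=ScanConfig)
    chrom_length_bp: int | None = None
    region: tuple[int, int] | None = None
    maf_min: float = 0.01
    hap_mode: str = "chromosome"
    group_method: str = "target_k"
    group_k_or_cutoff: int = 3
    min_support: int = 3
    merge_gap_bp: int = 0
    support_mode: str = "region"
    alpha: float = 0.05
    subpop_filter: str | None = None
    run_associate: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if "scan" in raw and raw["scan"] is not None:
            raw["scan"] = ScanConfig(**raw["scan"])
        if "region" in raw and raw["region"] is not None:
            raw["region"] = tuple(raw["region"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("simulation", "scan")
        }
        d["simulation"] = self.simulation.to_dict() if self.simulation else None
        d["scan"] = dict(self.scan.__dict__)
        return d

    def science_hashable(self) -> dict:
        """The config without the output location (for the manifest hash)."""
        d = self.to_jsonable()
        d.pop("outdir", None)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_json = json.dumps(config.science_hashable(), sort_keys=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "stages": [],
        "artifacts": {},
        "warnings": {},
    }
    manifest_path = outdir / "manifest.json"

    def finish_stage(name: str, t0: float, artifacts: dict[str, Path]) -> None:
        manifest["stages"].append({"name": name, "seconds": round(time.time() - t0, 3)})
        for label, p in artifacts.items():
            manifest["artifacts"][label] = {"path": str(p), "sha256": _sha256(Path(p))}

    def flush() -> None:
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    try:
        # stage 1: simulate (or register existing inputs)
        t0 = time.time()
        stage = "simulate"
        if config.simulation is not None:
            sim_cfg = config.simulation
            if sim_cfg.seed != config.seed:
                sim_cfg.seed = config.seed
            cohort = simulate_domestication(sim_cfg)
            paths = write_cohort(cohort, outdir / "cohort")
            vcf_path = paths["vcf"]
            popmap_path = paths["popmap"]
            traits_path = paths["traits"]
            finish_stage(stage, t0, {f"cohort_{k}": p for k, p in paths.items()})
        else:
            if not config.vcf or not config.popmap:
                raise ValueError("need vcf and popmap when no simulation is configured")
            vcf_path, popmap_path = Path(config.vcf), Path(config.popmap)
            traits_path = Path(config.traits) if config.traits else None
            finish_stage(stage, t0, {})

        # stage 2: read inputs
        t0 = time.time()
        stage = "read"
        matrix = read_vcf(vcf_path)
        pop_map = read_population_map(popmap_path)
        annotations = read_bed(config.annotations) if config.annotations else None
        rows = {
            p: matrix.chromosome_rows([a for a in matrix.accessions if pop_map.get(a) == p])
            for p in ("S", "L", "C")
        }
        chrom_length = config.chrom_length_bp
        if chrom_length is None and config.simulation is not None:
            chrom_length = config.simulation.chrom_length_bp
        if chrom_length is None:
            chrom_length = int(matrix.positions[-1])
        finish_stage(stage, t0, {})

        # stage 3: diversity scan
        t0 = time.time()
        stage = "scan"
        pi_s = windowed_pi(matrix, rows["S"], config.scan, chrom_length, stat_name="pi_S")
        pi_c = windowed_pi(matrix, rows["C"], config.scan, chrom_length, stat_name="pi_C")
        ratio = pi_ratio(pi_s, pi_c)
        fst = windowed_fst(matrix, rows["S"], rows["C"], config.scan, chrom_length)
        artifacts = {}
        for track in (pi_s, pi_c, ratio, fst):
            p = outdir / f"track_{track.stat_name}.tsv"
            write_stat_track(track, p)
            artifacts[f"track_{track.stat_name}"] = p
        finish_stage(stage, t0, artifacts)

        # stage 4: XP-EHH (cultivar vs wild)
        t0 = time.time()
        stage = "xpehh"
        xp = xpehh_scan(matrix, rows["C"], rows["S"], config.scan)
        xp.norm = normalize_xpehh(xp.raw)
        xp_track = xpehh_window_track(xp, config.scan, chrom_length)
        site_path = outdir / "xpehh_sites.tsv"
        with open(site_path, "w") as fh:
            fh.write("chrom\tpos\traw_xpehh\tnorm_xpehh\n")
            for pos, raw, norm in zip(xp.positions, xp.raw, xp.norm):
                fh.write(
                    f"{xp.chrom}\t{pos}\t"
                    f"{'NA' if np.isnan(raw) else f'{raw:.6f}'}\t"
                    f"{'NA' if np.isnan(norm) else f'{norm:.6f}'}\n"
                )
        track_path = outdir / "track_xpehh_norm.tsv"
        write_stat_track(xp_track, track_path)
        manifest["warnings"]["xpehh_edge_clips"] = xp.edge_clips
        finish_stage(stage, t0, {"xpehh_sites": site_path, "track_xpehh_norm": track_path})

        # stage 5: sweep calling
        t0 = time.time()
        stage = "callsweeps"
        tracks = {"pi_ratio": ratio, "fst": fst, "xpehh_norm": xp_track}
        thresholds = {
            name: sw.empirical_threshold(track, config.scan.top_quantile)
            for name, track in tracks.items()
        }
        regions = sw.call_sweeps(
            tracks,
            thresholds,
            min_support=config.min_support,
            merge_gap_bp=config.merge_gap_bp,
            support_mode=config.support_mode,
        )
        if annotations is not None:
            regions = sw.annotate_regions(regions, annotations)
        regions_path = outdir / "sweep_regions.tsv"
        sw.write_regions(regions, regions_path)
        finish_stage(stage, t0, {"sweep_regions": regions_path})

        # stage 6: haplotypes + network + groups + frequencies
        t0 = time.time()
        stage = "haplotype_network"
        if config.region is not None:
            region = config.region
        elif regions:
            widest = max(regions, key=lambda r: r.end - r.start0)
            region = (widest.start0, widest.end)
        else:
            region = (0, chrom_length)
        gene = hap.extract_gene_variants(matrix, region, config.maf_min)
        table = hap.collapse_haplotypes(gene, pop_map, mode=config.hap_mode)
        table_path = outdir / "haplotype_table.tsv"
        hap.write_haplotype_table(table, table_path)
        manifest["warnings"]["haplotype_excluded"] = dict(table.excluded)
        artifacts = {"haplotype_table": table_path}
        assignment = None
        if len(table.table) >= 2:
            network = hap.mj_network(table)
            net_path = outdir / "haplotype_network.graphml"
            hap.write_network(network, net_path)
            artifacts["haplotype_network"] = net_path
            try:
                assignment = hap.assign_major_groups(
                    network, config.group_method, config.group_k_or_cutoff
                )
            except ValueError:
                assignment = hap.assign_major_groups(network, "edge_cut", 2)
            freqs = hap.haplotype_frequencies(table, assignment)
            freq_path = outdir / "haplotype_frequencies.tsv"
            freqs.hap_freqs.to_csv(freq_path, sep="\t", float_format="%.6f")
            artifacts["haplotype_frequencies"] = freq_path
            if freqs.group_tests is not None:
                gt_path = outdir / "group_frequency_tests.tsv"
                freqs.group_tests.to_csv(gt_path, sep="\t", float_format="%.6g")
                artifacts["group_frequency_tests"] = gt_path
        finish_stage(stage, t0, artifacts)

        # stage 7: trait association
        t0 = time.time()
        stage = "associate"
        artifacts = {}
        if config.run_associate:
            if traits_path is None or not Path(traits_path).exists():
                raise FileNotFoundError(f"trait table not found: {traits_path}")
            traits = read_trait_table(traits_path)
            if assignment is None:
                raise ValueError("no haplotype groups available for association")
            labels, excluded = hap.accession_group_labels(gene, assignment)
            manifest["warnings"]["association_excluded"] = dict(excluded)
            result = associate_groups(
                traits,
                labels,
                alpha=config.alpha,
                subpop_filter=config.subpop_filter,
                pop_map=pop_map,
            )
            assoc_path = outdir / "trait_association.tsv"
            result.summary.to_csv(assoc_path, sep="\t", index=False, float_format="%.6g")
            pair_path = outdir / "trait_pairwise_tests.tsv"
            result.pairwise.to_csv(pair_path, sep="\t", index=False, float_format="%.6g")
            artifacts = {"trait_association": assoc_path, "trait_pairwise_tests": pair_path}
        finish_stage(stage, t0, artifacts)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        flush()
        raise StageError(stage, exc) from exc

    flush()
    return manifest
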