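"""End-to-end pipeline driver: simulate -> qc -> map -> scan -> synteny ->
anchor -> report.

Every stage writes its outputs into the run directory together with a
manifest entry (input/output SHA-256 hashes, parameters, stage seed).  All
randomness flows from the single configured seed through named per-stage
substreams; no stage reads the wall clock.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from cavemap import anchoring, io, linkage, marker_qc, qtl, synteny
from cavemap.simcross import SimConfig, simulate_cross, simulate_hit_tables

log = logging.getLogger("cavemap")

ALL_STAGES = ("simulate", "qc", "map", "scan", "synteny", "anchor", "report")


@dataclass
class PipelineConfig:
    out_dir: str = "cavemap_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: SimConfig = field(default_factory=lambda: SimConfig(
        n_chromosomes=5, markers_per_chromosome=24, chrom_length_cM=60.0,
        trait_locus=(1, 30.0)))
    chi2_cutoff: float = 50.0
    grouping_lod_max: int = 50
    rounds: int = 3
    scan_methods: tuple[str, ...] = ("mr", "em", "hk")
    scan_step_cM: float = 1.0
    scan_epsilon: float = 0.001
    n_permutations: int = 1000
    alphas: tuple[float, ...] = (0.05, 0.001)
    evalue_cutoff: float = 10.0
    flank_width: int = 2000
    decoy_rate: float = 0.3
    conserved_fraction: float = 0.6
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**{k: (tuple(v) if k == "trait_locus" and v else v)
                           for k, v in raw.pop("sim", {}).items()})
        for key in ("stages", "scan_methods", "alphas"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=sim, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the artifact directory.

    Stage failures abort with the stage name and offending input.  Re-running
    with the same configuration and seed reproduces every output byte for
    byte.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {stage: int(s.generate_state(1)[0] % (2**31))
             for stage, s in zip(
                 ALL_STAGES, np.random.SeedSequence(config.seed).spawn(len(ALL_STAGES)))}
    manifest: dict = {"seed": config.seed, "stages": {}}
    artifacts: dict[str, Path] = {}

    def record(stage, params, inputs, outputs):
        manifest["stages"][stage] = {
            "seed": seeds[stage],
            "params": params,
            "inputs": {str(p.name): _sha256(p) for p in inputs},
            "outputs": {str(p.name): _sha256(p) for p in outputs},
        }

    def path(name):
        return out / name

    for stage in config.stages:
        try:
            if stage == "simulate":
                sim_cfg = SimConfig(**{**asdict(config.sim),
                                       "seed": seeds["simulate"]})
                truemap, panelset, phen = simulate_cross(sim_cfg)
                io.write_genotypes(panelset, path("genotypes.tsv"))
                io.write_phenotypes(phen, path("phenotypes.tsv"))
                io.write_scaffold_table(truemap.markers, path("scaffolds.tsv"))
                truth = truemap.markers.reset_index()
                io._write_tsv(truth, path("truth_markers.tsv"))
                tables, hit_truth = simulate_hit_tables(
                    truemap, config.decoy_rate, config.conserved_fraction,
                    seed=seeds["simulate"] + 1)
                for route, table in tables.items():
                    io.write_hit_table(table, path(f"hits_{route}.tsv"))
                lengths = {f"Dchr{k}": sim_cfg.chrom_length_cM * 0.6
                           for k in range(1, sim_cfg.n_chromosomes + 1)}
                io.write_chrom_lengths(lengths, path("chrom_lengths.tsv"))
                record(stage, {"sim": asdict(sim_cfg)}, [],
                       [path(n) for n in ("genotypes.tsv", "phenotypes.tsv",
                                          "scaffolds.tsv", "hits_direct.tsv",
                                          "hits_genomic.tsv",
                                          "hits_transcriptomic.tsv",
                                          "chrom_lengths.tsv")])
            elif stage == "qc":
                panelset = io.read_genotypes(path("genotypes.tsv"))
                coded, report = marker_qc.screen_and_code(
                    panelset, chi2_cutoff=config.chi2_cutoff)
                frame = marker_qc.coded_frame(coded, list(panelset.f2.columns))
                io.write_coded(frame, path("coded.tsv"))
                io.write_json(report.as_dict(), path("qc_report.json"))
                record(stage, {"chi2_cutoff": config.chi2_cutoff},
                       [path("genotypes.tsv")],
                       [path("coded.tsv"), path("qc_report.json")])
            elif stage == "map":
                frame = io.read_coded(path("coded.tsv"))
                ids, codes, _ = io.coded_codes_matrix(frame)
                if not ids:
                    raise PipelineError(stage, "no retained markers in coded.tsv")
                protocol = linkage.MapProtocol(
                    grouping_lod_max=config.grouping_lod_max,
                    rounds=config.rounds)
                gmap, audit = linkage.build_map(ids, codes, protocol)
                io.write_map(gmap, path("map.tsv"))
                io.write_json(audit, path("map_audit.json"))
                io.write_json(linkage.map_summary(gmap), path("map_summary.json"))
                record(stage, {"rounds": config.rounds},
                       [path("coded.tsv")],
                       [path("map.tsv"), path("map_audit.json"),
                        path("map_summary.json")])
            elif stage == "scan":
                frame = io.read_coded(path("coded.tsv"))
                gmap = io.map_from_frame(io.read_map(path("map.tsv")))
                phen = io.read_phenotypes(path("phenotypes.tsv"))
                ids, codes, individuals = io.coded_codes_matrix(frame)
                import pandas as pd

                codes_df = pd.DataFrame(codes, index=ids, columns=individuals)
                grid = qtl.genotype_probs(gmap, codes_df,
                                          step_cM=config.scan_step_cM,
                                          epsilon=config.scan_epsilon)
                result = qtl.scanone(phen.loc[individuals].to_numpy(), grid,
                                     methods=config.scan_methods)
                thresholds = {}
                for method in config.scan_methods:
                    thresholds[method] = qtl.permutation_threshold(
                        phen.loc[individuals].to_numpy(), grid, method,
                        n_perm=config.n_permutations, alphas=config.alphas,
                        seed=seeds["scan"])
                result.thresholds = thresholds
                io._write_tsv(result.frame(), path("scan.tsv"))
                io.write_json({m: {str(a): v for a, v in t.items()}
                               for m, t in thresholds.items()},
                              path("scan_thresholds.json"))
                peak_pos, peak_lod = result.peak(config.scan_methods[0])
                peak_codes = codes_df.loc[peak_pos["marker"]] \
                    if peak_pos["marker"] else None
                if peak_codes is not None:
                    eff = qtl.effect_summary(peak_codes.to_numpy(),
                                             phen.loc[individuals].to_numpy())
                    io._write_tsv(eff.reset_index(), path("effects.tsv"))
                record(stage, {"methods": list(config.scan_methods),
                               "n_perm": config.n_permutations},
                       [path("coded.tsv"), path("map.tsv"),
                        path("phenotypes.tsv")],
                       [path("scan.tsv"), path("scan_thresholds.json")])
            elif stage == "synteny":
                mapf = io.read_map(path("map.tsv"))
                marker_group = dict(zip(mapf.marker, mapf.group))
                tables = {}
                results = {}
                for route in ("direct", "genomic", "transcriptomic"):
                    table = synteny.parse_hit_table(
                        path(f"hits_{route}.tsv"),
                        evalue_cutoff=config.evalue_cutoff, route=route)
                    collapsed = synteny.collapse_per_target(table)
                    tables[route] = collapsed
                    results[route] = synteny.resolve_route(collapsed,
                                                           marker_group)
                combined = synteny.combine_routes(results, tables, marker_group)
                links = synteny.links_frame(combined, mapf)
                io._write_tsv(links, path("links.tsv"))
                lengths = io.read_chrom_lengths(path("chrom_lengths.tsv"))
                report = synteny.synteny_stats(links, lengths)
                report["category_counts"] = {
                    route: synteny.category_counts(results[route],
                                                   len(mapf)).n.to_dict()
                    for route in results}
                report["combined_categories"] = synteny.category_counts(
                    combined, len(mapf)).n.to_dict()
                io.write_json(report, path("synteny_report.json"))
                oxford = synteny.oxford_matrix(links)
                oxford.to_csv(path("oxford.tsv"), sep="\t")
                io.write_circos_links(synteny.circos_lines(links),
                                      path("circos_links.txt"))
                record(stage, {"evalue_cutoff": config.evalue_cutoff},
                       [path(f"hits_{r}.tsv") for r in
                        ("direct", "genomic", "transcriptomic")],
                       [path("links.tsv"), path("synteny_report.json"),
                        path("oxford.tsv"), path("circos_links.txt")])
            elif stage == "anchor":
                mapf = io.read_map(path("map.tsv"))
                scaffolds = io.read_scaffold_table(path("scaffolds.tsv"))
                anchors, summary = anchoring.anchor_scaffolds(mapf, scaffolds)
                io._write_tsv(anchoring.anchors_frame(anchors),
                              path("anchors.tsv"))
                io.write_json(summary, path("anchor_summary.json"))
                record(stage, {}, [path("map.tsv"), path("scaffolds.tsv")],
                       [path("anchors.tsv"), path("anchor_summary.json")])
            elif stage == "report":
                report = {}
                for name in ("qc_report.json", "map_summary.json",
                             "scan_thresholds.json", "synteny_report.json",
                             "anchor_summary.json"):
                    p = path(name)
                    if p.exists():
                        import json

                        report[name.removesuffix(".json")] = json.loads(
                            p.read_text())
                io.write_json(report, path("report.json"))
                record(stage, {}, [], [path("report.json")])
            else:
                raise PipelineError(stage, f"unknown stage")
            log.info("stage %s complete", stage)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    io.write_json(manifest, out / "manifest.json")
    return out
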