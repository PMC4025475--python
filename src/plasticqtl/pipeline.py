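"""Config-driven end-to-end runs.

Stages: load or simulate a cross -> filter markers -> estimate the genetic
map -> single-environment scans (1000 permutations) -> GEI scans over all
environment pairs (100 permutations) -> candidate collation -> pair /
anchored / triple interaction scans (10,000 permutations) -> summaries.
Defaults mirror the analysis protocol the package implements; every stage
draws its seed from an independent stream spawned from the master seed, so
adding or removing one scan never perturbs another.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import platform
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cross_data import (
    CrossDataset,
    filter_markers,
    read_cross,
    write_genotypes,
    write_phenotypes,
    write_results,
)
from .epistasis_scan import (
    build_candidates,
    resolve_markers,
    scan_anchored,
    scan_pairs,
    scan_triples,
)
from .errors import ConfigError, InsufficientDataError
from .gei_scan import scan_gei
from .linkage_core import estimate_map, genotype_probabilities
from .qtl_scan import call_peaks, permute_threshold
from .summaries import broad_heritability, env_correlations
from .synthetic_cross import PlantedEffect, SimulationConfig, simulate_cross

logger = logging.getLogger(__name__)


@dataclass
class ScanSettings:
    step_cm: float = 2.0
    n_perm_single: int = 1000
    n_perm_gei: int = 100
    n_perm_interaction: int = 10000
    p_max: float = 0.2              # reporting threshold for all call tables
    candidate_gei_p: float = 0.5    # GEI candidate inclusion threshold


@dataclass
class FilterSettings:
    max_missing: float = 1.0
    min_maf: float = 0.0
    snp_only: bool = False


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    output_dir: str = "plasticqtl_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    genotype_path: str | None = None
    phenotype_path: str | None = None
    map_path: str | None = None
    filters: FilterSettings = field(default_factory=FilterSettings)
    scans: ScanSettings = field(default_factory=ScanSettings)
    anchors: list[str] | str = "auto"   # locus strings / marker ids, or "auto"
    n_auto_anchors: int = 3             # per parameter when anchors == "auto"
    environments: list[str] | None = None   # optional subset
    parameters: list[str] | None = None

    def __post_init__(self):
        if self.simulation is None and (self.genotype_path is None
                                        or self.phenotype_path is None):
            raise ConfigError("config needs either a simulation section or "
                              "genotype+phenotype paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        for key in ("output_dir", "seed", "anchors", "n_auto_anchors",
                    "environments", "parameters"):
            if key in raw:
                kwargs[key] = raw[key]
        inputs = raw.get("inputs", {})
        kwargs["genotype_path"] = inputs.get("genotypes")
        kwargs["phenotype_path"] = inputs.get("phenotypes")
        kwargs["map_path"] = inputs.get("map")
        if "filters" in raw:
            kwargs["filters"] = FilterSettings(**raw["filters"])
        if "scans" in raw:
            kwargs["scans"] = ScanSettings(**raw["scans"])
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            effects = [
                PlantedEffect(e["kind"],
                              tuple((int(c), float(p)) for c, p in e["loci"]),
                              {str(k): float(v) for k, v in e["effects"].items()},
                              e.get("parameter", "doubling_time"))
                for e in sim.pop("effects", [])
            ]
            n_chrom = sim.pop("n_chromosomes", 16)
            length = sim.pop("chromosome_length_cm", 100.0)
            n_mark = sim.pop("markers_per_chromosome", 30)
            sim["chromosomes"] = [(c + 1, length, n_mark) for c in range(n_chrom)]
            sim["planted_effects"] = effects
            sim.setdefault("seed", raw.get("seed", 0))
            kwargs["simulation"] = SimulationConfig(**sim)
        return cls(**kwargs)


@dataclass
class RunResult:
    output_dir: Path
    dataset: CrossDataset
    single_calls: list
    gei_calls: list
    pair_calls: list
    anchored_calls: list
    triple_calls: list
    manifest: dict


def _stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    # stable per-stage stream: stage name hashed (stably) into the spawn key
    key = zlib.crc32(stage.encode())
    return np.random.SeedSequence(entropy=int(master), spawn_key=(key,))


def auto_anchors(single_calls: list, n_per_parameter: int = 3) -> list[str]:
    """Large-effect anchors: the top-LOD distinct markers per parameter."""
    out: list[str] = []
    by_param: dict[str, list] = {}
    for c in single_calls:
        by_param.setdefault(c.parameter, []).append(c)
    for param in sorted(by_param):
        calls = sorted(by_param[param], key=lambda c: -c.lod)
        seen = set()
        for c in calls:
            if c.marker_id in seen or c.marker_id in out:
                continue
            seen.add(c.marker_id)
            out.append(c.marker_id)
            if len(seen) >= n_per_parameter:
                break
    return out


def run_pipeline(cfg: PipelineConfig) -> RunResult:
    """Execute the full analysis and write result tables + a run manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"plasticqtl_version": __version__,
                      "python": platform.python_version(),
                      "seed": cfg.seed, "stages": {}}

    def _stage(name: str, **info):
        manifest["stages"][name] = info
        logger.info("stage %s: %s", name, info)

    # ---- load or simulate ------------------------------------------------
    if cfg.simulation is not None:
        d = simulate_cross(cfg.simulation)
        write_genotypes(d.genotypes, out / "genotypes.tsv", out / "map_physical.tsv")
        write_phenotypes(d.phenotypes, out / "phenotypes.tsv")
        _stage("simulate", n_segregants=d.genotypes.n_segregants,
               n_markers=d.genotypes.n_markers)
    else:
        d = read_cross(cfg.genotype_path, cfg.phenotype_path, cfg.map_path)
        _stage("read", n_segregants=d.genotypes.n_segregants,
               n_markers=d.genotypes.n_markers)

    envs = cfg.environments or d.phenotypes.environments
    params = cfg.parameters or d.phenotypes.parameters

    # ---- filter ----------------------------------------------------------
    f = cfg.filters
    g = filter_markers(d.genotypes, f.max_missing, f.min_maf, f.snp_only)
    if g.n_markers != d.genotypes.n_markers:
        d = CrossDataset(g, d.phenotypes)
    _stage("filter", n_markers=d.genotypes.n_markers)

    # ---- map -------------------------------------------------------------
    gmap = estimate_map(d.genotypes)
    gmap.write(out / "map.tsv")
    _stage("map", total_cm=round(gmap.total_length_cm(), 2))

    s = cfg.scans
    probs_grid = genotype_probabilities(d.genotypes, gmap, s.step_cm)
    probs_markers = genotype_probabilities(d.genotypes, gmap, 0.0)

    # ---- single-environment scans ---------------------------------------
    single_results, single_calls = [], []
    for param, env in itertools.product(params, envs):
        try:
            res = permute_threshold(
                d, gmap, param, env, n_perm=s.n_perm_single,
                seed=_stage_seed(cfg.seed, f"single:{param}:{env}"),
                step_cm=s.step_cm, probs=probs_grid)
        except InsufficientDataError as exc:
            logger.warning("single scan %s/%s skipped: %s", param, env, exc)
            continue
        single_results.append(res)
        single_calls.extend(call_peaks(res, d, p_max=s.p_max))
    write_results(single_calls, out / "single_calls.tsv")
    _stage("scan_single", n_scans=len(single_results), n_calls=len(single_calls))

    # ---- GEI scans -------------------------------------------------------
    gei_results, gei_calls = [], []
    single_loci_by_param_env = {
        (c.parameter, c.environment, c.marker_id) for c in single_calls
    }
    for param in params:
        for env_a, env_b in itertools.combinations(envs, 2):
            try:
                res, calls = scan_gei(
                    d, gmap, param, env_a, env_b, step_cm=s.step_cm,
                    n_perm=s.n_perm_gei,
                    seed=_stage_seed(cfg.seed, f"gei:{param}:{env_a}:{env_b}"),
                    p_max=s.p_max, probs=probs_grid)
            except InsufficientDataError as exc:
                logger.warning("GEI scan %s/%s-%s skipped: %s",
                               param, env_a, env_b, exc)
                continue
            for c in calls:
                c.novel = not any(
                    (param, e, c.marker_id) in single_loci_by_param_env
                    for e in (env_a, env_b)
                )
            gei_results.append(res)
            gei_calls.extend(calls)
    write_results(gei_calls, out / "gei_calls.tsv")
    _stage("scan_gei", n_scans=len(gei_results), n_calls=len(gei_calls))

    # ---- candidate collation --------------------------------------------
    cands = build_candidates(single_results, gei_results,
                             gei_p_max=s.candidate_gei_p)
    cands.table.to_csv(out / "candidates.tsv", sep="\t", index=False)
    _stage("candidates", n_candidates=len(cands))

    # ---- interaction scans ----------------------------------------------
    pair_calls, anchored_calls, triple_calls = [], [], []
    if cfg.anchors == "auto":
        anchors = auto_anchors(single_calls, cfg.n_auto_anchors)
    else:
        anchors = resolve_markers(d, list(cfg.anchors)) if cfg.anchors else []
    manifest["anchors"] = anchors

    if len(cands) >= 2:
        for param, env in itertools.product(params, envs):
            common = dict(n_perm=s.n_perm_interaction, p_max=s.p_max,
                          probs=probs_markers)
            pcs = scan_pairs(d, gmap, cands, param, env,
                             seed=_stage_seed(cfg.seed, f"pairs:{param}:{env}"),
                             **common)
            pair_calls.extend(pcs)
            if anchors:
                anchored_calls.extend(scan_anchored(
                    d, gmap, anchors, cands, param, env,
                    seed=_stage_seed(cfg.seed, f"anchored:{param}:{env}"),
                    **common))
                if pcs:
                    triple_calls.extend(scan_triples(
                        d, gmap, anchors, pcs, param, env,
                        seed=_stage_seed(cfg.seed, f"triples:{param}:{env}"),
                        **common))
    write_results(pair_calls, out / "pair_calls.tsv")
    write_results(anchored_calls, out / "anchored_calls.tsv")
    write_results(triple_calls, out / "triple_calls.tsv")
    _stage("scan_interactions", n_pairs=len(pair_calls),
           n_anchored=len(anchored_calls), n_triples=len(triple_calls))

    # ---- summaries -------------------------------------------------------
    for param in params:
        corr = env_correlations(d.phenotypes, param)
        corr.r.to_csv(out / f"correlations_{param}.tsv", sep="\t")
    h2_rows = []
    if d.phenotypes.n_replicates >= 2:
        for param, env in itertools.product(params, envs):
            try:
                h = broad_heritability(d.phenotypes, param, env)
            except InsufficientDataError:
                continue
            h2_rows.append(dataclasses.asdict(h))
    pd.DataFrame(h2_rows).to_csv(out / "heritability.tsv", sep="\t", index=False)
    _stage("summaries", n_heritability=len(h2_rows))

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunResult(out, d, single_calls, gei_calls, pair_calls,
                     anchored_calls, triple_calls, manifest)
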