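"""Seeded simulation studies: type-I calibration, planted-effect recovery,
and simulator physics checks.

These studies quantify how the scan machinery behaves under the panel the
simulator emulates (144 segregants, 16 chromosomes x 100 cM with 30 markers
each, replicate-free phenotypes).  They are the package's own evidence for
calibration and power and are reused by the acceptance script.

Effect-size conventions (see :func:`plasticqtl.effect_for_variance`):
a "25% variance" additive QTL is the study's large-effect scale (LOD around
9-10 at n = 144); interactions at 15% (two-locus) and 12% (three-way) of
phenotypic variance are the planted epistatic scales.
"""

from __future__ import annotations

import logging

import numpy as np

from .epistasis_scan import candidate_set_from_markers, scan_pairs, scan_triples
from .gei_scan import scan_gei
from .linkage_core import estimate_map, haldane_r
from .qtl_scan import permute_threshold
from .synthetic_cross import (
    PlantedEffect,
    SimulationConfig,
    effect_for_variance,
    simulate_cross,
    simulate_genotypes,
)

logger = logging.getLogger(__name__)

#: cM-per-bp of the synthetic physical map (used to convert peak distances)
_KB_PER_CM = 2.5


def _seed(master_seed: int, *path: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(path))


def _int_seed(master_seed: int, *path: int) -> int:
    return int(_seed(master_seed, *path).generate_state(1)[0] % (2 ** 31))


def _planted_marker_bp(d, chrom: int, pos_cm: float) -> int:
    """bp of the marker the planted effect actually landed on."""
    sub = d.genotypes.markers[d.genotypes.markers["chromosome"] == chrom]
    cm = sub["position_cm"].to_numpy()
    return int(sub["position_bp"].iloc[int(np.argmin(np.abs(cm - pos_cm)))])


def _dist_cm(bp_a: int, bp_b: int) -> float:
    return abs(bp_a - bp_b) / (_KB_PER_CM * 1000.0)


def type1_calibration(
    n_datasets: int = 400,
    n_perm: int = 200,
    master_seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Fraction of global-null datasets whose best single-scan peak has p <= alpha.

    Each dataset is a no-effect cross (pure Gaussian phenotype); the reported
    rate should sit near alpha for a calibrated genome-wide-max permutation test.
    """
    hits = 0
    for rep in range(n_datasets):
        cfg = SimulationConfig(seed=_int_seed(master_seed, 1, rep),
                               environments=["glucose"], parameters=["doubling_time"])
        d = simulate_cross(cfg)
        gmap = estimate_map(d.genotypes)
        res = permute_threshold(d, gmap, "doubling_time", "glucose",
                                n_perm=n_perm, seed=_seed(master_seed, 2, rep))
        if res.p_value(res.max_lod) <= alpha:
            hits += 1
    return {"rate": hits / n_datasets, "n": n_datasets, "alpha": alpha,
            "n_perm": n_perm}


def additive_recovery(
    n_reps: int = 200,
    variance_fraction: float = 0.25,
    n_perm: int = 200,
    master_seed: int = 0,
    max_dist_cm: float = 5.0,
    alpha: float = 0.05,
) -> dict:
    """Recovery of one planted additive QTL: genome-best peak within
    ``max_dist_cm`` of the planted marker and p <= alpha."""
    effect = effect_for_variance(variance_fraction, 1.0)
    chrom, pos_cm = 5, 50.0
    hits = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(
            environments=["glucose"], parameters=["doubling_time"],
            planted_effects=[PlantedEffect("additive", ((chrom, pos_cm),),
                                           {"glucose": effect})],
            seed=_int_seed(master_seed, 3, rep))
        d = simulate_cross(cfg)
        bp_true = _planted_marker_bp(d, chrom, pos_cm)
        gmap = estimate_map(d.genotypes)
        res = permute_threshold(d, gmap, "doubling_time", "glucose",
                                n_perm=n_perm, seed=_seed(master_seed, 4, rep))
        peaks = res.chromosome_peaks()
        best = peaks.loc[peaks["lod"].idxmax()]
        if (best["chromosome"] == chrom
                and _dist_cm(int(best["position_bp"]), bp_true) <= max_dist_cm
                and res.p_value(best["lod"]) <= alpha):
            hits += 1
    return {"rate": hits / n_reps, "n": n_reps, "effect": effect,
            "variance_fraction": variance_fraction}


def crossover_recovery(
    n_reps: int = 200,
    variance_fraction: float = 0.25,
    n_perm: int = 100,
    master_seed: int = 0,
    max_dist_cm: float = 5.0,
    alpha: float = 0.05,
) -> dict:
    """Recovery + classification of a planted crossover GxE QTL.

    The locus has equal-magnitude, opposite-signed allele effects in the two
    environments (each sized to ``variance_fraction`` of single-environment
    variance).  Success: a GEI call at p <= alpha within ``max_dist_cm`` of
    the planted marker, classified 'crossover'.
    """
    effect = effect_for_variance(variance_fraction, 1.0)
    chrom, pos_cm = 9, 40.0
    env_a, env_b = "glucose", "ethanol"
    hits = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(
            environments=[env_a, env_b], parameters=["doubling_time"],
            planted_effects=[PlantedEffect("gxe_crossover", ((chrom, pos_cm),),
                                           {env_a: effect, env_b: -effect})],
            seed=_int_seed(master_seed, 5, rep))
        d = simulate_cross(cfg)
        bp_true = _planted_marker_bp(d, chrom, pos_cm)
        gmap = estimate_map(d.genotypes)
        _, calls = scan_gei(d, gmap, "doubling_time", env_a, env_b,
                            n_perm=n_perm, seed=_seed(master_seed, 6, rep),
                            p_max=alpha)
        ok = [c for c in calls
              if c.chromosome == chrom
              and _dist_cm(c.position_bp, bp_true) <= max_dist_cm
              and c.gei_class == "crossover"]
        if ok:
            hits += 1
    return {"rate": hits / n_reps, "n": n_reps, "effect": effect}


def _decoy_candidates(d, gmap, exclude_bp: set[int]):
    """One mid-chromosome marker per chromosome, emulating collated scan peaks."""
    ids = []
    for chrom in sorted(d.genotypes.markers["chromosome"].unique()):
        sub = d.genotypes.markers[d.genotypes.markers["chromosome"] == chrom]
        cm = sub["position_cm"].to_numpy()
        j = int(np.argmin(np.abs(cm - 50.0)))
        if int(sub["position_bp"].iloc[j]) not in exclude_bp:
            ids.append(sub["id"].iloc[j])
    return ids


def pair_recovery(
    n_reps: int = 200,
    interaction_fraction: float = 0.15,
    n_perm: int = 200,
    master_seed: int = 0,
    p_max: float = 0.2,
) -> dict:
    """Recovery of a planted two-locus interaction by the candidate-pair scan.

    The interaction term explains ``interaction_fraction`` of phenotypic
    variance with no main effects; the candidate set holds the two planted
    markers plus one decoy marker per chromosome (as collated candidate sets
    do).  Success: the planted pair called at p <= p_max under the set-max
    permutation null.
    """
    eff = effect_for_variance(interaction_fraction, 1.0, order=2)
    loci = ((3, 30.0), (8, 70.0))
    hits = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(
            environments=["sucrose"], parameters=["maxOD"],
            planted_effects=[PlantedEffect("epistatic2", loci, {"sucrose": eff},
                                           parameter="maxOD")],
            seed=_int_seed(master_seed, 7, rep))
        d = simulate_cross(cfg)
        gmap = estimate_map(d.genotypes)
        planted_ids, planted_bp = [], set()
        for chrom, pos_cm in loci:
            bp = _planted_marker_bp(d, chrom, pos_cm)
            planted_bp.add(bp)
            sub = d.genotypes.markers
            planted_ids.append(
                sub.loc[(sub["chromosome"] == chrom) & (sub["position_bp"] == bp),
                        "id"].iloc[0])
        cand_ids = planted_ids + _decoy_candidates(d, gmap, planted_bp)
        cands = candidate_set_from_markers(d, gmap, cand_ids)
        calls = scan_pairs(d, gmap, cands, "maxOD", "sucrose", n_perm=n_perm,
                           seed=_seed(master_seed, 8, rep), p_max=p_max)
        want = frozenset(planted_ids)
        if any(frozenset(m for _, _, m in c.loci) == want for c in calls):
            hits += 1
    return {"rate": hits / n_reps, "n": n_reps, "effect": eff}


def triple_recovery(
    n_reps: int = 200,
    threeway_fraction: float = 0.12,
    pair_fraction: float = 0.15,
    n_perm: int = 200,
    master_seed: int = 0,
    p_max: float = 0.2,
) -> dict:
    """Recovery of a planted three-way term by the anchored triple scan.

    Architecture: a two-locus interaction (``pair_fraction`` of variance)
    between loci 2 and 3 plus a pure three-way term (``threeway_fraction``)
    over loci 1-3; locus 1 plays the large-effect anchor.  The pair scan runs
    first on planted + decoy candidates, its calls feed the triple scan.
    Success: the planted triple called at p <= p_max.
    """
    e3 = effect_for_variance(threeway_fraction, 1.0, order=3)
    e2 = effect_for_variance(pair_fraction, 1.0, order=2)
    anchor_locus = (2, 60.0)
    pair_loci = ((3, 30.0), (8, 70.0))
    hits = 0
    for rep in range(n_reps):
        cfg = SimulationConfig(
            environments=["sucrose"], parameters=["maxOD"],
            planted_effects=[
                PlantedEffect("epistatic2", pair_loci, {"sucrose": e2},
                              parameter="maxOD"),
                PlantedEffect("epistatic3", (anchor_locus,) + pair_loci,
                              {"sucrose": e3}, parameter="maxOD"),
            ],
            seed=_int_seed(master_seed, 9, rep))
        d = simulate_cross(cfg)
        gmap = estimate_map(d.genotypes)
        sub = d.genotypes.markers

        def _mid(chrom, pos_cm):
            bp = _planted_marker_bp(d, chrom, pos_cm)
            return sub.loc[(sub["chromosome"] == chrom)
                           & (sub["position_bp"] == bp), "id"].iloc[0], bp

        anchor_id, anchor_bp = _mid(*anchor_locus)
        pair_ids, pair_bp = [], set()
        for chrom, pos_cm in pair_loci:
            mid, bp = _mid(chrom, pos_cm)
            pair_ids.append(mid)
            pair_bp.add(bp)
        cand_ids = pair_ids + _decoy_candidates(d, gmap, pair_bp | {anchor_bp})
        cands = candidate_set_from_markers(d, gmap, cand_ids)
        pair_calls = scan_pairs(d, gmap, cands, "maxOD", "sucrose",
                                n_perm=n_perm, seed=_seed(master_seed, 10, rep),
                                p_max=0.5)
        if not pair_calls:
            continue
        triples = scan_triples(d, gmap, [anchor_id], pair_calls, "maxOD",
                               "sucrose", n_perm=n_perm,
                               seed=_seed(master_seed, 11, rep), p_max=p_max)
        want = frozenset([anchor_id] + pair_ids)
        if any(frozenset(m for _, _, m in c.loci) == want for c in triples):
            hits += 1
    return {"rate": hits / n_reps, "n": n_reps,
            "threeway_effect": e3, "pair_effect": e2}


def simulator_physics(
    n_segregants: int = 10000,
    master_seed: int = 0,
    distances_cm: tuple[float, ...] = (5.0, 10.0, 25.0, 50.0, 80.0),
) -> dict:
    """Empirical recombination fractions vs Haldane predictions; allele freqs.

    Simulates two-marker chromosomes at each distance with ``n_segregants``
    meioses and reports the largest deviation in binomial-SE units, plus the
    largest allele-frequency deviation from 0.5 in SE units on a standard
    panel layout.
    """
    chroms = [(i + 1, d, 2) for i, d in enumerate(distances_cm)]
    cfg = SimulationConfig(n_segregants=n_segregants, chromosomes=chroms,
                           environments=["glucose"], parameters=["doubling_time"],
                           seed=_int_seed(master_seed, 12))
    g = simulate_genotypes(cfg)
    max_z = 0.0
    rows = []
    for chrom, dist, _ in chroms:
        idx = np.flatnonzero(g.markers["chromosome"].to_numpy() == chrom)
        a, b = g.calls[:, idx[0]], g.calls[:, idx[1]]
        r_emp = float(np.mean(a != b))
        r_th = float(haldane_r(dist))
        se = np.sqrt(r_th * (1 - r_th) / n_segregants)
        z = abs(r_emp - r_th) / se
        max_z = max(max_z, z)
        rows.append({"distance_cm": dist, "r_theory": r_th, "r_empirical": r_emp,
                     "z": z})
    freqs = g.calls.mean(axis=0)
    se_f = 0.5 / np.sqrt(n_segregants)
    max_freq_z = float(np.max(np.abs(freqs - 0.5)) / se_f)
    return {"max_rf_z": float(max_z), "max_allele_freq_z": max_freq_z,
            "n": n_segregants, "per_distance": rows}
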