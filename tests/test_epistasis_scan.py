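"""Two- and three-locus interaction statistics, candidate collation and the
set-restricted permutation scans."""

import numpy as np
import pytest
import statsmodels.api as sm

from plasticqtl import (
    PlantedEffect,
    SimulationConfig,
    build_candidates,
    candidate_set_from_markers,
    estimate_map,
    permute_threshold,
    scan_anchored,
    scan_gei,
    scan_pairs,
    scan_triples,
    simulate_cross,
    three_qtl_lod,
    two_qtl_lod,
)
from plasticqtl.epistasis_scan import three_qtl_lod_vs_additive
from plasticqtl.errors import ConfigError, InsufficientDataError


def oracle_nested(y, X_base, X_full):
    rss0 = sm.OLS(y, X_base).fit().ssr
    rss1 = sm.OLS(y, X_full).fit().ssr
    return 0.5 * len(y) * np.log10(rss0 / rss1)


def _rand_pair_instance(rng, n=40):
    x1 = (rng.random(n) < 0.5).astype(float)
    x2 = (rng.random(n) < 0.5).astype(float)
    y = rng.normal(size=n) + rng.normal() * x1 * x2
    return y, x1, x2


class TestTwoQtlLod:
    def test_purely_additive_phenotype_gives_zero(self):
        rng = np.random.default_rng(0)
        n = 50
        x1 = (rng.random(n) < 0.5).astype(float)
        x2 = (rng.random(n) < 0.5).astype(float)
        y = 1.5 * x1 - 0.7 * x2 + 2.0
        assert two_qtl_lod(y, x1, x2) == pytest.approx(0.0, abs=1e-9)

    def test_xor_pattern_matches_oracle(self):
        # balanced 2x2 classes with means (0,1,1,0): the additive model cannot
        # absorb the XOR contrast, the product term absorbs it completely
        x1 = np.array([0, 0, 1, 1, 0, 0, 1, 1], dtype=float)
        x2 = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        rng = np.random.default_rng(1)
        y = (x1 != x2).astype(float) + 0.05 * rng.normal(size=8)
        ones = np.ones(8)
        base = np.column_stack([ones, x1, x2])
        full = np.column_stack([base, x1 * x2])
        expect = oracle_nested(y, base, full)
        assert two_qtl_lod(y, x1, x2) == pytest.approx(expect, abs=1e-9)
        assert expect > 2

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            y, x1, x2 = _rand_pair_instance(rng)
            ones = np.ones(len(y))
            base = np.column_stack([ones, x1, x2])
            full = np.column_stack([base, x1 * x2])
            assert two_qtl_lod(y, x1, x2) == pytest.approx(
                oracle_nested(y, base, full), abs=1e-9)

    def test_symmetric_in_loci(self):
        rng = np.random.default_rng(3)
        y, x1, x2 = _rand_pair_instance(rng)
        assert two_qtl_lod(y, x1, x2) == pytest.approx(two_qtl_lod(y, x2, x1),
                                                       abs=1e-12)

    def test_affine_recoding_invariance(self):
        # 0/1 vs +/-0.5 coding spans the same model space
        rng = np.random.default_rng(4)
        y, x1, x2 = _rand_pair_instance(rng)
        assert two_qtl_lod(y, x1, x2) == pytest.approx(
            two_qtl_lod(y, x1 - 0.5, x2 - 0.5), abs=1e-9)

    def test_collinear_pair_rejected(self):
        rng = np.random.default_rng(5)
        x1 = (rng.random(30) < 0.5).astype(float)
        with pytest.raises(ValueError):
            two_qtl_lod(rng.normal(size=30), x1, x1.copy())

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            two_qtl_lod([1, 2, 3], [0, 1, 0], [1, 0, 1])


class TestThreeQtlLod:
    def test_pairwise_only_structure_gives_zero(self):
        rng = np.random.default_rng(6)
        n = 64
        x1, x2, x3 = ((rng.random(n) < 0.5).astype(float) for _ in range(3))
        y = x1 * x2 - 0.5 * x2 * x3 + x1 - x3
        assert three_qtl_lod(y, x1, x2, x3) == pytest.approx(0.0, abs=1e-9)

    def test_balanced_three_way_contrast_matches_oracle(self):
        # balanced 2x2x2 design, means follow the pure three-way contrast
        grid = np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).reshape(3, -1).T
        reps = 4
        X = np.repeat(grid, reps, axis=0).astype(float)
        x1, x2, x3 = X[:, 0], X[:, 1], X[:, 2]
        contrast = (2 * x1 - 1) * (2 * x2 - 1) * (2 * x3 - 1)
        rng = np.random.default_rng(7)
        y = contrast + 0.1 * rng.normal(size=len(contrast))
        ones = np.ones(len(y))
        base = np.column_stack([ones, x1, x2, x3, x1 * x2, x1 * x3, x2 * x3])
        full = np.column_stack([base, x1 * x2 * x3])
        expect = oracle_nested(y, base, full)
        assert three_qtl_lod(y, x1, x2, x3) == pytest.approx(expect, abs=1e-9)
        assert expect > 5

    def test_symmetric_under_locus_permutation(self):
        rng = np.random.default_rng(8)
        n = 60
        x1, x2, x3 = ((rng.random(n) < 0.5).astype(float) for _ in range(3))
        y = rng.normal(size=n) + x1 * x2 * x3
        ref = three_qtl_lod(y, x1, x2, x3)
        assert three_qtl_lod(y, x3, x1, x2) == pytest.approx(ref, abs=1e-9)
        assert three_qtl_lod(y, x2, x3, x1) == pytest.approx(ref, abs=1e-9)

    def test_full_vs_null_additivity_chain(self):
        # LOD(full vs additive) = LOD(pairwise vs additive) + LOD(full vs pairwise)
        rng = np.random.default_rng(9)
        n = 60
        x1, x2, x3 = ((rng.random(n) < 0.5).astype(float) for _ in range(3))
        y = rng.normal(size=n) + x1 * x2 + 0.8 * x1 * x2 * x3
        ones = np.ones(n)
        add = np.column_stack([ones, x1, x2, x3])
        pair = np.column_stack([add, x1 * x2, x1 * x3, x2 * x3])
        lod_pair_vs_add = oracle_nested(y, add, pair)
        total = three_qtl_lod_vs_additive(y, x1, x2, x3)
        assert total == pytest.approx(
            lod_pair_vs_add + three_qtl_lod(y, x1, x2, x3), abs=1e-9)


def _planted_cross(seed, effects, envs=("glucose",), params=("doubling_time",)):
    cfg = SimulationConfig(
        chromosomes=[(c, 100.0, 15) for c in range(1, 7)],
        environments=list(envs), parameters=list(params),
        planted_effects=effects, seed=seed)
    return simulate_cross(cfg), cfg


def _marker_at(d, chrom, cm):
    sub = d.genotypes.markers[d.genotypes.markers["chromosome"] == chrom]
    j = int(np.argmin(np.abs(sub["position_cm"].to_numpy() - cm)))
    return sub["id"].iloc[j]


class TestBuildCandidates:
    def test_mixed_size_planted_qtl_all_collated(self):
        d, _ = _planted_cross(30, [
            PlantedEffect("additive", ((1, 50.0),), {"glucose": 1.2}),
            PlantedEffect("additive", ((3, 20.0),), {"glucose": 0.6}),
            PlantedEffect("additive", ((5, 80.0),), {"glucose": 0.8}),
        ])
        gmap = estimate_map(d.genotypes)
        res = permute_threshold(d, gmap, "doubling_time", "glucose",
                                n_perm=200, seed=3)
        cands = build_candidates([res], [])
        # each planted chromosome's peak marker must be collated, and each
        # peak must localize near its planted position
        peaks = res.chromosome_peaks().set_index("chromosome")
        for chrom, cm in ((1, 50.0), (3, 20.0), (5, 80.0)):
            peak = peaks.loc[chrom]
            assert peak["marker_id"] in cands.marker_ids
            assert abs(peak["position_cm"] - cm) < 15.0
        assert (cands.table["source"] == "single_env").all()

    def test_subthreshold_peak_still_included_when_above_null_floor(self):
        d, _ = _planted_cross(31, [
            PlantedEffect("additive", ((2, 40.0),), {"glucose": 0.55}),
        ])
        gmap = estimate_map(d.genotypes)
        res = permute_threshold(d, gmap, "doubling_time", "glucose",
                                n_perm=200, seed=4)
        peak = res.chromosome_peaks().set_index("chromosome").loc[2]
        floor = res.perm_null.min()
        cands = build_candidates([res], [])
        assert (peak["marker_id"] in cands.marker_ids) == (peak["lod"] > floor)

    def test_gei_candidates_tagged(self):
        d, _ = _planted_cross(32, [
            PlantedEffect("gxe_crossover", ((4, 60.0),),
                          {"glucose": 1.0, "ethanol": -1.0}),
        ], envs=("glucose", "ethanol"))
        gmap = estimate_map(d.genotypes)
        res, _ = scan_gei(d, gmap, "doubling_time", "glucose", "ethanol",
                          n_perm=100, seed=5)
        cands = build_candidates([], [res])
        row = cands.table.set_index("marker_id").loc[_marker_at(d, 4, 60.0)]
        assert row["source"] == "gei"


class TestSetScans:
    def _pair_setup(self, seed):
        eff = 4 * np.sqrt(0.15 / 0.85)
        d, _ = _planted_cross(seed, [
            PlantedEffect("epistatic2", ((2, 30.0), (5, 70.0)), {"glucose": eff}),
        ])
        gmap = estimate_map(d.genotypes)
        planted = [_marker_at(d, 2, 30.0), _marker_at(d, 5, 70.0)]
        decoys = [_marker_at(d, c, 50.0) for c in (1, 3, 4, 6)]
        cands = candidate_set_from_markers(d, gmap, planted + decoys)
        return d, gmap, cands, planted

    def test_planted_pair_recovered(self):
        d, gmap, cands, planted = self._pair_setup(40)
        calls = scan_pairs(d, gmap, cands, "doubling_time", "glucose",
                           n_perm=200, seed=1, p_max=0.2)
        found = {frozenset(m for _, _, m in c.loci) for c in calls}
        assert frozenset(planted) in found
        call = next(c for c in calls
                    if frozenset(m for _, _, m in c.loci) == frozenset(planted))
        assert not call.anchored
        assert set(call.class_means) == {"SS", "SY", "YS", "YY"}
        assert sum(v[2] for v in call.class_means.values()) == 144

    def test_linked_pair_excluded_by_guard(self):
        d, gmap, _, _ = self._pair_setup(41)
        near = [_marker_at(d, 1, 40.0), _marker_at(d, 1, 50.0)]
        cands = candidate_set_from_markers(d, gmap, near)
        calls = scan_pairs(d, gmap, cands, "doubling_time", "glucose",
                           n_perm=50, seed=2, p_max=1.0)
        assert calls == []

    def test_anchored_scan_restricted_and_flagged(self):
        d, gmap, cands, planted = self._pair_setup(42)
        calls = scan_anchored(d, gmap, [planted[0]], cands, "doubling_time",
                              "glucose", n_perm=200, seed=3, p_max=0.2)
        assert calls
        for c in calls:
            assert c.anchored
            assert planted[0] in {m for _, _, m in c.loci}

    def test_missing_anchor_is_config_error(self):
        d, gmap, cands, _ = self._pair_setup(43)
        with pytest.raises(ConfigError, match="nope"):
            scan_anchored(d, gmap, ["nope"], cands, "doubling_time", "glucose")

    def test_triples_empty_without_pairs(self):
        d, gmap, _, planted = self._pair_setup(44)
        assert scan_triples(d, gmap, [planted[0]], [], "doubling_time",
                            "glucose") == []

    def test_planted_three_way_recovered(self):
        e3 = 8 * np.sqrt(0.12 / 0.88)
        e2 = 4 * np.sqrt(0.15 / 0.85)
        d, _ = _planted_cross(45, [
            PlantedEffect("epistatic2", ((2, 30.0), (5, 70.0)), {"glucose": e2}),
            PlantedEffect("epistatic3", ((1, 60.0), (2, 30.0), (5, 70.0)),
                          {"glucose": e3}),
        ])
        gmap = estimate_map(d.genotypes)
        anchor = _marker_at(d, 1, 60.0)
        planted = [_marker_at(d, 2, 30.0), _marker_at(d, 5, 70.0)]
        cands = candidate_set_from_markers(
            d, gmap, planted + [_marker_at(d, c, 50.0) for c in (3, 4, 6)])
        pairs = scan_pairs(d, gmap, cands, "doubling_time", "glucose",
                           n_perm=200, seed=4, p_max=0.5)
        triples = scan_triples(d, gmap, [anchor], pairs, "doubling_time",
                               "glucose", n_perm=200, seed=5, p_max=0.2)
        found = {frozenset(m for _, _, m in c.loci) for c in triples}
        assert frozenset([anchor] + planted) in found
        call = next(iter(triples))
        assert call.anchor == anchor
        assert len(call.class_means) == 8
        assert call.secondary_lod is not None

    def test_set_max_null_is_conservative_under_global_null(self):
        # no planted effects: the set-max p-value at alpha should reject at
        # most ~alpha of the time (30 null datasets, alpha = 0.2)
        alpha, hits, n_data = 0.2, 0, 30
        for rep in range(n_data):
            d, _ = _planted_cross(600 + rep, [])
            gmap = estimate_map(d.genotypes)
            cands = candidate_set_from_markers(
                d, gmap, [_marker_at(d, c, 50.0) for c in range(1, 7)])
            calls = scan_pairs(d, gmap, cands, "doubling_time", "glucose",
                               n_perm=100, seed=rep, p_max=alpha)
            hits += bool(calls)
        se = np.sqrt(alpha * (1 - alpha) / n_data)
        assert hits / n_data <= alpha + 3 * se
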