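"""Gene-environment interaction LOD, scan and reaction-norm classification."""

import numpy as np
import pytest
import statsmodels.api as sm

from plasticqtl import (
    CrossDataset,
    PhenotypeTable,
    PlantedEffect,
    SimulationConfig,
    classify_gei,
    estimate_map,
    gei_lod,
    scan_gei,
    simulate_cross,
)
from plasticqtl.gei_scan import AlleleSummary, GeiCall
from plasticqtl.regression import gei_scan_lods


def oracle_gei_lods(ya, yb, x):
    """Independent stacked-OLS computation of (interaction, additive, full)."""
    n = len(ya)
    y = np.concatenate([ya, yb])
    E = np.concatenate([np.zeros(n), np.ones(n)])
    xx = np.concatenate([x, x])
    null = sm.OLS(y, sm.add_constant(E)).fit().ssr
    add = sm.OLS(y, sm.add_constant(np.column_stack([E, xx]))).fit().ssr
    full = sm.OLS(y, sm.add_constant(np.column_stack([E, xx, xx * E]))).fit().ssr
    N = 2 * n
    return (0.5 * N * np.log10(add / full),
            0.5 * N * np.log10(null / add),
            0.5 * N * np.log10(null / full))


def _rand_instance(rng, n=40):
    x = (rng.random(n) < 0.5).astype(float)
    ya = rng.normal(size=n) + rng.normal() * x
    yb = rng.normal(size=n) + rng.normal() * x
    return ya, yb, x


class TestGeiLod:
    def test_matches_stacked_ols_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            ya, yb, x = _rand_instance(rng)
            expect, _, _ = oracle_gei_lods(ya, yb, x)
            assert gei_lod(ya, yb, x) == pytest.approx(expect, abs=1e-9)

    def test_symmetric_in_environments(self):
        rng = np.random.default_rng(1)
        ya, yb, x = _rand_instance(rng)
        assert gei_lod(ya, yb, x) == pytest.approx(gei_lod(yb, ya, x), abs=1e-9)

    def test_identical_environments_zero(self):
        rng = np.random.default_rng(2)
        ya, _, x = _rand_instance(rng)
        assert gei_lod(ya, ya.copy(), x) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_crossover_large_lod_no_additive_signal(self):
        rng = np.random.default_rng(3)
        n = 60
        x = (rng.random(n) < 0.5).astype(float)
        noise = 0.01 * rng.normal(size=n)
        ya = x + noise
        yb = -x + noise
        lod_int, lod_add, lod_full = gei_scan_lods(ya, yb, x[:, None])
        assert lod_int[0] > 20
        # additive genotype term explains (nearly) nothing
        assert lod_add[0] < 0.5
        assert lod_full[0] == pytest.approx(lod_add[0] + lod_int[0], abs=1e-9)

    def test_zero_when_interaction_coefficient_zero(self):
        # construct yb so the interaction contrast (yb - ya) is orthogonal to
        # the centered genotype: the fitted interaction coefficient is 0
        rng = np.random.default_rng(4)
        n = 30
        x = (rng.random(n) < 0.5).astype(float)
        ya = rng.normal(size=n)
        yb = rng.normal(size=n)
        xc = x - x.mean()
        diff = yb - ya
        yb = yb - (diff @ xc) / (xc @ xc) * xc
        assert gei_lod(ya, yb, x) == pytest.approx(0.0, abs=1e-9)

    def test_nested_additivity_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ya, yb, x = _rand_instance(rng, n=25)
            lod_int, lod_add, lod_full = gei_scan_lods(ya, yb, x[:, None])
            o_int, o_add, o_full = oracle_gei_lods(ya, yb, x)
            assert lod_full[0] == pytest.approx(lod_add[0] + lod_int[0], abs=1e-9)
            assert lod_full[0] == pytest.approx(o_full, abs=1e-9)
            assert lod_add[0] == pytest.approx(o_add, abs=1e-9)


def _summary(mean_s, se_s, mean_y, se_y, n=30):
    return AlleleSummary(mean_s, se_s, n, mean_y, se_y, n)


def _call(means, envs=("lactose", "ethanol")):
    return GeiCall(2, 708904, "mk", envs, 5.0, 6.0, 0.01, "unclassified",
                   means, "maxOD")


class TestClassifyGei:
    def test_crossover_sign_flip_with_separation(self):
        call = _call({"lactose": _summary(2.0, 0.1, 0.0, 0.1),
                      "ethanol": _summary(0.0, 0.1, 2.0, 0.1)})
        assert classify_gei(call) == "crossover"

    def test_scale_same_sign_different_magnitude(self):
        call = _call({"lactose": _summary(3.0, 0.1, 0.0, 0.1),
                      "ethanol": _summary(1.0, 0.1, 0.0, 0.1)})
        assert classify_gei(call) == "scale"

    def test_environment_specific_separation_in_one(self):
        call = _call({"lactose": _summary(2.0, 0.1, 0.0, 0.1),
                      "ethanol": _summary(0.05, 0.1, 0.0, 0.1)})
        assert classify_gei(call) == "environment_specific"

    def test_unclassified_when_no_separation(self):
        call = _call({"lactose": _summary(0.1, 0.2, 0.0, 0.2),
                      "ethanol": _summary(0.1, 0.2, 0.0, 0.2)})
        assert classify_gei(call) == "unclassified"

    def test_unclassified_when_se_missing(self):
        call = _call({"lactose": _summary(2.0, float("nan"), 0.0, 0.1),
                      "ethanol": _summary(2.0, 0.1, 0.0, 0.1)})
        assert classify_gei(call) == "unclassified"

    def test_equal_magnitudes_fall_to_scale(self):
        call = _call({"lactose": _summary(2.0, 0.1, 0.0, 0.1),
                      "ethanol": _summary(2.0, 0.1, 0.0, 0.1)})
        assert classify_gei(call) == "scale"


class TestScanGei:
    def test_identical_environment_data_flat_profile(self, small_cross):
        d, _ = small_cross
        # copy glucose values into ethanol: no interaction anywhere
        p = d.phenotypes
        p.values[:, 1] = p.values[:, 0]
        d2 = CrossDataset(d.genotypes, p)
        gmap = estimate_map(d2.genotypes)
        res, calls = scan_gei(d2, gmap, "doubling_time", "glucose", "ethanol",
                              n_perm=20, seed=0, p_max=0.05)
        assert res.max_lod == pytest.approx(0.0, abs=1e-9)
        assert calls == []

    def test_planted_crossover_recovered_and_classified(self):
        cfg = SimulationConfig(
            chromosomes=[(c, 100.0, 20) for c in range(1, 5)],
            environments=["glucose", "ethanol"], parameters=["doubling_time"],
            planted_effects=[PlantedEffect("gxe_crossover", ((3, 50.0),),
                                           {"glucose": 1.2, "ethanol": -1.2})],
            seed=21)
        d = simulate_cross(cfg)
        gmap = estimate_map(d.genotypes)
        res, calls = scan_gei(d, gmap, "doubling_time", "glucose", "ethanol",
                              n_perm=100, seed=1, p_max=0.05)
        hit = [c for c in calls if c.chromosome == 3]
        assert len(hit) == 1
        assert hit[0].gei_class == "crossover"
        assert hit[0].interaction_lod == res.max_lod

    def test_scale_architecture_rarely_called_crossover(self):
        # same-sign effects of different magnitude: the crossover label should
        # essentially never appear (misclassification bound < 5%; 30 replicates)
        crossover = 0
        for rep in range(30):
            cfg = SimulationConfig(
                chromosomes=[(c, 100.0, 15) for c in range(1, 3)],
                environments=["lactose", "glucose"], parameters=["doubling_time"],
                planted_effects=[PlantedEffect("gxe_scale", ((1, 50.0),),
                                               {"lactose": 1.6, "glucose": 0.6})],
                seed=500 + rep)
            d = simulate_cross(cfg)
            gmap = estimate_map(d.genotypes)
            _, calls = scan_gei(d, gmap, "doubling_time", "lactose", "glucose",
                                n_perm=50, seed=rep, p_max=0.2)
            crossover += any(c.gei_class == "crossover" for c in calls
                             if c.chromosome == 1)
        assert crossover <= 1
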