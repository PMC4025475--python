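"""Simulator physics (Haldane recombination, allele frequencies) and the
planted-effect generative model."""

import numpy as np
import pytest

from plasticqtl import (
    CrossDataset,
    PlantedEffect,
    SimulationConfig,
    effect_for_variance,
    haldane_r,
    mask_data,
    simulate_cross,
    simulate_genotypes,
    simulate_phenotypes,
)
from plasticqtl.errors import ConfigError

from conftest import make_genotypes, make_phenotypes


def _two_marker_cfg(dist_cm, n, seed=0):
    return SimulationConfig(n_segregants=n, chromosomes=[(1, dist_cm, 2)],
                            environments=["glucose"], parameters=["doubling_time"],
                            seed=seed)


class TestMeiosis:
    def test_zero_distance_no_recombinants(self):
        g = simulate_genotypes(_two_marker_cfg(1e-9, 500))
        assert np.all(g.calls[:, 0] == g.calls[:, 1])

    @pytest.mark.parametrize("dist", [10.0, 50.0])
    def test_recombinant_fraction_matches_haldane(self, dist):
        n = 10_000
        g = simulate_genotypes(_two_marker_cfg(dist, n, seed=int(dist)))
        r_emp = np.mean(g.calls[:, 0] != g.calls[:, 1])
        r_th = haldane_r(dist)
        se = np.sqrt(r_th * (1 - r_th) / n)
        assert abs(r_emp - r_th) < 3 * se

    def test_unlinked_markers_half(self):
        cfg = SimulationConfig(n_segregants=10_000,
                               chromosomes=[(1, 50.0, 1), (2, 50.0, 1)],
                               environments=["glucose"],
                               parameters=["doubling_time"], seed=4)
        g = simulate_genotypes(cfg)
        r = np.mean(g.calls[:, 0] != g.calls[:, 1])
        assert abs(r - 0.5) < 3 * 0.5 / np.sqrt(10_000)

    def test_allele_frequency_half(self):
        cfg = SimulationConfig(n_segregants=10_000,
                               chromosomes=[(1, 100.0, 10)],
                               environments=["glucose"],
                               parameters=["doubling_time"], seed=11)
        g = simulate_genotypes(cfg)
        freqs = g.calls.mean(axis=0)
        assert np.all(np.abs(freqs - 0.5) < 3 * 0.5 / np.sqrt(10_000))


class TestPhenotypeModel:
    def test_zero_effects_reduce_to_baseline(self):
        cfg = SimulationConfig(n_segregants=50, chromosomes=[(1, 50.0, 5)],
                               environments=["glucose"], parameters=["maxOD"],
                               baseline={("glucose", "maxOD"): 3.5},
                               noise_sd=1e-12, seed=1)
        d = simulate_cross(cfg)
        np.testing.assert_allclose(d.phenotypes.get("maxOD", "glucose"), 3.5,
                                   atol=1e-9)

    def test_additive_effect_equals_allele_mean_difference(self):
        cfg = SimulationConfig(n_segregants=200, chromosomes=[(1, 50.0, 5)],
                               environments=["glucose"], parameters=["doubling_time"],
                               planted_effects=[PlantedEffect(
                                   "additive", ((1, 25.0),), {"glucose": 0.8})],
                               noise_sd=1e-12, seed=2)
        d = simulate_cross(cfg)
        y = d.phenotypes.get("doubling_time", "glucose")
        sub = d.genotypes.markers[d.genotypes.markers["chromosome"] == 1]
        j = int(np.argmin(np.abs(sub["position_cm"].to_numpy() - 25.0)))
        calls = d.genotypes.calls[:, j]
        diff = y[calls == 1].mean() - y[calls == 0].mean()
        assert diff == pytest.approx(0.8, abs=1e-9)

    def test_pure_epistasis_has_no_marginal_effect_in_balanced_design(self):
        # balanced 2x2 classes built by hand; effect e on the product term only
        reps = 16
        x1 = np.repeat([1.0, 1.0, 0.0, 0.0], reps)
        x2 = np.repeat([1.0, 0.0, 1.0, 0.0], reps)
        g = make_genotypes(np.column_stack([x1, x2]), chrom=[1, 2])
        g.markers["position_cm"] = [0.0, 0.0]
        cfg = SimulationConfig(n_segregants=len(x1),
                               chromosomes=[(1, 1.0, 1), (2, 1.0, 1)],
                               environments=["sucrose"], parameters=["maxOD"],
                               planted_effects=[PlantedEffect(
                                   "epistatic2", ((1, 0.0), (2, 0.0)),
                                   {"sucrose": 2.0}, parameter="maxOD")],
                               noise_sd=1e-12, seed=3)
        p = simulate_phenotypes(g, cfg)
        y = p.get("maxOD", "sucrose")
        # group means follow the XOR pattern +/- e/4
        for a in (0, 1):
            for b in (0, 1):
                m = y[(x1 == a) & (x2 == b)].mean()
                assert m == pytest.approx(2.0 * (a - 0.5) * (b - 0.5), abs=1e-9)
        # marginal (single-locus) regression slope is exactly zero
        assert y[x1 == 1].mean() - y[x1 == 0].mean() == pytest.approx(0.0, abs=1e-9)

    def test_variance_decomposition(self):
        # independent loci: total variance ~= sum effect^2/4^k + noise^2
        a, e2, sd = 1.0, 1.2, 0.7
        cfg = SimulationConfig(
            n_segregants=20_000,
            chromosomes=[(1, 50.0, 3), (2, 50.0, 3), (3, 50.0, 3)],
            environments=["glucose"], parameters=["doubling_time"],
            planted_effects=[
                PlantedEffect("additive", ((1, 25.0),), {"glucose": a}),
                PlantedEffect("epistatic2", ((2, 25.0), (3, 25.0)),
                              {"glucose": e2}),
            ],
            noise_sd=sd, seed=6)
        d = simulate_cross(cfg)
        y = d.phenotypes.get("doubling_time", "glucose")
        expect = a ** 2 / 4 + e2 ** 2 / 16 + sd ** 2
        assert np.var(y) == pytest.approx(expect, rel=0.05)

    def test_locus_outside_map_is_config_error(self):
        cfg = SimulationConfig(chromosomes=[(1, 50.0, 5)],
                               environments=["glucose"],
                               parameters=["doubling_time"],
                               planted_effects=[PlantedEffect(
                                   "additive", ((1, 80.0),), {"glucose": 1.0})],
                               seed=0)
        with pytest.raises(ConfigError):
            simulate_cross(cfg)

    def test_crossover_effect_requires_opposite_signs(self):
        with pytest.raises(ConfigError):
            PlantedEffect("gxe_crossover", ((1, 10.0),), {"a": 1.0, "b": 2.0})

    def test_effect_for_variance_inverts(self):
        # a 25% QTL against unit noise: effect^2/4 / (effect^2/4 + 1) = 0.25
        eff = effect_for_variance(0.25, 1.0)
        v = eff ** 2 / 4
        assert v / (v + 1.0) == pytest.approx(0.25, abs=1e-12)
        e3 = effect_for_variance(0.12, 1.0, order=3)
        v3 = e3 ** 2 / 64
        assert v3 / (v3 + 1.0) == pytest.approx(0.12, abs=1e-12)


class TestMasking:
    def _dataset(self, seed=0, missing_rate=0.0):
        cfg = SimulationConfig(n_segregants=100, chromosomes=[(1, 100.0, 100)],
                               environments=["glucose"], parameters=["doubling_time"],
                               missing_rate=missing_rate, seed=seed)
        g = simulate_genotypes(cfg)
        return CrossDataset(g, simulate_phenotypes(g, cfg)), cfg

    def test_zero_rate_identity(self):
        d, cfg = self._dataset()
        assert mask_data(d, cfg) is d

    def test_missing_count_within_binomial_error(self):
        d, cfg = self._dataset(seed=8, missing_rate=0.1)
        masked = mask_data(d, cfg)
        n_missing = int(np.isnan(masked.genotypes.calls).sum())
        n_calls = masked.genotypes.calls.size
        se = np.sqrt(n_calls * 0.1 * 0.9)
        assert abs(n_missing - 0.1 * n_calls) < 3 * se

    def test_same_seed_same_mask(self):
        d, cfg = self._dataset(seed=8, missing_rate=0.1)
        m1 = mask_data(d, cfg)
        m2 = mask_data(d, cfg)
        np.testing.assert_array_equal(np.isnan(m1.genotypes.calls),
                                      np.isnan(m2.genotypes.calls))

    def test_phenotypes_untouched(self):
        d, cfg = self._dataset(seed=8, missing_rate=0.3)
        masked = mask_data(d, cfg)
        np.testing.assert_array_equal(masked.phenotypes.values,
                                      d.phenotypes.values)


class TestReproducibility:
    def test_identical_seed_bit_identical_dataset(self):
        cfg = SimulationConfig(n_segregants=60, chromosomes=[(1, 80.0, 15)],
                               environments=["glucose", "ethanol"],
                               parameters=["doubling_time"],
                               missing_rate=0.05, seed=77)
        d1, d2 = simulate_cross(cfg), simulate_cross(cfg)
        np.testing.assert_array_equal(d1.genotypes.calls, d2.genotypes.calls)
        np.testing.assert_array_equal(d1.phenotypes.values, d2.phenotypes.values)
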