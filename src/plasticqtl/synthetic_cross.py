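"""Simulator of haploid biparental crosses with planted genetic architectures.

Meiosis follows a no-interference crossover process consistent with the
Haldane map function: between loci d cM apart the recombination fraction is
(1 - exp(-d/50))/2, and every marker segregates S/Y at expected frequency
0.5.  Phenotypes are built from a linear model:

    y(seg, env, param) = mu(env, param)
                         + sum additive / GxE terms   effect_e * c(locus)
                         + sum epistatic terms        effect_e * prod c(loci)
                         + Normal(0, noise_sd)        per replicate

with the genotype coded c = +0.5 (S) / -0.5 (Y), so a planted "effect" is
exactly the between-allele mean difference for a single-locus term.  Scans
are invariant to affine genotype recoding, so the 0/1 probability scale used
by the mapping code sees the same signal.

The default panel emulates the study system: 144 segregants, 16 chromosomes
of 100 cM with 30 markers each, 7 carbon-source environments, 2 growth
parameters.  Marker density is configurable up to tens of thousands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cross_data import (
    ENVIRONMENTS,
    PARAMETERS,
    CrossDataset,
    GenotypeMatrix,
    PhenotypeTable,
)
from .errors import ConfigError
from .linkage_core import haldane_r

EFFECT_KINDS = ("additive", "gxe_scale", "gxe_specific", "gxe_crossover",
                "epistatic2", "epistatic3")


@dataclass(frozen=True)
class PlantedEffect:
    """One planted term of the generative model.

    ``loci`` are (chromosome, position_cm) pairs (1 locus for additive/GxE
    kinds, 2 for epistatic2, 3 for epistatic3); ``effects`` maps environment
    -> effect size in phenotype units (environments not listed get 0).
    """

    kind: str
    loci: tuple[tuple[int, float], ...]
    effects: dict[str, float]
    parameter: str = "doubling_time"

    def __post_init__(self):
        if self.kind not in EFFECT_KINDS:
            raise ConfigError(f"unknown effect kind {self.kind!r}")
        arity = {"additive": 1, "gxe_scale": 1, "gxe_specific": 1,
                 "gxe_crossover": 1, "epistatic2": 2, "epistatic3": 3}[self.kind]
        if len(self.loci) != arity:
            raise ConfigError(f"{self.kind} effect needs {arity} locus/loci, "
                              f"got {len(self.loci)}")
        nz = [v for v in self.effects.values() if v != 0]
        if self.kind == "gxe_crossover":
            if len(nz) < 2 or max(np.sign(nz)) == min(np.sign(nz)):
                raise ConfigError("gxe_crossover needs opposite-signed effects "
                                  "in (at least) two environments")
        if self.kind == "gxe_specific":
            if len(nz) >= len(self.effects) and len(self.effects) > 1:
                raise ConfigError("gxe_specific needs a zero effect in some "
                                  "environment")


def default_chromosomes(n_chrom: int = 16, length_cm: float = 100.0,
                        n_markers: int = 30) -> list[tuple[int, float, int]]:
    return [(c + 1, length_cm, n_markers) for c in range(n_chrom)]


@dataclass
class SimulationConfig:
    """Panel layout, planted architecture, noise and missingness."""

    n_segregants: int = 144
    chromosomes: list[tuple[int, float, int]] = field(default_factory=default_chromosomes)
    environments: list[str] = field(default_factory=lambda: list(ENVIRONMENTS))
    parameters: list[str] = field(default_factory=lambda: list(PARAMETERS))
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    noise_sd: float | dict[tuple[str, str], float] = 1.0
    baseline: dict[tuple[str, str], float] = field(default_factory=dict)
    missing_rate: float = 0.0
    n_replicates: int = 1
    seed: int = 0
    #: kb per cM used to synthesize physical marker coordinates
    kb_per_cm: float = 2.5

    def __post_init__(self):
        if self.n_segregants < 1:
            raise ConfigError("n_segregants must be positive")
        for chrom, length, m in self.chromosomes:
            if length <= 0 or m < 1:
                raise ConfigError(f"bad chromosome spec {(chrom, length, m)}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        for sd in (self.noise_sd.values() if isinstance(self.noise_sd, dict)
                   else [self.noise_sd]):
            if sd <= 0:
                raise ConfigError("noise_sd must be > 0")

    def noise_for(self, environment: str, parameter: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd[(environment, parameter)])
        return float(self.noise_sd)


def _marker_frame(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict[int, np.ndarray]]:
    rows = []
    cm_by_chrom: dict[int, np.ndarray] = {}
    for chrom, length, m in cfg.chromosomes:
        cm = np.linspace(0.0, length, m)
        cm_by_chrom[chrom] = cm
        prev_bp = 0
        for k, pos in enumerate(cm):
            bp = int(round(pos * cfg.kb_per_cm * 1000)) + 1  # 1-based coordinates
            bp = max(bp, prev_bp + 1)  # physical positions strictly increasing
            prev_bp = bp
            rows.append((f"c{chrom:02d}m{k + 1:04d}", chrom, bp, pos))
    return (pd.DataFrame(rows, columns=["id", "chromosome", "position_bp",
                                        "position_cm"]),
            cm_by_chrom)


def simulate_genotypes(cfg: SimulationConfig,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Simulate the segregant genotype matrix.

    Each chromosome of each segregant is a haploid S/Y mosaic: a fair start
    allele at the left telomere, then recombination between adjacent markers
    with the Haldane probability for their cM separation (no interference).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    markers, cm_by_chrom = _marker_frame(cfg)
    n = cfg.n_segregants
    blocks = []
    for chrom, length, m in cfg.chromosomes:
        cm = cm_by_chrom[chrom]
        start = rng.integers(0, 2, size=n)
        if m > 1:
            r = haldane_r(np.diff(cm))
            recomb = rng.random((n, m - 1)) < r[None, :]
            flips = np.concatenate([start[:, None], recomb.astype(int)], axis=1)
            geno = np.cumsum(flips, axis=1) % 2
        else:
            geno = start[:, None]
        blocks.append(geno.astype(float))
    calls = np.concatenate(blocks, axis=1)
    ids = [f"seg{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(ids, markers, calls)


def _locus_column(g: GenotypeMatrix, chrom: int, pos_cm: float) -> np.ndarray:
    """Genotype at the marker nearest to (chrom, pos_cm); error if off-map."""
    sub = g.markers[g.markers["chromosome"] == chrom]
    if sub.empty:
        raise ConfigError(f"planted locus on absent chromosome {chrom}")
    cm = sub["position_cm"].to_numpy()
    if not (cm.min() - 1e-9 <= pos_cm <= cm.max() + 1e-9):
        raise ConfigError(
            f"planted locus {pos_cm} cM outside chromosome {chrom} "
            f"[{cm.min()}, {cm.max()}] cM"
        )
    j = sub.index[int(np.argmin(np.abs(cm - pos_cm)))]
    return g.calls[:, j]


def simulate_phenotypes(g: GenotypeMatrix, cfg: SimulationConfig,
                        rng: np.random.Generator | None = None) -> PhenotypeTable:
    """Build phenotypes from the planted architecture plus Gaussian noise."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n = g.n_segregants
    n_env, n_par, n_rep = len(cfg.environments), len(cfg.parameters), cfg.n_replicates
    values = np.zeros((n, n_env, n_par, n_rep))
    for ei, env in enumerate(cfg.environments):
        for pi, par in enumerate(cfg.parameters):
            mu = cfg.baseline.get((env, par), 0.0)
            signal = np.full(n, mu)
            for eff in cfg.planted_effects:
                if eff.parameter != par:
                    continue
                size = eff.effects.get(env, 0.0)
                if size == 0.0:
                    continue
                coded = np.ones(n)
                for chrom, pos_cm in eff.loci:
                    coded = coded * (_locus_column(g, chrom, pos_cm) - 0.5)
                signal = signal + size * coded
            sd = cfg.noise_for(env, par)
            values[:, ei, pi, :] = signal[:, None] + rng.normal(0.0, sd, (n, n_rep))
    return PhenotypeTable(list(g.segregant_ids), list(cfg.environments),
                          list(cfg.parameters), values)


def mask_data(d: CrossDataset, cfg: SimulationConfig,
              rng: np.random.Generator | None = None) -> CrossDataset:
    """Mask genotype calls to missing independently at ``cfg.missing_rate``.

    Phenotypes are untouched.  Seeded: the same config yields the same mask.
    """
    if cfg.missing_rate == 0.0:
        return d
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    calls = d.genotypes.calls.copy()
    mask = rng.random(calls.shape) < cfg.missing_rate
    calls[mask] = np.nan
    g = GenotypeMatrix(list(d.genotypes.segregant_ids), d.genotypes.markers, calls)
    return CrossDataset(g, d.phenotypes)


def simulate_cross(cfg: SimulationConfig) -> CrossDataset:
    """Genotypes + phenotypes + masking from one seeded config (bit-reproducible)."""
    g = simulate_genotypes(cfg)
    p = simulate_phenotypes(g, cfg)
    return mask_data(CrossDataset(g, p), cfg)


# effect-size helpers -------------------------------------------------------

def effect_for_variance(fraction: float, noise_sd: float, order: int = 1,
                        other_variance: float = 0.0) -> float:
    """Effect size whose term explains ``fraction`` of total phenotypic variance.

    With +/-0.5 coding, a planted term of order k (k independent loci) has
    variance effect^2 / 4^k.  Solves
        effect^2/4^k = fraction * (effect^2/4^k + other_variance + noise_sd^2).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    resid = other_variance + noise_sd ** 2
    v = fraction * resid / (1.0 - fraction)
    return float(2.0 ** order * np.sqrt(v))
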