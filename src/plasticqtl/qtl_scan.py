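"""Single-environment interval mapping by Haley-Knott regression.

The phenotype is regressed on the conditional probability of the S allele at
each grid position; LOD = (n/2)*log10(RSS0/RSS1) against the intercept-only
null.  Genome-wide significance comes from a permutation test in which the
phenotype vector is shuffled against the genotypes and the genome-wide
maximum LOD of each shuffle forms the null distribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross_data import CrossDataset
from .errors import InsufficientDataError
from .linkage_core import GeneticMap, GenotypeProbability, genotype_probabilities
from .naming import format_locus, parse_locus
from .regression import single_scan_lods, single_scan_perm_max

logger = logging.getLogger(__name__)

#: default pseudomarker spacing for single-environment and GEI scans
DEFAULT_STEP_CM = 2.0


def permutation_p(null: np.ndarray, observed: float) -> float:
    """p = max(k, 1)/n_perm with k = #{null >= observed} (floor at 1/n_perm)."""
    n_perm = len(null)
    k = int(np.sum(null >= observed))
    return max(k, 1) / n_perm


@dataclass
class ScanResult:
    """A per-position LOD profile with optional permutation null.

    ``grid`` is the probability grid (chromosome, position_cm, marker_id,
    position_bp, is_marker); ``lod`` aligns with it.  ``secondary_lod`` holds
    a companion profile where a scan defines one (e.g. the full-vs-null LOD
    of a GEI scan, whose primary profile is the interaction LOD).
    """

    scan_type: str
    parameter: str
    environments: tuple[str, ...]
    grid: pd.DataFrame
    lod: np.ndarray
    n_used: int
    perm_null: np.ndarray | None = None
    secondary_lod: np.ndarray | None = None

    @property
    def n_perm(self) -> int:
        return 0 if self.perm_null is None else len(self.perm_null)

    def p_value(self, lod: float) -> float:
        if self.perm_null is None:
            raise ValueError("no permutation null attached to this scan")
        return permutation_p(self.perm_null, lod)

    @property
    def max_lod(self) -> float:
        return float(np.max(self.lod)) if len(self.lod) else 0.0

    def chromosome_peaks(self) -> pd.DataFrame:
        """Per-chromosome maximum-LOD grid row (ties -> smallest bp position)."""
        rows = []
        chroms = self.grid["chromosome"].to_numpy()
        for chrom in np.unique(chroms):
            idx = np.flatnonzero(chroms == chrom)
            lods = self.lod[idx]
            best = idx[int(np.argmax(lods))]  # argmax takes first = smallest position
            rows.append({"chromosome": int(chrom), "grid_index": int(best),
                         "lod": float(self.lod[best]),
                         "marker_id": self.grid["marker_id"].iloc[best],
                         "position_bp": int(self.grid["position_bp"].iloc[best]),
                         "position_cm": float(self.grid["position_cm"].iloc[best])})
        return pd.DataFrame(rows)


@dataclass
class QtlCall:
    """A called QTL peak: locus, LOD, permutation p, allele effect."""

    chromosome: int
    position_bp: int
    marker_id: str
    lod: float
    p_value: float
    effect: float           # mean(S) - mean(Y) at the nearest marker
    effect_se: float
    variance_explained: float
    parameter: str
    environment: str

    @property
    def locus(self) -> str:
        return format_locus(self.chromosome, self.position_bp)

    def to_row(self) -> dict:
        return {
            "scan_type": "single", "parameter": self.parameter,
            "environments": self.environment, "loci": self.locus,
            "lod": self.lod, "p_value": self.p_value,
            "effect": self.effect, "effect_se": self.effect_se,
            "variance_explained": self.variance_explained,
            "detail": json.dumps({"marker_id": self.marker_id}),
        }

    @classmethod
    def from_row(cls, row: dict) -> "QtlCall":
        chrom, bp = parse_locus(row["loci"])
        detail = json.loads(row["detail"]) if row.get("detail") else {}
        return cls(chrom, bp, detail.get("marker_id", ""), float(row["lod"]),
                   float(row["p_value"]), float(row["effect"]), float(row["effect_se"]),
                   float(row["variance_explained"]), row["parameter"], row["environments"])


def hk_lod(y: np.ndarray, x: np.ndarray) -> float:
    """Haley-Knott LOD of ``y ~ mu + b*x`` against the intercept-only null.

    Missing phenotypes are dropped pairwise; needs >= 3 observations and a
    non-constant regressor.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if y.size < 3:
        raise InsufficientDataError(f"only {y.size} complete observations (need >= 3)")
    if np.ptp(x) == 0:
        raise ValueError("regressor is constant; LOD undefined")
    return float(single_scan_lods(y, x[:, None])[0])


def allele_effect(y: np.ndarray, calls: np.ndarray) -> tuple[float, float]:
    """Allele-mean difference (S - Y) and its SE from observed marker calls."""
    ok = np.isfinite(y) & np.isfinite(calls)
    ys = y[ok & (calls == 1.0)]
    yy = y[ok & (calls == 0.0)]
    if ys.size < 2 or yy.size < 2:
        return float("nan"), float("nan")
    se = float(np.sqrt(ys.var(ddof=1) / ys.size + yy.var(ddof=1) / yy.size))
    return float(ys.mean() - yy.mean()), se


def scan_one(
    d: CrossDataset,
    gmap: GeneticMap,
    parameter: str,
    environment: str,
    step_cm: float = DEFAULT_STEP_CM,
    probs: GenotypeProbability | None = None,
) -> ScanResult:
    """Genome-wide Haley-Knott LOD profile for one (parameter, environment).

    Segregants with a missing phenotype are dropped for this scan only.
    ``probs`` may be passed to reuse a precomputed probability grid.
    """
    if probs is None:
        probs = genotype_probabilities(d.genotypes, gmap, step_cm)
    y = d.phenotypes.get(parameter, environment)
    ok = np.isfinite(y)
    n_used = int(ok.sum())
    if n_used < 3:
        raise InsufficientDataError(
            f"{parameter}/{environment}: only {n_used} phenotyped segregants"
        )
    lod = single_scan_lods(y[ok], probs.probs[ok])
    return ScanResult("single", parameter, (environment,), probs.grid, lod, n_used)


def permute_threshold(
    d: CrossDataset,
    gmap: GeneticMap,
    parameter: str,
    environment: str,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    step_cm: float = DEFAULT_STEP_CM,
    probs: GenotypeProbability | None = None,
    result: ScanResult | None = None,
) -> ScanResult:
    """Attach a genome-wide-maximum permutation null to a single scan.

    Each permutation shuffles the phenotype vector against the segregant
    genotypes (preserving LD) and stores the genome-wide max LOD.  Returns
    the ScanResult with ``perm_null`` filled; seeded and reproducible.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if probs is None:
        probs = genotype_probabilities(d.genotypes, gmap, step_cm)
    if result is None:
        result = scan_one(d, gmap, parameter, environment, step_cm, probs)
    rng = np.random.default_rng(seed)
    y = d.phenotypes.get(parameter, environment)
    ok = np.isfinite(y)
    result.perm_null = single_scan_perm_max(y[ok], probs.probs[ok], n_perm, rng)
    return result


def call_peaks(s: ScanResult, d: CrossDataset, p_max: float = 0.2) -> list[QtlCall]:
    """One QtlCall per chromosome at the max-LOD position with p <= p_max.

    Effect and SE come from allele-group means at the nearest marker;
    variance explained is 1 - RSS1/RSS0 at the peak = 1 - 10^(-2*LOD/n).
    """
    if s.perm_null is None:
        raise ValueError("call_peaks requires a permutation null (run permute_threshold)")
    env = s.environments[0]
    y = d.phenotypes.get(s.parameter, env)
    calls = []
    for _, peak in s.chromosome_peaks().iterrows():
        p = s.p_value(peak["lod"])
        if p > p_max or peak["lod"] <= 0:
            continue
        j = d.genotypes.marker_index(peak["marker_id"])
        eff, se = allele_effect(y, d.genotypes.calls[:, j])
        r2 = 1.0 - 10.0 ** (-2.0 * peak["lod"] / s.n_used)
        calls.append(QtlCall(int(peak["chromosome"]), int(peak["position_bp"]),
                             peak["marker_id"], float(peak["lod"]), p, eff, se,
                             float(r2), s.parameter, env))
    return calls
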