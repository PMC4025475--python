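"""Gene-environment interaction (GEI) mapping across environment pairs.

Phenotypes from two environments are stacked and the environment enters the
Haley-Knott regression as an additive and interactive covariate:

    additive   y ~ mu + bE*E + bg*x
    full       y ~ mu + bE*E + bg*x + bgE*(x*E)

The interaction LOD, (N/2)*log10(RSS_additive/RSS_full) with N the pooled
observation count, is the primary GEI statistic; the full-vs-null LOD
(against y ~ mu + bE*E) is computed alongside, and the two satisfy
full = additive + interaction exactly.

Called GEI QTL are classified into reaction-norm classes (scale,
environment-specific, crossover) from allele means +/- 1 SE in each
environment: the classes are decided by whether the two allele intervals
separate in each environment and whether the allele-effect sign flips.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .cross_data import CrossDataset
from .errors import InsufficientDataError
from .linkage_core import GeneticMap, GenotypeProbability, genotype_probabilities
from .naming import format_locus, parse_locus
from .qtl_scan import DEFAULT_STEP_CM, ScanResult, permutation_p
from .regression import gei_scan_lods, gei_scan_perm_max

logger = logging.getLogger(__name__)

GEI_CLASSES = ("scale", "environment_specific", "crossover", "unclassified")


@dataclass
class AlleleSummary:
    """Per-environment allele-group means +/- SE at a marker."""

    mean_s: float
    se_s: float
    n_s: int
    mean_y: float
    se_y: float
    n_y: int

    @property
    def delta(self) -> float:
        """Allele-mean difference, S minus Y."""
        return self.mean_s - self.mean_y

    @property
    def separated(self) -> bool:
        """True when the +/- 1 SE intervals of the two allele means do not overlap."""
        if not (np.isfinite(self.se_s) and np.isfinite(self.se_y)):
            return False
        return abs(self.delta) > self.se_s + self.se_y


@dataclass
class GeiCall:
    """A called GEI QTL for one environment pair."""

    chromosome: int
    position_bp: int
    marker_id: str
    environment_pair: tuple[str, str]
    interaction_lod: float
    full_lod: float
    p_value: float
    gei_class: str
    means: dict[str, AlleleSummary]   # environment -> allele summary
    parameter: str
    novel: bool | None = None         # set by the pipeline (not in single scans)

    @property
    def locus(self) -> str:
        return format_locus(self.chromosome, self.position_bp)

    def to_row(self) -> dict:
        detail = {
            "marker_id": self.marker_id,
            "full_lod": self.full_lod,
            "means": {e: vars(m) for e, m in self.means.items()},
        }
        if self.novel is not None:
            detail["novel"] = self.novel
        return {
            "scan_type": "gei", "parameter": self.parameter,
            "environments": ",".join(self.environment_pair), "loci": self.locus,
            "lod": self.interaction_lod, "p_value": self.p_value,
            "gei_class": self.gei_class, "detail": json.dumps(detail),
        }

    @classmethod
    def from_row(cls, row: dict) -> "GeiCall":
        chrom, bp = parse_locus(row["loci"])
        detail = json.loads(row["detail"]) if row.get("detail") else {}
        means = {e: AlleleSummary(**v) for e, v in detail.get("means", {}).items()}
        envs = tuple(row["environments"].split(","))
        return cls(chrom, bp, detail.get("marker_id", ""), envs, float(row["lod"]),
                   float(detail.get("full_lod", "nan")), float(row["p_value"]),
                   row["gei_class"], means, row["parameter"],
                   detail.get("novel"))


def gei_lod(ya: np.ndarray, yb: np.ndarray, x: np.ndarray) -> float:
    """Interaction LOD at one position for a paired two-environment phenotype.

    ``ya``/``yb`` are aligned per-segregant phenotypes in the two
    environments and ``x`` the genotype (probability of S).  Segregants
    missing either phenotype are dropped; pooled n must be >= 6.
    """
    ya = np.asarray(ya, dtype=float)
    yb = np.asarray(yb, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(ya) & np.isfinite(yb) & np.isfinite(x)
    if 2 * int(ok.sum()) < 6:
        raise InsufficientDataError("pooled observation count below 6")
    if np.ptp(x[ok]) == 0:
        raise ValueError("regressor is constant; interaction LOD undefined")
    lod_int, _, _ = gei_scan_lods(ya[ok], yb[ok], x[ok, None])
    return float(lod_int[0])


def allele_summary(y: np.ndarray, calls: np.ndarray) -> AlleleSummary:
    """Allele-group means, SEs and counts for one environment at one marker."""
    ok = np.isfinite(y) & np.isfinite(calls)
    ys = y[ok & (calls == 1.0)]
    yy = y[ok & (calls == 0.0)]

    def _se(v: np.ndarray) -> float:
        return float(np.sqrt(v.var(ddof=1) / v.size)) if v.size >= 2 else float("nan")

    return AlleleSummary(
        float(ys.mean()) if ys.size else float("nan"), _se(ys), int(ys.size),
        float(yy.mean()) if yy.size else float("nan"), _se(yy), int(yy.size),
    )


def classify_gei(call: GeiCall) -> str:
    """Reaction-norm class from allele means +/- 1 SE in the two environments.

    crossover: separated in both environments with opposite-signed allele
    effects; scale: separated in both with the same sign (including the
    measure-zero tie |dA| == |dB|); environment_specific: separated in
    exactly one; unclassified otherwise (including missing SEs).
    """
    ea, eb = call.environment_pair
    if ea not in call.means or eb not in call.means:
        return "unclassified"
    ma, mb = call.means[ea], call.means[eb]
    finite = all(np.isfinite(v) for m in (ma, mb)
                 for v in (m.mean_s, m.mean_y, m.se_s, m.se_y))
    if not finite:
        return "unclassified"
    sep_a, sep_b = ma.separated, mb.separated
    if sep_a and sep_b:
        return "crossover" if np.sign(ma.delta) != np.sign(mb.delta) else "scale"
    if sep_a != sep_b:
        return "environment_specific"
    return "unclassified"


def scan_gei(
    d: CrossDataset,
    gmap: GeneticMap,
    parameter: str,
    env_a: str,
    env_b: str,
    step_cm: float = DEFAULT_STEP_CM,
    n_perm: int = 100,
    seed: int | np.random.SeedSequence = 0,
    p_max: float = 0.2,
    probs: GenotypeProbability | None = None,
) -> tuple[ScanResult, list[GeiCall]]:
    """Genome-wide GEI scan for one environment pair.

    Returns the interaction-LOD profile (full-vs-null profile in
    ``secondary_lod``) with its permutation null, plus one GeiCall per
    chromosome whose peak reaches p <= p_max.  The permutation unit is the
    segregant with its (envA, envB) phenotype pair kept intact.
    """
    if probs is None:
        probs = genotype_probabilities(d.genotypes, gmap, step_cm)
    ya = d.phenotypes.get(parameter, env_a)
    yb = d.phenotypes.get(parameter, env_b)
    ok = np.isfinite(ya) & np.isfinite(yb)
    n_pairs = int(ok.sum())
    if 2 * n_pairs < 6:
        raise InsufficientDataError(
            f"{parameter}/{env_a}-{env_b}: only {n_pairs} paired segregants"
        )
    dropped = int((np.isfinite(ya) | np.isfinite(yb)).sum()) - n_pairs
    if dropped:
        logger.warning("scan_gei: dropped %d unpaired segregants", dropped)
    X = probs.probs[ok]
    lod_int, lod_add, lod_full = gei_scan_lods(ya[ok], yb[ok], X)
    result = ScanResult("gei", parameter, (env_a, env_b), probs.grid, lod_int,
                        2 * n_pairs, secondary_lod=lod_full)
    rng = np.random.default_rng(seed)
    result.perm_null = gei_scan_perm_max(ya[ok], yb[ok], X, n_perm, rng)

    calls: list[GeiCall] = []
    for _, peak in result.chromosome_peaks().iterrows():
        p = permutation_p(result.perm_null, peak["lod"])
        if p > p_max or peak["lod"] <= 0:
            continue
        j = d.genotypes.marker_index(peak["marker_id"])
        marker_calls = d.genotypes.calls[:, j]
        means = {env_a: allele_summary(ya, marker_calls),
                 env_b: allele_summary(yb, marker_calls)}
        gi = int(peak["grid_index"])
        call = GeiCall(int(peak["chromosome"]), int(peak["position_bp"]),
                       peak["marker_id"], (env_a, env_b), float(peak["lod"]),
                       float(result.secondary_lod[gi]), p, "unclassified",
                       means, parameter)
        call.gei_class = classify_gei(call)
        calls.append(call)
    return result, calls
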