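"""Targeted multi-QTL interaction scans with set-restricted permutation nulls.

Genome-wide exhaustive epistasis scans are underpowered at ~144 segregants,
so the strategy is targeted: collate a candidate marker set from relaxed
single-environment evidence (permutation p < 1, i.e. peak LOD above the
smallest genome-wide null maximum) and from GEI evidence (p < 0.5); test all
candidate pairs, pairs anchored at named large-effect QTL, and triples built
from an anchor plus a called pair.  Each scan's significance comes from a
permutation null of the maximum interaction LOD over the same tuple set, so
multiplicity over the set is handled exactly like the genome-max null of a
single scan.

Statistics (n = phenotyped segregants):
  two-locus   additive [1, x1, x2]           vs + x1*x2
  three-locus all-pairwise [1, mains, pairs] vs + x1*x2*x3
LOD = (n/2)*log10(RSS_base/RSS_full); the three-locus baseline includes all
pairwise products so the statistic isolates the pure three-way contrast.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross_data import CrossDataset
from .errors import ConfigError, InsufficientDataError
from .linkage_core import GeneticMap, GenotypeProbability, genotype_probabilities
from .naming import format_locus, parse_locus
from .qtl_scan import ScanResult, permutation_p
from .regression import (
    InteractionDesigns,
    fit_rss,
    lod_from_rss,
    make_pair_designs,
    make_triple_designs,
)

logger = logging.getLogger(__name__)

#: collinearity guards for locus tuples
MAX_PAIR_CORR = 0.9
MIN_SEP_CM = 25.0


@dataclass
class CandidateSet:
    """De-duplicated candidate markers for interaction scans, with provenance.

    ``table`` columns: marker_id, chromosome, position_bp, position_cm,
    source ('single_env', 'gei' or 'large_effect_anchor'; multiple sources
    joined with '+'), parameters, environments.
    """

    table: pd.DataFrame

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def build_candidates(
    single_results: list[ScanResult],
    gei_results: list[ScanResult],
    gei_p_max: float = 0.5,
) -> CandidateSet:
    """Collate candidate markers from single-environment and GEI scans.

    From each single-environment scan, the per-chromosome peak marker enters
    if its LOD exceeds the smallest genome-wide null maximum (permutation
    p < 1).  From each GEI scan, peaks with p < ``gei_p_max`` enter.  The
    union over scans is de-duplicated by marker id, provenance merged.
    """
    entries: dict[str, dict] = {}

    def _add(peak, source: str, parameter: str, environments: tuple[str, ...]):
        mid = peak["marker_id"]
        e = entries.setdefault(mid, {
            "marker_id": mid, "chromosome": int(peak["chromosome"]),
            "position_bp": int(peak["position_bp"]),
            "position_cm": float(peak["position_cm"]),
            "sources": set(), "parameters": set(), "environments": set(),
        })
        e["sources"].add(source)
        e["parameters"].add(parameter)
        e["environments"].update(environments)

    for res in single_results:
        if res.perm_null is None:
            raise ValueError("single-environment scans must carry permutation nulls")
        floor = float(np.min(res.perm_null))
        for _, peak in res.chromosome_peaks().iterrows():
            if peak["lod"] > floor:
                _add(peak, "single_env", res.parameter, res.environments)
    for res in gei_results:
        if res.perm_null is None:
            raise ValueError("GEI scans must carry permutation nulls")
        for _, peak in res.chromosome_peaks().iterrows():
            if peak["lod"] > 0 and permutation_p(res.perm_null, peak["lod"]) < gei_p_max:
                _add(peak, "gei", res.parameter, res.environments)

    if not entries:
        logger.warning("build_candidates: empty candidate set; interaction scans "
                       "will be skipped")
    rows = [{
        "marker_id": e["marker_id"], "chromosome": e["chromosome"],
        "position_bp": e["position_bp"], "position_cm": e["position_cm"],
        "source": "+".join(sorted(e["sources"])),
        "parameters": "+".join(sorted(e["parameters"])),
        "environments": "+".join(sorted(e["environments"])),
    } for e in entries.values()]
    table = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp",
                                        "position_cm", "source", "parameters",
                                        "environments"])
    if len(table):
        table = table.sort_values(["chromosome", "position_bp"]).reset_index(drop=True)
    return CandidateSet(table)


def candidate_set_from_markers(
    d: CrossDataset, gmap: GeneticMap, marker_ids: list[str],
    source: str = "single_env",
) -> CandidateSet:
    """Build a CandidateSet directly from marker ids (targeted analyses)."""
    rows = []
    for mid in marker_ids:
        j = d.genotypes.marker_index(mid)
        m = d.genotypes.markers.iloc[j]
        cm = gmap.table.loc[gmap.table["id"] == mid, "position_cm"]
        rows.append({"marker_id": mid, "chromosome": int(m["chromosome"]),
                     "position_bp": int(m["position_bp"]),
                     "position_cm": float(cm.iloc[0]) if len(cm) else float("nan"),
                     "source": source, "parameters": "", "environments": ""})
    return CandidateSet(pd.DataFrame(rows))


@dataclass
class InteractionCall:
    """A called two- or three-locus interaction."""

    loci: list[tuple[int, int, str]]      # (chromosome, position_bp, marker_id)
    interaction_lod: float
    p_value: float
    anchored: bool
    class_means: dict[str, tuple[float, float, int]]  # 'SY..' -> (mean, se, n)
    parameter: str
    environment: str
    scan_type: str = "pair"               # pair | anchored_pair | triple
    p_per_tuple: float | None = None      # per-tuple (non set-max) permutation p
    secondary_lod: float | None = None    # triples: full-vs-additive LOD
    anchor: str | None = None             # triples: anchor marker id
    source_pair: tuple[str, str] | None = None  # triples: contributing pair

    @property
    def locus(self) -> str:
        return "-".join(format_locus(c, bp) for c, bp, _ in self.loci)

    def to_row(self) -> dict:
        detail = {
            "marker_ids": [m for _, _, m in self.loci],
            "class_means": self.class_means,
        }
        if self.p_per_tuple is not None:
            detail["p_per_tuple"] = self.p_per_tuple
        if self.secondary_lod is not None:
            detail["secondary_lod"] = self.secondary_lod
        if self.anchor is not None:
            detail["anchor"] = self.anchor
        if self.source_pair is not None:
            detail["source_pair"] = list(self.source_pair)
        return {
            "scan_type": self.scan_type, "parameter": self.parameter,
            "environments": self.environment, "loci": self.locus,
            "lod": self.interaction_lod, "p_value": self.p_value,
            "anchored": self.anchored, "detail": json.dumps(detail),
        }

    @classmethod
    def from_row(cls, row: dict) -> "InteractionCall":
        detail = json.loads(row["detail"]) if row.get("detail") else {}
        locus_parts = row["loci"].split(")-")
        locus_parts = [p if p.endswith(")") else p + ")" for p in locus_parts]
        mids = detail.get("marker_ids", [""] * len(locus_parts))
        loci = []
        for part, mid in zip(locus_parts, mids):
            c, bp = parse_locus(part)
            loci.append((c, bp, mid))
        cm = {k: tuple(v) for k, v in detail.get("class_means", {}).items()}
        sp = detail.get("source_pair")
        return cls(loci, float(row["lod"]), float(row["p_value"]),
                   row.get("anchored") == "true", cm, row["parameter"],
                   row["environments"], row["scan_type"],
                   detail.get("p_per_tuple"), detail.get("secondary_lod"),
                   detail.get("anchor"), tuple(sp) if sp else None)


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------

def _check_tuple(xs: list[np.ndarray], n_min: int) -> None:
    n = xs[0].size
    if n < n_min:
        raise InsufficientDataError(f"need >= {n_min} observations, got {n}")
    for a, b in itertools.combinations(xs, 2):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValueError("constant genotype vector")
        r = np.corrcoef(a, b)[0, 1]
        if abs(r) > MAX_PAIR_CORR:
            raise ValueError(f"collinear locus pair (|r| = {abs(r):.3f} > {MAX_PAIR_CORR})")


def two_qtl_lod(y: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> float:
    """Two-locus interaction LOD: additive [1, x1, x2] vs + x1*x2."""
    y, x1, x2 = (np.asarray(v, dtype=float) for v in (y, x1, x2))
    ok = np.isfinite(y) & np.isfinite(x1) & np.isfinite(x2)
    y, x1, x2 = y[ok], x1[ok], x2[ok]
    _check_tuple([x1, x2], 8)
    ones = np.ones_like(y)
    base = np.column_stack([ones, x1, x2])
    rss_a = fit_rss(y, base)
    rss_f = fit_rss(y, np.column_stack([base, x1 * x2]))
    return lod_from_rss(y.size, rss_a, rss_f)


def three_qtl_lod(
    y: np.ndarray, x1: np.ndarray, x2: np.ndarray, x3: np.ndarray
) -> float:
    """Three-locus interaction LOD: all-pairwise baseline vs + x1*x2*x3."""
    y, x1, x2, x3 = (np.asarray(v, dtype=float) for v in (y, x1, x2, x3))
    ok = np.isfinite(y) & np.isfinite(x1) & np.isfinite(x2) & np.isfinite(x3)
    y, x1, x2, x3 = y[ok], x1[ok], x2[ok], x3[ok]
    _check_tuple([x1, x2, x3], 16)
    ones = np.ones_like(y)
    base = np.column_stack([ones, x1, x2, x3, x1 * x2, x1 * x3, x2 * x3])
    rss_p = fit_rss(y, base)
    rss_f = fit_rss(y, np.column_stack([base, x1 * x2 * x3]))
    return lod_from_rss(y.size, rss_p, rss_f)


def three_qtl_lod_vs_additive(
    y: np.ndarray, x1: np.ndarray, x2: np.ndarray, x3: np.ndarray
) -> float:
    """Secondary three-locus statistic: full model vs main-effects-only baseline."""
    y, x1, x2, x3 = (np.asarray(v, dtype=float) for v in (y, x1, x2, x3))
    ok = np.isfinite(y) & np.isfinite(x1) & np.isfinite(x2) & np.isfinite(x3)
    y, x1, x2, x3 = y[ok], x1[ok], x2[ok], x3[ok]
    ones = np.ones_like(y)
    add = np.column_stack([ones, x1, x2, x3])
    full = np.column_stack([add, x1 * x2, x1 * x3, x2 * x3, x1 * x2 * x3])
    return lod_from_rss(y.size, fit_rss(y, add), fit_rss(y, full))


# ---------------------------------------------------------------------------
# set scans
# ---------------------------------------------------------------------------

def _marker_vectors(
    d: CrossDataset, gmap: GeneticMap, probs: GenotypeProbability | None
) -> GenotypeProbability:
    """Imputed genotype probabilities at markers only (interaction scans use
    markers, not pseudomarkers)."""
    if probs is not None:
        return probs
    return genotype_probabilities(d.genotypes, gmap, step_cm=0.0)


def resolve_markers(d: CrossDataset, names: list[str]) -> list[str]:
    """Resolve marker ids or chrN(pos) locus strings to marker ids."""
    out = []
    ids = set(d.genotypes.markers["id"])
    for name in names:
        if name in ids:
            out.append(name)
            continue
        try:
            chrom, bp = parse_locus(name)
        except ValueError:
            raise ConfigError(f"marker {name!r} not found in genotype matrix")
        hit = d.genotypes.markers.query("chromosome == @chrom and position_bp == @bp")
        if hit.empty:
            raise ConfigError(f"marker {name!r} not found in genotype matrix")
        out.append(hit["id"].iloc[0])
    return out


def _pair_admissible(c1: dict, c2: dict, x1: np.ndarray, x2: np.ndarray,
                     max_corr: float, min_sep_cm: float) -> bool:
    """Collinearity guard: same-chromosome pairs closer than min_sep_cm, or
    |r| above max_corr, are excluded (linked markers, not true epistasis)."""
    if c1["marker_id"] == c2["marker_id"]:
        return False
    if c1["chromosome"] == c2["chromosome"]:
        if abs(c1["position_cm"] - c2["position_cm"]) < min_sep_cm:
            return False
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        return False
    if abs(np.corrcoef(x1, x2)[0, 1]) > max_corr:
        return False
    return True


def _class_label(bits: tuple[int, ...]) -> str:
    return "".join("S" if b == 1 else "Y" for b in bits)


def genotype_class_means(
    d: CrossDataset, marker_ids: list[str], parameter: str, environment: str
) -> dict[str, tuple[float, float, int]]:
    """Mean, SE and n per multi-locus genotype class (S/Y words, stated order).

    Uses observed (non-imputed) calls; segregants missing a phenotype or any
    of the marker calls are dropped.
    """
    y = d.phenotypes.get(parameter, environment)
    cols = [d.genotypes.calls[:, d.genotypes.marker_index(m)] for m in marker_ids]
    ok = np.isfinite(y)
    for c in cols:
        ok &= np.isfinite(c)
    out: dict[str, tuple[float, float, int]] = {}
    for bits in itertools.product((1, 0), repeat=len(cols)):
        mask = ok.copy()
        for c, b in zip(cols, bits):
            mask &= c == b
        v = y[mask]
        if v.size == 0:
            out[_class_label(bits)] = (float("nan"), float("nan"), 0)
        else:
            se = float(np.sqrt(v.var(ddof=1) / v.size)) if v.size >= 2 else float("nan")
            out[_class_label(bits)] = (float(v.mean()), se, int(v.size))
    return out


def _run_tuple_scan(
    d: CrossDataset,
    tuples: list[tuple[str, ...]],
    designs: InteractionDesigns,
    parameter: str,
    environment: str,
    y: np.ndarray,
    n_perm: int,
    seed,
    p_max: float,
    scan_type: str,
    anchored: bool,
    extras: list[dict] | None = None,
) -> list[InteractionCall]:
    rng = np.random.default_rng(seed)
    observed = designs.lods(y[None, :])[0]
    null_matrix = designs.perm_max(y, n_perm, rng, return_matrix=True)
    null_max = null_matrix.max(axis=1)
    calls = []
    for t, mids in enumerate(tuples):
        if not designs.valid[t]:
            continue
        p = permutation_p(null_max, observed[t])
        if p > p_max or observed[t] <= 0:
            continue
        p_tuple = permutation_p(null_matrix[:, t], observed[t])
        loci = []
        for mid in mids:
            j = d.genotypes.marker_index(mid)
            m = d.genotypes.markers.iloc[j]
            loci.append((int(m["chromosome"]), int(m["position_bp"]), mid))
        call = InteractionCall(
            loci, float(observed[t]), p, anchored,
            genotype_class_means(d, list(mids), parameter, environment),
            parameter, environment, scan_type, p_per_tuple=p_tuple,
        )
        if extras is not None:
            for k, v in extras[t].items():
                setattr(call, k, v)
        calls.append(call)
    calls.sort(key=lambda c: (-c.interaction_lod, c.locus))
    return calls


def _scan_setup(d, gmap, parameter, environment, probs):
    probs = _marker_vectors(d, gmap, probs)
    y = d.phenotypes.get(parameter, environment)
    ok = np.isfinite(y)
    if int(ok.sum()) < 8:
        raise InsufficientDataError(f"{parameter}/{environment}: too few phenotyped segregants")
    xcol = {}
    return probs, y[ok], ok, xcol


def scan_pairs(
    d: CrossDataset,
    gmap: GeneticMap,
    cands: CandidateSet,
    parameter: str,
    environment: str,
    n_perm: int = 10000,
    seed: int | np.random.SeedSequence = 0,
    p_max: float = 0.2,
    max_corr: float = MAX_PAIR_CORR,
    min_sep_cm: float = MIN_SEP_CM,
    probs: GenotypeProbability | None = None,
) -> list[InteractionCall]:
    """Two-locus interaction scan over all admissible candidate pairs.

    The permutation null is the per-shuffle maximum interaction LOD over the
    same pair set; p = max(k,1)/n_perm.  Calls at p <= p_max.
    """
    if len(cands) < 2:
        logger.warning("scan_pairs: fewer than 2 candidates; nothing to test")
        return []
    probs, y, ok, _ = _scan_setup(d, gmap, parameter, environment, probs)
    recs = cands.table.to_dict("records")
    xs = {r["marker_id"]: probs.marker_column(r["marker_id"])[ok] for r in recs}
    tuples, design_x = [], []
    for c1, c2 in itertools.combinations(recs, 2):
        x1, x2 = xs[c1["marker_id"]], xs[c2["marker_id"]]
        if not _pair_admissible(c1, c2, x1, x2, max_corr, min_sep_cm):
            continue
        tuples.append((c1["marker_id"], c2["marker_id"]))
        design_x.append((x1, x2))
    if not tuples:
        logger.warning("scan_pairs: no admissible pairs after collinearity guard")
        return []
    designs = make_pair_designs(y.size, design_x)
    return _run_tuple_scan(d, tuples, designs, parameter, environment, y,
                           n_perm, seed, p_max, "pair", anchored=False)


def scan_anchored(
    d: CrossDataset,
    gmap: GeneticMap,
    anchors: list[str],
    cands: CandidateSet,
    parameter: str,
    environment: str,
    n_perm: int = 10000,
    seed: int | np.random.SeedSequence = 0,
    p_max: float = 0.2,
    max_corr: float = MAX_PAIR_CORR,
    min_sep_cm: float = MIN_SEP_CM,
    probs: GenotypeProbability | None = None,
) -> list[InteractionCall]:
    """Two-locus scan restricted to (large-effect anchor) x (candidate) pairs.

    The permutation null is the maximum over this restricted pair set only.
    """
    if not anchors:
        raise ConfigError("anchored scan needs at least one anchor marker")
    anchor_ids = resolve_markers(d, anchors)
    probs, y, ok, _ = _scan_setup(d, gmap, parameter, environment, probs)
    anchor_recs = candidate_set_from_markers(d, gmap, anchor_ids,
                                             source="large_effect_anchor").table
    recs = cands.table.to_dict("records")
    tuples, design_x = [], []
    seen = set()
    for _, a in anchor_recs.iterrows():
        xa = probs.marker_column(a["marker_id"])[ok]
        for c in recs:
            key = frozenset((a["marker_id"], c["marker_id"]))
            if key in seen:
                continue
            xc = probs.marker_column(c["marker_id"])[ok]
            if not _pair_admissible(dict(a), c, xa, xc, max_corr, min_sep_cm):
                continue
            seen.add(key)
            tuples.append((a["marker_id"], c["marker_id"]))
            design_x.append((xa, xc))
    if not tuples:
        logger.warning("scan_anchored: no admissible anchor-candidate pairs")
        return []
    designs = make_pair_designs(y.size, design_x)
    return _run_tuple_scan(d, tuples, designs, parameter, environment, y,
                           n_perm, seed, p_max, "anchored_pair", anchored=True)


def scan_triples(
    d: CrossDataset,
    gmap: GeneticMap,
    anchors: list[str],
    pair_calls: list[InteractionCall],
    parameter: str,
    environment: str,
    n_perm: int = 10000,
    seed: int | np.random.SeedSequence = 0,
    p_max: float = 0.2,
    max_corr: float = MAX_PAIR_CORR,
    min_sep_cm: float = MIN_SEP_CM,
    probs: GenotypeProbability | None = None,
) -> list[InteractionCall]:
    """Three-locus scan over {anchor} x {called pairs}, set-max null.

    The primary LOD isolates the pure three-way term (all-pairwise baseline);
    the full-vs-additive LOD is stored as ``secondary_lod``.
    """
    if not pair_calls:
        logger.warning("scan_triples: no pair calls to extend")
        return []
    anchor_ids = resolve_markers(d, anchors)
    probs, y, ok, _ = _scan_setup(d, gmap, parameter, environment, probs)
    xs: dict[str, np.ndarray] = {}

    def _x(mid: str) -> np.ndarray:
        if mid not in xs:
            xs[mid] = probs.marker_column(mid)[ok]
        return xs[mid]

    def _rec(mid: str) -> dict:
        j = d.genotypes.marker_index(mid)
        m = d.genotypes.markers.iloc[j]
        cm = gmap.table.loc[gmap.table["id"] == mid, "position_cm"]
        return {"marker_id": mid, "chromosome": int(m["chromosome"]),
                "position_cm": float(cm.iloc[0]) if len(cm) else float("nan")}

    tuples, design_x, extras = [], [], []
    seen = set()
    for a in anchor_ids:
        ra = _rec(a)
        for pc in pair_calls:
            m1, m2 = pc.loci[0][2], pc.loci[1][2]
            if a in (m1, m2):
                continue
            key = frozenset((a, m1, m2))
            if key in seen:
                continue
            r1, r2 = _rec(m1), _rec(m2)
            if not (_pair_admissible(ra, r1, _x(a), _x(m1), max_corr, min_sep_cm)
                    and _pair_admissible(ra, r2, _x(a), _x(m2), max_corr, min_sep_cm)):
                continue
            seen.add(key)
            tuples.append((a, m1, m2))
            design_x.append((_x(a), _x(m1), _x(m2)))
            extras.append({"anchor": a, "source_pair": (m1, m2)})
    if not tuples:
        logger.warning("scan_triples: no admissible triples")
        return []
    designs = make_triple_designs(y.size, design_x)
    calls = _run_tuple_scan(d, tuples, designs, parameter, environment, y,
                            n_perm, seed, p_max, "triple", anchored=True,
                            extras=extras)
    for call in calls:
        x1, x2, x3 = (_x(m) for _, _, m in call.loci)
        call.secondary_lod = three_qtl_lod_vs_additive(y, x1, x2, x3)
    return calls
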