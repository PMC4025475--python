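"""Genetic-map estimation and conditional genotype probabilities.

Two-point recombination fractions between physically adjacent markers are
converted to centimorgans with the Haldane map function (no crossover
interference), d = -50*ln(1-2r).  Conditional probabilities
P(genotype = S | flanking observed markers) support both imputation at missing
markers and a pseudomarker grid between markers (interval mapping).

Marker order is taken from physical bp order and never re-estimated: markers
come from sequencing, so order is known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross_data import GenotypeMatrix
from .errors import InsufficientDataError, UndefinedLinkageError

logger = logging.getLogger(__name__)

#: adjacent-pair recombination fractions are clipped just below 0.5 during map
#: building so that chromosomes stay one linkage group (assignment is known
#: from the physical map); 0.4999 maps to ~426 cM.
MAX_MAP_RF = 0.4999


def haldane_cm(r: float) -> float:
    """Haldane map distance in cM for recombination fraction ``r``.

    d = -50*ln(1-2r); exact inverse of :func:`haldane_r`.
    Raises for r >= 0.5 (infinite distance: caller must break the linkage group).
    """
    r = float(r)
    if not 0.0 <= r:
        raise ValueError(f"recombination fraction must be >= 0, got {r}")
    if r >= 0.5:
        raise UndefinedLinkageError(f"r = {r} >= 0.5 implies infinite map distance")
    return -50.0 * np.log1p(-2.0 * r)


def haldane_r(d_cm) :
    """Recombination fraction at Haldane distance ``d_cm``: (1 - e^(-d/50)) / 2."""
    d = np.asarray(d_cm, dtype=float)
    out = 0.5 * -np.expm1(-d / 50.0)
    return float(out) if np.isscalar(d_cm) else out


def estimate_rf(g: GenotypeMatrix, i: int, j: int) -> float:
    """Two-point recombination fraction between markers ``i`` and ``j``.

    r-hat = (#discordant parental calls) / (#segregants non-missing at both),
    truncated to [0, 0.5].
    """
    a, b = g.calls[:, i], g.calls[:, j]
    ok = np.isfinite(a) & np.isfinite(b)
    n = int(ok.sum())
    if n < 2:
        raise InsufficientDataError(
            f"fewer than 2 segregants informative for markers {i}, {j}"
        )
    disc = int(np.sum(a[ok] != b[ok]))
    return min(disc / n, 0.5)


@dataclass
class GeneticMap:
    """Ordered markers per chromosome with estimated cM positions.

    ``table`` columns: id, chromosome, position_bp, position_cm, rf_prev
    (recombination fraction to the previous marker on the same chromosome;
    NaN for the first marker of each chromosome).
    """

    table: pd.DataFrame

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.table["chromosome"].unique().tolist())

    def chromosome_table(self, chrom: int) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom]

    def total_length_cm(self) -> float:
        return float(sum(t["position_cm"].iloc[-1] - t["position_cm"].iloc[0]
                         for _, t in self.table.groupby("chromosome")))

    def write(self, path) -> None:
        self.table[["chromosome", "id", "position_bp", "position_cm"]].rename(
            columns={"id": "marker"}
        ).to_csv(path, sep="\t", index=False)


def estimate_map(g: GenotypeMatrix) -> GeneticMap:
    """Build the genetic map from adjacent two-point recombination fractions.

    cM positions accumulate Haldane distances along each chromosome starting
    at 0; adjacent r-hat is clipped to :data:`MAX_MAP_RF` (physical order and
    chromosome assignment are trusted, so linkage groups are never broken).
    """
    rows = []
    chroms = g.markers["chromosome"].to_numpy()
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        cm = 0.0
        prev_rf = np.nan
        for k, j in enumerate(idx):
            if k > 0:
                try:
                    r = estimate_rf(g, int(idx[k - 1]), int(j))
                except InsufficientDataError:
                    r = 0.0
                    logger.warning("no informative pairs for adjacent markers "
                                   "%s-%s; assuming r=0",
                                   g.markers['id'].iloc[idx[k - 1]], g.markers['id'].iloc[j])
                if r >= 0.5:
                    logger.warning(
                        "adjacent markers %s-%s have r-hat >= 0.5; clipping to %.4f",
                        g.markers["id"].iloc[idx[k - 1]], g.markers["id"].iloc[j], MAX_MAP_RF,
                    )
                prev_rf = min(r, MAX_MAP_RF)
                cm += haldane_cm(prev_rf)
            row = g.markers.iloc[j]
            rows.append((row["id"], int(chrom), int(row["position_bp"]), cm, prev_rf))
            prev_rf = np.nan
    table = pd.DataFrame(rows, columns=["id", "chromosome", "position_bp",
                                        "position_cm", "rf_prev"])
    return GeneticMap(table)


def true_map(g: GenotypeMatrix) -> GeneticMap:
    """Map taken directly from the position_cm column (e.g. simulated truth)."""
    t = g.markers[["id", "chromosome", "position_bp", "position_cm"]].copy()
    if t["position_cm"].isna().any():
        raise ValueError("position_cm not filled; use estimate_map")
    t["rf_prev"] = np.nan
    return GeneticMap(t.reset_index(drop=True))


@dataclass
class GenotypeProbability:
    """P(S) on a position grid for every segregant.

    ``grid`` columns: chromosome, position_cm, marker_id (nearest marker),
    position_bp (of the nearest marker), is_marker.
    ``probs`` has shape (n_segregants, n_positions).
    """

    segregant_ids: list[str]
    grid: pd.DataFrame
    probs: np.ndarray

    @property
    def n_positions(self) -> int:
        return len(self.grid)

    def column(self, pos_index: int) -> np.ndarray:
        return self.probs[:, pos_index]

    def marker_column(self, marker_id: str) -> np.ndarray:
        hits = np.flatnonzero(
            ((self.grid["marker_id"] == marker_id) & self.grid["is_marker"]).to_numpy()
        )
        if hits.size == 0:
            raise KeyError(f"marker {marker_id!r} not on probability grid")
        return self.probs[:, int(hits[0])]


def _grid_positions(marker_cm: np.ndarray, step_cm: float) -> tuple[np.ndarray, np.ndarray]:
    """Grid positions for one chromosome.

    Returns (positions_cm, source_marker) where source_marker[k] is the index
    of the marker sitting exactly at grid point k, or -1 for a pseudomarker.
    Every marker keeps its own grid point even when two markers share a cM
    coordinate (zero observed recombinants), so marker identity is never lost.
    """
    m = marker_cm.size
    if step_cm <= 0:
        return marker_cm.copy(), np.arange(m)
    lo, hi = marker_cm[0], marker_cm[-1]
    extra = np.arange(lo, hi, step_cm)
    extra = extra[~np.isin(np.round(extra, 9), np.round(marker_cm, 9))]
    pos = np.concatenate([marker_cm, extra])
    src = np.concatenate([np.arange(m), np.full(extra.size, -1, dtype=int)])
    order = np.argsort(pos, kind="stable")
    return pos[order], src[order]


def _cond_prob(gl: np.ndarray, gr: np.ndarray, rl: float, rr: float) -> np.ndarray:
    """P(S at q) given flanking genotypes gl, gr (prob-of-S in {0,1}) and
    recombination fractions rl, rr to the flanks (NaN genotype = no flank)."""
    # forward message from the left flank
    pl = np.where(np.isnan(gl), 0.5, gl * (1 - rl) + (1 - gl) * rl)
    # likelihood of the right observation given state at q
    lik_s = np.where(np.isnan(gr), 0.5, gr * (1 - rr) + (1 - gr) * rr)
    lik_y = 1.0 - lik_s
    num = pl * lik_s
    den = num + (1.0 - pl) * lik_y
    return np.where(den > 0, num / den, 0.5)


def genotype_probabilities(
    g: GenotypeMatrix, gmap: GeneticMap, step_cm: float = 0.0
) -> GenotypeProbability:
    """Conditional P(S) at every grid position for every segregant.

    Flanks are the nearest informative (non-missing) markers on each side with
    no cap on distance; positions beyond terminal informative markers use the
    single-flank formula; segregants with no data on a chromosome get P = 0.5.
    ``step_cm = 0`` means markers only; otherwise pseudomarkers are inserted
    so grid spacing is at most ``step_cm``.
    """
    if step_cm < 0:
        raise ValueError("step_cm must be >= 0")
    grid_rows = []
    prob_blocks = []
    n_seg = g.n_segregants
    chroms_all = g.markers["chromosome"].to_numpy()
    for chrom in np.unique(chroms_all):
        midx = np.flatnonzero(chroms_all == chrom)
        sub = gmap.table[gmap.table["chromosome"] == chrom]
        if len(sub) != midx.size:
            raise ValueError("map does not match genotype markers on chromosome %s" % chrom)
        mcm = sub["position_cm"].to_numpy(dtype=float)
        mids = sub["id"].to_numpy()
        mbp = sub["position_bp"].to_numpy()
        q, src = _grid_positions(mcm, step_cm)
        nearest = np.where(
            src >= 0, src, np.argmin(np.abs(q[:, None] - mcm[None, :]), axis=1)
        )
        is_marker = src >= 0
        calls = g.calls[:, midx]  # (n_seg, m)

        block = np.full((n_seg, q.size), 0.5)
        obs_mask = np.isfinite(calls)
        if obs_mask.all():
            # fast path: every segregant shares the same flank indices
            li = np.searchsorted(mcm, q, side="right") - 1
            ri = np.searchsorted(mcm, q, side="left")
            has_l, has_r = li >= 0, ri < mcm.size
            dl = np.where(has_l, q - mcm[np.clip(li, 0, None)], np.inf)
            dr = np.where(has_r, mcm[np.clip(ri, None, mcm.size - 1)] - q, np.inf)
            gl = np.where(has_l, calls[:, np.clip(li, 0, None)], np.nan)
            gr = np.where(has_r, calls[:, np.clip(ri, None, mcm.size - 1)], np.nan)
            block = _cond_prob(gl, gr, haldane_r(np.where(np.isfinite(dl), dl, 0.0)),
                               haldane_r(np.where(np.isfinite(dr), dr, 0.0)))
        else:
            for s in range(n_seg):
                oi = np.flatnonzero(obs_mask[s])
                if oi.size == 0:
                    continue  # stays 0.5
                ocm = mcm[oi]
                li = np.searchsorted(ocm, q, side="right") - 1
                ri = np.searchsorted(ocm, q, side="left")
                has_l, has_r = li >= 0, ri < ocm.size
                gl = np.where(has_l, calls[s, oi[np.clip(li, 0, None)]], np.nan)
                gr = np.where(has_r, calls[s, oi[np.clip(ri, None, ocm.size - 1)]], np.nan)
                dl = np.where(has_l, q - ocm[np.clip(li, 0, None)], 0.0)
                dr = np.where(has_r, ocm[np.clip(ri, None, ocm.size - 1)] - q, 0.0)
                block[s] = _cond_prob(gl, gr, haldane_r(dl), haldane_r(dr))
        prob_blocks.append(block)
        for k in range(q.size):
            grid_rows.append((int(chrom), float(q[k]), mids[nearest[k]],
                              int(mbp[nearest[k]]), bool(is_marker[k])))
    grid = pd.DataFrame(grid_rows, columns=["chromosome", "position_cm", "marker_id",
                                            "position_bp", "is_marker"])
    probs = np.concatenate(prob_blocks, axis=1) if prob_blocks else np.zeros((n_seg, 0))
    return GenotypeProbability(list(g.segregant_ids), grid, probs)
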