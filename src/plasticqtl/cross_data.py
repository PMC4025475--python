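"""Data model and I/O for haploid biparental-cross datasets.

A :class:`CrossDataset` bundles a segregant genotype matrix (parental codes
S/Y with missing values), a marker map (chromosome + bp, cM filled by map
estimation) and a multi-environment phenotype table (e.g. doubling time and
maxOD across carbon sources).

Internal genotype coding is the probability-of-S scale: S -> 1.0, Y -> 0.0,
missing -> NaN, so "effect of the S allele" has a consistent sign everywhere.
Marker order is always (chromosome, position_bp)-sorted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DataFormatError,
    DataValidationError,
    EmptyResultError,
    InputError,
)
from .naming import chrom_to_int, format_locus

logger = logging.getLogger(__name__)

#: canonical environments of the growth assay (any subset is accepted)
ENVIRONMENTS = (
    "ethanol", "fructose", "glucose", "glycerol", "lactose", "maltose", "sucrose",
)
#: canonical growth parameters
PARAMETERS = ("doubling_time", "maxOD")

MARKER_COLUMNS = ["id", "chromosome", "position_bp", "position_cm"]


@dataclass(frozen=True)
class Marker:
    """A single biallelic marker on the genetic map."""

    id: str
    chromosome: int
    position_bp: int
    position_cm: float = float("nan")

    @property
    def locus(self) -> str:
        return format_locus(self.chromosome, self.position_bp)


def _normalize_marker_frame(markers: pd.DataFrame) -> pd.DataFrame:
    df = markers.copy()
    if "position_cm" not in df.columns:
        df["position_cm"] = np.nan
    missing = [c for c in ("id", "chromosome", "position_bp") if c not in df.columns]
    if missing:
        raise DataFormatError(f"marker table missing columns: {missing}")
    df["id"] = df["id"].astype(str)
    df["chromosome"] = df["chromosome"].map(chrom_to_int).astype(int)
    df["position_bp"] = df["position_bp"].astype(int)
    df["position_cm"] = df["position_cm"].astype(float)
    return df.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Segregant x marker matrix of parental calls.

    ``calls[i, j]`` is 1.0 (S allele), 0.0 (Y allele) or NaN (missing) for
    segregant ``i`` at marker ``j``.  Markers are sorted by
    (chromosome, position_bp) at construction.
    """

    segregant_ids: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.markers = _normalize_marker_frame(self.markers)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.segregant_ids), len(self.markers)):
            raise DataValidationError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.segregant_ids)} segregants x {len(self.markers)} markers"
            )
        finite = self.calls[np.isfinite(self.calls)]
        bad = finite[(finite != 0.0) & (finite != 1.0)]
        if bad.size:
            raise DataValidationError(
                f"genotype calls must be 0, 1 or NaN; found {sorted(set(bad))[:5]}"
            )
        order = np.lexsort(
            (self.markers["position_bp"].to_numpy(), self.markers["chromosome"].to_numpy())
        )
        if not np.array_equal(order, np.arange(len(order))):
            self.markers = self.markers.iloc[order].reset_index(drop=True)
            self.calls = self.calls[:, order]
        dup = self.markers.duplicated(subset=["chromosome", "position_bp"])
        if dup.any():
            name = self.markers.loc[dup.idxmax(), "id"]
            raise DataValidationError(f"duplicate (chromosome, bp) position at marker {name}")

    @property
    def n_segregants(self) -> int:
        return len(self.segregant_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker(self, j: int) -> Marker:
        row = self.markers.iloc[j]
        return Marker(row["id"], int(row["chromosome"]), int(row["position_bp"]),
                      float(row["position_cm"]))

    def marker_index(self, marker_id: str) -> int:
        hits = np.flatnonzero((self.markers["id"] == marker_id).to_numpy())
        if hits.size == 0:
            raise KeyError(f"marker {marker_id!r} not in genotype matrix")
        return int(hits[0])

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.mean(np.isnan(self.calls), axis=0)

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-marker minor allele frequency (NaN where no calls)."""
        obs = np.isfinite(self.calls)
        count = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(count > 0,
                         np.nansum(self.calls, axis=0) / np.maximum(count, 1),
                         np.nan)
        return np.minimum(p, 1.0 - p)


@dataclass
class PhenotypeTable:
    """Segregant x environment x parameter (x replicate) phenotype values.

    Missing values are NaN and stay NaN (never coerced to zero).  Scans consume
    replicate means; replicates only matter for heritability estimation.
    """

    segregant_ids: list[str]
    environments: list[str]
    parameters: list[str]
    values: np.ndarray  # (n_seg, n_env, n_param, n_rep)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 3:
            self.values = self.values[..., None]
        expected = (len(self.segregant_ids), len(self.environments), len(self.parameters))
        if self.values.shape[:3] != expected:
            raise DataValidationError(
                f"phenotype values shape {self.values.shape} inconsistent with axes {expected}"
            )

    @property
    def n_replicates(self) -> int:
        return self.values.shape[3]

    def get(self, parameter: str, environment: str, *, replicates: bool = False) -> np.ndarray:
        """Phenotype vector for one (parameter, environment).

        Returns the replicate mean (ignoring missing replicates) unless
        ``replicates=True``, in which case the (n_seg, n_rep) slab is returned.
        """
        e = self.environments.index(environment)
        p = self.parameters.index(parameter)
        slab = self.values[:, e, p, :]
        if replicates:
            return slab
        obs = np.isfinite(slab)
        n = obs.sum(axis=1)
        return np.where(n > 0, np.nansum(np.where(obs, slab, 0.0), axis=1)
                        / np.maximum(n, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: segregant, environment, parameter, replicate, value."""
        n_s, n_e, n_p, n_r = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.segregant_ids, self.environments, self.parameters, range(1, n_r + 1)],
            names=["segregant", "environment", "parameter", "replicate"],
        )
        df = pd.DataFrame({"value": self.values.reshape(-1)}, index=idx).reset_index()
        return df.dropna(subset=["value"]).reset_index(drop=True)


@dataclass
class CrossDataset:
    """Genotypes + phenotypes for one segregant panel, identically ordered."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable

    def __post_init__(self) -> None:
        if self.genotypes.segregant_ids != self.phenotypes.segregant_ids:
            raise DataValidationError(
                "segregant ids differ between genotype and phenotype components"
            )

    @property
    def segregant_ids(self) -> list[str]:
        return self.genotypes.segregant_ids


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_DEFAULT_CODES = {"S": 1.0, "Y": 0.0}
_DEFAULT_MISSING = {"", "NA", "N/A", "NAN", "-"}


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, sniffing tab vs comma from the header line."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise DataFormatError(f"{path}: empty file or blank header")
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_genotypes(
    genotype_path: str | Path,
    map_path: str | Path | None = None,
    *,
    codes: Mapping[str, float] = _DEFAULT_CODES,
    missing_codes: Iterable[str] = _DEFAULT_MISSING,
) -> GenotypeMatrix:
    """Read a genotype table (one row per marker, one column per segregant).

    The genotype file needs a ``marker`` (or ``id``) column; ``chromosome`` and
    ``position_bp`` may be in the genotype file itself or in a separate map
    file keyed by marker id.
    """
    df = _read_table(genotype_path)
    df.columns = [c.strip() for c in df.columns]
    cols = {c.lower(): c for c in df.columns}
    id_col = cols.get("marker") or cols.get("id")
    if id_col is None:
        raise DataFormatError(f"{genotype_path}: no 'marker' or 'id' column in header")

    meta_cols = [id_col]
    marker_meta = pd.DataFrame({"id": df[id_col].astype(str)})
    for want in ("chromosome", "position_bp", "position_cm", "ref", "alt", "type"):
        if want in cols:
            marker_meta[want] = df[cols[want]]
            meta_cols.append(cols[want])

    if map_path is not None:
        mp = _read_table(map_path)
        mp.columns = [c.strip().lower() for c in mp.columns]
        if "marker" in mp.columns:
            mp = mp.rename(columns={"marker": "id"})
        if "id" not in mp.columns:
            raise DataFormatError(f"{map_path}: no 'marker'/'id' column")
        marker_meta = marker_meta[["id"] + [c for c in ("ref", "alt", "type")
                                           if c in marker_meta.columns]]
        marker_meta = marker_meta.merge(mp, on="id", how="left")
    for req in ("chromosome", "position_bp"):
        if req not in marker_meta.columns or (marker_meta[req].astype(str) == "").any():
            raise DataFormatError(
                f"marker positions incomplete: column {req!r} absent or blank "
                f"(supply it in the genotype file or a map file)"
            )

    seg_cols = [c for c in df.columns if c not in meta_cols]
    if not seg_cols:
        raise DataFormatError(f"{genotype_path}: no segregant columns found")
    missing_set = {m.upper() for m in missing_codes}
    code_map = {str(k): float(v) for k, v in codes.items()}
    raw = df[seg_cols].to_numpy(dtype=str)
    calls = np.full(raw.shape, np.nan)
    unmatched_mask = np.ones(raw.shape, dtype=bool)
    for code, val in code_map.items():
        hit = raw == code
        calls[hit] = val
        unmatched_mask &= ~hit
    for m in missing_set:
        unmatched_mask &= ~(np.char.upper(raw) == m)
    if unmatched_mask.any():
        i, j = np.argwhere(unmatched_mask)[0]
        raise DataValidationError(
            f"non-biallelic genotype code {raw[i, j]!r} at marker "
            f"{marker_meta['id'].iloc[i]!r} (segregant {seg_cols[j]!r})"
        )
    # rows are markers -> transpose to segregant x marker
    return GenotypeMatrix(list(seg_cols), marker_meta, calls.T)


def read_phenotypes(phenotype_path: str | Path) -> PhenotypeTable:
    """Read a long-format phenotype table.

    Required columns: segregant, environment, parameter, value; an optional
    replicate column distinguishes repeated measurements.
    """
    df = _read_table(phenotype_path)
    df.columns = [c.strip().lower() for c in df.columns]
    for req in ("segregant", "environment", "parameter", "value"):
        if req not in df.columns:
            raise DataFormatError(f"{phenotype_path}: missing column {req!r}")
    if "replicate" not in df.columns:
        df["replicate"] = "1"
    segs = list(dict.fromkeys(df["segregant"]))
    envs = list(dict.fromkeys(df["environment"]))
    params = list(dict.fromkeys(df["parameter"]))
    reps = sorted(set(df["replicate"]))
    values = np.full((len(segs), len(envs), len(params), len(reps)), np.nan)
    s_ix = {s: i for i, s in enumerate(segs)}
    e_ix = {e: i for i, e in enumerate(envs)}
    p_ix = {p: i for i, p in enumerate(params)}
    r_ix = {r: i for i, r in enumerate(reps)}
    def _parse(x: str) -> float:
        # python float() is correctly rounded (pandas' fast parser is not),
        # keeping the write -> read round trip bit-exact
        try:
            return float(x)
        except ValueError:
            return float("nan")

    val = df["value"].map(_parse)
    values[
        df["segregant"].map(s_ix).to_numpy(),
        df["environment"].map(e_ix).to_numpy(),
        df["parameter"].map(p_ix).to_numpy(),
        df["replicate"].map(r_ix).to_numpy(),
    ] = val.to_numpy()
    return PhenotypeTable(segs, envs, params, values)


def read_cross(
    genotype_path: str | Path,
    phenotype_path: str | Path,
    map_path: str | Path | None = None,
    *,
    codes: Mapping[str, float] = _DEFAULT_CODES,
    missing_codes: Iterable[str] = _DEFAULT_MISSING,
) -> CrossDataset:
    """Read and align genotype + phenotype tables into a CrossDataset.

    Segregants present in only one of the two files are dropped with a logged
    warning; zero overlap is an error.
    """
    g = read_genotypes(genotype_path, map_path, codes=codes, missing_codes=missing_codes)
    p = read_phenotypes(phenotype_path)
    shared = [s for s in g.segregant_ids if s in set(p.segregant_ids)]
    if not shared:
        raise InputError("no segregants shared between genotype and phenotype files")
    dropped = (set(g.segregant_ids) | set(p.segregant_ids)) - set(shared)
    if dropped:
        logger.warning(
            "dropping %d segregant(s) present in only one input: %s",
            len(dropped), sorted(dropped)[:10],
        )
    g_ix = [g.segregant_ids.index(s) for s in shared]
    p_ix = [p.segregant_ids.index(s) for s in shared]
    g2 = GenotypeMatrix(shared, g.markers, g.calls[g_ix])
    p2 = PhenotypeTable(shared, p.environments, p.parameters, p.values[p_ix])
    logger.info("read cross: %d segregants, %d markers, %d environments x %d parameters",
                len(shared), g2.n_markers, len(p2.environments), len(p2.parameters))
    return CrossDataset(g2, p2)


def filter_markers(
    g: GenotypeMatrix,
    max_missing: float = 1.0,
    min_maf: float = 0.0,
    snp_only: bool = False,
) -> GenotypeMatrix:
    """Drop markers exceeding a missingness cap, below a MAF floor, or non-SNP.

    The SNP filter needs ``ref``/``alt`` (single-base alleles) or ``type``
    (== 'snp') columns in the marker table; without them it is a logged no-op.
    Idempotent; marker order preserved.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    keep = g.missing_fraction() <= max_missing
    if min_maf > 0:
        maf = g.minor_allele_frequency()
        keep &= np.nan_to_num(maf, nan=-1.0) >= min_maf
    if snp_only:
        cols = g.markers.columns
        if "ref" in cols and "alt" in cols:
            keep &= (
                (g.markers["ref"].astype(str).str.len() == 1)
                & (g.markers["alt"].astype(str).str.len() == 1)
            ).to_numpy()
        elif "type" in cols:
            keep &= (g.markers["type"].astype(str).str.lower() == "snp").to_numpy()
        else:
            logger.warning("snp_only requested but marker table has no ref/alt or type column")
    if not keep.any():
        raise EmptyResultError("all markers removed by filters")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_markers: removed %d of %d markers", n_drop, g.n_markers)
    return GenotypeMatrix(
        list(g.segregant_ids), g.markers.loc[keep].reset_index(drop=True), g.calls[:, keep]
    )


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "scan_type", "parameter", "environments", "loci", "lod", "p_value",
    "gei_class", "effect", "effect_se", "variance_explained", "anchored", "detail",
]


def _fmt(x: object) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        if np.isnan(x):
            return ""
        return repr(x)
    if isinstance(x, bool):
        return "true" if x else "false"
    return str(x)


def write_results(calls: Sequence, path: str | Path) -> Path:
    """Write a list of call records (Qtl/Gei/Interaction) to a TSV.

    The layout is a fixed superset of columns; loci are printed in
    ``chrXIV(465,189)`` notation, multiple loci joined with ``-``.  Output is
    bit-identical across runs for the same call objects.
    """
    path = Path(path)
    rows = [c.to_row() for c in calls]
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c)) for c in RESULT_COLUMNS) + "\n")
    return path


def read_results(path: str | Path) -> list:
    """Read back a TSV written by :func:`write_results` into call objects."""
    from .qtl_scan import QtlCall
    from .gei_scan import GeiCall
    from .epistasis_scan import InteractionCall

    by_type = {"single": QtlCall, "gei": GeiCall,
               "pair": InteractionCall, "anchored_pair": InteractionCall,
               "triple": InteractionCall}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != RESULT_COLUMNS:
        raise DataFormatError(f"{path}: unexpected result columns {list(df.columns)}")
    out = []
    for _, row in df.iterrows():
        cls = by_type.get(row["scan_type"])
        if cls is None:
            raise DataFormatError(f"{path}: unknown scan_type {row['scan_type']!r}")
        out.append(cls.from_row(row.to_dict()))
    return out


# ---------------------------------------------------------------------------
# dataset writers (so the pipeline is closed under simulation)
# ---------------------------------------------------------------------------

def write_genotypes(g: GenotypeMatrix, genotype_path: str | Path,
                    map_path: str | Path | None = None) -> None:
    """Write marker x segregant genotype TSV (S/Y/NA codes) and optionally a map TSV."""
    inv = {1.0: "S", 0.0: "Y"}
    with open(genotype_path, "w") as fh:
        fh.write("marker\tchromosome\tposition_bp\t" + "\t".join(g.segregant_ids) + "\n")
        for j in range(g.n_markers):
            row = g.markers.iloc[j]
            codes = [inv.get(v, "NA") for v in g.calls[:, j]]
            fh.write(f"{row['id']}\t{int(row['chromosome'])}\t{int(row['position_bp'])}\t"
                     + "\t".join(codes) + "\n")
    if map_path is not None:
        g.markers[["id", "chromosome", "position_bp", "position_cm"]].rename(
            columns={"id": "marker"}
        ).to_csv(map_path, sep="\t", index=False)


def write_phenotypes(p: PhenotypeTable, path: str | Path) -> None:
    """Write the long-format phenotype TSV (full float precision, so the
    write->read round trip is exact)."""
    df = p.to_frame()
    df["value"] = df["value"].map(repr)
    df.to_csv(path, sep="\t", index=False)
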