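"""Cross-environment correlations, broad-sense heritability, effect tables.

These are the descriptive layers around the scans: pairwise-complete Pearson
correlations of a growth parameter between environments, a replicate-based
one-way random-effects decomposition for broad-sense heritability, and
per-genotype-class mean +/- SE tables for 1-3 loci (the data behind
reaction-norm and interaction scatter plots).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross_data import CrossDataset, PhenotypeTable
from .errors import InsufficientDataError
from .epistasis_scan import genotype_class_means


@dataclass
class CorrelationMatrix:
    """Environments x environments Pearson r for one parameter."""

    parameter: str
    r: pd.DataFrame          # symmetric, diagonal 1
    n: pd.DataFrame          # pairwise-complete sample sizes

    def range(self) -> tuple[float, float]:
        """(min, max) off-diagonal correlation."""
        vals = self.r.to_numpy()
        off = vals[~np.eye(len(vals), dtype=bool)]
        off = off[np.isfinite(off)]
        return float(off.min()), float(off.max())


def env_correlations(p: PhenotypeTable, parameter: str) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations between environments.

    Each environment pair needs at least 3 pairwise-complete segregants,
    otherwise its entry is NaN.
    """
    envs = p.environments
    k = len(envs)
    r = np.eye(k)
    n = np.zeros((k, k), dtype=int)
    vecs = {e: p.get(parameter, e) for e in envs}
    for i in range(k):
        n[i, i] = int(np.isfinite(vecs[envs[i]]).sum())
    for i, j in itertools.combinations(range(k), 2):
        a, b = vecs[envs[i]], vecs[envs[j]]
        ok = np.isfinite(a) & np.isfinite(b)
        n[i, j] = n[j, i] = int(ok.sum())
        if ok.sum() < 3 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
            r[i, j] = r[j, i] = np.nan
        else:
            r[i, j] = r[j, i] = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return CorrelationMatrix(
        parameter,
        pd.DataFrame(r, index=envs, columns=envs),
        pd.DataFrame(n, index=envs, columns=envs),
    )


@dataclass
class HeritabilityEstimate:
    """Broad-sense heritability from replicate measurements."""

    parameter: str
    environment: str
    h2: float
    var_between: float       # genetic (between-segregant) variance component
    var_within: float        # residual (within-segregant) variance component
    n_segregants: int
    mean_replicates: float


def broad_heritability(p: PhenotypeTable, parameter: str,
                       environment: str) -> HeritabilityEstimate:
    """One-way random-effects H2 = var_between / (var_between + var_within).

    Variance components come from the ANOVA mean squares with the unbalanced
    replicate-count correction n0 = (N - sum(n_i^2)/N) / (k - 1); a negative
    between-segregant component is truncated to 0.  Requires >= 2 replicates
    for >= 10 segregants.
    """
    slab = p.get(parameter, environment, replicates=True)  # (n_seg, n_rep)
    counts = np.isfinite(slab).sum(axis=1)
    use = counts >= 2
    if int(use.sum()) < 10:
        raise InsufficientDataError(
            f"{parameter}/{environment}: need >= 2 replicates for >= 10 segregants "
            f"(have {int(use.sum())})"
        )
    groups = [slab[i][np.isfinite(slab[i])] for i in np.flatnonzero(use)]
    k = len(groups)
    ns = np.array([g.size for g in groups], dtype=float)
    N = ns.sum()
    grand = np.concatenate(groups).mean()
    ss_b = float(sum(n_i * (g.mean() - grand) ** 2 for n_i, g in zip(ns, groups)))
    ss_w = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_b = ss_b / (k - 1)
    ms_w = ss_w / (N - k) if N > k else 0.0
    n0 = (N - (ns ** 2).sum() / N) / (k - 1)
    var_b = max((ms_b - ms_w) / n0, 0.0)
    var_w = ms_w
    total = var_b + var_w
    h2 = var_b / total if total > 0 else 1.0  # zero residual noise: all genetic
    return HeritabilityEstimate(parameter, environment, float(h2), var_b, var_w,
                                k, float(ns.mean()))


def effect_table(d: CrossDataset, marker_ids: list[str], parameter: str,
                 environment: str) -> pd.DataFrame:
    """Per-genotype-class mean +/- SE table for 1-3 loci.

    Rows are the 2/4/8 genotype classes keyed by S/Y words in the stated
    locus order (e.g. 'SYS'), with columns genotype, mean, se, n.
    """
    if not 1 <= len(marker_ids) <= 3:
        raise ValueError("effect_table supports 1-3 loci")
    means = genotype_class_means(d, marker_ids, parameter, environment)
    rows = [{"genotype": k, "mean": v[0], "se": v[1], "n": v[2]}
            for k, v in means.items()]
    return pd.DataFrame(rows, columns=["genotype", "mean", "se", "n"])
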