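"""Nested least-squares LOD machinery shared by all scans.

For Gaussian linear models fitted by least squares, the LOD score of an
alternative model against a nested null is

    LOD = (n/2) * log10(RSS_null / RSS_alt),

with n the number of observations.  All scan statistics in this package
(single-environment Haley-Knott, gene-environment interaction, two- and
three-locus epistasis) are of this form and differ only in the two design
matrices.  Scalar entry points here use explicit least-squares fits; the
vectorized routines compute the same quantities for many markers and many
permutations at once through projections, and are validated against the
scalar path in the test suite.
"""

from __future__ import annotations

import numpy as np

from .errors import InsufficientDataError

#: RSS ratio guard: a perfect fit is capped so LOD stays finite
RSS_EPS = 1e-12


def lod_from_rss(n: int, rss_null: float, rss_alt: float) -> float:
    """(n/2) * log10(RSS_null/RSS_alt), capped for (near-)perfect fits."""
    if rss_null <= 0.0:
        return 0.0
    rss_alt = max(rss_alt, RSS_EPS * rss_null)
    return max(0.5 * n * np.log10(rss_null / rss_alt), 0.0)


def fit_rss(y: np.ndarray, X: np.ndarray) -> float:
    """Residual sum of squares of the least-squares fit of y on columns of X."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def nested_lod(y: np.ndarray, X_null: np.ndarray, X_extra: np.ndarray) -> float:
    """LOD of the model [X_null | X_extra] against the model X_null."""
    y = np.asarray(y, dtype=float)
    rss0 = fit_rss(y, X_null)
    rss1 = fit_rss(y, np.column_stack([X_null, X_extra]))
    return lod_from_rss(len(y), rss0, rss1)


# ---------------------------------------------------------------------------
# vectorized single-predictor scan (Haley-Knott)
# ---------------------------------------------------------------------------

def _standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center columns and scale to unit norm; flag (near-)constant columns."""
    Xc = X - X.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Xc, axis=0)
    scale = np.max(np.abs(X), axis=0) + 1.0
    degenerate = norms <= 1e-10 * scale * np.sqrt(X.shape[0])
    safe = np.where(degenerate, 1.0, norms)
    return Xc / safe, degenerate


def single_scan_lods(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """LOD of y ~ mu + b*x for every column x of X.

    Uses LOD = -(n/2)*log10(1 - r^2): for a single regressor the RSS ratio is
    1 - r^2 of the simple regression.  Constant columns get LOD 0.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise InsufficientDataError("need at least 3 observations for a scan")
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm <= 0:
        return np.zeros(X.shape[1])
    Xs, degenerate = _standardize_columns(X)
    r = (yc / ynorm) @ Xs
    r2 = np.clip(r * r, 0.0, 1.0 - RSS_EPS)
    lod = -0.5 * n * np.log10(1.0 - r2)
    lod[degenerate] = 0.0
    return lod


def single_scan_perm_max(
    y: np.ndarray, X: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Genome-wide maximum single-scan LOD for each phenotype permutation."""
    y = np.asarray(y, dtype=float)
    n = y.size
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    Xs, degenerate = _standardize_columns(X)
    if ynorm <= 0 or bool(degenerate.all()):
        return np.zeros(n_perm)
    Xs = Xs[:, ~degenerate]
    P = np.empty((n_perm, n))
    for k in range(n_perm):
        P[k] = yc[rng.permutation(n)]
    R = (P / ynorm) @ Xs
    r2 = np.clip(R * R, 0.0, 1.0 - RSS_EPS)
    return (-0.5 * n * np.log10(1.0 - r2)).max(axis=1)


# ---------------------------------------------------------------------------
# vectorized paired two-environment (GEI) scan
# ---------------------------------------------------------------------------

def gei_scan_lods(
    ya: np.ndarray, yb: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interaction, additive and full-vs-null LODs for every column of X.

    Observations from the two environments are stacked (N = 2n).  Models:
      null      y ~ mu + bE*E
      additive  y ~ mu + bE*E + bg*x
      full      y ~ mu + bE*E + bg*x + bgE*x*E
    Returns (interaction_lod, additive_lod, full_lod) where
    interaction = full-vs-additive, additive = additive-vs-null,
    full = full-vs-null; full = additive + interaction by construction.

    Derivation used here: after projecting out [1, E], the phenotype residual
    is (a, b) = per-environment centered halves; the residualized genotype
    column is (xc, xc) and the residualized product term is orthogonalized to
    it as (-xc/2, +xc/2), with xc the centered genotype.  The additive fit
    therefore depends on (a+b).xc and the interaction fit on (b-a).xc.
    """
    ya = np.asarray(ya, dtype=float)
    yb = np.asarray(yb, dtype=float)
    n = ya.size
    N = 2 * n
    a = ya - ya.mean()
    b = yb - yb.mean()
    rss_null = float(a @ a + b @ b)
    Xc, degenerate = _standardize_columns(X)  # unit-norm centered columns
    s_add = (a + b) @ Xc
    s_int = (b - a) @ Xc
    # ||(xc,xc)||^2 = 2, ||(-xc/2, xc/2)||^2 = 1/2 on the unit-norm scale
    ss_add = s_add * s_add / 2.0
    ss_int = s_int * s_int / 2.0
    rss_a = np.maximum(rss_null - ss_add, 0.0)
    rss_f = np.maximum(rss_a - ss_int, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod_int = np.array([lod_from_rss(N, ra, rf) for ra, rf in zip(rss_a, rss_f)])
        lod_add = np.array([lod_from_rss(N, rss_null, ra) for ra in rss_a])
    lod_int[degenerate] = 0.0
    lod_add[degenerate] = 0.0
    return lod_int, lod_add, lod_add + lod_int


def gei_scan_perm_max(
    ya: np.ndarray, yb: np.ndarray, X: np.ndarray, n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Max interaction LOD per permutation of segregant identity.

    Each permutation reassigns whole (envA, envB) phenotype pairs to
    segregants, preserving the between-environment phenotype correlation
    under the null.
    """
    ya = np.asarray(ya, dtype=float)
    yb = np.asarray(yb, dtype=float)
    n = ya.size
    N = 2 * n
    a = ya - ya.mean()
    b = yb - yb.mean()
    rss_null = float(a @ a + b @ b)
    Xc, degenerate = _standardize_columns(X)
    Xc = Xc[:, ~degenerate]
    if Xc.shape[1] == 0 or rss_null <= 0:
        return np.zeros(n_perm)
    Sa = np.empty((n_perm, n))
    Si = np.empty((n_perm, n))
    add = a + b
    dif = b - a
    for k in range(n_perm):
        p = rng.permutation(n)
        Sa[k] = add[p]
        Si[k] = dif[p]
    Da = Sa @ Xc
    Di = Si @ Xc
    ss_add = Da * Da / 2.0
    ss_int = Di * Di / 2.0
    rss_a = np.maximum(rss_null - ss_add, 0.0)
    rss_f = np.maximum(rss_a - ss_int, RSS_EPS * rss_null)
    lod = 0.5 * N * np.log10(np.maximum(rss_a, RSS_EPS * rss_null) / rss_f)
    lod = np.maximum(lod, 0.0)
    return lod.max(axis=1)


# ---------------------------------------------------------------------------
# interaction-set machinery (pairs / triples with set-max permutation nulls)
# ---------------------------------------------------------------------------

class InteractionDesigns:
    """Precomputed designs for a set of locus tuples sharing one phenotype.

    For tuple t with base design A_t (intercept, main effects and, for
    triples, pairwise products) and interaction column w_t, store an
    orthonormal basis Q_t of A_t and the unit vector u_t = residual of w_t
    against Q_t.  For any phenotype vector y:

        RSS_base(t) = ||y||^2 - ||Q_t' y||^2
        RSS_full(t) = RSS_base(t) - (u_t' y)^2

    so observed statistics and all permutation statistics reduce to one
    matrix product against [Q_1 u_1 Q_2 u_2 ...].
    """

    def __init__(self, base_designs: list[np.ndarray], int_columns: list[np.ndarray]):
        self.n = base_designs[0].shape[0] if base_designs else 0
        self.n_tuples = len(base_designs)
        qs, us, ok = [], [], []
        width = []
        for A, w in zip(base_designs, int_columns):
            Q, R = np.linalg.qr(A)
            keep = np.abs(np.diag(R)) > 1e-9 * max(1.0, np.abs(R).max())
            Q = Q[:, keep]
            u = w - Q @ (Q.T @ w)
            nu = np.linalg.norm(u)
            # rank-deficient interaction term (e.g. collinear loci): unusable
            valid = nu > 1e-8 * max(1.0, np.linalg.norm(w))
            u = u / nu if valid else np.zeros_like(u)
            qs.append(Q)
            us.append(u)
            ok.append(valid)
            width.append(Q.shape[1])
        self.valid = np.array(ok, dtype=bool)
        self._widths = width
        if self.n_tuples:
            self._M = np.concatenate(
                [np.column_stack([q, u[:, None]]) for q, u in zip(qs, us)], axis=1
            )
        else:
            self._M = np.zeros((self.n, 0))

    def lods(self, Y: np.ndarray) -> np.ndarray:
        """Interaction LODs, shape (n_phenotypes, n_tuples); Y is (k, n)."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        yss = np.einsum("ij,ij->i", Y, Y)[:, None]
        D = Y @ self._M  # (k, sum(width+1))
        lods = np.zeros((Y.shape[0], self.n_tuples))
        col = 0
        for t, w in enumerate(self._widths):
            proj = D[:, col:col + w]
            uy = D[:, col + w]
            col += w + 1
            if not self.valid[t]:
                continue
            rss_base = np.maximum(yss[:, 0] - np.einsum("ij,ij->i", proj, proj), 0.0)
            rss_full = np.maximum(rss_base - uy * uy, RSS_EPS * np.maximum(rss_base, 1e-300))
            good = rss_base > 0
            lods[good, t] = np.maximum(
                0.5 * self.n * np.log10(rss_base[good] / rss_full[good]), 0.0
            )
        return lods

    def perm_max(self, y: np.ndarray, n_perm: int, rng: np.random.Generator,
                 return_matrix: bool = False):
        """Set-maximum interaction LOD per phenotype permutation."""
        y = np.asarray(y, dtype=float)
        P = np.empty((n_perm, y.size))
        for k in range(n_perm):
            P[k] = y[rng.permutation(y.size)]
        L = self.lods(P)
        return L if return_matrix else L.max(axis=1)


def make_pair_designs(y_len: int, xs: list[tuple[np.ndarray, np.ndarray]]) -> InteractionDesigns:
    """Designs for two-locus tuples: base [1, x1, x2], interaction x1*x2."""
    ones = np.ones(y_len)
    bases, ints = [], []
    for x1, x2 in xs:
        bases.append(np.column_stack([ones, x1, x2]))
        ints.append(x1 * x2)
    return InteractionDesigns(bases, ints)


def make_triple_designs(
    y_len: int, xs: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
) -> InteractionDesigns:
    """Designs for three-locus tuples: base has mains + all pairwise products,
    interaction is the three-way product, so the LOD isolates the pure
    three-way contrast."""
    ones = np.ones(y_len)
    bases, ints = [], []
    for x1, x2, x3 in xs:
        bases.append(np.column_stack([ones, x1, x2, x3, x1 * x2, x1 * x3, x2 * x3]))
        ints.append(x1 * x2 * x3)
    return InteractionDesigns(bases, ints)
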