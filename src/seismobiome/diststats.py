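"""Dissimilarity matrices, Mantel permutation tests, principal coordinates.

The study's multivariate chain: per-window seismic energy and precipitation
become 1-D Euclidean dissimilarity matrices; the 0–1-scaled geochemistry
becomes a multivariate Euclidean matrix; the singleton-filtered OTU table a
Bray-Curtis matrix. Mantel permutation regressions relate the matrices;
principal coordinates (PCO, metric MDS via Gower double-centering) ordins
the geochemical matrix, and the leading axis is regressed on window energy.

Conventions fixed here (the upstream software, PAST, leaves them
unstated): Mantel permutes rows and columns of the second matrix
simultaneously; for n ≤ 5 samples all n! relabelings are enumerated and
the p-value is exact, otherwise Monte-Carlo sampling with the add-one
correction ``p = (1 + hits) / (1 + n_perm)``; the default tail is
two-sided on r. PCO applies no Lingoes/Cailliez correction — negative
eigenvalues are reported as such, and axis percent-variance is relative to
the sum of positive eigenvalues. "adj R" of the axis regression is the
signed square root of the adjusted R², with the two-sided slope-t p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats as sstats
from skbio import DistanceMatrix

__all__ = [
    "MantelResult",
    "PcoResult",
    "AxisRegression",
    "euclidean_matrix",
    "braycurtis_matrix",
    "mantel",
    "pco",
    "axis_regression",
]


def _as_labels(labels, n):
    return [str(x) for x in (labels if labels is not None else range(n))]


def euclidean_matrix(data, labels=None) -> DistanceMatrix:
    """Pairwise Euclidean distances between rows.

    ``data`` may be a DataFrame (rows = samples; the index provides labels),
    a 2-D array, or a 1-D sequence of per-window scalars (energy,
    precipitation), for which the distance is |xi - xj|. NaNs are rejected
    with the offending row/column named.
    """
    if isinstance(data, pd.DataFrame):
        if data.isna().any().any():
            bad_cols = list(data.columns[data.isna().any()])
            bad_rows = list(data.index[data.isna().any(axis=1)])
            raise ValueError(f"NaN values in rows {bad_rows}, columns {bad_cols}")
        labels = labels if labels is not None else data.index
        mat = data.to_numpy(dtype=float)
    else:
        mat = np.asarray(data, dtype=float)
        if np.isnan(mat).any():
            raise ValueError(f"NaN values at positions {np.argwhere(np.isnan(mat)).tolist()}")
    if mat.ndim == 1:
        mat = mat[:, None]
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    d = squareform(pdist(mat, metric="euclidean"))
    return DistanceMatrix(d, ids=_as_labels(labels, mat.shape[0]))


def braycurtis_matrix(otu_table) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between sampling dates of an OtuTable.

    BC(i,j) = Σ|x_i − x_j| / Σ(x_i + x_j) over OTUs; 0 = identical,
    1 = disjoint communities. Apply singleton filtering first.
    """
    ab = otu_table.abundance if hasattr(otu_table, "abundance") else pd.DataFrame(otu_table)
    samples = ab.T  # rows = sampling dates
    totals = samples.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError(
            f"all-zero sample(s): {list(totals.index[totals <= 0])}; Bray-Curtis undefined"
        )
    d = squareform(pdist(samples.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(d, ids=_as_labels(samples.index, samples.shape[0]))


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str
    seed: int | None
    method: str  # "exact" (exhaustive) or "monte-carlo"

    def __post_init__(self):
        if not (-1 - 1e-9 <= self.r <= 1 + 1e-9):
            raise ValueError("Mantel r outside [-1, 1]")
        if not (0 < self.p <= 1):
            raise ValueError("p-value outside (0, 1]")


_TIE_EPS = 1e-12


def _tail_hits(r_perm, r_obs, tail):
    if tail == "two-sided":
        return np.abs(r_perm) >= np.abs(r_obs) - _TIE_EPS
    if tail == "greater":
        return r_perm >= r_obs - _TIE_EPS
    if tail == "less":
        return r_perm <= r_obs + _TIE_EPS
    raise ValueError(f"unknown tail {tail!r}")


def _tri_r(a_tri, b_tris):
    """Pearson r of a fixed triangle against one or many triangles."""
    b = np.atleast_2d(b_tris)
    ac = a_tri - a_tri.mean()
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac**2).sum() * (bc**2).sum(axis=1))
    if np.any(denom == 0):
        raise ValueError("zero-variance distance triangle; Mantel r undefined")
    return (bc @ ac) / denom


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    tail: str = "two-sided",
    exhaustive_max_n: int = 5,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of corresponding lower-triangle entries;
    the null distribution permutes the rows and columns of ``b``
    simultaneously. For ``n <= exhaustive_max_n`` all n! relabelings are
    enumerated (exact p, the identity included); otherwise ``n_perm``
    Monte-Carlo draws with add-one correction. Labels must match.
    """
    if list(a.ids) != list(b.ids):
        raise ValueError(f"label mismatch: {list(a.ids)} vs {list(b.ids)}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    iu = np.triu_indices(n, k=1)
    A = a.data
    B = b.data
    a_tri = A[iu]
    r_obs = float(_tri_r(a_tri, B[iu])[0])

    if n <= exhaustive_max_n:
        perms = np.array(list(permutations(range(n))))
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        method = "monte-carlo"
    rows = perms[:, iu[0]]
    cols = perms[:, iu[1]]
    r_perm = _tri_r(a_tri, B[rows, cols])
    hits = _tail_hits(r_perm, r_obs, tail)
    if method == "exact":
        p = float(hits.sum()) / len(perms)
        n_eff = len(perms)
    else:
        p = (1.0 + float(hits.sum())) / (1.0 + n_perm)
        n_eff = n_perm
    return MantelResult(r=r_obs, p=p, n_perm=n_eff, tail=tail, seed=seed, method=method)


@dataclass
class PcoResult:
    eigenvalues: np.ndarray  # descending, negatives included
    scores: pd.DataFrame  # samples × positive axes
    pct_variance: np.ndarray  # per axis, relative to sum of positive eigenvalues

    @property
    def n_positive(self) -> int:
        return self.scores.shape[1]


def pco(dm: DistanceMatrix) -> PcoResult:
    """Principal coordinates (Gower) of a dissimilarity matrix.

    Double-centres −½ D∘D, eigendecomposes, and sorts axes by eigenvalue.
    Scores are returned for positive axes only (scaled by √λ); negative
    eigenvalues are reported, not corrected. For a Euclidean input the
    pairwise distances among scores reproduce the input matrix.
    """
    D = dm.data
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    J = np.eye(n) - np.ones((n, n)) / n
    Bc = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(Bc)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] *= -1
    tol = max(np.abs(eigval).max(), 1.0) * 1e-12
    pos = eigval > tol
    pos_sum = eigval[pos].sum()
    pct = 100.0 * eigval / pos_sum
    scores = eigvec[:, pos] * np.sqrt(eigval[pos])
    cols = [f"PCO{i + 1}" for i in range(int(pos.sum()))]
    return PcoResult(
        eigenvalues=eigval,
        scores=pd.DataFrame(scores, index=list(dm.ids), columns=cols),
        pct_variance=pct,
    )


@dataclass(frozen=True)
class AxisRegression:
    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    adj_r: float  # sign(slope) * sqrt(max(adj R², 0))
    adj_p: float  # two-sided slope t-test p
    n: int

    def __post_init__(self):
        if abs(self.adj_r) > 1 + 1e-9:
            raise ValueError("|adj_r| must be <= 1")


def axis_regression(scores, covariate) -> AxisRegression:
    """OLS of ordination-axis scores on a per-window covariate.

    Reports the "adjusted R" convention: adj R² = 1 − (1 − R²)(n−1)/(n−2),
    adj_r = sign(slope)·√max(adj R², 0), with the two-sided p-value of the
    slope t-test.
    """
    y = np.asarray(scores, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("scores and covariate must be equal-length 1-D")
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance covariate")
    fit = sstats.linregress(x, y)
    r2 = fit.rvalue**2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    adj_r = math.copysign(math.sqrt(max(adj_r2, 0.0)), fit.slope) if fit.slope != 0 else 0.0
    return AxisRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2),
        adj_r_squared=float(adj_r2),
        adj_r=float(adj_r),
        adj_p=float(fit.pvalue),
        n=n,
    )
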