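"""Community dissimilarity and ordination statistics.

Implements the statistical layer shared by community ecology and
microbiome analysis: Bray–Curtis dissimilarity on raw (unstandardised)
abundances, 2-D non-metric multidimensional scaling minimising Kruskal
stress-1, the ANOSIM rank permutation test, Welch's two-sample t-test
and ordinary least-squares regression.  Bray–Curtis, NMDS and ANOSIM
are implemented here (they are the load-bearing pieces and their exact
conventions — no standardisation, stress-1, average ranks, +1-corrected
permutation p — matter); Welch and OLS delegate to scipy behind a thin
validating surface.

All stochastic routines take an explicit integer seed and reproduce
bit-identically from (inputs, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SampleTable",
    "DissimilarityMatrix",
    "Ordination2D",
    "AnosimResult",
    "RegressionResult",
    "DegeneratePairError",
    "bray_curtis",
    "nmds2",
    "anosim",
    "welch_t",
    "linreg",
    "REQUIRED_COLUMNS",
]

#: Leading metadata columns of a sample table; every later column is a species.
REQUIRED_COLUMNS = ["sample_id", "station_id", "lon", "lat", "depth_m"]


class DegeneratePairError(ValueError):
    """A pair of samples with zero total abundance has no Bray–Curtis value."""


@dataclass(frozen=True)
class SampleTable:
    """Per-sample species abundances with position and depth.

    Wraps a DataFrame whose columns are ``sample_id, station_id, lon,
    lat, depth_m`` followed by one column per species holding
    abundances in cells L⁻¹.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample table is missing required columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id values: {dups}")
        ab = self.abundances()
        if not np.issubdtype(ab.values.dtype, np.number):
            raise ValueError("species abundance columns must be numeric")
        if (ab.values < 0).any():
            rows = df.index[(ab.values < 0).any(axis=1)].tolist()
            raise ValueError(f"negative abundances in rows {rows}")
        if (df["depth_m"] < 0).any():
            raise ValueError("depth_m must be non-negative (positive down)")
        if (df["lat"].abs() > 90).any():
            raise ValueError("latitude outside [-90, 90]")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def species(self) -> list[str]:
        """Species column names (all columns after depth_m)."""
        cols = list(self.data.columns)
        return cols[cols.index("depth_m") + 1 :]

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].astype(str).tolist()

    def abundances(self) -> pd.DataFrame:
        return self.data[self.species]

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Labelled symmetric dissimilarity matrix with zero diagonal."""

    D: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError(f"dissimilarity matrix must be square, got {D.shape}")
        if len(self.labels) != D.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.isfinite(D).all():
            raise ValueError("dissimilarity matrix contains non-finite values")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(D), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix diagonal is not zero")
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0.0)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "labels", list(self.labels))

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy condensed order."""
        return squareform(self.D, checks=False)

    @property
    def n(self) -> int:
        return self.D.shape[0]


@dataclass(frozen=True)
class Ordination2D:
    """A 2-D NMDS configuration with its Kruskal stress-1."""

    coordinates: np.ndarray
    stress: float
    labels: list[str]
    n_restarts: int
    seed: int
    converged: bool
    stress_sequence: np.ndarray = field(default_factory=lambda: np.array([]))

    def coords_for(self, label: str) -> np.ndarray:
        try:
            return self.coordinates[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"label {label!r} not in ordination") from None


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    n_perm: int
    seed: int
    method: str = "permutation"


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# Bray–Curtis

def bray_curtis(table: SampleTable) -> DissimilarityMatrix:
    """Pairwise Bray–Curtis dissimilarity on raw abundances.

    BC[i, j] = Σ_n |s_n,i − s_n,j| / Σ_n (s_n,i + s_n,j) over the species
    n; no standardisation or transformation is applied first.  A pair of
    samples that are both entirely zero has an undefined index and
    raises :class:`DegeneratePairError` naming the samples.
    """
    if len(table) < 2:
        raise ValueError("Bray-Curtis needs at least 2 samples")
    X = table.abundances().to_numpy(dtype=float)
    num = squareform(pdist(X, metric="cityblock"), checks=False)
    totals = X.sum(axis=1)
    den = totals[:, None] + totals[None, :]
    ids = table.sample_ids
    bad = np.argwhere((den == 0) & ~np.eye(len(X), dtype=bool))
    if bad.size:
        i, j = bad[0]
        raise DegeneratePairError(
            f"samples {ids[i]!r} and {ids[j]!r} are both all-zero; "
            "Bray-Curtis is undefined for this pair"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(D=D, labels=ids)


# ---------------------------------------------------------------------------
# NMDS

def _classical_scaling_init(D: np.ndarray) -> np.ndarray:
    """Principal-coordinates (Torgerson) initial configuration in 2-D."""
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:2]
    w2 = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w2)[None, :]


def _stress1(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((dist**2).sum())
    if denom == 0.0:
        return 0.0
    return math.sqrt(float(((dist - dhat) ** 2).sum()) / denom)


class _MonotoneFit:
    """Isotonic (PAVA) regression of distances on a fixed dissimilarity order.

    Ties in the dissimilarities are pooled first (secondary approach:
    tied input values receive a common fitted disparity), then the
    pool-adjacent-violators pass runs on the tie-block means, weighted
    by block size.  The tie structure is precomputed once per NMDS
    problem since the dissimilarity vector never changes.
    """

    def __init__(self, dvec: np.ndarray) -> None:
        self.order = np.argsort(dvec, kind="stable")
        _, self.block = np.unique(dvec[self.order], return_inverse=True)
        self.counts = np.bincount(self.block).astype(float)
        self.inverse = np.empty_like(self.order)
        self.inverse[self.order] = np.arange(len(dvec))

    def __call__(self, dist: np.ndarray) -> np.ndarray:
        y = dist[self.order]
        block_mean = np.bincount(self.block, weights=y) / self.counts
        fitted = isotonic_regression(block_mean, weights=self.counts).x
        return fitted[self.block][self.inverse]


def _nmds_single(
    dvec: np.ndarray, X0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, np.ndarray, bool]:
    """One SMACOF run: isotonic fit + Guttman transform, monotone in stress."""
    n = X0.shape[0]
    iso = _MonotoneFit(dvec)
    X = X0.copy()
    dist = pdist(X)
    dhat = iso(dist)
    s = _stress1(dist, dhat)
    history = [s]
    converged = False
    iu = np.triu_indices(n, k=1)
    for _ in range(max_iter):
        # Guttman transform toward the current disparities
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        B = np.zeros((n, n))
        B[iu] = -ratio
        B = B + B.T
        np.fill_diagonal(B, -B.sum(axis=1))
        X_new = (B @ X) / n
        dist_new = pdist(X_new)
        dhat_new = iso(dist_new)
        s_new = _stress1(dist_new, dhat_new)
        if s_new > s:          # keep the sequence non-increasing
            converged = True
            break
        X, dist, dhat = X_new, dist_new, dhat_new
        history.append(s_new)
        if s - s_new < tol:
            converged = True
            s = s_new
            break
        s = s_new
    return X, s, np.asarray(history), converged


def nmds2(
    D: DissimilarityMatrix,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> Ordination2D:
    """2-D non-metric MDS minimising Kruskal stress-1.

    stress-1 = sqrt(Σ (d − d̂)² / Σ d²), where d are configuration
    distances and d̂ their isotonic (pool-adjacent-violators, average
    ranks for ties) regression on the input dissimilarity order.  The
    first start is a classical-scaling configuration — deterministic and
    equivariant under relabelling — followed by ``n_restarts − 1``
    seeded random starts; the lowest-stress solution is returned,
    centred and rotated to its principal axes with a fixed sign
    convention so results are reproducible.
    """
    n = D.n
    if n < 4:
        raise ValueError(f"NMDS needs at least 4 points, got {n}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    dvec = D.condensed()
    if dvec.max() == 0.0:
        # all points identical: the zero configuration is exact
        coords = np.zeros((n, 2))
        return Ordination2D(
            coordinates=coords, stress=0.0, labels=list(D.labels),
            n_restarts=n_restarts, seed=seed, converged=True,
            stress_sequence=np.array([0.0]),
        )

    scale = float(dvec.mean())
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, np.ndarray, bool] | None = None
    for r in range(n_restarts):
        X0 = (
            _classical_scaling_init(D.D)
            if r == 0
            else rng.standard_normal((n, 2)) * scale
        )
        result = _nmds_single(dvec, X0, max_iter, tol)
        if best is None or result[1] < best[1]:
            best = result

    X, stress, history, converged = best
    X = X - X.mean(axis=0)
    # rotate to principal axes; fix signs so the largest-|coordinate|
    # entry of each axis is positive
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    for ax in range(X.shape[1]):
        k = np.argmax(np.abs(X[:, ax]))
        if X[k, ax] < 0:
            X[:, ax] = -X[:, ax]
    return Ordination2D(
        coordinates=X, stress=stress, labels=list(D.labels),
        n_restarts=n_restarts, seed=seed, converged=converged,
        stress_sequence=history,
    )


# ---------------------------------------------------------------------------
# ANOSIM

def _anosim_R(ranks: np.ndarray, same_group: np.ndarray, M: int) -> float:
    r_within = ranks[same_group].mean()
    r_between = ranks[~same_group].mean()
    return float((r_between - r_within) / (M / 2.0))


def _count_distinct_assignments(sizes: list[int]) -> int:
    total = math.factorial(sum(sizes))
    for s in sizes:
        total //= math.factorial(s)
    return total


def _multiset_permutations(items: list):
    """All distinct orderings of a multiset (recursive generator, small n only)."""
    if len(items) <= 1:
        yield tuple(items)
        return
    seen = set()
    for k in range(len(items)):
        if items[k] in seen:
            continue
        seen.add(items[k])
        rest = items[:k] + items[k + 1 :]
        for tail in _multiset_permutations(rest):
            yield (items[k],) + tail


def anosim(
    D: DissimilarityMatrix,
    groups,
    n_perm: int = 9999,
    seed: int = 0,
    method: str = "auto",
) -> AnosimResult:
    """Analysis of similarities: rank test of between- vs within-group
    dissimilarity.

    R = (mean rank between − mean rank within) / (M/2), with M = n(n−1)/2
    pairwise dissimilarities ranked with average ranks for ties; R ∈
    [−1, 1], ≈ 0 under no group structure.  The p-value permutes group
    labels: ``method="permutation"`` draws ``n_perm`` seeded shuffles
    and applies the +1 correction, p = (1 + #{R* ≥ R}) / (n_perm + 1);
    ``method="exact"`` enumerates every distinct label assignment and
    counts the fraction with R* ≥ R (the identity included).
    ``method="auto"`` chooses exact when the number of distinct
    assignments is at most ``n_perm``.
    """
    groups = np.asarray(groups)
    if len(groups) != D.n:
        raise ValueError("one group label per sample is required")
    labels_, counts = np.unique(groups, return_counts=True)
    if len(labels_) < 2 or (counts < 2).any():
        raise ValueError(
            "ANOSIM needs >= 2 groups each with >= 2 members; got sizes "
            f"{dict(zip(labels_.tolist(), counts.tolist()))}"
        )
    dvec = D.condensed()
    ranks = stats.rankdata(dvec)
    n = D.n
    M = n * (n - 1) // 2
    iu, ju = np.triu_indices(n, k=1)
    same = groups[iu] == groups[ju]
    R_obs = _anosim_R(ranks, same, M)

    n_distinct = _count_distinct_assignments(counts.tolist())
    if method == "auto":
        method = "exact" if n_distinct <= max(n_perm, 1) else "permutation"

    if method == "exact":
        if n_distinct > 200_000:
            raise ValueError(
                f"{n_distinct} distinct assignments is too many for exact "
                "enumeration; use method='permutation'"
            )
        count_ge = 0
        for perm in _multiset_permutations(list(groups)):
            g = np.asarray(perm)
            s = g[iu] == g[ju]
            if _anosim_R(ranks, s, M) >= R_obs - 1e-12:
                count_ge += 1
        p = count_ge / n_distinct
        return AnosimResult(R=R_obs, p=p, n_perm=n_distinct, seed=seed, method="exact")

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        g = rng.permutation(groups)
        s = g[iu] == g[ju]
        if _anosim_R(ranks, s, M) >= R_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (n_perm + 1)
    return AnosimResult(R=R_obs, p=p, n_perm=n_perm, seed=seed, method="permutation")


# ---------------------------------------------------------------------------
# Welch t and OLS (scipy-backed)

def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's two-sample t-test (Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("both samples have zero variance with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def linreg(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with R² and two-sided slope p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("regression needs n >= 3")
    if np.var(x) == 0:
        raise ValueError("x has zero variance; slope is undefined")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if not np.isfinite(r2):      # constant y: SStot = 0
        r2 = 0.0
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        p=p,
        n=len(x),
    )
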