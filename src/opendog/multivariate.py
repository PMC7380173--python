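"""Multivariate analysis of run-level feature tables.

The analysis chain applied to a runs x features table:

1. :func:`log_standardize` — log-transform (with declared per-feature
   offsets for bounded or sign-changing variables) followed by per-column
   z-scoring.
2. :func:`correlation_screen` — pairwise-complete Pearson correlations with
   t-test p-values and optional Benjamini-Hochberg adjustment.
3. :func:`bootstrap_median_diff` — bias-corrected-and-accelerated (BCa)
   bootstrap confidence intervals for between-group median differences.
4. :func:`discriminant_analysis` — canonical discriminant analysis with a
   Wilks' lambda MANOVA test (Bartlett chi-square approximation), ridge
   regularization of the within-class scatter when near-singular.
5. :func:`pca_rotated` — PCA on the feature correlation matrix with varimax
   rotation of the retained components.
6. :func:`two_way_ward` — Ward hierarchical clustering of entities (dogs)
   on their latent-axis scores, and independently of the axes themselves on
   correlation distance, with the dog-cluster count fixed a priori.

All stochastic steps take an explicit seed and are reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.spatial.distance
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .features import FEATURE_NAMES

#: default log-transform offsets; features bounded in [-1, 1] (cosine-based)
#: or in [0, 1] (proportions, resultant lengths) are shifted by 1 + eps so
#: the log argument is strictly positive; QT (a nonnegative rate that can be
#: exactly zero) is shifted by 1.
LOG_OFFSET_EPS = 1e-6
DEFAULT_LOG_OFFSETS: dict[str, float] = {
    "DAD": 1.0 + LOG_OFFSET_EPS,
    "RAD": 1.0 + LOG_OFFSET_EPS,
    "PTA": 1.0 + LOG_OFFSET_EPS,
    "OC": 1.0 + LOG_OFFSET_EPS,
    "ROC": 1.0 + LOG_OFFSET_EPS,
    "PO": 1.0 + LOG_OFFSET_EPS,
    "QT": 1.0,
}

META_COLUMNS = ("run_id", "dog_id", "group_label")


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    rho: pd.DataFrame       # features x features Pearson rho
    p: pd.DataFrame         # two-sided t-test p-values
    n: pd.DataFrame         # pairwise-complete counts
    p_adjusted: pd.DataFrame | None = None  # Benjamini-Hochberg


@dataclass
class EstimationResult:
    feature: str
    median_diff: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


@dataclass
class DFAResult:
    canonical_axes: pd.DataFrame   # features x axes loading vectors
    scores: pd.DataFrame           # rows x axes canonical coordinates
    group_means: pd.DataFrame      # groups x axes centroids
    eigenvalues: np.ndarray
    wilks_lambda: float
    chi2: float
    df: int
    p_value: float
    regularized: bool
    ridge: float


@dataclass
class PCAResult:
    loadings: pd.DataFrame         # features x components (factor loadings)
    variance_pct: np.ndarray       # per-component %, descending (unrotated)
    scores: pd.DataFrame           # rows x components, unit variance
    rotated: bool = False
    rotation_matrix: np.ndarray | None = None
    rotated_loadings: pd.DataFrame | None = None
    rotated_variance_pct: np.ndarray | None = None
    rotated_scores: pd.DataFrame | None = None


@dataclass
class ClusterResult:
    assignments: pd.Series          # entity -> cluster id (1..k)
    linkage: np.ndarray             # scipy linkage matrix (entities)
    merge_heights: np.ndarray
    axis_assignments: pd.Series | None = None
    axis_linkage: np.ndarray | None = None


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def split_feature_table(table: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a feature table into (metadata, feature block) frames."""
    meta_cols = [c for c in META_COLUMNS if c in table.columns]
    feat_cols = [c for c in table.columns if c not in meta_cols]
    return table[meta_cols], table[feat_cols]


def log_standardize(table: pd.DataFrame,
                    offsets: dict[str, float] | None = None) -> pd.DataFrame:
    """Natural log then per-column z-score (mean 0, sample sd 1).

    ``offsets`` maps feature name -> additive shift applied before the log;
    defaults cover the bounded features.  Missing values are excluded from
    the moments and stay missing.  A feature that is non-positive after its
    shift raises :class:`AnalysisError` naming the feature.
    """
    offsets = DEFAULT_LOG_OFFSETS if offsets is None else offsets
    meta, feats = split_feature_table(table)
    out = {}
    for col in feats.columns:
        x = feats[col].astype(float) + offsets.get(col, 0.0)
        if (x[x.notna()] <= 0).any():
            raise AnalysisError(
                f"feature {col!r} non-positive after offset "
                f"{offsets.get(col, 0.0)}; declare a larger offset")
        z = np.log(x)
        sd = z.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise AnalysisError(f"feature {col!r} is constant; cannot z-score")
        out[col] = (z - z.mean()) / sd
    return pd.concat([meta.reset_index(drop=True),
                      pd.DataFrame(out).reset_index(drop=True)], axis=1)


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------

def correlation_screen(table: pd.DataFrame, adjust: bool = True,
                       min_pairs: int = 4) -> CorrelationResult:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    p-values use the exact t transform t = r sqrt((n-2)/(1-r^2)).  Constant
    columns yield NaN correlations (flagged by a warning).  When ``adjust``
    is set a Benjamini-Hochberg matrix over the off-diagonal upper triangle
    is attached.
    """
    _, feats = split_feature_table(table)
    cols = list(feats.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    for i in range(k):
        xi = feats[cols[i]].astype(float).to_numpy()
        for j in range(i, k):
            xj = feats[cols[j]].astype(float).to_numpy()
            ok = np.isfinite(xi) & np.isfinite(xj)
            n = int(ok.sum())
            nmat[i, j] = nmat[j, i] = n
            if i == j:
                rho[i, j] = 1.0
                pmat[i, j] = 0.0
                continue
            if n < min_pairs:
                continue
            a, b = xi[ok], xj[ok]
            if a.std() == 0 or b.std() == 0:
                warnings.warn(f"constant column in pair ({cols[i]}, {cols[j]})")
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            rho[i, j] = rho[j, i] = r
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * math.sqrt((n - 2) / (1.0 - r * r))
                p = 2.0 * stats.t.sf(abs(t), df=n - 2)
            pmat[i, j] = pmat[j, i] = p

    result = CorrelationResult(
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        p=pd.DataFrame(pmat, index=cols, columns=cols),
        n=pd.DataFrame(nmat, index=cols, columns=cols))
    if adjust:
        iu = np.triu_indices(k, 1)
        raw = pmat[iu]
        ok = np.isfinite(raw)
        adj = np.full_like(raw, np.nan)
        if ok.sum():
            adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
        padj = np.full((k, k), np.nan)
        padj[iu] = adj
        padj.T[iu] = adj
        np.fill_diagonal(padj, 0.0)
        result.p_adjusted = pd.DataFrame(padj, index=cols, columns=cols)
    return result


# ---------------------------------------------------------------------------
# bootstrap estimation
# ---------------------------------------------------------------------------

def bootstrap_median_diff(a: Sequence[float], b: Sequence[float],
                          n_boot: int = 5000, seed: int = 0,
                          alpha: float = 0.05, feature: str = "",
                          _force_percentile: bool = False
                          ) -> EstimationResult:
    """BCa bootstrap CI for median(b) - median(a), two independent groups.

    The bias correction z0 comes from the proportion of bootstrap replicates
    below the observed difference; the acceleration comes from a grouped
    delete-one jackknife.  With ``_force_percentile`` both terms are zeroed,
    degenerating to the percentile interval (used as an internal consistency
    check).  Resampling is within-group with replacement.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise AnalysisError("each group needs >= 3 values")
    if n_boot < 1000:
        warnings.warn(f"n_boot = {n_boot} < 1000; intervals will be unstable")

    theta_hat = float(np.median(b) - np.median(a))
    rng = np.random.default_rng(seed)
    boot_a = np.median(rng.choice(a, size=(n_boot, len(a))), axis=1)
    boot_b = np.median(rng.choice(b, size=(n_boot, len(b))), axis=1)
    theta = boot_b - boot_a

    if np.ptp(theta) == 0:  # degenerate identical constants
        v = float(theta[0])
        return EstimationResult(feature, theta_hat, v, v, n_boot, seed)

    if _force_percentile:
        z0 = acc = 0.0
    else:
        prop = (theta < theta_hat).mean() + 0.5 * (theta == theta_hat).mean()
        prop = min(max(prop, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
        z0 = stats.norm.ppf(prop)
        # grouped jackknife over both samples
        jack = []
        med_b = np.median(b)
        for i in range(len(a)):
            jack.append(np.median(b) - np.median(np.delete(a, i)))
        med_a = np.median(a)
        for i in range(len(b)):
            jack.append(np.median(np.delete(b, i)) - med_a)
        jack = np.asarray(jack)
        resid = jack.mean() - jack
        denom = (resid ** 2).sum() ** 1.5
        acc = (resid ** 3).sum() / (6.0 * denom) if denom > 0 else 0.0

    z = stats.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
    adj = stats.norm.cdf(z0 + (z0 + z) / (1.0 - acc * (z0 + z)))
    lo, hi = np.quantile(theta, adj)
    return EstimationResult(feature, theta_hat, float(lo), float(hi),
                            n_boot, seed)


# ---------------------------------------------------------------------------
# discriminant analysis
# ---------------------------------------------------------------------------

def _impute_matrix(feats: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Column-mean imputation; returns the matrix and the imputed columns."""
    X = feats.astype(float).to_numpy()
    imputed = []
    for j, col in enumerate(feats.columns):
        nan = ~np.isfinite(X[:, j])
        if nan.all():
            raise AnalysisError(f"feature {col!r} entirely missing")
        if nan.any():
            X[nan, j] = X[~nan, j].mean()
            imputed.append(col)
    return X, imputed


def discriminant_analysis(table: pd.DataFrame, labels: Sequence[str],
                          ridge: float = 1e-3) -> DFAResult:
    """Canonical discriminant analysis with a Wilks' lambda MANOVA test.

    Canonical axes are eigenvectors of W^-1 B (within- and between-class
    scatter); the within scatter receives a ridge term
    ``ridge * trace(W)/p * I`` when near-singular.  Wilks lambda is
    prod 1/(1 + lambda_i); its p-value uses Bartlett's chi-square
    approximation with p(g-1) degrees of freedom.  Axes are scaled so the
    pooled within-class variance of each canonical score is 1.
    """
    _, feats = split_feature_table(table)
    X, _ = _impute_matrix(feats)
    y = np.asarray(labels)
    n, p = X.shape
    if len(y) != n:
        raise AnalysisError("labels length must match table rows")
    groups = [g for g in pd.unique(y)]
    g = len(groups)
    if g < 2:
        raise AnalysisError("need >= 2 groups")
    counts = {grp: int((y == grp).sum()) for grp in groups}
    if min(counts.values()) < 2:
        raise AnalysisError(f"every group needs >= 2 rows: {counts}")
    if n <= p:
        raise AnalysisError(
            f"{n} rows <= {p} features; reduce dimension first (dfa_space=pca)")

    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    means = {}
    for grp in groups:
        Xg = X[y == grp]
        mg = Xg.mean(axis=0)
        means[grp] = mg
        C = Xg - mg
        W += C.T @ C
        d = (mg - grand)[:, None]
        B += len(Xg) * (d @ d.T)

    # ridge-regularize when near-singular
    regularized = False
    cond = np.linalg.cond(W)
    Wr = W
    if not np.isfinite(cond) or cond > 1e10:
        Wr = W + ridge * (np.trace(W) / p) * np.eye(p)
        regularized = True

    evals, evecs = scipy.linalg.eigh(B, Wr)
    order = np.argsort(evals)[::-1]
    n_axes = min(g - 1, p)
    lam = np.clip(evals[order][:n_axes], 0.0, None)
    V = evecs[:, order][:, :n_axes]
    # scale axes to unit pooled within-class variance
    for j in range(n_axes):
        s2 = V[:, j] @ (Wr / (n - g)) @ V[:, j]
        if s2 > 0:
            V[:, j] = V[:, j] / math.sqrt(s2)
        if np.abs(V[:, j]).max() > 0 and V[np.abs(V[:, j]).argmax(), j] < 0:
            V[:, j] = -V[:, j]

    wilks = float(np.prod(1.0 / (1.0 + lam)))
    chi2_stat = -(n - 1 - (p + g) / 2.0) * math.log(max(wilks, 1e-300))
    df = p * (g - 1)
    p_value = float(stats.chi2.sf(chi2_stat, df))

    axis_names = [f"CAN{i + 1}" for i in range(n_axes)]
    scores = (X - grand) @ V
    return DFAResult(
        canonical_axes=pd.DataFrame(V, index=feats.columns, columns=axis_names),
        scores=pd.DataFrame(scores, columns=axis_names),
        group_means=pd.DataFrame(
            {grp: (means[grp] - grand) @ V for grp in groups}).T.set_axis(
                axis_names, axis=1),
        eigenvalues=lam, wilks_lambda=wilks, chi2=float(chi2_stat), df=df,
        p_value=p_value, regularized=regularized, ridge=ridge)


# ---------------------------------------------------------------------------
# PCA with varimax rotation
# ---------------------------------------------------------------------------

def varimax(loadings: np.ndarray, max_iter: int = 500,
            tol: float = 1e-10) -> np.ndarray:
    """Orthogonal varimax rotation matrix for a p x k loading matrix.

    Classic SVD-based iteration maximizing the variance of squared loadings
    within each rotated component (no Kaiser row normalization).
    """
    p, k = loadings.shape
    R = np.eye(k)
    if k < 2:
        return R
    var_old = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(
            loadings.T @ (L ** 3 - L @ np.diag((L ** 2).sum(axis=0)) / p))
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol * max(var_new, 1.0):
            break
        var_old = var_new
    return R


def pca_rotated(table: pd.DataFrame, n_components: int = 4,
                rotation: str | None = "varimax") -> PCAResult:
    """PCA on the feature correlation matrix, optionally varimax-rotated.

    Unrotated variance percentages are eigenvalue shares (descending);
    rotated variance percentages are recomputed from the rotated squared
    loadings.  Component signs are fixed so each component's
    largest-magnitude loading is positive.  Scores have unit variance.
    """
    _, feats = split_feature_table(table)
    X, _ = _impute_matrix(feats)
    n, p = X.shape
    if n <= n_components:
        raise AnalysisError(f"{n} rows <= {n_components} components")
    # correlation matrix of the (already standardized) features
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    C = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    if n_components > int((evals > 1e-10).sum()):
        raise AnalysisError("n_components exceeds the rank of the data")
    lam = evals[:n_components]
    V = evecs[:, order][:, :n_components]
    for j in range(n_components):  # deterministic sign
        if V[np.abs(V[:, j]).argmax(), j] < 0:
            V[:, j] = -V[:, j]
    variance_pct = 100.0 * evals / p
    loadings = V * np.sqrt(lam)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    # unit-variance component scores
    scores = (Z @ V) / np.sqrt(np.maximum((Z @ V).var(axis=0, ddof=1), 1e-30))

    result = PCAResult(
        loadings=pd.DataFrame(loadings, index=feats.columns, columns=comp_names),
        variance_pct=variance_pct[:n_components],
        scores=pd.DataFrame(scores, columns=comp_names))
    if rotation is None:
        return result
    if rotation != "varimax":
        raise AnalysisError(f"unknown rotation {rotation!r}")
    R = varimax(loadings)
    L = loadings @ R
    signs = np.ones(n_components)
    for j in range(n_components):
        if L[np.abs(L[:, j]).argmax(), j] < 0:
            signs[j] = -1.0
    L = L * signs
    rot_var = 100.0 * (L ** 2).sum(axis=0) / p
    order_r = np.argsort(rot_var)[::-1]
    L = L[:, order_r]
    rot_var = rot_var[order_r]
    # regression-estimator scores for the rotated solution, computed
    # through the full inverse correlation matrix as factor-analysis
    # software does (F = Z C^-1 L).  Unlike an orthogonal rotation of the
    # unit-variance PCs, these columns are generally correlated -- the
    # standard behavior of rotated-factor scores.  Rescaled to unit sd.
    raw = Z @ np.linalg.solve(C, L)
    rot_scores = raw / raw.std(axis=0, ddof=1)
    rot_names = [f"RC{i + 1}" for i in range(n_components)]
    result.rotated = True
    result.rotation_matrix = (R * signs)[:, order_r]
    result.rotated_loadings = pd.DataFrame(
        L, index=feats.columns, columns=rot_names)
    result.rotated_variance_pct = rot_var
    result.rotated_scores = pd.DataFrame(rot_scores, columns=rot_names)
    return result


def label_axes(pca: PCAResult, threshold: float = 0.5
               ) -> dict[str, list[str]]:
    """Salient features per rotated axis: |loading| >= threshold, by magnitude."""
    if pca.rotated_loadings is None:
        raise AnalysisError("label_axes requires rotated loadings")
    out: dict[str, list[str]] = {}
    for axis in pca.rotated_loadings.columns:
        col = pca.rotated_loadings[axis]
        sal = col[col.abs() >= threshold]
        out[axis] = list(sal.reindex(sal.abs().sort_values(ascending=False).index).index)
        if not out[axis]:
            warnings.warn(f"no salient loadings on {axis} at |loading| >= {threshold}")
    return out


# ---------------------------------------------------------------------------
# two-way Ward clustering
# ---------------------------------------------------------------------------

def two_way_ward(scores: pd.DataFrame, k: int = 4,
                 k_axes: int = 2,
                 axis_profiles: pd.DataFrame | None = None) -> ClusterResult:
    """Ward clustering of entities on Euclidean distance, cut at ``k``, and
    independently of the axes (columns) on correlation distance.

    ``scores`` rows are entities (typically per-dog means of latent-axis
    scores), columns are axes.  Axis similarity is taken from
    ``axis_profiles`` (typically the rotated loading matrix, one column per
    axis) when given: loading profiles describe what an axis measures and
    are far less noisy than a handful of per-entity means.  Without
    profiles the score columns themselves are used.  Axis distance is
    1 - |corr|: the sign of a rotated axis is arbitrary, so anti-correlated
    axes are as similar as correlated ones.  Merge heights are monotone
    non-decreasing under Ward linkage.
    """
    X = scores.to_numpy(dtype=float)
    if len(X) < k:
        raise AnalysisError(f"{len(X)} entities < k = {k}")
    Zl = hierarchy.linkage(X, method="ward")
    assign = hierarchy.fcluster(Zl, t=k, criterion="maxclust")
    result = ClusterResult(
        assignments=pd.Series(assign, index=scores.index, name="cluster"),
        linkage=Zl, merge_heights=Zl[:, 2])
    prof = scores if axis_profiles is None else axis_profiles
    if scores.shape[1] >= 2 and k_axes >= 1:
        corr = np.corrcoef(prof.to_numpy(dtype=float), rowvar=False)
        dist = 1.0 - np.abs(corr)
        cond = scipy.spatial.distance.squareform(dist, checks=False)
        Za = hierarchy.linkage(cond, method="ward")
        axis_assign = hierarchy.fcluster(Za, t=min(k_axes, scores.shape[1]),
                                         criterion="maxclust")
        result.axis_assignments = pd.Series(
            axis_assign, index=scores.columns, name="axis_cluster")
        result.axis_linkage = Za
    return result


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch heights."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_h: float) -> str:
        length = max(parent_h - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        return (f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
                f":{length:.6g}")

    return rec(tree, tree.dist) + ";"
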