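"""Multivariate analysis: NIPALS PCA, PLS1 regression with leave-one-out
cross-validation and outlier flagging, median-linkage hierarchical
clustering, and multivariate curve resolution by alternating least squares
(MCR-ALS) with non-negativity constraints.

All routines operate on plain ``n_samples x n_points`` matrices; callers
pass ``SpectraSet.matrix`` after the preprocessing they want.  PCA and PLSR
are intended to run on offset-corrected, non-averaged replicate spectra;
curve resolution runs on concentration-averaged sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .core import SpectraError

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500


# ---------------------------------------------------------------------------
# PCA (NIPALS)


@dataclass
class PCAModel:
    scores: np.ndarray                     # n x k
    loadings: np.ndarray                   # p x k, unit-norm columns
    explained_variance_fraction: np.ndarray
    mean_: np.ndarray
    converged: np.ndarray                  # bool per component

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Centered-data reconstruction from all retained components."""
        return self.scores @ self.loadings.T


def _nipals_component(X: np.ndarray, tol: float, max_iter: int):
    """One NIPALS PCA component of (already centered) X."""
    t = X[:, int(np.argmax(np.sum(X ** 2, axis=0)))].copy()
    if not np.any(t):
        t = X[:, 0] + 1e-30
    converged = False
    for _ in range(max_iter):
        p = X.T @ t / (t @ t)
        p /= np.linalg.norm(p)
        t_new = X @ p
        if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
            t = t_new
            converged = True
            break
        t = t_new
    p = X.T @ t / (t @ t)
    norm = np.linalg.norm(p)
    p /= norm
    t = t * norm
    return t, p, converged


def pca_nipals(X: np.ndarray, k: int, tol: float = NIPALS_TOL,
               max_iter: int = NIPALS_MAX_ITER) -> PCAModel:
    """NIPALS PCA with successive deflation.

    X is mean-centered internally.  Component signs are fixed so the
    loading element of largest magnitude is positive.  Non-convergence is
    warned about and the partial (but still deflated) model returned.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise SpectraError("PCA needs at least two samples")
    if not 1 <= k <= min(n - 1, p):
        raise SpectraError(f"k={k} outside 1..min(n-1, p)")
    mean = X.mean(axis=0)
    Xc = X - mean
    total_ss = float(np.sum(Xc ** 2))
    T = np.zeros((n, k))
    P = np.zeros((p, k))
    conv = np.zeros(k, dtype=bool)
    for a in range(k):
        t, pv, ok = _nipals_component(Xc, tol, max_iter)
        if not ok:
            warnings.warn(f"NIPALS PCA component {a + 1} did not converge "
                          f"in {max_iter} iterations")
        j = int(np.argmax(np.abs(pv)))
        if pv[j] < 0:
            pv, t = -pv, -t
        T[:, a], P[:, a], conv[a] = t, pv, ok
        Xc = Xc - np.outer(t, pv)
    ev = np.sum(T ** 2, axis=0) / total_ss if total_ss > 0 else np.zeros(k)
    return PCAModel(T, P, ev, mean, conv)


def pca_press_loo(X: np.ndarray, k_max: int) -> np.ndarray:
    """Leave-one-out reconstruction PRESS per component count 1..k_max.

    Reported for inspection of model complexity; not used for selection.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    press = np.zeros(k_max)
    for i in range(n):
        rest = np.delete(X, i, axis=0)
        model = pca_nipals(rest, k_max)
        xc = X[i] - model.mean_
        for k in range(1, k_max + 1):
            P = model.loadings[:, :k]
            press[k - 1] += float(np.sum((xc - P @ (P.T @ xc)) ** 2))
    return press


# ---------------------------------------------------------------------------
# Median-linkage clustering (WPGMC, squared Euclidean)


@dataclass
class ClusterTree:
    """Agglomerative merge history under median linkage.

    ``merges[i] = (a, b, height)`` joins clusters a and b at the given
    squared-Euclidean median-linkage height; original points are 0..n-1
    and the cluster formed by merge i gets id n+i (scipy convention).
    """

    n_points: int
    merges: list[tuple[int, int, float]]

    def flat_labels(self, n_clusters: int) -> np.ndarray:
        """Cut the tree at ``n_clusters``; labels follow the order of each
        cluster's smallest member index."""
        n = self.n_points
        if not 1 <= n_clusters <= n:
            raise SpectraError(f"n_clusters={n_clusters} outside 1..{n}")
        parent = {i: i for i in range(n)}
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for step, (a, b, _h) in enumerate(self.merges[:n - n_clusters]):
            members[n + step] = members.pop(a) + members.pop(b)
        labels = np.empty(n, dtype=int)
        clusters = sorted(members.values(), key=min)
        for lab, mem in enumerate(clusters):
            labels[mem] = lab
        return labels


def mlc_cluster(X: np.ndarray, n_clusters: int = 8) -> ClusterTree:
    """Median-linkage (WPGMC) agglomeration on squared Euclidean distances.

    Cluster distances follow the Lance-Williams recursion
    ``d(k, i+j) = d(ki)/2 + d(kj)/2 - d(ij)/4``; merge ties break on the
    smallest pair of cluster ids.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 1:
        raise SpectraError("empty data")
    if n_clusters > n:
        raise SpectraError(f"n_clusters={n_clusters} exceeds n={n}")
    # squared Euclidean distance matrix between current clusters
    sq = np.sum(X ** 2, axis=1)
    D = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
    np.fill_diagonal(D, np.inf)
    ids = list(range(n))
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        m = D.shape[0]
        flat = int(np.argmin(D))          # first minimum -> smallest indices
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        h = float(D[i, j])
        new_row = 0.5 * D[i] + 0.5 * D[j] - 0.25 * h
        merges.append((ids[i], ids[j], h))
        keep = [r for r in range(m) if r not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       new_row[keep][None, :]])
        D = np.hstack([D, np.append(new_row[keep], np.inf)[:, None]])
        ids = [ids[r] for r in keep] + [n + step]
    return ClusterTree(n, merges)


# ---------------------------------------------------------------------------
# PLS1 (NIPALS) and leave-one-out cross-validation


@dataclass
class PLSRModel:
    n_factors: int
    x_scores: np.ndarray        # n x k
    x_loadings: np.ndarray      # p x k
    weights: np.ndarray         # p x k
    y_loadings: np.ndarray      # k
    coef_per_factor: np.ndarray  # p x k, column a = coefficients using 1..a+1
    x_mean: np.ndarray
    y_mean: float
    r2_per_factor: np.ndarray           # training R^2, cumulative factors
    explained_x_variance: np.ndarray    # cumulative fractions, per factor
    explained_y_variance: np.ndarray    # cumulative fractions (= R^2)

    @property
    def coef_(self) -> np.ndarray:
        return self.coef_per_factor[:, -1]

    def predict(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        b = self.coef_per_factor[:, (k or self.n_factors) - 1]
        return (np.asarray(X, dtype=float) - self.x_mean) @ b + self.y_mean


@dataclass
class CVResult:
    y_true: np.ndarray
    y_pred: np.ndarray
    r2_cv: float
    rmsecv: float

    @property
    def residuals(self) -> np.ndarray:
        return self.y_pred - self.y_true


def plsr_fit(X: np.ndarray, y: np.ndarray, k: int) -> PLSRModel:
    """PLS1 via NIPALS with deflation of X and y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise SpectraError("X and y sizes differ")
    if np.std(y) == 0:
        raise SpectraError("constant response; PLSR is undefined")
    if not 1 <= k <= min(n - 1, p):
        raise SpectraError(f"k={k} outside 1..min(n-1, p)")
    x_mean, y_mean = X.mean(axis=0), float(y.mean())
    E, f = X - x_mean, y - y_mean
    ss_x, ss_y = float(np.sum(E ** 2)), float(np.sum(f ** 2))
    W = np.zeros((p, k))
    P = np.zeros((p, k))
    T = np.zeros((n, k))
    q = np.zeros(k)
    for a in range(k):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw == 0:
            # response fully deflated; keep remaining factors at zero
            W, P, T, q = W[:, :a], P[:, :a], T[:, :a], q[:a]
            k = a
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        pv = E.T @ t / tt
        qa = float(f @ t / tt)
        E = E - np.outer(t, pv)
        f = f - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pv, t, qa
    if k == 0:
        raise SpectraError("no PLS factor could be extracted")
    coef = np.zeros((p, k))
    r2 = np.zeros(k)
    exp_x = np.zeros(k)
    fc = y - y_mean
    for a in range(1, k + 1):
        b = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a],
                                       np.eye(a)) @ q[:a]
        coef[:, a - 1] = b
        resid = fc - (X - x_mean) @ b
        r2[a - 1] = 1.0 - float(np.sum(resid ** 2)) / ss_y
        exp_x[a - 1] = float(np.sum(
            (T[:, :a] ** 2).sum(axis=0) * (P[:, :a] ** 2).sum(axis=0))) / ss_x
    return PLSRModel(k, T, P, W, q, coef, x_mean, y_mean, r2, exp_x,
                     r2.copy())


def plsr_loo(X: np.ndarray, y: np.ndarray, k: int,
             groups: np.ndarray | None = None) -> CVResult:
    """Full leave-one-out cross-validation (refit per left-out sample).

    With ``groups`` given, whole groups (e.g. preparations) are left out
    together instead of single measured spectra.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise SpectraError("LOO needs at least three samples")
    folds = ([np.array([i]) for i in range(n)] if groups is None else
             [np.nonzero(np.asarray(groups) == g)[0]
              for g in dict.fromkeys(np.asarray(groups))])
    y_pred = np.empty(n)
    for idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[idx] = False
        model = plsr_fit(X[mask], y[mask], min(k, int(mask.sum()) - 1))
        y_pred[idx] = model.predict(X[idx])
    ss_res = float(np.sum((y_pred - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return CVResult(y.copy(), y_pred, 1.0 - ss_res / ss_tot,
                    float(np.sqrt(ss_res / n)))


def flag_outliers(cv: CVResult, threshold_multiplier: float = 3.0
                  ) -> np.ndarray:
    """Indices whose |CV residual| exceeds threshold_multiplier * RMSECV."""
    return np.nonzero(np.abs(cv.residuals)
                      > threshold_multiplier * cv.rmsecv)[0]


# ---------------------------------------------------------------------------
# MCR-ALS


@dataclass
class MCRResult:
    C: np.ndarray               # n x k, non-negative concentration profiles
    S: np.ndarray               # k x p, non-negative component spectra
    lack_of_fit: list[float]    # per accepted iteration
    iterations: int
    converged: bool


def _nnls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A x - b||, x >= 0, for every column b of B; solutions
    are returned as columns.

    For two components the exact solution is found analytically from the
    normal equations (the active set is one of {both free, x1=0, x2=0}),
    vectorized over all columns; otherwise scipy's active-set NNLS runs
    per column.
    """
    k = A.shape[1]
    G = A.T @ A
    if k == 2 and np.linalg.det(G) > 1e-12 * np.trace(G) ** 2:
        F = A.T @ B                                    # 2 x q
        X = np.linalg.solve(G, F)
        # fallback candidates with one variable clamped to zero
        x1 = np.maximum(F[0] / G[0, 0], 0.0)
        x2 = np.maximum(F[1] / G[1, 1], 0.0)
        # objective q(x) = x'Gx/2 - x'F (residual norm up to a constant)
        q1 = 0.5 * G[0, 0] * x1 ** 2 - x1 * F[0]
        q2 = 0.5 * G[1, 1] * x2 ** 2 - x2 * F[1]
        infeasible = np.any(X < 0, axis=0)
        use1 = infeasible & (q1 <= q2)
        use2 = infeasible & ~use1
        X[:, use1] = np.vstack([x1[use1], np.zeros(use1.sum())])
        X[:, use2] = np.vstack([np.zeros(use2.sum()), x2[use2]])
        return X
    out = np.empty((k, B.shape[1]))
    for j in range(B.shape[1]):
        out[:, j], _ = nnls(A, B[:, j])
    return out


def mcr_als(X: np.ndarray, S_init: np.ndarray, tol: float = 1e-8,
            max_iter: int = 200) -> MCRResult:
    """Bilinear decomposition X ~ C S by alternating non-negative least
    squares, initialized from reference spectra estimates ``S_init``.

    Non-negativity of both factors is enforced by the solver (active-set
    NNLS), not by clipping.  Iteration stops when the relative change of
    the lack of fit, sqrt(sum(residual^2)/sum(X^2)), drops below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    S = np.asarray(S_init, dtype=float).copy()
    if S.ndim != 2 or S.shape[1] != X.shape[1]:
        raise SpectraError("S_init must be k x n_points")
    if np.any(S < 0):
        raise SpectraError("S_init must be non-negative")
    total = float(np.sum(X ** 2))
    if total == 0:
        raise SpectraError("all-zero data matrix")
    lof_hist: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C = _nnls_rows(S.T, X.T).T          # given S, solve rows of C
        S = _nnls_rows(C, X)                # given C, solve columns of S
        lof = float(np.sqrt(np.sum((X - C @ S) ** 2) / total))
        if lof_hist and lof_hist[-1] > 0:
            if abs(lof_hist[-1] - lof) < tol * max(lof_hist[-1], 1e-300):
                lof_hist.append(lof)
                converged = True
                break
        elif lof_hist and lof_hist[-1] == 0.0:
            lof_hist.append(lof)
            converged = True
            break
        lof_hist.append(lof)
        if lof <= 1e-14:
            converged = True
            break
    return MCRResult(C, S, lof_hist, it, converged)


def match_components(S: np.ndarray, references: np.ndarray) -> np.ndarray:
    """Permutation matching resolved spectra rows to reference rows by
    maximal cosine similarity (greedy on the best remaining pair)."""
    k = S.shape[0]
    cos = np.zeros((k, references.shape[0]))
    for a in range(k):
        for b in range(references.shape[0]):
            cos[a, b] = cosine_similarity(S[a], references[b])
    perm = -np.ones(references.shape[0], dtype=int)
    used = set()
    for _ in range(min(k, references.shape[0])):
        a, b = np.unravel_index(
            np.argmax(np.where(np.isfinite(cos), cos, -np.inf)), cos.shape)
        perm[b] = a
        cos[a, :] = -np.inf
        cos[:, b] = -np.inf
        used.add(a)
    return perm


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))
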