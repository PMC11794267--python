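"""Dimensionality reduction and feature selection for EMG feature tables.

Six methods under a common fit/transform interface:

* **PCA** -- linear projection onto top principal components.
* **LDA** -- generalized-eigenvector solution of the between/within scatter
  problem.  Feature tables built from the catalog contain exactly collinear
  columns (IAV = IEMG, AAC = DAMV), which make the within-class scatter
  singular; this is detected and raised as :class:`SingularScatterError`
  naming the offending columns rather than silently regularized (an optional
  ridge is available).
* **PPCA** -- probabilistic PCA: the factor model ``x = W z + mu + eps`` with
  isotropic noise ``eps ~ N(0, sigma^2 I)``, fit by expectation-maximization.
  The marginal log-likelihood is tracked per iteration and must never
  decrease (EM guarantee).
* **GPLVM** -- Gaussian process latent variable model: latent coordinates
  ``X`` and kernel hyperparameters jointly minimize the negative GP marginal
  log-likelihood ``D/2 log|K| + 1/2 tr(K^{-1} Y Y^T)`` with an RBF (or
  linear) kernel plus noise, by L-BFGS from a PCA initialization.  With a
  linear kernel the optimum spans the principal subspace, which is the
  PPCA/PCA consistency check used in the tests.
* **ReliefF** -- multiclass nearest-hit/nearest-miss feature weighting, miss
  contributions weighted by class priors.
* **Lasso** -- one-vs-rest L1-penalized logistic regression over a penalty
  grid; the penalty is chosen by cross-validated accuracy and the selection
  is the union of nonzero-coefficient columns.

``evaluate_reduction`` plugs any of these into the cross-validation harness:
the method is fit on each training fold only and applied to its test fold
before the ANN sees the data.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import optimize as sopt
from sklearn.decomposition import PCA as _SkPCA
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier

from .classifier import ANNConfig, evaluate_cv, stratified_folds
from .features import FeatureMatrix, zscore_apply, zscore_fit

__all__ = [
    "Embedding", "SelectionMask", "SingularScatterError",
    "pca_fit", "lda_fit", "ppca_em", "gplvm_fit", "relieff", "lasso_select",
    "evaluate_reduction", "make_reducer_factory", "REDUCTION_METHODS",
]


class ParameterError(ValueError):
    pass


class SingularScatterError(np.linalg.LinAlgError):
    """Within-class scatter is numerically singular (collinear columns)."""

    def __init__(self, condition: float, collinear_columns):
        self.condition = condition
        self.collinear_columns = list(collinear_columns)
        super().__init__(
            f"within-class scatter condition number {condition:.3g} exceeds 1e12; "
            f"collinear/degenerate columns: {self.collinear_columns}"
        )


@dataclass
class Embedding:
    method: str
    latent: np.ndarray            # [n_rows x d]
    d: int
    diagnostics: dict = field(default_factory=dict)
    _transform: callable = None

    def transform(self, Xnew: np.ndarray) -> np.ndarray:
        if self._transform is None:
            raise NotImplementedError(f"{self.method} has no transform")
        return self._transform(np.asarray(Xnew, dtype=float))


@dataclass
class SelectionMask:
    method: str
    weights: np.ndarray           # per input column
    selected: np.ndarray          # column indices
    params: dict = field(default_factory=dict)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.selected]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_fit(X: np.ndarray, d: int) -> Embedding:
    X = np.asarray(X, dtype=float)
    if not 1 <= d <= min(X.shape):
        raise ParameterError(f"d={d} outside [1, min(n_rows, n_cols)={min(X.shape)}]")
    model = _SkPCA(n_components=d, svd_solver="full")
    latent = model.fit_transform(X)
    return Embedding(
        method="pca", latent=latent, d=d,
        diagnostics={
            "explained_variance": model.explained_variance_.copy(),
            "explained_variance_ratio": model.explained_variance_ratio_.copy(),
            "components": model.components_.copy(),
            "mean": model.mean_.copy(),
        },
        _transform=model.transform,
    )


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

def _collinear_columns(X: np.ndarray) -> list:
    """Zero-variance columns plus pairs with |correlation| ~ 1."""
    bad = []
    sd = X.std(axis=0)
    bad.extend(int(i) for i in np.flatnonzero(sd < 1e-12))
    ok = np.flatnonzero(sd >= 1e-12)
    if len(ok) >= 2:
        corr = np.corrcoef(X[:, ok], rowvar=False)
        ii, jj = np.triu_indices_from(corr, k=1)
        for a, b in zip(ii, jj):
            if abs(corr[a, b]) > 1 - 1e-10:
                bad.extend([int(ok[a]), int(ok[b])])
    return sorted(set(bad))


def lda_fit(X: np.ndarray, y: np.ndarray, d: int, ridge: float = 0.0) -> Embedding:
    """Fisher discriminant projection maximizing between/within scatter ratio."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if d > len(classes) - 1:
        raise ParameterError(f"d={d} exceeds n_classes-1={len(classes) - 1}")
    n, p = X.shape
    mean = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in classes:
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        dev = Xc - mc
        Sw += dev.T @ dev
        diff = (mc - mean)[:, None]
        Sb += len(Xc) * (diff @ diff.T)
    if ridge > 0:
        Sw = Sw + ridge * np.trace(Sw) / p * np.eye(p)
    cond = np.linalg.cond(Sw)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularScatterError(cond, _collinear_columns(X))
    evals, evecs = sla.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1][:d]
    W = evecs[:, order]

    def transform(Xn):
        return (np.asarray(Xn, dtype=float) - mean) @ W

    return Embedding(method="lda", latent=transform(X), d=d,
                     diagnostics={"eigenvalues": evals[order], "directions": W,
                                  "condition": cond},
                     _transform=transform)


# ---------------------------------------------------------------------------
# Probabilistic PCA via EM
# ---------------------------------------------------------------------------

def _ppca_loglik(S: np.ndarray, W: np.ndarray, sigma2: float, n: int) -> float:
    p = S.shape[0]
    C = W @ W.T + sigma2 * np.eye(p)
    sign, logdet = np.linalg.slogdet(C)
    Cinv = np.linalg.inv(C)
    return -0.5 * n * (p * np.log(2 * np.pi) + logdet + np.trace(Cinv @ S))


def ppca_em(X: np.ndarray, d: int, tol: float = 1e-6, max_iter: int = 500,
            seed: int = 0) -> Embedding:
    """Fit the PPCA factor model by EM (Tipping & Bishop formulation).

    Returns loadings ``W``, isotropic noise variance ``sigma2``, latent
    posterior means, and the per-iteration marginal log-likelihood trace.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= d < p:
        raise ParameterError(f"d={d} must satisfy 1 <= d < n_cols={p}")
    mu = X.mean(axis=0)
    Xc = X - mu
    S = Xc.T @ Xc / n
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((p, d)) * 0.1
    sigma2 = float(np.trace(S) / p)
    trace = []
    converged = False
    for _ in range(max_iter):
        # E-step sufficient statistics via M = W'W + sigma2 I
        M = W.T @ W + sigma2 * np.eye(d)
        Minv = np.linalg.inv(M)
        SW = S @ W
        # M-step (uses the sample covariance form)
        W_new = SW @ np.linalg.inv(sigma2 * np.eye(d) + Minv @ W.T @ SW)
        sigma2_new = float(np.trace(S - SW @ Minv @ W_new.T) / p)
        sigma2_new = max(sigma2_new, 1e-12)
        W, sigma2 = W_new, sigma2_new
        ll = _ppca_loglik(S, W, sigma2, n)
        if trace and abs(ll - trace[-1]) < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
    if not converged:
        warnings.warn(f"PPCA EM did not converge in {max_iter} iterations")

    Mfinal = W.T @ W + sigma2 * np.eye(d)
    Minv = np.linalg.inv(Mfinal)

    def transform(Xn):
        return (np.asarray(Xn, dtype=float) - mu) @ W @ Minv.T

    return Embedding(
        method="ppca", latent=transform(X), d=d,
        diagnostics={"W": W, "sigma2": sigma2, "mu": mu,
                     "loglik_trace": np.asarray(trace), "converged": converged},
        _transform=transform,
    )


# ---------------------------------------------------------------------------
# GPLVM
# ---------------------------------------------------------------------------

def _gplvm_kernel(X, params, kernel):
    """Kernel matrix and cached pieces. params = (log sf2, log ell2, log sn2)."""
    sf2, ell2, sn2 = np.exp(params)
    if kernel == "rbf":
        sq = np.sum(X ** 2, axis=1)
        r2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
        E = sf2 * np.exp(-0.5 * r2 / ell2)
        K = E + sn2 * np.eye(len(X))
        return K, E, r2
    elif kernel == "linear":
        E = sf2 * (X @ X.T)
        K = E + sn2 * np.eye(len(X))
        return K, E, None
    raise ParameterError(f"unknown kernel {kernel!r}")


def _gplvm_obj_grad(z, n, q, Y, kernel):
    """Negative log marginal likelihood and its gradient w.r.t. latents + hypers."""
    X = z[: n * q].reshape(n, q)
    params = z[n * q:]
    sf2, ell2, sn2 = np.exp(params)
    D = Y.shape[1]
    K, E, r2 = _gplvm_kernel(X, params, kernel)
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(z)
    Kinv = sla.cho_solve((L, True), np.eye(n))
    A = sla.cho_solve((L, True), Y)          # K^{-1} Y
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    obj = 0.5 * D * logdet + 0.5 * np.sum(Y * A) + 0.5 * n * D * np.log(2 * np.pi)
    # dL/dK
    G = 0.5 * (D * Kinv - A @ A.T)
    if kernel == "rbf":
        B = G * E
        gX = (2.0 / ell2) * (B @ X - B.sum(axis=1)[:, None] * X)
        g_sf2 = np.sum(G * E)                         # d/d log sf2
        g_ell2 = np.sum(G * E * r2) * 0.5 / ell2      # d/d log ell2
    else:
        gX = 2.0 * sf2 * (G @ X)
        g_sf2 = np.sum(G * E)
        g_ell2 = 0.0
    g_sn2 = sn2 * np.trace(G)
    grad = np.concatenate([gX.ravel(), [g_sf2, g_ell2, g_sn2]])
    return obj, grad


def gplvm_fit(X: np.ndarray, d: int, kernel: str = "rbf", init: str = "pca",
              max_iter: int = 200, seed: int = 0, max_points: int = 3000) -> Embedding:
    """MAP GPLVM: minimize the GP negative log marginal likelihood over
    latent coordinates and kernel hyperparameters jointly (L-BFGS, PCA init).

    ``X`` here is the observed high-dimensional data (rows = samples); the
    fitted latent coordinates live in ``latent``.  Out-of-sample rows are
    projected by per-point optimization of the GP predictive likelihood.
    """
    Y = np.asarray(X, dtype=float)
    n, p = Y.shape
    if not 1 <= d < p:
        raise ParameterError(f"d={d} must satisfy 1 <= d < n_cols={p}")
    if n > max_points:
        raise ParameterError(
            f"{n} rows exceeds max_points={max_points} for dense kernel algebra; "
            "subsample or raise max_points"
        )
    mu = Y.mean(axis=0)
    Yc = Y - mu
    if init == "pca":
        X0 = pca_fit(Yc, d).latent
    else:
        X0 = np.random.default_rng(seed).standard_normal((n, d))
    X0 = X0 / np.maximum(X0.std(axis=0), 1e-12)
    var_y = Yc.var()
    params0 = np.log([max(var_y, 1e-8), 1.0, max(0.1 * var_y, 1e-8)])
    z0 = np.concatenate([X0.ravel(), params0])

    trace = []

    def fun(z):
        obj, grad = _gplvm_obj_grad(z, n, d, Yc, kernel)
        return obj, grad

    init_obj = fun(z0)[0]
    if not np.isfinite(init_obj):
        raise RuntimeError("non-finite GPLVM objective at initialization")
    trace.append(init_obj)

    def cb(z):
        trace.append(fun(z)[0])

    res = sopt.minimize(fun, z0, jac=True, method="L-BFGS-B",
                        options={"maxiter": max_iter}, callback=cb)
    if not np.isfinite(res.fun):
        raise RuntimeError(f"non-finite GPLVM objective; trace={trace}")
    z = res.x if res.fun <= init_obj else z0
    final_obj = min(res.fun, init_obj)
    latent = z[: n * d].reshape(n, d)
    params = z[n * d:]
    sf2, ell2, sn2 = np.exp(params)
    K, _, _ = _gplvm_kernel(latent, params, kernel)
    L = np.linalg.cholesky(K)
    KinvY = sla.cho_solve((L, True), Yc)
    Kinv = sla.cho_solve((L, True), np.eye(n))

    def _kvec(xstar):
        if kernel == "rbf":
            r2 = np.sum((latent - xstar) ** 2, axis=1)
            return sf2 * np.exp(-0.5 * r2 / ell2)
        return sf2 * (latent @ xstar)

    def _project_one(ystar, x_init):
        # GP predictive NLL of the new data row as a function of its latent
        def nll_grad(xs):
            ks = _kvec(xs)
            if kernel == "rbf":
                dk = ks[:, None] * (latent - xs) / ell2        # n x d
                kss = sf2
                dkss = np.zeros_like(xs)
            else:
                dk = sf2 * latent
                kss = sf2 * (xs @ xs)
                dkss = 2.0 * sf2 * xs
            alpha = Kinv @ ks
            mean_pred = KinvY.T @ ks
            var = max(kss + sn2 - ks @ alpha, 1e-10)
            resid = ystar - mean_pred
            rss = resid @ resid
            val = 0.5 * p * np.log(var) + 0.5 * rss / var
            dvar = dkss - 2.0 * (alpha @ dk)
            dmean = KinvY.T @ dk                                # p x d
            grad = (0.5 * p / var - 0.5 * rss / var ** 2) * dvar \
                - (resid @ dmean) / var
            return val, grad
        out = sopt.minimize(nll_grad, x_init, jac=True, method="L-BFGS-B",
                            options={"maxiter": 30})
        return out.x

    def transform(Xn):
        Xn = np.asarray(Xn, dtype=float) - mu
        # init each point at the latent of its nearest training row (data space)
        proj = np.empty((len(Xn), d))
        for i, ystar in enumerate(Xn):
            j = int(np.argmin(np.sum((Yc - ystar) ** 2, axis=1)))
            proj[i] = _project_one(ystar, latent[j].copy())
        return proj

    return Embedding(
        method="gplvm", latent=latent, d=d,
        diagnostics={"objective_trace": np.asarray(trace),
                     "final_objective": float(final_obj),
                     "init_objective": float(trace[0]),
                     "kernel": kernel,
                     "sf2": float(sf2), "ell2": float(ell2), "sn2": float(sn2)},
        _transform=transform,
    )


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------

def relieff(X: np.ndarray, y: np.ndarray, k_neighbors: int = 10,
            n_select: int | None = None, seed: int = 0) -> SelectionMask:
    """Multiclass ReliefF weights; selection = top ``n_select`` columns.

    For every row, the k nearest same-class rows (hits) pull its features'
    weights down by their mean absolute difference and the k nearest rows of
    each other class (misses) push them up, weighted by the class priors
    renormalized over the miss classes.  Differences are scaled by each
    feature's range, the standard normalization.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k_neighbors + 1:
        raise ParameterError(
            f"smallest class has {counts.min()} rows; need >= k_neighbors+1="
            f"{k_neighbors + 1}"
        )
    if n_select is None:
        n_select = max(1, p // 4)
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    span = np.maximum(X.max(axis=0) - X.min(axis=0), 1e-12)
    if n <= 2000:
        sq = np.sum(X ** 2, axis=1)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
    else:
        d2 = None
    weights = np.zeros(p)
    for i in range(n):
        if d2 is not None:
            dist = d2[i]
        else:
            dist = np.sum((X - X[i]) ** 2, axis=1)
        same = np.flatnonzero((y == y[i]))
        same = same[same != i]
        hits = same[np.argsort(dist[same])[:k_neighbors]]
        weights -= np.mean(np.abs(X[hits] - X[i]) / span, axis=0) / n
        p_not = 1.0 - priors[y[i]]
        for c in classes:
            if c == y[i]:
                continue
            other = np.flatnonzero(y == c)
            misses = other[np.argsort(dist[other])[:k_neighbors]]
            w_c = priors[c] / p_not
            weights += w_c * np.mean(np.abs(X[misses] - X[i]) / span, axis=0) / n
    selected = np.sort(np.argsort(weights)[::-1][:n_select])
    return SelectionMask(method="relieff", weights=weights, selected=selected,
                         params={"k_neighbors": k_neighbors, "n_select": n_select})


# ---------------------------------------------------------------------------
# Lasso (L1 logistic) selection
# ---------------------------------------------------------------------------

def lasso_select(X: np.ndarray, y: np.ndarray, lambda_grid=None,
                 cv_folds: int = 5, seed: int = 0) -> SelectionMask:
    """One-vs-rest L1 logistic selection; penalty chosen by CV accuracy.

    ``lambda_grid`` holds penalty strengths (inverse of sklearn's C).  The
    selected columns are those with any nonzero coefficient at the chosen
    penalty.  If every penalty zeroes everything, fall back to the smallest
    penalty with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ParameterError("need >= 2 classes")
    if lambda_grid is None:
        lambda_grid = np.logspace(-2, 2, 9)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))

    def fit_at(lam, Xtr, ytr):
        base = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                  C=1.0 / lam, random_state=seed, max_iter=500)
        model = OneVsRestClassifier(base)
        model.fit(Xtr, ytr)
        return model

    def coefs(model):
        return np.vstack([est.coef_ for est in model.estimators_])

    folds = stratified_folds(y, k=cv_folds, seed=seed)
    cv_acc = {}
    for lam in lambda_grid:
        accs = [np.mean(fit_at(lam, X[tr], y[tr]).predict(X[te]) == y[te])
                for tr, te in folds]
        cv_acc[float(lam)] = float(np.mean(accs))
    best_lam = max(cv_acc, key=lambda l: (cv_acc[l], l))  # prefer sparser on ties
    model = fit_at(best_lam, X, y)
    coef = np.abs(coefs(model)).max(axis=0)
    selected = np.flatnonzero(coef > 0)
    if selected.size == 0:
        nonempty = None
        for lam in lambda_grid:
            m = fit_at(lam, X, y)
            c = np.abs(coefs(m)).max(axis=0)
            if np.any(c > 0):
                nonempty, coef, best_lam = np.flatnonzero(c > 0), c, float(lam)
                break
        if nonempty is None:
            warnings.warn("all coefficients zero at every penalty; selecting nothing")
            selected = np.array([], dtype=int)
        else:
            warnings.warn(
                f"empty selection at CV-chosen penalty; falling back to lambda={best_lam}"
            )
            selected = nonempty
    return SelectionMask(method="lasso", weights=coef, selected=selected,
                         params={"lambda": float(best_lam), "cv_accuracy": cv_acc})


# ---------------------------------------------------------------------------
# Reduction-method comparison harness
# ---------------------------------------------------------------------------

REDUCTION_METHODS = ("none", "pca", "lda", "ppca", "gplvm", "relieff", "lasso")


class _Identity:
    def fit(self, X, y):
        return self

    def transform(self, X):
        return X


class _EmbeddingReducer:
    def __init__(self, fit_fn):
        self._fit_fn = fit_fn
        self._emb = None

    def fit(self, X, y):
        self._emb = self._fit_fn(X, y)
        return self

    def transform(self, X):
        return self._emb.transform(X)


def _variance_dim(X, frac=0.95):
    ev = _SkPCA(svd_solver="full").fit(X).explained_variance_ratio_
    return max(1, int(np.searchsorted(np.cumsum(ev), frac) + 1))


def make_reducer_factory(method: str, params: dict | None = None, seed: int = 0):
    """Factory of per-fold reducers for :func:`evaluate_cv`.

    Defaults: PCA/PPCA keep components covering 99% variance (on
    amplitude-coded sEMG features the class contrasts are lower-variance
    than the common amplitude mode, which a 95% cut can discard), GPLVM uses
    d=10 (capped below n_cols), ReliefF selects 25% of columns, Lasso picks
    its penalty by internal CV.
    """
    params = dict(params or {})
    if method == "none":
        return _Identity
    if method == "pca":
        frac = params.get("variance_fraction", 0.99)
        d_fixed = params.get("d")
        return lambda: _EmbeddingReducer(
            lambda X, y: pca_fit(X, d_fixed or _variance_dim(X, frac)))
    if method == "lda":
        d = params.get("d")
        return lambda: _EmbeddingReducer(
            lambda X, y: lda_fit(X, y, d or (len(np.unique(y)) - 1),
                                 ridge=params.get("ridge", 0.0)))
    if method == "ppca":
        frac = params.get("variance_fraction", 0.99)
        d_fixed = params.get("d")
        return lambda: _EmbeddingReducer(
            lambda X, y: ppca_em(X, d_fixed or min(_variance_dim(X, frac),
                                                   X.shape[1] - 1),
                                 seed=seed))
    if method == "gplvm":
        d = params.get("d", 10)
        return lambda: _EmbeddingReducer(
            lambda X, y: gplvm_fit(X, min(d, X.shape[1] - 1),
                                   kernel=params.get("kernel", "rbf"),
                                   max_iter=params.get("max_iter", 100),
                                   seed=seed,
                                   max_points=params.get("max_points", 3000)))
    if method == "relieff":
        return lambda: _MaskReducer(
            lambda X, y: relieff(X, y,
                                 k_neighbors=params.get("k_neighbors", 10),
                                 n_select=params.get("n_select"), seed=seed))
    if method == "lasso":
        return lambda: _MaskReducer(
            lambda X, y: lasso_select(X, y, lambda_grid=params.get("lambda_grid"),
                                      cv_folds=params.get("cv_folds", 5), seed=seed))
    raise ParameterError(f"unknown reduction method {method!r}")


class _MaskReducer:
    def __init__(self, fit_fn):
        self._fit_fn = fit_fn
        self._mask = None

    def fit(self, X, y):
        self._mask = self._fit_fn(X, y)
        return self

    def transform(self, X):
        return self._mask.transform(X)


def evaluate_reduction(fm: FeatureMatrix, method: str, method_params: dict | None,
                       cfg: ANNConfig | None = None, k: int = 5, seed: int = 0,
                       folds=None):
    """CV accuracy of the ANN after per-fold reduction; returns (CVReport, seconds).

    Wall-clock seconds are informational only (hardware dependent).
    """
    if method not in REDUCTION_METHODS:
        raise ParameterError(f"method must be one of {REDUCTION_METHODS}")
    factory = make_reducer_factory(method, method_params, seed=seed)
    t0 = time.perf_counter()
    report = evaluate_cv(fm.values, fm.labels, cfg, k=k, seed=seed, folds=folds,
                         reducer_factory=factory)
    return report, time.perf_counter() - t0
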