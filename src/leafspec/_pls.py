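"""Fast univariate-response partial least squares (PLS1) with k-fold CV.

Wavelength selection scores on the order of 10⁵ candidate band subsets, each
by a full 5-fold PLS cross-validation, so this module provides a minimal
NIPALS PLS1 written against raw ndarrays and jitted with numba when
available (it degrades gracefully to plain numpy).  Columns and the response
are mean-centred per training fold; predictions are accumulated component by
component so that a single pass yields the cross-validated error for every
latent-variable count from 1 to ``max_lv``.

Fold assignment is stratified on the response: samples are ranked by y and
fold labels shuffled within consecutive rank blocks, which stabilises RMSECV
across candidate subsets.  Because folds depend only on (y, seed), every
subset scored within one selection step sees identical folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = ["PLSModel", "PLSCVResult", "center_columns", "make_folds", "pls_cv", "pls_fit"]

_EPS = 1e-12


@njit(cache=False)
def _fit_kernel(X, y, max_lv):
    n, p = X.shape
    xm = np.zeros(p)
    for j in range(p):
        xm[j] = X[:, j].mean()
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    a_cap = min(max_lv, p, n - 1)
    W = np.zeros((p, max_lv))
    P = np.zeros((p, max_lv))
    q = np.zeros(max_lv)
    a_eff = 0
    for comp in range(a_cap):
        w = np.dot(yc, Xc)
        nw = np.sqrt(np.dot(w, w))
        if nw <= _EPS:
            break
        w = w / nw
        t = np.dot(Xc, w)
        tt = np.dot(t, t)
        if tt <= _EPS:
            break
        pvec = np.dot(t, Xc) / tt
        qa = np.dot(yc, t) / tt
        Xc = Xc - t.reshape(-1, 1) * pvec.reshape(1, -1)
        W[:, comp] = w
        P[:, comp] = pvec
        q[comp] = qa
        a_eff += 1
    return xm, ym, W, P, q, a_eff


@njit(cache=False)
def _predict_kernel(X, xm, ym, W, P, q, a):
    n = X.shape[0]
    Xd = X - xm
    yhat = np.full(n, ym)
    for comp in range(a):
        w = np.ascontiguousarray(W[:, comp])
        pvec = np.ascontiguousarray(P[:, comp])
        t = np.dot(Xd, w)
        yhat = yhat + q[comp] * t
        Xd = Xd - t.reshape(-1, 1) * pvec.reshape(1, -1)
    return yhat


@njit(cache=False, fastmath=True)
def _cv_press_kernel_T(XT, y, fold_id, n_folds, max_lv):
    # XT is band-major (p, n): every inner loop walks a contiguous row.
    p, n = XT.shape
    press = np.zeros(max_lv)
    w = np.empty(p)
    pv = np.empty(p)
    for f in range(n_folds):
        nte = 0
        for i in range(n):
            if fold_id[i] == f:
                nte += 1
        ntr = n - nte
        if nte == 0 or ntr < 2:
            continue
        XcT = np.empty((p, ntr))
        XdT = np.empty((p, nte))
        ytr = np.empty(ntr)
        yte = np.empty(nte)
        a = 0
        b = 0
        for i in range(n):
            if fold_id[i] == f:
                yte[b] = y[i]
                b += 1
            else:
                ytr[a] = y[i]
                a += 1
        for j in range(p):
            row = XT[j]
            a = 0
            b = 0
            for i in range(n):
                if fold_id[i] == f:
                    XdT[j, b] = row[i]
                    b += 1
                else:
                    XcT[j, a] = row[i]
                    a += 1
        # centre on training means only
        for j in range(p):
            m = 0.0
            for i in range(ntr):
                m += XcT[j, i]
            m /= ntr
            for i in range(ntr):
                XcT[j, i] -= m
            for i in range(nte):
                XdT[j, i] -= m
        ym = 0.0
        for i in range(ntr):
            ym += ytr[i]
        ym /= ntr
        yc = ytr - ym
        yhat = np.full(nte, ym)
        t = np.empty(ntr)
        tte = np.empty(nte)
        a_cap = min(max_lv, p, ntr - 1)
        for comp in range(max_lv):
            if comp < a_cap:
                # one pass: unnormalised weights w_j = x_j·yc and score t = Σ w_j x_j
                for i in range(ntr):
                    t[i] = 0.0
                nw2 = 0.0
                for j in range(p):
                    row = XcT[j]
                    s = 0.0
                    for i in range(ntr):
                        s += row[i] * yc[i]
                    w[j] = s
                    nw2 += s * s
                if nw2 > _EPS:
                    inv = 1.0 / np.sqrt(nw2)
                    for j in range(p):
                        wj = w[j] * inv
                        w[j] = wj
                        row = XcT[j]
                        for i in range(ntr):
                            t[i] += wj * row[i]
                    tt = 0.0
                    for i in range(ntr):
                        tt += t[i] * t[i]
                    if tt > _EPS:
                        qy = 0.0
                        for i in range(ntr):
                            qy += yc[i] * t[i]
                        qa = qy / tt
                        # loadings, train deflation, and test scores in one pass
                        for i in range(nte):
                            tte[i] = 0.0
                        for j in range(p):
                            row = XcT[j]
                            s = 0.0
                            for i in range(ntr):
                                s += row[i] * t[i]
                            pj = s / tt
                            pv[j] = pj
                            for i in range(ntr):
                                row[i] -= pj * t[i]
                            rowd = XdT[j]
                            wj = w[j]
                            for i in range(nte):
                                tte[i] += wj * rowd[i]
                        for j in range(p):
                            pj = pv[j]
                            rowd = XdT[j]
                            for i in range(nte):
                                rowd[i] -= pj * tte[i]
                        for i in range(nte):
                            yhat[i] += qa * tte[i]
            sse = 0.0
            for i in range(nte):
                d = yte[i] - yhat[i]
                sse += d * d
            press[comp] += sse
    return press


def center_columns(X: np.ndarray, y: np.ndarray | None = None):
    """Mean-centre columns of X (and y), returning copies plus the means.

    Returns ``(Xc, x_mean)`` or ``(Xc, yc, x_mean, y_mean)``.  The stored
    means are re-applied at prediction time so that no test-set statistics
    leak into a fitted model.
    """
    X = np.asarray(X, dtype=float)
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    if y is None:
        return Xc, x_mean
    y = np.asarray(y, dtype=float)
    y_mean = float(y.mean())
    return Xc, y - y_mean, x_mean, y_mean


def make_folds(y: np.ndarray, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Response-stratified fold labels: shuffle labels within y-rank blocks."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > n:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    fold_id = np.empty(n, dtype=np.int64)
    for start in range(0, n, n_folds):
        block = order[start : start + n_folds]
        fold_id[block] = rng.permutation(n_folds)[: block.size]
    return fold_id


@dataclass
class PLSModel:
    """A fitted PLS1 model (centring means + loadings)."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray
    loadings: np.ndarray
    coefs_y: np.ndarray
    n_components: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(np.atleast_2d(X), dtype=float)
        return _predict_kernel(
            X, self.x_mean, self.y_mean, self.weights, self.loadings,
            self.coefs_y, self.n_components,
        )


@dataclass
class PLSCVResult:
    """Outcome of latent-variable selection by k-fold cross-validation."""

    nlvs: int  # optimal latent-variable count
    rmsecv: float  # at nlvs
    rmsec: float  # full-calibration refit at nlvs
    rmsecv_by_lv: np.ndarray  # index a-1 -> a latent variables
    model: PLSModel  # refit on all rows at nlvs


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit PLS1 with ``n_components`` latent variables (capped by rank bounds)."""
    X = np.ascontiguousarray(np.atleast_2d(X), dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if n_components < 1:
        raise ValueError("n_components must be at least 1")
    xm, ym, W, P, q, a_eff = _fit_kernel(X, y, n_components)
    return PLSModel(x_mean=xm, y_mean=ym, weights=W, loadings=P,
                    coefs_y=q, n_components=a_eff)


def cv_score_T(
    XT: np.ndarray, y: np.ndarray, fold_id: np.ndarray, max_lv: int = 10
) -> float:
    """Minimum RMSECV over 1…max_lv latent variables for band-major ``XT``.

    Hot path of subset scoring: no refit, and the caller can gather candidate
    band subsets as contiguous row slices of a pre-transposed matrix.
    """
    p, n = XT.shape
    n_folds = int(fold_id.max()) + 1
    press = _cv_press_kernel_T(XT, y, fold_id, n_folds, max(1, min(max_lv, p)))
    return float(np.sqrt(press.min() / n))


def cv_score(
    X: np.ndarray, y: np.ndarray, fold_id: np.ndarray, max_lv: int = 10
) -> float:
    """Minimum RMSECV over 1…max_lv latent variables (no refit)."""
    XT = np.ascontiguousarray(np.atleast_2d(X).T, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    return cv_score_T(XT, y, fold_id, max_lv)


def pls_cv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 10,
    folds: int | np.ndarray = 5,
    seed: int = 0,
) -> PLSCVResult:
    """Choose the PLS latent-variable count by k-fold cross-validation.

    ``folds`` may be a fold count (labels derived from ``y`` and ``seed``) or
    a precomputed per-sample label array, which lets many candidate band
    subsets share identical folds.  Ties in RMSECV resolve to fewer
    components.  RMSEC comes from the full-data refit at the chosen count.
    """
    X = np.ascontiguousarray(np.atleast_2d(X), dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on sample count")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance")
    if isinstance(folds, (int, np.integer)):
        fold_id = make_folds(y, int(folds), seed)
        n_folds = int(folds)
    else:
        fold_id = np.ascontiguousarray(folds, dtype=np.int64)
        n_folds = int(fold_id.max()) + 1
    max_lv_eff = max(1, min(max_lv, p))
    XT = np.ascontiguousarray(X.T)
    press = _cv_press_kernel_T(XT, y, fold_id, n_folds, max_lv_eff)
    rmsecv_by_lv = np.sqrt(press / n)
    nlvs = int(np.argmin(rmsecv_by_lv)) + 1
    model = pls_fit(X, y, nlvs)
    rmsec = float(np.sqrt(np.mean((y - model.predict(X)) ** 2)))
    return PLSCVResult(
        nlvs=nlvs,
        rmsecv=float(rmsecv_by_lv[nlvs - 1]),
        rmsec=rmsec,
        rmsecv_by_lv=rmsecv_by_lv,
        model=model,
    )
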