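"""Deterministic one-dimensional Gaussian mixtures for bimodality checks.

A small EM implementation specialized to 1-d data with one or two
components.  Initialization is deterministic (quantile splits), so results
are reproducible without a seed, and a fit costs microseconds — the
genome-wide screen runs it twice per gene.  Agreement with
scikit-learn's GaussianMixture is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# floor on component SDs (log10 scale): prevents the EM from collapsing a
# component onto a couple of tail points, a degenerate "mode" whose density
# spike would otherwise dominate the likelihood comparison
_SD_FLOOR = 1e-2
_LOG2PI = np.log(2 * np.pi)


@dataclass
class Gmm1dFit:
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    n_components: int


def _loglik_k1(x):
    mu = x.mean()
    sd = max(x.std(), _SD_FLOOR)
    ll = -0.5 * (_LOG2PI + 2 * np.log(sd) + ((x - mu) / sd) ** 2).sum()
    return mu, sd, float(ll)


def fit_gmm1d(x: np.ndarray, n_components: int, max_iter: int = 300, tol: float = 1e-5) -> Gmm1dFit:
    x = np.asarray(x, dtype=float)
    n = x.size
    if n_components == 1:
        mu, sd, ll = _loglik_k1(x)
        bic = 2 * np.log(n) - 2 * ll
        return Gmm1dFit(np.array([1.0]), np.array([mu]), np.array([sd]), ll, bic, 1)
    if n_components != 2:
        raise ValueError("only 1 or 2 components supported")

    best = None
    for q in (0.25, 0.5, 0.75):
        thr = np.quantile(x, q)
        lo, hi = x[x <= thr], x[x > thr]
        if lo.size < 2 or hi.size < 2:
            continue
        params = (
            np.array([lo.size / n, hi.size / n]),
            np.array([lo.mean(), hi.mean()]),
            np.maximum([lo.std(), hi.std()], _SD_FLOOR),
        )
        fit = _em(x, *params, max_iter, tol)
        if best is None or fit[3] > best[3]:
            best = fit
    if best is None:  # degenerate spread; fall back to single component
        mu, sd, ll = _loglik_k1(x)
        bic = 2 * np.log(n) - 2 * ll
        return Gmm1dFit(np.array([1.0]), np.array([mu]), np.array([sd]), ll, bic, 1)
    w, mu, sd, ll = best
    bic = 5 * np.log(n) - 2 * ll
    order = np.argsort(mu)
    return Gmm1dFit(w[order], mu[order], sd[order], ll, bic, 2)


def fit_gmm1d_batch(X: np.ndarray, max_iter: int = 200, tol: float = 1e-5):
    """Fit 1- and 2-component mixtures to every row of ``X`` at once.

    Same initializations and stopping rule as :func:`fit_gmm1d`, vectorized
    across rows (genes); the genome-wide screen calls this once instead of
    once per gene.  Returns a dict of per-row arrays: means/sds/weights of
    the best 2-component fit (components sorted by mean), log-likelihoods
    and BICs of both fits.
    """
    X = np.asarray(X, dtype=float)
    G, n = X.shape
    mu1 = X.mean(axis=1)
    sd1 = np.maximum(X.std(axis=1), _SD_FLOOR)
    ll1 = -0.5 * (
        n * (_LOG2PI + 2 * np.log(sd1))
        + (((X - mu1[:, None]) / sd1[:, None]) ** 2).sum(axis=1)
    )
    bic1 = 2 * np.log(n) - 2 * ll1

    Xs = np.sort(X, axis=1)
    best = None
    for q in (0.25, 0.5, 0.75):
        k = int(round(q * n))
        if k < 2 or n - k < 2:
            continue
        lo, hi = Xs[:, :k], Xs[:, k:]
        w0 = np.tile([k / n, 1 - k / n], (G, 1))
        mu0 = np.column_stack([lo.mean(axis=1), hi.mean(axis=1)])
        sd0 = np.maximum(
            np.column_stack([lo.std(axis=1), hi.std(axis=1)]), _SD_FLOOR
        )
        w, mu, sd, ll = _em_batch(X, w0, mu0, sd0, max_iter, tol)
        if best is None:
            best = [w, mu, sd, ll]
        else:
            better = ll > best[3]
            for arr, new in zip(best[:3], (w, mu, sd)):
                arr[better] = new[better]
            best[3] = np.maximum(best[3], ll)
    w, mu, sd, ll2 = best
    order = np.argsort(mu, axis=1)
    w = np.take_along_axis(w, order, axis=1)
    mu = np.take_along_axis(mu, order, axis=1)
    sd = np.take_along_axis(sd, order, axis=1)
    bic2 = 5 * np.log(n) - 2 * ll2
    return {
        "weights": w, "means": mu, "sds": sd,
        "loglik1": ll1, "bic1": bic1, "loglik2": ll2, "bic2": bic2,
    }


def _em_batch(X, w, mu, sd, max_iter, tol):
    """EM on every row at once, retiring converged rows in blocks of 10."""
    G, n = X.shape
    W, MU, SD = w.copy(), mu.copy(), sd.copy()
    LL = np.full(G, -np.inf)
    active = np.arange(G)
    Xa, w, mu, sd = X, w.copy(), mu.copy(), sd.copy()
    ll_old = np.full(G, -np.inf)
    for it in range(max_iter):
        logp = (
            np.log(w)[:, :, None]
            - 0.5
            * (
                _LOG2PI
                + 2 * np.log(sd)[:, :, None]
                + ((Xa[:, None, :] - mu[:, :, None]) / sd[:, :, None]) ** 2
            )
        )
        m = logp.max(axis=1)
        lse = m + np.log(np.exp(logp - m[:, None, :]).sum(axis=1))
        ll = lse.sum(axis=1)
        resp = np.exp(logp - lse[:, None, :])
        nk = np.maximum(resp.sum(axis=2), 1e-12)
        w = nk / n
        mu = (resp * Xa[:, None, :]).sum(axis=2) / nk
        var = (resp * Xa[:, None, :] ** 2).sum(axis=2) / nk - mu**2
        sd = np.sqrt(np.maximum(var, _SD_FLOOR**2))
        done = (ll - ll_old[active]) < tol * n
        ll_old[active] = ll
        W[active], MU[active], SD[active], LL[active] = w, mu, sd, ll
        if it % 10 == 9 or it == max_iter - 1:
            keep = ~done
            if not keep.any():
                break
            if not keep.all():
                active = active[keep]
                Xa = Xa[keep]
                w, mu, sd = w[keep], mu[keep], sd[keep]
    return W, MU, SD, LL


def _em(x, w, mu, sd, max_iter, tol):
    n = x.size
    ll_old = -np.inf
    for _ in range(max_iter):
        # E step in log space
        logp = (
            np.log(w)[:, None]
            - 0.5 * (_LOG2PI + 2 * np.log(sd)[:, None] + ((x[None, :] - mu[:, None]) / sd[:, None]) ** 2)
        )
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        resp = np.exp(logp - lse)
        # M step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp @ x) / nk
        var = (resp @ x**2) / nk - mu**2
        sd = np.sqrt(np.maximum(var, _SD_FLOOR**2))
        # per-sample likelihood change, as in scikit-learn's lower-bound rule
        if ll - ll_old < tol * n:
            break
        ll_old = ll
    return w, mu, sd, ll
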