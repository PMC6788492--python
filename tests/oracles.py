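"""Independent brute-force / closed-form oracles used by the tests.

Every function here re-derives a quantity from first principles (loops,
eigendecompositions, textbook formulas) without touching the package's
implementation paths, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def pearson_p_oracle(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p from the textbook t transform, via loops."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2.0 * float(stats.t.sf(abs(t), n - 2))


def student_t_oracle(a, b) -> tuple[float, float]:
    """Pooled-variance two-sample t-test (b vs a), textbook formulas."""
    a = list(map(float, a))
    b = list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (mb - ma) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * float(stats.t.sf(abs(t), na + nb - 2))
    return t, p


def pca_oracle(X: np.ndarray, scale: bool):
    """PCA via eigendecomposition of the covariance/correlation matrix.

    Returns (explained_fraction, scores, loadings) with the same
    largest-|loading|-positive sign convention as the package.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    c = X.mean(axis=0)
    Z = X - c
    if scale:
        Z = Z / X.std(axis=0, ddof=1)
    C = Z.T @ Z / (n - 1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    r = min(n - 1, p)
    w, V = np.clip(w[:r], 0, None), V[:, :r]
    for j in range(r):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    scores = Z @ V
    explained = w * (n - 1) / (Z**2).sum()
    return explained, scores, V


def youden_oracle(scores, labels, positive):
    """Exhaustive search over every midpoint cutpoint and both orientations."""
    s = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) == positive
    uniq = np.unique(s)
    cands = [-np.inf, np.inf] + [
        (a + b) / 2.0 for a, b in zip(uniq[:-1], uniq[1:])
    ]
    best = -np.inf
    for t in cands:
        for orient in ("above", "below"):
            pred = s > t if orient == "above" else s < t
            sens = (pred & pos).sum() / pos.sum()
            spec = (~pred & ~pos).sum() / (~pos).sum()
            best = max(best, sens + spec - 1.0)
    return best


def stability_oracle(y: np.ndarray, strata: list):
    """Model-based reference-gene stability, straight from the equations.

    Pure-Python loops: sample-centering, per-stratum means and variances,
    the k/(k-2) intragroup bias correction, moment estimate of the
    between-stratum deviation variance, shrunken deviations, and
    rho_i = mean_g(|dtilde_ig| + sqrt(sigma2_ig / n_g)).  Returns
    (gene_stabilities, pair_stabilities) with pairs keyed by index tuples.
    """
    y = np.asarray(y, dtype=float)
    k, n = y.shape
    groups = sorted(set(strata))
    G = len(groups)
    # sample centering
    z = [[y[i][j] - sum(y[t][j] for t in range(k)) / k for j in range(n)] for i in range(k)]
    zbar = [[0.0] * G for _ in range(k)]
    u = [[0.0] * G for _ in range(k)]
    n_g = []
    for gi, g in enumerate(groups):
        idx = [j for j in range(n) if strata[j] == g]
        n_g.append(len(idx))
        v = []
        for i in range(k):
            vals = [z[i][j] for j in idx]
            m = sum(vals) / len(vals)
            zbar[i][gi] = m
            v.append(sum((x - m) ** 2 for x in vals) / (len(vals) - 1))
        vsum = sum(v)
        for i in range(k):
            if k > 2:
                sigma2 = max((v[i] - vsum / (k * k - k)) * k / (k - 2), 0.0)
            else:
                sigma2 = v[i]
            u[i][gi] = sigma2 / len(idx)
    d = [
        [zbar[i][gi] - sum(zbar[i]) / G for gi in range(G)]
        for i in range(k)
    ]
    ssd = sum(d[i][gi] ** 2 for i in range(k) for gi in range(G))
    ubar = sum(u[i][gi] for i in range(k) for gi in range(G)) / (k * G)
    gamma2 = max(ssd / ((k - 1) * (G - 1)) - ubar, 0.0)
    dt = [
        [
            d[i][gi] * gamma2 / (gamma2 + u[i][gi]) if gamma2 + u[i][gi] > 0 else 0.0
            for gi in range(G)
        ]
        for i in range(k)
    ]
    rho = [
        sum(abs(dt[i][gi]) + math.sqrt(u[i][gi]) for gi in range(G)) / G
        for i in range(k)
    ]
    pairs = {}
    for i, j in itertools.combinations(range(k), 2):
        vals = [
            abs((dt[i][gi] + dt[j][gi]) / 2.0) + math.sqrt((u[i][gi] + u[j][gi]) / 4.0)
            for gi in range(G)
        ]
        pairs[(i, j)] = sum(vals) / G
    return rho, pairs
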