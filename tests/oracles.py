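"""Independent brute-force oracles used to check the package's estimators.

Everything here is deliberately naive — plain Python loops, explicit
enumeration, textbook linear algebra — and shares no code with the
implementation under test.
"""

from itertools import combinations, permutations

import numpy as np


def brute_cwm(trait_values, abundances):
    """Weighted mean by explicit loop over species with known traits."""
    num = 0.0
    den = 0.0
    for t, a in zip(trait_values, abundances):
        if t is None or (isinstance(t, float) and np.isnan(t)):
            continue
        num += t * a
        den += a
    return num / den if den > 0 else float("nan")


def brute_awm(gradient_values, abundances):
    num = 0.0
    total = 0.0
    for L, a in zip(gradient_values, abundances):
        num += L * a
        total += a
    return num / total


def brute_awsd(gradient_values, abundances):
    awm = brute_awm(gradient_values, abundances)
    ss = 0.0
    total = 0.0
    for L, a in zip(gradient_values, abundances):
        ss += a * (L - awm) ** 2
        total += a
    return (ss / total) ** 0.5


def sequential_anova_ss(y, term_blocks):
    """Type-I sums of squares by incremental least-squares projection.

    ``term_blocks`` is an ordered list of design-matrix blocks (2-d arrays,
    intercept NOT included).  Returns the per-term SS list and the residual
    SS, computed by comparing residual sums of squares of nested fits.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    prev = rss(X)
    ss_terms = []
    for block in term_blocks:
        X = np.hstack([X, np.asarray(block, dtype=float).reshape(n, -1)])
        cur = rss(X)
        ss_terms.append(prev - cur)
        prev = cur
    return ss_terms, prev


def irls_poisson(X, y, tol=1e-12, max_iter=200):
    """Poisson log-link GLM by hand-rolled iteratively reweighted LS.

    Returns (beta, deviance_trace).  The deviance must decrease (up to
    floating noise) across iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    devs = []

    def deviance(mu):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * (term - (y - mu)).sum())

    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(eta)
        devs.append(deviance(mu))
        W = mu
        z = eta + (y - mu) / mu
        WX = X * W[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    devs.append(deviance(np.exp(X @ beta)))
    return beta, devs


def enumerate_null_awm(pool_values, abundances):
    """Every null AWM: all site subsets x all abundance assignments."""
    pool_values = [float(v) for v in pool_values]
    abundances = [float(a) for a in abundances]
    total = sum(abundances)
    n = len(abundances)
    draws = []
    for subset in combinations(range(len(pool_values)), n):
        vals = [pool_values[i] for i in subset]
        for perm in permutations(abundances):
            draws.append(sum(v * a for v, a in zip(vals, perm)) / total)
    return np.array(draws)


def brute_spearman_S(x, y):
    """S statistic from first principles with midranks for ties."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    return sum((a - b) ** 2 for a, b in zip(rx, ry))
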