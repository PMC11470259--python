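"""Independent brute-force oracles used by the test suite.

Everything here is deliberately coded with plain loops and scalars, separate
from the package's vectorized implementations, so the two routes can be
compared numerically.
"""

from __future__ import annotations

import math

import numpy as np


def combat_brute_force(X, batches, correction_mode="both", tol=1e-12,
                       max_iter=100000):
    """Loop-based standardize -> moments -> EB fixed point -> adjust."""
    X = np.asarray(X, dtype=float)
    N, D = X.shape
    batches = list(batches)
    levels = []
    for b in batches:
        if b not in levels:
            levels.append(b)
    idx = {lv: [j for j in range(N) if batches[j] == lv] for lv in levels}

    # grand mean and pooled scale
    alpha = np.zeros(D)
    sigma2 = np.zeros(D)
    for g in range(D):
        for lv in levels:
            rows = idx[lv]
            m = sum(X[j, g] for j in rows) / len(rows)
            alpha[g] += (len(rows) / N) * m
            sigma2[g] += sum((X[j, g] - m) ** 2 for j in rows)
        sigma2[g] /= N
    sigma = np.sqrt(sigma2)
    Z = np.zeros_like(X)
    for j in range(N):
        for g in range(D):
            Z[j, g] = (X[j, g] - alpha[g]) / sigma[g]

    Xs = np.zeros_like(X)
    for lv in levels:
        rows = idx[lv]
        n = len(rows)
        gamma_hat = np.array([sum(Z[j, g] for j in rows) / n for g in range(D)])
        delta2_hat = np.array([
            sum((Z[j, g] - gamma_hat[g]) ** 2 for j in rows) / (n - 1)
            for g in range(D)
        ])
        gbar = float(np.mean(gamma_hat))
        tau2 = float(sum((v - gbar) ** 2 for v in gamma_hat) / (D - 1))
        V = float(np.mean(delta2_hat))
        S2 = float(sum((v - V) ** 2 for v in delta2_hat) / (D - 1))
        if S2 <= 1e-12 * V * V:
            lam, theta = 1.0, 0.0
        else:
            lam = (V * V + 2.0 * S2) / S2
            theta = (V ** 3 + V * S2) / S2

        g_star = gamma_hat.copy()
        d2_star = delta2_hat.copy()
        for _ in range(max_iter):
            g_new = np.array([
                (n * tau2 * gamma_hat[g] + d2_star[g] * gbar)
                / (n * tau2 + d2_star[g]) for g in range(D)
            ])
            d2_new = np.array([
                (theta + 0.5 * sum((Z[j, g] - g_new[g]) ** 2 for j in rows))
                / (n / 2.0 + lam - 1.0) for g in range(D)
            ])
            ch = max(
                max(abs(g_new[g] - g_star[g]) / max(abs(g_star[g]), 1e-12)
                    for g in range(D)),
                max(abs(d2_new[g] - d2_star[g]) / max(abs(d2_star[g]), 1e-12)
                    for g in range(D)),
            )
            g_star, d2_star = g_new, d2_new
            if ch < tol:
                break

        g_adj = g_star.copy()
        d_adj = np.sqrt(d2_star)
        if correction_mode == "additive_only":
            d_adj = np.ones(D)
        elif correction_mode == "multiplicative_only":
            g_adj = np.zeros(D)
        for j in rows:
            for g in range(D):
                Xs[j, g] = sigma[g] * (Z[j, g] - g_adj[g]) / d_adj[g] + alpha[g]
    return Xs


def nonparametric_shrink_brute_force(Z, gamma_hat, delta2_hat):
    """Double-loop leave-one-out posterior with log-space weights."""
    Z = np.asarray(Z, dtype=float)
    n, D = Z.shape
    g_star = np.zeros(D)
    d2_star = np.zeros(D)
    for g in range(D):
        logw = []
        cand = []
        for gp in range(D):
            if gp == g:
                continue
            ll = 0.0
            for j in range(n):
                ll += (-0.5 * math.log(2.0 * math.pi * delta2_hat[gp])
                       - (Z[j, g] - gamma_hat[gp]) ** 2 / (2.0 * delta2_hat[gp]))
            logw.append(ll)
            cand.append(gp)
        mx = max(logw)
        w = [math.exp(v - mx) for v in logw]
        tot = sum(w)
        g_star[g] = sum(wi * gamma_hat[gp] for wi, gp in zip(w, cand)) / tot
        d2_star[g] = sum(wi * delta2_hat[gp] for wi, gp in zip(w, cand)) / tot
    return g_star, d2_star


def auroc_pairwise(scores, labels) -> float:
    """Exhaustive positive/negative pair counting with half-tie credit."""
    scores = list(map(float, scores))
    labels = list(map(bool, labels))
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def bh_step_up(pvals):
    """Reference BH step-up, coded from the definition."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank, 1.0)
        q[i] = val
        prev = val
    return q
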