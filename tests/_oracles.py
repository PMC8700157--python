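"""Independent numeric convex-solver oracles for the prox subproblems.

Strategy: replace each nonsmooth term |x| (or ||x||_2) by its smoothed form
sqrt(x^2 + eps^2) (sqrt(||x||^2 + eps^2)) and minimize the resulting smooth,
strongly convex objective by damped Newton, with eps continuation down to
1e-12.  The smoothing bias is O(eps), so the continuation limit agrees with
the exact minimizer to ~1e-10 — well inside every tolerance asserted against
these oracles.  Nothing here shares code with the package's closed-form /
dynamic-programming prox operators.
"""

from __future__ import annotations

import numpy as np

# Continuation stops near 1e-9: below that, double precision cannot resolve
# the smoothed subgradient inside a fused group (d/sqrt(d^2+eps^2) quantizes),
# and the residual smoothing bias is O(1e-7) — inside every asserted tolerance.
STAGES = (1e-2, 1e-4, 1e-6, 1e-8, 1e-9)


def _newton(grad, hess, x0, tol=1e-10, maxit=300):
    """Damped Newton on a smooth strongly convex function via its gradient."""
    x = np.asarray(x0, dtype=float).copy()
    for _ in range(maxit):
        g = grad(x)
        gn = np.linalg.norm(g)
        if gn < tol:
            break
        step = np.linalg.solve(hess(x), g)
        t = 1.0
        for _ in range(50):
            xn = x - t * step
            if np.linalg.norm(grad(xn)) <= (1 - 1e-3 * t) * gn + 1e-18:
                break
            t *= 0.5
        x = xn
    return x


def fused_vec_oracle(a, alpha, beta):
    """argmin 1/2||t-a||^2 + alpha*sum|t_k| + beta*sum_{k<l}|t_k - t_l|."""
    a = np.asarray(a, dtype=float)
    x = a.copy()
    for eps in STAGES:
        def grad(t):
            d = t[:, None] - t[None, :]
            return (
                (t - a)
                + alpha * t / np.sqrt(t**2 + eps**2)
                + beta * np.sum(d / np.sqrt(d**2 + eps**2), axis=1)
            )

        def hess(t):
            d = t[:, None] - t[None, :]
            w = eps**2 / np.sqrt(d**2 + eps**2) ** 3
            np.fill_diagonal(w, 0.0)
            H = -beta * w
            np.fill_diagonal(
                H, 1.0 + alpha * eps**2 / np.sqrt(t**2 + eps**2) ** 3 + beta * w.sum(axis=1)
            )
            return H

        x = _newton(grad, hess, x)
    return x


def group_vec_oracle(a, t1, t2):
    """argmin 1/2||t-a||^2 + t1*sum|t_k| + t2*||t||_2."""
    a = np.asarray(a, dtype=float)
    x = a.copy()
    for eps in STAGES:
        def grad(t):
            r = np.sqrt(np.sum(t**2) + eps**2)
            return (t - a) + t1 * t / np.sqrt(t**2 + eps**2) + t2 * t / r

        def hess(t):
            r = np.sqrt(np.sum(t**2) + eps**2)
            H = t2 * (np.eye(t.size) / r - np.outer(t, t) / r**3)
            H[np.diag_indices_from(H)] += 1.0 + t1 * eps**2 / np.sqrt(t**2 + eps**2) ** 3
            return H

        x = _newton(grad, hess, x)
    return x


def chain_vec_oracle(y, w):
    """argmin 1/2||t-y||^2 + sum_i w_i |t_i - t_{i+1}| (weighted chain)."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    m = y.size
    x = y.copy()
    for eps in STAGES:
        def grad(t):
            d = np.diff(t)
            s = w * d / np.sqrt(d**2 + eps**2)
            g = t - y
            g[:-1] -= s
            g[1:] += s
            return g

        def hess(t):
            d = np.diff(t)
            c = w * eps**2 / np.sqrt(d**2 + eps**2) ** 3
            H = np.diag(np.ones(m) + np.r_[c, 0] + np.r_[0, c])
            for i in range(m - 1):
                H[i, i + 1] = H[i + 1, i] = -c[i]
            return H

        x = _newton(grad, hess, x)
    return x


def prox_whole_oracle(A, eta, family, lambda1, lambda2):
    """Whole-problem prox oracle over the full (K, p, p) variable stack.

    Minimizes 1/2||Theta - A||_F^2 + eta*g(Theta) over all K*p*p entries at
    once (no use of the cellwise separability the package exploits).
    """
    A = np.asarray(A, dtype=float)
    K, p, _ = A.shape
    n = K * p * p
    a = A.ravel()
    t1 = eta * lambda1
    t2 = eta * lambda2

    def ind(k, i, j):
        return (k * p + i) * p + j

    l1_idx = np.array(
        [ind(k, i, j) for k in range(K) for i in range(p) for j in range(p) if i != j],
        dtype=int,
    )
    if family == "fused":
        pairs = [
            (ind(k, i, j), ind(l, i, j))
            for k in range(K)
            for l in range(k + 1, K)
            for i in range(p)
            for j in range(p)
        ]
        pa = np.array([q[0] for q in pairs], dtype=int)
        pb = np.array([q[1] for q in pairs], dtype=int)
    else:
        groups = [
            np.array([ind(k, i, j) for k in range(K)], dtype=int)
            for i in range(p)
            for j in range(p)
            if i != j
        ]

    x = a.copy()
    for eps in STAGES:
        def grad(t):
            g = t - a
            u = t[l1_idx]
            g[l1_idx] += t1 * u / np.sqrt(u**2 + eps**2)
            if family == "fused":
                d = t[pa] - t[pb]
                s = t2 * d / np.sqrt(d**2 + eps**2)
                np.add.at(g, pa, s)
                np.add.at(g, pb, -s)
            else:
                for gi in groups:
                    v = t[gi]
                    g[gi] += t2 * v / np.sqrt(np.sum(v**2) + eps**2)
            return g

        def hess(t):
            H = np.eye(n)
            u = t[l1_idx]
            H[l1_idx, l1_idx] += t1 * eps**2 / np.sqrt(u**2 + eps**2) ** 3
            if family == "fused":
                d = t[pa] - t[pb]
                c = t2 * eps**2 / np.sqrt(d**2 + eps**2) ** 3
                for q in range(len(pa)):
                    i, j = pa[q], pb[q]
                    H[i, i] += c[q]
                    H[j, j] += c[q]
                    H[i, j] -= c[q]
                    H[j, i] -= c[q]
            else:
                for gi in groups:
                    v = t[gi]
                    r = np.sqrt(np.sum(v**2) + eps**2)
                    blk = t2 * (np.eye(v.size) / r - np.outer(v, v) / r**3)
                    H[np.ix_(gi, gi)] += blk
            return H

        x = _newton(grad, hess, x)
    return x.reshape(K, p, p)
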