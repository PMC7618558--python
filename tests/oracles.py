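"""Independent reference implementations used to cross-check the package.

These deliberately take different computational routes from the library code
(explicit loops, scaled least squares, linear-space enumeration) so that
agreement is evidence of correctness rather than shared bugs.
"""

import itertools

import numpy as np


def wls_through_origin(bx, by, sy):
    """IVW oracle: weighted least squares via a scaled lstsq solve."""
    w = 1.0 / np.asarray(sy, float) ** 2
    X = (np.asarray(bx, float) * np.sqrt(w))[:, None]
    y = np.asarray(by, float) * np.sqrt(w)
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    theta = float(theta[0])
    se_fixed = float(X[:, 0] @ X[:, 0]) ** -0.5
    resid = y - X[:, 0] * theta
    q = float(resid @ resid)
    return theta, se_fixed, q


def wls_with_intercept(bx, by, sy):
    """Egger oracle: 2-parameter WLS via scaled lstsq."""
    w = 1.0 / np.asarray(sy, float) ** 2
    sw = np.sqrt(w)
    X = np.column_stack([sw, np.asarray(bx, float) * sw])
    y = np.asarray(by, float) * sw
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    q = float(resid @ resid)
    cov = np.linalg.inv(X.T @ X)
    return coef, np.sqrt(np.diag(cov)), q


def brute_weighted_quantile(values, weights, q):
    """Weighted quantile by explicit piecewise-linear scan."""
    pairs = sorted(zip(values, weights))
    v = [p[0] for p in pairs]
    w = [p[1] for p in pairs]
    total = sum(w)
    s = []
    acc = 0.0
    for wi in w:
        s.append((acc + wi / 2) / total)
        acc += wi
    if q <= s[0]:
        return v[0]
    if q >= s[-1]:
        return v[-1]
    for i in range(len(s) - 1):
        if s[i] <= q <= s[i + 1]:
            frac = (q - s[i]) / (s[i + 1] - s[i])
            return v[i] + frac * (v[i + 1] - v[i])
    raise AssertionError("unreachable")


def coloc_enumeration(l1, l2, p1, p2, p12):
    """Posterior hypothesis probabilities by linear-space enumeration over
    every causal-variant assignment (trait1 config x trait2 config)."""
    bf1 = np.exp(np.asarray(l1, float))
    bf2 = np.exp(np.asarray(l2, float))
    k = len(bf1)
    h = np.zeros(5)
    h[0] = 1.0
    for j in range(k):
        h[1] += p1 * bf1[j]
        h[2] += p2 * bf2[j]
        h[4] += p12 * bf1[j] * bf2[j]
    for j, m in itertools.product(range(k), range(k)):
        if j != m:
            h[3] += p1 * p2 * bf1[j] * bf2[m]
    return h / h.sum()


def brute_force_clump(df, ld, r2_threshold, window_bp):
    """Greedy clumping re-implemented with explicit per-candidate scans."""
    rows = df.to_dict(orient="records")
    rows.sort(key=lambda r: (r["pval"], r["chrom"], r["pos"], r["variant_id"]))
    kept = []
    for cand in rows:
        blocked = False
        for acc in kept:
            if (
                acc["chrom"] == cand["chrom"]
                and abs(acc["pos"] - cand["pos"]) <= window_bp
                and ld.r2(acc["variant_id"], cand["variant_id"]) >= r2_threshold
            ):
                blocked = True
                break
        if not blocked:
            kept.append(cand)
    return [r["variant_id"] for r in kept]
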