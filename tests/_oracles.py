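"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths (and vectorized
shortcuts): plain loops, sorting, and math.comb, so that agreement with
the production implementations is meaningful.
"""

import math

import numpy as np


def bh_brute_force(pvals):
    """BH q-values as min over achievable thresholds, O(m^2) loops."""
    p = list(map(float, pvals))
    m = len(p)
    q = []
    for pi in p:
        best = 1.0
        for t in p:
            if t >= pi:
                count = sum(1 for x in p if x <= t)
                best = min(best, t * m / count)
        q.append(min(best, 1.0))
    return q


def two_proportion_z(x1, n1, x2, n2):
    """Classic pooled two-proportion z statistic."""
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    return (p1 - p2) / se


def hypergeom_upper_tail(k, N, K, n):
    """P[X >= k] for X ~ Hypergeom(N, K, n) via exact combinatorics."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        if n - x > N - K:
            continue
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def pca_scores_eig(matrix, k):
    """PCA scores via explicit covariance eigendecomposition."""
    X = np.asarray(matrix, dtype=float)
    centered = X - X.mean(axis=0)
    cov = centered.T @ centered / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scores = centered @ vecs[:, :k]
    frac = vals / vals.sum()
    return scores, frac[:k]


def tmm_by_hand(counts, trim_m=0.30, trim_a=0.05):
    """Step-by-step TMM on a small counts matrix (genes x samples)."""
    counts = np.asarray(counts, dtype=float)
    G, S = counts.shape
    libs = [counts[:, j].sum() for j in range(S)]

    # reference: sample whose 75th-percentile cpm is closest to the mean
    q75 = []
    for j in range(S):
        cpm = sorted(counts[g, j] / (libs[j] / 1e6) for g in range(G))
        q75.append(np.quantile(cpm, 0.75))
    mean_q75 = sum(q75) / S
    ref = min(range(S), key=lambda j: abs(q75[j] - mean_q75))

    log_factors = []
    for j in range(S):
        if j == ref:
            log_factors.append(0.0)
            continue
        ms, as_, ws = [], [], []
        for g in range(G):
            o, r = counts[g, j], counts[g, ref]
            if o > 0 and r > 0:
                po, pr = o / libs[j], r / libs[ref]
                ms.append(math.log2(po / pr))
                as_.append(0.5 * math.log2(po * pr))
                ws.append((libs[j] - o) / (libs[j] * o)
                          + (libs[ref] - r) / (libs[ref] * r))
        n = len(ms)
        if n == 0 or max(abs(m) for m in ms) < 1e-6:
            log_factors.append(0.0)
            continue
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = {i: r + 1 for r, i in enumerate(
            sorted(range(n), key=lambda i: ms[i]))}
        rank_a = {i: r + 1 for r, i in enumerate(
            sorted(range(n), key=lambda i: as_[i]))}
        num = den = 0.0
        kept = 0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += ms[i] / ws[i]
                den += 1.0 / ws[i]
                kept += 1
        log_factors.append(num / den if kept else 0.0)

    factors = [2.0 ** lf for lf in log_factors]
    gm = math.exp(sum(math.log(f) for f in factors) / S)
    return [f / gm for f in factors], ref
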