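"""Independent brute-force oracles used to cross-check the implementation."""

import numpy as np


def bh_stepup(pvals, alpha=0.05):
    """Benjamini-Hochberg by direct definition: reject the largest k with
    p_(k) <= k*alpha/m; q-values as the monotone minimum of m*p_(i)/i."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m * p[order[i]] / (i + 1))
        q_sorted[i] = running
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    k = 0
    for i in range(m):
        if p[order[i]] <= (i + 1) * alpha / m:
            k = i + 1
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject, q


def trapezoid_auc(scores, labels):
    """Area under the empirical ROC step curve by trapezoidal integration,
    enumerating every distinct threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    thresholds = np.r_[np.inf, np.unique(scores)[::-1]]
    tpr = [np.mean(scores[labels] >= t) for t in thresholds]
    fpr = [np.mean(scores[~labels] >= t) for t in thresholds]
    tpr, fpr = np.array(tpr), np.array(fpr)
    return float(np.trapezoid(tpr, fpr))


def pairwise_auc(scores, labels):
    """AUC by exhaustive pair enumeration with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


def overlap(a_start, a_stop, b_start, b_stop):
    return a_start < b_stop and b_start < a_stop


def brute_penetrance(calls_per_case, band_intervals):
    """Quadratic per-case overlap count: band -> (gain_frac, loss_frac)."""
    n = len(calls_per_case)
    out = {}
    for band, (chrom, start, stop) in band_intervals.items():
        fracs = {}
        for direction in ("gain", "loss"):
            k = sum(
                any(c.direction == direction and c.chrom == chrom
                    and overlap(c.start, c.stop, start, stop) for c in calls)
                for calls in calls_per_case.values())
            fracs[direction] = k / n
        out[band] = (fracs["gain"], fracs["loss"])
    return out


def brute_runs(states, chroms, min_len):
    """Maximal constant-sign runs not crossing chromosomes, as
    (start_idx, stop_idx_inclusive, sign) with length >= min_len."""
    runs = []
    i = 0
    n = len(states)
    while i < n:
        if states[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and states[j + 1] == states[i] and chroms[j + 1] == chroms[i]:
            j += 1
        if j - i + 1 >= min_len:
            runs.append((i, j, states[i]))
        i = j + 1
    return runs


def brute_upgma_heights(dist):
    """Average-linkage merge heights by direct agglomeration on a full
    distance matrix, using unweighted (size-proportional) averaging."""
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for ai, a in enumerate(keys):
            for b in keys[ai + 1:]:
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        new_key = max(clusters) + 1
        clusters[new_key] = clusters.pop(a) + clusters.pop(b)
    return np.array(heights)


def fisher_two_sided(table):
    """Two-sided Fisher exact p by full hypergeometric enumeration with the
    minimum-likelihood rule."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # relative slack for ties in floating point, as standard implementations use
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))
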