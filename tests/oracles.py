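"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive — explicit loops, full rescans,
textbook recurrences — and shares no code with the implementation under
test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import hypergeom


def brute_force_clump(ids, chrom, pos, pvals, dosage, r2_threshold, window_kb):
    """Greedy clumping that rescans the full candidate list every round."""
    ids = list(ids)
    chrom = list(chrom)
    pos = list(pos)
    pvals = list(pvals)
    alive = set(range(len(ids)))
    kept = []
    while alive:
        best = min(alive, key=lambda i: (pvals[i], chrom[i], pos[i]))
        kept.append(best)
        alive.discard(best)
        for j in list(alive):
            if chrom[j] != chrom[best]:
                continue
            if abs(pos[j] - pos[best]) > window_kb * 1000:
                continue
            x, y = dosage[:, best], dosage[:, j]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r * r >= r2_threshold:
                alive.discard(j)
    kept_ids = [ids[i] for i in kept]
    return sorted(kept_ids, key=lambda v: (chrom[ids.index(v)], pos[ids.index(v)]))


def loop_score(dosage, betas, pvals, threshold):
    """Per-individual explicit-loop PRS at one threshold (strict p < t)."""
    n_ind, n_var = dosage.shape
    out = np.zeros(n_ind)
    for i in range(n_ind):
        total = 0.0
        for v in range(n_var):
            if pvals[v] < threshold:
                total += dosage[i, v] * betas[v]
        out[i] = total
    return out


def lance_williams_ward(X):
    """Naive agglomerative Ward clustering via the Lance-Williams recurrence.

    Returns (merge_heights, partitions) where partitions[k] is a list of
    frozensets giving the k-cluster partition.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    # Ward merge-criterion squared distances; for singletons these are the
    # squared Euclidean distances, and the Lance-Williams recurrence below
    # updates them directly. Merge height is their square root.
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(np.sum((X[i] - X[j]) ** 2))

    def get(i, j):
        return d2[(i, j) if i < j else (j, i)]

    partitions = {n: sorted(clusters.values(), key=min)}
    heights = []
    next_id = n
    active = list(range(n))
    while len(active) > 1:
        best = None
        for a_i, i in enumerate(active):
            for j in active[a_i + 1:]:
                cost = get(i, j)
                if best is None or cost < best[0] - 1e-15:
                    best = (cost, i, j)
        cost, i, j = best
        heights.append(np.sqrt(cost))
        new = next_id
        next_id += 1
        for m in active:
            if m in (i, j):
                continue
            ni, nj, nm = sizes[i], sizes[j], sizes[m]
            dim, djm, dij = get(i, m), get(j, m), get(i, j)
            d2[(min(m, new), max(m, new))] = (
                (ni + nm) * dim + (nj + nm) * djm - nm * dij
            ) / (ni + nj + nm)
        clusters[new] = clusters[i] | clusters[j]
        sizes[new] = sizes[i] + sizes[j]
        active = [m for m in active if m not in (i, j)] + [new]
        partitions[len(active)] = sorted((clusters[m] for m in active), key=min)
    return heights, partitions


def direct_silhouette(X, labels):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.sqrt(np.sum((X[i] - X[j]) ** 2))
    s = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        a = np.mean([D[i, j] for j in same]) if same else 0.0
        b = np.inf
        for c in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == c]
            b = min(b, np.mean([D[i, j] for j in other]))
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s


def direct_dunn(X, labels, sentinel=1e12):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    uniq = sorted(set(labels))
    inter = np.inf
    intra = 0.0
    for c in uniq:
        pts = X[labels == c]
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                intra = max(intra, float(np.linalg.norm(pts[i] - pts[j])))
    for ci in range(len(uniq)):
        for cj in range(ci + 1, len(uniq)):
            for p in X[labels == uniq[ci]]:
                for q in X[labels == uniq[cj]]:
                    inter = min(inter, float(np.linalg.norm(p - q)))
    return sentinel if intra == 0 else min(inter / intra, sentinel)


def direct_connectivity(X, labels, L):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(labels)
    total = 0.0
    for i in range(n):
        dists = [(np.linalg.norm(X[i] - X[j]), j) for j in range(n) if j != i]
        dists.sort()
        for rank, (_, j) in enumerate(dists[:L], start=1):
            if labels[j] != labels[i]:
                total += 1.0 / rank
    return total


def fisher_enumeration_p(table):
    """Two-sided Fisher p by full hypergeometric enumeration (minlike rule)."""
    a, b = table[0]
    c, d = table[1]
    M, ntag, nsamp = a + b + c + d, a + c, a + b
    lo = max(0, nsamp - (M - ntag))
    hi = min(ntag, nsamp)
    xs = np.arange(lo, hi + 1)
    probs = hypergeom.pmf(xs, M, ntag, nsamp)
    p_obs = hypergeom.pmf(a, M, ntag, nsamp)
    # scipy's minlike rule: include tables with pmf <= pmf(observed) (1 + eps)
    return float(probs[probs <= p_obs * (1 + 1e-10)].sum())


def exact_subgroup_permutation_p(values, k, observed_mean):
    """Enumerate all C(n, k) subgroup assignments; one-sided toward excess."""
    values = np.asarray(values, float)
    n = len(values)
    hits = sum(1 for idx in combinations(range(n), k)
               if values[list(idx)].mean() >= observed_mean)
    return hits / comb(n, k)


def paired_t_oracle(a, b):
    """Textbook paired t from the difference vector; returns (t, p, ci)."""
    from scipy.stats import t as tdist

    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    mean = d.mean()
    se = d.std(ddof=1) / np.sqrt(n)
    t_stat = mean / se
    p = 2 * tdist.sf(abs(t_stat), n - 1)
    tcrit = tdist.ppf(0.975, n - 1)
    return t_stat, p, (mean - tcrit * se, mean + tcrit * se)


def bh_stepup(pvals):
    """Direct Benjamini-Hochberg step-up with enforced monotonicity."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * n / rank_from_top)
        adj[i] = val
        prev = val
    return adj
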