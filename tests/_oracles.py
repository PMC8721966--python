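"""Independent, deliberately naive reference implementations.

Everything here is written as straight-line scalar/loop code, independent
of the vectorized package implementations, so the two can be compared on
random fixtures.  Slow by design; only for small inputs.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def rank_average_ties(values):
    """1-based ranks with ties given their average rank."""
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2)
    return ranks


def oracle_quantile_normalize(matrix):
    """Rank-mean quantile normalization with average-tie handling."""
    a = np.asarray(matrix, dtype=float)
    n, m = a.shape
    ref = [np.mean([sorted(a[:, j])[i] for j in range(m)]) for i in range(n)]
    out = np.empty_like(a)
    for j in range(m):
        col = sorted(a[:, j])
        for i in range(n):
            positions = [k for k in range(n) if col[k] == a[i, j]]
            out[i, j] = np.mean([ref[k] for k in positions])
    return out


def oracle_tmm_factors(counts, logratio_trim=0.30, abs_trim=0.05):
    """Trimmed mean of M-values, loop form: reference by 75th percentile of
    count/library-size closest to its mean; double trim by M and A ranks;
    inverse-variance weighted mean of surviving M; geometric-mean centering."""
    y = np.asarray(counts, dtype=float)
    n_genes, n_samples = y.shape
    lib = [sum(y[:, j]) for j in range(n_samples)]
    f75 = [np.quantile([y[i, j] / lib[j] for i in range(n_genes)], 0.75)
           for j in range(n_samples)]
    mean75 = sum(f75) / n_samples
    ref = min(range(n_samples), key=lambda j: abs(f75[j] - mean75))

    factors = []
    for k in range(n_samples):
        if k == ref:
            factors.append(1.0)
            continue
        ms, As, vs = [], [], []
        for g in range(n_genes):
            o, r = y[g, k], y[g, ref]
            if o > 0 and r > 0:
                ms.append(math.log2((o / lib[k]) / (r / lib[ref])))
                As.append(0.5 * math.log2((o / lib[k]) * (r / lib[ref])))
                vs.append((lib[k] - o) / (lib[k] * o) + (lib[ref] - r) / (lib[ref] * r))
        if not ms or max(abs(m) for m in ms) < 1e-6:
            factors.append(1.0)
            continue
        n = len(ms)
        lo_m = math.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * abs_trim) + 1
        hi_a = n + 1 - lo_a
        rm = rank_average_ties(ms)
        ra = rank_average_ties(As)
        num = den = 0.0
        kept = 0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += ms[i] / vs[i]
                den += 1.0 / vs[i]
                kept += 1
        factors.append(2.0 ** (num / den) if kept else 1.0)
    gm = math.exp(sum(math.log(f) for f in factors) / n_samples)
    return [f / gm for f in factors]


def oracle_uq_factors(counts, quantile=0.75):
    y = np.asarray(counts, dtype=float)
    lib = [sum(col) for col in y.T]
    nonzero = [row for row in y if sum(row) > 0]
    factors = []
    for j in range(y.shape[1]):
        q = np.quantile([row[j] for row in nonzero], quantile)
        factors.append(q / lib[j])
    gm = math.exp(sum(math.log(f) for f in factors) / len(factors))
    return [f / gm for f in factors]


def oracle_clr(weights):
    """CLR re-weighting by per-gene z-scores of off-diagonal weights
    (population SD over the n-1 values), negatives clipped."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    mu, sd = [], []
    for i in range(n):
        offdiag = [w[i, j] for j in range(n) if j != i]
        m = sum(offdiag) / (n - 1)
        var = sum((x - m) ** 2 for x in offdiag) / (n - 1)
        mu.append(m)
        sd.append(math.sqrt(var))
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            zi = 0.0 if sd[i] == 0 else max(0.0, (w[i, j] - mu[i]) / sd[i])
            zj = 0.0 if sd[j] == 0 else max(0.0, (w[j, i] - mu[j]) / sd[j])
            out[i, j] = math.sqrt(zi ** 2 + zj ** 2)
    return out


def oracle_wto(weights, variant="sign"):
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    a = w if variant == "sign" else np.abs(w)
    k = [sum(abs(a[i, u]) for u in range(n) if u != i) for i in range(n)]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            den = min(k[i], k[j]) + 1 - abs(a[i, j])
            out[i, j] = (shared + a[i, j]) / den
    return out


def oracle_confusion_sweep(weights, labels):
    """Threshold-by-threshold confusion counts at every distinct weight."""
    pairs = list(zip(weights, labels))
    n_pos = sum(1 for _, y in pairs if y == 1)
    n_neg = len(pairs) - n_pos
    rows = []
    for t in sorted({w for w, _ in pairs}, reverse=True):
        tp = sum(1 for w, y in pairs if w >= t and y == 1)
        fp = sum(1 for w, y in pairs if w >= t and y == 0)
        rows.append((t, tp, fp, n_neg - fp, n_pos - tp))
    return rows, n_pos, n_neg


def oracle_auprc(weights, labels):
    """Trapezoidal PR area over the distinct-threshold sweep, anchored at
    recall 0 with the first row's precision."""
    rows, n_pos, _ = oracle_confusion_sweep(weights, labels)
    points = [(0.0, rows[0][1] / (rows[0][1] + rows[0][2]))]
    for _, tp, fp, _, _ in rows:
        points.append((tp / n_pos, tp / (tp + fp)))
    area = 0.0
    for (r0, p0), (r1, p1) in zip(points, points[1:]):
        area += (r1 - r0) * (p0 + p1) / 2
    return area


def oracle_auroc(weights, labels):
    rows, n_pos, n_neg = oracle_confusion_sweep(weights, labels)
    points = [(0.0, 0.0)] + [(fp / n_neg, tp / n_pos) for _, tp, fp, _, _ in rows]
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        area += (x1 - x0) * (y0 + y1) / 2
    return area


def oracle_precision_at_recall(weights, labels, level):
    rows, n_pos, _ = oracle_confusion_sweep(weights, labels)
    for _, tp, fp, _, _ in rows:
        if tp / n_pos >= level:
            return tp / (tp + fp)
    raise AssertionError("recall never reaches the requested level")


def oracle_signed_rank_tail(n, w_obs):
    """Exact one-sided P(W+ >= w_obs) for n distinct non-zero differences,
    by full enumeration of the 2^n equally likely sign assignments
    (dynamic programming over ranks)."""
    ways = {0: 1}
    for rank in range(1, n + 1):
        nxt = {}
        for w, c in ways.items():
            nxt[w] = nxt.get(w, 0) + c
            nxt[w + rank] = nxt.get(w + rank, 0) + c
        ways = nxt
    total = 2 ** n
    return sum(c for w, c in ways.items() if w >= w_obs) / total


def oracle_bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = pvalues[i] * m / (rank_idx + 1)
        running_min = min(running_min, val)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def oracle_hypergeom_tail(n_overlap, size_a, size_b, universe):
    """P(|A ∩ B| >= n_overlap) by counting draws of B with A fixed."""
    total = math.comb(universe, size_b)
    hits = 0
    for k in range(n_overlap, min(size_a, size_b) + 1):
        hits += math.comb(size_a, k) * math.comb(universe - size_a, size_b - k)
    return hits / total


def oracle_naive_standard_pairs(term_genes, specific, general, alpha, universe):
    """Exhaustive pair enumeration of the gold-standard construction rule."""
    positives = set()
    for t in specific:
        for a, b in combinations(sorted(term_genes.get(t, ())), 2):
            positives.add((min(a, b), max(a, b)))
    similar = set()
    for t1, t2 in combinations(sorted(specific), 2):
        g1, g2 = set(term_genes.get(t1, ())), set(term_genes.get(t2, ()))
        if not g1 or not g2:
            continue
        if oracle_hypergeom_tail(len(g1 & g2), len(g1), len(g2), universe) < alpha:
            similar.add(frozenset((t1, t2)))
    pos_genes = sorted({g for p in positives for g in p})
    negatives = set()
    for a, b in combinations(pos_genes, 2):
        pair = (min(a, b), max(a, b))
        if pair in positives:
            continue
        terms_a = {t for t in specific if a in term_genes.get(t, ())}
        terms_b = {t for t in specific if b in term_genes.get(t, ())}
        if any(frozenset((t1, t2)) in similar for t1 in terms_a for t2 in terms_b
               if t1 != t2):
            continue
        if any(a in term_genes.get(t, ()) and b in term_genes.get(t, ())
               for t in general):
            continue
        negatives.add(pair)
    return positives, negatives
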