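"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is deliberately coded from first principles (explicit
formulas, exhaustive enumeration, naive O(n^3) agglomeration) so the main
code paths are checked against arithmetic that shares none of their
implementation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import betainc, stdtr


def welch_p(a, b) -> float:
    """Two-sided Welch t-test p-value from the textbook formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * (1 - stdtr(df, abs(t)))


def pooled_t_p(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * (1 - stdtr(na + nb - 2, abs(t)))


def pearson_r_p(x, y) -> tuple[float, float]:
    """Pearson r and two-sided P via the incomplete-beta form of the
    t distribution."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / math.sqrt((xm ** 2).sum() * (ym ** 2).sum())
    df = n - 2
    # two-sided P = I_{df/(df+t^2)}(df/2, 1/2)
    t2 = r ** 2 * df / max(1 - r ** 2, 1e-300)
    p = betainc(df / 2, 0.5, df / (df + t2))
    return r, float(p)


def chi2_2x2(a, b, c, d) -> tuple[float, float]:
    """(ad-bc)^2 N / (row/col products) and its chi2(1) tail, computed via
    the explicit sum of (O-E)^2/E."""
    from scipy.stats import chi2

    obs = np.array([[a, b], [c, d]], float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(stat), float(chi2.sf(stat, 1))


def hypergeom_upper_tail(k, N, K, n) -> float:
    """P(X >= k) by exhaustive summation with exact binomials."""
    lo, hi = max(k, 0), min(K, n)
    total = 0
    for i in range(lo, hi + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / math.comb(N, n)


def fisher_greater(a, b, c, d) -> float:
    """One-sided (over-representation) Fisher exact P for [[a,b],[c,d]]."""
    return hypergeom_upper_tail(a, a + b + c + d, a + c, a + b)


def bh_stepup(pvals) -> np.ndarray:
    """BH adjusted p-values by the direct step-up definition."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj


def naive_ward(X) -> list[float]:
    """O(n^3) Ward agglomeration; returns sorted merge heights.

    Uses the direct definition: merging clusters A, B costs
    sqrt(2 |A||B| / (|A|+|B|)) * ||centroid_A - centroid_B||  (the scipy
    height convention), recomputed from scratch from cluster members at
    every step.
    """
    X = np.asarray(X, float)
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                ca = X[clusters[i]].mean(axis=0)
                cb = X[clusters[j]].mean(axis=0)
                na, nb = len(clusters[i]), len(clusters[j])
                h = math.sqrt(2 * na * nb / (na + nb)) * \
                    float(np.linalg.norm(ca - cb))
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        heights.append(h)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return sorted(heights)


def naive_pwm_hits(seqs, counts, pseudocount, score_frac) -> list[bool]:
    """Per-window hit calls by exhaustive per-position rescoring on both
    strands with explicit log-odds arithmetic."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    counts = np.asarray(counts, float)
    L = counts.shape[1]
    probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=0)
    lo = np.log2(probs / 0.25)
    max_score = sum(max(lo[:, j]) for j in range(L))
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for seq in seqs:
        rc = "".join(comp[c] for c in reversed(seq))
        best = -np.inf
        for strand_seq in (seq, rc):
            for s in range(len(strand_seq) - L + 1):
                sub = strand_seq[s:s + L]
                if "N" in sub:
                    continue
                score = sum(lo[idx[c], j] for j, c in enumerate(sub))
                best = max(best, score)
        hits.append(best >= score_frac * max_score)
    return hits
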