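"""Independent oracles used by the test suite.

Each oracle re-derives a quantity by brute force (arbitrary-precision
arithmetic, exhaustive dynamic programming, or enumeration) without touching
the implementation path it checks.
"""
from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import mpmath as mp
import numpy as np
from scipy.stats import rankdata


def posterior_oracle(allele_counts, ref_idx, alt_idx, p_no_mutation,
                     base_error, grid, dps=60):
    """Arbitrary-precision log-space evaluation of the substitution posterior.

    Mirrors the model definition only: multinomial likelihood over the four
    allele counts with per-allele probabilities mixing F and the error rate,
    prior mass p0 on F=0 and (1-p0)/|grid| on each grid fraction.
    """
    with mp.workdps(dps):
        counts = [mp.mpf(int(c)) for c in allele_counts]
        n = sum(counts)

        def log_pmf(F):
            q = [mp.mpf(0)] * 4
            q[ref_idx] = 1 - F
            q[alt_idx] = q[alt_idx] + F
            e = mp.mpf(base_error)
            probs = [qi * (1 - e) + (1 - qi) * (e / 3) for qi in q]
            lp = mp.loggamma(n + 1)
            for c, p in zip(counts, probs):
                lp -= mp.loggamma(c + 1)
                if c > 0:
                    if p == 0:
                        return mp.mpf("-inf")
                    lp += c * mp.log(p)
            return lp

        p0 = mp.mpf(p_no_mutation)
        h0 = mp.e ** log_pmf(mp.mpf(0)) * p0
        z = h0
        for f in grid:
            z += mp.e ** log_pmf(mp.mpf(float(f))) * (1 - p0) / len(grid)
        return float(1 - h0 / z)


def affine_alignment_score(a: str, b: str, match=1.0, mismatch=-2.0,
                           gap_open=-5.0, gap_extend=-1.0):
    """Gotoh global affine-gap DP; gap of length L scores open+(L-1)*extend."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


def fisher_exact_oracle(table) -> float:
    """Two-sided Fisher p by exact-rational enumeration over fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        return Fraction(comb(r1, k) * comb(r2, c1 - k), comb(n, c1))

    p_obs = pmf(a)
    # scipy's two-sided rule: sum tables with pmf <= pmf_obs * (1 + 1e-7)
    thresh = p_obs + p_obs / 10_000_000
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = pmf(k)
        if p <= thresh:
            total += p
    return float(total)


def wilcoxon_enumeration_oracle(x, y) -> float:
    """Exact two-sided rank-sum p over all group assignments (mid-ranks)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = rankdata(pooled)
    mean_w = n * (n + m + 1) / 2.0
    w_obs = ranks[:n].sum()
    dev = abs(w_obs - mean_w)
    hits = total = 0
    for comb_idx in itertools.combinations(range(n + m), n):
        total += 1
        if abs(ranks[list(comb_idx)].sum() - mean_w) >= dev - 1e-9:
            hits += 1
    return hits / total


def conditional_chi2_p(table, mid: bool = False) -> float:
    """Exact conditional (hypergeometric-null) tail p of the Pearson statistic.

    Enumerates the 2x2 tables with the observed margins and sums the
    probabilities of those whose Pearson statistic is >= the observed one.
    With ``mid=True`` the observed statistic's own probability counts half
    (the mid-p convention, the right comparison point for a continuous
    asymptotic approximation to a discrete null).
    """
    from scipy.stats import hypergeom

    t = np.asarray(table, float)
    (a, b), (c, d) = t
    r1, r2, c1 = a + b, c + d, a + c
    n = t.sum()

    def stat(k):
        tt = np.array([[k, r1 - k], [c1 - k, r2 - (c1 - k)]], float)
        e = np.outer(tt.sum(1), tt.sum(0)) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(e > 0, (tt - e) ** 2 / e, 0.0)
        return contrib.sum()

    s_obs = stat(a)
    ks = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    probs = hypergeom.pmf(ks, n, r1, c1)
    greater = float(probs[[stat(k) > s_obs + 1e-12 for k in ks]].sum())
    equal = float(probs[[abs(stat(k) - s_obs) <= 1e-12 for k in ks]].sum())
    return greater + (0.5 * equal if mid else equal)


def bh_stepup_oracle(pvalues):
    """Benjamini-Hochberg step-up computed longhand."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p, kind="stable")
    n = p.size
    q_sorted = p[order] * n / np.arange(1, n + 1)
    for i in range(n - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
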