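"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written as slow, transparent, step-by-step
re-implementations from the published definitions of each method, sharing
no code with the package.
"""

from __future__ import annotations

import math
import statistics

import numpy as np
from scipy.stats import rankdata


def mrn_oracle(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, gene by gene with explicit loops.

    The median over genes follows the reference estimator's log-scale
    convention: with an even number of usable genes the size factor is the
    geometric mean of the two middle ratios.
    """
    n_genes, n_samples = counts.shape
    ref = []
    usable = []
    for g in range(n_genes):
        row = [counts[g, s] for s in range(n_samples)]
        if all(v > 0 for v in row):
            log_mean = sum(math.log(v) for v in row) / n_samples
            ref.append(math.exp(log_mean))
            usable.append(g)
    if not usable:
        raise ValueError("no all-positive gene")
    factors = []
    for s in range(n_samples):
        ratios = sorted(counts[g, s] / ref[i] for i, g in enumerate(usable))
        k = len(ratios)
        if k % 2 == 1:
            med = ratios[k // 2]
        else:
            med = math.sqrt(ratios[k // 2 - 1] * ratios[k // 2])
        factors.append(med)
    return np.array(factors)


def tmm_oracle(
    counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05
) -> np.ndarray:
    """Trimmed mean of M-values, spelled out step by step.

    Reference sample: depth-normalized 75th percentile closest to the mean.
    For each sample: M/A over genes positive in both; keep genes whose
    average ranks of M and A both fall inside the [floor(n*trim)+1,
    n+1-(floor(n*trim)+1)] band; factor = 2**(sum w*M / sum w) with
    w = 1/(delta-method binomial variance); rescale to geometric mean 1.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    q75 = np.array(
        [np.percentile(counts[:, s] / lib[s], 75) for s in range(counts.shape[1])]
    )
    ref_s = int(np.argmin(np.abs(q75 - q75.mean())))
    log2f = []
    for s in range(counts.shape[1]):
        if s == ref_s:
            log2f.append(0.0)
            continue
        ms, as_, ws = [], [], []
        for g in range(counts.shape[0]):
            y, r = counts[g, s], counts[g, ref_s]
            if y > 0 and r > 0:
                po, pr = y / lib[s], r / lib[ref_s]
                ms.append(math.log2(po / pr))
                as_.append(0.5 * math.log2(po * pr))
                ws.append(
                    1.0
                    / (
                        (lib[s] - y) / (lib[s] * y)
                        + (lib[ref_s] - r) / (lib[ref_s] * r)
                    )
                )
        n = len(ms)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(ms)
        ra = rankdata(as_)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += ws[i] * ms[i]
                den += ws[i]
        log2f.append(num / den)
    f = np.array([2.0**v for v in log2f])
    return f / math.exp(np.mean([math.log(v) for v in f]))


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration with exact binomials."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if 0 in (r1, r2, c1, b + d):
        return 1.0

    def prob(k: int) -> float:
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def bh_oracle(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def spearman_oracle(x, y) -> float:
    """Spearman rho as Pearson on average ranks, from the definition."""
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))
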