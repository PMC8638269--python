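"""Quantifying the compositional artifact, plus bimodality testing,
signature scoring and cohort-level meta-correlation.

``bias_curves`` is the package's demonstration piece: on data with *no*
planted mito-nuclear correlation it shows that total-count normalizations
(TPM/FPKM) manufacture negative mito-nuclear and positive random-random
correlations that grow with the cohort's mean mitochondrial read fraction,
while median-of-ratios and TMM scaling leave the null flat.

``dip_statistic`` implements Hartigan's dip — the sup-norm distance from
the empirical CDF to the nearest unimodal CDF — via the greatest-convex-
minorant / least-concave-majorant construction, with a seeded Monte-Carlo
uniform null for p values.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .correlate import expressed_nuclear_genes, fdr_adjust, pairwise_spearman, _between_pairs, _within_pairs
from .io import CountMatrix, substream
from .normalize import NormalizedMatrix, mt_fraction, normalize
from .regress import DesignSpec, regress_out

__all__ = [
    "CohortBiasSummary",
    "DipResult",
    "SignatureScore",
    "MetaCorrelationResult",
    "bias_curves",
    "bias_regression",
    "dip_statistic",
    "dip_test",
    "signature_score",
    "meta_correlation",
    "variance_explained",
]


# ---------------------------------------------------------------------------
# composition-bias curves


@dataclass
class CohortBiasSummary:
    cohort: str
    method: str
    mt_mean: float
    mt_cv: float
    median_set_pair: float
    median_set_random: float
    median_random_random: float

    def as_row(self) -> dict:
        return self.__dict__.copy()


def bias_curves(
    cm: CountMatrix,
    set_a: Sequence[str],
    set_b: Sequence[str],
    methods: Sequence[str] = ("tpm", "mrn", "tmm"),
    design: DesignSpec | None = None,
    pool: Sequence[str] | None = None,
    panel_size: int = 126,
    random_panel_size: int = 100,
    n_iterations: int = 100,
    expression_threshold: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cohort, per-method composition-bias summary.

    For each cohort and normalization method: normalize within the cohort,
    regress out the design, and report (a) the median Spearman rho over all
    set-A x set-B pairs, (b) the mean over iterations of the median rho of
    set A against random ``panel_size``-gene panels, and (c) the mean over
    iterations of the median rho within random ``random_panel_size``-gene
    panels — alongside the cohort's mean and CV of the mitochondrial read
    fraction.

    ``pool`` defaults to the expressed nuclear genes (median TPM above the
    threshold) outside both sets, so the random panels are functionally
    unrelated to either set.
    """
    if not methods:
        raise ValueError("methods list is empty")
    if cm.metadata is None or "cohort" not in cm.metadata.columns:
        raise ValueError("count matrix needs cohort metadata")
    set_a, set_b = list(set_a), list(set_b)
    if pool is None:
        pool = list(
            expressed_nuclear_genes(
                cm, expression_threshold, exclude=set_a + set_b
            )
        )
    pool = list(pool)
    if len(pool) < max(panel_size, random_panel_size):
        raise ValueError(
            f"random pool has {len(pool)} genes; need at least "
            f"{max(panel_size, random_panel_size)}"
        )
    rng = substream(seed, "bias_curves")
    frac = mt_fraction(cm)
    rows = []
    for cohort, cmeta in cm.metadata.groupby("cohort", sort=True):
        sub = cm.subset_samples(list(cmeta.index))
        f = frac.loc[cmeta.index]
        # panels are drawn once per cohort and shared across methods so the
        # method contrast is not confounded by panel choice
        set_panels = [
            rng.choice(len(pool), size=panel_size, replace=False)
            for _ in range(n_iterations)
        ]
        rr_panels = [
            rng.choice(len(pool), size=random_panel_size, replace=False)
            for _ in range(n_iterations)
        ]
        for method in methods:
            norm = normalize(sub, method)
            resid = regress_out(norm, sub.metadata, design, scope="per_cohort")
            genes = list(dict.fromkeys(set_a + set_b + pool))
            mat = pairwise_spearman(resid.values.loc[genes])
            pool_idx = mat.index.get_indexer(pool)
            a_idx = mat.index.get_indexer(set_a)
            arr = mat.to_numpy()

            med_ab = float(np.median(_between_pairs(mat, set_a, set_b)))
            med_ar = float(
                np.mean(
                    [
                        np.median(arr[np.ix_(a_idx, pool_idx[p])])
                        for p in set_panels
                    ]
                )
            )
            rr_meds = []
            for p in rr_panels:
                block = arr[np.ix_(pool_idx[p], pool_idx[p])]
                rr_meds.append(np.median(block[np.triu_indices(len(p), k=1)]))
            rows.append(
                CohortBiasSummary(
                    cohort=cohort,
                    method=method,
                    mt_mean=float(f.mean()),
                    mt_cv=float(f.std(ddof=1) / f.mean()),
                    median_set_pair=med_ab,
                    median_set_random=med_ar,
                    median_random_random=float(np.mean(rr_meds)),
                ).as_row()
            )
    return pd.DataFrame(rows)


def bias_regression(
    summaries: pd.DataFrame,
    outcome: str = "median_set_pair",
    method: str | None = None,
) -> dict[str, dict]:
    """Regress a cohort-level bias outcome on the mitochondrial-fraction
    mean, and on {mean, CV, mean x CV}.

    Returns, per predictor set, the OLS coefficients, R-squared, F-test p,
    and the Spearman correlation of the outcome with the mean fraction.
    """
    df = summaries if method is None else summaries[summaries["method"] == method]
    if df["cohort"].nunique() < 4:
        raise ValueError("need at least 4 cohorts")
    y = df[outcome].to_numpy(float)
    if np.ptp(y) > 0:
        rho, rho_p = stats.spearmanr(df["mt_mean"], y)
    else:  # constant outcome: rank correlation undefined
        rho, rho_p = float("nan"), float("nan")
    out = {}
    designs = {
        "mean": df[["mt_mean"]].copy(),
        "mean+cv": pd.DataFrame(
            {
                "mt_mean": df["mt_mean"],
                "mt_cv": df["mt_cv"],
                "mean_x_cv": df["mt_mean"] * df["mt_cv"],
            }
        ),
    }
    for name, X in designs.items():
        # drop aliased (collinear) predictors deterministically
        keep, dropped = [], []
        for col in X.columns:
            trial = X[keep + [col]].to_numpy(float)
            if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), trial])) == len(keep) + 2:
                keep.append(col)
            else:
                dropped.append(col)
        fit = sm.OLS(y, sm.add_constant(X[keep].to_numpy(float))).fit()
        out[name] = {
            "coefficients": dict(zip(["intercept"] + keep, fit.params)),
            "p_values": dict(zip(["intercept"] + keep, fit.pvalues)),
            "r_squared": float(fit.rsquared),
            "f_pvalue": float(fit.f_pvalue),
            "spearman_rho": float(rho),
            "spearman_p": float(rho_p),
            "dropped": dropped,
        }
    return out


# ---------------------------------------------------------------------------
# Hartigan's dip


def dip_statistic(values: Iterable[float]) -> float:
    """Hartigan's dip statistic.

    D is the sup-norm distance from the empirical CDF of ``values`` to the
    nearest unimodal CDF, found by iteratively fitting the greatest convex
    minorant below and least concave majorant above the ECDF and narrowing
    onto the modal interval.  D is bounded below by 1/(2n) (an ECDF step of
    1/n can never be matched better) and above by 0.25.
    """
    x = np.sort(np.asarray(list(values), dtype=float))
    n = x.size
    if n < 4 or not np.isfinite(x).all():
        raise ValueError("need at least 4 finite values")
    if x[0] == x[-1]:
        return 1.0 / (2.0 * n)

    # 1-based arrays, translated from the published dip algorithm
    xs = np.empty(n + 1)
    xs[1:] = x
    mn = np.zeros(n + 1, dtype=int)
    mj = np.zeros(n + 1, dtype=int)

    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (xs[j] - xs[mnj]) * (mnj - mnmnj) < (
                xs[mnj] - xs[mnmnj]
            ) * (j - mnj):
                break
            mn[j] = mnmnj

    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (xs[k] - xs[mjk]) * (mjk - mjmjk) < (
                xs[mjk] - xs[mjmjk]
            ) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # in ECDF-count units; final division by 2n gives the 1/(2n) floor
    gcm = np.zeros(n + 2, dtype=int)
    lcm = np.zeros(n + 2, dtype=int)

    while True:
        # change points of the GCM from high down to low
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = l_gcm = i
        ix = ig - 1
        # change points of the LCM from low up to high
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = l_lcm = i
        iv = 2

        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (xs[lcmiv] - xs[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (xs[gcmix] - xs[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (xs[gcmix] - xs[lcmiv1]) * (lcmiv - lcmiv1) / (
                        xs[lcmiv] - xs[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # largest deviation of the ECDF from the GCM below the modal interval
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (xs[jj] - xs[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # and from the LCM above it
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                for jj in range(jb, je + 1):
                    t = (xs[jj] - xs[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew
        low = gcm[ig]
        high = lcm[ih]
        if dip >= d:
            break

    return dip / (2.0 * n)


@dataclass
class DipResult:
    statistic: float
    p_value: float
    n: int
    n_mc: int


@lru_cache(maxsize=32)
def _uniform_null_dips(n: int, n_mc: int, seed: int) -> tuple[float, ...]:
    rng = substream(seed, f"dip_null:{n}:{n_mc}")
    return tuple(dip_statistic(rng.uniform(size=n)) for _ in range(n_mc))


def dip_test(
    values: Iterable[float], n_mc: int = 2000, seed: int = 0
) -> DipResult:
    """Monte-Carlo dip test against the uniform(0,1) null.

    p = fraction of uniform samples of size n whose dip is at least the
    observed one, floored at the 1/n_mc resolution.  The null distribution
    is cached per (n, n_mc, seed), so testing many panels of one cohort
    reuses a single simulation.
    """
    import warnings

    if n_mc < 100:
        warnings.warn("n_mc < 100 gives very coarse p resolution")
    x = np.asarray(list(values), dtype=float)
    d = dip_statistic(x)
    null = np.array(_uniform_null_dips(x.size, n_mc, seed))
    p = max(float((null >= d).mean()), 1.0 / n_mc)
    return DipResult(statistic=d, p_value=p, n=x.size, n_mc=n_mc)


# ---------------------------------------------------------------------------
# signature scoring and meta-correlation


@dataclass
class SignatureScore:
    scores: pd.Series
    signature: str
    transform: str
    n_genes_used: int
    n_genes_excluded: int


def signature_score(
    normalized: NormalizedMatrix | pd.DataFrame,
    signature_genes: Sequence[str],
    transform: str = "log2p1",
    name: str = "signature",
) -> SignatureScore:
    """Per-sample mean of standardized, variance-stabilized expression over
    a signature gene set (the proliferative-index style score).

    ``log2p1`` applies log2(x+1) as a variance-stabilizing approximation
    before z-scoring each gene across samples; zero-variance genes are
    excluded and counted.
    """
    values = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
    present = [g for g in signature_genes if g in values.index]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    sub = values.loc[present].to_numpy(float)
    if transform == "log2p1":
        sub = np.log2(sub + 1.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    sd = sub.std(axis=1)
    usable = sd > 0
    if not usable.any():
        raise ValueError("all signature genes have zero variance")
    z = (sub[usable] - sub[usable].mean(axis=1, keepdims=True)) / sd[usable, None]
    return SignatureScore(
        scores=pd.Series(z.mean(axis=0), index=values.columns),
        signature=name,
        transform=transform,
        n_genes_used=int(usable.sum()),
        n_genes_excluded=len(signature_genes) - int(usable.sum()),
    )


@dataclass
class MetaCorrelationResult:
    per_gene: pd.DataFrame  # rho, p, fdr per gene
    top: list[str]
    bottom: list[str]
    n_dropped_constant: int


def meta_correlation(
    mean_expr_by_cohort: pd.DataFrame,
    cohort_outcome: pd.Series,
    top_n: int = 1000,
) -> MetaCorrelationResult:
    """Correlate each gene's cohort-mean expression with a cohort-level
    outcome (e.g. the cohort's set-pair correlation).

    Returns per-gene Spearman rho with BH-FDR and the ranked top/bottom
    gene lists.  Constant genes are dropped and counted.
    """
    cohorts = mean_expr_by_cohort.columns
    if len(cohorts) < 4:
        raise ValueError("need at least 4 cohorts")
    y = cohort_outcome.loc[cohorts].to_numpy(float)
    X = mean_expr_by_cohort.to_numpy(float)
    keep = X.std(axis=1) > 0
    n_dropped = int((~keep).sum())
    rho, p = stats.spearmanr(X[keep].T, y)
    # spearmanr on a matrix returns the full correlation matrix; the last
    # row/column against y is what we need
    if np.ndim(rho) == 2:
        rho = rho[-1, :-1]
        p = p[-1, :-1]
    genes = mean_expr_by_cohort.index[keep]
    per_gene = pd.DataFrame(
        {"rho": rho, "p": p}, index=genes
    ).sort_values("rho", ascending=False)
    per_gene["fdr"] = np.nan
    ok = per_gene["p"].notna()
    per_gene.loc[ok, "fdr"] = fdr_adjust(per_gene.loc[ok, "p"].clip(lower=1e-300))
    if top_n > len(per_gene):
        import warnings

        warnings.warn(f"top_n={top_n} capped at {len(per_gene)} genes")
        top_n = len(per_gene)
    return MetaCorrelationResult(
        per_gene=per_gene,
        top=list(per_gene.index[:top_n]),
        bottom=list(per_gene.index[-top_n:][::-1]),
        n_dropped_constant=n_dropped,
    )


def variance_explained(
    predictors: pd.Series | pd.DataFrame, outcome: pd.Series
) -> tuple[float, float]:
    """OLS R-squared and F-test p of an outcome on one or more predictors
    (e.g. how much of the variation in set-pair coordination a single
    transcription factor's expression explains)."""
    X = predictors.to_frame() if isinstance(predictors, pd.Series) else predictors
    X = X.loc[outcome.index]
    if len(outcome) < 4:
        raise ValueError("need at least 4 observations")
    if (X.std(axis=0) <= 0).any():
        raise ValueError("zero-variance predictor")
    fit = sm.OLS(outcome.to_numpy(float), sm.add_constant(X.to_numpy(float))).fit()
    return float(fit.rsquared), float(fit.f_pvalue)
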