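"""Resampling correlation machinery for gene-set co-expression.

Two complementary estimands:

* **combined across cohorts** — to ask whether two gene sets co-vary across
  donors while ignoring between-cohort expression differences, residuals are
  ranked *within* each cohort on a fixed-size subsample, the within-cohort
  ranks are concatenated across cohorts, and Spearman's rho is computed on
  the aggregate (Pearson on the concatenated ranks; within-cohort ranks
  repeat identically across cohorts, so re-ranking globally would only
  introduce ties).  The subsample-rank-aggregate step is repeated R times
  and the elementwise median over iterations is reported.

* **within one cohort** — all samples are used; the set-pair summary is the
  median Spearman's rho over every between-set gene pair.  Inference comes
  from a nonparametric bootstrap over samples (percentile CI, empirical
  sign-crossing p with the 1/B substitution when no bootstrap value crosses
  zero) and from a random-gene null: the second set is replaced by random
  panels of expressed nuclear genes, the null medians are checked for
  normality (Shapiro-Wilk), and the observed median is standardized into a
  Z statistic against the null mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, substream
from .normalize import mrn_factors, apply_scaling, tpm
from .regress import DesignSpec, regress_out

__all__ = [
    "CorrelationMatrixResult",
    "SetPairSummary",
    "NullDistribution",
    "MatchedPairResult",
    "rank_within_cohort",
    "combined_set_correlation",
    "cohort_set_correlation",
    "bootstrap_median_correlation",
    "random_gene_null",
    "matched_pair_analysis",
    "fisher_exact_2x2",
    "fdr_adjust",
    "expressed_nuclear_genes",
    "summarize_cohorts",
]


# ---------------------------------------------------------------------------
# vectorized primitives


def _rank_rows(arr: np.ndarray) -> np.ndarray:
    return stats.rankdata(arr, axis=1, method="average")


def _standardize_rows(arr: np.ndarray) -> np.ndarray:
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (arr - mu) / sd, np.nan)
    return z


def _pearson_blocks(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between two matrices sharing columns."""
    za, zb = _standardize_rows(a), _standardize_rows(b)
    return za @ zb.T / a.shape[1]


def pairwise_spearman(values: pd.DataFrame) -> pd.DataFrame:
    """Full gene x gene Spearman matrix (ranks then Pearson)."""
    r = _rank_rows(values.to_numpy(float))
    c = _pearson_blocks(r, r)
    return pd.DataFrame(c, index=values.index, columns=values.index)


def _between_pairs(mat: pd.DataFrame, set_a: Sequence[str], set_b: Sequence[str]) -> np.ndarray:
    """Flatten the A x B block, excluding pairs where the same gene appears
    on both sides."""
    sub = mat.loc[list(set_a), list(set_b)].to_numpy(float).copy()
    for i, g in enumerate(set_a):
        if g in set_b:
            sub[i, list(set_b).index(g)] = np.nan
    return sub[~np.isnan(sub)]


def _within_pairs(mat: pd.DataFrame, set_a: Sequence[str]) -> np.ndarray:
    sub = mat.loc[list(set_a), list(set_a)].to_numpy(float)
    iu = np.triu_indices(len(set_a), k=1)
    vals = sub[iu]
    return vals[~np.isnan(vals)]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CorrelationMatrixResult:
    """gene x gene matrix of median Spearman rho over iterations."""

    matrix: pd.DataFrame
    n_iterations: int
    subsample_size: int
    set_a: list[str] = field(default_factory=list)
    set_b: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy()
        np.fill_diagonal(m, 1.0)

    def between_set_median(self) -> float:
        return float(np.median(_between_pairs(self.matrix, self.set_a, self.set_b)))

    def within_set_median(self, which: str = "a") -> float:
        genes = self.set_a if which == "a" else self.set_b
        return float(np.median(_within_pairs(self.matrix, genes)))

    def clustering_order(self) -> list[str]:
        """Average-linkage hierarchical clustering order on distance 1 - rho,
        intended to be frozen once and reused across displays."""
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        d = 1.0 - self.matrix.to_numpy()
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2
        link = hierarchy.linkage(squareform(d, checks=False), method="average")
        order = hierarchy.leaves_list(link)
        return [self.matrix.index[i] for i in order]


@dataclass
class SetPairSummary:
    """Within-cohort median set-pair correlation with bootstrap inference."""

    cohort: str
    median_rho: float
    ci_low: float
    ci_high: float
    p_value: float  # raw sign-conditional fraction (one-tailed against 0)
    p_is_bound: bool
    n_samples: int
    n_bootstrap: int
    p_two_sided: float = float("nan")  # 2x the raw fraction, capped at 1
    fdr: float = float("nan")
    significance: str = "ns"
    n_redrawn: int = 0

    def as_row(self) -> dict:
        return {
            "cohort": self.cohort,
            "median_rho": self.median_rho,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "p_two_sided": self.p_two_sided,
            "p_is_bound": self.p_is_bound,
            "fdr": self.fdr,
            "significance": self.significance,
            "n_samples": self.n_samples,
        }


@dataclass
class NullDistribution:
    """Random-gene-panel null for an observed set-pair median."""

    cohort: str
    observed_median: float
    null_medians: np.ndarray
    shapiro_p: float
    z: float
    p_two_sided: float
    p_one_sided: float
    fdr: float = float("nan")


@dataclass
class MatchedPairResult:
    per_cohort: pd.DataFrame  # cohort, class, median_rho, bootstrap_se, fdr...
    table: np.ndarray  # 2x2 significant-positive counts
    fisher_p: float
    odds_ratio: float
    n_dropped_normals: int = 0


# ---------------------------------------------------------------------------
# operations


def rank_within_cohort(
    residuals: pd.DataFrame, cohort_labels: pd.Series
) -> pd.DataFrame:
    """Average ranks of each gene's residuals, computed separately within
    every cohort.  Constant genes get all-equal (midpoint) ranks."""
    labels = cohort_labels.loc[residuals.columns]
    out = np.empty(residuals.shape)
    for _, idx in labels.groupby(labels, sort=False).groups.items():
        loc = residuals.columns.get_indexer(idx)
        if len(loc) < 3:
            raise ValueError("each cohort must contribute at least 3 samples")
        out[:, loc] = _rank_rows(residuals.to_numpy(float)[:, loc])
    return pd.DataFrame(out, index=residuals.index, columns=residuals.columns)


def combined_set_correlation(
    residuals: pd.DataFrame,
    cohort_labels: pd.Series,
    set_a: Sequence[str],
    set_b: Sequence[str],
    k: int = 100,
    n_iterations: int = 100,
    seed: int = 0,
) -> CorrelationMatrixResult:
    """Subsample k samples per cohort, rank within cohort, aggregate ranks,
    correlate; repeat and take the elementwise median.

    Equal subsample sizes keep every cohort equally represented regardless
    of its true size.
    """
    set_a, set_b = list(set_a), list(set_b)
    genes = list(dict.fromkeys(set_a + set_b))
    sub = residuals.loc[genes]
    labels = cohort_labels.loc[residuals.columns]
    groups = {c: idx for c, idx in labels.groupby(labels, sort=False).groups.items()}
    too_small = [c for c, idx in groups.items() if len(idx) < k]
    if too_small:
        raise ValueError(
            f"cohorts smaller than subsample size k={k}: {sorted(too_small)}"
        )
    rng = substream(seed, "combined_set_correlation")
    vals = sub.to_numpy(float)
    col_loc = {c: sub.columns.get_indexer(idx) for c, idx in groups.items()}

    stack = np.empty((n_iterations, len(genes), len(genes)))
    for it in range(n_iterations):
        blocks = []
        for c in groups:
            loc = col_loc[c]
            chosen = rng.choice(loc, size=k, replace=False)
            blocks.append(_rank_rows(vals[:, chosen]))
        agg = np.hstack(blocks)
        stack[it] = _pearson_blocks(agg, agg)
    med = np.median(stack, axis=0)
    return CorrelationMatrixResult(
        pd.DataFrame(med, index=genes, columns=genes),
        n_iterations=n_iterations,
        subsample_size=k,
        set_a=set_a,
        set_b=set_b,
    )


def cohort_set_correlation(
    residuals: pd.DataFrame,
    set_a: Sequence[str],
    set_b: Sequence[str],
) -> tuple[float, pd.DataFrame]:
    """Median Spearman rho over all between-set gene pairs on all samples.

    Returns (median, full A x B pair matrix).  Pairs involving a constant
    gene, or the same gene on both sides, are excluded from the median.
    """
    set_a, set_b = list(set_a), list(set_b)
    genes = list(dict.fromkeys(set_a + set_b))
    ranks = _rank_rows(residuals.loc[genes].to_numpy(float))
    mat = pd.DataFrame(
        _pearson_blocks(ranks, ranks), index=genes, columns=genes
    )
    pair = mat.loc[set_a, set_b]
    vals = _between_pairs(mat, set_a, set_b)
    if vals.size == 0:
        raise ValueError("no valid between-set pairs")
    return float(np.median(vals)), pair


def bootstrap_median_correlation(
    residuals: pd.DataFrame,
    set_a: Sequence[str],
    set_b: Sequence[str],
    n_bootstrap: int = 1000,
    seed: int = 0,
    cohort: str = "",
    max_redraws: int = 100,
) -> SetPairSummary:
    """Bootstrap the within-cohort median set-pair correlation.

    Samples are resampled with replacement ``n_bootstrap`` times and the
    median recomputed.  The 95% CI is the 2.5th/97.5th percentile band.
    The empirical p value is the fraction of bootstrap medians on the
    opposite side of zero from the observed median; when that fraction is
    zero it is replaced by 1/n_bootstrap and flagged as an upper bound.  An
    observed median of exactly zero gives p = 1.
    """
    set_a, set_b = list(set_a), list(set_b)
    genes = list(dict.fromkeys(set_a + set_b))
    vals = residuals.loc[genes].to_numpy(float)
    n = vals.shape[1]
    observed, _ = cohort_set_correlation(residuals, set_a, set_b)
    rng = substream(seed, f"bootstrap:{cohort}")

    a_pos = [genes.index(g) for g in set_a]
    b_pos = [genes.index(g) for g in set_b]
    same = [(i, j) for i, g in enumerate(set_a) for j, h in enumerate(set_b) if g == h]

    medians = np.empty(n_bootstrap)
    n_redrawn = 0
    for b in range(n_bootstrap):
        for _ in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            sub = vals[:, idx]
            if (sub.max(axis=1) > sub.min(axis=1)).all():
                break
            n_redrawn += 1
        else:
            raise ValueError("could not draw a non-degenerate bootstrap sample")
        ranks = _rank_rows(sub)
        c = _pearson_blocks(ranks[a_pos], ranks[b_pos])
        for i, j in same:
            c[i, j] = np.nan
        medians[b] = np.nanmedian(c)

    lo, hi = np.percentile(medians, [2.5, 97.5])
    if observed == 0.0:
        p, bound = 1.0, False
    else:
        crossing = (medians <= 0).mean() if observed > 0 else (medians >= 0).mean()
        if crossing == 0.0:
            p, bound = 1.0 / n_bootstrap, True
        else:
            p, bound = float(crossing), False
    return SetPairSummary(
        cohort=cohort,
        median_rho=float(observed),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p,
        p_is_bound=bound,
        n_samples=n,
        n_bootstrap=n_bootstrap,
        p_two_sided=min(1.0, 2.0 * p),
        n_redrawn=n_redrawn,
    )


def summarize_cohorts(
    summaries: Sequence[SetPairSummary], fdr_level: float = 0.05
) -> list[SetPairSummary]:
    """Apply BH-FDR across cohorts and set the significance calls."""
    qs = fdr_adjust([s.p_value for s in summaries])
    for s, q in zip(summaries, qs):
        s.fdr = float(q)
        if q < fdr_level:
            s.significance = "positive" if s.median_rho > 0 else "negative"
        else:
            s.significance = "ns"
    return list(summaries)


def expressed_nuclear_genes(
    cm: CountMatrix, threshold: float = 5.0, exclude: Sequence[str] = ()
) -> pd.Index:
    """Nuclear genes whose median TPM across all samples exceeds the
    threshold — the eligibility pool for random null panels."""
    t = tpm(cm).values
    med = t.median(axis=1)
    nuclear = cm.nuclear_genes()
    keep = nuclear[(med.loc[nuclear] > threshold).to_numpy()]
    return keep.difference(pd.Index(exclude), sort=False)


def random_gene_null(
    residuals: pd.DataFrame,
    set_a: Sequence[str],
    observed_median: float,
    eligible: Sequence[str],
    panel_size: int = 126,
    n_iterations: int = 100,
    seed: int = 0,
    cohort: str = "",
) -> NullDistribution:
    """Null distribution of set-vs-random-panel median correlations.

    Each iteration replaces the comparison set with ``panel_size`` genes
    drawn from the eligible pool; the observed median is standardized
    against the null medians (Z = (obs - mean)/sd), with a normal-CDF p
    (two-sided by default; the one-sided tail is also reported) and a
    Shapiro-Wilk check that the null medians are compatible with normality.
    """
    eligible = [g for g in eligible if g not in set(set_a)]
    if len(eligible) < panel_size:
        raise ValueError(
            f"only {len(eligible)} eligible genes for a panel of {panel_size}"
        )
    rng = substream(seed, f"random_gene_null:{cohort}")
    # rank once; each panel is then a cheap block of the rank-correlation
    genes = list(dict.fromkeys(list(set_a) + eligible))
    ranks = _rank_rows(residuals.loc[genes].to_numpy(float))
    z = _standardize_rows(ranks)
    n = z.shape[1]
    a_pos = [genes.index(g) for g in set_a]
    pool_pos = np.array([genes.index(g) for g in eligible])
    za = z[a_pos]
    medians = np.empty(n_iterations)
    for it in range(n_iterations):
        panel = pool_pos[rng.choice(len(pool_pos), size=panel_size, replace=False)]
        medians[it] = np.median(za @ z[panel].T / n)
    mu, sd = medians.mean(), medians.std(ddof=1)
    z = (observed_median - mu) / sd
    p_two = float(2 * stats.norm.sf(abs(z)))
    p_one = float(stats.norm.sf(z) if z > 0 else stats.norm.cdf(z))
    shapiro_p = float(stats.shapiro(medians).pvalue)
    return NullDistribution(
        cohort=cohort,
        observed_median=float(observed_median),
        null_medians=medians,
        shapiro_p=shapiro_p,
        z=float(z),
        p_two_sided=p_two,
        p_one_sided=p_one,
    )


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test by hypergeometric enumeration.

    p = sum of probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's.  Returns
    (p, sample odds ratio).  A zero margin gives p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 integer array")
    a, b = t[0]
    c, d = t[1]
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    if 0 in (row1, row2, col1, b + d):
        return 1.0, float(odds)
    support = np.arange(max(0, col1 - row2), min(col1, row1) + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0), float(odds)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# matched tumour / normal comparison


def _subsample_se(
    residuals: pd.DataFrame,
    set_a: Sequence[str],
    set_b: Sequence[str],
    frac: float,
    n_draws: int,
    rng: np.random.Generator,
) -> float:
    """SD of the median set-pair rho over unique subsets of ``frac`` of the
    samples (the matched-pair error bar)."""
    n = residuals.shape[1]
    m = max(3, int(round(frac * n)))
    seen: set[tuple[int, ...]] = set()
    medians = []
    attempts = 0
    while len(medians) < n_draws and attempts < n_draws * 20:
        attempts += 1
        idx = tuple(sorted(rng.choice(n, size=m, replace=False)))
        if idx in seen:
            continue
        seen.add(idx)
        med, _ = cohort_set_correlation(residuals.iloc[:, list(idx)], set_a, set_b)
        medians.append(med)
    return float(np.std(medians, ddof=1))


def matched_pair_analysis(
    cm: CountMatrix,
    set_a: Sequence[str],
    set_b: Sequence[str],
    min_normals: int = 10,
    seed: int = 0,
    n_bootstrap: int = 1000,
    subsample_frac: float = 0.9,
    n_subsample: int = 100,
    design: DesignSpec | None = None,
    fdr_level: float = 0.05,
) -> MatchedPairResult:
    """Donor-matched tumour vs adjacent-normal set-pair correlations.

    Cohorts with at least ``min_normals`` adjacent-normal samples are kept.
    Each normal sample is matched 1:1 to a primary-tumour sample from the
    same donor (one retained at random if several match; normals without a
    tumour counterpart are dropped and counted).  Within each cohort and
    class the counts are MRN-normalized, confounders regressed out, and the
    median set-pair rho computed with a subsampling SE and a bootstrap
    significance call; the cross-cohort 2x2 table of significant-positive
    calls is tested with Fisher's exact test.
    """
    meta = cm.metadata
    if meta is None or "sample_class" not in meta.columns:
        raise ValueError("matched-pair analysis requires sample_class metadata")
    rng = substream(seed, "matched_pair")
    rows = []
    n_dropped = 0
    kept_cohorts = []
    summaries: dict[str, list[SetPairSummary]] = {
        "primary_tumor": [],
        "adjacent_normal": [],
    }
    for cohort, cmeta in meta.groupby("cohort", sort=True):
        normals = cmeta[cmeta["sample_class"] == "adjacent_normal"]
        tumors = cmeta[cmeta["sample_class"] == "primary_tumor"]
        if len(normals) < min_normals:
            continue
        pairs = []
        for sid, row in normals.iterrows():
            cand = tumors.index[tumors["donor_id"] == row["donor_id"]]
            if len(cand) == 0:
                n_dropped += 1
                continue
            chosen = cand[rng.integers(0, len(cand))]
            pairs.append((sid, chosen))
        if len(pairs) < min_normals:
            continue
        kept_cohorts.append(cohort)
        normal_ids = [p[0] for p in pairs]
        tumor_ids = [p[1] for p in pairs]
        for cls, ids in (
            ("adjacent_normal", normal_ids),
            ("primary_tumor", tumor_ids),
        ):
            sub = cm.subset_samples(ids)
            norm = apply_scaling(sub, mrn_factors(sub))
            resid = regress_out(norm, sub.metadata, design, scope="per_cohort")
            med, _ = cohort_set_correlation(resid.values, set_a, set_b)
            se = _subsample_se(
                resid.values, set_a, set_b, subsample_frac, n_subsample, rng
            )
            summ = bootstrap_median_correlation(
                resid.values,
                set_a,
                set_b,
                n_bootstrap=n_bootstrap,
                seed=seed,
                cohort=f"{cohort}:{cls}",
            )
            summaries[cls].append(summ)
            rows.append(
                {
                    "cohort": cohort,
                    "sample_class": cls,
                    "n_pairs": len(ids),
                    "median_rho": med,
                    "bootstrap_se": se,
                    "p_value": summ.p_value,
                }
            )
    if not kept_cohorts:
        raise ValueError(f"no cohort has >= {min_normals} matched normal samples")
    for cls in summaries:
        summarize_cohorts(summaries[cls], fdr_level)
    per_cohort = pd.DataFrame(rows)
    fdr_map = {
        (s.cohort.split(":")[0], cls): (s.fdr, s.significance)
        for cls in summaries
        for s in summaries[cls]
    }
    per_cohort["fdr"] = [
        fdr_map[(r["cohort"], r["sample_class"])][0] for _, r in per_cohort.iterrows()
    ]
    per_cohort["significance"] = [
        fdr_map[(r["cohort"], r["sample_class"])][1] for _, r in per_cohort.iterrows()
    ]
    n_cohorts = len(kept_cohorts)
    pos_t = sum(s.significance == "positive" for s in summaries["primary_tumor"])
    pos_n = sum(s.significance == "positive" for s in summaries["adjacent_normal"])
    table = np.array(
        [[pos_t, n_cohorts - pos_t], [pos_n, n_cohorts - pos_n]], dtype=np.int64
    )
    p, odds = fisher_exact_2x2(table)
    return MatchedPairResult(
        per_cohort=per_cohort,
        table=table,
        fisher_p=p,
        odds_ratio=odds,
        n_dropped_normals=n_dropped,
    )
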