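"""Library-size and composition normalizations for RNA-seq count matrices.

Implements the six schemes whose behaviour under library-composition bias
this package compares:

``fpkm``
    count * 1e9 / (length_bp * library_size).
``tpm``
    FPKM rescaled so each sample sums to 1e6.  Because columns are forced to
    a fixed total, TPM is zero-sum within a sample: any transcript group that
    dominates the read pool (mitochondrial RNA, haemoglobin, ...) depresses
    every other gene's value, which is the compositional artifact the
    diagnostics module quantifies.
``cpm_excluding``
    counts per million with a chosen gene set (typically the mitochondrial
    genes) removed from the denominator used for the remaining genes; the
    excluded genes themselves are scaled by the full library total.  No
    length term.
``uq``
    upper-quartile scaling: the 75th percentile of a sample's non-zero
    counts, factors rescaled to geometric mean 1 relative to library size.
``mrn``
    median-of-ratios size factors (the DESeq2 estimator): a geometric-mean
    reference over genes positive in every sample, size factor = median of
    the sample/reference ratios.  Values are "pseudocounts" count/factor.
``tmm``
    trimmed mean of M-values (the edgeR estimator): doubly trimmed,
    precision-weighted mean of per-gene log ratios against a reference
    sample, factors rescaled to geometric mean 1.

MRN and TMM build their scale from the bulk of moderately expressed genes,
which makes them insensitive to a minority of dominant transcripts; that
robustness is the property the rest of the package demonstrates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "ScalingFactors",
    "fpkm",
    "tpm",
    "cpm_excluding",
    "uq_factors",
    "mrn_factors",
    "tmm_factors",
    "apply_scaling",
    "mt_fraction",
    "normalize",
    "METHODS",
]

METHODS = ("tpm", "fpkm", "cpm_excl", "uq", "mrn", "tmm")


@dataclass
class NormalizedMatrix:
    """genes x samples normalized expression values tagged with provenance."""

    values: pd.DataFrame
    method: str
    source_hash: str = ""
    excluded_sets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("normalized values must be finite")


@dataclass
class ScalingFactors:
    """Per-sample scaling factors.

    ``factors`` is the method's normalization factor (geometric mean 1 across
    samples for UQ/TMM; the raw median-of-ratios size factor for MRN, which
    follows the DESeq2 convention of no product rescaling).  ``library_size``
    is the per-sample total count, kept so the effective scale
    library_size * factor can be reconstructed.
    """

    factors: pd.Series
    method: str
    library_size: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    raw: pd.Series | None = None  # method-specific basis (UQ: the 75th pct)

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("scaling factors must be strictly positive")

    @property
    def scale(self) -> pd.Series:
        """Effective per-sample scale: library_size * factor for UQ/TMM,
        the size factor itself for MRN."""
        if self.method == "mrn":
            return self.factors
        return self.library_size * self.factors


def _check_libraries(cm: CountMatrix) -> pd.Series:
    lib = cm.library_sizes().astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero-count library for samples: {bad}")
    return lib


def fpkm(cm: CountMatrix) -> NormalizedMatrix:
    """Fragments per kilobase of transcript per million mapped reads."""
    lib = _check_libraries(cm)
    lengths = cm.lengths.to_numpy(float)[:, None]
    vals = cm.counts.to_numpy(float) * 1e9 / (lengths * lib.to_numpy()[None, :])
    return NormalizedMatrix(
        pd.DataFrame(vals, index=cm.genes, columns=cm.samples),
        "fpkm",
        cm.content_hash(),
    )


def tpm(cm: CountMatrix, via_fpkm: bool = False) -> NormalizedMatrix:
    """Transcripts per million: length-normalized rates scaled so each
    sample sums to 1e6.

    ``via_fpkm=True`` takes the route FPKM_i / sum_j FPKM_j * 1e6; the
    direct route divides the length-normalized rate by its sample total.
    The two agree to floating-point precision (asserted in tests).
    """
    if via_fpkm:
        f = fpkm(cm).values.to_numpy()
        vals = f / f.sum(axis=0, keepdims=True) * 1e6
    else:
        _check_libraries(cm)
        rate = cm.counts.to_numpy(float) / cm.lengths.to_numpy(float)[:, None]
        vals = rate / rate.sum(axis=0, keepdims=True) * 1e6
    return NormalizedMatrix(
        pd.DataFrame(vals, index=cm.genes, columns=cm.samples),
        "tpm",
        cm.content_hash(),
    )


def cpm_excluding(cm: CountMatrix, excluded: Iterable[str]) -> NormalizedMatrix:
    """Counts per million with `excluded` genes removed from the denominator
    used for all other genes.

    The excluded genes are still reported, scaled by the full library total.
    No length normalization is applied: for correlation analysis, which never
    compares genes within a sample, the missing length term is a per-gene
    constant and is irrelevant to rank statistics.
    """
    excluded = list(excluded)
    missing = set(excluded) - set(cm.genes)
    if missing:
        raise ValueError(f"excluded genes not in matrix: {sorted(missing)[:5]}")
    lib = _check_libraries(cm)
    mask = cm.genes.isin(excluded)
    counts = cm.counts.to_numpy(float)
    denom = lib.to_numpy() - counts[mask].sum(axis=0)
    if (denom <= 0).any():
        bad = cm.samples[denom <= 0].tolist()
        raise ValueError(f"exclusion leaves no counts in samples: {bad}")
    vals = np.empty_like(counts)
    vals[~mask] = counts[~mask] * 1e6 / denom[None, :]
    vals[mask] = counts[mask] * 1e6 / lib.to_numpy()[None, :]
    return NormalizedMatrix(
        pd.DataFrame(vals, index=cm.genes, columns=cm.samples),
        "cpm_excl",
        cm.content_hash(),
        excluded_sets=("excluded",) if excluded else (),
    )


def uq_factors(cm: CountMatrix) -> ScalingFactors:
    """Upper-quartile normalization factors.

    Per sample: the 75th percentile (linear-interpolation quantile) of the
    non-zero counts, divided by library size, then rescaled so the factors
    have geometric mean 1 across samples.
    """
    lib = _check_libraries(cm)
    counts = cm.counts.to_numpy(float)
    quarts = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        nz = counts[:, j][counts[:, j] > 0]
        if nz.size == 0:
            raise ValueError(f"all-zero sample {cm.samples[j]!r}")
        quarts[j] = np.percentile(nz, 75)
    f = quarts / lib.to_numpy()
    f = f / np.exp(np.mean(np.log(f)))
    return ScalingFactors(
        pd.Series(f, index=cm.samples), "uq", lib,
        raw=pd.Series(quarts, index=cm.samples),
    )


def mrn_factors(cm: CountMatrix) -> ScalingFactors:
    """Median-of-ratios size factors (DESeq2's estimateSizeFactors).

    reference_g = geometric mean of gene g's counts across samples, taken
    over genes positive in every sample; size factor of sample s = median
    over those genes of count_gs / reference_g.
    """
    counts = cm.counts.to_numpy(float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "median-of-ratios undefined: no gene has positive counts in "
            "every sample"
        )
    # median taken on the log scale, matching the reference estimator: for
    # an even number of usable genes this is the geometric mean of the two
    # middle ratios
    logc = np.log(counts[positive])
    ref = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - ref, axis=0))
    return ScalingFactors(
        pd.Series(factors, index=cm.samples), "mrn", cm.library_sizes().astype(float)
    )


def _quantile_all(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    # depth-normalized quantile over ALL genes (zeros included), as used by
    # edgeR to pick the TMM reference sample
    return np.percentile(counts / lib[None, :], p * 100, axis=0)


def tmm_factors(
    cm: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> ScalingFactors:
    """Trimmed-mean-of-M-values normalization factors.

    Follows the published TMM algorithm with its default trims: reference
    sample = the one whose depth-normalized upper quartile is closest to the
    mean upper quartile; per-gene log-ratio M and log-abundance A computed on
    depth-normalized counts for genes positive in both sample and reference;
    the upper and lower ``trim_m`` of M and ``trim_a`` of A are discarded;
    the factor is 2**(precision-weighted mean of the surviving M), weights
    being inverse asymptotic binomial variances; factors are rescaled to
    geometric mean 1.
    """
    lib = _check_libraries(cm).to_numpy()
    counts = cm.counts.to_numpy(float)
    n_samples = counts.shape[1]
    if reference is None:
        q = _quantile_all(counts, lib)
        ref_idx = int(np.argmin(np.abs(q - q.mean())))
    else:
        ref_idx = cm.samples.get_loc(reference)
    ref = counts[:, ref_idx]
    ref_lib = lib[ref_idx]

    log_factors = np.zeros(n_samples)
    for j in range(n_samples):
        if j == ref_idx:
            continue
        obs = counts[:, j]
        ok = (obs > 0) & (ref > 0)
        p_obs = obs[ok] / lib[j]
        p_ref = ref[ok] / ref_lib
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        # drop infinite abundance (edgeR guard; cannot occur with ok mask)
        n = m.size
        if n == 0:
            raise ValueError(
                f"no genes shared between sample {cm.samples[j]!r} and reference"
            )
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() < 3:
            raise ValueError(
                f"fewer than 3 genes survive TMM trimming for sample "
                f"{cm.samples[j]!r}"
            )
        # asymptotic binomial variance of M (delta method)
        w = 1.0 / (
            (lib[j] - obs[ok]) / (lib[j] * obs[ok])
            + (ref_lib - ref[ok]) / (ref_lib * ref[ok])
        )
        log_factors[j] = np.sum(w[keep] * m[keep]) / np.sum(w[keep])

    f = 2.0**log_factors
    f = f / np.exp(np.mean(np.log(f)))
    return ScalingFactors(
        pd.Series(f, index=cm.samples), "tmm", pd.Series(lib, index=cm.samples)
    )


def apply_scaling(cm: CountMatrix, factors: ScalingFactors) -> NormalizedMatrix:
    """Turn scaling factors into a normalized matrix.

    UQ/TMM: value = count * 1e6 / (library_size * factor).
    MRN: value = count / size_factor (normalized pseudocounts).
    """
    if not factors.factors.index.equals(cm.samples):
        raise ValueError("factor samples do not match count matrix samples")
    counts = cm.counts.to_numpy(float)
    if factors.method == "mrn":
        vals = counts / factors.factors.to_numpy()[None, :]
    elif factors.method in ("uq", "tmm"):
        scale = factors.library_size.to_numpy() * factors.factors.to_numpy()
        vals = counts * 1e6 / scale[None, :]
    else:
        raise ValueError(f"unknown factor method {factors.method!r}")
    return NormalizedMatrix(
        pd.DataFrame(vals, index=cm.genes, columns=cm.samples),
        factors.method,
        cm.content_hash(),
    )


def mt_fraction(cm: CountMatrix, mt_set: Iterable[str] | None = None) -> pd.Series:
    """Per-sample fraction of total counts carried by mitochondrial genes.

    ``mt_set`` defaults to the annotation's mitochondrial genes.
    """
    if mt_set is None:
        mt = cm.mito_genes()
    else:
        mt = pd.Index(list(mt_set))
        if len(mt) == 0:
            raise ValueError("mt_set is empty")
    lib = _check_libraries(cm)
    frac = cm.counts.loc[cm.genes.isin(mt)].sum(axis=0) / lib
    return frac


def normalize(
    cm: CountMatrix, method: str, excluded: Iterable[str] | None = None
) -> NormalizedMatrix:
    """Dispatch on the six method tags (``cpm_excl`` requires ``excluded``,
    defaulting to the annotation's mitochondrial genes)."""
    method = method.lower().replace("-", "_")
    if method == "tpm":
        return tpm(cm)
    if method == "fpkm":
        return fpkm(cm)
    if method == "cpm_excl":
        if excluded is None:
            excluded = cm.mito_genes()
        return cpm_excluding(cm, excluded)
    if method == "uq":
        return apply_scaling(cm, uq_factors(cm))
    if method == "mrn":
        return apply_scaling(cm, mrn_factors(cm))
    if method == "tmm":
        return apply_scaling(cm, tmm_factors(cm))
    raise ValueError(f"unknown normalization method {method!r}")
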