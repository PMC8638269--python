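"""Multi-cohort RNA-seq count simulator with a latent mitochondrial-RNA
fraction, planted block correlations and confounder effects.

The generator emulates the data-generating process behind the compositional
artifact this package studies.  Each cohort (a "tissue") has:

* a latent per-sample mitochondrial activity factor, log-normal with a
  target mean read share (``mt_fraction_mean``, anywhere from ~5% to >60% of
  reads in real tissues) and a coefficient of variation
  (``mt_fraction_cv``, emulating the wide within-tissue spread of mtRNA
  levels).  This factor is the common latent of the mitochondrial gene
  block, so mitochondrial genes are strongly co-expressed, as they are in
  real data where they share a polycistronic transcription unit;
* a nuclear-OXPHOS block sharing its own latent factor, optionally
  correlated with the mitochondrial factor (``rho_mt_nu``, the planted
  mito-nuclear coordination; 0 for null scenarios);
* independent background genes;
* additive confounder shifts (age, sex, batch) on the log scale;
* per-sample library sizes, with expression rates renormalized to the
  library total before negative-binomial sampling — sequencing only measures
  proportions, so a sample with high mitochondrial activity necessarily
  yields fewer nuclear reads.  This renormalization step is what creates
  the TPM/FPKM artifact downstream.

Rank-correlation targets are planted through a Gaussian copula with the
Pearson-Spearman correction r = 2*sin(pi*rho_s/6), making the planted
Spearman exact at the latent-rate level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSetCatalog, substream

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "generate_dataset",
    "inject_dominant_genes",
    "generate_matched_dataset",
    "spearman_to_pearson",
]


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula correction: the Pearson correlation of a bivariate
    normal whose Spearman correlation is ``rho_s``."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _per_cohort(value, n: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.repeat(arr, n)
    if arr.size != n:
        raise ValueError(f"{name}: expected 1 or {n} values, got {arr.size}")
    return arr


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults describe a moderate multi-tissue design: 5 cohorts of 150
    samples, the canonical 13 mitochondrial-OXPHOS and 126 nuclear-OXPHOS
    gene set sizes, 200 expressed background genes, mitochondrial read
    share 30% with CV 0.3, tight mitochondrial co-expression
    (Spearman 0.8), moderate nuclear-OXPHOS co-expression (0.35) and no
    planted mito-nuclear coordination (the null that total-count
    normalizations distort).

    ``bio_log_sd`` (residual between-donor biological variation, log scale)
    defaults to 0.2, i.e. ~20% CV: at this desk scale the 126-gene block is
    a far larger fraction of the gene panel than any co-expression program
    is of a real transcriptome, and keeping block amplitudes moderate
    preserves the real-data property that the nuclear read pool is not
    destabilized by a single program.
    """

    n_cohorts: int = 5
    samples_per_cohort: int = 150
    n_mt_genes: int = 13
    n_nuoxphos_genes: int = 126
    n_background_genes: int = 200
    mt_fraction_mean: float | Sequence[float] = 0.3
    mt_fraction_cv: float | Sequence[float] = 0.3
    rho_mt: float = 0.8
    rho_nu: float = 0.35
    rho_mt_nu: float = 0.0
    bio_log_sd: float = 0.2
    confounder_effects: dict = field(
        default_factory=lambda: {"age": 0.003, "sex": 0.10, "batch": 0.10}
    )
    library_log_mean: float = float(np.log(2e6))
    library_log_sd: float = 0.3
    nb_dispersion: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        f = _per_cohort(self.mt_fraction_mean, self.n_cohorts, "mt_fraction_mean")
        cv = _per_cohort(self.mt_fraction_cv, self.n_cohorts, "mt_fraction_cv")
        if ((f <= 0) | (f >= 1)).any():
            raise ValueError("mt_fraction_mean must lie in (0, 1)")
        if (cv < 0).any():
            raise ValueError("mt_fraction_cv must be >= 0")
        for name in ("rho_mt", "rho_nu", "rho_mt_nu"):
            if abs(getattr(self, name)) >= 1:
                raise ValueError(f"|{name}| must be < 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if (cv > 0).any() and self.rho_mt <= 0:
            raise ValueError(
                "mt_fraction_cv > 0 requires rho_mt > 0: the mitochondrial "
                "activity factor is the block's shared latent, so a varying "
                "mt fraction necessarily correlates mitochondrial genes"
            )
        if self.rho_mt_nu != 0.0:
            r_mt = spearman_to_pearson(self.rho_mt)
            r_nu = spearman_to_pearson(self.rho_nu)
            if r_mt <= 0 or r_nu <= 0:
                raise ValueError(
                    "planting rho_mt_nu requires positive rho_mt and rho_nu"
                )
            rho_f = spearman_to_pearson(self.rho_mt_nu) / np.sqrt(r_mt * r_nu)
            if abs(rho_f) > 1:
                raise ValueError(
                    "infeasible correlation structure: |rho_mt_nu| too large "
                    "relative to the within-block correlations "
                    "(factor correlation would need to be "
                    f"{rho_f:.3f})"
                )


@dataclass
class SimulationTruth:
    """Everything the generator knows that an analyst would have to infer."""

    rates: pd.DataFrame  # latent expression rates (pre-renormalization)
    mt_activity: pd.Series  # per-sample latent mt factor (log scale, N(0,1))
    nu_factor: pd.Series  # per-sample nuclear-block factor
    planted: dict  # planted Spearman targets and mt-fraction params
    confounders: pd.DataFrame  # realized design (age, sex, batch)
    gene_effects: pd.DataFrame  # per-gene confounder coefficients


AGE_BRACKETS = ["20-29", "30-39", "40-49", "50-59", "60-69", "70-79"]


def _gene_ids(cfg: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    mt = [f"MT-G{i+1:02d}" for i in range(cfg.n_mt_genes)]
    nu = [f"NUOX-{i+1:03d}" for i in range(cfg.n_nuoxphos_genes)]
    bg = [f"BG-{i+1:04d}" for i in range(cfg.n_background_genes)]
    return mt, nu, bg


def generate_dataset(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, GeneSetCatalog, SimulationTruth]:
    """Draw one multi-cohort dataset.

    Returns the count matrix (metadata attached), a catalogue with the
    ``mtOXPHOS`` / ``nuOXPHOS`` / ``background`` sets, and the truth object
    holding every latent used.
    """
    rng = substream(cfg.seed, "synthetic_data")
    mt_ids, nu_ids, bg_ids = _gene_ids(cfg)
    gene_ids = mt_ids + nu_ids + bg_ids
    n_genes = len(gene_ids)
    n_mt, n_nu = len(mt_ids), len(nu_ids)

    f_mean = _per_cohort(cfg.mt_fraction_mean, cfg.n_cohorts, "mt_fraction_mean")
    f_cv = _per_cohort(cfg.mt_fraction_cv, cfg.n_cohorts, "mt_fraction_cv")

    # gene catalogue: lengths log-uniform 300-10k bp to exercise length
    # normalization; mt transcripts kept in the same range
    lengths = np.exp(rng.uniform(np.log(300), np.log(10_000), n_genes)).astype(int)
    annotation = pd.DataFrame(
        {
            "symbol": gene_ids,
            "length_bp": lengths,
            "origin": ["mitochondrial"] * n_mt + ["nuclear"] * (n_genes - n_mt),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # relative baseline expression (counts scale, before mt share calibration)
    base_mt = np.exp(rng.normal(np.log(1000), 0.5, n_mt))
    base_nu = np.exp(rng.normal(np.log(300), 0.5, n_nu))
    base_bg = np.exp(rng.normal(np.log(150), 0.8, len(bg_ids)))

    # copula loadings
    r_mt = spearman_to_pearson(cfg.rho_mt)
    r_nu = spearman_to_pearson(cfg.rho_nu)
    r_cross = spearman_to_pearson(cfg.rho_mt_nu)
    rho_f = 0.0
    if r_cross != 0.0:
        rho_f = r_cross / np.sqrt(r_mt * r_nu)

    # per-gene confounder coefficients (log-scale), shared across cohorts
    eff = cfg.confounder_effects
    beta_age = rng.normal(0.0, eff.get("age", 0.0), n_genes)
    beta_sex = rng.normal(0.0, eff.get("sex", 0.0), n_genes)
    n_batches = 3
    beta_batch = rng.normal(0.0, eff.get("batch", 0.0), (n_genes, n_batches))

    all_counts, all_rates, meta_rows = [], [], []
    mt_act_all, nu_fac_all = [], []
    sample_ids: list[str] = []

    for c in range(cfg.n_cohorts):
        n = cfg.samples_per_cohort
        cohort = f"cohort{c+1:02d}"
        ids = [f"{cohort}-S{i+1:04d}" for i in range(n)]
        sample_ids += ids

        # latent factors
        w = rng.normal(size=n)  # mt activity (standardized log scale)
        eps = rng.normal(size=n)
        v = rho_f * w + np.sqrt(max(0.0, 1 - rho_f**2)) * eps

        # mitochondrial block: common log-sd fixed by the mt-fraction CV
        sigma_m = float(np.sqrt(np.log1p(f_cv[c] ** 2)))
        if sigma_m > 0:
            sigma_mt_tot = sigma_m / np.sqrt(r_mt)
        else:  # cv == 0: block correlation still possible via bio noise
            sigma_m = np.sqrt(r_mt) * cfg.bio_log_sd if cfg.rho_mt > 0 else 0.0
            sigma_mt_tot = cfg.bio_log_sd if cfg.rho_mt > 0 else 0.0
        sigma_mt_ind = float(np.sqrt(max(0.0, sigma_mt_tot**2 - sigma_m**2)))

        s_nu_com = np.sqrt(max(r_nu, 0.0)) * cfg.bio_log_sd
        s_nu_ind = np.sqrt(max(0.0, cfg.bio_log_sd**2 - s_nu_com**2))

        # log deviations, mean-corrected so E[exp(.)] = 1 per gene
        z_mt = sigma_m * w[None, :] + sigma_mt_ind * rng.normal(size=(n_mt, n))
        z_mt -= 0.5 * (sigma_m**2 + sigma_mt_ind**2)
        z_nu = s_nu_com * v[None, :] + s_nu_ind * rng.normal(size=(n_nu, n))
        z_nu -= 0.5 * (s_nu_com**2 + s_nu_ind**2)
        z_bg = cfg.bio_log_sd * rng.normal(size=(len(bg_ids), n))
        z_bg -= 0.5 * cfg.bio_log_sd**2

        # confounders
        brackets = rng.choice(AGE_BRACKETS, size=n)
        age_mid = np.array([(int(b[:2]) + int(b[3:])) / 2 for b in brackets])
        sex = rng.integers(0, 2, size=n)
        batch = rng.integers(0, n_batches, size=n)
        hardy = rng.integers(0, 5, size=n)
        ischemic = np.round(rng.uniform(60, 1400, size=n), 1)
        conf_shift = (
            beta_age[:, None] * (age_mid - age_mid.mean())[None, :]
            + beta_sex[:, None] * (sex - 0.5)[None, :]
            + beta_batch[:, batch]
        )

        # calibrate the mt baseline so the expected read share equals f_mean
        m_total = base_mt.sum()
        nuc_total = base_nu.sum() + base_bg.sum()
        alpha = f_mean[c] * nuc_total / ((1.0 - f_mean[c]) * m_total)

        base = np.concatenate([alpha * base_mt, base_nu, base_bg])
        z = np.vstack([z_mt, z_nu, z_bg])
        rates = base[:, None] * np.exp(z + conf_shift)

        # sequencing: proportions times library size, NB sampling
        lib = np.exp(
            rng.normal(cfg.library_log_mean, cfg.library_log_sd, size=n)
        )
        mu = rates / rates.sum(axis=0, keepdims=True) * lib[None, :]
        if cfg.nb_dispersion > 0:
            shape = 1.0 / cfg.nb_dispersion
            lam = rng.gamma(shape, mu / shape)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mu)

        all_counts.append(counts)
        all_rates.append(rates)
        mt_act_all.append(w)
        nu_fac_all.append(v)
        for i, sid in enumerate(ids):
            meta_rows.append(
                {
                    "sample_id": sid,
                    "cohort": cohort,
                    "donor_id": f"{cohort}-D{i+1:04d}",
                    "age_bracket": brackets[i],
                    "sex": "male" if sex[i] else "female",
                    "batch": f"batch{batch[i]+1}",
                    "hardy_scale": int(hardy[i]),
                    "ischemic_time": float(ischemic[i]),
                    "sample_class": "healthy",
                }
            )

    counts = pd.DataFrame(
        np.hstack(all_counts).astype(np.int64), index=gene_ids, columns=sample_ids
    )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    cm = CountMatrix(counts, annotation, metadata)
    catalog = GeneSetCatalog(
        {"mtOXPHOS": mt_ids, "nuOXPHOS": nu_ids, "background": bg_ids}
    )
    truth = SimulationTruth(
        rates=pd.DataFrame(np.hstack(all_rates), index=gene_ids, columns=sample_ids),
        mt_activity=pd.Series(np.concatenate(mt_act_all), index=sample_ids),
        nu_factor=pd.Series(np.concatenate(nu_fac_all), index=sample_ids),
        planted={
            "rho_mt": cfg.rho_mt,
            "rho_nu": cfg.rho_nu,
            "rho_mt_nu": cfg.rho_mt_nu,
            "mt_fraction_mean": f_mean.tolist(),
            "mt_fraction_cv": f_cv.tolist(),
        },
        confounders=metadata[["cohort", "age_bracket", "sex", "batch"]].copy(),
        gene_effects=pd.DataFrame(
            {"age": beta_age, "sex": beta_sex}, index=gene_ids
        ),
    )
    return cm, catalog, truth


def inject_dominant_genes(
    cm: CountMatrix, gene_ids: Sequence[str], share: float
) -> CountMatrix:
    """Rescale the named genes so their pooled expected share of each
    sample's counts equals ``share``.

    Emulates tissues where a handful of non-mitochondrial transcripts
    dominate the library (haemoglobin genes at ~40% of whole-blood reads,
    serine proteases in pancreas).  Other genes keep their counts, so the
    relative proportions among them are untouched; the named genes keep
    their relative proportions among themselves.
    """
    gene_ids = list(gene_ids)
    missing = set(gene_ids) - set(cm.genes)
    if missing:
        raise ValueError(f"genes not in matrix: {sorted(missing)}")
    if not 0 < share < 1:
        raise ValueError("share must lie in (0, 1)")
    counts = cm.counts.to_numpy(float).copy()
    mask = cm.genes.isin(gene_ids)
    dom = counts[mask].sum(axis=0)
    rest = counts[~mask].sum(axis=0)
    if (dom <= 0).any():
        bad = cm.samples[dom <= 0].tolist()
        raise ValueError(f"dominant genes have zero counts in samples: {bad}")
    k = share * rest / ((1.0 - share) * dom)
    counts[mask] = np.round(counts[mask] * k[None, :])
    out = pd.DataFrame(
        counts.astype(np.int64), index=cm.genes, columns=cm.samples
    )
    return CountMatrix(out, cm.annotation, cm.metadata)


def generate_matched_dataset(
    n_cohorts: int = 14,
    samples_per_class: int = 30,
    rho_tumor: float = 0.5,
    rho_normal: float = 0.0,
    seed: int = 0,
    **config_kwargs,
) -> tuple[CountMatrix, GeneSetCatalog, dict]:
    """Tumour/adjacent-normal cohorts sharing donors, with mito-nuclear
    coordination planted only where requested (default: tumour only).

    Emulates the matched-pair design: every donor contributes one
    primary-tumour and one adjacent-normal sample.  Returns one combined
    CountMatrix whose metadata carries ``sample_class`` and shared
    ``donor_id`` values, plus per-class truth objects.
    """
    frames, metas, truths = [], [], {}
    catalog = None
    annotation = None
    for cls, rho, tag in (
        ("primary_tumor", rho_tumor, "T"),
        ("adjacent_normal", rho_normal, "N"),
    ):
        cfg = SimulationConfig(
            n_cohorts=n_cohorts,
            samples_per_cohort=samples_per_class,
            rho_mt_nu=rho,
            seed=seed + (1 if cls == "primary_tumor" else 2),
            **config_kwargs,
        )
        cm, cat, truth = generate_dataset(cfg)
        meta = cm.metadata.copy()
        meta["sample_class"] = cls
        # donors shared across classes within a cohort: strip the class tag
        meta["donor_id"] = [
            d for d in meta["donor_id"]
        ]  # donor ids already align by position across the two calls
        new_ids = [f"{s}-{tag}" for s in cm.samples]
        counts = cm.counts.copy()
        counts.columns = new_ids
        meta.index = pd.Index(new_ids, name="sample_id")
        frames.append(counts)
        metas.append(meta)
        truths[cls] = truth
        catalog = cat
        annotation = cm.annotation
    counts = pd.concat(frames, axis=1)
    metadata = pd.concat(metas, axis=0)
    return CountMatrix(counts, annotation, metadata), catalog, truths
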