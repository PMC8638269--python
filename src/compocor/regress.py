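"""Per-gene removal of known confounders by ordinary least squares.

Before correlating genes across donors, technical and demographic
covariates (age bracket, sex, death classification, ischemic time,
sequencing batch) are regressed out of each gene's normalized expression;
the residuals carry the donor-to-donor variation of interest.

Two scopes are supported.  ``per_cohort`` fits each cohort separately.
``combined`` fits one model across cohorts, expanding covariate-by-cohort
interactions and adding donor and batch as categorical blocks — a
fixed-effects approximation of a mixed model with donor and batch as random
effects: with the many levels these factors have, the difference between
fixed-effects absorption and random-effect shrinkage is immaterial for the
rank-based statistics computed downstream, and the fixed-effects fit is
deterministic.  An exact mixed-model backend is a declared extension point.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalize import NormalizedMatrix

__all__ = ["DesignSpec", "ResidualMatrix", "age_midpoint", "regress_out"]

_BRACKET_RE = re.compile(r"^\s*(\d+)\s*-\s*(\d+)\s*$")


def age_midpoint(bracket: str) -> float:
    """Midpoint of an age bracket string like ``"50-59"`` -> 54.5."""
    m = _BRACKET_RE.match(str(bracket))
    if not m:
        raise ValueError(f"malformed age bracket: {bracket!r}")
    lo, hi = int(m.group(1)), int(m.group(2))
    return (lo + hi) / 2.0


@dataclass
class DesignSpec:
    """Which metadata columns enter the per-gene linear model.

    ``numeric`` columns enter as-is, except ``age_bracket`` which is parsed
    to its midpoint.  ``categorical`` columns are dummy-expanded (first
    level dropped).  In combined scope, columns listed in
    ``interact_with_cohort`` get cohort-interaction terms, and
    ``blocking`` factors (donor, batch) are absorbed as categorical blocks.
    """

    numeric: list[str] = field(default_factory=list)
    categorical: list[str] = field(default_factory=list)
    interact_with_cohort: list[str] = field(default_factory=list)
    blocking: list[str] = field(default_factory=list)

    @classmethod
    def gtex_style(cls) -> "DesignSpec":
        """Age, sex, death classification, ischemic time and sequencing
        batch; donor absorbed as a block in combined-scope fits only (each
        donor appears once per cohort)."""
        return cls(
            numeric=["age_bracket", "ischemic_time"],
            categorical=["sex", "hardy_scale", "batch"],
            interact_with_cohort=["age_bracket", "ischemic_time", "sex", "hardy_scale"],
            blocking=["donor_id"],
        )

    @classmethod
    def from_yaml(cls, path) -> "DesignSpec":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ResidualMatrix:
    """genes x samples OLS residuals with fit provenance."""

    values: pd.DataFrame
    design_columns: list[str]
    scope: str
    dropped_columns: list[str] = field(default_factory=list)
    r_squared: pd.Series | None = None


def _numeric_column(meta: pd.DataFrame, col: str) -> np.ndarray:
    s = meta[col]
    if col == "age_bracket":
        return np.array([age_midpoint(b) for b in s])
    return s.astype(float).to_numpy()


def _build_design(
    meta: pd.DataFrame, design: DesignSpec, scope: str
) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(meta))}
    for c in design.numeric:
        cols[c] = _numeric_column(meta, c)
    for c in design.categorical:
        d = pd.get_dummies(meta[c].astype(str), prefix=c, drop_first=True)
        for name in d.columns:
            cols[name] = d[name].to_numpy(float)
    X = pd.DataFrame(cols, index=meta.index)
    if scope == "combined":
        cohort_d = pd.get_dummies(meta["cohort"].astype(str), prefix="cohort",
                                  drop_first=True)
        for name in cohort_d.columns:
            X[name] = cohort_d[name].to_numpy(float)
        for c in design.interact_with_cohort:
            base_cols = [k for k in X.columns if k == c or k.startswith(f"{c}_")]
            for b in base_cols:
                for name in cohort_d.columns:
                    X[f"{b}:{name}"] = X[b] * cohort_d[name].to_numpy(float)
        for c in design.blocking:
            d = pd.get_dummies(meta[c].astype(str), prefix=c, drop_first=True)
            for name in d.columns:
                X[name] = d[name].to_numpy(float)
    return X


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedy rank-revealing pass: keep the first occurrence of each
    independent column, drop the rest (deterministic)."""
    keep: list[int] = []
    dropped: list[str] = []
    rank = 0
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > rank:
            keep.append(j)
            rank += 1
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped


def _ols_residuals(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # hat-matrix-free projection via least squares; Y is genes x samples
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T
    resid = Y - fitted
    tss = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    rss = (resid**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
    return resid, r2


def regress_out(
    normalized: NormalizedMatrix | pd.DataFrame,
    metadata: pd.DataFrame,
    design: DesignSpec | None = None,
    scope: str = "per_cohort",
) -> ResidualMatrix:
    """OLS residuals of each gene on the confounder design.

    ``design=None`` fits intercept-only models (residual = value minus the
    per-cohort gene mean).  Aliased design columns are dropped
    deterministically (first occurrence kept) and reported.
    """
    if scope not in ("per_cohort", "combined"):
        raise ValueError("scope must be 'per_cohort' or 'combined'")
    values = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
    meta = metadata.loc[values.columns]
    design = design or DesignSpec()

    out = np.empty(values.shape)
    r2 = np.empty(values.shape[0])
    dropped_all: list[str] = []
    design_cols: list[str] = []

    if scope == "per_cohort":
        groups = meta.groupby("cohort", sort=False).groups if "cohort" in meta else {
            "all": meta.index
        }
        rss_tot = np.zeros(values.shape[0])
        tss_tot = np.zeros(values.shape[0])
        for _, idx in groups.items():
            loc = values.columns.get_indexer(idx)
            X = _build_design(meta.loc[idx], design, "per_cohort")
            Xa, kept, dropped = _drop_aliased(
                X.to_numpy(float), list(X.columns)
            )
            if Xa.shape[1] >= len(idx):
                raise ValueError(
                    "more design parameters than samples; reduce the design"
                )
            Y = values.to_numpy(float)[:, loc]
            resid, _ = _ols_residuals(Y, Xa)
            out[:, loc] = resid
            dropped_all += dropped
            design_cols = kept
            rss_tot += (resid**2).sum(axis=1)
            tss_tot += ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(tss_tot > 0, 1.0 - rss_tot / tss_tot, 0.0)
    else:
        X = _build_design(meta, design, "combined")
        Xa, kept, dropped = _drop_aliased(X.to_numpy(float), list(X.columns))
        if Xa.shape[1] >= values.shape[1]:
            raise ValueError(
                "more design parameters than samples after interaction "
                "expansion; reduce the design"
            )
        out, r2 = _ols_residuals(values.to_numpy(float), Xa)
        dropped_all = dropped
        design_cols = kept

    return ResidualMatrix(
        pd.DataFrame(out, index=values.index, columns=values.columns),
        design_columns=design_cols,
        scope=scope,
        dropped_columns=dropped_all,
        r_squared=pd.Series(r2, index=values.index),
    )
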