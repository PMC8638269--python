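"""Data model and file I/O shared by all pipeline stages.

The central container is :class:`CountMatrix`: a gene-by-sample table of raw
read counts together with a gene annotation (transcript length and genomic
origin, mitochondrial vs nuclear) and optional per-sample metadata.  Counts
are stored as a pandas DataFrame so downstream stages can slice by gene id or
sample id without bookkeeping.

Readers accept the plain-text formats these data are normally exchanged in:
tab-separated gene x sample tables (first column ``gene_id``, header row of
sample ids), MatrixMarket triplets with sidecar row/column name files, GMT
gene-set files and one-id-per-line lists.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = [
    "CountMatrix",
    "GeneSetCatalog",
    "AnalysisConfig",
    "FormatError",
    "ValidationError",
    "read_counts",
    "read_annotation",
    "read_metadata",
    "read_gene_sets",
    "write_counts",
    "write_gene_sets",
    "write_tables",
    "substream",
]

ORIGINS = ("mitochondrial", "nuclear")


class FormatError(ValueError):
    """A file does not conform to the expected layout (non-numeric or
    negative entries, malformed lines)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates an invariant (duplicate
    ids, unknown genes, empty sets)."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, reproducible RNG substream.

    All randomness in the package flows from one user-facing seed; each
    pipeline stage draws from an independent stream keyed by a stable hash of
    its name, so adding iterations to one stage never perturbs another.
    """
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Raw RNA-seq counts with gene annotation and optional sample metadata.

    Parameters
    ----------
    counts
        genes x samples DataFrame of non-negative integers; index = gene ids,
        columns = sample ids.
    annotation
        DataFrame indexed by gene id with columns ``symbol``, ``length_bp``
        (positive int, transcript length used for rate normalizations) and
        ``origin`` (``"mitochondrial"`` or ``"nuclear"``).  Must cover every
        gene in ``counts``.
    metadata
        Optional DataFrame indexed by sample id; must cover every sample.
        Expected columns include ``cohort`` plus any covariates
        (``age_bracket``, ``sex``, ``batch``, ...).
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if c.columns.has_duplicates:
            dupes = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("counts must be numeric")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        missing = c.index.difference(self.annotation.index)
        if len(missing):
            raise ValidationError(
                f"{len(missing)} genes absent from annotation: "
                f"{missing[:5].tolist()}"
            )
        ann = self.annotation.loc[c.index]
        if (ann["length_bp"] <= 0).any():
            raise ValidationError("annotation length_bp must be >= 1")
        bad = set(ann["origin"]) - set(ORIGINS)
        if bad:
            raise ValidationError(f"unknown gene origin values: {sorted(bad)}")
        if self.metadata is not None:
            missing = c.columns.difference(self.metadata.index)
            if len(missing):
                raise ValidationError(
                    f"samples without metadata: {missing[:5].tolist()}"
                )

    # convenience accessors -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def lengths(self) -> pd.Series:
        return self.annotation.loc[self.genes, "length_bp"]

    @property
    def origin(self) -> pd.Series:
        return self.annotation.loc[self.genes, "origin"]

    def mito_genes(self) -> pd.Index:
        return self.genes[(self.origin == "mitochondrial").to_numpy()]

    def nuclear_genes(self) -> pd.Index:
        return self.genes[(self.origin == "nuclear").to_numpy()]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        meta = None
        if self.metadata is not None:
            meta = self.metadata.loc[list(sample_ids)]
        return CountMatrix(self.counts[list(sample_ids)], self.annotation, meta)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.counts.to_numpy()).tobytes())
        h.update("\x00".join(self.genes).encode())
        h.update("\x00".join(self.samples).encode())
        return h.hexdigest()[:16]

    def __eq__(self, other: object) -> bool:  # value equality for round-trips
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.counts.shape == other.counts.shape
            and self.genes.equals(other.genes)
            and self.samples.equals(other.samples)
            and (self.counts.to_numpy() == other.counts.to_numpy()).all()
        )


@dataclass
class GeneSetCatalog:
    """Named gene sets (e.g. the 13 mtOXPHOS and 126 nuOXPHOS ids).

    ``unresolved`` keeps ids that did not match the annotation: they are
    reported, never silently dropped, but excluded from computation.
    """

    sets: dict[str, list[str]]
    unresolved: dict[str, list[str]] = field(default_factory=dict)
    duplicate_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, ids in self.sets.items():
            if not ids:
                raise ValidationError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sets.items()}

    def resolve(self, universe: Iterable[str]) -> "GeneSetCatalog":
        """Split each set into resolvable / unresolvable ids against a gene
        universe; unresolvable ids move to ``unresolved``."""
        uni = set(universe)
        sets: dict[str, list[str]] = {}
        unresolved: dict[str, list[str]] = dict(self.unresolved)
        for name, ids in self.sets.items():
            keep = [g for g in ids if g in uni]
            lost = [g for g in ids if g not in uni]
            if not keep:
                raise ValidationError(
                    f"gene set {name!r}: no ids resolvable against the matrix"
                )
            sets[name] = keep
            if lost:
                unresolved[name] = unresolved.get(name, []) + lost
        return GeneSetCatalog(sets, unresolved, dict(self.duplicate_counts))


@dataclass
class AnalysisConfig:
    """Tunable knobs of the correlation pipeline, recorded in every output.

    Defaults follow the study design this package emulates: 100-sample
    subsamples aggregated over 100 iterations, 1000 bootstrap resamples,
    126-gene random null panels over 100 iterations, and a median-TPM > 5
    expression filter.
    """

    normalization: str = "mrn"
    subsample_size: int = 100
    n_iterations: int = 100
    bootstrap_reps: int = 1000
    null_panel_size: int = 126
    null_iterations: int = 100
    expression_threshold: float = 5.0
    fdr_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "subsample_size",
            "n_iterations",
            "bootstrap_reps",
            "null_panel_size",
            "null_iterations",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# readers


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str})
    required = {"gene_id", "symbol", "length_bp", "origin"}
    missing = required - set(ann.columns)
    if missing:
        raise FormatError(f"annotation missing columns: {sorted(missing)}")
    if ann["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene_id in annotation")
    ann = ann.set_index("gene_id")
    ann["length_bp"] = ann["length_bp"].astype(int)
    return ann


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise FormatError("metadata must have a sample_id column")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    return meta.set_index("sample_id")


def _read_counts_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric count entry in {path}: {exc}") from exc
    return df


def _read_counts_mtx(path: Path) -> pd.DataFrame:
    """MatrixMarket triplet with `<stem>.rows` / `<stem>.cols` name files."""
    mat = scipy.io.mmread(path)
    rows = Path(str(path) + ".rows")
    cols = Path(str(path) + ".cols")
    if not rows.exists() or not cols.exists():
        raise FormatError(f"missing sidecar name files for {path}")
    gene_ids = rows.read_text().split()
    sample_ids = cols.read_text().split()
    dense = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.int64
    )
    if dense.shape != (len(gene_ids), len(sample_ids)):
        raise FormatError("MTX dimensions do not match sidecar name files")
    return pd.DataFrame(dense, index=gene_ids, columns=sample_ids)


def read_counts(
    path: str | Path,
    annotation_path: str | Path,
    metadata_path: str | Path | None = None,
) -> CountMatrix:
    """Read a count matrix (TSV or MTX triplet) plus its gene annotation.

    Genes absent from the annotation are rejected with a named list rather
    than silently dropped.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        counts = _read_counts_mtx(path)
    else:
        counts = _read_counts_tsv(path)
    annotation = read_annotation(annotation_path)
    metadata = read_metadata(metadata_path) if metadata_path else None
    return CountMatrix(counts, annotation, metadata)


def read_gene_sets(path: str | Path) -> GeneSetCatalog:
    """Read gene sets from GMT (name, description, ids...) or a plain
    one-id-per-line file (set named after the file stem).

    Duplicate ids within a set are de-duplicated (first occurrence kept) and
    counted in ``duplicate_counts``.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    dup: dict[str, int] = {}
    text = path.read_text()
    if path.suffix.lower() == ".gmt":
        for line in text.splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"malformed GMT line: {line[:60]!r}")
            name, ids = parts[0], parts[2:]
            ids = [g for g in ids if g]
            seen: dict[str, None] = dict.fromkeys(ids)
            dup[name] = len(ids) - len(seen)
            sets[name] = list(seen)
    else:
        ids = [ln.strip() for ln in text.splitlines() if ln.strip()]
        seen = dict.fromkeys(ids)
        name = path.stem
        dup[name] = len(ids) - len(seen)
        sets[name] = list(seen)
    return GeneSetCatalog(sets, duplicate_counts=dup)


# ---------------------------------------------------------------------------
# writers


def write_counts(cm: CountMatrix, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        out = cm.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.counts.to_numpy()))
        # mmwrite appends .mtx if absent; normalise
        written = path if path.suffix == ".mtx" else path.with_suffix(".mtx")
        Path(str(written) + ".rows").write_text("\n".join(cm.genes) + "\n")
        Path(str(written) + ".cols").write_text("\n".join(cm.samples) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    out = annotation.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_gene_sets(catalog: GeneSetCatalog, path: str | Path) -> None:
    lines = []
    for name, ids in catalog.sets.items():
        lines.append("\t".join([name, "compocor"] + list(ids)))
    Path(path).write_text("\n".join(lines) + "\n")


def write_tables(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
) -> dict:
    """Write result tables as TSVs plus a JSON run summary.

    The summary embeds the seed and a config hash so any output directory is
    auditable: same seed + config => byte-identical tables.
    Returns the manifest (also written as ``run_summary.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for name, table in results.items():
        fname = f"{name}.tsv"
        table.to_csv(out_dir / fname, sep="\t", float_format="%.10g")
        files.append(fname)
    cfg = config or AnalysisConfig()
    manifest = {
        "files": files,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
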