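"""Expression-matrix I/O, run configuration and result serialization.

Conventions used throughout the package: genes are rows, samples are
columns, and values are linear-scale (un-logged) non-negative expression
intensities.  Supported on-disk formats are TSV/CSV (header row = sample
ids, first column = gene ids) and GCT v1.2.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("camix")

_FLOAT_FMT = "%.12g"  # >= 12 significant digits in every numeric table


class ExpressionMatrixError(ValueError):
    """Raised when an input matrix violates the model's assumptions."""


@dataclasses.dataclass
class ExpressionMatrix:
    """Non-negative genes x samples expression matrix.

    Attributes
    ----------
    gene_ids : list of str
        Unique row identifiers.
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Linear-scale intensities, all >= 0.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ExpressionMatrixError("expression values must be 2-D")
        n, j = self.values.shape
        if n != len(self.gene_ids) or j != len(self.sample_ids):
            raise ExpressionMatrixError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids / {len(self.sample_ids)} sample ids"
            )
        if len(set(self.gene_ids)) != n:
            dup = pd.Index(self.gene_ids)
            dup = sorted(dup[dup.duplicated()].unique())
            raise ExpressionMatrixError(f"duplicate gene ids: {dup[:5]}")
        if len(set(self.sample_ids)) != j:
            raise ExpressionMatrixError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            i, k = np.argwhere(~np.isfinite(self.values))[0]
            raise ExpressionMatrixError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[k]!r}"
            )
        if np.any(self.values < 0):
            i, k = np.argwhere(self.values < 0)[0]
            raise ExpressionMatrixError(
                f"negative expression value {self.values[i, k]} at gene "
                f"{self.gene_ids[i]!r}, sample {self.sample_ids[k]!r} "
                "(expression must be linear-scale and non-negative)"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_genes(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx], list(self.sample_ids), self.values[idx]
        )


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration.

    Defaults follow the method's reference settings: 5%/95% signal filter,
    M = 50 clusters, damping 0.5, stability window of 10 iterations.
    """

    k_min: int = 2
    k_max: int = 8
    n_clusters: int = 50
    filter_low_q: float = 0.05
    filter_high_q: float = 0.95
    noise_floor: float = 1e-12
    norm_choice: str = "l1"  # marker standardization norm: "l1" or "l2"
    seed: int = 0
    reduction: str = "none"  # {"none", "sample_cluster", "pca"}
    target_dim: int | None = None
    damping: float = 0.5
    max_iter: int = 1000
    stable_iter: int = 10
    subset_budget: float = 5e6
    unlog_base: float | None = None

    def __post_init__(self):
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        if not 0.0 <= self.filter_low_q < self.filter_high_q <= 1.0:
            raise ValueError("need 0 <= filter_low_q < filter_high_q <= 1")
        if self.norm_choice not in ("l1", "l2"):
            raise ValueError("norm_choice must be 'l1' or 'l2'")
        if self.reduction not in ("none", "sample_cluster", "pca"):
            raise ValueError("reduction must be none|sample_cluster|pca")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class RunResult:
    """Everything a pipeline run produces, ready for serialization."""

    selected_K: int
    mdl_curve: pd.DataFrame  # index K; columns neg_log_likelihood, penalty, total
    mixing_matrix: pd.DataFrame  # samples x K, rows sum to 1
    marker_table: pd.DataFrame  # columns gene, subpopulation, cluster_id
    profiles: pd.DataFrame  # genes x K, >= 0
    config: dict
    fit_error: float = np.nan

    def __post_init__(self):
        rows = self.mixing_matrix.to_numpy().sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("mixing matrix rows must sum to 1")
        if np.any(self.profiles.to_numpy() < 0):
            raise ValueError("profiles must be non-negative")


def read_expression(path, fmt: str | None = None,
                    unlog_base: float | None = None) -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV, CSV or GCT.

    ``fmt`` is inferred from the file suffix when omitted.  Negative,
    non-numeric or duplicated entries are rejected with coordinates.
    ``unlog_base`` exponentiates log-scale input back to linear scale
    before validation (logged data may legitimately contain negatives).
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".") or "tsv"
    fmt = fmt.lower()
    if fmt not in ("tsv", "csv", "gct", "txt"):
        raise ValueError(f"unsupported format {fmt!r}")
    if fmt == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ValueError(f"unsupported GCT version line {version!r}")
            fh.readline()  # dimensions line; shapes re-validated below
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=[c for c in ("Description", "DESCRIPTION") if c in df.columns])
    else:
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ExpressionMatrixError(
                    f"non-numeric value at gene {gene!r}, sample {col!r}"
                ) from exc
        raise
    if unlog_base is not None:
        if unlog_base <= 1:
            raise ValueError("log base must be > 1")
        values = np.power(float(unlog_base), values)
    return ExpressionMatrix(list(df.index), list(df.columns), values)


def write_expression(expr: ExpressionMatrix, path, fmt: str | None = None) -> Path:
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".") or "tsv"
    df = expr.to_frame()
    if fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
            out = df.copy()
            out.insert(0, "Description", expr.gene_ids)
            out.index.name = "Name"
            out.to_csv(fh, sep="\t", float_format=_FLOAT_FMT)
    else:
        df.index.name = "gene"
        df.to_csv(path, sep="," if fmt == "csv" else "\t", float_format=_FLOAT_FMT)
    return path


def write_results(result: RunResult, outdir) -> dict:
    """Write markers/proportions/profiles/MDL tables plus a JSON summary.

    Returns a dict mapping artifact name to path.  All numeric output is
    written with 12 significant digits so that reloads round-trip to
    <= 1e-9 relative error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    markers = result.marker_table.copy()
    paths["markers"] = outdir / "markers.tsv"
    markers.to_csv(paths["markers"], sep="\t", index=False)

    prop = result.mixing_matrix.copy()
    prop.index.name = "sample"
    paths["proportions"] = outdir / "proportions.tsv"
    prop.to_csv(paths["proportions"], sep="\t", float_format=_FLOAT_FMT)

    prof = result.profiles.copy()
    prof.index.name = "gene"
    paths["profiles"] = outdir / "profiles.tsv"
    prof.to_csv(paths["profiles"], sep="\t", float_format=_FLOAT_FMT)

    mdl = result.mdl_curve.copy()
    mdl.index.name = "K"
    mdl["selected"] = (mdl.index == result.selected_K).astype(int)
    paths["mdl"] = outdir / "mdl.tsv"
    mdl.to_csv(paths["mdl"], sep="\t", float_format=_FLOAT_FMT)

    summary = {
        "selected_K": int(result.selected_K),
        "fit_error": None if np.isnan(result.fit_error) else float(result.fit_error),
        "config": result.config,
        "seed": result.config.get("seed"),
        "n_markers": int(len(markers)),
    }
    paths["summary"] = outdir / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote %d result files to %s", len(paths), outdir)
    return paths


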