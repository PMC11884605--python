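"""Table IO, normalization and per-condition covariance estimation.

Pareto scaling — mean centering followed by division by the square root of
the sample standard deviation — is the standard compromise in metabolomics
between leaving high-abundance metabolites dominant (centering only) and
inflating pure-noise variables (unit variance). It is applied on the
multivariate-statistics branch of the pipeline; the Jacobian-inference
branch defaults to the raw concentration covariance, because the Lyapunov
relation links the *physical* fluctuation covariance to the physical
Jacobian. Both choices are exposed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .table import MetaboliteTable

__all__ = [
    "ScalingRecord",
    "CovarianceModel",
    "read_table",
    "pareto_scale",
    "scale_table",
    "condition_covariance",
    "SCALINGS",
]

SCALINGS = ("none", "center", "pareto", "unit-variance")


@dataclass
class ScalingRecord:
    """Provenance of a column-wise scaling: x -> (x - mean) / factor."""

    scaling: str
    metabolites: list[str]
    means: np.ndarray
    factors: np.ndarray
    constant_columns: list[str] = field(default_factory=list)

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values - self.means) / self.factors

    def to_json(self) -> str:
        return json.dumps(
            {
                "scaling": self.scaling,
                "metabolites": self.metabolites,
                "means": [float(x) for x in self.means],
                "factors": [float(x) for x in self.factors],
                "constant_columns": self.constant_columns,
            },
            indent=1,
        )


@dataclass
class CovarianceModel:
    """Per-condition covariance with its preprocessing provenance."""

    condition: str
    metabolites: list[str]
    cov: np.ndarray
    n_samples: int
    scaling: str
    source_hash: str = ""
    shrinkage_intensity: float = 0.0

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        n = len(self.metabolites)
        if self.cov.shape != (n, n):
            raise ValueError("covariance shape does not match metabolite count")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance not symmetric")
        if np.any(np.diag(self.cov) < -1e-12):
            raise ValueError("negative variance on the diagonal")

    def to_csv(self, path: str | Path, float_format: str = "%.10g") -> None:
        pd.DataFrame(self.cov, index=self.metabolites, columns=self.metabolites).to_csv(
            path, float_format=float_format
        )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_table(
    path: str | Path,
    missing: str = "NA",
    impute: str = "half-min",
) -> tuple[MetaboliteTable, dict]:
    """Read a CSV/TSV metabolite table; returns (table, imputation report).

    The file needs ``sample_id`` and ``condition`` columns; every other
    column is a metabolite. Missing cells (the ``missing`` token or empty)
    are imputed per metabolite: ``half-min`` replaces them with half the
    column minimum, the standard treatment for below-quantification values
    in targeted panels; ``error`` refuses missing data.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, na_values=[missing], keep_default_na=True)
    if "condition" not in df.columns:
        raise ValueError(f"{path.name}: no 'condition' column")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path.name}: no 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise ValueError(f"{path.name}: duplicate sample ids {dups}")
    met_cols = [c for c in df.columns if c not in ("sample_id", "condition")]
    report: dict = {"policy": impute, "imputed": {}}
    for c in met_cols:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any():
            raise ValueError(
                f"{path.name}: non-numeric cell(s) in column {c!r} "
                f"(rows {list(df.index[bad][:5])})"
            )
        n_missing = int(col.isna().sum())
        if n_missing:
            if impute == "error":
                raise ValueError(f"{path.name}: missing values in column {c!r}")
            if col.notna().sum() == 0:
                raise ValueError(f"{path.name}: column {c!r} is entirely missing")
            fill = 0.5 * float(col.min())
            col = col.fillna(fill)
            report["imputed"][c] = {"count": n_missing, "value": fill}
        df[c] = col
    table = MetaboliteTable.from_frame(df)
    return table, report


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------


def _scaling_factors(values: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    constant = sd <= 1e-300
    if scaling == "none":
        return np.zeros_like(means), np.ones_like(means), constant
    if scaling == "center":
        return means, np.ones_like(means), constant
    if scaling == "pareto":
        factors = np.where(constant, 1.0, np.sqrt(sd))
        return means, factors, constant
    if scaling == "unit-variance":
        factors = np.where(constant, 1.0, sd)
        return means, factors, constant
    raise ValueError(f"unknown scaling {scaling!r}; one of {SCALINGS}")


def scale_table(
    table: MetaboliteTable, scaling: str
) -> tuple[MetaboliteTable, ScalingRecord]:
    """Apply a column-wise scaling; constant columns are centered and flagged."""
    means, factors, constant = _scaling_factors(table.values, scaling)
    record = ScalingRecord(
        scaling=scaling,
        metabolites=list(table.metabolites),
        means=means,
        factors=factors,
        constant_columns=[m for m, c in zip(table.metabolites, constant) if c],
    )
    scaled = MetaboliteTable(
        sample_ids=list(table.sample_ids),
        conditions=list(table.conditions),
        metabolites=list(table.metabolites),
        values=record.apply(table.values),
    )
    return scaled, record


def pareto_scale(table: MetaboliteTable) -> tuple[MetaboliteTable, ScalingRecord]:
    """Mean-center and divide each column by sqrt(sample SD)."""
    return scale_table(table, "pareto")


# ---------------------------------------------------------------------------
# covariance
# ---------------------------------------------------------------------------


def _shrinkage_intensity(X: np.ndarray) -> float:
    """Schafer-Strimmer intensity for shrinking off-diagonals to zero.

    lambda* = sum Var(s_ij) / sum s_ij^2 over i != j, clipped to [0, 1];
    the usual analytic choice when replicates are scarcer than metabolites.
    """
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / (n - 1)
    W = np.einsum("ti,tj->tij", Xc, Xc)
    var_s = W.var(axis=0, ddof=1) * n / (n - 1) ** 2
    off = ~np.eye(p, dtype=bool)
    denom = float((S[off] ** 2).sum())
    if denom <= 0:
        return 0.0
    lam = float(var_s[off].sum()) / denom
    return float(np.clip(lam, 0.0, 1.0))


def condition_covariance(
    table: MetaboliteTable,
    condition: str,
    scaling: str = "none",
    shrinkage: str = "auto",
) -> CovarianceModel:
    """Sample covariance (n-1 denominator) of one condition's rows.

    ``shrinkage="auto"`` applies diagonal-target linear shrinkage with an
    analytically chosen intensity only when there are fewer samples than
    metabolites; ``"never"`` disables it.
    """
    sub = table.subset(condition)
    if sub.n_samples < 3:
        raise ValueError(
            f"condition {condition!r} has {sub.n_samples} samples; need >= 3"
        )
    scaled, record = scale_table(sub, scaling)
    X = scaled.values
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    lam = 0.0
    if shrinkage == "auto" and sub.n_samples < sub.n_metabolites:
        lam = _shrinkage_intensity(X)
        cov = (1 - lam) * cov + lam * np.diag(np.diag(cov))
    elif shrinkage not in ("auto", "never"):
        raise ValueError("shrinkage must be 'auto' or 'never'")
    cov = 0.5 * (cov + cov.T)
    return CovarianceModel(
        condition=condition,
        metabolites=list(table.metabolites),
        cov=cov,
        n_samples=sub.n_samples,
        scaling=scaling,
        source_hash=table.source_hash(),
        shrinkage_intensity=lam,
    )
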