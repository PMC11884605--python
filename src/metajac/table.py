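"""Replicate metabolite-abundance tables: the pipeline's tabular currency."""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MetaboliteTable"]


@dataclass
class MetaboliteTable:
    """Samples x metabolites abundance matrix with a condition label per sample.

    ``values`` holds nonnegative abundances in arbitrary units; row order is
    sample order, column order metabolite order (network species order when
    the table comes from the simulator).
    """

    sample_ids: list[str]
    conditions: list[str]
    metabolites: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        ns, nm = self.values.shape
        if len(self.sample_ids) != ns or len(self.conditions) != ns:
            raise ValueError("sample_ids/conditions length must match row count")
        if len(self.metabolites) != nm:
            raise ValueError("metabolites length must match column count")
        if len(set(self.sample_ids)) != ns:
            raise ValueError("duplicate sample ids")

    # -- accessors -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def condition_labels(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen

    def subset(self, condition: str) -> "MetaboliteTable":
        mask = [c == condition for c in self.conditions]
        if not any(mask):
            raise KeyError(f"no samples with condition {condition!r}")
        idx = np.flatnonzero(mask)
        return MetaboliteTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            conditions=[self.conditions[i] for i in idx],
            metabolites=list(self.metabolites),
            values=self.values[idx],
        )

    def check_invariants(self, min_per_condition: int = 3) -> None:
        """Raise if abundances are negative/non-finite or a condition is
        too small for covariance estimation."""
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite abundances")
        if np.any(self.values < 0):
            raise ValueError("negative abundances")
        for label in self.condition_labels():
            count = self.conditions.count(label)
            if count < min_per_condition:
                raise ValueError(
                    f"condition {label!r} has {count} samples; "
                    f"need >= {min_per_condition}"
                )

    # -- pandas / IO -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.metabolites)
        df.insert(0, "condition", self.conditions)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MetaboliteTable":
        if "condition" not in df.columns:
            raise ValueError("table must have a 'condition' column")
        if "sample_id" not in df.columns:
            df = df.copy()
            df.insert(0, "sample_id", [f"s{i}" for i in range(len(df))])
        mets = [c for c in df.columns if c not in ("sample_id", "condition")]
        return cls(
            sample_ids=[str(s) for s in df["sample_id"]],
            conditions=[str(c) for c in df["condition"]],
            metabolites=mets,
            values=df[mets].to_numpy(dtype=float),
        )

    def to_csv(self, path: str | Path | None = None, float_format: str = "%.10g"):
        df = self.to_frame()
        if path is None:
            buf = io.StringIO()
            df.to_csv(buf, index=False, float_format=float_format)
            return buf.getvalue()
        df.to_csv(path, index=False, float_format=float_format)
        return None

    def source_hash(self) -> str:
        """Stable content hash used for provenance in downstream records."""
        return hashlib.sha256(self.to_csv().encode()).hexdigest()[:16]
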