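"""Forward and inverse Lyapunov problems: the reconstruction core.

For a stable linear(ized) system dx = J x dt + noise, the stationary
covariance COV of the fluctuations satisfies the Lyapunov equation

    J COV + COV J^T = -2 FLU,

where FLU is the fluctuation (diffusion) matrix of the Gaussian noise.
The forward direction (J, FLU -> COV) is a standard Sylvester-type solve.
The inverse direction — reconstructing the biochemical Jacobian from the
replicate covariance of metabolomics data — is underdetermined in general
(n^2 unknowns, n(n+1)/2 equations), and is made solvable by restricting
the unknowns to the stoichiometry-derived sparsity pattern of the
metabolic network. Bootstrap resampling of replicates provides per-entry
standard errors, which feed a cross-condition differential analysis with
pathway-level aggregation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import solve_continuous_lyapunov

from .network import MetabolicNetwork, SparsityPattern, jacobian_sparsity
from .preprocess import CovarianceModel, condition_covariance
from .table import MetaboliteTable

__all__ = [
    "FluctuationSpec",
    "JacobianEstimate",
    "DifferentialJacobianReport",
    "StabilityError",
    "solve_forward",
    "solve_inverse",
    "bootstrap_jacobian",
    "differential_jacobian",
]


class StabilityError(ValueError):
    """The drift matrix is not Hurwitz; message lists offending eigenvalues."""


@dataclass(frozen=True)
class FluctuationSpec:
    """Diagonal fluctuation matrix FLU.

    ``identity`` is the default when nothing is known about the noise: all
    scale-dependent outputs are reported alongside the FLU used, and signs
    and rankings are invariant to a global FLU rescaling (FLU -> c FLU
    maps J -> c J).
    """

    mode: str = "identity"
    values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("identity", "diagonal"):
            raise ValueError("mode must be 'identity' or 'diagonal'")
        if self.mode == "diagonal":
            if not self.values:
                raise ValueError("diagonal mode needs values")
            if any(v < 0 for v in self.values) or not any(v > 0 for v in self.values):
                raise ValueError("diagonal values must be >= 0 with at least one > 0")

    @classmethod
    def identity(cls) -> "FluctuationSpec":
        return cls(mode="identity")

    @classmethod
    def diagonal(cls, values: Sequence[float]) -> "FluctuationSpec":
        return cls(mode="diagonal", values=tuple(float(v) for v in values))

    @classmethod
    def from_noise_sd(cls, noise_sd: float, n: int) -> "FluctuationSpec":
        """FLU matching the simulator's Langevin convention.

        For dx = J x dt + noise_sd dW the stationary covariance solves
        J C + C J^T = -noise_sd^2 I, so FLU = diag(noise_sd^2 / 2) — pinned
        by the scalar Ornstein-Uhlenbeck closed form sigma^2 / (2 k).
        """
        return cls.diagonal([noise_sd**2 / 2.0] * n)

    def matrix(self, n: int) -> np.ndarray:
        if self.mode == "identity":
            return np.eye(n)
        if len(self.values) != n:
            raise ValueError(f"FLU has {len(self.values)} values for n = {n}")
        return np.diag(np.asarray(self.values, dtype=float))


@dataclass
class JacobianEstimate:
    """Jacobian entries on a sparsity pattern, with fit diagnostics."""

    pattern: SparsityPattern
    entries: list[tuple[int, int]]  # sorted pattern entries, fixing value order
    values: np.ndarray
    residual_norm: float
    rank_deficient: bool
    condition: str = ""
    metabolites: list[str] = field(default_factory=list)
    bootstrap_se: np.ndarray | None = None

    @property
    def n_equations(self) -> int:
        return self.pattern.n * (self.pattern.n + 1) // 2

    @property
    def n_unknowns(self) -> int:
        return self.pattern.n_entries

    def matrix(self) -> np.ndarray:
        J = np.zeros((self.pattern.n, self.pattern.n))
        for (i, j), v in zip(self.entries, self.values):
            J[i, j] = v
        return J

    def is_stable(self) -> bool:
        """Diagnostic only: instability is reported, never corrected."""
        return bool(np.all(np.linalg.eigvals(self.matrix()).real < 0))

    def to_tsv(self, path: str | Path) -> None:
        ids = self.metabolites or [str(i) for i in range(self.pattern.n)]
        lines = ["row_id\tcol_id\tvalue\tse\tcondition"]
        se = self.bootstrap_se if self.bootstrap_se is not None else [np.nan] * len(self.values)
        for (i, j), v, s in zip(self.entries, self.values, se):
            lines.append(f"{ids[i]}\t{ids[j]}\t{v:.10g}\t{s:.10g}\t{self.condition}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# forward problem
# ---------------------------------------------------------------------------


def solve_forward(J: np.ndarray, flu: FluctuationSpec) -> np.ndarray:
    """Unique symmetric PSD solution COV of J COV + COV J^T = -2 FLU.

    Requires J to be Hurwitz (all eigenvalues in the open left half
    plane); otherwise the stationary covariance does not exist and a
    StabilityError lists the offending eigenvalues.
    """
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("J must be square")
    n = J.shape[0]
    eigs = np.linalg.eigvals(J)
    bad = eigs[eigs.real >= 0]
    if bad.size:
        raise StabilityError(
            f"J is not stable; eigenvalues with nonnegative real part: {bad}"
        )
    F = flu.matrix(n)
    C = solve_continuous_lyapunov(J, -2.0 * F)
    C = 0.5 * (C + C.T)
    resid = np.linalg.norm(J @ C + C @ J.T + 2.0 * F)
    if resid > 1e-10 * max(1.0, np.linalg.norm(F)):
        raise RuntimeError(f"Lyapunov solve residual too large: {resid:.3e}")
    return C


# ---------------------------------------------------------------------------
# inverse problem
# ---------------------------------------------------------------------------


def build_inverse_system(
    cov: np.ndarray, flu_mat: np.ndarray, entries: list[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Linear system A x = b over the free Jacobian entries.

    One equation per unordered index pair (i <= j):
        sum_k COV[k, j] J[i, k] + sum_k COV[k, i] J[j, k] = -2 FLU[i, j].
    Enumerating unordered pairs gives exactly n(n+1)/2 rows, which resolves
    the symmetric redundancy of the matrix equation.
    """
    n = cov.shape[0]
    col = {e: a for a, e in enumerate(entries)}
    rows = []
    b = []
    A = np.zeros((n * (n + 1) // 2, len(entries)))
    r = 0
    bvec = np.zeros(n * (n + 1) // 2)
    for i in range(n):
        for j in range(i, n):
            for k in range(n):
                a = col.get((i, k))
                if a is not None:
                    A[r, a] += cov[k, j]
                a = col.get((j, k))
                if a is not None:
                    A[r, a] += cov[k, i]
            bvec[r] = -2.0 * flu_mat[i, j]
            r += 1
    return A, bvec


def solve_inverse(
    cov: CovarianceModel | np.ndarray,
    flu: FluctuationSpec,
    pattern: SparsityPattern,
    ridge: float = 0.0,
    strict: bool = False,
    condition: str = "",
    metabolites: Sequence[str] | None = None,
) -> JacobianEstimate:
    """Reconstruct the Jacobian from a replicate covariance matrix.

    Least squares over the pattern's free entries; ``ridge > 0`` adds
    Tikhonov regularization, ``ridge = 0`` returns the minimum-norm
    solution when the system is rank deficient (or raises, when
    ``strict``). The estimate is *not* forced stable — instability of the
    reconstruction is a diagnostic worth seeing, not a defect to hide.
    """
    if isinstance(cov, CovarianceModel):
        condition = condition or cov.condition
        metabolites = metabolites or cov.metabolites
        cov = cov.cov
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    if cov.shape != (n, n):
        raise ValueError("covariance must be square")
    if pattern.n != n:
        raise ValueError(f"pattern is over n = {pattern.n}, covariance n = {n}")
    if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, np.abs(cov).max())):
        raise ValueError("covariance not symmetric")
    F = flu.matrix(n)
    entries = pattern.sorted_entries()
    A, b = build_inverse_system(cov, F, entries)

    rank = int(np.linalg.matrix_rank(A)) if A.size else 0
    rank_deficient = rank < len(entries)
    if len(entries) > A.shape[0]:
        rank_deficient = True
    if rank_deficient and strict and ridge == 0.0:
        raise np.linalg.LinAlgError(
            f"inverse system rank deficient (rank {rank} < {len(entries)} unknowns) "
            "and strict mode requested with ridge = 0"
        )
    if ridge > 0.0:
        x = np.linalg.solve(A.T @ A + ridge * np.eye(len(entries)), A.T @ b)
    elif len(entries) == 0:
        x = np.zeros(0)
    else:
        x, *_ = np.linalg.lstsq(A, b, rcond=None)

    J = np.zeros((n, n))
    for (i, j), v in zip(entries, x):
        J[i, j] = v
    residual = float(np.linalg.norm(J @ cov + cov @ J.T + 2.0 * F))
    return JacobianEstimate(
        pattern=pattern,
        entries=entries,
        values=x,
        residual_norm=residual,
        rank_deficient=rank_deficient,
        condition=condition,
        metabolites=list(metabolites) if metabolites else [],
    )


# ---------------------------------------------------------------------------
# bootstrap and differential analysis
# ---------------------------------------------------------------------------


def bootstrap_jacobian(
    table: MetaboliteTable,
    condition: str,
    net: MetabolicNetwork,
    flu: FluctuationSpec,
    B: int = 200,
    seed: int | np.random.Generator = 0,
    ridge: float = 0.0,
    scaling: str = "none",
    max_retries: int = 100,
) -> JacobianEstimate:
    """Point estimate from the full data plus bootstrap standard errors.

    Resamples the condition's replicates with replacement B times;
    degenerate resamples (a metabolite with zero variance) are redrawn up
    to a retry cap. Reproducible given the seed.
    """
    if B < 50:
        raise ValueError("need B >= 50 bootstrap resamples")
    sub = table.subset(condition)
    if sub.n_samples < 4:
        raise ValueError(f"condition {condition!r}: need >= 4 samples to bootstrap")
    pattern = jacobian_sparsity(net)
    cov_model = condition_covariance(table, condition, scaling=scaling)
    est = solve_inverse(cov_model, flu, pattern, ridge=ridge)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = sub.n_samples
    boot_vals = np.empty((B, len(est.entries)))
    for b in range(B):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            X = sub.values[idx]
            var = X.var(axis=0, ddof=1)
            if np.all(var > 1e-300):
                break
        else:
            raise RuntimeError(
                f"condition {condition!r}: degenerate covariance in every one of "
                f"{max_retries} bootstrap redraws"
            )
        if scaling != "none":
            from .preprocess import _scaling_factors

            means, factors, _ = _scaling_factors(X, scaling)
            X = (X - means) / factors
        cov_b = np.cov(X, rowvar=False, ddof=1)
        boot_vals[b] = solve_inverse(np.atleast_2d(cov_b), flu, pattern).values
    est.bootstrap_se = boot_vals.std(axis=0, ddof=1)
    return est


@dataclass
class DifferentialJacobianReport:
    """Entry-wise Jacobian contrast between two conditions.

    z scores use pooled bootstrap SEs with a Gaussian reference; no
    multiple-testing correction is applied across entries — the unit of
    inference is the pathway aggregate (mean |z| over entries whose row
    species carries the pathway tag).
    """

    entries: list[tuple[int, int]]
    entry_ids: list[tuple[str, str]]
    delta: np.ndarray
    z: np.ndarray
    pathway_scores: dict[str, float]
    ranking: list[tuple[str, str]]
    condition_a: str = ""
    condition_b: str = ""

    def top_entry(self) -> tuple[str, str]:
        return self.ranking[0]

    def to_dict(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "entries": [
                {
                    "row": ri,
                    "col": ci,
                    "delta": float(d),
                    "z": float(z),
                }
                for (ri, ci), d, z in zip(self.entry_ids, self.delta, self.z)
            ],
            "pathway_scores": {k: float(v) for k, v in self.pathway_scores.items()},
            "ranking": [list(e) for e in self.ranking],
            "notes": [
                "z = (value_b - value_a) / sqrt(se_a^2 + se_b^2), Gaussian reference",
                "no per-entry multiple-testing correction; inference unit is the pathway score",
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        lines = ["row_id\tcol_id\tdelta\tz"]
        for (ri, ci), d, z in zip(self.entry_ids, self.delta, self.z):
            lines.append(f"{ri}\t{ci}\t{d:.10g}\t{z:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")


def differential_jacobian(
    est_a: JacobianEstimate,
    est_b: JacobianEstimate,
    net: MetabolicNetwork,
) -> DifferentialJacobianReport:
    """Compare two bootstrapped Jacobian estimates entry by entry.

    delta = value_b - value_a; z = delta / pooled SE; pathway score =
    mean |z| over entries whose *row* species carries the tag (the row is
    the species whose balance the entry perturbs). Ranking is by |z|
    descending with lexicographic (row id, col id) tie-break.
    """
    if est_a.pattern.entries != est_b.pattern.entries:
        raise ValueError("estimates have different sparsity patterns")
    if est_a.metabolites != est_b.metabolites:
        raise ValueError("estimates have different metabolite order")
    if est_a.bootstrap_se is None or est_b.bootstrap_se is None:
        raise ValueError("both estimates need bootstrap_se (run bootstrap_jacobian)")
    ids = est_a.metabolites or [str(i) for i in range(est_a.pattern.n)]
    entries = est_a.entries
    delta = est_b.values - est_a.values
    pooled = np.sqrt(est_a.bootstrap_se**2 + est_b.bootstrap_se**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(pooled > 0, delta / pooled, np.where(delta == 0, 0.0, np.inf))
    entry_ids = [(ids[i], ids[j]) for i, j in entries]

    tags = net.pathway_tags()
    scores: dict[str, list[float]] = {}
    for (i, j), zv in zip(entries, np.abs(z)):
        tag = tags.get(ids[i], "")
        if tag:
            scores.setdefault(tag, []).append(float(zv))
    pathway_scores = {t: float(np.mean(v)) for t, v in scores.items()}

    order = sorted(
        range(len(entries)),
        key=lambda a: (-abs(z[a]), entry_ids[a][0], entry_ids[a][1]),
    )
    ranking = [entry_ids[a] for a in order]
    return DifferentialJacobianReport(
        entries=list(entries),
        entry_ids=entry_ids,
        delta=delta,
        z=z,
        pathway_scores=pathway_scores,
        ranking=ranking,
        condition_a=est_a.condition,
        condition_b=est_b.condition,
    )
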