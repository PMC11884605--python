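"""Targeted-metabolomics multivariate statistics.

PCA for overview, OPLS-DA (one predictive component after iterative
removal of class-orthogonal variation) for discrimination, VIP scores for
variable importance, a 200-permutation overfitting check, and the
screening rule: a metabolite is differential when VIP > 1 and p < 0.05
(two-tailed t test for two groups, one-way ANOVA for more). Fold change
is the log (base 2 by default) of the group mean ratio. A Cohen's d
helper supports power-analysis bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from .preprocess import ScalingRecord, scale_table
from .table import MetaboliteTable

__all__ = [
    "PcaResult",
    "OplsModel",
    "PermutationRecord",
    "MetaboliteScreenResult",
    "fit_pca",
    "fit_oplsda",
    "vip_scores",
    "permutation_validity",
    "screen_metabolites",
    "cohens_d",
]


def cohens_d(mean_diff: float, sd: float) -> float:
    """Standardized effect size d = mean difference / standard deviation."""
    if not sd > 0:
        raise ValueError("sd must be positive")
    return mean_diff / sd


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray  # (p, k)
    r2x: np.ndarray  # explained-variance fraction per component
    metabolites: list[str]

    @property
    def r2x_cum(self) -> np.ndarray:
        return np.cumsum(self.r2x)


def fit_pca(
    table: MetaboliteTable, n_components: int, scaling: str = "pareto"
) -> PcaResult:
    """Principal components of the scaled table, ordered by explained variance."""
    scaled, _ = scale_table(table, scaling)
    X = scaled.values
    limit = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= limit:
        raise ValueError(f"n_components must be in [1, {limit}]")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PcaResult(
        scores=scores,
        loadings=pca.components_.T,
        r2x=pca.explained_variance_ratio_,
        metabolites=list(table.metabolites),
    )


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


@dataclass
class OplsModel:
    """Fitted OPLS-DA model with one predictive component.

    Weights/loadings follow the usual NIPALS conventions; orthogonal
    components (class-uncorrelated variation) are stored separately from
    the single predictive component. Q2 comes from seeded stratified
    cross-validation.
    """

    classes: tuple[str, str]
    metabolites: list[str]
    scaling_record: ScalingRecord
    y_mean: float
    # predictive component
    weights: np.ndarray  # (p,)
    loadings: np.ndarray  # (p,)
    scores: np.ndarray  # (n,)
    q: float  # y loading
    # orthogonal components
    ortho_weights: np.ndarray  # (p, k)
    ortho_loadings: np.ndarray  # (p, k)
    ortho_scores: np.ndarray  # (n, k)
    r2x_cum: float
    r2y_cum: float
    q2_cum: float
    cv_folds: int
    seed: int
    vip: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.vip is None:
            self.vip = vip_scores(self)

    @property
    def n_ortho(self) -> int:
        return self.ortho_weights.shape[1]

    def _transform(self, X: np.ndarray) -> np.ndarray:
        """Scale new raw data and strip its orthogonal variation."""
        Xs = self.scaling_record.apply(X)
        for a in range(self.n_ortho):
            w_o = self.ortho_weights[:, a]
            p_o = self.ortho_loadings[:, a]
            t_o = Xs @ w_o
            Xs = Xs - np.outer(t_o, p_o)
        return Xs

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        t = self._transform(np.asarray(X, float)) @ self.weights
        return t * self.q + self.y_mean

    def predict(self, X: np.ndarray) -> list[str]:
        yhat = self.decision_function(X)
        return [self.classes[1] if v >= 0.5 else self.classes[0] for v in yhat]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "classes": list(self.classes),
                    "n_ortho": self.n_ortho,
                    "cv_folds": self.cv_folds,
                    "R2X_cum": float(self.r2x_cum),
                    "R2Y_cum": float(self.r2y_cum),
                    "Q2_cum": float(self.q2_cum),
                    "vip": {m: float(v) for m, v in zip(self.metabolites, self.vip)},
                },
                indent=1,
            )
            + "\n"
        )


def _opls_core(
    X: np.ndarray, y: np.ndarray, n_ortho: int
) -> dict:
    """NIPALS-style OPLS on centered X, centered y: returns all blocks."""
    X0 = X.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_ortho):
        w = X.T @ y / (y @ y)
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = X @ w
        p = X.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:  # no orthogonal variation left
            break
        w_o /= n_o
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X = X - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    w = X.T @ y / (y @ y)
    w /= np.linalg.norm(w)
    t = X @ w
    p = X.T @ t / (t @ t)
    q = (y @ t) / (t @ t)
    p_feat = X.shape[1]
    stack = lambda lst: (
        np.column_stack(lst) if lst else np.zeros((p_feat, 0))
    )
    ss_x0 = float((X0**2).sum())
    modeled = float((np.outer(t, p) ** 2).sum()) + sum(
        float((np.outer(tt, pp) ** 2).sum()) for tt, pp in zip(T_o, P_o)
    )
    return {
        "w": w,
        "t": t,
        "p": p,
        "q": q,
        "W_o": stack(W_o),
        "P_o": stack(P_o),
        "T_o": stack(T_o).reshape(X.shape[0], -1),
        "r2x": modeled / ss_x0 if ss_x0 > 0 else 0.0,
    }


def _predict_core(core: dict, X: np.ndarray) -> np.ndarray:
    for a in range(core["W_o"].shape[1]):
        t_o = X @ core["W_o"][:, a]
        X = X - np.outer(t_o, core["P_o"][:, a])
    return (X @ core["w"]) * core["q"]


def fit_oplsda(
    table: MetaboliteTable,
    classes: tuple[str, str] | None = None,
    n_ortho: int = 1,
    cv_folds: int = 7,
    seed: int = 0,
    scaling: str = "pareto",
) -> OplsModel:
    """Fit a two-class OPLS-DA model on the (Pareto-scaled) table.

    The response is the dummy-coded class label; ``n_ortho`` orthogonal
    components are removed before the single predictive component. R2Y is
    the explained fraction of the response, Q2 its cross-validated
    counterpart from seeded stratified folds (folds are reduced with a
    warning when a class is smaller than ``cv_folds``).
    """
    labels = table.conditions
    if classes is None:
        uniq = table.condition_labels()
        if len(uniq) != 2:
            raise ValueError(f"need exactly two classes, table has {uniq}")
        classes = (uniq[0], uniq[1])
    keep = [i for i, c in enumerate(labels) if c in classes]
    if len(keep) < len(labels):
        table = MetaboliteTable(
            sample_ids=[table.sample_ids[i] for i in keep],
            conditions=[table.conditions[i] for i in keep],
            metabolites=list(table.metabolites),
            values=table.values[keep],
        )
        labels = table.conditions
    counts = {c: labels.count(c) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"each class needs >= 2 samples, got {counts}")
    folds = cv_folds
    if min(counts.values()) < cv_folds:
        folds = max(2, min(counts.values()))
        warnings.warn(
            f"reducing cv_folds from {cv_folds} to {folds}: smallest class has "
            f"{min(counts.values())} samples",
            stacklevel=2,
        )

    scaled, record = scale_table(table, scaling)
    X = scaled.values
    y_raw = np.array([1.0 if c == classes[1] else 0.0 for c in labels])
    y_mean = float(y_raw.mean())
    y = y_raw - y_mean

    core = _opls_core(X, y, n_ortho)
    ss_y = float((y**2).sum())
    r2y = 1.0 - float(((y - core["t"] * core["q"]) ** 2).sum()) / ss_y

    # cross-validated Q2: rescale inside each training fold
    press = 0.0
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    raw = table.values
    for train, test in skf.split(raw, y_raw):
        sub = MetaboliteTable(
            sample_ids=[table.sample_ids[i] for i in train],
            conditions=[table.conditions[i] for i in train],
            metabolites=list(table.metabolites),
            values=raw[train],
        )
        tr_scaled, tr_record = scale_table(sub, scaling)
        ytr = y_raw[train] - y_raw[train].mean()
        core_tr = _opls_core(tr_scaled.values, ytr, n_ortho)
        Xte = tr_record.apply(raw[test])
        yhat = _predict_core(core_tr, Xte) + y_raw[train].mean()
        press += float(((y_raw[test] - yhat) ** 2).sum())
    q2 = 1.0 - press / ss_y

    return OplsModel(
        classes=classes,
        metabolites=list(table.metabolites),
        scaling_record=record,
        y_mean=y_mean,
        weights=core["w"],
        loadings=core["p"],
        scores=core["t"],
        q=float(core["q"]),
        ortho_weights=core["W_o"],
        ortho_loadings=core["P_o"],
        ortho_scores=core["T_o"],
        r2x_cum=float(core["r2x"]),
        r2y_cum=float(r2y),
        q2_cum=float(q2),
        cv_folds=folds,
        seed=seed,
    )


def vip_scores(model: OplsModel) -> np.ndarray:
    """Variable importance in projection from the predictive component.

    VIP_j = sqrt(p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a) over the
    predictive component(s); with a single component this reduces to
    sqrt(p) |w_j| / ||w||, and mean(VIP^2) = 1 exactly. Orthogonal
    components carry no class information and are excluded by design.
    """
    w = model.weights
    p = w.size
    frac = (w / np.linalg.norm(w)) ** 2
    return np.sqrt(p * frac)


# ---------------------------------------------------------------------------
# permutation validation
# ---------------------------------------------------------------------------


@dataclass
class PermutationRecord:
    """Outcome of the label-permutation overfitting test.

    For each of n_perm permutations the model is refit and (R2Y, Q2)
    recorded against the absolute correlation between permuted and true
    labels. Straight lines through those points (anchored by the real
    model at correlation 1) are evaluated at correlation 0. The model is
    flagged valid when both intercepts fall below the unpermuted R2Y and
    Q2 *and* the permutation test on Q2 rejects at alpha = 0.05: the
    intercept comparison alone cannot reject an uninformative model,
    because its unpermuted fit is exchangeable with the permuted ones.
    """

    n_perm: int
    r2y_perm: np.ndarray
    q2_perm: np.ndarray
    label_correlation: np.ndarray
    r2y_intercept: float
    q2_intercept: float
    r2y_model: float
    q2_model: float

    @property
    def valid(self) -> bool:
        return bool(
            self.r2y_intercept < self.r2y_model
            and self.q2_intercept < self.q2_model
            and self.p_value() < 0.05
        )

    def p_value(self) -> float:
        """Permutation p for Q2: (#{permuted Q2 >= model Q2} + 1)/(n_perm + 1)."""
        return float((np.sum(self.q2_perm >= self.q2_model) + 1) / (self.n_perm + 1))


def permutation_validity(
    table: MetaboliteTable,
    classes: tuple[str, str],
    model: OplsModel,
    n_perm: int = 200,
    seed: int = 0,
) -> PermutationRecord:
    """Refit the model n_perm times with permuted class labels."""
    labels = np.array(table.conditions)
    keep = np.flatnonzero(np.isin(labels, classes))
    sub = MetaboliteTable(
        sample_ids=[table.sample_ids[i] for i in keep],
        conditions=[table.conditions[i] for i in keep],
        metabolites=list(table.metabolites),
        values=table.values[keep],
    )
    y_true = np.array([1.0 if c == classes[1] else 0.0 for c in sub.conditions])
    rng = np.random.default_rng(seed)
    r2y_perm = np.empty(n_perm)
    q2_perm = np.empty(n_perm)
    corr = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(y_true))
        perm_labels = [sub.conditions[i] for i in perm]
        ptab = MetaboliteTable(
            sample_ids=list(sub.sample_ids),
            conditions=perm_labels,
            metabolites=list(sub.metabolites),
            values=sub.values,
        )
        m = fit_oplsda(
            ptab,
            classes=classes,
            n_ortho=model.n_ortho,
            cv_folds=model.cv_folds,
            seed=model.seed,
        )
        r2y_perm[b] = m.r2y_cum
        q2_perm[b] = m.q2_cum
        y_perm = y_true[perm]
        if y_true.std() == 0 or y_perm.std() == 0:
            corr[b] = 0.0
        else:
            corr[b] = abs(float(np.corrcoef(y_true, y_perm)[0, 1]))

    def intercept(values: np.ndarray, anchor: float) -> float:
        x = np.append(corr, 1.0)
        v = np.append(values, anchor)
        slope, icept = np.polyfit(x, v, 1)
        return float(icept)

    return PermutationRecord(
        n_perm=n_perm,
        r2y_perm=r2y_perm,
        q2_perm=q2_perm,
        label_correlation=corr,
        r2y_intercept=intercept(r2y_perm, model.r2y_cum),
        q2_intercept=intercept(q2_perm, model.q2_cum),
        r2y_model=model.r2y_cum,
        q2_model=model.q2_cum,
    )


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


@dataclass
class MetaboliteScreenResult:
    """Per-metabolite VIP, p value, fold change and the selection flag.

    selected <=> (VIP > 1.0 and p < 0.05). No multiple-testing correction
    by default (set ``fdr=True`` in ``screen_metabolites`` for a
    Benjamini-Hochberg adjusted column).
    """

    table: pd.DataFrame  # columns: metabolite, vip, p_value, fold_change, selected

    def selected(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "metabolite"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adj, 0, 1)
    return out


def screen_metabolites(
    table: MetaboliteTable,
    groups: Sequence[str],
    vip: np.ndarray | OplsModel,
    fc_base: float = 2.0,
    fdr: bool = False,
) -> MetaboliteScreenResult:
    """Differential-metabolite screen on the raw (unscaled) table.

    Two groups: two-tailed two-sample t test and fold change
    log_base(mean_b / mean_a); more groups: one-way ANOVA (fold change then
    contrasts the last group against the first). A zero group mean is
    replaced by half the smallest positive value in the table, flagged in
    the output.
    """
    if isinstance(vip, OplsModel):
        vip = vip.vip
    vip = np.asarray(vip, float)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if vip.size != table.n_metabolites:
        raise ValueError("vip length must equal metabolite count")
    subs = [table.subset(g) for g in groups]
    for g, s in zip(groups, subs):
        if s.n_samples < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    pvals = np.empty(table.n_metabolites)
    fc = np.empty(table.n_metabolites)
    eps_flag = []
    positive = table.values[table.values > 0]
    eps = 0.5 * float(positive.min()) if positive.size else 1e-12
    for j in range(table.n_metabolites):
        cols = [s.values[:, j] for s in subs]
        if len(groups) == 2:
            pvals[j] = sps.ttest_ind(cols[0], cols[1], equal_var=True).pvalue
        else:
            pvals[j] = sps.f_oneway(*cols).pvalue
        mean_a, mean_b = float(cols[0].mean()), float(cols[-1].mean())
        flagged = False
        if mean_a <= 0:
            mean_a, flagged = eps, True
        if mean_b <= 0:
            mean_b, flagged = eps, True
        fc[j] = np.log(mean_b / mean_a) / np.log(fc_base)
        eps_flag.append(flagged)

    selected = (vip > 1.0) & (pvals < 0.05)
    df = pd.DataFrame(
        {
            "metabolite": table.metabolites,
            "vip": vip,
            "p_value": pvals,
            "fold_change": fc,
            "selected": selected,
            "fc_epsilon_adjusted": eps_flag,
        }
    )
    if fdr:
        df["p_adj"] = _bh_adjust(pvals)
    return MetaboliteScreenResult(table=df)
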