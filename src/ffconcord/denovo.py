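"""De-novo ER/HER2 gene-module derivation and ROC validation.

Differentially expressed genes between marker-positive and
marker-negative samples are found per dataset with a fold-change plus
Welch's t-test screen on log2 expression: a gene enters the module when
``|linear fold change| > fc_threshold`` (default 2, i.e. |log2FC| > 1)
and the two-sided Welch p-value is below ``p_threshold`` (default 0.05,
uncorrected by design — the screen deliberately follows the classic
fold-change + raw-p selection style).  The gene's weight is the sign of
its log2 fold change (up in the marker-positive group -> +1).

Validation scores the module on an independent cohort and measures the
area under the ROC curve; paired AUCs of two modules on the same cohort
are compared with DeLong's test for correlated ROC curves.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix, PhenotypeTable
from .modules import GeneModule, module_score


class DenovoError(ValueError):
    """Raised when no gene passes the selection thresholds."""


# ---------------------------------------------------------------------------
# Welch's t-test
# ---------------------------------------------------------------------------


def welch_t(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns ``(t, df, p)`` two-sided.

    Degenerate case: both groups constant with equal means gives
    ``t = 0, p = 1`` (df falls back to ``n_a + n_b - 2``).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float("inf") * np.sign(a.mean() - b.mean()), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def differential_expression(
    expr: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Per-gene Welch t and log2 fold change, positive minus negative group.

    ``expr`` is gene x sample log2; ``labels`` maps sample -> 'pos'/'neg'.
    The fold change is the difference of group means in log2 space (the
    ratio of geometric means on the linear scale).
    """
    labels = labels.reindex(expr.columns)
    pos = expr.loc[:, (labels == "pos").to_numpy()]
    neg = expr.loc[:, (labels == "neg").to_numpy()]
    if pos.shape[1] < 2 or neg.shape[1] < 2:
        raise ValueError("need >= 2 samples per status group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(pos.to_numpy(), neg.to_numpy(), axis=1, equal_var=False)
    log2fc = pos.mean(axis=1) - neg.mean(axis=1)
    t = pd.Series(res.statistic, index=expr.index)
    p = pd.Series(res.pvalue, index=expr.index)
    df = pd.Series(res.df, index=expr.index)
    degenerate = t.isna() & (log2fc == 0)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    return pd.DataFrame({"log2fc": log2fc, "t": t, "df": df, "p": p})


def derive_denovo_module(
    e: ExpressionMatrix,
    pheno: PhenotypeTable,
    marker: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    gene_universe: set[str] | None = None,
    module_id: str | None = None,
) -> tuple[GeneModule, pd.DataFrame]:
    """Derive a de-novo marker module from one dataset.

    ``gene_universe`` restricts the tested genes (e.g. to a PVAC-selected
    set); ``None`` uses all genes of the dataset.  Returns the module and
    the full differential-expression table with a ``passes`` flag:
    ``passes = (|log2fc| > log2(fc_threshold)) & (p < p_threshold)``.
    Raises :class:`DenovoError` when no gene passes.
    """
    expr = e.values
    if gene_universe is not None:
        expr = expr.loc[expr.index.intersection(gene_universe)]
    labels = pheno.status(marker).reindex(expr.columns)
    table = differential_expression(expr, labels)
    table["passes"] = (table["log2fc"].abs() > np.log2(fc_threshold)) & (
        table["p"] < p_threshold
    )
    chosen = table.index[table["passes"]]
    if len(chosen) == 0:
        raise DenovoError(
            f"no genes pass |FC| > {fc_threshold} and p < {p_threshold} for {marker}"
        )
    genes = [(g, 1 if table.loc[g, "log2fc"] > 0 else -1) for g in chosen]
    mod = GeneModule(
        module_id=module_id or f"denovo_{marker}",
        genes=genes,
        description=f"de-novo {marker} module",
        provenance="denovo",
    )
    return mod, table


def module_overlap(mod_a: GeneModule, mod_b: GeneModule) -> tuple[int, float, float]:
    """Shared gene count and percentage of each module's size."""
    a = set(mod_a.gene_symbols)
    b = set(mod_b.gene_symbols)
    shared = len(a & b)
    return shared, 100.0 * shared / len(a), 100.0 * shared / len(b)


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the pairwise-comparison probability (ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Empirical ROC curve points (fpr, tpr, threshold)."""
    fpr, tpr, thr = roc_curve(np.asarray(labels), np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and structural components V10 (positives), V01 (negatives)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    # psi(x, y) = 1 if x > y, 0.5 if tied, 0 otherwise
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(psi.mean()), v10, v01


def delong_test(
    scores1: np.ndarray, scores2: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """DeLong's test for two correlated ROC curves on the same samples.

    Returns ``(auc1, auc2, p)`` with a two-sided p-value from the
    asymptotic normal distribution of the paired AUC difference using the
    structural-components covariance estimator.  A degenerate variance
    (e.g. both scores order the classes identically and perfectly) yields
    p = 1 with a warning.
    """
    y = np.asarray(labels).astype(bool)
    if y.all() or (~y).all():
        raise ValueError("DeLong test needs both classes present")
    a1, v10_1, v01_1 = _delong_components(scores1, y)
    a2, v10_2, v01_2 = _delong_components(scores2, y)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.stack([v01_1, v01_2]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        warnings.warn("degenerate DeLong variance; p set to 1")
        return a1, a2, 1.0
    z = (a1 - a2) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return a1, a2, p


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------


class DenovoModuleClassifier(ClassifierMixin, BaseEstimator):
    """Fold-change + Welch-t signature learner in estimator form.

    ``fit(X, y)`` takes a samples x genes DataFrame of log2 expression
    (columns are gene symbols) and binary labels, derives the weighted
    module, and stores it as ``module_``; ``decision_function`` returns
    the module score per sample and ``predict`` thresholds it at the
    midpoint of the training class-mean scores.

    Parameters
    ----------
    fc_threshold : float
        Minimal absolute *linear* fold change (default 2).
    p_threshold : float
        Maximal Welch p-value (default 0.05, uncorrected).
    """

    def __init__(self, fc_threshold: float = 2.0, p_threshold: float = 0.05):
        self.fc_threshold = fc_threshold
        self.p_threshold = p_threshold

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x genes DataFrame with gene columns")
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("need exactly two classes")
        self.classes_ = classes
        labels = pd.Series(np.where(y == classes[1], "pos", "neg"), index=X.index)
        table = differential_expression(X.T, labels)
        table["passes"] = (table["log2fc"].abs() > np.log2(self.fc_threshold)) & (
            table["p"] < self.p_threshold
        )
        chosen = table.index[table["passes"]]
        if len(chosen) == 0:
            raise DenovoError("no genes pass the fold-change/p-value screen")
        self.de_table_ = table
        self.module_ = GeneModule(
            module_id="denovo",
            genes=[(g, 1 if table.loc[g, "log2fc"] > 0 else -1) for g in chosen],
            provenance="denovo",
        )
        self.n_features_in_ = X.shape[1]
        train_scores = self.decision_function(X)
        self.threshold_ = float(
            (train_scores[y == classes[1]].mean() + train_scores[y == classes[0]].mean())
            / 2.0
        )
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self)
        return module_score(X.T, self.module_).to_numpy()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self)
        s = self.decision_function(X)
        return np.where(s > self.threshold_, self.classes_[1], self.classes_[0])
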