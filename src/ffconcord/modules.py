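"""Weighted gene modules and module-score statistics.

A gene module is a set of genes with +/-1 weights giving the direction of
each gene's association with the biological signal the module interrogates
(pathway activity, mutation status, ...).  The primary score used here is
the *difference of class means*:

    score(sample) = mean(log2 expr of +1 genes) - mean(log2 expr of -1 genes)

so a positive score directly states that positively associated genes are,
on average, higher expressed than negatively associated ones — an
interpretation the classic weighted average only supports when the two
weight classes are equally large.  Scores are computed on log2 expression
and all log2 values are expected to be positive (linear expression > 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ModuleError(ValueError):
    """Raised when a module cannot be scored on a dataset."""


@dataclass(frozen=True)
class GeneModule:
    """A weighted (+/-1) gene set.

    Attributes
    ----------
    module_id : str
    genes : list of (gene_symbol, weight)
        Weights are +1 or -1; genes are unique within the module.
    description : str
    provenance : str
        One of ``external_set1``, ``external_set2``, ``control``,
        ``denovo``, ``subset`` — bookkeeping only.
    """

    module_id: str
    genes: tuple[tuple[str, int], ...]
    description: str = ""
    provenance: str = "external_set1"

    def __init__(
        self,
        module_id: str,
        genes,
        description: str = "",
        provenance: str = "external_set1",
    ) -> None:
        genes = tuple((str(g), int(w)) for g, w in genes)
        symbols = [g for g, _ in genes]
        if len(set(symbols)) != len(symbols):
            raise ModuleError(f"module {module_id!r}: duplicate genes")
        if any(w not in (1, -1) for _, w in genes):
            raise ModuleError(f"module {module_id!r}: weights must be +1/-1")
        if not genes:
            raise ModuleError(f"module {module_id!r}: empty module")
        object.__setattr__(self, "module_id", module_id)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "description", description)
        object.__setattr__(self, "provenance", provenance)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_symbols(self) -> list[str]:
        return [g for g, _ in self.genes]

    def weights(self) -> pd.Series:
        return pd.Series({g: w for g, w in self.genes}, dtype=float)

    def restricted_to(
        self, genes: set[str], module_id: str | None = None, provenance: str = "subset"
    ) -> "GeneModule | None":
        """Module restricted to *genes*; ``None`` if nothing survives."""
        kept = [(g, w) for g, w in self.genes if g in genes]
        if not kept:
            return None
        return GeneModule(
            module_id=module_id or self.module_id,
            genes=kept,
            description=self.description,
            provenance=provenance,
        )


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------


def _present_weights(expr: pd.DataFrame, mod: GeneModule) -> pd.Series:
    w = mod.weights()
    present = w.index.intersection(expr.index)
    if len(present) == 0:
        raise ModuleError(f"module {mod.module_id!r}: no module genes in dataset")
    return w.loc[present]


def module_score(expr: pd.DataFrame, mod: GeneModule) -> pd.Series:
    """Difference-of-class-means module score per sample.

    *expr* is a gene x sample log2 matrix.  Genes absent from *expr* are
    ignored; an empty weight class contributes 0 to the difference, so an
    all-positive control module scores as the plain mean of its genes.
    """
    w = _present_weights(expr, mod)
    pos = w.index[w > 0]
    neg = w.index[w < 0]
    zero = pd.Series(0.0, index=expr.columns)
    pos_mean = expr.loc[pos].mean(axis=0) if len(pos) else zero
    neg_mean = expr.loc[neg].mean(axis=0) if len(neg) else zero
    out = pos_mean - neg_mean
    out.name = mod.module_id
    return out


def weighted_average_score(expr: pd.DataFrame, mod: GeneModule) -> pd.Series:
    """Classic weighted-average score: sum(w_g * expr_g) / n present genes.

    Provided for diagnostics; equals :func:`module_score` only when the
    positive and negative classes are equally large (up to the per-class
    normalization).
    """
    w = _present_weights(expr, mod)
    out = expr.loc[w.index].mul(w, axis=0).sum(axis=0) / float(len(w))
    out.name = mod.module_id
    return out


def score_modules(
    expr: pd.DataFrame,
    modules: list[GeneModule],
    min_size: int = 2,
    method: str = "difference",
) -> pd.DataFrame:
    """Score a collection of modules; returns module x sample table.

    Modules with fewer than *min_size* genes present in *expr* are
    silently dropped (they carry too little signal to interpret).
    """
    scorer = module_score if method == "difference" else weighted_average_score
    rows = {}
    for mod in modules:
        present = [g for g in mod.gene_symbols if g in expr.index]
        if len(present) < min_size:
            continue
        rows[mod.module_id] = scorer(expr, mod)
    return pd.DataFrame(rows).T.reindex(columns=expr.columns)


# ---------------------------------------------------------------------------
# subsets
# ---------------------------------------------------------------------------


def derive_module_subset(
    mod: GeneModule, selected_genes: set[str], min_size: int = 2
) -> GeneModule | None:
    """Module restricted to *selected_genes* (e.g. PVAC-selected genes).

    Returns ``None`` — the discard signal — when fewer than *min_size*
    genes survive; callers enforce the cross-dataset "discard all
    versions" rule.
    """
    sub = mod.restricted_to(set(selected_genes))
    if sub is None or len(sub) < min_size:
        return None
    return sub


def complement_subset(
    mod: GeneModule, selected_genes: set[str], min_size: int = 2
) -> GeneModule | None:
    """Module restricted to the genes *not* in *selected_genes*."""
    keep = set(mod.gene_symbols) - set(selected_genes)
    sub = mod.restricted_to(keep)
    if sub is None or len(sub) < min_size:
        return None
    return sub


def quartile_subsets(
    mod: GeneModule, expr: pd.DataFrame
) -> dict[str, GeneModule | None]:
    """Split a module into q1..q4 subsets by dataset-specific mean expression.

    Per-gene means across samples are computed for the module genes
    present in *expr*; quartile membership comes from the empirical
    quartiles of those means (ties at a boundary fall into the lower
    quartile), so mean expression is ordered q4 > q3 > q2 > q1.
    """
    present = [g for g in mod.gene_symbols if g in expr.index]
    if not present:
        raise ModuleError(f"module {mod.module_id!r}: no genes present")
    means = expr.loc[present].mean(axis=1)
    qs = means.quantile([0.25, 0.5, 0.75]).to_numpy()
    out: dict[str, GeneModule | None] = {}
    bins = np.searchsorted(qs, means.to_numpy(), side="left")  # ties -> lower
    for k in range(4):
        members = set(means.index[bins == k])
        out[f"q{k + 1}"] = mod.restricted_to(members)
    return out


def validate_module_subset(
    full_scores_ref: pd.Series,
    subset_scores_ref: "pd.Series | list[pd.Series]",
    rho_subset_valid: float = 0.9,
) -> bool:
    """Keep flag for a module: every subset version must track the full module.

    Computes Spearman correlation between the full-module scores and each
    subset version's scores on the reference dataset; the module is kept
    only if every version reaches *rho_subset_valid*.  A constant score
    vector makes the correlation undefined and counts as a failure.
    """
    if isinstance(subset_scores_ref, pd.Series):
        subset_scores_ref = [subset_scores_ref]
    for sub in subset_scores_ref:
        sub = sub.reindex(full_scores_ref.index)
        if sub.nunique() <= 1 or full_scores_ref.nunique() <= 1:
            warnings.warn("constant score vector: correlation undefined, dropping")
            return False
        rho = stats.spearmanr(full_scores_ref.to_numpy(), sub.to_numpy()).statistic
        if not rho >= rho_subset_valid:
            return False
    return True


# ---------------------------------------------------------------------------
# module diagnostics
# ---------------------------------------------------------------------------


def module_coherence(mod: GeneModule, expr: pd.DataFrame) -> float:
    """Mean pairwise Spearman correlation of module genes across samples."""
    present = [g for g in mod.gene_symbols if g in expr.index]
    if len(present) < 2:
        raise ModuleError(f"module {mod.module_id!r}: needs >= 2 genes present")
    sub = expr.loc[present]
    constant = sub.nunique(axis=1) <= 1
    if constant.any():
        warnings.warn(
            f"module {mod.module_id!r}: {int(constant.sum())} constant genes "
            "contribute 0 to coherence"
        )
    ranks = sub.rank(axis=1)
    c = np.corrcoef(ranks.to_numpy())
    c = np.nan_to_num(c, nan=0.0)
    n = len(present)
    iu = np.triu_indices(n, k=1)
    return float(c[iu].mean())


def module_mean_expression(mod: GeneModule, expr: pd.DataFrame) -> float:
    """Grand mean of per-gene mean expression of module genes."""
    present = [g for g in mod.gene_symbols if g in expr.index]
    if not present:
        raise ModuleError(f"module {mod.module_id!r}: no genes present")
    return float(expr.loc[present].mean(axis=1).mean())
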