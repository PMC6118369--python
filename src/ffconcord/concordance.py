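"""Reference-vs-matched concordance measurement.

Three comparison schemes mirror the matched study design: ``ref1`` takes
the gold-standard FF PM-MM dataset as reference and compares every other
dataset to it; ``ref2`` references the FF PM-only dataset against its
matched FFPE datasets; ``ref3`` compares the two FFPE PM-only datasets
to each other.  All correlations are Spearman.

Module-score concordance uses a robust leave-one-out average: with n
paired samples, the Spearman correlation is computed on every
(n-1)-sample subset and averaged.  A module is *reproducible* in a
matched dataset when this average exceeds ``rho_reproducible``
(strictly; default 0.8).  Gene- and sample-level correlations use plain
Spearman across the paired samples / common features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .modules import GeneModule, derive_module_subset, score_modules


@dataclass
class ComparisonSpec:
    """One reference dataset against a list of matched datasets."""

    comparison_id: str
    reference_dataset: str
    matched_datasets: list[str]

    def __post_init__(self) -> None:
        if self.reference_dataset in self.matched_datasets:
            raise ValueError("reference dataset cannot appear among matched datasets")


@dataclass
class ConcordanceReport:
    """Tables produced by :func:`run_comparison`."""

    comparison_id: str
    module_rho: pd.DataFrame  # rows (module, version), columns matched datasets
    reproducible: pd.DataFrame  # bool, same shape
    fraction_reproducible: pd.DataFrame  # version x matched dataset
    gene_rho: dict[str, pd.Series] = field(default_factory=dict)
    sample_rho: dict[str, pd.Series] = field(default_factory=dict)
    skipped_subsets: int = 0
    dropped_modules: list[str] = field(default_factory=list)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(a, b).statistic
    return float(rho)


def robust_module_correlation(
    scores_ref: pd.Series, scores_test: pd.Series
) -> tuple[float, int]:
    """Leave-one-out-averaged Spearman correlation of two paired score vectors.

    All n subsets of size n-1 are enumerated; the Spearman correlation is
    computed on each and the arithmetic mean returned.  Subsets where
    either vector is constant have an undefined correlation and are
    skipped (with a warning); the count of skipped subsets is returned
    alongside the mean.  NaN is returned if every subset is degenerate.
    """
    test = scores_test.reindex(scores_ref.index)
    a = scores_ref.to_numpy(dtype=float)
    b = test.to_numpy(dtype=float)
    n = len(a)
    if n < 4:
        raise ValueError("robust correlation needs at least 4 paired samples")
    rhos = []
    skipped = 0
    for leave in range(n):
        keep = np.arange(n) != leave
        aa, bb = a[keep], b[keep]
        if len(np.unique(aa)) == 1 or len(np.unique(bb)) == 1:
            skipped += 1
            continue
        rhos.append(_spearman(aa, bb))
    if skipped:
        warnings.warn(f"{skipped} constant leave-one-out subsets skipped")
    return (float(np.mean(rhos)) if rhos else float("nan")), skipped


def gene_correlations(
    ref: ExpressionMatrix, test: ExpressionMatrix, high_rho: float = 0.75
) -> tuple[pd.Series, float]:
    """Per-gene Spearman correlation across paired samples, on common genes.

    Returns the per-gene rho series and the fraction of genes with rho
    above ``high_rho`` (descriptive cut 0.75).  Genes constant in either
    dataset have undefined correlation and are excluded.
    """
    common = ref.values.index.intersection(test.values.index)
    if len(common) == 0:
        raise ValueError("no common genes between datasets")
    a = ref.values.loc[common]
    b = test.values.loc[common, a.columns]
    ra = a.rank(axis=1).to_numpy()
    rb = b.rank(axis=1).to_numpy()
    ok = (np.ptp(ra, axis=1) > 0) & (np.ptp(rb, axis=1) > 0)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    denom = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra * rb).sum(axis=1) / denom
    out = pd.Series(rho, index=common)[ok]
    frac = float((out > high_rho).mean()) if len(out) else float("nan")
    return out, frac


def sample_correlations(
    ref: ExpressionMatrix, test: ExpressionMatrix, level: str = "gene"
) -> pd.Series:
    """Per-sample Spearman correlation across common features.

    ``level='probeset'`` is only meaningful when both datasets share an
    array design; the caller is expected to reject cross-design
    probeset-level requests (see :func:`run_comparison`).
    """
    if level not in ("gene", "probeset"):
        raise ValueError(f"unknown level {level!r}")
    if ref.level != level or test.level != level:
        raise ValueError(f"both matrices must be {level}-level")
    common = ref.values.index.intersection(test.values.index)
    if len(common) == 0:
        raise ValueError("no common features between datasets")
    out = {}
    for s in ref.values.columns:
        out[s] = _spearman(
            ref.values.loc[common, s].to_numpy(), test.values.loc[common, s].to_numpy()
        )
    return pd.Series(out)


def cross_dataset_module_keep(
    modules: list[GeneModule],
    selected_genes_by_version: dict[str, set[str]],
    min_size: int = 2,
) -> dict[str, bool]:
    """The "discard all versions" rule across datasets and strategies.

    ``selected_genes_by_version`` maps a version key (dataset x strategy)
    to its selected gene set.  A module is kept only if *every* version's
    subset retains at least ``min_size`` genes.
    """
    keep = {}
    for mod in modules:
        keep[mod.module_id] = all(
            derive_module_subset(mod, genes, min_size=min_size) is not None
            for genes in selected_genes_by_version.values()
        )
    return keep


def run_comparison(
    spec: ComparisonSpec,
    gene_exprs: dict[str, ExpressionMatrix],
    modules: list[GeneModule],
    selected_genes_by_version: dict[str, dict[str, set[str]]] | None = None,
    rho_reproducible: float = 0.8,
    min_module_size: int = 2,
    subset_versions: bool = True,
) -> ConcordanceReport:
    """Full-module and subset-version concordance for one comparison.

    For every module (and, when ``subset_versions`` and PVAC selections
    are given, every per-dataset subset version) the matched datasets'
    scores are correlated against the REFERENCE dataset's *full-module*
    scores with the robust leave-one-out average.  Modules dropped by the
    size rule in any dataset are recorded, not failed.

    ``selected_genes_by_version`` maps strategy -> dataset -> selected
    gene symbols.
    """
    ref_id = spec.reference_dataset
    full_ref_scores = score_modules(gene_exprs[ref_id].values, modules, min_size=min_module_size)
    strategies = list(selected_genes_by_version or {})

    rows: dict[tuple[str, str], dict[str, float]] = {}
    skipped_total = 0
    dropped: list[str] = []
    for mod in modules:
        if mod.module_id not in full_ref_scores.index:
            dropped.append(mod.module_id)
            continue
        ref_scores = full_ref_scores.loc[mod.module_id]
        for ds in spec.matched_datasets:
            expr = gene_exprs[ds].values
            versions: dict[str, GeneModule | None] = {"full": mod}
            if subset_versions:
                for strat in strategies:
                    sel = selected_genes_by_version[strat].get(ds)
                    if sel is None:
                        continue
                    versions[strat] = derive_module_subset(mod, sel, min_size=min_module_size)
            for vname, vmod in versions.items():
                key = (mod.module_id, vname)
                rows.setdefault(key, {})
                if vmod is None:
                    rows[key][ds] = float("nan")
                    continue
                present = [g for g in vmod.gene_symbols if g in expr.index]
                if len(present) < min_module_size:
                    rows[key][ds] = float("nan")
                    continue
                test_scores = score_modules(expr, [vmod], min_size=min_module_size)
                if vmod.module_id not in test_scores.index:
                    rows[key][ds] = float("nan")
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, skipped = robust_module_correlation(
                        ref_scores, test_scores.loc[vmod.module_id]
                    )
                skipped_total += skipped
                rows[key][ds] = rho
    module_rho = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=spec.matched_datasets
    )
    module_rho.index = pd.MultiIndex.from_tuples(module_rho.index, names=["module", "version"])
    reproducible = module_rho > rho_reproducible
    # fraction among modules whose rho is defined for that version/dataset
    defined = module_rho.notna()
    frac = reproducible.groupby(level="version").sum() / defined.groupby(level="version").sum()

    gene_rho: dict[str, pd.Series] = {}
    sample_rho: dict[str, pd.Series] = {}
    for ds in spec.matched_datasets:
        rho_series, _ = gene_correlations(gene_exprs[ref_id], gene_exprs[ds])
        gene_rho[ds] = rho_series
        sample_rho[ds] = sample_correlations(gene_exprs[ref_id], gene_exprs[ds], level="gene")
    return ConcordanceReport(
        comparison_id=spec.comparison_id,
        module_rho=module_rho,
        reproducible=reproducible,
        fraction_reproducible=frac,
        gene_rho=gene_rho,
        sample_rho=sample_rho,
        skipped_subsets=skipped_total,
        dropped_modules=dropped,
    )
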