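"""Probe-level preprocessing: RMA-style background correction, quantile
normalization and median-polish summarization, plus gene-level collapse.

The stage order is fixed: background-correct (linear scale, per sample)
-> quantile-normalize (linear) -> log2 -> median-polish summarize to
probesets -> collapse probesets to genes by maximal variance.  Each
dataset is normalized independently of the others.

The transformers follow the scikit-learn estimator protocol
(``fit``/``transform`` on a samples x features array) and compose in a
:class:`sklearn.pipeline.Pipeline`; the module-level functions are thin
wrappers that keep the field's probes x samples orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .design import ArrayDesign
from .io import ExpressionMatrix, ProbeMatrix


class PreprocessError(ValueError):
    """Raised on degenerate inputs to a preprocessing stage."""


# ---------------------------------------------------------------------------
# normal + exponential background model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormexpParams:
    """Parameters of the normal(mu, sigma) + exponential(mean alpha) convolution."""

    mu: float
    sigma: float
    alpha: float  # exponential MEAN (scale), not rate

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.alpha <= 0:
            raise PreprocessError("normexp requires sigma > 0 and alpha > 0")


def estimate_normexp_params(x: np.ndarray, n_bins: int = 64) -> NormexpParams:
    """Mode-anchored moment estimate of the normexp parameters.

    ``mu`` is the histogram mode of the intensities (background
    location), ``sigma`` the root-mean-square deviation of the values at
    or below the mode (treating the lower tail as the reflected half of
    the background normal), and ``alpha`` the mean excess of the values
    above the mode (exponential signal mean).
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise PreprocessError("constant intensity column: cannot estimate background")
    counts, edges = np.histogram(x, bins=n_bins)
    k = int(np.argmax(counts))
    mu = 0.5 * (edges[k] + edges[k + 1])
    # refine: the signal exponential flattens the coarse histogram, so zoom
    # into the neighbourhood of the coarse mode with a finer grid
    width = edges[k + 1] - edges[k]
    local = x[(x >= mu - 2 * width) & (x <= mu + 2 * width)]
    if len(local) >= 50:
        counts, edges = np.histogram(local, bins=32)
        k = int(np.argmax(counts))
        mu = 0.5 * (edges[k] + edges[k + 1])
    lower = x[x <= mu]
    sigma = float(np.sqrt(np.mean((lower - mu) ** 2))) if len(lower) else 0.0
    upper = x[x > mu]
    alpha = float(np.mean(upper - mu)) if len(upper) else 0.0
    sigma = max(sigma, 1e-6 * max(abs(mu), 1.0))
    alpha = max(alpha, 1e-6 * max(abs(mu), 1.0))
    return NormexpParams(mu=mu, sigma=sigma, alpha=alpha)


def normexp_signal(x: np.ndarray, params: NormexpParams) -> np.ndarray:
    """Posterior mean E[signal | observed] under the normexp convolution.

    With X = S + B, B ~ N(mu, sigma^2), S ~ Exp(mean alpha), the
    posterior of S given X = x is a normal N(mu_sf, sigma^2) truncated to
    [0, inf) with ``mu_sf = x - mu - sigma^2 / alpha``, whose mean is
    ``mu_sf + sigma * phi(mu_sf/sigma) / Phi(mu_sf/sigma)``.  The
    log-space evaluation keeps the far-left tail stable.
    """
    x = np.asarray(x, dtype=float)
    mu_sf = x - params.mu - params.sigma**2 / params.alpha
    c = mu_sf / params.sigma
    mills = np.exp(norm.logpdf(c) - norm.logcdf(c))
    out = mu_sf + params.sigma * mills
    return np.maximum(out, np.finfo(float).tiny)


class RmaBackgroundCorrector(BaseEstimator, TransformerMixin):
    """Per-sample normexp background correction of linear intensities.

    Each sample (row of X) carries its own optical/hybridization
    background, so parameters are estimated — or injected via the
    ``params`` argument — per sample at transform time; ``fit`` only
    records the feature count.

    Parameters
    ----------
    params : NormexpParams or None
        Fixed parameters applied to every sample; estimated per sample
        from the data when ``None``.
    """

    def __init__(self, params: NormexpParams | None = None):
        self.params = params

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            p = self.params or estimate_normexp_params(X[i])
            out[i] = normexp_signal(X[i], p)
        return out


def rma_background_correct(
    m: ProbeMatrix, params: NormexpParams | None = None
) -> ProbeMatrix:
    """Background-correct a probe x sample matrix, per sample.

    Raises a :class:`PreprocessError` naming the sample when a column is
    constant and parameters cannot be estimated.
    """
    vals = m.values
    out = {}
    for sample in vals.columns:
        x = vals[sample].to_numpy(dtype=float)
        try:
            p = params or estimate_normexp_params(x)
        except PreprocessError as exc:
            raise PreprocessError(f"sample {sample!r}: {exc}") from exc
        out[sample] = normexp_signal(x, p)
    return ProbeMatrix(
        design_id=m.design_id,
        values=pd.DataFrame(out, index=vals.index),
    )


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Map every sample's empirical distribution onto a common reference.

    ``fit`` computes the reference distribution as the across-sample mean
    of each row of the sorted data; ``transform`` replaces each sample's
    ordered values by that reference (ordinal ranks, stable ties), so on
    the fitted data every sample ends up with the identical sorted value
    vector.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.reference_distribution_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        ref = self.reference_distribution_
        if X.shape[1] != len(ref):
            raise ValueError("feature count differs from fit-time data")
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            order = np.argsort(X[i], kind="stable")
            out[i, order] = ref
        return out


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns (samples) of a feature x sample frame.

    After normalization every column holds the identical multiset of
    values: the across-column mean of the sorted columns.  A
    single-column input is returned unchanged with a warning.
    """
    if values.shape[1] == 1:
        warnings.warn("quantile normalization of a single sample is a no-op")
        return values.copy()
    qn = QuantileNormalizer().fit(values.to_numpy().T)
    out = qn.transform(values.to_numpy().T).T
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# median polish summarization
# ---------------------------------------------------------------------------


def median_polish(
    x: np.ndarray, max_iter: int = 10, tol: float = 0.01
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a probes x samples block.

    Fits ``x[i, j] ~ overall + row[i] + col[j]`` by alternating row and
    column median sweeps, stopping when the sum of absolute residuals
    changes by less than ``tol`` or after ``max_iter`` iterations.
    Returns ``(overall, row_effects, col_effects, residuals)``.
    """
    r = np.array(x, dtype=float)
    if r.ndim != 2 or r.size == 0:
        raise PreprocessError("median polish needs a non-empty 2-D block")
    t = 0.0
    row = np.zeros(r.shape[0])
    col = np.zeros(r.shape[1])
    old_sum = np.abs(r).sum()
    for _ in range(max_iter):
        rm = np.median(r, axis=1)
        r -= rm[:, None]
        row += rm
        delta = np.median(col)
        col -= delta
        t += delta
        cm = np.median(r, axis=0)
        r -= cm[None, :]
        col += cm
        delta = np.median(row)
        row -= delta
        t += delta
        new_sum = np.abs(r).sum()
        if abs(new_sum - old_sum) < tol:
            break
        old_sum = new_sum
    return t, row, col, r


class MedianPolishSummarizer(BaseEstimator, TransformerMixin):
    """Summarize log2 probe intensities to probeset expression.

    ``transform`` maps a samples x probes array to samples x probesets:
    for each probeset the additive model is fitted by median polish and
    the probeset expression of sample ``j`` is ``overall + col_effect_j``.
    Anti-genomic probesets are summarized like genomic ones (background
    diagnostics need them).
    """

    def __init__(self, design: ArrayDesign, max_iter: int = 10, tol: float = 0.01):
        self.design = design
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        pm = self.design.pm_probes
        if X.shape[1] != len(pm):
            raise ValueError(
                f"expected {len(pm)} PM probe features, got {X.shape[1]}"
            )
        self.n_features_in_ = X.shape[1]
        self.probeset_ids_ = list(self.design.probesets.index)
        groups = pm.groupby("probeset_id", sort=False).indices
        self._groups = [(ps, np.asarray(groups[ps])) for ps in self.probeset_ids_]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self._groups)))
        for k, (ps, idx) in enumerate(self._groups):
            if len(idx) == 0:
                raise PreprocessError(f"probeset {ps!r} has no probes")
            block = X[:, idx].T  # probes x samples
            t, _, col, _ = median_polish(block, self.max_iter, self.tol)
            out[:, k] = t + col
        return out


def median_polish_summarize(
    values: pd.DataFrame, design: ArrayDesign, max_iter: int = 10, tol: float = 0.01
) -> ExpressionMatrix:
    """Summarize a log2 PM-probe x sample frame to probeset level."""
    pm_ids = design.pm_probes["probe_id"]
    vals = values.loc[pm_ids]
    mp = MedianPolishSummarizer(design, max_iter=max_iter, tol=tol).fit(vals.to_numpy().T)
    out = mp.transform(vals.to_numpy().T).T
    return ExpressionMatrix(
        level="probeset",
        values=pd.DataFrame(out, index=pd.Index(mp.probeset_ids_, name="probeset_id"), columns=vals.columns),
    )


# ---------------------------------------------------------------------------
# gene-level collapse
# ---------------------------------------------------------------------------


def collapse_to_genes(e: ExpressionMatrix, design: ArrayDesign) -> ExpressionMatrix:
    """Collapse probeset expression to gene level by maximal variance.

    For every gene the probeset with the largest across-sample variance
    *in this dataset* is kept; anti-genomic and unannotated probesets are
    dropped.  A gene can therefore be represented by different probesets
    in different datasets — deliberate, as that is how per-dataset
    max-variance selection behaves.
    """
    if e.level != "probeset":
        raise ValueError("collapse_to_genes expects a probeset-level matrix")
    ps = design.probesets
    annotated = ps.index[(~ps["is_antigenomic"]) & ps["gene_symbol"].notna()]
    vals = e.values.loc[e.values.index.intersection(annotated)]
    gene_of = ps.loc[vals.index, "gene_symbol"]
    variances = vals.var(axis=1, ddof=1)
    pick = (
        pd.DataFrame({"gene": gene_of, "var": variances})
        .sort_values(["gene", "var"], kind="stable")
        .groupby("gene", sort=True)
        .tail(1)
    )
    out = vals.loc[pick.index]
    out.index = pd.Index(pick["gene"].values, name="gene")
    return ExpressionMatrix(level="gene", values=out.sort_index())


def preprocess_dataset(
    m: ProbeMatrix,
    design: ArrayDesign,
    normexp_params: NormexpParams | None = None,
    include_antigenomic_in_norm: bool = True,
    max_iter: int = 10,
    tol: float = 0.01,
) -> tuple[pd.DataFrame, ExpressionMatrix, ExpressionMatrix]:
    """Full probe-level chain for one dataset.

    Background-correct PM (and anti-genomic) probes on the linear scale,
    quantile-normalize across samples, log2-transform, median-polish to
    probesets and collapse to genes.  Returns ``(normalized log2 probe
    frame, probeset ExpressionMatrix, gene ExpressionMatrix)``.

    ``include_antigenomic_in_norm=False`` drops anti-genomic probes from
    the quantile-normalization reference distribution (they are then
    normalized separately, on their own distribution).
    """
    pm_ids = design.pm_probes["probe_id"]
    sub = ProbeMatrix(design_id=m.design_id, values=m.values.loc[pm_ids])
    corrected = rma_background_correct(sub, params=normexp_params)
    vals = corrected.values
    if include_antigenomic_in_norm or design.design_kind == "pm_mm":
        normalized = quantile_normalize(vals)
    else:
        ag = design.antigenomic_probesets
        ag_probes = design.pm_probes.loc[
            design.pm_probes["probeset_id"].isin(ag), "probe_id"
        ]
        genomic_probes = vals.index.difference(ag_probes, sort=False)
        normalized = pd.concat(
            [quantile_normalize(vals.loc[genomic_probes]), quantile_normalize(vals.loc[ag_probes])]
        ).loc[vals.index]
    log2probes = np.log2(normalized)
    probeset = median_polish_summarize(log2probes, design, max_iter=max_iter, tol=tol)
    gene = collapse_to_genes(probeset, design)
    return log2probes, probeset, gene
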