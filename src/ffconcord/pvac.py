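"""PVAC probe-coherence filtering.

PVAC scores each probeset by the proportion of probe-level variation
captured by the first principal component: probes of a probeset that
truly track their transcript rise and fall together across samples, so
their centered covariance is close to rank one and the score approaches
1; probes measuring only noise/background spread their variance across
components.  A cutoff separating reliable from unreliable probesets is
derived from "negative" probesets known to measure nothing:

* ``AAB`` — probesets called Absent in every sample (requires detection
  calls; breaks down when detection is compromised, e.g. by an
  unrealistically low background), or
* ``AG`` — the design's anti-genomic background probesets (PM-only
  designs), which need no detection calls at all.

Scores are computed on background-corrected, quantile-normalized log2
probe data; the covariance uses centering only (no rescaling of probes),
preserving the probe-agreement interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .design import ArrayDesign
from .detection import DetectionCalls

AAB = "AAB"
AG = "AG"


class PvacError(ValueError):
    """Raised when negatives are unavailable or insufficient."""


@dataclass
class PvacResult:
    """Outcome of PVAC filtering on one dataset."""

    scores: pd.Series  # per probeset, in [0, 1]
    negatives_used: list[str]
    strategy: str  # 'AAB' | 'AG'
    cutoff: float
    selected: pd.Series = field(repr=False)  # bool per probeset

    def selected_probesets(self) -> pd.Index:
        return self.selected.index[self.selected]

    def selected_genes(self, design: ArrayDesign) -> set[str]:
        """Gene symbols of the selected probesets (unannotated dropped)."""
        genes = design.probesets.loc[self.selected_probesets(), "gene_symbol"]
        return set(genes.dropna())


def pvac_score_block(x: np.ndarray) -> float:
    """PVAC score of one probes x samples block.

    Probes are centered across samples; the score is the largest
    eigenvalue of the probe x probe covariance divided by the eigenvalue
    sum (equivalently the leading squared singular value of the centered
    block over the total).  A block with zero total variance has an
    undefined score and is assigned 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    total = float((centered**2).sum())
    if total == 0.0:
        warnings.warn("probeset with zero total variance: PVAC score set to 0")
        return 0.0
    s = np.linalg.svd(centered, compute_uv=False)
    return float(s[0] ** 2 / total)


def pvac_scores(values: pd.DataFrame, design: ArrayDesign) -> pd.Series:
    """PVAC score per probeset of ``design``.

    ``values`` is a log2 probe x sample frame (background-corrected and
    normalized).  Every probeset with >= 2 probes is scored, anti-genomic
    ones included; >= 3 samples are required for the covariance to be
    meaningful.
    """
    if values.shape[1] < 3:
        raise PvacError("PVAC needs at least 3 samples")
    pm = design.pm_probes
    x = values.loc[pm["probe_id"]].to_numpy()
    groups = pm.reset_index(drop=True).groupby("probeset_id", sort=False).indices
    out = {}
    for ps, idx in groups.items():
        if len(idx) < 2:
            continue
        out[ps] = pvac_score_block(x[idx])
    return pd.Series(out, name="pvac_score").reindex(design.probesets.index).dropna()


def select_negative_probesets(
    design: ArrayDesign,
    strategy: str,
    calls: DetectionCalls | None = None,
) -> list[str]:
    """Negative (not-expressed) probesets for cutoff derivation.

    ``AAB``: genomic probesets Absent in every sample (needs *calls*);
    ``AG``: exactly the design's anti-genomic probesets.
    """
    if strategy == AG:
        ag = list(design.antigenomic_probesets)
        if not ag:
            raise PvacError("AG strategy requires anti-genomic probesets in the design")
        return ag
    if strategy == AAB:
        if calls is None:
            raise PvacError("AAB strategy requires detection calls")
        genomic = design.genomic_probesets
        absent_all = ~calls.present.loc[genomic].any(axis=1)
        negatives = list(genomic[absent_all])
        if not negatives:
            raise PvacError(
                "no all-absent probesets: detection may be compromised; "
                "use AG or lower alpha"
            )
        return negatives
    raise ValueError(f"unknown strategy {strategy!r}")


def pvac_filter(
    scores: pd.Series,
    negatives: list[str],
    design: ArrayDesign,
    strategy: str,
    q: float = 0.95,
    cutoff_rule: str = "quantile",
) -> PvacResult:
    """Select probesets whose score exceeds the negatives-derived cutoff.

    The cutoff is the ``q``-quantile (default 0.95) of the negative
    probesets' scores (``cutoff_rule='max'`` uses their maximum instead).
    Selection is strict (score > cutoff); anti-genomic probesets are
    never selected.  At least 5 negatives with defined scores are
    required.
    """
    neg_scores = scores.reindex(negatives).dropna()
    if len(neg_scores) < 5:
        raise PvacError(
            f"only {len(neg_scores)} negative probesets with scores; need >= 5"
        )
    if cutoff_rule == "quantile":
        cutoff = float(neg_scores.quantile(q))
    elif cutoff_rule == "max":
        cutoff = float(neg_scores.max())
    else:
        raise ValueError(f"unknown cutoff_rule {cutoff_rule!r}")
    selected = scores > cutoff
    ag = design.antigenomic_probesets
    selected.loc[selected.index.intersection(ag)] = False
    return PvacResult(
        scores=scores,
        negatives_used=list(neg_scores.index),
        strategy=strategy,
        cutoff=cutoff,
        selected=selected,
    )


def run_pvac(
    values: pd.DataFrame,
    design: ArrayDesign,
    strategy: str,
    calls: DetectionCalls | None = None,
    q: float = 0.95,
    cutoff_rule: str = "quantile",
) -> PvacResult:
    """Score, pick negatives and filter in one call."""
    scores = pvac_scores(values, design)
    negatives = select_negative_probesets(design, strategy, calls=calls)
    return pvac_filter(scores, negatives, design, strategy, q=q, cutoff_rule=cutoff_rule)


class PvacSelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector over probeset-level features.

    ``fit`` expects ``X`` as samples x PM-probes (log2, normalized) in the
    probe order of ``design.pm_probes``; the fitted support maps to the
    design's probesets, and ``transform`` then operates on samples x
    probeset matrices (e.g. median-polish output).

    Parameters
    ----------
    design : ArrayDesign
    strategy : 'AG' or 'AAB'
    calls : DetectionCalls, optional (required for 'AAB')
    q : float
        Quantile of negative scores used as cutoff.
    """

    def __init__(
        self,
        design: ArrayDesign,
        strategy: str = AG,
        calls: DetectionCalls | None = None,
        q: float = 0.95,
        cutoff_rule: str = "quantile",
    ):
        self.design = design
        self.strategy = strategy
        self.calls = calls
        self.q = q
        self.cutoff_rule = cutoff_rule

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        pm = self.design.pm_probes
        if X.shape[1] != len(pm):
            raise ValueError(f"expected {len(pm)} PM-probe features, got {X.shape[1]}")
        values = pd.DataFrame(X.T, index=pm["probe_id"].values)
        self.result_ = run_pvac(
            values,
            self.design,
            self.strategy,
            calls=self.calls,
            q=self.q,
            cutoff_rule=self.cutoff_rule,
        )
        self.n_features_in_ = X.shape[1]
        self.probeset_ids_ = list(self.design.probesets.index)
        self.scores_ = self.result_.scores.reindex(self.probeset_ids_).to_numpy()
        self.cutoff_ = self.result_.cutoff
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self)
        return self.result_.selected.reindex(self.probeset_ids_, fill_value=False).to_numpy()

    def transform(self, X):
        """Filter a samples x probeset matrix down to selected probesets."""
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.probeset_ids_):
            raise ValueError(
                f"expected {len(self.probeset_ids_)} probeset features, got {X.shape[1]}"
            )
        return X[:, self._get_support_mask()]
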