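"""Present/Absent detection calling.

Two algorithms, selected by array design:

* PM-MM designs: a MAS5-like call per probeset and sample.  Each probe
  pair yields a discrimination score ``R_i = (PM_i - MM_i)/(PM_i + MM_i)``
  and a one-sided Wilcoxon signed-rank test asks whether the median of
  ``R - tau`` exceeds zero (``tau`` defaults to the conventional 0.015).

* PM-only designs: no MM partners exist, so the anti-genomic background
  probesets supply the reference.  Per sample, all probes of all
  anti-genomic probesets are pooled into a background vector and each
  genomic probeset's probes are compared against it with a one-sided
  (greater) Wilcoxon rank-sum test — exact for small pools without ties,
  normal approximation with tie correction otherwise.

Calls are binary Present/Absent at significance level ``alpha`` (default
0.05); no Marginal category is emitted.  Detection runs on raw (linear,
un-normalized) intensities, as is conventional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import PM_MM, PM_ONLY, ArrayDesign
from .io import ProbeMatrix


class DetectionError(ValueError):
    """Raised when a design cannot support the requested call algorithm."""


@dataclass
class DetectionCalls:
    """Per-probeset, per-sample Present/Absent calls with p-values."""

    present: pd.DataFrame  # bool, probeset x sample
    p_values: pd.DataFrame  # float, probeset x sample
    alpha: float
    method: str  # 'mas5_like' | 'pm_only_ag'

    def __post_init__(self) -> None:
        if not self.present.equals(self.p_values < self.alpha):
            raise ValueError("call invariant violated: present != (p < alpha)")

    def calls_frame(self) -> pd.DataFrame:
        """'P'/'A' string frame, the on-disk representation."""
        return self.present.map(lambda b: "P" if b else "A")


def signed_rank_p(d: np.ndarray) -> float:
    """One-sided (greater) Wilcoxon signed-rank p for one vector.

    Zeros are dropped (Wilcoxon's convention); an all-zero vector has an
    undefined statistic and returns p = 1 with a warning.
    """
    d = np.asarray(d, dtype=float)
    nz = d[d != 0]
    if len(nz) == 0:
        warnings.warn("all discrimination scores equal tau; Absent with p = 1")
        return 1.0
    res = stats.wilcoxon(nz, alternative="greater")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def detect_pm_mm(
    m: ProbeMatrix,
    design: ArrayDesign,
    tau: float = 0.015,
    alpha: float = 0.05,
) -> DetectionCalls:
    """MAS5-like detection calls for a PM-MM design.

    A probeset whose discrimination scores all equal ``tau`` exactly
    (e.g. PM == MM everywhere with ``tau = 0``) has an undefined test
    statistic; it is called Absent with p = 1 and a warning.
    """
    if design.design_kind != PM_MM:
        raise DetectionError("detect_pm_mm requires a pm_mm design")
    partner = design.mm_partner()
    pm_ids = partner.index
    pm = m.values.loc[pm_ids].to_numpy()
    mm = m.values.loc[partner.values].to_numpy()
    d = (pm - mm) / (pm + mm) - tau
    ps_of = design.probeset_of_probe().loc[pm_ids]
    samples = m.values.columns
    pvals = pd.DataFrame(1.0, index=design.probesets.index, columns=samples)

    # batch probesets of equal size into one vectorized signed-rank call;
    # slices containing exact zeros fall back to the scalar path
    groups = ps_of.groupby(ps_of.values, sort=False).groups
    by_size: dict[int, list[tuple[str, np.ndarray]]] = {}
    pos_of = pd.Series(np.arange(len(pm_ids)), index=pm_ids)
    for ps, probe_idx in groups.items():
        rows = pos_of.loc[probe_idx].to_numpy()
        by_size.setdefault(len(rows), []).append((ps, rows))
    for size, members in by_size.items():
        ids = [ps for ps, _ in members]
        stack = np.stack([d[rows] for _, rows in members])  # (G, size, n_samples)
        flat = stack.transpose(0, 2, 1).reshape(-1, size)  # (G*n_samples, size)
        has_zero = (flat == 0).any(axis=1)
        p = np.ones(len(flat))
        if (~has_zero).any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats.wilcoxon(flat[~has_zero], alternative="greater", axis=1)
            p[~has_zero] = np.nan_to_num(np.atleast_1d(res.pvalue), nan=1.0)
        for i in np.flatnonzero(has_zero):
            p[i] = signed_rank_p(flat[i])
        pvals.loc[ids] = p.reshape(len(members), len(samples))
    return DetectionCalls(
        present=pvals < alpha, p_values=pvals, alpha=alpha, method="mas5_like"
    )


def rank_sum_p(
    x: np.ndarray, background: np.ndarray, method: str = "auto"
) -> np.ndarray:
    """One-sided (greater) rank-sum p of rows of ``x`` vs ``background``.

    ``x`` has shape (batch, n1) and ``background`` (n2,) or (batch, n2).
    ``'auto'`` chooses the exact null when the pooled size is at most 60
    and the data are tie-free, else the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    background = np.asarray(background, dtype=float)
    if background.ndim == 1:
        background = np.broadcast_to(background, (x.shape[0], len(background)))
    n1, n2 = x.shape[1], background.shape[1]
    if method == "auto":
        pooled = np.concatenate([x, background], axis=1)
        tie_free = all(len(np.unique(row)) == n1 + n2 for row in pooled)
        method = "exact" if (n1 + n2) <= 60 and tie_free else "asymptotic"
    res = stats.mannwhitneyu(
        x, background, alternative="greater", method=method, axis=1
    )
    return np.atleast_1d(np.asarray(res.pvalue, dtype=float))


def detect_pm_only(
    m: ProbeMatrix,
    design: ArrayDesign,
    alpha: float = 0.05,
    method: str = "auto",
    ag_pool: str = "all",
) -> DetectionCalls:
    """Anti-genomic rank-sum detection calls for a PM-only design.

    Per sample, the probes of all anti-genomic probesets are pooled into
    one background reference vector (``ag_pool='all'``; the
    ``'per_probeset_sample'`` alternative keeps one probe per
    anti-genomic probeset).  Each genomic probeset's probes are tested
    against the pool one-sidedly (greater).  Anti-genomic probesets are
    themselves tested against the pool of the *other* anti-genomic
    probesets, so they carry calls too and may be Present by chance.
    """
    if design.design_kind != PM_ONLY:
        raise DetectionError("detect_pm_only requires a pm_only design")
    ag_sets = design.antigenomic_probesets
    if len(ag_sets) == 0:
        raise DetectionError("PM-only detection requires anti-genomic probesets")
    if ag_pool not in ("all", "per_probeset_sample"):
        raise ValueError(f"unknown ag_pool {ag_pool!r}")
    ps_of = design.probeset_of_probe()
    ag_probe_mask = ps_of.isin(ag_sets)
    ag_probes = ps_of.index[ag_probe_mask]
    if ag_pool == "per_probeset_sample":
        ag_probes = ag_probes[~ps_of.loc[ag_probes].duplicated()]
    vals = m.values
    samples = vals.columns
    pvals = pd.DataFrame(1.0, index=design.probesets.index, columns=samples)
    bg = vals.loc[ag_probes].to_numpy()  # (n_bg, n_samples)
    ag_of_bg = ps_of.loc[ag_probes].to_numpy()

    groups = design.pm_probes.groupby("probeset_id", sort=False)["probe_id"]
    sizes = groups.size()
    genomic = design.genomic_probesets
    # genomic probesets share (n1, n2): batch per probe-count per sample
    for n1 in sorted(sizes.loc[genomic].unique()):
        ids = sizes.loc[genomic].index[sizes.loc[genomic] == n1]
        probe_rows = design.pm_probes.set_index("probeset_id").loc[ids, "probe_id"]
        x = vals.loc[probe_rows].to_numpy().reshape(len(ids), n1, len(samples))
        for j, s in enumerate(samples):
            pvals.loc[ids, s] = rank_sum_p(x[:, :, j], bg[:, j], method=method)
    for ps in ag_sets:
        probe_ids = groups.get_group(ps)
        x = vals.loc[probe_ids].to_numpy()
        other = bg[ag_of_bg != ps]
        for j, s in enumerate(samples):
            pvals.loc[ps, s] = rank_sum_p(x[:, j][None, :], other[:, j], method=method)[0]
    return DetectionCalls(
        present=pvals < alpha, p_values=pvals, alpha=alpha, method="pm_only_ag"
    )


def detect(
    m: ProbeMatrix, design: ArrayDesign, alpha: float = 0.05, tau: float = 0.015
) -> DetectionCalls:
    """Dispatch on the design kind."""
    if design.design_kind == PM_MM:
        return detect_pm_mm(m, design, tau=tau, alpha=alpha)
    return detect_pm_only(m, design, alpha=alpha)


def percent_present(calls: DetectionCalls, design: ArrayDesign) -> pd.Series:
    """Fraction of *genomic* probesets called Present, per sample."""
    genomic = design.genomic_probesets
    return calls.present.loc[genomic].mean(axis=0)
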