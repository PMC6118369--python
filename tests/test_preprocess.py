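"""Preprocessing stages against hand-computed and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from ffconcord.io import ExpressionMatrix, ProbeMatrix
from ffconcord.preprocess import (
    MedianPolishSummarizer,
    NormexpParams,
    PreprocessError,
    QuantileNormalizer,
    RmaBackgroundCorrector,
    collapse_to_genes,
    estimate_normexp_params,
    median_polish,
    median_polish_summarize,
    normexp_signal,
    preprocess_dataset,
    quantile_normalize,
    rma_background_correct,
)


# ---------------------------------------------------------------------------
# normexp background correction
# ---------------------------------------------------------------------------


def normexp_conditional_mean_quadrature(x: float, p: NormexpParams) -> float:
    """Independent oracle: numeric integration of E[S | X = x].

    Posterior density of the signal S given the observation x is
    proportional to phi((x - s - mu)/sigma) * exp(-s/alpha) on s >= 0.
    """
    def weight(s):
        return stats.norm.pdf(x - s, loc=p.mu, scale=p.sigma) * np.exp(-s / p.alpha)

    upper = x + 20 * p.sigma + 20 * p.alpha
    # the posterior is a narrow spike near x - mu: give quad breakpoints
    peak = max(x - p.mu, 0.0)
    pts = sorted({max(peak - 8 * p.sigma, 0.0), peak, min(peak + 8 * p.sigma, upper)})
    num, _ = integrate.quad(lambda s: s * weight(s), 0, upper, limit=400, points=pts)
    den, _ = integrate.quad(weight, 0, upper, limit=400, points=pts)
    return num / den


class TestNormexp:
    PARAMS = NormexpParams(mu=100.0, sigma=10.0, alpha=500.0)

    @pytest.mark.parametrize("x", np.linspace(60.0, 5000.0, 20))
    def test_matches_quadrature_oracle(self, x):
        """Closed form agrees with numeric integration to 1e-6 relative."""
        expected = normexp_conditional_mean_quadrature(float(x), self.PARAMS)
        got = float(normexp_signal(np.array([x]), self.PARAMS)[0])
        assert got == pytest.approx(expected, rel=1e-6)

    def test_monotone_and_bounded_by_input(self, rng):
        x = np.sort(rng.uniform(60, 5000, 200))
        y = normexp_signal(x, self.PARAMS)
        assert np.all(np.diff(y) > 0)
        assert np.all(y > 0)
        assert np.all(y <= x)

    def test_constant_column_rejected(self):
        m = ProbeMatrix("d", pd.DataFrame({"s1": [5.0, 5.0, 5.0]}, index=list("abc")))
        with pytest.raises(PreprocessError, match="s1"):
            rma_background_correct(m)

    def test_parameter_recovery_on_simulated_background(self, rng):
        """Mode-anchored estimates land near the generating parameters."""
        x = rng.normal(100, 10, 8000) + rng.exponential(500, 8000)
        p = estimate_normexp_params(x)
        # the mode-anchored moment scheme is deliberately simple; the signal
        # exponential tilts the local histogram, biasing mu upward a little
        assert p.mu == pytest.approx(100, abs=30)
        assert p.alpha == pytest.approx(500, rel=0.35)

    def test_estimator_transform_matches_function(self, rng):
        vals = pd.DataFrame(
            rng.uniform(50, 2000, (30, 4)),
            index=[f"p{i}" for i in range(30)],
            columns=list("abcd"),
        )
        m = ProbeMatrix("d", vals)
        out_fn = rma_background_correct(m, params=self.PARAMS).values.to_numpy()
        est = RmaBackgroundCorrector(params=self.PARAMS).fit(vals.to_numpy().T)
        out_est = est.transform(vals.to_numpy().T).T
        np.testing.assert_allclose(out_fn, out_est)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------


class TestQuantileNormalize:
    def test_hand_worked_example(self):
        """Columns (1,2,3) and (4,3,2) both map onto sorted-row means."""
        df = pd.DataFrame({"c1": [1.0, 2.0, 3.0], "c2": [4.0, 3.0, 2.0]}, index=list("xyz"))
        out = quantile_normalize(df)
        np.testing.assert_allclose(out["c1"], [1.5, 2.5, 3.5])
        np.testing.assert_allclose(out["c2"], [3.5, 2.5, 1.5])

    def test_identical_columns_are_fixed_point(self, rng):
        col = rng.uniform(0, 10, 50)
        df = pd.DataFrame({"a": col, "b": col.copy()})
        out = quantile_normalize(df)
        np.testing.assert_allclose(out.to_numpy(), df.to_numpy())

    def test_equal_sorted_columns_property(self, rng):
        df = pd.DataFrame(rng.uniform(1, 100, (200, 6)))
        out = quantile_normalize(df)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        for j in range(1, 6):
            np.testing.assert_array_equal(sorted_cols[:, j], sorted_cols[:, 0])

    def test_single_column_warns_and_passes_through(self):
        df = pd.DataFrame({"only": [3.0, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="single sample"):
            out = quantile_normalize(df)
        np.testing.assert_allclose(out["only"], df["only"])

    def test_estimator_maps_new_data_onto_reference(self, rng):
        X = rng.uniform(0, 1, (5, 40))
        qn = QuantileNormalizer().fit(X)
        new = rng.uniform(0, 1, (2, 40))
        out = qn.transform(new)
        for row in out:
            np.testing.assert_allclose(np.sort(row), qn.reference_distribution_)


# ---------------------------------------------------------------------------
# median polish
# ---------------------------------------------------------------------------


def median_polish_oracle(x, max_iter=10, tol=0.01):
    """Independent re-implementation (R-medpolish style, explicit loops)."""
    z = [[float(v) for v in row] for row in x]
    nr, nc = len(z), len(z[0])
    t = 0.0
    r = [0.0] * nr
    c = [0.0] * nc
    med = lambda v: float(np.median(v))
    oldsum = sum(abs(v) for row in z for v in row)
    for _ in range(max_iter):
        for i in range(nr):
            m = med(z[i])
            r[i] += m
            for j in range(nc):
                z[i][j] -= m
        delta = med(c)
        c = [v - delta for v in c]
        t += delta
        for j in range(nc):
            m = med([z[i][j] for i in range(nr)])
            c[j] += m
            for i in range(nr):
                z[i][j] -= m
        delta = med(r)
        r = [v - delta for v in r]
        t += delta
        newsum = sum(abs(v) for row in z for v in row)
        if abs(newsum - oldsum) < tol:
            break
        oldsum = newsum
    return t, np.array(r), np.array(c)


class TestMedianPolish:
    def test_two_by_two_hand_fixture(self):
        """[[1,2],[3,4]] summarizes to (2.0, 3.0)."""
        t, row, col, resid = median_polish(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(t + col, [2.0, 3.0])
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_single_probe_is_identity(self):
        x = np.array([[5.0, 7.0, 6.0]])
        t, row, col, _ = median_polish(x)
        np.testing.assert_allclose(t + col, x[0])

    def test_against_independent_oracle(self, rng):
        """100 random 11 x 8 blocks agree with the re-implementation to 1e-8."""
        for _ in range(100):
            x = rng.normal(8, 2, (11, 8))
            t, row, col, _ = median_polish(x)
            t2, _, col2 = median_polish_oracle(x)
            np.testing.assert_allclose(t + col, t2 + col2, atol=1e-8)

    def test_summarizer_over_design(self, small_experiment, pm_only_design):
        m = small_experiment.datasets["ff.B"]
        log2 = np.log2(m.values.loc[pm_only_design.pm_probes["probe_id"]])
        e = median_polish_summarize(log2, pm_only_design)
        assert e.level == "probeset"
        assert list(e.values.index) == list(pm_only_design.probesets.index)
        # summaries fall inside the probe-level value range per probeset
        ps0 = pm_only_design.probesets.index[0]
        probes0 = pm_only_design.pm_probes.query("probeset_id == @ps0")["probe_id"]
        lo, hi = log2.loc[probes0].min().min(), log2.loc[probes0].max().max()
        assert ((e.values.loc[ps0] >= lo - 1) & (e.values.loc[ps0] <= hi + 1)).all()

    def test_empty_probeset_errors(self):
        with pytest.raises(PreprocessError):
            median_polish(np.empty((0, 0)))


# ---------------------------------------------------------------------------
# gene collapse
# ---------------------------------------------------------------------------


class TestCollapseToGenes:
    def _design_with_duplicates(self, small_cfg):
        from dataclasses import replace

        from ffconcord.design import PM_ONLY
        from ffconcord.simulate import make_array_design

        cfg = replace(small_cfg, duplicate_probeset_frac=0.1)
        return make_array_design(cfg, PM_ONLY, "dup")

    def test_max_variance_probeset_wins(self, small_cfg, rng):
        design = self._design_with_duplicates(small_cfg)
        ps_ids = design.probesets.index
        vals = pd.DataFrame(
            rng.normal(8, 1, (len(ps_ids), 8)), index=ps_ids,
            columns=[f"s{i}" for i in range(8)],
        )
        e = ExpressionMatrix(level="probeset", values=vals)
        out = collapse_to_genes(e, design)
        # brute-force argmax-variance oracle per gene
        annotated = design.probesets[
            (~design.probesets["is_antigenomic"]) & design.probesets["gene_symbol"].notna()
        ]
        for gene, block in annotated.groupby("gene_symbol"):
            best = vals.loc[block.index].var(axis=1, ddof=1).idxmax()
            np.testing.assert_allclose(out.values.loc[gene], vals.loc[best])

    def test_forced_choice_zero_variance(self, small_cfg):
        design = self._design_with_duplicates(small_cfg)
        gene = design.probesets["gene_symbol"].dropna().iloc[0]
        dup = design.probesets.index[design.probesets["gene_symbol"] == gene]
        assert len(dup) == 2
        vals = pd.DataFrame(7.0, index=design.probesets.index, columns=list("abcd"))
        vals.loc[dup[1]] = [1.0, 5.0, 2.0, 9.0]  # variance 0.8-ish vs 0
        out = collapse_to_genes(ExpressionMatrix(level="probeset", values=vals), design)
        np.testing.assert_allclose(out.values.loc[gene], [1.0, 5.0, 2.0, 9.0])

    def test_antigenomic_dropped(self, pm_only_design, rng):
        vals = pd.DataFrame(
            rng.normal(8, 1, (len(pm_only_design.probesets), 4)),
            index=pm_only_design.probesets.index, columns=list("abcd"),
        )
        out = collapse_to_genes(ExpressionMatrix(level="probeset", values=vals), pm_only_design)
        assert not set(out.values.index) & set(pm_only_design.antigenomic_probesets)
        assert out.level == "gene"


class TestFullChain:
    def test_stage_contracts_and_positive_gene_matrix(self, small_experiment):
        """background-correct -> quantile -> log2 -> polish -> collapse."""
        exp = small_experiment
        ds = "ff.B"
        design = exp.truth.designs[exp.truth.dataset_design[ds]]
        log2probes, ps_expr, gene_expr = preprocess_dataset(exp.datasets[ds], design)
        # equal-distribution property survives into the log2 probe matrix
        sorted_cols = np.sort(log2probes.to_numpy(), axis=0)
        for j in range(1, sorted_cols.shape[1]):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-9)
        assert (gene_expr.values.to_numpy() > 0).all()
        assert gene_expr.level == "gene"
        assert ps_expr.values.shape[0] == len(design.probesets)
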