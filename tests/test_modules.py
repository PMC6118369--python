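"""Module representation, scoring, subsets and diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ffconcord.modules import (
    GeneModule,
    ModuleError,
    complement_subset,
    derive_module_subset,
    module_coherence,
    module_mean_expression,
    module_score,
    quartile_subsets,
    score_modules,
    validate_module_subset,
    weighted_average_score,
)


def _expr(data: dict, samples=None) -> pd.DataFrame:
    df = pd.DataFrame(data).T
    if samples:
        df.columns = samples
    return df


class TestGeneModule:
    def test_duplicate_genes_rejected(self):
        with pytest.raises(ModuleError, match="duplicate"):
            GeneModule("m", [("A", 1), ("A", -1)])

    def test_bad_weight_rejected(self):
        with pytest.raises(ModuleError, match="weights"):
            GeneModule("m", [("A", 2)])

    def test_empty_rejected(self):
        with pytest.raises(ModuleError, match="empty"):
            GeneModule("m", [])


class TestModuleScore:
    def test_singleton_identity(self):
        e = _expr({"ESR1": [7.3, 8.0]})
        s = module_score(e, GeneModule("m", [("ESR1", 1)]))
        np.testing.assert_allclose(s, [7.3, 8.0])

    def test_difference_of_class_means(self):
        e = _expr({"a": [5.0], "b": [7.0], "c": [4.0]})
        mod = GeneModule("m", [("a", 1), ("b", 1), ("c", -1)])
        assert module_score(e, mod).iloc[0] == pytest.approx(2.0)
        assert weighted_average_score(e, mod).iloc[0] == pytest.approx(8.0 / 3.0)

    def test_all_positive_equals_plain_mean(self, rng):
        e = pd.DataFrame(rng.uniform(4, 10, (6, 5)), index=list("abcdef"))
        mod = GeneModule("m", [(g, 1) for g in "abcdef"])
        np.testing.assert_allclose(module_score(e, mod), e.mean(axis=0))
        np.testing.assert_allclose(weighted_average_score(e, mod), e.mean(axis=0))

    def test_sign_property_random_fixtures(self, rng):
        """score > 0 exactly when mean(positives) > mean(negatives)."""
        for _ in range(300):
            n_pos = rng.integers(1, 5)
            n_neg = rng.integers(1, 5)
            genes = [f"g{i}" for i in range(n_pos + n_neg)]
            e = pd.DataFrame(rng.uniform(1, 12, (len(genes), 3)), index=genes)
            mod = GeneModule(
                "m", [(g, 1) for g in genes[:n_pos]] + [(g, -1) for g in genes[n_pos:]]
            )
            s = module_score(e, mod)
            pos_mean = e.loc[genes[:n_pos]].mean(axis=0)
            neg_mean = e.loc[genes[n_pos:]].mean(axis=0)
            np.testing.assert_array_equal(s > 0, pos_mean > neg_mean)

    def test_equal_class_sizes_match_per_class_weighted_average(self, rng):
        """With |pos| = |neg| = k, the difference of means equals
        sum(w*x)/k — the per-class-normalized weighted average."""
        for _ in range(50):
            k = int(rng.integers(1, 6))
            genes = [f"g{i}" for i in range(2 * k)]
            e = pd.DataFrame(rng.uniform(1, 12, (2 * k, 4)), index=genes)
            mod = GeneModule(
                "m", [(g, 1) for g in genes[:k]] + [(g, -1) for g in genes[k:]]
            )
            per_class = weighted_average_score(e, mod) * (2 * k) / k
            np.testing.assert_allclose(module_score(e, mod), per_class)

    def test_absent_genes_ignored_and_error_when_none(self):
        e = _expr({"a": [5.0]})
        mod = GeneModule("m", [("a", 1), ("zz", -1)])
        assert module_score(e, mod).iloc[0] == pytest.approx(5.0)
        with pytest.raises(ModuleError, match="no module genes"):
            module_score(e, GeneModule("m2", [("xx", 1)]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.permutations(list("abcde")))
    def test_gene_order_invariance(self, order):
        e = pd.DataFrame(
            np.arange(15, dtype=float).reshape(5, 3) + 1, index=list("abcde")
        )
        weights = dict(zip("abcde", [1, 1, -1, 1, -1]))
        base = module_score(e, GeneModule("m", [(g, weights[g]) for g in "abcde"]))
        perm = module_score(e, GeneModule("m", [(g, weights[g]) for g in order]))
        np.testing.assert_allclose(base, perm)

    def test_adding_gene_at_class_mean_is_neutral(self):
        e = _expr({"a": [5.0, 6.0], "b": [7.0, 8.0], "c": [4.0, 2.0]})
        mod = GeneModule("m", [("a", 1), ("b", 1), ("c", -1)])
        base = module_score(e, mod)
        e2 = e.copy()
        e2.loc["d"] = e.loc[["a", "b"]].mean(axis=0)
        mod2 = GeneModule("m", [("a", 1), ("b", 1), ("d", 1), ("c", -1)])
        np.testing.assert_allclose(module_score(e2, mod2), base)

    def test_score_modules_drops_small_modules(self, rng):
        e = pd.DataFrame(rng.uniform(1, 10, (4, 3)), index=list("abcd"))
        mods = [
            GeneModule("ok", [("a", 1), ("b", -1)]),
            GeneModule("toosmall", [("a", 1), ("zz", 1)]),  # 1 present gene
        ]
        out = score_modules(e, mods, min_size=2)
        assert list(out.index) == ["ok"]


class TestSubsets:
    MOD = GeneModule("m", [("a", 1), ("b", 1), ("c", -1), ("d", -1), ("e", 1)])

    def test_subset_keeps_weights(self):
        sub = derive_module_subset(self.MOD, {"a", "c", "e"})
        assert sub is not None
        assert dict(sub.genes) == {"a": 1, "c": -1, "e": 1}

    def test_small_subset_discarded(self):
        assert derive_module_subset(self.MOD, {"a"}) is None
        assert derive_module_subset(self.MOD, set()) is None

    def test_complement_partition(self):
        sel = {"a", "c", "e"}
        sub = derive_module_subset(self.MOD, sel)
        comp = complement_subset(self.MOD, sel)
        assert comp is not None
        assert set(sub.gene_symbols) | set(comp.gene_symbols) == set(self.MOD.gene_symbols)
        assert not set(sub.gene_symbols) & set(comp.gene_symbols)

    def test_complement_empty_when_all_selected(self):
        assert complement_subset(self.MOD, set(self.MOD.gene_symbols)) is None

    def test_cross_dataset_discard_matches_set_logic_oracle(self, rng):
        """any-version-below-minimum -> module dropped everywhere."""
        from ffconcord.concordance import cross_dataset_module_keep

        genes = [f"g{i}" for i in range(30)]
        modules = [
            GeneModule(
                f"m{k}",
                [(g, int(w)) for g, w in zip(
                    rng.choice(genes, size=rng.integers(3, 8), replace=False),
                    rng.choice([1, -1], 8),
                )],
            )
            for k in range(20)
        ]
        versions = {
            f"v{j}": set(rng.choice(genes, size=rng.integers(5, 25), replace=False))
            for j in range(10)
        }
        keep = cross_dataset_module_keep(modules, versions, min_size=2)
        for mod in modules:
            expected = all(
                len(set(mod.gene_symbols) & sel) >= 2 for sel in versions.values()
            )
            assert keep[mod.module_id] == expected


class TestQuartiles:
    def test_forced_partition_eight_genes(self):
        e = pd.DataFrame(
            {f"g{i}": [float(i + 1)] * 4 for i in range(8)}
        ).T
        mod = GeneModule("m", [(f"g{i}", 1) for i in range(8)])
        qs = quartile_subsets(mod, e)
        assert set(qs["q1"].gene_symbols) == {"g0", "g1"}
        assert set(qs["q2"].gene_symbols) == {"g2", "g3"}
        assert set(qs["q3"].gene_symbols) == {"g4", "g5"}
        assert set(qs["q4"].gene_symbols) == {"g6", "g7"}

    def test_four_genes_one_per_quartile(self):
        e = pd.DataFrame({f"g{i}": [float(i)] * 3 for i in range(4)}).T
        qs = quartile_subsets(GeneModule("m", [(f"g{i}", 1) for i in range(4)]), e)
        for k in range(4):
            assert qs[f"q{k + 1}"].gene_symbols == [f"g{k}"]

    def test_mean_ordering_property(self, rng):
        genes = [f"g{i}" for i in range(40)]
        e = pd.DataFrame(rng.uniform(2, 12, (40, 6)), index=genes)
        qs = quartile_subsets(GeneModule("m", [(g, 1) for g in genes]), e)
        means = [
            e.loc[qs[f"q{k}"].gene_symbols].mean(axis=1).mean() for k in (1, 2, 3, 4)
        ]
        assert means[0] < means[1] < means[2] < means[3]


class TestValidation:
    def test_identical_subset_kept(self, rng):
        s = pd.Series(rng.uniform(0, 5, 8))
        assert validate_module_subset(s, s.copy())

    def test_anti_monotone_dropped(self):
        s = pd.Series(np.arange(8.0))
        assert not validate_module_subset(s, s.iloc[::-1].reset_index(drop=True))

    def test_boundary_decisions_match_spearman_oracle(self, rng):
        for _ in range(100):
            a = pd.Series(rng.normal(0, 1, 8))
            b = pd.Series(a + rng.normal(0, rng.uniform(0.05, 1.0), 8))
            rho = stats.spearmanr(a, b).statistic
            assert validate_module_subset(a, b, 0.9) == (rho >= 0.9)

    def test_constant_vector_fails_with_warning(self):
        a = pd.Series(np.arange(8.0))
        with pytest.warns(UserWarning, match="constant"):
            assert not validate_module_subset(a, pd.Series(np.ones(8)))


class TestDiagnostics:
    def test_perfectly_correlated_pair_coherence_one(self):
        e = _expr({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        assert module_coherence(GeneModule("m", [("a", 1), ("b", 1)]), e) == pytest.approx(1.0)

    def test_constant_module_mean_expression(self):
        e = _expr({"a": [3.0] * 4, "b": [3.0] * 4})
        assert module_mean_expression(GeneModule("m", [("a", 1), ("b", 1)]), e) == 3.0

    def test_coherence_matches_all_pairs_oracle(self, rng):
        genes = list("abcdefg")
        e = pd.DataFrame(rng.normal(8, 2, (7, 10)), index=genes)
        got = module_coherence(GeneModule("m", [(g, 1) for g in genes]), e)
        rhos = []
        for i in range(7):
            for j in range(i + 1, 7):
                rhos.append(stats.spearmanr(e.iloc[i], e.iloc[j]).statistic)
        assert got == pytest.approx(np.mean(rhos), abs=1e-10)

    def test_quartile_top_correlates_at_least_as_well_as_bottom(self):
        """q4 (bright-gene) subsets track reference full-module scores no
        worse than q1 subsets on degraded data, averaged over modules."""
        import warnings

        from ffconcord.concordance import robust_module_correlation
        from ffconcord.preprocess import preprocess_dataset
        from ffconcord.simulate import (
            SimulationConfig,
            make_module_collection,
            simulate_matched_experiment,
        )

        cfg = SimulationConfig(
            seed=7, n_genes=400, n_de_genes=20, n_antigenomic=15,
            degradation_severity={"ffpe.A": 0.8, "ffpe.B1": 0.7, "ffpe.B2": 0.7},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            exp = simulate_matched_experiment(cfg)
            design_b = exp.truth.designs[exp.truth.dataset_design["ff.B"]]
            _, _, ref = preprocess_dataset(exp.datasets["ff.B"], design_b)
            tests = {
                ds: preprocess_dataset(exp.datasets[ds], design_b)[2]
                for ds in ("ffpe.B1", "ffpe.B2")
            }
            mods = make_module_collection(exp.truth, cfg, n_random=40)
            diffs = []
            for test in tests.values():
                for mod in mods:
                    present = [g for g in mod.gene_symbols if g in test.values.index]
                    if len(present) < 12:
                        continue
                    qs = quartile_subsets(mod, test.values)
                    if qs["q1"] is None or qs["q4"] is None:
                        continue
                    full_ref = module_score(ref.values, mod)
                    r4, _ = robust_module_correlation(
                        full_ref, module_score(test.values, qs["q4"])
                    )
                    r1, _ = robust_module_correlation(
                        full_ref, module_score(test.values, qs["q1"])
                    )
                    diffs.append(r4 - r1)
        assert len(diffs) >= 20
        assert np.mean(diffs) >= 0.0
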