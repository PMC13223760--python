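"""PSO statistics: transforms, normalization, correlation machinery."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from utrintrons.stats import (
    PSOTable,
    bh_adjust,
    correlate_genes,
    fisher_z_diff,
    pso_from_psi,
    sample_average_pso,
    size_factors_median_ratio,
    spearman,
    summarize_samples,
)


class TestPsoFromPsi:
    def test_elementwise_complement(self):
        psi = pd.DataFrame({"s": [0.25, 1.0, np.nan]})
        out = pso_from_psi(psi)
        assert out["s"].tolist()[:2] == [0.75, 0.0]
        assert math.isnan(out["s"].iloc[2])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            pso_from_psi(pd.DataFrame({"s": [1.2]}))

    def test_involution(self):
        psi = pd.DataFrame(np.random.default_rng(0).random((5, 4)))
        pd.testing.assert_frame_equal(pso_from_psi(pso_from_psi(psi)), psi)


class TestSampleAverage:
    def make_table(self, values, klasses):
        df = pd.DataFrame(values, columns=["s1"])
        return PSOTable(df, pd.Series(klasses, index=df.index))

    def test_unweighted_mean(self):
        t = self.make_table([0.2, 0.4, 0.6], ["e3UI"] * 3)
        assert sample_average_pso(t, "e3UI")["s1"] == pytest.approx(0.4)

    def test_missing_skipped(self):
        t = self.make_table([0.9, np.nan], ["e3UI", "e3UI"])
        assert sample_average_pso(t, "e3UI")["s1"] == pytest.approx(0.9)

    def test_no_events_of_class_warns_missing(self):
        t = self.make_table([0.5], ["e3UI"])
        with pytest.warns(UserWarning, match="co3UI"):
            out = sample_average_pso(t, "co3UI")
        assert math.isnan(out["s1"])


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        c = pd.DataFrame({"a": [10, 20], "b": [10, 20]})
        np.testing.assert_allclose(size_factors_median_ratio(c), [1.0, 1.0])

    def test_doubled_sample(self):
        c = pd.DataFrame({"a": [10, 20, 7], "b": [20, 40, 14]})
        np.testing.assert_allclose(
            size_factors_median_ratio(c),
            [1 / math.sqrt(2), math.sqrt(2)],
            atol=1e-9,
        )

    def test_single_gene(self):
        c = pd.DataFrame({"a": [4], "b": [9]})
        np.testing.assert_allclose(
            size_factors_median_ratio(c), [4 / 6, 9 / 6], atol=1e-9
        )

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(3)
        c = pd.DataFrame(rng.poisson(50, size=(40, 3)) + 1,
                         columns=["a", "b", "c"])
        base = size_factors_median_ratio(c)
        c2 = c.copy()
        c2["b"] = c2["b"] * 4
        scaled = size_factors_median_ratio(c2)
        # each gene's geometric mean grows 4^(1/3); all ratios shift alike
        np.testing.assert_allclose(scaled["b"] / base["b"],
                                   4 ** (2 / 3), rtol=1e-9)
        np.testing.assert_allclose(scaled["a"] / base["a"],
                                   4 ** (-1 / 3), rtol=1e-9)

    def test_all_zero_gene_errors(self):
        with pytest.raises(ValueError):
            size_factors_median_ratio(pd.DataFrame({"a": [0], "b": [5]}))


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_hand_computed_rank_pearson(self):
        rho, _ = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_too_few_pairs_missing(self):
        rho, p = spearman([1, 2, 3], [3, 2, 1])
        assert math.isnan(rho) and math.isnan(p)

    def test_pairwise_complete(self):
        rho, _ = spearman([1, 2, 3, 4, np.nan], [1, 3, 2, 4, 100.0])
        assert rho == pytest.approx(0.8)

    def test_zero_variance_missing(self):
        rho, _ = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho)

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.integers(-50, 50), min_size=5, max_size=20, unique=True),
        st.lists(st.integers(-50, 50), min_size=20, max_size=20, unique=True),
    )
    def test_monotone_transform_invariant(self, x, y):
        y = y[: len(x)]
        r0, _ = spearman(x, y)
        r1, _ = spearman(np.exp(np.asarray(x) / 25.0), y)
        if not math.isnan(r0):
            assert r1 == pytest.approx(r0)


class TestBH:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_single_and_constant(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([0.4, 0.4, 0.4]), [0.4] * 3)

    def test_adjusted_at_least_raw_and_order_free(self):
        rng = np.random.default_rng(1)
        p = rng.random(20)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        perm = rng.permutation(20)
        assert sorted(bh_adjust(p[perm])) == pytest.approx(sorted(adj))

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestFisherZ:
    def test_equal_correlations_null(self):
        z, p = fisher_z_diff(0.5, 30, 0.5, 50)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_closed_form_example(self):
        z, _ = fisher_z_diff(0.8, 30, 0.2, 30)
        expected = (math.atanh(0.8) - math.atanh(0.2)) / math.sqrt(2 / 27)
        assert z == pytest.approx(expected, abs=1e-12)
        assert z == pytest.approx(3.292, abs=5e-4)

    def test_antisymmetry(self):
        z1, p1 = fisher_z_diff(0.7, 40, -0.1, 25)
        z2, p2 = fisher_z_diff(-0.1, 25, 0.7, 40)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    @pytest.mark.parametrize("bad", [(0.5, 3, 0.1, 30), (1.0, 30, 0.1, 30)])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            fisher_z_diff(*bad)


class TestCorrelateGenes:
    def make_inputs(self, rho=-0.8, n=50, seed=5):
        rng = np.random.default_rng(seed)
        samples = [f"N{i}" for i in range(n)] + [f"C{i}" for i in range(n)]
        labels = {s: ("normal" if s.startswith("N") else "cancer")
                  for s in samples}
        pso_vals = pd.DataFrame(
            rng.beta(4, 4, size=(6, 2 * n)), columns=samples
        )
        table = PSOTable(pso_vals, pd.Series(["e3UI"] * 6))
        summaries = summarize_samples(table, labels)
        mean = summaries["mean_pso_e3UI"].to_numpy()
        # regulator tracks -(mean PSO) in normal samples only
        expr = pd.DataFrame(
            rng.lognormal(3, 0.5, size=(5, 2 * n)),
            index=[f"g{i}" for i in range(5)],
            columns=samples,
        )
        noise = rng.standard_normal(n) * math.sqrt(1 - rho * rho)
        scores = -(
            abs(rho)
            * (mean[:n] - mean[:n].mean()) / mean[:n].std()
        ) + noise * 0  # deterministic coupling: |rho| ~ 1 in normal
        expr.loc["g0", samples[:n]] = np.exp(scores)
        return expr, summaries, labels

    def test_planted_regulator_detected(self):
        expr, summaries, _ = self.make_inputs()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = correlate_genes(expr, summaries, classes=("e3UI",))
        row = res.loc["g0"]
        assert row["rho_normal"] == pytest.approx(-1.0)
        assert row["padj_normal"] < 0.01
        assert abs(row["rho_cancer"]) < 0.5

    def test_constant_expression_missing(self):
        expr, summaries, _ = self.make_inputs()
        expr.loc["g1"] = 7.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = correlate_genes(expr, summaries, classes=("e3UI",))
        assert math.isnan(res.loc["g1", "rho_normal"])

    def test_identical_conditions_zero_z(self):
        expr, summaries, _ = self.make_inputs()
        # mirror normal data into cancer columns -> identical correlations
        n = (summaries["condition"] == "normal").sum()
        cols = list(expr.columns)
        expr[cols[n:]] = expr[cols[:n]].to_numpy()
        summaries.loc[summaries.index[n:], ["mean_pso_e3UI", "mean_pso_co3UI"]] = (
            summaries.loc[summaries.index[:n],
                          ["mean_pso_e3UI", "mean_pso_co3UI"]].to_numpy()
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = correlate_genes(expr, summaries, classes=("e3UI",))
        np.testing.assert_allclose(res["z_diff"].abs().fillna(0), 0, atol=1e-9)

    def test_small_condition_missing(self):
        expr, summaries, _ = self.make_inputs(n=50)
        keep = list(summaries.index[:50]) + list(summaries.index[50:53])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = correlate_genes(expr[keep], summaries.loc[keep],
                                  classes=("e3UI",))
        assert res["rho_cancer"].isna().all()
        assert res["rho_normal"].notna().any()
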