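"""RPM, distance to the median, frequency, correlations, similarity ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scdrift.core_io import ExpressionMatrix
from scdrift.synthetic_data import SimExprSpec, simulate_expression
from scdrift.txn_variability import (
    cell_correlation_analysis,
    distance_to_median,
    expression_frequency,
    normalise_rpm,
    similarity_to_young,
    top_variable_genes,
)


def toy_matrix(counts, totals):
    frame = pd.DataFrame(counts)
    return ExpressionMatrix(counts=frame, mapped_total=pd.Series(totals))


class TestNormaliseRPM:
    def test_direct_value(self):
        m = toy_matrix({"c1": [5, 0]}, {"c1": 1e6})
        rpm = normalise_rpm(m)
        assert rpm.loc[0, "c1"] == 5.0

    def test_scale_invariance_per_cell(self):
        m1 = toy_matrix({"c1": [5, 10]}, {"c1": 2e5})
        m2 = toy_matrix({"c1": [10, 20]}, {"c1": 4e5})
        assert normalise_rpm(m1).equals(normalise_rpm(m2))

    def test_column_sum_is_assigned_fraction_of_1e6(self):
        m = toy_matrix({"c1": [30, 70]}, {"c1": 400.0})
        # assigned/mapped = 100/400 -> column sum = 0.25e6
        assert normalise_rpm(m)["c1"].sum() == pytest.approx(0.25e6)


class TestDistanceToMedian:
    def test_flat_cv2_gives_zero_dm(self, rng):
        n = 150
        means = np.linspace(20, 500, n)
        # construct genes whose sample cv2 is identical: two-point design
        cells = 40
        counts = {}
        for j in range(cells):
            counts[f"c{j}"] = means * (1.2 if j % 2 else 0.8)
        norm = pd.DataFrame(counts, index=[f"g{i}" for i in range(n)])
        out = distance_to_median(norm, min_mean=10, window=50)
        assert np.allclose(out["dm"], 0.0, atol=1e-10)

    def test_min_mean_excludes_genes(self, rng):
        norm = pd.DataFrame(
            rng.poisson(50, size=(120, 30)).astype(float),
            index=[f"g{i}" for i in range(120)],
        )
        norm.loc["low"] = 9.9
        norm.loc["low", norm.columns[0]] = 10.0  # mean still < 10
        out = distance_to_median(norm, min_mean=10, window=50)
        assert "low" not in out.index

    def test_too_few_genes_errors(self, rng):
        norm = pd.DataFrame(rng.poisson(50, size=(20, 10)).astype(float))
        with pytest.raises(ValueError, match="window"):
            distance_to_median(norm, min_mean=10, window=100)

    def test_dm_uncorrelated_with_mean_and_recovers_dispersion(self):
        # NB counts, equal dispersion except an inflated block
        disp = tuple([0.1] * 1800 + [0.5] * 200)
        spec = SimExprSpec(
            n_genes=2000, n_cells=200,
            mean_grid=tuple(np.geomspace(20, 2000, 40)),
            dispersion=disp, seed=42, mapped_offset=0,
        )
        m = simulate_expression(spec)
        norm = normalise_rpm(m)
        out = distance_to_median(norm, min_mean=10, window=100)
        rho = stats.spearmanr(out["dm"], out["mean_rpm"]).statistic
        assert abs(rho) < 0.1
        inflated = out.index.str.slice(5).astype(int) >= 1800
        ranks = stats.rankdata(out["dm"])
        n1, n0 = inflated.sum(), (~inflated).sum()
        auc = (ranks[inflated].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        assert auc > 0.9

    def test_dm_invariant_to_global_depth_rescaling(self, rng):
        counts = pd.DataFrame(
            rng.poisson(100, size=(150, 30)).astype(float),
            index=[f"g{i}" for i in range(150)],
        )
        totals = pd.Series(1e5, index=counts.columns)
        m1 = ExpressionMatrix(counts=counts, mapped_total=totals)
        m2 = ExpressionMatrix(counts=counts, mapped_total=totals * 4)
        out1 = distance_to_median(normalise_rpm(m1), min_mean=10, window=50)
        out2 = distance_to_median(normalise_rpm(m2), min_mean=10 / 4, window=50)
        assert np.allclose(out1["dm"], out2["dm"])


class TestExpressionFrequency:
    def test_fraction_of_expressing_cells(self):
        m = toy_matrix(
            {"y1": [0, 3], "y2": [0, 0], "o1": [3, 5], "o2": [5, 0]},
            {c: 1e5 for c in ("y1", "y2", "o1", "o2")},
        )
        labels = pd.Series(
            {"y1": "young", "y2": "young", "o1": "old", "o2": "old"}
        )
        out = expression_frequency(m, labels)
        assert out.loc[0, "freq_young"] == 0.0
        assert out.loc[0, "freq_old"] == 1.0
        assert out.loc[1, "freq_young"] == 0.5
        assert out.loc[1, "delta_freq"] == pytest.approx(0.0)

    def test_dropout_simulation_recovers_flagged_genes(self):
        spec_y = SimExprSpec(n_genes=300, n_cells=120, mean_grid=(3.0,),
                             dropout_logit_params=(np.log(9.0), 0.0), seed=1)
        spec_o = SimExprSpec(n_genes=300, n_cells=120, mean_grid=(3.0,),
                             dropout_logit_params=(np.log(7 / 3), 0.0), seed=2)
        my, mo = simulate_expression(spec_y), simulate_expression(spec_o)
        counts = pd.concat(
            [my.counts.add_prefix("y"), mo.counts.add_prefix("o")], axis=1
        )
        m = ExpressionMatrix(
            counts=counts, mapped_total=pd.Series(1e5, index=counts.columns)
        )
        labels = pd.Series(
            ["young"] * 120 + ["old"] * 120, index=counts.columns
        )
        out = expression_frequency(m, labels)
        # detection 0.9 vs 0.7 on non-zero draws; P(count>0 | detected) ~ 0.95
        observed = out["delta_freq"].mean()
        se = out["delta_freq"].std(ddof=1) / np.sqrt(len(out))
        assert observed > 0.1
        assert out["flagged"].mean() > 0.5


class TestTopVariableGenes:
    def frame(self):
        return pd.DataFrame(
            {"dm": [0.5, 0.9, 0.9, 0.1]},
            index=pd.Index(["gB", "gC", "gA", "gD"], name="gene_id"),
        )

    def test_unique_max(self):
        assert top_variable_genes(self.frame(), 1) == ["gA"]

    def test_tie_broken_lexicographically(self):
        assert top_variable_genes(self.frame(), 2) == ["gA", "gC"]

    def test_overflow_returns_all_with_warning(self):
        with pytest.warns(UserWarning):
            got = top_variable_genes(self.frame(), 10)
        assert len(got) == 4


class TestCellCorrelation:
    def test_duplicated_cells_have_rho_one(self, rng):
        base = rng.poisson(50, size=100).astype(float)
        norm = pd.DataFrame({"c1": base, "c2": base, "c3": base[::-1]})
        pairs, _ = cell_correlation_analysis(norm, norm.index)
        row = pairs.set_index(["cell_i", "cell_j"]).loc[("c1", "c2"), "rho"]
        assert row == pytest.approx(1.0)

    def test_cohort_means_deterministic_given_seed(self, rng):
        norm = pd.DataFrame(
            rng.poisson(30, size=(80, 25)).astype(float),
            columns=[f"c{i}" for i in range(25)],
        )
        _, a = cell_correlation_analysis(norm, norm.index, cohort_size=5,
                                         n_iter=20, seed=3)
        _, b = cell_correlation_analysis(norm, norm.index, cohort_size=5,
                                         n_iter=20, seed=3)
        assert a.equals(b)

    def test_low_dispersion_group_more_correlated(self):
        young = simulate_expression(SimExprSpec(
            n_genes=300, n_cells=30, mean_grid=(50.0, 200.0), dispersion=0.1,
            seed=5, mapped_offset=0))
        old = simulate_expression(SimExprSpec(
            n_genes=300, n_cells=30, mean_grid=(50.0, 200.0), dispersion=0.4,
            seed=6, mapped_offset=0))
        counts = pd.concat(
            [young.counts.add_prefix("y"), old.counts.add_prefix("o")], axis=1)
        norm = counts.astype(float)
        groups = pd.Series(["young"] * 30 + ["old"] * 30, index=counts.columns)
        pairs, cohorts = cell_correlation_analysis(
            norm, norm.index, groups=groups, cohort_size=10, n_iter=50, seed=9)
        mean_by_group = cohorts.groupby("group")["mean_rho"].mean()
        assert mean_by_group["young"] > mean_by_group["old"]


class TestSimilarityToYoung:
    def test_reference_clone_ranks_first(self, rng):
        genes = [f"g{i}" for i in range(60)]
        young = pd.DataFrame(
            rng.poisson(40, size=(60, 5)).astype(float),
            index=genes, columns=[f"y{i}" for i in range(5)])
        reference_linear = 2 ** np.log2(young + 1).mean(axis=1) - 1
        old = pd.DataFrame({
            "clone": reference_linear,
            "shuffled": reference_linear.sample(frac=1, random_state=0).to_numpy(),
        }, index=genes)
        norm = pd.concat([young, old], axis=1)
        res = similarity_to_young(norm, list(young.columns), ["clone", "shuffled"])
        assert res.records.index[0] == "clone"
        assert res.records.loc["clone", "rho"] == pytest.approx(1.0)

    def test_min_cells_gene_filter(self, rng):
        genes = [f"g{i}" for i in range(30)]
        norm = pd.DataFrame(
            rng.poisson(20, size=(30, 8)).astype(float) + 1.0,
            index=genes, columns=[f"c{i}" for i in range(8)])
        norm.loc["rare"] = 0.0
        norm.loc["rare", ["c0", "c1", "c2", "c3"]] = 5.0  # 4 cells < 5
        res = similarity_to_young(norm, ["c0", "c1", "c2"],
                                  ["c3", "c4", "c5", "c6", "c7"])
        assert "rare" not in res.gene_correlations.index

    def test_gradient_recovered(self, rng):
        # old cells interpolate between the young mean and a perturbed state
        genes = [f"g{i}" for i in range(200)]
        young_mean = rng.uniform(2, 8, size=200)
        perturbed = rng.permutation(young_mean)
        young = pd.DataFrame(
            {f"y{i}": 2 ** young_mean - 1 for i in range(4)}, index=genes)
        alphas = np.linspace(0, 1, 12)
        old = pd.DataFrame(
            {f"o{i}": 2 ** ((1 - a) * young_mean + a * perturbed) - 1
             for i, a in enumerate(alphas)}, index=genes)
        norm = pd.concat([young, old], axis=1)
        res = similarity_to_young(norm, list(young.columns), list(old.columns))
        recovered = [int(c[1:]) for c in res.records.index]
        rho = stats.spearmanr(recovered, np.arange(12)).statistic
        assert rho > 0.95

    def test_ranking_invariant_to_gene_order_and_failing_genes(self, rng):
        genes = [f"g{i}" for i in range(50)]
        norm = pd.DataFrame(
            rng.poisson(25, size=(50, 10)).astype(float) + 1.0,
            index=genes, columns=[f"c{i}" for i in range(10)])
        young, old = [f"c{i}" for i in range(5)], [f"c{i}" for i in range(5, 10)]
        base = similarity_to_young(norm, young, old)
        shuffled = norm.sample(frac=1, random_state=1)
        extra = pd.concat([shuffled, pd.DataFrame(
            0.0, index=["dead1", "dead2"], columns=norm.columns)])
        res = similarity_to_young(extra, young, old)
        assert list(res.records.index) == list(base.records.index)
        assert np.allclose(res.records["rho"], base.records["rho"])
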