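"""Tests for the four stress-test experiments (at reduced problem sizes).

The full-size study conditions are exercised by the acceptance suite; here
the same machinery runs on smaller grids to check structure, determinism,
failure handling, and the qualitative science.
"""

import pandas as pd
import pytest

from foldbench import FCMethod, Family, PanelSpec, generate_panel
from foldbench.experiments import (
    NON_BOOTSTRAP_METHODS,
    lognormal_mean_bias_bits,
    run_distribution_stress,
    run_permutation_stress,
    run_significance_panel,
    run_variance_sweep,
)
from foldbench.simulate import SimSpec, generate
from foldbench.core import log_ratio


@pytest.fixture(scope="module")
def small_stress():
    return run_distribution_stress(
        n_levels=(10, 2000),
        fc_grid=(1 / 3, 1.0, 3.0),
        methods=NON_BOOTSTRAP_METHODS,
        reps=3,
        seed=7,
    )


@pytest.fixture(scope="module")
def small_sweep():
    return run_variance_sweep(
        fc_grid=(0.25, 0.5, 1.0, 2.0, 4.0),
        s_ratio_grid=(0.5, 1.0, 2.0),
        s_a_levels=(1.0,),
        n=2000,
        reps=4,
        methods=(FCMethod.LOG_OF_MEANS, FCMethod.MEAN_OF_LOGS),
        seed=11,
    )


class TestDistributionStress:
    def test_identity_rows_recover_exactly(self, small_stress):
        summ = small_stress.summary
        ident = summ[(summ["family"] == "identity") & (summ["transform"] == "raw")]
        assert (ident["mean_abs_error"].abs() < 1e-9).all()

    def test_cells_carry_generating_spec(self, small_stress):
        cells = small_stress.cells
        for col in ("family", "fc_true", "n", "s_a", "s_b", "m_a", "seed",
                    "replicate", "method", "transform"):
            assert col in cells.columns

    def test_cells_recomputable_from_recorded_seed(self, small_stress):
        row = small_stress.cells.query(
            "family == 'lognormal' and transform == 'raw' "
            "and method == 'MEAN_OF_LOGS' and not failed"
        ).iloc[0]
        spec = SimSpec(
            family=Family(row["family"]), m_a=row["m_a"], fc_true=row["fc_true"],
            s_a=row["s_a"], s_b=row["s_b"], n_a=int(row["n"]), n_b=int(row["n"]),
            seed=int(row["seed"]),
        )
        lr = log_ratio(generate(spec), FCMethod.MEAN_OF_LOGS)
        assert lr == pytest.approx(row["log_ratio"], abs=1e-12)

    def test_rerun_with_same_seed_is_identical(self):
        kwargs = dict(n_levels=(50,), fc_grid=(2.0,), reps=2, seed=3,
                      methods=(FCMethod.PAIRS_MEDIAN_BOOTSTRAP,))
        r1 = run_distribution_stress(**kwargs)
        r2 = run_distribution_stress(**kwargs)
        pd.testing.assert_frame_equal(r1.cells, r2.cells)

    def test_arithmetic_mean_worst_on_cross_family_rows(self):
        """Mean-based ratios inflate by exp(s^2/2) when exactly one group is
        log-normal; median-based ratios do not."""
        rep = run_distribution_stress(
            n_levels=(2000,), fc_grid=(2.0,), reps=5, relog=False, seed=13,
            methods=(FCMethod.LOG_OF_MEANS, FCMethod.LOG_OF_MEDIANS,
                     FCMethod.MEAN_OF_LOGS),
        )
        summ = rep.summary
        for fam in ("mixed_normal_lognormal", "mixed_lognormal_normal"):
            sub = summ[summ["family"] == fam].set_index("method")
            assert (
                sub.loc["LOG_OF_MEANS", "mean_abs_error"]
                > sub.loc["LOG_OF_MEDIANS", "mean_abs_error"]
            )
            assert (
                sub.loc["LOG_OF_MEANS", "mean_abs_error"]
                > sub.loc["MEAN_OF_LOGS", "mean_abs_error"]
            )

    def test_relog_preserves_ranking_on_identity_and_normal(self):
        rep = run_distribution_stress(
            n_levels=(2000,),
            fc_grid=(1 / 3, 0.5, 1.0, 2.0, 3.0),
            methods=(FCMethod.LOG_OF_MEANS, FCMethod.MEDIAN_OF_LOGS),
            reps=5, relog=True, seed=17,
        )
        ranks = rep.tables["relog_rank_preservation"]
        ident = ranks[ranks["family"] == "identity"]
        assert (ident["rank_spearman_raw_vs_relog"] > 1 - 1e-9).all()
        normal = ranks[ranks["family"] == "normal"]
        assert (normal["rank_spearman_raw_vs_relog"] > 0.9).all()

    def test_small_n_failures_recorded_not_raised(self):
        """Normal draws at tiny m/s ratios can go non-positive; such cells
        become failure records instead of aborting the grid."""
        rep = run_distribution_stress(
            n_levels=(200,), fc_grid=(1.0,), reps=2, relog=False, seed=5,
            m_a=10.0, s_normal=10.0,
            methods=(FCMethod.MEAN_OF_LOGS,),
            families=(Family.NORMAL,),
        )
        assert rep.cells["failed"].any()
        assert rep.cells.loc[rep.cells["failed"], "failure"].str.len().gt(0).all()


class TestVarianceSweep:
    def test_equal_spread_panel_near_zero_error(self, small_sweep):
        summ = small_sweep.summary
        eq = summ[(summ["s_ratio"] == 1.0) & (summ["method"] == "LOG_OF_MEANS")]
        # at s_a = s_b the closed-form bias vanishes; fc_true = 1 sits on the
        # signed-fold scale's +1/-1 gap where any sampling noise produces an
        # O(2) jump, so the boundary cell is judged separately below
        off_boundary = eq[eq["fc_true"] != 1.0]
        assert off_boundary["mean_error"].abs().max() < 0.35
        # at the boundary the log-ratio itself is still unbiased
        boundary = eq[eq["fc_true"] == 1.0]
        assert boundary["mean_log_ratio"].abs().max() < 0.1

    def test_unequal_spread_error_sign_matches_bias_direction(self, small_sweep):
        """Estimated ratio is fc * exp((s_b^2-s_a^2)/2): below truth for
        s_b < s_a, above it for s_b > s_a, across the whole fc grid."""
        summ = small_sweep.summary
        lom = summ[summ["method"] == "LOG_OF_MEANS"]
        below = lom[lom["s_ratio"] == 0.5]
        above = lom[lom["s_ratio"] == 2.0]
        assert (below["mean_error"] < 0).all()
        assert (above["mean_error"] > 0).all()

    def test_error_trend_reverses_direction_at_fc_one(self):
        """In the s_b != s_a panels the error-vs-fc trend flips slope at
        fc = 1 (the reported direction reversal)."""
        from scipy.stats import linregress

        rep = run_variance_sweep(
            fc_grid=(0.2, 0.4, 0.6, 0.8, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0),
            s_ratio_grid=(0.5,), s_a_levels=(1.0,), n=4000, reps=6,
            methods=(FCMethod.LOG_OF_MEANS,), seed=19,
        )
        summ = rep.summary.sort_values("fc_true")
        low = summ[summ["fc_true"] < 1.0]
        high = summ[summ["fc_true"] > 1.0]
        slope_low = linregress(low["fc_true"], low["mean_error"]).slope
        slope_high = linregress(high["fc_true"], high["mean_error"]).slope
        assert slope_low > 0 > slope_high

    def test_trend_table_contains_ols_fit_per_panel(self, small_sweep):
        trends = small_sweep.tables["trends"]
        assert set(trends["method"]) == {"LOG_OF_MEANS", "MEAN_OF_LOGS"}
        assert {"slope", "intercept", "rvalue"} <= set(trends.columns)

    def test_robust_method_beats_arithmetic_mean_under_unequal_spread(
        self, small_sweep
    ):
        summ = small_sweep.summary
        uneq = summ[summ["s_ratio"] != 1.0]
        worst = uneq.groupby("method")["mean_abs_error"].max()
        assert worst["MEAN_OF_LOGS"] < worst["LOG_OF_MEANS"]

    def test_predicted_bias_column_matches_closed_form(self, small_sweep):
        cells = small_sweep.cells
        row = cells.iloc[0]
        assert row["predicted_bias_bits"] == pytest.approx(
            lognormal_mean_bias_bits(row["s_a"], row["s_b"])
        )


@pytest.fixture(scope="module")
def report():
    return run_significance_panel(
        d=40,
        methods=(FCMethod.LOG_OF_MEANS, FCMethod.MEAN_OF_LOGS,
                 FCMethod.LOG_OF_MEDIANS, FCMethod.PAIRS_MEDIAN),
        seed=23,
    )


class TestSignificancePanel:
    def test_normal_panel_correlations_positive_and_tight(self, report):
        summ = report.summary
        normal = summ[summ["family"] == "normal"]
        assert (normal["rho_significance"] > 0).all()
        for _, grp in normal.groupby("test"):
            assert grp["rho_significance"].max() - grp["rho_significance"].min() < 0.15

    def test_crossovers_only_on_lognormal_panel(self, report):
        x = report.tables["crossovers"]
        assert (x["family"] == "lognormal").all()
        assert len(x) >= 1

    def test_estimates_correlate_with_true_fc(self, report):
        normal = report.summary[report.summary["family"] == "normal"]
        assert (normal["rho_true_fc"] > 0.5).all()

    def test_volcano_table_is_tidy(self, report):
        cells = report.cells
        expected = {"variable_id", "method", "log_ratio", "fc", "test",
                    "p_value", "neg_log10_p"}
        assert expected <= set(cells.columns)
        counts = cells.groupby(["family", "variable_id"]).size()
        assert (counts == 4 * 2).all()  # 4 methods x 2 tests

    def test_degenerate_constant_fc_panel_flagged(self):
        rep = run_significance_panel(
            d=3, families=(Family.LOGNORMAL,), ratio_range=(1.0, 1.0),
            methods=(FCMethod.MEAN_OF_LOGS,), seed=2,
        )
        # |log2 fc_true| is constant, so its correlation is undefined
        assert rep.summary["rho_true_fc"].isna().all()


@pytest.fixture(scope="module")
def mixed_matrix():
    panel = generate_panel(PanelSpec(d=40, family=None, n_a=12, n_b=15, seed=29))
    return panel.to_matrix()


class TestPermutationStress:
    def test_value_multiset_conserved(self, mixed_matrix):
        matrix, labels = mixed_matrix
        rep = run_permutation_stress(
            matrix, labels, methods=(FCMethod.MEAN_OF_LOGS,), seed=1
        )
        assert rep.tables["pooled_moments"]["n_values"].iloc[0] == matrix.size
        # skewness of the pooled values survives permutation by construction
        from scipy.stats import skew

        assert rep.tables["pooled_moments"]["skewness"].iloc[0] == pytest.approx(
            float(skew(matrix.to_numpy().ravel()))
        )

    def test_unpermuted_all_normal_panel_methods_agree(self):
        panel = generate_panel(
            PanelSpec(d=60, family=Family.NORMAL, normal_s_range=(20.0, 80.0),
                      n_a=25, n_b=25, seed=41)
        )
        matrix, labels = panel.to_matrix()
        rep = run_permutation_stress(
            matrix, labels, permute=False, seed=1,
            methods=NON_BOOTSTRAP_METHODS,
        )
        corr = rep.tables["method_correlations"]
        assert (corr.to_numpy() > 0.95).all()

    def test_permuted_run_reports_method_and_test_tables(self, mixed_matrix):
        matrix, labels = mixed_matrix
        rep = run_permutation_stress(
            matrix, labels,
            methods=(FCMethod.LOG_OF_MEANS, FCMethod.PAIRS_MEDIAN), seed=3,
        )
        assert rep.tables["method_correlations"].shape == (2, 2)
        assert set(rep.summary["test"]) == {"WILCOXON_MWU", "T_TEST"}

    def test_pairs_median_tracks_wilcoxon_best_on_permuted_data(self):
        """After global permutation each variable's groups are random draws
        from a wildly skewed pool; the paired-median estimator agrees most
        strongly with the rank test's significance ordering."""
        panel = generate_panel(PanelSpec(d=200, family=None, n_a=20, n_b=25,
                                         seed=47))
        matrix, labels = panel.to_matrix()
        rep = run_permutation_stress(
            matrix, labels, seed=47, methods=NON_BOOTSTRAP_METHODS
        )
        wilcoxon = rep.summary[
            rep.summary["test"] == "WILCOXON_MWU"
        ].set_index("method")["rho"]
        assert wilcoxon.idxmax() == "PAIRS_MEDIAN"
        assert wilcoxon["PAIRS_MEDIAN"] > wilcoxon["LOG_OF_MEANS"]

    def test_report_write_round_trip(self, tmp_path, mixed_matrix):
        matrix, labels = mixed_matrix
        rep = run_permutation_stress(
            matrix, labels, methods=(FCMethod.MEAN_OF_LOGS,), seed=3
        )
        written = rep.write(tmp_path)
        assert (tmp_path / "permutation_stress_cells.tsv").exists()
        assert (tmp_path / "permutation_stress_manifest.json").exists()
        back = pd.read_csv(tmp_path / "permutation_stress_cells.tsv", sep="\t")
        assert len(back) == len(rep.cells)

    def test_optional_plot_output(self, tmp_path, small_sweep):
        written = small_sweep.write(tmp_path, plots=True)
        pngs = [p for p in written if p.suffix == ".png"]
        assert pngs and all(p.exists() for p in pngs)
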