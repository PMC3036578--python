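"""Design construction, execution plumbing, ANOVA partitioning, aggregates."""

import numpy as np
import pandas as pd
import pytest

from netherit.experiments import (
    SingularDesignError,
    aic_comparison,
    build_design,
    execute_design,
    partition_variance,
    summarize_figures,
    write_summary,
)
from netherit.genotype import InvalidParameterError


class TestBuildDesign:
    def test_published_run_counts(self):
        assert build_design("network_main").n_runs == 720
        assert build_design("linear_main").n_runs == 360
        assert build_design("va_trigger").n_runs == 720

    def test_single_replicate_counts(self):
        assert build_design("network_main", replicates=1).n_runs == 240
        assert build_design("linear_main", replicates=1).n_runs == 120

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_design("grid_search")

    def test_linear_mutation_rates_doubled(self):
        t = build_design("linear_main").table
        assert sorted(t["mu"].unique()) == [2e-5, 2e-4, 2e-3]
        assert "topology" not in t.columns

    def test_full_crossing_and_unique_seeds(self):
        d = build_design("network_main", replicates=2, master_seed=5)
        t = d.table
        cells = t.groupby(["n", "topology", "mu", "r", "omega", "dE"]).size()
        assert (cells == 2).all()
        assert t["run_id"].is_unique
        assert t["seed"].is_unique
        assert (t["seed"] < 2**31).all()

    def test_trigger_design_thresholds(self):
        t = build_design("va_trigger").table
        assert sorted(t["va_threshold"].unique()) == [5.0, 10.0, 20.0]


def _tiny_design():
    d = build_design("linear_main", replicates=1, master_seed=9)
    d.table = d.table[d.table.n.isin([16, 64]) & (d.table.mu == 2e-3)
                      & (d.table.r == 0.5) & (d.table.omega == 2.0)
                      & (d.table.dE == 20.0)].reset_index(drop=True)
    return d


class TestExecuteDesign:
    def test_one_summary_row_per_run(self):
        d = _tiny_design()
        out = execute_design(d, population=60, horizon=30)
        assert len(out) == len(d.table)
        assert set(d.table["run_id"]) == set(out["run_id"])

    def test_deterministic_given_master_seed(self):
        d = _tiny_design()
        a = execute_design(d, population=60, horizon=30)
        b = execute_design(d, population=60, horizon=30)
        pd.testing.assert_frame_equal(a, b)

    def test_horizon_scale_respected(self):
        d = _tiny_design()
        out = execute_design(d, population=60, horizon=15)
        assert (out["n_generations"] <= 15).all()

    def test_resumability_skips_completed_runs(self):
        d = _tiny_design()
        first = execute_design(d, population=60, horizon=20)
        partial = first.iloc[:1]
        resumed = execute_design(d, population=60, horizon=20, existing=partial)
        assert len(resumed) == len(first)
        pd.testing.assert_frame_equal(
            resumed.sort_values("run_id").reset_index(drop=True),
            first.sort_values("run_id").reset_index(drop=True),
        )

    def test_metadata_records_scale(self, tmp_path):
        d = _tiny_design()
        out = execute_design(d, population=60, horizon=20)
        assert out.attrs["meta"]["population"] == 60
        write_summary(out, str(tmp_path / "s.csv"))
        assert (tmp_path / "s.csv.meta.json").exists()


def _one_way_table(rng):
    """2 groups x 10 runs with known means and noise."""
    g = np.repeat([0, 1], 10)
    y = np.where(g == 0, 10.0, 14.0) + rng.normal(0, 1.0, 20)
    return pd.DataFrame({"grp": g, "resp": y})


class TestPartitionVariance:
    def test_matches_hand_computed_one_way_anova(self, rng):
        df = _one_way_table(rng)
        part = partition_variance(df, "resp", ["C(grp)"], log_transform=False)
        y = df["resp"].to_numpy()
        means = df.groupby("grp")["resp"].transform("mean").to_numpy()
        ss_between = ((means - y.mean()) ** 2).sum()
        ss_total = ((y - y.mean()) ** 2).sum()
        assert part.table["percent_ss"].iloc[0] == pytest.approx(
            100 * ss_between / ss_total
        )

    def test_percentages_close_to_decomposition_identity(self, rng):
        df = _one_way_table(rng)
        df["x"] = rng.normal(size=len(df))
        part = partition_variance(
            df, "resp", ["C(grp)", "x", "C(grp):x"], log_transform=False
        )
        assert part.explained_percent + part.residual_percent == pytest.approx(100.0)

    def test_pure_noise_explains_little(self, rng):
        df = pd.DataFrame(
            {"grp": np.repeat(np.arange(2), 200), "resp": rng.normal(size=400)}
        )
        part = partition_variance(df, "resp", ["C(grp)"], log_transform=False)
        assert part.table["percent_ss"].iloc[0] < 3.0

    def test_singular_design_rejected(self, rng):
        df = _one_way_table(rng)
        df["dup"] = df["grp"]
        with pytest.raises(SingularDesignError):
            partition_variance(df, "resp", ["C(grp)", "C(dup)"], log_transform=False)

    def test_mostly_undefined_response_rejected(self, rng):
        df = _one_way_table(rng)
        df.loc[:10, "resp"] = np.nan
        with pytest.raises(InvalidParameterError):
            partition_variance(df, "resp", ["C(grp)"], log_transform=False)

    def test_effect_direction_sign(self, rng):
        df = _one_way_table(rng)  # group 1 mean higher
        part = partition_variance(df, "resp", ["C(grp)"], log_transform=False)
        assert part.directions["C(grp)"] == 1

    def test_aic_comparison_prefers_true_model(self, rng):
        df = _one_way_table(rng)
        out = aic_comparison(df, "resp", ["1"], ["C(grp)"], log_transform=False)
        assert out["delta_aic"] > 0  # reduced (intercept-only) fits worse


class TestSummarizeFigures:
    def test_aggregates_match_brute_force_groupby(self):
        df = pd.DataFrame(
            {
                "n": [16, 16, 16, 64, 64, 64],
                "r": [0.05, 0.05, 0.5, 0.05, 0.5, 0.5],
                "topology": ["random"] * 6,
                "omega": [2.0] * 6,
                "dE": [20.0] * 6,
                "dVA_dt": [1.0, 3.0, 5.0, 2.0, 4.0, 6.0],
                "dVP_dt": [0.5] * 6,
                "mean_h2_last100": [0.2, 0.4, 0.3, 0.1, 0.5, 0.7],
                "recovery_time": [3, 5, np.nan, 7, 9, 11],
            }
        )
        figs = summarize_figures(df)
        g = figs["dVA_dt_by_size_r"]
        got = g.loc[(g.n == 16) & (g.r == 0.05), "mean"].item()
        assert got == pytest.approx(2.0)
        rec = figs["recovery_by_size_dE"]
        assert rec.loc[rec.n == 16, "count"].item() == 2  # NaN excluded

    def test_single_run_group_has_undefined_ci(self):
        df = pd.DataFrame(
            {"n": [16], "r": [0.05], "dVA_dt": [1.5], "dVP_dt": [0.1]}
        )
        figs = summarize_figures(df)
        row = figs["dVA_dt_by_size_r"].iloc[0]
        assert row["mean"] == 1.5 and np.isnan(row["sem"])

    def test_missing_columns_skip_grouping(self):
        df = pd.DataFrame({"n": [16, 64], "r": [0.05, 0.5], "dVA_dt": [1.0, 2.0],
                           "dVP_dt": [0.2, 0.1]})
        figs = summarize_figures(df)
        assert "h2_by_size_topology" not in figs
        assert "dVA_dt_by_size_r" in figs


class TestDirectionalBehaviour:
    def test_small_networks_have_higher_heritability(self):
        """Mini design: pre-change mean h2 declines from 16- to 256-gene
        networks under low recombination (the canalization-period direction)."""
        d = build_design("network_main", replicates=2, master_seed=31)
        t = d.table
        d.table = t[t.n.isin([16, 256]) & (t.mu == 1e-3) & (t.r == 0.05)
                    & (t.omega == 2.0) & (t.dE == 20.0)].reset_index(drop=True)
        out = execute_design(d, population=150, horizon=120)
        ok = out[~out["extinct"]]
        means = ok.groupby("n")["mean_h2_last50_prechange"].mean()
        assert means.loc[16] > means.loc[256]
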