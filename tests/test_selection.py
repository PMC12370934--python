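import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpkinetics.selection import (
    DesignError,
    bic_table,
    compute_rpi,
    fit_tree,
    select_model_sets,
    tukey_groups,
    two_way_anova,
)


def synth_bic_frame(
    model_effects: dict[str, float],
    cat_effects: dict[str, float],
    n_per_cell: int = 6,
    sd: float = 2.0,
    seed: int = 0,
    base: float = 40.0,
) -> pd.DataFrame:
    """Additive two-factor Gaussian BIC table for selection-layer tests."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for m, em in model_effects.items():
        for c, ec in cat_effects.items():
            for _ in range(n_per_cell):
                rows.append((f"s{i}", c, m, base + em + ec + rng.normal(0, sd)))
                i += 1
    return pd.DataFrame(rows, columns=["sample_id", "feed_category", "model_name", "bic"])


MODELS6 = {f"M{i}": e for i, e in enumerate([-8.0, -7.5, 0.0, 1.0, 6.0, 12.0])}
CATS3 = {"Compound": -2.0, "Corn": 0.0, "Soft cereal": 3.0}


class TestTwoWayAnova:
    def test_full_factorial_dfs(self):
        models = {f"M{i}": float(i) for i in range(21)}
        cats = {c: float(j) for j, c in enumerate(
            ["Compound", "Corn", "Processed protein", "Legumes", "Soft cereal", "Others"])}
        df = synth_bic_frame(models, cats, n_per_cell=2, seed=1)
        res = two_way_anova(df)
        assert res.df_model == 20
        assert res.df_category == 5
        assert res.df_interaction == 100

    def test_constant_response_all_flat(self):
        df = synth_bic_frame(MODELS6, CATS3, n_per_cell=3, sd=0.0, seed=2)
        df["bic"] = 40.0
        res = two_way_anova(df)
        assert res.table.loc["model_name", "sum_sq"] == 0.0
        assert res.table.loc["model_name", "p"] == 1.0
        assert res.table.loc["interaction", "p"] == 1.0

    def test_balanced_2x2_matches_hand_computed_ss(self):
        # cells (2 reps each): A/X: 10,12  A/Y: 20,22  B/X: 30,32  B/Y: 44,46
        rows = []
        data = {("A", "X"): (10, 12), ("A", "Y"): (20, 22),
                ("B", "X"): (30, 32), ("B", "Y"): (44, 46)}
        i = 0
        for (m, c), vals in data.items():
            for v in vals:
                rows.append((f"s{i}", c, m, float(v)))
                i += 1
        df = pd.DataFrame(rows, columns=["sample_id", "feed_category", "model_name", "bic"])
        # balanced design: Type II == classic sums of squares, by hand:
        # grand = 27; model means A=16, B=38 -> SS_m = 4*(11^2+11^2) = 968
        # cat means X=21, Y=33 -> SS_c = 4*(6^2+6^2) = 288
        # cell means 11,21,31,45; interaction deviation +/-1 -> SS_i = 8
        # residual: each cell +-1 around its mean -> 8*1 = 8
        res = two_way_anova(df)
        assert res.table.loc["model_name", "sum_sq"] == pytest.approx(968.0)
        assert res.table.loc["feed_category", "sum_sq"] == pytest.approx(288.0)
        assert res.table.loc["interaction", "sum_sq"] == pytest.approx(8.0)
        assert res.table.loc["residual", "sum_sq"] == pytest.approx(8.0)

    def test_balanced_decomposition_sums_to_total(self):
        df = synth_bic_frame(MODELS6, CATS3, n_per_cell=4, seed=3)
        res = two_way_anova(df)
        total = float(((df["bic"] - df["bic"].mean()) ** 2).sum())
        parts = float(res.table["sum_sq"].sum())
        assert parts == pytest.approx(total, rel=1e-10)

    def test_empty_cell_raises_design_error(self):
        df = synth_bic_frame(MODELS6, CATS3, n_per_cell=2, seed=4)
        df = df[~((df.model_name == "M0") & (df.feed_category == "Corn"))]
        with pytest.raises(DesignError):
            two_way_anova(df)

    def test_single_factor_level_raises(self):
        df = synth_bic_frame({"M0": 0.0}, CATS3, n_per_cell=3)
        with pytest.raises(DesignError):
            two_way_anova(df)


class TestTukeyGroups:
    def test_identical_models_share_a_letter(self):
        df = synth_bic_frame({"M0": 0.0, "M1": 0.0}, {"Corn": 0.0}, n_per_cell=6, sd=0.0)
        g = tukey_groups(df)
        letters = g.letters["Corn"]
        assert set(letters["M0"]) & set(letters["M1"])

    def test_far_outlier_gets_own_group(self):
        # M2 shifted far beyond any honest significant difference
        df = synth_bic_frame({"M0": 0.0, "M1": 0.5, "M2": 60.0}, {"Corn": 0.0},
                             n_per_cell=8, sd=1.0, seed=5)
        g = tukey_groups(df)
        letters = g.letters["Corn"]
        assert set(letters["M0"]) & set(letters["M1"])
        assert not set(letters["M2"]) & (set(letters["M0"]) | set(letters["M1"]))
        assert g.lower_models("Corn") == ["M2"]

    def test_letters_cover_every_model(self):
        df = synth_bic_frame(MODELS6, CATS3, n_per_cell=6, seed=6)
        g = tukey_groups(df)
        for cat in CATS3:
            assert set(g.letters[cat]) == set(MODELS6)
            assert all(len(v) >= 1 for v in g.letters[cat].values())

    def test_critical_difference_oracle_three_models(self):
        # compare the implementation against a direct Tukey-Kramer computation
        from scipy.stats import studentized_range
        df = synth_bic_frame({"M0": 0.0, "M1": 2.0, "M2": 4.5}, {"Corn": 0.0},
                             n_per_cell=10, sd=2.0, seed=7)
        g = tukey_groups(df, alpha=0.05)
        sub = df[df.feed_category == "Corn"]
        stats = sub.groupby("model_name")["bic"].agg(["mean", "count"])
        sse = sum(((x - x.mean()) ** 2).sum() for _, x in sub.groupby("model_name")["bic"])
        dfe = len(sub) - 3
        q = studentized_range.ppf(0.95, 3, dfe)
        crit = q * np.sqrt(sse / dfe / 2 * (1 / 10 + 1 / 10))
        for a in stats.index:
            for b in stats.index:
                if a >= b:
                    continue
                differ = abs(stats.loc[a, "mean"] - stats.loc[b, "mean"]) > crit
                shared = set(g.letters["Corn"][a]) & set(g.letters["Corn"][b])
                assert differ == (not shared)

    def test_true_best_lands_in_best_group(self):
        # Monte Carlo: strong separation, n=50 per cell
        hits = 0
        runs = 10
        for seed in range(runs):
            df = synth_bic_frame({"Best": -6.0, "Mid": 0.0, "Worse": 4.0, "Worst": 9.0},
                                 {"Corn": 0.0}, n_per_cell=50, sd=4.0, seed=seed)
            g = tukey_groups(df)
            if "Best" in g.top_models("Corn"):
                hits += 1
        assert hits >= int(0.95 * runs)

    def test_single_model_trivial_group(self):
        df = synth_bic_frame({"M0": 0.0}, {"Corn": 0.0}, n_per_cell=4)
        g = tukey_groups(df)
        assert g.letters["Corn"] == {"M0": "a"}


class TestFitTree:
    def test_constant_response_no_splits(self):
        df = synth_bic_frame(MODELS6, CATS3, n_per_cell=3, sd=0.0)
        df["bic"] = 42.0
        rep = fit_tree(df, seed=0)
        assert rep.n_splits == 0
        assert rep.shares == {}
        assert len(rep.leaves) == 1

    def test_separable_construction_first_split(self):
        # two clean response levels keyed on model identity
        df = synth_bic_frame({"A": 0.0, "B": 0.0, "C": 40.0, "D": 40.0},
                             {"Corn": 0.0, "Compound": 0.0}, n_per_cell=10,
                             sd=0.01, seed=8, base=10.0)
        rep = fit_tree(df, seed=1)
        assert rep.validation_r2 > 0.99
        best_leaf_models = set(rep.leaves.iloc[0]["models"])
        assert best_leaf_models == {"A", "B"}
        assert rep.shares["model_name"] > 99.0

    def test_leaf_counts_and_means_are_exact(self):
        df = synth_bic_frame(MODELS6, CATS3, n_per_cell=6, seed=9)
        rep = fit_tree(df, split_fraction=0.7, seed=2)
        n_train = int(round(0.7 * len(df)))
        assert int(rep.leaves["count"].sum()) == n_train
        assert rep.training_r2 >= 0.0

    def test_shares_sum_to_100(self):
        df = synth_bic_frame(MODELS6, CATS3, n_per_cell=6, seed=10)
        rep = fit_tree(df, seed=3)
        assert rep.n_splits >= 1
        assert sum(rep.shares.values()) == pytest.approx(100.0)

    def test_model_effect_dominates_category_share(self):
        # injected model-effect SS twice the category-effect SS (exact spread)
        m_spread = np.linspace(-12.0, 12.0, 8)
        c_spread = np.linspace(-12.0, 12.0, 4) / np.sqrt(2.0 * np.var(np.linspace(-12, 12, 4)) / np.var(m_spread))
        m_eff = {f"M{i}": float(v) for i, v in enumerate(m_spread)}
        c_eff = {c: float(v) for c, v in zip(
            ["Compound", "Corn", "Legumes", "Others"], c_spread)}
        df = synth_bic_frame(m_eff, c_eff, n_per_cell=12, sd=2.0, seed=11)
        rep = fit_tree(df, seed=4)
        assert rep.shares["model_name"] > rep.shares["feed_category"]

    def test_degenerate_split_fraction_raises(self):
        df = synth_bic_frame(MODELS6, CATS3, n_per_cell=4)
        with pytest.raises(ValueError):
            fit_tree(df, split_fraction=1.0)

    def test_too_few_rows_raises(self):
        df = synth_bic_frame({"M0": 0.0, "M1": 1.0}, {"Corn": 0.0}, n_per_cell=3)
        with pytest.raises(DesignError):
            fit_tree(df)


class TestComputeRpi:
    def test_printed_compound_row(self):
        assert compute_rpi(29.6, 58.0, 40.1) == pytest.approx(70.8, abs=0.05)

    def test_printed_processed_protein_row(self):
        assert compute_rpi(22.6, 55.0, 34.4) == pytest.approx(94.2, abs=0.05)

    def test_equal_sets_give_zero(self):
        assert compute_rpi(33.0, 33.0, 40.0) == 0.0

    def test_nonpositive_average_raises(self):
        with pytest.raises(ValueError):
            compute_rpi(10.0, 20.0, 0.0)

    @given(st.floats(1e-3, 1e3), st.floats(0, 100), st.floats(0, 100),
           st.floats(1.0, 100.0))
    @settings(max_examples=60, deadline=None)
    def test_invariant_to_common_rescaling(self, scale, top, lower, allm):
        base = compute_rpi(top, lower, allm)
        scaled = compute_rpi(top * scale, lower * scale, allm * scale)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestSelectModelSets:
    def test_structure_and_disjointness(self):
        df = synth_bic_frame(MODELS6, CATS3, n_per_cell=8, sd=1.0, seed=12)
        g = tukey_groups(df)
        out = select_model_sets(g, df)
        assert set(out["feed_category"]) == set(CATS3)
        for row in out.itertuples(index=False):
            assert len(row.top_models) >= 1
            assert not set(row.top_models) & set(row.lower_models)
            assert row.rpi == pytest.approx(
                100 * (row.avg_bic_lower - row.avg_bic_top) / row.avg_bic_all)

    def test_all_models_equal_rpi_zero(self):
        df = synth_bic_frame({"M0": 0.0, "M1": 0.0, "M2": 0.0}, {"Corn": 0.0},
                             n_per_cell=5, sd=0.0)
        g = tukey_groups(df)
        out = select_model_sets(g, df)
        assert set(out.iloc[0]["top_models"]) == {"M0", "M1", "M2"}
        assert out.iloc[0]["rpi"] == 0.0

    def test_printed_averages_reproduce_printed_rpi(self):
        printed = {
            "Compound": (29.6, 58.0, 40.1, 70.8),
            "Corn": (37.1, 58.9, 48.2, 45.2),
            "Processed protein": (22.6, 55.0, 34.4, 94.2),
            "Legumes": (29.6, 61.0, 42.9, 73.2),
            "Soft cereal": (44.7, 62.6, 52.0, 34.4),
            "Others": (35.5, 58.0, 43.6, 51.6),
        }
        for top, lower, allm, rpi in printed.values():
            assert compute_rpi(top, lower, allm) == pytest.approx(rpi, abs=0.05)


class TestBicTable:
    def test_filters_non_converged(self):
        df = synth_bic_frame({"M0": 0.0, "M1": 1.0}, {"Corn": 0.0}, n_per_cell=3)
        df["converged"] = [True] * (len(df) - 2) + [False, False]
        out = bic_table(df)
        assert len(out) == len(df) - 2

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError):
            bic_table(pd.DataFrame({"bic": [1.0]}))
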