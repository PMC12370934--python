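"""Model-selection layer on the profile x model BIC table.

Four stages: a two-factor fixed-effects ANOVA of BIC on model name and feed
category (Type II sums of squares for the unbalanced design), Tukey-Kramer
all-pairs comparisons per feed category with a compact letter display, a
single CART regression tree on the two categorical predictors (70/30
train/validation, tuned on validation RMSE) with a leaf report and per-
predictor split sum-of-squares contribution shares, and the relative
performance improvement (RPI) statistic
``100 * (lower-set mean BIC - top-set mean BIC) / all-model mean BIC``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "DesignError",
    "AnovaResult",
    "TukeyGrouping",
    "TreeReport",
    "bic_table",
    "two_way_anova",
    "tukey_groups",
    "fit_tree",
    "compute_rpi",
    "select_model_sets",
]

_REQUIRED = ["sample_id", "feed_category", "model_name", "bic"]


class DesignError(ValueError):
    """Raised when the factorial layout cannot support the requested analysis."""


def bic_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Converged rows of a fit-results frame, reduced to the BIC columns."""
    missing = [c for c in _REQUIRED if c not in fits.columns]
    if missing:
        raise ValueError(f"fit frame lacks columns {missing}")
    out = fits
    if "converged" in fits.columns:
        out = fits[fits["converged"].astype(bool)]
    out = out.loc[:, _REQUIRED].dropna(subset=["bic"]).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# ANOVA


@dataclass(frozen=True)
class AnovaResult:
    table: pd.DataFrame  # index: model_name, feed_category, interaction, residual

    def __getitem__(self, source: str) -> pd.Series:
        return self.table.loc[source]

    @property
    def df_model(self) -> int:
        return int(self.table.loc["model_name", "df"])

    @property
    def df_category(self) -> int:
        return int(self.table.loc["feed_category", "df"])

    @property
    def df_interaction(self) -> int:
        return int(self.table.loc["interaction", "df"])


def two_way_anova(table: pd.DataFrame) -> AnovaResult:
    """Type II factorial ANOVA of BIC on model name, feed category and their
    interaction.  Requires every model x category cell to be occupied."""
    df = bic_table(table)
    models = sorted(df["model_name"].unique())
    cats = sorted(df["feed_category"].unique())
    if len(models) < 2 or len(cats) < 2:
        raise DesignError("need at least two models and two feed categories")
    cell = df.groupby(["model_name", "feed_category"]).size()
    if len(cell) < len(models) * len(cats):
        have = set(cell.index)
        empty = [(m, c) for m in models for c in cats if (m, c) not in have]
        raise DesignError(f"empty design cells make the interaction inestimable: {empty[:5]}...")
    if not (cell >= 2).any():
        raise DesignError("no cell has replication; residual variance inestimable")

    y = df["bic"].to_numpy(dtype=float)
    tss = float(np.sum((y - y.mean()) ** 2))
    dfm, dfc = len(models) - 1, len(cats) - 1
    dfi = dfm * dfc
    dfr = len(df) - len(models) * len(cats)
    if tss <= 1e-10 * max(1.0, abs(y.mean())) ** 2 * len(y):
        # Degenerate flat response: all effects zero, nothing to reject.
        out = pd.DataFrame(
            {"sum_sq": [0.0, 0.0, 0.0, 0.0], "df": [dfm, dfc, dfi, dfr],
             "F": [0.0, 0.0, 0.0, math.nan], "p": [1.0, 1.0, 1.0, math.nan]},
            index=["model_name", "feed_category", "interaction", "residual"],
        )
        return AnovaResult(out)

    ols = smf.ols("bic ~ C(model_name) * C(feed_category)", data=df).fit()
    raw = sm.stats.anova_lm(ols, typ=2)
    rename = {
        "C(model_name)": "model_name",
        "C(feed_category)": "feed_category",
        "C(model_name):C(feed_category)": "interaction",
        "Residual": "residual",
    }
    raw = raw.rename(index=rename)
    out = raw.loc[["model_name", "feed_category", "interaction", "residual"],
                  ["sum_sq", "df", "F", "PR(>F)"]].rename(columns={"PR(>F)": "p"})
    out["df"] = out["df"].astype(int)
    return AnovaResult(out)


# ---------------------------------------------------------------------------
# Tukey-Kramer with compact letter display


def _compact_letters(levels: Sequence[str], different: np.ndarray) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``levels`` must be ordered (best first); ``different[i, j]`` is True when
    levels i and j differ significantly.  Levels sharing a letter are pairwise
    non-significant.
    """
    columns: list[set[int]] = [set(range(len(levels)))]
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            if not different[i, j]:
                continue
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                columns.extend([col - {j}, col - {i}])
            # absorb duplicates and strict subsets
            deduped: list[set[int]] = []
            for col in columns:
                if col and not any(col < other for other in columns) and col not in deduped:
                    deduped.append(col)
            columns = deduped
    columns.sort(key=lambda c: min(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    labels = [alphabet[i] if i < 26 else f"z{i - 25}" for i in range(len(columns))]
    out = {level: "" for level in levels}
    for label, col in zip(labels, columns):
        for idx in sorted(col):
            out[levels[idx]] += label
    return out


@dataclass(frozen=True)
class TukeyGrouping:
    alpha: float
    letters: Mapping[str, Mapping[str, str]]  # category -> model -> letters
    means: Mapping[str, Mapping[str, float]]  # category -> model -> mean BIC

    def top_models(self, category: str) -> list[str]:
        """Models statistically tied with the lowest-mean model."""
        return self._shared_with_extreme(category, best=True)

    def lower_models(self, category: str) -> list[str]:
        """Models statistically tied with the highest-mean model."""
        return self._shared_with_extreme(category, best=False)

    def _shared_with_extreme(self, category: str, best: bool) -> list[str]:
        means = self.means[category]
        letters = self.letters[category]
        pick = min(means, key=means.get) if best else max(means, key=means.get)
        mark = set(letters[pick])
        chosen = [m for m in means if set(letters[m]) & mark]
        return sorted(chosen, key=means.get)


def tukey_groups(table: pd.DataFrame, alpha: float = 0.05) -> TukeyGrouping:
    """Per-category all-pairs model comparison via the studentized range
    (Tukey-Kramer for unequal cell sizes) with a compact letter display."""
    df = bic_table(table)
    letters: dict[str, dict[str, str]] = {}
    means_out: dict[str, dict[str, float]] = {}
    for category, sub in df.groupby("feed_category"):
        stats = sub.groupby("model_name")["bic"].agg(["mean", "count"])
        order = stats.sort_values("mean").index.tolist()
        g = len(order)
        means = stats["mean"].to_dict()
        means_out[category] = {m: float(means[m]) for m in order}
        if g == 1:
            letters[category] = {order[0]: "a"}
            continue
        n = stats["count"]
        sse = float(
            sub.groupby("model_name")["bic"].apply(lambda x: ((x - x.mean()) ** 2).sum()).sum()
        )
        dfe = int(len(sub) - g)
        if dfe <= 0 or sse <= 0:
            crit = np.zeros((g, g))
        else:
            mse = sse / dfe
            q = float(studentized_range.ppf(1.0 - alpha, g, dfe))
            half = np.array([1.0 / n[m] for m in order])
            crit = q * np.sqrt(mse / 2.0 * (half[:, None] + half[None, :]))
        mu = np.array([means[m] for m in order])
        different = np.abs(mu[:, None] - mu[None, :]) > crit
        letters[category] = _compact_letters(order, different)
    return TukeyGrouping(alpha=alpha, letters=letters, means=means_out)


# ---------------------------------------------------------------------------
# Regression tree


@dataclass(frozen=True)
class TreeReport:
    n_splits: int
    max_depth: int
    min_samples_leaf: int
    training_r2: float
    training_rmse: float
    validation_r2: float
    validation_rmse: float
    leaves: pd.DataFrame  # models, categories, mean_bic, count (training rows)
    shares: Mapping[str, float]  # predictor -> % of split sum of squares

    def top_leaf_models(self, category: str) -> list[str]:
        """Models in the lowest-BIC leaf containing the category."""
        for row in self.leaves.itertuples(index=False):
            if category in row.categories:
                return list(row.models)
        return []


def _r2_rmse(y: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    rss = float(np.sum((y - pred) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    return r2, math.sqrt(rss / y.size)


def fit_tree(
    table: pd.DataFrame,
    split_fraction: float = 0.7,
    seed: int = 0,
    max_depth_grid: Sequence[int] = (3, 4, 5, 6, 7, 8),
    min_leaf_grid: Sequence[int] = (5, 10, 20),
) -> TreeReport:
    """CART regression of BIC on the two categorical predictors.

    Levels are target-encoded by their training-mean BIC, which for a
    single-output squared-error tree is equivalent to the optimal
    mean-ordered subset split over categories.  Tree control (depth, minimum
    leaf size) is tuned on the held-out validation split.
    """
    if not 0.0 < split_fraction < 1.0:
        raise ValueError(f"split_fraction must be in (0, 1), got {split_fraction}")
    df = bic_table(table)
    if len(df) < 20:
        raise DesignError("need at least 20 rows to grow a tree")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(df))
    n_train = int(round(split_fraction * len(df)))
    train = df.iloc[perm[:n_train]].reset_index(drop=True)
    valid = df.iloc[perm[n_train:]].reset_index(drop=True)

    overall = float(train["bic"].mean())
    enc_model = train.groupby("model_name")["bic"].mean()
    enc_cat = train.groupby("feed_category")["bic"].mean()

    def encode(frame: pd.DataFrame) -> np.ndarray:
        xm = frame["model_name"].map(enc_model).fillna(overall).to_numpy()
        xc = frame["feed_category"].map(enc_cat).fillna(overall).to_numpy()
        return np.column_stack([xm, xc])

    X_train, y_train = encode(train), train["bic"].to_numpy(dtype=float)
    X_valid, y_valid = encode(valid), valid["bic"].to_numpy(dtype=float)

    best = None
    for depth in max_depth_grid:
        for leaf in min_leaf_grid:
            tree = DecisionTreeRegressor(
                criterion="squared_error", max_depth=depth,
                min_samples_leaf=leaf, random_state=0,
            ).fit(X_train, y_train)
            _, vrmse = _r2_rmse(y_valid, tree.predict(X_valid))
            key = (vrmse, depth, leaf)
            if best is None or key < best[0]:
                best = (key, tree, depth, leaf)
    _, tree, depth, leaf = best

    tr_r2, tr_rmse = _r2_rmse(y_train, tree.predict(X_train))
    va_r2, va_rmse = _r2_rmse(y_valid, tree.predict(X_valid))

    t = tree.tree_
    internal = t.children_left != -1
    n_splits = int(np.sum(internal))
    ss_by_feature = {0: 0.0, 1: 0.0}
    for node in np.flatnonzero(internal):
        left, right = t.children_left[node], t.children_right[node]
        dec = (
            t.weighted_n_node_samples[node] * t.impurity[node]
            - t.weighted_n_node_samples[left] * t.impurity[left]
            - t.weighted_n_node_samples[right] * t.impurity[right]
        )
        ss_by_feature[int(t.feature[node])] += float(dec)
    total_ss = sum(ss_by_feature.values())
    shares = (
        {"model_name": 100.0 * ss_by_feature[0] / total_ss,
         "feed_category": 100.0 * ss_by_feature[1] / total_ss}
        if total_ss > 0
        else {}
    )

    leaf_ids = tree.apply(X_train)
    rows = []
    model_order = enc_model.sort_values().index.tolist()
    cat_order = enc_cat.sort_values().index.tolist()
    for lid in np.unique(leaf_ids):
        members = train.iloc[np.flatnonzero(leaf_ids == lid)]
        rows.append(
            {
                "models": tuple(m for m in model_order if m in set(members["model_name"])),
                "categories": tuple(c for c in cat_order if c in set(members["feed_category"])),
                "mean_bic": float(members["bic"].mean()),
                "count": int(len(members)),
            }
        )
    leaves = pd.DataFrame(rows).sort_values("mean_bic", ignore_index=True)

    return TreeReport(
        n_splits=n_splits,
        max_depth=depth,
        min_samples_leaf=leaf,
        training_r2=tr_r2,
        training_rmse=tr_rmse,
        validation_r2=va_r2,
        validation_rmse=va_rmse,
        leaves=leaves,
        shares=shares,
    )


# ---------------------------------------------------------------------------
# RPI


def compute_rpi(top_avg: float, lower_avg: float, all_avg: float) -> float:
    """Relative performance improvement, percent."""
    if not all_avg > 0:
        raise ValueError(f"average BIC over all models must be positive, got {all_avg}")
    return 100.0 * (lower_avg - top_avg) / all_avg


def select_model_sets(grouping: TukeyGrouping, table: pd.DataFrame) -> pd.DataFrame:
    """Per-category top/lower model sets (Tukey letters) and their RPI.

    The top set shares a letter with the best (lowest mean BIC) model, the
    lower set with the worst; averages are unweighted over the table rows of
    the involved models.
    """
    df = bic_table(table)
    rows = []
    for category in grouping.means:
        sub = df[df["feed_category"] == category]
        top = grouping.top_models(category)
        lower = grouping.lower_models(category)
        avg_top = float(sub[sub["model_name"].isin(top)]["bic"].mean())
        avg_lower = float(sub[sub["model_name"].isin(lower)]["bic"].mean())
        avg_all = float(sub["bic"].mean())
        rows.append(
            {
                "feed_category": category,
                "top_models": tuple(top),
                "lower_models": tuple(lower),
                "avg_bic_top": avg_top,
                "avg_bic_lower": avg_lower,
                "avg_bic_all": avg_all,
                "difference": avg_lower - avg_top,
                "rpi": compute_rpi(avg_top, avg_lower, avg_all),
            }
        )
    return pd.DataFrame(rows)
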