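"""CSV/JSON dialects, validation and run manifests.

Profiles travel as long-format CSV (``sample_id,feed_category,time_h,gp_ml``,
UTF-8, dot decimal); fit results as one wide CSV row per profile x model
with absent parameters left empty; reports and manifests as JSON (full
precision).  CSV numbers are written with 6 significant digits.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import FEED_CATEGORIES, FitResult, GPProfile, results_to_frame
from .selection import AnovaResult, TreeReport, TukeyGrouping

__all__ = [
    "ParseError",
    "read_profiles",
    "write_profiles",
    "write_fits",
    "read_fits",
    "write_manifest",
    "report_to_dict",
    "write_report",
    "validate_report",
]

logger = logging.getLogger("gpkinetics.io")

PROFILE_COLUMNS = ("sample_id", "feed_category", "time_h", "gp_ml")


class ParseError(ValueError):
    """Raised for malformed input files; message carries line numbers."""


def _sig6(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{float(x):.6g}"


def read_profiles(path: str | Path) -> list[GPProfile]:
    """Load and validate long-format profiles.

    Rows are checked for numeric time/volume values and duplicate
    (sample, time) pairs; a profile lacking its t=0 reading gets the
    definitional (0 h, 0 mL) point imputed with a warning; unknown feed
    categories are accepted but flagged.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")

    bad_lines = []
    for col in ("time_h", "gp_ml"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna()]
        bad_lines.extend((int(i) + 2, col) for i in bad)  # +2: header + 1-based
        df[col] = converted
    if bad_lines:
        raise ParseError(f"{path}: non-numeric cells at lines {sorted(set(b[0] for b in bad_lines))}")

    dup = df.duplicated(subset=["sample_id", "time_h"], keep=False)
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup]]
        raise ParseError(f"{path}: duplicate (sample_id, time_h) rows at lines {lines}")

    unknown = sorted(set(df["feed_category"]) - set(FEED_CATEGORIES))
    if unknown:
        logger.warning("%s: feed categories outside the standard six: %s", path, unknown)

    profiles = []
    for sample_id, sub in df.groupby("sample_id", sort=False):
        sub = sub.sort_values("time_h")
        times = sub["time_h"].to_numpy(dtype=float)
        volumes = sub["gp_ml"].to_numpy(dtype=float)
        if times[0] != 0.0:
            logger.warning("%s: profile %s lacks a t=0 reading; imputing (0, 0)", path, sample_id)
            times = np.concatenate([[0.0], times])
            volumes = np.concatenate([[0.0], volumes])
        category = str(sub["feed_category"].iloc[0])
        profiles.append(
            GPProfile(sample_id=str(sample_id), feed_category=category,
                      times=tuple(times), volumes=tuple(volumes))
        )
    return profiles


def write_profiles(profiles: Iterable[GPProfile], path: str | Path) -> None:
    path = Path(path)
    rows = []
    for p in profiles:
        for t, v in zip(p.times, p.volumes):
            rows.append((p.sample_id, p.feed_category, _sig6(t), _sig6(v)))
    out = pd.DataFrame(rows, columns=list(PROFILE_COLUMNS))
    out.to_csv(path, index=False)


def write_fits(results: Sequence[FitResult] | pd.DataFrame, path: str | Path) -> pd.DataFrame:
    frame = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    formatted = frame.copy()
    for col in formatted.columns:
        if formatted[col].dtype.kind in "fc":
            formatted[col] = formatted[col].map(_sig6)
    formatted.to_csv(Path(path), index=False)
    return frame


def read_fits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    if "converged" in df.columns:
        df["converged"] = df["converged"].astype(bool)
    return df


def write_manifest(path: str | Path, manifest: Mapping) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _clean_nan(x):
    if isinstance(x, float) and math.isnan(x):
        return None
    return x


def report_to_dict(
    anova: AnovaResult,
    grouping: TukeyGrouping,
    tree: TreeReport,
    rpi: pd.DataFrame,
    meta: Mapping | None = None,
) -> dict:
    """Assemble the selection-stage JSON report."""
    anova_block = {
        source: {
            "sum_sq": _clean_nan(float(row["sum_sq"])),
            "df": int(row["df"]),
            "F": _clean_nan(float(row["F"])),
            "p": _clean_nan(float(row["p"])),
        }
        for source, row in anova.table.iterrows()
    }
    tukey_block = {
        "alpha": grouping.alpha,
        "letters": {c: dict(v) for c, v in grouping.letters.items()},
        "means": {c: dict(v) for c, v in grouping.means.items()},
        "top_models": {c: grouping.top_models(c) for c in grouping.means},
        "lower_models": {c: grouping.lower_models(c) for c in grouping.means},
    }
    tree_block = {
        "n_splits": tree.n_splits,
        "max_depth": tree.max_depth,
        "min_samples_leaf": tree.min_samples_leaf,
        "training_r2": _clean_nan(tree.training_r2),
        "training_rmse": tree.training_rmse,
        "validation_r2": _clean_nan(tree.validation_r2),
        "validation_rmse": tree.validation_rmse,
        "shares": dict(tree.shares),
        "leaves": [
            {
                "models": list(row.models),
                "categories": list(row.categories),
                "mean_bic": row.mean_bic,
                "count": row.count,
            }
            for row in tree.leaves.itertuples(index=False)
        ],
        "top_leaf_models": {
            c: tree.top_leaf_models(c) for c in grouping.means
        },
    }
    rpi_block = [
        {
            "feed_category": row.feed_category,
            "top_models": list(row.top_models),
            "lower_models": list(row.lower_models),
            "avg_bic_top": row.avg_bic_top,
            "avg_bic_lower": row.avg_bic_lower,
            "avg_bic_all": row.avg_bic_all,
            "difference": row.difference,
            "rpi": row.rpi,
        }
        for row in rpi.itertuples(index=False)
    ]
    return {
        "anova": anova_block,
        "tukey": tukey_block,
        "tree": tree_block,
        "rpi": rpi_block,
        "meta": dict(meta or {}),
    }


# Minimal structural schema for the selection report; shipped alongside the
# package so downstream consumers can check reports without extra deps.
_REPORT_SCHEMA = {
    "anova": dict,
    "tukey": dict,
    "tree": dict,
    "rpi": list,
    "meta": dict,
}
_TUKEY_KEYS = ("alpha", "letters", "means", "top_models", "lower_models")
_TREE_KEYS = ("n_splits", "shares", "leaves", "validation_rmse")
_RPI_KEYS = ("feed_category", "top_models", "lower_models", "avg_bic_top",
             "avg_bic_lower", "avg_bic_all", "difference", "rpi")


def validate_report(report: Mapping) -> None:
    """Raise ValueError when the report lacks the documented structure."""
    for key, typ in _REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing top-level key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report[{key!r}] must be {typ.__name__}")
    for key in _TUKEY_KEYS:
        if key not in report["tukey"]:
            raise ValueError(f"report['tukey'] missing {key!r}")
    for key in _TREE_KEYS:
        if key not in report["tree"]:
            raise ValueError(f"report['tree'] missing {key!r}")
    for i, row in enumerate(report["rpi"]):
        for key in _RPI_KEYS:
            if key not in row:
                raise ValueError(f"report['rpi'][{i}] missing {key!r}")


def write_report(report: Mapping, path: str | Path) -> None:
    validate_report(report)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
        fh.write("\n")
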