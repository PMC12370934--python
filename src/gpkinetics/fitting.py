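"""Constrained nonlinear least-squares fitting of catalogue models.

Each gas-production profile is fitted by minimising the residual sum of
squares between observed volumes and the model curve.  Parameter
constraints are enforced by smooth reparameterisation (log for strictly
positive parameters, shifted log for parameters bounded below by 1) so the
interior search is unconstrained; a small seeded multistart guards against
local minima.  Goodness of fit follows the Gaussian maximum-likelihood
convention throughout: ``rmse = sqrt(rss/n)``,
``loglik = -(n/2)(ln 2pi + ln(rss/n) + 1)`` and ``bic = k ln n - 2 loglik``.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .catalog import (
    MODELS,
    KineticSummary,
    ModelSpec,
    ParamVector,
    get_model,
    kinetic_summary,
)

__all__ = [
    "HOHENHEIM_GRID",
    "FEED_CATEGORIES",
    "GPProfile",
    "FitOptions",
    "GoodnessOfFit",
    "FitResult",
    "ResidualDiagnostics",
    "goodness_of_fit",
    "fit_model",
    "fit_all",
    "residual_diagnostics",
    "results_to_frame",
]

logger = logging.getLogger("gpkinetics.fitting")

#: The nine standard reading times of the Hohenheim gas test (h).
HOHENHEIM_GRID = (0.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0, 72.0)

#: The six feed categories used throughout the analysis.
FEED_CATEGORIES = (
    "Compound",
    "Corn",
    "Processed protein",
    "Legumes",
    "Soft cereal",
    "Others",
)

# Variance floor for the ML log-likelihood so numerically perfect fits stay
# finite and comparable (sigma ~ 1e-6 mL, far below any real reading error).
_SIGMA2_FLOOR = 1e-12


class DataError(ValueError):
    """Raised for profiles unusable by the requested fit."""


@dataclass(frozen=True)
class GPProfile:
    """One measured or simulated cumulative gas-production curve."""

    sample_id: str
    feed_category: str
    times: tuple[float, ...]
    volumes: tuple[float, ...]

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        if t.size != v.size:
            raise DataError(f"{self.sample_id}: times and volumes differ in length")
        if t.size < 2:
            raise DataError(f"{self.sample_id}: need at least two time points")
        if np.any(np.diff(t) <= 0):
            raise DataError(f"{self.sample_id}: times must be strictly increasing")
        if t[0] != 0.0:
            raise DataError(f"{self.sample_id}: first time point must be 0 h")
        if v[0] != 0.0:
            raise DataError(f"{self.sample_id}: volume at t=0 must be 0 (GP0 = 0)")
        if np.any(v < 0):
            raise DataError(f"{self.sample_id}: volumes must be non-negative")
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "volumes", tuple(float(x) for x in v))

    @property
    def n(self) -> int:
        return len(self.times)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.times), np.asarray(self.volumes)


@dataclass(frozen=True)
class FitOptions:
    max_iter: int = 500
    tol: float = 1e-10
    multistart: int = 5
    seed: int = 0
    jitter_sd: float = 0.3  # jitter of the transformed start values
    dense_grid_points: int = 289  # negative-prediction screen on [0, t_max]


@dataclass(frozen=True)
class GoodnessOfFit:
    rss: float
    r2: float
    rmse: float
    loglik: float
    bic: float


@dataclass(frozen=True)
class FitResult:
    sample_id: str
    feed_category: str
    model_name: str
    converged: bool
    failure_reason: str | None  # None | no-convergence | nan-estimates |
    #                             negative-predictions | constraint-violation
    estimates: ParamVector | None
    standard_errors: dict[str, float] = field(default_factory=dict)
    n: int = 0
    k: int = 0
    rss: float = math.nan
    r2: float = math.nan
    rmse: float = math.nan
    loglik: float = math.nan
    bic: float = math.nan
    kinetics: KineticSummary | None = None

    def predicted(self, profile: GPProfile) -> np.ndarray:
        if self.estimates is None:
            raise ValueError("no estimates available")
        spec = get_model(self.model_name)
        return np.asarray(spec.cdf(self.estimates, np.asarray(profile.times)))


@dataclass(frozen=True)
class ResidualDiagnostics:
    table: pd.DataFrame  # time_h, observed, predicted, residual
    mean_residual: float
    sign_runs: int
    expected_runs: float
    n_positive: int
    n_negative: int


def goodness_of_fit(observed: Sequence[float], predicted: Sequence[float], k: int) -> GoodnessOfFit:
    """RSS, R^2, RMSE, Gaussian ML log-likelihood and BIC for one fit."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have the same length")
    n = obs.size
    if n < 2:
        raise ValueError("need at least two observations")
    rss = float(np.sum((obs - pred) ** 2))
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    r2 = 1.0 - rss / tss
    rmse = math.sqrt(rss / n)
    sigma2 = max(rss / n, _SIGMA2_FLOOR)
    loglik = -(n / 2.0) * (math.log(2.0 * math.pi) + math.log(sigma2) + 1.0)
    bic = k * math.log(n) - 2.0 * loglik
    return GoodnessOfFit(rss=rss, r2=r2, rmse=rmse, loglik=loglik, bic=bic)


# ---------------------------------------------------------------------------
# Parameter transforms


def _transform_kind(spec: ModelSpec, name: str) -> str:
    if name == "mu":
        return "identity"
    labels = {c.label for c in spec.constraints}
    if f"{name}>1" in labels:
        return "shifted-log"
    return "log"  # m, r and every ">0"-bounded shape parameter


def _to_theta(spec: ModelSpec, values: np.ndarray) -> np.ndarray:
    out = np.empty_like(values)
    for i, name in enumerate(spec.param_names):
        kind = _transform_kind(spec, name)
        if kind == "identity":
            out[i] = values[i]
        elif kind == "log":
            out[i] = math.log(values[i])
        else:
            out[i] = math.log(values[i] - 1.0)
    return out


def _from_theta(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    theta = np.clip(theta, -700.0, 700.0)
    out = np.empty_like(theta)
    for i, name in enumerate(spec.param_names):
        kind = _transform_kind(spec, name)
        if kind == "identity":
            out[i] = theta[i]
        elif kind == "log":
            out[i] = math.exp(theta[i])
        else:
            out[i] = 1.0 + math.exp(theta[i])
    return out


def _initial_values(spec: ModelSpec, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    y_max = float(np.max(y))
    m0 = 1.05 * y_max
    pos = t[y >= 0.5 * y_max]
    t_half_obs = float(pos[0]) if pos.size and pos[0] > 0 else float(t[t > 0][0])
    r0 = math.log(2.0) / t_half_obs
    vals = []
    for name in spec.param_names:
        if name == "m":
            vals.append(m0)
        elif name == "r":
            vals.append(r0)
        elif name == "mu":
            vals.append(t_half_obs if spec.domain == "real" else 0.0)
        elif name == "a":
            vals.append(r0 if spec.name == "Generalized logistic" else 1.5)
        elif name == "p":
            vals.append(1.5)
    return np.asarray(vals, dtype=float)


def _fit_seed(options: FitOptions, spec: ModelSpec, sample_id: str) -> np.random.Generator:
    # Stable per (run seed, model, profile) so fit_all order never matters.
    tag = zlib.crc32(sample_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([options.seed, spec.number, tag]))


def _failure(profile: GPProfile, spec: ModelSpec, reason: str, estimates=None, se=None) -> FitResult:
    return FitResult(
        sample_id=profile.sample_id,
        feed_category=profile.feed_category,
        model_name=spec.name,
        converged=False,
        failure_reason=reason,
        estimates=estimates,
        standard_errors=se or {},
        n=profile.n,
        k=spec.k,
    )


def fit_model(profile: GPProfile, model: ModelSpec | str, options: FitOptions | None = None) -> FitResult:
    """Fit one catalogue model to one profile.

    Never raises for numerical trouble: failure modes are recorded in the
    returned record (``no-convergence``, ``nan-estimates``,
    ``negative-predictions``, ``constraint-violation``).  Raises only for
    structurally unusable input (too few points, unknown model).
    """
    spec = get_model(model) if isinstance(model, str) else model
    options = options or FitOptions()
    t, y = profile.arrays()
    if profile.n < spec.k + 1:
        raise DataError(
            f"{profile.sample_id}: {profile.n} points are too few for "
            f"{spec.name} ({spec.k} parameters)"
        )
    if float(np.max(y)) <= 0.0 or float(np.sum((y - y.mean()) ** 2)) == 0.0:
        return _failure(profile, spec, "no-convergence")

    x0 = _to_theta(spec, _initial_values(spec, t, y))
    rng = _fit_seed(options, spec, profile.sample_id)

    def residuals(theta: np.ndarray) -> np.ndarray:
        pv = ParamVector().with_values(spec.param_names, _from_theta(spec, theta))
        with np.errstate(all="ignore"):
            pred = spec.cdf(pv, t, validate=False)
        res = pred - y
        return np.nan_to_num(res, nan=1e8, posinf=1e8, neginf=-1e8)

    best = None
    any_success = False
    for start in range(max(1, options.multistart)):
        theta0 = x0 if start == 0 else x0 + rng.normal(0.0, options.jitter_sd, size=x0.size)
        try:
            sol = least_squares(
                residuals,
                theta0,
                method="lm",
                ftol=options.tol,
                xtol=options.tol,
                gtol=options.tol,
                max_nfev=options.max_iter * (spec.k + 1),
            )
        except Exception:  # pragma: no cover - LM very rarely raises
            continue
        any_success = any_success or bool(sol.success)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not any_success:
        return _failure(profile, spec, "no-convergence")

    values = _from_theta(spec, best.x)
    estimates = ParamVector().with_values(spec.param_names, values)
    if not np.all(np.isfinite(values)):
        return _failure(profile, spec, "nan-estimates")
    ok, violations = spec.validate(estimates)
    if not ok:
        return _failure(profile, spec, "constraint-violation", estimates=estimates)

    # Biological-plausibility screen on a dense grid (catches pathological
    # location estimates between sample points).
    dense = np.linspace(0.0, float(t[-1]), options.dense_grid_points)
    with np.errstate(all="ignore"):
        dense_pred = np.asarray(spec.cdf(estimates, dense, validate=False))
        pred = np.asarray(spec.cdf(estimates, t, validate=False))
    if not np.all(np.isfinite(pred)):
        return _failure(profile, spec, "nan-estimates", estimates=estimates)
    if np.any(dense_pred < -1e-8) or np.any(pred < -1e-8):
        return _failure(profile, spec, "negative-predictions", estimates=estimates)

    gof = goodness_of_fit(y, pred, spec.k)
    se = _standard_errors(spec, estimates, t, gof.rss, profile.n)
    kin = kinetic_summary(spec, estimates)
    return FitResult(
        sample_id=profile.sample_id,
        feed_category=profile.feed_category,
        model_name=spec.name,
        converged=True,
        failure_reason=None,
        estimates=estimates,
        standard_errors=se,
        n=profile.n,
        k=spec.k,
        rss=gof.rss,
        r2=gof.r2,
        rmse=gof.rmse,
        loglik=gof.loglik,
        bic=gof.bic,
        kinetics=kin,
    )


def _standard_errors(
    spec: ModelSpec, estimates: ParamVector, t: np.ndarray, rss: float, n: int
) -> dict[str, float]:
    """Asymptotic standard errors from a finite-difference Jacobian."""
    k = spec.k
    if n <= k:
        return {name: math.nan for name in spec.param_names}
    values = estimates.values_for(spec.param_names)
    J = np.empty((t.size, k))
    for j, name in enumerate(spec.param_names):
        h = 1e-6 * max(1.0, abs(values[j]))
        hi = values.copy()
        lo = values.copy()
        hi[j] += h
        lo[j] -= h
        pv_hi = ParamVector().with_values(spec.param_names, hi)
        pv_lo = ParamVector().with_values(spec.param_names, lo)
        with np.errstate(all="ignore"):
            J[:, j] = (
                np.asarray(spec.cdf(pv_hi, t, validate=False))
                - np.asarray(spec.cdf(pv_lo, t, validate=False))
            ) / (2.0 * h)
    sigma2 = rss / (n - k)
    try:
        cov = sigma2 * np.linalg.inv(J.T @ J)
        diag = np.diag(cov)
        se = np.sqrt(np.where(diag > 0, diag, np.nan))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return dict(zip(spec.param_names, (float(x) for x in se)))


def fit_all(
    profiles: Iterable[GPProfile],
    models: Iterable[ModelSpec | str] | None = None,
    options: FitOptions | None = None,
) -> list[FitResult]:
    """One record per profile x model pair; failures captured, never raised."""
    profiles = list(profiles)
    specs = [get_model(m) if isinstance(m, str) else m for m in (models if models is not None else MODELS)]
    if not profiles or not specs:
        raise ValueError("fit_all needs at least one profile and one model")
    options = options or FitOptions()
    results: list[FitResult] = []
    n_fail = 0
    for i, profile in enumerate(profiles):
        for spec in specs:
            try:
                res = fit_model(profile, spec, options)
            except Exception as exc:  # structural problems become failure records
                logger.warning("fit %s x %s errored: %s", profile.sample_id, spec.name, exc)
                res = _failure(profile, spec, "no-convergence")
            if not res.converged:
                n_fail += 1
            results.append(res)
        if (i + 1) % 100 == 0:
            logger.info("fitted %d/%d profiles (%d failures so far)", i + 1, len(profiles), n_fail)
    logger.info(
        "fit_all: %d profiles x %d models = %d records, %d failures",
        len(profiles), len(specs), len(results), n_fail,
    )
    return results


def residual_diagnostics(result: FitResult, profile: GPProfile) -> ResidualDiagnostics:
    """Per-time residual table plus a sign-runs summary for pattern checks."""
    if not result.converged:
        raise ValueError("residual diagnostics need a converged fit")
    t, y = profile.arrays()
    pred = result.predicted(profile)
    resid = y - pred
    signs = np.sign(resid[np.abs(resid) > 1e-8])  # numerically-zero residuals excluded
    runs = int(1 + np.sum(signs[1:] != signs[:-1])) if signs.size else 0
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    expected = 1.0 + 2.0 * n_pos * n_neg / (n_pos + n_neg) if (n_pos + n_neg) else 0.0
    table = pd.DataFrame(
        {"time_h": t, "observed": y, "predicted": pred, "residual": resid}
    )
    return ResidualDiagnostics(
        table=table,
        mean_residual=float(resid.mean()),
        sign_runs=runs,
        expected_runs=float(expected),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def results_to_frame(results: Sequence[FitResult]) -> pd.DataFrame:
    """Flatten fit records to one tidy row per profile x model."""
    rows = []
    for res in results:
        row: dict[str, object] = {
            "sample_id": res.sample_id,
            "feed_category": res.feed_category,
            "model_name": res.model_name,
            "converged": res.converged,
            "failure_reason": res.failure_reason or "none",
            "n": res.n,
            "k": res.k,
        }
        est = res.estimates.as_dict(drop_none=False) if res.estimates else {}
        for name in ("m", "r", "mu", "a", "p"):
            row[name] = est.get(name)
            row[f"se_{name}"] = res.standard_errors.get(name)
        row.update(rss=res.rss, r2=res.r2, rmse=res.rmse, loglik=res.loglik, bic=res.bic)
        if res.kinetics is not None:
            kin = res.kinetics
            row.update(
                t_half=kin.t_half,
                gp_half=kin.gp_half,
                t_star=kin.t_star,
                t_star_defined=kin.t_star_defined,
                gp_star=kin.gp_star,
                gp0=kin.gp0,
            )
        else:
            row.update(
                t_half=math.nan, gp_half=math.nan, t_star=math.nan,
                t_star_defined=False, gp_star=math.nan, gp0=math.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)
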