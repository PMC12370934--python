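"""Catalogue of 21 nonlinear gas-production models.

Each entry is a scaled cumulative distribution function ``F(t)`` rising from
(at most) 0 toward an asymptote ``m`` (mL gas per 200 mg DM), together with
its rate curve ``f(t) = F'(t)`` (mL/h), closed-form inflection time ``t*``
(mode of ``f``) and half-life ``t0.5`` (median of ``f``, where ``F = m/2``),
the parameter constraints under which those formulas are meaningful, and the
time domain on which the model is defined.

Parameters are kept in a fixed canonical order ``(m, r, mu, a, p)`` with
explicit absence (``None``) so result tables line up across models of
different arity.  All logarithms are natural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "PARAM_ORDER",
    "ParamVector",
    "ModelSpec",
    "KineticSummary",
    "InvalidParameterError",
    "UnknownModelError",
    "MODELS",
    "MODEL_NAMES",
    "list_models",
    "get_model",
    "validate_params",
    "evaluate_cdf",
    "evaluate_pdf",
    "kinetic_summary",
]

PARAM_ORDER = ("m", "r", "mu", "a", "p")

LN2 = math.log(2.0)


class InvalidParameterError(ValueError):
    """Raised when a parameter vector violates a model's assumptions."""

    def __init__(self, model_name: str, violations: Sequence[str]):
        self.model_name = model_name
        self.violations = list(violations)
        super().__init__(
            f"invalid parameters for {model_name!r}: violated "
            + ", ".join(self.violations)
        )


class UnknownModelError(KeyError):
    """Raised when a model name is not in the catalogue."""


@dataclass(frozen=True)
class ParamVector:
    """Canonical parameter vector; entries absent from a model stay ``None``.

    m : asymptotic maximum gas production (mL), required by every model.
    r : rate constant (1/h); absent in models without time scaling.
    mu : location / lag parameter (h); unbounded in sign where present.
    a, p : dimensionless shape parameters.
    """

    m: float | None = None
    r: float | None = None
    mu: float | None = None
    a: float | None = None
    p: float | None = None

    def as_dict(self, drop_none: bool = True) -> dict[str, float]:
        d = {k: getattr(self, k) for k in PARAM_ORDER}
        if drop_none:
            d = {k: v for k, v in d.items() if v is not None}
        return d

    def values_for(self, names: Iterable[str]) -> np.ndarray:
        vals = []
        for name in names:
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"parameter {name!r} is absent from {self}")
            vals.append(float(v))
        return np.asarray(vals, dtype=float)

    def with_values(self, names: Iterable[str], values: Iterable[float]) -> "ParamVector":
        return replace(self, **dict(zip(names, (float(v) for v in values))))


@dataclass(frozen=True)
class Constraint:
    label: str  # e.g. "a>1"
    check: Callable[[ParamVector], bool]


@dataclass(frozen=True)
class KineticSummary:
    """Analytic kinetic landmarks of a fitted curve.

    ``t_star`` is reported as 0.0 with ``t_star_defined=False`` when the
    closed form's precondition fails (monotone-rate models, or shape
    estimates at/below the threshold that makes the mode real and inside
    the time domain).
    """

    t_half: float
    gp_half: float
    t_star: float
    t_star_defined: bool
    gp_star: float
    gp0: float


@dataclass(frozen=True)
class ModelSpec:
    name: str
    number: int  # catalogue position, 1-based
    param_names: tuple[str, ...]
    _cdf: Callable[[np.ndarray, ParamVector], np.ndarray]
    _pdf: Callable[[np.ndarray, ParamVector], np.ndarray]
    _t_star: Callable[[ParamVector], float | None]
    _t_half: Callable[[ParamVector], float]
    constraints: tuple[Constraint, ...]
    domain: str  # "t>=0", "t>=mu" or "real"
    formulas: dict[str, str]

    @property
    def k(self) -> int:
        return len(self.param_names)

    def domain_low(self, params: ParamVector) -> float:
        if self.domain == "t>=0":
            return 0.0
        if self.domain == "t>=mu":
            return float(params.mu)
        return -math.inf

    def validate(self, params: ParamVector) -> tuple[bool, list[str]]:
        violations = [c.label for c in self.constraints if not c.check(params)]
        return (not violations), violations

    def require_valid(self, params: ParamVector) -> None:
        ok, violations = self.validate(params)
        if not ok:
            raise InvalidParameterError(self.name, violations)

    def cdf(self, params: ParamVector, t, validate: bool = True) -> np.ndarray:
        if validate:
            self.require_valid(params)
        t_arr = np.asarray(t, dtype=float)
        scalar = t_arr.ndim == 0
        t_arr = np.atleast_1d(t_arr)
        with np.errstate(all="ignore"):
            out = self._cdf(t_arr, params)
        lo = self.domain_low(params)
        if math.isfinite(lo):
            out = np.where(t_arr < lo, 0.0, out)
        return float(out[0]) if scalar else out

    def pdf(self, params: ParamVector, t, validate: bool = True) -> np.ndarray:
        if validate:
            self.require_valid(params)
        t_arr = np.asarray(t, dtype=float)
        scalar = t_arr.ndim == 0
        t_arr = np.atleast_1d(t_arr)
        with np.errstate(all="ignore"):
            out = self._pdf(t_arr, params)
        lo = self.domain_low(params)
        if math.isfinite(lo):
            out = np.where(t_arr < lo, 0.0, out)
        return float(out[0]) if scalar else out

    def t_half(self, params: ParamVector) -> float:
        return float(self._t_half(params))

    def t_star(self, params: ParamVector) -> tuple[float, bool]:
        """Analytic inflection time and a flag for whether it is defined.

        The closed form must yield a real number at or above the lower end
        of the time domain; otherwise (0.0, False) is returned, matching the
        convention of printing 0.00 for mode-less fits.
        """
        value = self._t_star(params)
        if value is None or not math.isfinite(value):
            return 0.0, False
        lo = self.domain_low(params)
        if math.isfinite(lo) and value < lo:
            return 0.0, False
        return float(value), True


# ---------------------------------------------------------------------------
# Numeric helpers

def _softplus(t: np.ndarray) -> np.ndarray:
    # log(1 + e^t) without overflow
    out = np.empty_like(t)
    hi = t > 30.0
    out[hi] = t[hi] + np.log1p(np.exp(-t[hi]))
    out[~hi] = np.log1p(np.exp(t[~hi]))
    return out


def _safe_pos(t: np.ndarray) -> np.ndarray:
    """Replace non-positive times by NaN so power laws never see t<=0."""
    return np.where(t > 0.0, t, np.nan)


def _fill0(values: np.ndarray, t: np.ndarray, at: float = 0.0) -> np.ndarray:
    """Patch the (right-)limit value at the lower domain edge."""
    return np.where(t <= 0.0, at, values)


# ---------------------------------------------------------------------------
# Model definitions (catalogue order)

def _burr3_cdf(t, pv):
    ts = _safe_pos(t)
    return _fill0(pv.m * (1.0 + ts ** (-pv.a)) ** (-pv.p), t)


def _burr3_pdf(t, pv):
    ts = _safe_pos(t)
    val = pv.m * pv.a * pv.p * (1.0 + ts ** (-pv.a)) ** (-pv.p) / ((1.0 + ts ** pv.a) * ts)
    return _fill0(val, t)


def _burr12_cdf(t, pv):
    return pv.m - pv.m * (1.0 + (pv.r * t) ** pv.a) ** (-pv.p)


def _burr12_pdf(t, pv):
    ts = _safe_pos(t)
    val = pv.m * pv.a * pv.p * (pv.r * ts) ** pv.a / ((1.0 + (pv.r * ts) ** pv.a) ** (pv.p + 1.0) * ts)
    return _fill0(val, t)  # a>1 -> limit 0 at t=0


def _cauchy_cdf(t, pv):
    return pv.m * (math.pi + 2.0 * np.arctan(pv.r * (t - pv.mu))) / (2.0 * math.pi)


def _cauchy_pdf(t, pv):
    return pv.m * pv.r / (math.pi * (1.0 + pv.r ** 2 * (t - pv.mu) ** 2))


def _dagum_cdf(t, pv):
    ts = _safe_pos(t)
    return _fill0(pv.m * (1.0 + (pv.r * ts) ** (-pv.a)) ** (-pv.p), t)


def _dagum_pdf(t, pv):
    ts = _safe_pos(t)
    val = pv.m * pv.a * pv.p * (pv.r * ts) ** (pv.a * pv.p) / (
        (1.0 + (pv.r * ts) ** pv.a) ** (pv.p + 1.0) * ts
    )
    return _fill0(val, t)


def _exp2_cdf(t, pv):
    return pv.m * -np.expm1(-pv.r * t)


def _exp2_pdf(t, pv):
    return pv.m * pv.r * np.exp(-pv.r * t)


def _exp3_cdf(t, pv):
    return pv.m * -np.expm1(-pv.r * (t - pv.mu))


def _exp3_pdf(t, pv):
    return pv.m * pv.r * np.exp(-pv.r * (t - pv.mu))


def _expexp_cdf(t, pv):
    return pv.m * (-np.expm1(-pv.r * t)) ** pv.a


def _expexp_pdf(t, pv):
    ts = _safe_pos(t)
    val = pv.m * pv.a * pv.r * (-np.expm1(-pv.r * ts)) ** pv.a / np.expm1(pv.r * ts)
    if pv.a > 1.0:
        lim = 0.0
    elif pv.a == 1.0:
        lim = pv.m * pv.r
    else:
        lim = np.inf
    return _fill0(val, t, at=lim)


def _frechet_cdf(t, pv):
    ts = _safe_pos(t)
    return _fill0(pv.m * np.exp(-((pv.r * ts) ** (-pv.a))), t)


def _frechet_pdf(t, pv):
    ts = _safe_pos(t)
    val = pv.m * pv.a * np.exp(-((pv.r * ts) ** (-pv.a))) / (pv.r ** pv.a * ts ** (1.0 + pv.a))
    return _fill0(val, t)


def _genlog_cdf(t, pv):
    return pv.m - pv.m * np.exp(-pv.a * _softplus(t))


def _genlog_pdf(t, pv):
    return pv.m * pv.a * np.exp(t - (pv.a + 1.0) * _softplus(t))


def _gompertz_cdf(t, pv):
    ln_a = math.log(pv.a)
    z = pv.r * (1.0 - np.exp(t * ln_a)) / ln_a
    return pv.m * -np.expm1(z)


def _gompertz_pdf(t, pv):
    ln_a = math.log(pv.a)
    at = np.exp(t * ln_a)
    return pv.m * pv.r * at * np.exp(pv.r * (1.0 - at) / ln_a)


def _gumbel_cdf(t, pv):
    return pv.m * -np.expm1(-np.exp(pv.r * (t - pv.mu)))


def _gumbel_pdf(t, pv):
    z = pv.r * (t - pv.mu)
    return pv.m * pv.r * np.exp(z - np.exp(z))


def _halfcauchy_cdf(t, pv):
    return 2.0 * pv.m * np.arctan(pv.r * (t - pv.mu)) / math.pi


def _halfcauchy_pdf(t, pv):
    return 2.0 * pv.m * pv.r / (math.pi * (1.0 + pv.r ** 2 * (t - pv.mu) ** 2))


def _halflog_cdf(t, pv):
    return pv.m * np.tanh(pv.r * t / 2.0)


def _halflog_pdf(t, pv):
    return pv.m * pv.r / (1.0 + np.cosh(pv.r * t))


def _invexp_cdf(t, pv):
    ts = _safe_pos(t)
    return _fill0(pv.m * np.exp(-1.0 / (pv.r * ts)), t)


def _invexp_pdf(t, pv):
    ts = _safe_pos(t)
    val = pv.m * np.exp(-1.0 / (pv.r * ts)) / (pv.r * ts ** 2)
    return _fill0(val, t)


def _invpara_cdf(t, pv):
    ts = _safe_pos(t)
    return _fill0(pv.m * (1.0 + (pv.r * ts) ** (-pv.a)) ** (-pv.a), t)


def _invpara_pdf(t, pv):
    ts = _safe_pos(t)
    val = pv.m * pv.a ** 2 * (pv.r * ts) ** (pv.a ** 2) / (
        (1.0 + (pv.r * ts) ** pv.a) ** (1.0 + pv.a) * ts
    )
    return _fill0(val, t)


def _logistic_cdf(t, pv):
    return pv.m * 0.5 * (1.0 + np.tanh(pv.r * (t - pv.mu) / 2.0))


def _logistic_pdf(t, pv):
    return pv.m * pv.r / (2.0 + 2.0 * np.cosh(pv.r * (t - pv.mu)))


def _loglog_cdf(t, pv):
    return pv.m - pv.m / (1.0 + (pv.r * t) ** pv.a)


def _loglog_pdf(t, pv):
    ts = _safe_pos(t)
    val = pv.m * pv.a * pv.r ** pv.a * ts ** (pv.a - 1.0) / (1.0 + (pv.r * ts) ** pv.a) ** 2
    if pv.a > 1.0:
        lim = 0.0
    elif pv.a == 1.0:
        lim = pv.m * pv.r
    else:
        lim = np.inf
    return _fill0(val, t, at=lim)


def _para_cdf(t, pv):
    return pv.m - pv.m * (1.0 + (pv.r * t) ** pv.a) ** (-pv.a)


def _para_pdf(t, pv):
    ts = _safe_pos(t)
    val = pv.m * pv.a ** 2 * (pv.r * ts) ** pv.a / ((1.0 + (pv.r * ts) ** pv.a) ** (pv.a + 1.0) * ts)
    return _fill0(val, t)


def _ray2_cdf(t, pv):
    return pv.m * -np.expm1(-((pv.r * t) ** 2) / 2.0)


def _ray2_pdf(t, pv):
    return pv.m * pv.r ** 2 * t * np.exp(-((pv.r * t) ** 2) / 2.0)


def _ray3_cdf(t, pv):
    return pv.m * -np.expm1(-(pv.r ** 2) * (t - pv.mu) ** 2 / 2.0)


def _ray3_pdf(t, pv):
    return pv.m * pv.r ** 2 * (t - pv.mu) * np.exp(-(pv.r ** 2) * (t - pv.mu) ** 2 / 2.0)


def _weibull_cdf(t, pv):
    return pv.m * -np.expm1(-((pv.r * t) ** pv.a))


def _weibull_pdf(t, pv):
    ts = _safe_pos(t)
    val = pv.m * pv.a * pv.r ** pv.a * ts ** (pv.a - 1.0) * np.exp(-((pv.r * ts) ** pv.a))
    if pv.a > 1.0:
        lim = 0.0
    elif pv.a == 1.0:
        lim = pv.m * pv.r
    else:
        lim = np.inf
    return _fill0(val, t, at=lim)


# --- closed-form landmarks --------------------------------------------------

def _ts_burr3(pv):
    x = (pv.a * pv.p - 1.0) / (1.0 + pv.a)
    return x ** (1.0 / pv.a) if x > 0 else None


def _ts_burr12(pv):
    x = (pv.a - 1.0) / (1.0 + pv.a * pv.p)
    return x ** (1.0 / pv.a) / pv.r if x > 0 else None


def _ts_dagum(pv):
    x = (pv.a * pv.p - 1.0) / (pv.a + 1.0)
    return x ** (1.0 / pv.a) / pv.r if x > 0 else None


def _ts_expexp(pv):
    return math.log(pv.a) / pv.r if pv.a > 1.0 else None


def _ts_gompertz(pv):
    ln_a = math.log(pv.a)
    x = ln_a / pv.r
    return math.log(x) / ln_a if x > 0 else None


def _ts_invpara(pv):
    return (pv.a - 1.0) ** (1.0 / pv.a) / pv.r if pv.a > 1.0 else None


def _ts_loglog(pv):
    if pv.a <= 1.0:
        return None
    return ((pv.a - 1.0) / (pv.a + 1.0)) ** (1.0 / pv.a) / pv.r


def _ts_para(pv):
    if pv.a <= 1.0:
        return None
    return ((pv.a - 1.0) / (pv.a ** 2 + 1.0)) ** (1.0 / pv.a) / pv.r


def _ts_weibull(pv):
    if pv.a <= 1.0:
        return None
    return ((pv.a - 1.0) / pv.a) ** (1.0 / pv.a) / pv.r


def _positive(name: str) -> Constraint:
    return Constraint(f"{name}>0", lambda pv, _n=name: getattr(pv, _n) is not None and getattr(pv, _n) > 0)


def _greater1(name: str) -> Constraint:
    return Constraint(f"{name}>1", lambda pv, _n=name: getattr(pv, _n) is not None and getattr(pv, _n) > 1)


def _present(name: str) -> Constraint:
    return Constraint(f"{name} present", lambda pv, _n=name: getattr(pv, _n) is not None)


def _spec(number, name, params, cdf, pdf, t_star, t_half, extra, domain, formulas):
    cons: list[Constraint] = []
    for pname in params:
        if pname == "m":
            cons.append(_positive("m"))
        elif pname == "r":
            cons.append(_positive("r"))
        elif pname == "mu":
            cons.append(_present("mu"))
    cons.extend(extra)
    return ModelSpec(
        name=name,
        number=number,
        param_names=tuple(params),
        _cdf=cdf,
        _pdf=pdf,
        _t_star=t_star,
        _t_half=t_half,
        constraints=tuple(cons),
        domain=domain,
        formulas=formulas,
    )


MODELS: tuple[ModelSpec, ...] = (
    _spec(
        1, "Burr III", ("m", "a", "p"), _burr3_cdf, _burr3_pdf,
        _ts_burr3,
        lambda pv: (2.0 ** (1.0 / pv.p) - 1.0) ** (-1.0 / pv.a),
        [_greater1("a"), _greater1("p")], "t>=0",
        {"F": "m*(1+t^-a)^-p", "f": "m*a*p*(1+t^-a)^-p/((1+t^a)*t)",
         "t*": "((a*p-1)/(1+a))^(1/a)", "t0.5": "(2^(1/p)-1)^(-1/a)"},
    ),
    _spec(
        2, "Burr XII", ("m", "r", "a", "p"), _burr12_cdf, _burr12_pdf,
        _ts_burr12,
        lambda pv: (2.0 ** (1.0 / pv.p) - 1.0) ** (1.0 / pv.a) / pv.r,
        [_greater1("a"), _positive("p")], "t>=0",
        {"F": "m-m*(1+(r*t)^a)^-p", "f": "m*a*p*(r*t)^a/((1+(r*t)^a)^(p+1)*t)",
         "t*": "((a-1)/(1+a*p))^(1/a)/r", "t0.5": "(2^(1/p)-1)^(1/a)/r"},
    ),
    _spec(
        3, "Cauchy", ("m", "r", "mu"), _cauchy_cdf, _cauchy_pdf,
        lambda pv: pv.mu, lambda pv: pv.mu,
        [], "real",
        {"F": "m*(pi+2*arctan(r*(t-mu)))/(2*pi)", "f": "m*r/(pi*(1+r^2*(t-mu)^2))",
         "t*": "mu", "t0.5": "mu"},
    ),
    _spec(
        4, "Dagum", ("m", "r", "a", "p"), _dagum_cdf, _dagum_pdf,
        _ts_dagum,
        lambda pv: (2.0 ** (1.0 / pv.p) - 1.0) ** (-1.0 / pv.a) / pv.r,
        [_greater1("a"), _greater1("p")], "t>=0",
        {"F": "m*(1+(r*t)^-a)^-p", "f": "m*a*p*(r*t)^(a*p)/((1+(r*t)^a)^(p+1)*t)",
         "t*": "((a*p-1)/(a+1))^(1/a)/r", "t0.5": "(2^(1/p)-1)^(-1/a)/r"},
    ),
    _spec(
        5, "Exponential 2p", ("m", "r"), _exp2_cdf, _exp2_pdf,
        lambda pv: 0.0, lambda pv: LN2 / pv.r,
        [], "t>=0",
        {"F": "m*(1-exp(-r*t))", "f": "m*r*exp(-r*t)", "t*": "0", "t0.5": "ln(2)/r"},
    ),
    _spec(
        6, "Exponential 3p", ("m", "r", "mu"), _exp3_cdf, _exp3_pdf,
        lambda pv: pv.mu, lambda pv: pv.mu + LN2 / pv.r,
        [], "t>=mu",
        {"F": "m*(1-exp(-r*(t-mu)))", "f": "m*r*exp(-r*(t-mu))",
         "t*": "mu", "t0.5": "mu+ln(2)/r"},
    ),
    _spec(
        7, "Exponentiated exponential", ("m", "r", "a"), _expexp_cdf, _expexp_pdf,
        _ts_expexp,
        lambda pv: -math.log(1.0 - 2.0 ** (-1.0 / pv.a)) / pv.r,
        [_positive("a")], "t>=0",
        {"F": "m*(1-exp(-r*t))^a", "f": "m*a*r*(1-exp(-r*t))^a/(exp(r*t)-1)",
         "t*": "ln(a)/r", "t0.5": "-ln(1-2^(-1/a))/r"},
    ),
    _spec(
        8, "Frechet", ("m", "r", "a"), _frechet_cdf, _frechet_pdf,
        lambda pv: (pv.a / (1.0 + pv.a)) ** (1.0 / pv.a) / pv.r,
        lambda pv: LN2 ** (-1.0 / pv.a) / pv.r,
        [_positive("a")], "t>=0",
        {"F": "m*exp(-(r*t)^-a)", "f": "m*a*exp(-(r*t)^-a)/(r^a*t^(1+a))",
         "t*": "(a/(1+a))^(1/a)/r", "t0.5": "ln(2)^(-1/a)/r"},
    ),
    _spec(
        9, "Generalized logistic", ("m", "a"), _genlog_cdf, _genlog_pdf,
        lambda pv: -math.log(pv.a),
        lambda pv: math.log(2.0 ** (1.0 / pv.a) - 1.0),
        [_positive("a")], "real",
        {"F": "m-m*(1+exp(t))^-a", "f": "m*a*exp(t)/(1+exp(t))^(a+1)",
         "t*": "-ln(a)", "t0.5": "ln(2^(1/a)-1)"},
    ),
    _spec(
        10, "Gompertz", ("m", "r", "a"), _gompertz_cdf, _gompertz_pdf,
        _ts_gompertz,
        lambda pv: math.log(1.0 + LN2 * math.log(pv.a) / pv.r) / math.log(pv.a),
        [_greater1("a")], "t>=0",
        {"F": "m*(1-exp((r-r*a^t)/ln(a)))", "f": "m*r*a^t*exp((r-r*a^t)/ln(a))",
         "t*": "ln(ln(a)/r)/ln(a)", "t0.5": "ln(1+ln(2)*ln(a)/r)/ln(a)"},
    ),
    _spec(
        11, "Gumbel", ("m", "r", "mu"), _gumbel_cdf, _gumbel_pdf,
        lambda pv: pv.mu, lambda pv: pv.mu + math.log(LN2) / pv.r,
        [], "real",
        {"F": "m-m*exp(-exp(r*(t-mu)))", "f": "m*r*exp(r*(t-mu)-exp(r*(t-mu)))",
         "t*": "mu", "t0.5": "mu+ln(ln(2))/r"},
    ),
    _spec(
        12, "Half Cauchy", ("m", "r", "mu"), _halfcauchy_cdf, _halfcauchy_pdf,
        lambda pv: pv.mu, lambda pv: pv.mu + 1.0 / pv.r,
        [], "t>=mu",
        {"F": "2*m*arctan(r*(t-mu))/pi", "f": "2*m*r/(pi*(1+r^2*(t-mu)^2))",
         "t*": "mu", "t0.5": "mu+1/r"},
    ),
    _spec(
        13, "Half logistic", ("m", "r"), _halflog_cdf, _halflog_pdf,
        lambda pv: 0.0, lambda pv: math.log(3.0) / pv.r,
        [], "t>=0",
        {"F": "m*tanh(r*t/2)", "f": "m*r/(1+cosh(r*t))", "t*": "0", "t0.5": "ln(3)/r"},
    ),
    _spec(
        14, "Inverse exponential", ("m", "r"), _invexp_cdf, _invexp_pdf,
        lambda pv: 1.0 / (2.0 * pv.r), lambda pv: 1.0 / (pv.r * LN2),
        [], "t>=0",
        {"F": "m*exp(-1/(r*t))", "f": "m*exp(-1/(r*t))/(r*t^2)",
         "t*": "1/(2*r)", "t0.5": "1/(r*ln(2))"},
    ),
    _spec(
        15, "Inverse paralogistic", ("m", "r", "a"), _invpara_cdf, _invpara_pdf,
        _ts_invpara,
        lambda pv: (2.0 ** (1.0 / pv.a) - 1.0) ** (-1.0 / pv.a) / pv.r,
        [_greater1("a")], "t>=0",
        {"F": "m*(1+(r*t)^-a)^-a", "f": "m*a^2*(r*t)^(a^2)/((1+(r*t)^a)^(1+a)*t)",
         "t*": "(a-1)^(1/a)/r", "t0.5": "(2^(1/a)-1)^(-1/a)/r"},
    ),
    _spec(
        16, "Logistic", ("m", "r", "mu"), _logistic_cdf, _logistic_pdf,
        lambda pv: pv.mu, lambda pv: pv.mu,
        [], "real",
        {"F": "m/(1+exp(-r*(t-mu)))", "f": "m*r/(2+2*cosh(r*(t-mu)))",
         "t*": "mu", "t0.5": "mu"},
    ),
    _spec(
        17, "Log-logistic", ("m", "r", "a"), _loglog_cdf, _loglog_pdf,
        _ts_loglog, lambda pv: 1.0 / pv.r,
        [_positive("a")], "t>=0",
        {"F": "m-m/(1+(r*t)^a)", "f": "m*a*r^a*t^(a-1)/(1+(r*t)^a)^2",
         "t*": "((a-1)/(a+1))^(1/a)/r", "t0.5": "1/r"},
    ),
    _spec(
        18, "Paralogistic", ("m", "r", "a"), _para_cdf, _para_pdf,
        _ts_para,
        lambda pv: (2.0 ** (1.0 / pv.a) - 1.0) ** (1.0 / pv.a) / pv.r,
        [_greater1("a")], "t>=0",
        {"F": "m-m*(1+(r*t)^a)^-a", "f": "m*a^2*(r*t)^a/((1+(r*t)^a)^(a+1)*t)",
         "t*": "((a-1)/(a^2+1))^(1/a)/r", "t0.5": "(2^(1/a)-1)^(1/a)/r"},
    ),
    _spec(
        19, "Rayleigh 2p", ("m", "r"), _ray2_cdf, _ray2_pdf,
        lambda pv: 1.0 / pv.r, lambda pv: math.sqrt(math.log(4.0)) / pv.r,
        [], "t>=0",
        {"F": "m*(1-exp(-(r*t)^2/2))", "f": "m*r^2*t*exp(-(r*t)^2/2)",
         "t*": "1/r", "t0.5": "sqrt(ln(4))/r"},
    ),
    _spec(
        20, "Rayleigh 3p", ("m", "r", "mu"), _ray3_cdf, _ray3_pdf,
        lambda pv: pv.mu + 1.0 / pv.r,
        lambda pv: pv.mu + math.sqrt(math.log(4.0)) / pv.r,
        [], "t>=mu",
        {"F": "m*(1-exp(-r^2*(t-mu)^2/2))", "f": "m*r^2*(t-mu)*exp(-r^2*(t-mu)^2/2)",
         "t*": "mu+1/r", "t0.5": "mu+sqrt(ln(4))/r"},
    ),
    _spec(
        21, "Weibull", ("m", "r", "a"), _weibull_cdf, _weibull_pdf,
        _ts_weibull, lambda pv: LN2 ** (1.0 / pv.a) / pv.r,
        [_greater1("a")], "t>=0",
        {"F": "m*(1-exp(-(r*t)^a))", "f": "m*a*r^a*t^(a-1)*exp(-(r*t)^a)",
         "t*": "((a-1)/a)^(1/a)/r", "t0.5": "ln(2)^(1/a)/r"},
    ),
)

MODEL_NAMES: tuple[str, ...] = tuple(spec.name for spec in MODELS)
_BY_NAME = {spec.name: spec for spec in MODELS}


def list_models() -> tuple[ModelSpec, ...]:
    """All 21 catalogue entries in their fixed order."""
    return MODELS


def get_model(name: str) -> ModelSpec:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise UnknownModelError(name) from None


def validate_params(model: ModelSpec | str, params: ParamVector) -> tuple[bool, list[str]]:
    """Verdict plus the list of violated constraint labels (empty iff valid)."""
    spec = get_model(model) if isinstance(model, str) else model
    return spec.validate(params)


def evaluate_cdf(model: ModelSpec | str, params: ParamVector, t) -> np.ndarray:
    spec = get_model(model) if isinstance(model, str) else model
    return spec.cdf(params, t)


def evaluate_pdf(model: ModelSpec | str, params: ParamVector, t) -> np.ndarray:
    spec = get_model(model) if isinstance(model, str) else model
    return spec.pdf(params, t)


def kinetic_summary(model: ModelSpec | str, params: ParamVector) -> KineticSummary:
    """Closed-form half-life / inflection summary for one parameter vector."""
    spec = get_model(model) if isinstance(model, str) else model
    spec.require_valid(params)
    t_half = spec.t_half(params)
    t_star, defined = spec.t_star(params)
    gp_star = float(spec.cdf(params, t_star, validate=False)) if defined else 0.0
    gp0 = float(spec.cdf(params, 0.0, validate=False))
    return KineticSummary(
        t_half=t_half,
        gp_half=params.m / 2.0,
        t_star=t_star,
        t_star_defined=defined,
        gp_star=gp_star,
        gp0=gp0,
    )
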