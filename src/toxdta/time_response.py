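"""Time-response curve fitting and lethal-time (LT10/LT50) estimation.

Percent survival through time under a continuous press exposure is fitted with
the standard sigmoidal dose-response families — log-logistic with 3, 4 or 5
parameters (including the 3-parameter form with its upper asymptote fixed at
100% survival, the dominant model for this design) and the two 4-parameter
Weibull forms — by nonlinear least squares.  Candidate fits are compared by
AIC, and the selected curve is inverted to the lethal time LT_p: the exposure
duration at which survival has declined by p percent.  Confidence limits come
from the delta method on the natural (day) scale with a t quantile, so a wide
or weakly identified curve can legitimately produce a negative lower limit.

Parameter naming follows the dose-response modelling convention: ``b`` slope,
``c`` lower asymptote (%), ``d`` upper asymptote (%), ``e`` inflection time
(days), ``f`` asymmetry.

Replicate-level percent survival at each observation day is treated as
independent Gaussian data; the repeated-measures correlation of a cohort
observed through time is ignored (a known limitation, see the methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ModelFamily",
    "ModelFit",
    "LTEstimate",
    "FAMILIES",
    "FAMILY_ORDER",
    "TimeResponseError",
    "InsufficientDataError",
    "SelectionError",
    "LTUnavailableError",
    "NonToxicDirectionError",
    "model_curve",
    "fit_model",
    "select_best",
    "estimate_lt",
]

PARAM_NAMES = ("b", "c", "d", "e", "f")


class TimeResponseError(Exception):
    """Base class for time-response modelling errors."""


class InsufficientDataError(TimeResponseError):
    """Fewer distinct observation days than free parameters."""


class SelectionError(TimeResponseError):
    """No converged fit available; the group is non-modellable."""


class LTUnavailableError(TimeResponseError):
    """A lethal-time estimate cannot be derived from this fit."""


class NonToxicDirectionError(LTUnavailableError):
    """The fitted curve does not decrease with time (no decline to invert)."""


@dataclass(frozen=True)
class ModelFamily:
    """One sigmoidal time-response family.

    ``free`` names the estimated parameters; the rest of (b, c, d, e, f) are
    held at ``fixed`` values.  ``k`` is the number of free parameters, which
    drives the AIC penalty and the residual degrees of freedom.
    """

    name: str
    kind: str  # "LL" | "W1" | "W2"
    free: tuple[str, ...]
    fixed: dict[str, float]

    @property
    def k(self) -> int:
        return len(self.free)

    def full_params(self, free_values: Sequence[float]) -> dict[str, float]:
        params = dict(self.fixed)
        params.update(zip(self.free, free_values))
        return params


#: The candidate set, in the deterministic tie-break order used by selection:
#: fewest parameters first, then the fixed study order.
FAMILIES: dict[str, ModelFamily] = {
    "LL3u100": ModelFamily("LL3u100", "LL", ("b", "e"), {"c": 0.0, "d": 100.0, "f": 1.0}),
    "LL3": ModelFamily("LL3", "LL", ("b", "d", "e"), {"c": 0.0, "f": 1.0}),
    "LL4": ModelFamily("LL4", "LL", ("b", "c", "d", "e"), {"f": 1.0}),
    "W14": ModelFamily("W14", "W1", ("b", "c", "d", "e"), {"f": 1.0}),
    "W24": ModelFamily("W24", "W2", ("b", "c", "d", "e"), {"f": 1.0}),
    "LL5": ModelFamily("LL5", "LL", ("b", "c", "d", "e", "f"), {}),
}

FAMILY_ORDER = tuple(FAMILIES)


def _as_family(family: ModelFamily | str) -> ModelFamily:
    if isinstance(family, ModelFamily):
        return family
    try:
        return FAMILIES[family]
    except KeyError:
        raise TimeResponseError(f"unknown model family {family!r}") from None


def model_curve(
    family: ModelFamily | str, params: dict[str, float], t: float | np.ndarray
) -> float | np.ndarray:
    """Predicted percent survival at time ``t`` (days) for one family.

    The shared building block is z = exp(b * (ln t - ln e)) = (t/e)^b:

    * log-logistic:  c + (d - c) / (1 + z)^f
    * Weibull-1:     c + (d - c) * exp(-z)
    * Weibull-2:     c + (d - c) * (1 - exp(-z))
    """
    fam = _as_family(family)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise TimeResponseError(f"time must be positive, got {t!r}")
    b, c, d, e, f = (params.get(n, fam.fixed.get(n)) for n in PARAM_NAMES)
    with np.errstate(over="ignore"):
        z = np.exp(b * (np.log(t_arr) - math.log(e)))
        if fam.kind == "LL":
            y = c + (d - c) / (1.0 + z) ** f
        elif fam.kind == "W1":
            y = c + (d - c) * np.exp(-z)
        else:  # W2
            y = c + (d - c) * (1.0 - np.exp(-z))
    return float(y) if np.isscalar(t) or t_arr.ndim == 0 else y


@dataclass(frozen=True)
class ModelFit:
    """A fitted time-response curve for one group."""

    family: ModelFamily
    params: dict[str, float]
    cov: np.ndarray | None  # covariance of the free parameters, or None
    rss: float
    n_obs: int
    aic: float
    converged: bool
    message: str = ""

    @property
    def free_values(self) -> np.ndarray:
        return np.array([self.params[n] for n in self.family.free], dtype=float)

    def predict(self, t: float | np.ndarray) -> float | np.ndarray:
        return model_curve(self.family, self.params, t)

    @property
    def decreasing(self) -> bool:
        """Whether the fitted curve declines with time (the toxic direction)."""
        b = self.params["b"]
        return b < 0 if self.family.kind == "W2" else b > 0


@dataclass(frozen=True)
class LTEstimate:
    """Lethal time for a p% survival decline with delta-method confidence limits."""

    p: float
    estimate: float
    lower: float
    upper: float
    level: float = 0.95

    @property
    def interval(self) -> tuple[float, float]:
        return (self.lower, self.upper)


def _aic(rss: float, n: int, k: int) -> float:
    """Gaussian least-squares AIC, counting the residual variance as a parameter.

    Only the ordering across families fitted to the same data matters.
    """
    if rss <= 0.0:
        return -math.inf
    return n * math.log(rss / n) + 2.0 * (k + 1)


_START_SLOPES = (1.0, 0.5, 5.0, -1.0, -0.5, -5.0)


def fit_model(
    days: Sequence[float],
    percent_survival: Sequence[float],
    family: ModelFamily | str,
) -> ModelFit:
    """Least-squares fit of one family to (day, percent survival) data.

    ``days``/``percent_survival`` are the replicate-level observations for a
    single group, one entry per replicate per observation day.  Degenerate
    data (e.g. constant 100% survival, as in a clean control) yield
    ``converged=False`` rather than an exception so that downstream scoring
    can treat the group as non-modellable.
    """
    fam = _as_family(family)
    x = np.asarray(days, dtype=float)
    y = np.asarray(percent_survival, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise TimeResponseError("days and percent_survival must be equal-length 1-d")
    if np.any(x <= 0):
        raise TimeResponseError("observation days must be positive")
    n = len(x)
    if len(np.unique(x)) < fam.k:
        raise InsufficientDataError(
            f"{fam.name} needs >= {fam.k} distinct days, got {len(np.unique(x))}"
        )

    def failed(msg: str) -> ModelFit:
        params = fam.full_params([math.nan] * fam.k)
        return ModelFit(fam, params, None, math.nan, n, math.nan, False, msg)

    if np.ptp(y) < 1e-9:
        return failed("degenerate data: constant response")

    lower = np.array([{"e": 1e-9, "f": 1e-9}.get(nm, -np.inf) for nm in fam.free])
    upper = np.full(fam.k, np.inf)
    starts = {
        "b": 1.0,
        "c": float(np.min(y)),
        "d": float(np.max(y)),
        "e": float(np.median(x)),
        "f": 1.0,
    }

    def residuals(theta: np.ndarray) -> np.ndarray:
        return model_curve(fam, fam.full_params(theta), x) - y

    best = None
    for b0 in _START_SLOPES:
        theta0 = np.array([b0 if nm == "b" else starts[nm] for nm in fam.free])
        theta0 = np.clip(theta0, lower + 1e-9, None)
        try:
            res = optimize.least_squares(residuals, theta0, bounds=(lower, upper))
        except Exception:  # numerical breakdown for a bad start
            continue
        if not (res.success and np.all(np.isfinite(res.x))):
            continue
        rss = float(2.0 * res.cost)
        if best is None or rss < best.cost * 2.0 - 1e-12:
            best = res
        if rss < 1e-10:  # exact data; no better start exists
            break
    if best is None:
        return failed("optimizer failed from all starting values")

    rss = float(2.0 * best.cost)
    params = fam.full_params(best.x)
    cov = None
    if n > fam.k:
        jtj = best.jac.T @ best.jac
        sigma2 = rss / (n - fam.k)
        try:
            cov = np.linalg.inv(jtj) * sigma2
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(jtj) * sigma2
        cov = (cov + cov.T) / 2.0  # enforce exact symmetry
    return ModelFit(fam, params, cov, rss, n, _aic(rss, n, fam.k), True, best.message)


def select_best(fits: Sequence[ModelFit]) -> ModelFit:
    """The converged fit with the lowest AIC.

    Ties are broken deterministically: fewer free parameters first, then the
    fixed family order (LL3u100, LL3, LL4, W14, W24, LL5).
    """
    converged = [f for f in fits if f.converged]
    if not converged:
        raise SelectionError("no converged fit: group is non-modellable")
    return min(
        converged,
        key=lambda f: (f.aic, f.family.k, FAMILY_ORDER.index(f.family.name)),
    )


def _invert_curve(fam: ModelFamily, params: dict[str, float], p: float, relative: bool) -> float:
    """Closed-form LT_p: time at which the curve reaches its p% decline target."""
    b, c, d, e, f = (params[n] for n in PARAM_NAMES)
    if relative:
        # target = d - (p/100)(d - c): the decline is taken over the fitted range,
        # so z = (t/e)^b solves a fraction that does not involve c and d.
        if fam.kind == "LL":
            z = (100.0 / (100.0 - p)) ** (1.0 / f) - 1.0
        elif fam.kind == "W1":
            z = -math.log1p(-p / 100.0)
        else:  # W2
            z = -math.log(p / 100.0)
    else:
        # absolute target: percent survival equal to 100 - p
        target = 100.0 - p
        lo, hi = min(c, d), max(c, d)
        if not lo < target < hi:
            raise LTUnavailableError(
                f"absolute target {target}% outside fitted asymptote range ({lo:.3g}, {hi:.3g})"
            )
        ratio = (target - c) / (d - c)
        if fam.kind == "LL":
            z = ratio ** (-1.0 / f) - 1.0
        elif fam.kind == "W1":
            z = -math.log(ratio)
        else:  # W2
            z = -math.log1p(-ratio)
    if z <= 0:
        raise LTUnavailableError(f"no positive-time solution for p={p}")
    return e * z ** (1.0 / b)


def estimate_lt(
    fit: ModelFit,
    p: float,
    level: float = 0.95,
    relative: bool = True,
) -> LTEstimate:
    """Lethal time LT_p from a converged fit, with delta-method confidence limits.

    ``relative=True`` (default) reads the p% decline against the fitted
    asymptote range, solving f(t) = d - (p/100)(d - c); with the dominant
    model (upper asymptote fixed at 100, lower at 0) this coincides with the
    absolute reading f(t) = 100 - p, available via ``relative=False``.

    The confidence interval is Wald-type on the natural (day) scale with a
    t quantile at n - k degrees of freedom; the lower limit may be negative.
    """
    if not fit.converged:
        raise LTUnavailableError("fit did not converge; LT unavailable")
    if not 0.0 < p < 100.0:
        raise TimeResponseError(f"p must be in (0, 100), got {p}")
    if not fit.decreasing:
        raise NonToxicDirectionError(
            f"fitted {fit.family.name} curve is non-decreasing (b={fit.params['b']:.3g}); "
            "no toxic-direction decline to invert"
        )
    fam = fit.family
    estimate = _invert_curve(fam, fit.params, p, relative)

    if fit.cov is None or fit.n_obs <= fam.k:
        return LTEstimate(p, estimate, math.nan, math.nan, level)

    theta = fit.free_values
    grad = np.empty(fam.k)
    for i, name in enumerate(fam.free):
        h = 1e-6 * max(1.0, abs(theta[i]))
        hi_p, lo_p = dict(fit.params), dict(fit.params)
        hi_p[name] = theta[i] + h
        lo_p[name] = theta[i] - h
        try:
            grad[i] = (_invert_curve(fam, hi_p, p, relative) - _invert_curve(fam, lo_p, p, relative)) / (2 * h)
        except (LTUnavailableError, ValueError, ZeroDivisionError):
            grad[i] = math.nan
    var = float(grad @ fit.cov @ grad)
    if not math.isfinite(var) or var < 0:
        return LTEstimate(p, estimate, math.nan, math.nan, level)
    half = stats.t.ppf(0.5 + level / 2.0, df=fit.n_obs - fam.k) * math.sqrt(var)
    return LTEstimate(p, estimate, estimate - half, estimate + half, level)
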