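"""Parametric survival distributions for extrapolating digitized trial curves.

The cohort model is driven entirely by parametric survival laws fitted to
(progression-free and overall) survival curves. Six families are supported;
the work-horse here is the log-logistic distribution

    S(t) = 1 / (1 + (lambda * t)**gamma),

whose median is ``1/lambda`` -- a convenient sanity bridge to the medians a
trial reports. All times are in months (1 month = 30.4375 days).

Fitting offers two objectives:

* ``"mle"`` -- maximum likelihood on individual event/censoring times,
  either given directly or reconstructed from a curve's numbers at risk
  (interval event counts, in the spirit of published pseudo-IPD methods);
* ``"wls"`` -- weighted least squares on the complementary log-log scale of
  bare digitized coordinates, for curves without at-risk information.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "Family",
    "ParametricSurvival",
    "KMCurve",
    "FitResult",
    "survival_at",
    "median_time",
    "transition_probability",
    "fit_parametric",
    "fit_ipd",
    "rank_fits",
]

MONTH_DAYS = 30.4375


class Family(str, enum.Enum):
    EXPONENTIAL = "exponential"
    WEIBULL = "weibull"
    LOG_NORMAL = "log-normal"
    LOG_LOGISTIC = "log-logistic"
    GOMPERTZ = "gompertz"
    GENERALIZED_GAMMA = "generalized-gamma"


#: number of free parameters per family
N_PARAMS = {
    Family.EXPONENTIAL: 1,
    Family.WEIBULL: 2,
    Family.LOG_NORMAL: 2,
    Family.LOG_LOGISTIC: 2,
    Family.GOMPERTZ: 2,
    Family.GENERALIZED_GAMMA: 3,
}


@dataclass(frozen=True)
class ParametricSurvival:
    """A parametric survival law in month units.

    ``params`` holds the family's parameter vector:

    * exponential: ``(rate,)``
    * weibull / log-logistic / gompertz: ``(scale, shape)`` = (lambda, gamma)
    * log-normal: ``(mu, sigma)`` on the log-time scale
    * generalized-gamma: ``(mu, sigma, Q)`` (Prentice parameterization)
    """

    family: Family
    params: tuple[float, ...]
    time_unit: str = "months"

    def __post_init__(self) -> None:
        fam = Family(self.family)
        object.__setattr__(self, "family", fam)
        p = tuple(float(x) for x in self.params)
        object.__setattr__(self, "params", p)
        if len(p) != N_PARAMS[fam]:
            raise ValueError(
                f"{fam.value} takes {N_PARAMS[fam]} parameters, got {len(p)}"
            )
        if fam in (Family.EXPONENTIAL, Family.WEIBULL, Family.LOG_LOGISTIC):
            if p[0] <= 0 or (len(p) > 1 and p[1] <= 0):
                raise ValueError(f"{fam.value} parameters must be positive: {p}")
        elif fam == Family.LOG_NORMAL:
            if p[1] <= 0:
                raise ValueError("log-normal sigma must be positive")
        elif fam == Family.GOMPERTZ:
            # negative shape (decelerating hazard) is legal for evaluation
            if p[0] <= 0:
                raise ValueError("gompertz rate must be positive")
        elif fam == Family.GENERALIZED_GAMMA:
            if p[1] <= 0:
                raise ValueError("generalized-gamma sigma must be positive")

    # -- convenience accessors for the two-parameter (lambda, gamma) families
    @property
    def scale(self) -> float:
        return self.params[0]

    @property
    def shape(self) -> float:
        if len(self.params) < 2:
            raise AttributeError(f"{self.family.value} has no shape parameter")
        return self.params[1]

    def survival(self, t):
        return survival_at(self, t)

    def median(self) -> float:
        return median_time(self)

    def quantile(self, s):
        """Time t with S(t) = s (inverse survival), used for simulation."""
        s = np.asarray(s, dtype=float)
        if np.any((s <= 0) | (s > 1)):
            raise ValueError("survival probability must lie in (0, 1]")
        lam = self.params[0]
        if self.family == Family.EXPONENTIAL:
            return -np.log(s) / lam
        if self.family == Family.WEIBULL:
            return (-np.log(s)) ** (1.0 / self.shape) / lam
        if self.family == Family.LOG_LOGISTIC:
            return (1.0 / s - 1.0) ** (1.0 / self.shape) / lam
        if self.family == Family.LOG_NORMAL:
            mu, sigma = self.params
            return np.exp(mu + sigma * stats.norm.isf(s))
        if self.family == Family.GOMPERTZ:
            lam, gam = self.params
            arg = 1.0 - gam / lam * np.log(s)
            if np.any(arg <= 0):
                raise ValueError("requested survival level is never reached")
            return np.log(arg) / gam
        # generalized gamma: numeric inversion
        def f(tt, target):
            return survival_at(self, tt) - target

        scalar = np.ndim(s) == 0
        out = []
        for si in np.atleast_1d(s):
            if si == 1.0:
                out.append(0.0)
                continue
            hi = 1.0
            while f(hi, si) > 0:
                hi *= 2.0
                if hi > 1e9:  # pragma: no cover - pathological parameters
                    raise ValueError("quantile search failed")
            out.append(optimize.brentq(f, 0.0, hi, args=(si,), xtol=1e-12))
        return out[0] if scalar else np.asarray(out)

    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "params": list(self.params),
            "time_unit": self.time_unit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParametricSurvival":
        return cls(Family(d["family"]), tuple(d["params"]), d.get("time_unit", "months"))

    @classmethod
    def log_logistic(cls, scale: float, shape: float) -> "ParametricSurvival":
        return cls(Family.LOG_LOGISTIC, (scale, shape))


def survival_at(dist, t):
    """S(t) for the given distribution; ``t`` in months, scalar or array.

    Accepts any object with a ``survival`` method (e.g. a hazard-ratio
    transformed curve) besides :class:`ParametricSurvival`.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if not isinstance(dist, ParametricSurvival):
        return dist.survival(t)
    p = dist.params
    if dist.family == Family.EXPONENTIAL:
        s = np.exp(-p[0] * t)
    elif dist.family == Family.WEIBULL:
        s = np.exp(-((p[0] * t) ** p[1]))
    elif dist.family == Family.LOG_LOGISTIC:
        s = 1.0 / (1.0 + (p[0] * t) ** p[1])
    elif dist.family == Family.LOG_NORMAL:
        mu, sigma = p
        with np.errstate(divide="ignore"):
            z = (np.log(np.where(t > 0, t, 1.0)) - mu) / sigma
        s = np.where(t > 0, stats.norm.sf(z), 1.0)
    elif dist.family == Family.GOMPERTZ:
        lam, gam = p
        if abs(gam) < 1e-12:
            s = np.exp(-lam * t)
        else:
            s = np.exp(-lam / gam * (np.expm1(gam * t)))
    else:  # generalized gamma, (mu, sigma, Q)
        mu, sigma, q = p
        if abs(q) < 1e-8:
            with np.errstate(divide="ignore"):
                z = (np.log(np.where(t > 0, t, 1.0)) - mu) / sigma
            s = np.where(t > 0, stats.norm.sf(z), 1.0)
        else:
            a = q ** -2
            with np.errstate(divide="ignore"):
                w = (np.log(np.where(t > 0, t, 1.0)) - mu) / sigma
            u = a * np.exp(q * w)
            g = special.gammainc(a, u)
            s = np.where(t > 0, np.where(q > 0, 1.0 - g, g), 1.0)
    return s if s.ndim else float(s)


def log_density(dist: ParametricSurvival, t):
    """log f(t); used by the likelihood."""
    t = np.asarray(t, dtype=float)
    p = dist.params
    if dist.family == Family.EXPONENTIAL:
        return np.log(p[0]) - p[0] * t
    if dist.family == Family.WEIBULL:
        lam, gam = p
        return (
            np.log(gam) + gam * np.log(lam) + (gam - 1.0) * np.log(t) - (lam * t) ** gam
        )
    if dist.family == Family.LOG_LOGISTIC:
        lam, gam = p
        lt = (lam * t) ** gam
        return (
            np.log(gam) + gam * np.log(lam) + (gam - 1.0) * np.log(t)
            - 2.0 * np.log1p(lt)
        )
    if dist.family == Family.LOG_NORMAL:
        mu, sigma = p
        return stats.norm.logpdf((np.log(t) - mu) / sigma) - np.log(sigma * t)
    if dist.family == Family.GOMPERTZ:
        lam, gam = p
        if abs(gam) < 1e-12:
            return np.log(lam) - lam * t
        return np.log(lam) + gam * t - lam / gam * np.expm1(gam * t)
    mu, sigma, q = p
    if abs(q) < 1e-8:
        return stats.norm.logpdf((np.log(t) - mu) / sigma) - np.log(sigma * t)
    a = q ** -2
    w = (np.log(t) - mu) / sigma
    u = a * np.exp(q * w)
    return (
        np.log(abs(q)) - np.log(sigma * t) - special.gammaln(a)
        + a * np.log(u) - u
    )


def median_time(dist: ParametricSurvival) -> float:
    """Time t with S(t) = 0.5; closed form for all families but one."""
    p = dist.params
    if dist.family == Family.EXPONENTIAL:
        return math.log(2.0) / p[0]
    if dist.family == Family.WEIBULL:
        return math.log(2.0) ** (1.0 / p[1]) / p[0]
    if dist.family == Family.LOG_LOGISTIC:
        return 1.0 / p[0]
    if dist.family == Family.LOG_NORMAL:
        return math.exp(p[0])
    if dist.family == Family.GOMPERTZ:
        lam, gam = p
        arg = 1.0 + gam / lam * math.log(2.0)
        if arg <= 0:
            raise ValueError("gompertz distribution has no finite median")
        return math.log(arg) / gam
    return float(dist.quantile(0.5))


def transition_probability(
    dist: ParametricSurvival, cycle_index: int, cycle_length: float
) -> float:
    """Probability of leaving the curve during cycle ``cycle_index``.

    Returns ``1 - S(k c) / S((k-1) c)`` -- the conditional exit probability
    for a cohort member still on the curve at the start of the cycle. When
    the cohort is already exhausted (S = 0) the convention is 1.
    """
    if cycle_index < 1:
        raise ValueError("cycle_index must be >= 1")
    if cycle_length <= 0:
        raise ValueError("cycle_length must be positive")
    s_prev = survival_at(dist, (cycle_index - 1) * cycle_length)
    if s_prev == 0.0:
        return 1.0
    s_now = survival_at(dist, cycle_index * cycle_length)
    return float(np.clip(1.0 - s_now / s_prev, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Kaplan-Meier curves (as fitting input) and fit results


@dataclass
class KMCurve:
    """Ordered (time, survival) coordinates, optionally with numbers at risk."""

    time: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.n_at_risk is not None:
            self.n_at_risk = np.asarray(self.n_at_risk, dtype=float)
        if self.time.shape != self.survival.shape:
            raise ValueError("time and survival must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival values must lie in [0, 1]")

    def cleaned(self) -> "KMCurve":
        """Monotone non-increasing copy (isotonic clipping from the left),
        duplicate times dropped keeping the lower survival."""
        t, idx = np.unique(self.time, return_index=True)
        s = np.minimum.accumulate(self.survival.copy())
        s = s[np.sort(idx)]
        n = self.n_at_risk[np.sort(idx)] if self.n_at_risk is not None else None
        return KMCurve(t, s, n)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"time_months": self.time, "survival": self.survival})
        if self.n_at_risk is not None:
            df["n_at_risk"] = self.n_at_risk
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "KMCurve":
        df = pd.read_csv(path)
        nar = df["n_at_risk"].to_numpy() if "n_at_risk" in df.columns else None
        return cls(df["time_months"].to_numpy(), df["survival"].to_numpy(), nar)


@dataclass
class FitResult:
    dist: ParametricSurvival
    loglik: float
    aic: float
    bic: float
    n: int
    n_events: int | None = None
    method: str = "mle"

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "family": self.dist.family.value,
            "params": list(self.dist.params),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "n": self.n,
            "n_events": self.n_events,
            "method": self.method,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


class FitError(RuntimeError):
    """Raised when a curve is degenerate or the optimizer fails."""


# -- internal: unconstrained <-> natural parameter transforms ---------------


def _to_natural(family: Family, theta: np.ndarray) -> tuple[float, ...]:
    if family == Family.EXPONENTIAL:
        return (math.exp(theta[0]),)
    if family in (Family.WEIBULL, Family.LOG_LOGISTIC, Family.GOMPERTZ):
        return (math.exp(theta[0]), math.exp(theta[1]))
    if family == Family.LOG_NORMAL:
        return (theta[0], math.exp(theta[1]))
    return (theta[0], math.exp(theta[1]), theta[2])  # generalized gamma


def _initial_theta(family: Family, curve_median: float) -> np.ndarray:
    lam0 = 1.0 / max(curve_median, 1e-6)
    if family == Family.EXPONENTIAL:
        return np.array([math.log(lam0 * math.log(2.0))])
    if family in (Family.WEIBULL, Family.LOG_LOGISTIC):
        return np.array([math.log(lam0), 0.0])
    if family == Family.GOMPERTZ:
        return np.array([math.log(lam0 * math.log(2.0)), math.log(0.05)])
    if family == Family.LOG_NORMAL:
        return np.array([math.log(curve_median), 0.0])
    return np.array([math.log(curve_median), 0.0, 0.5])


def _multistart(objective, theta0: np.ndarray):
    """Nelder-Mead from ``theta0``; perturbed restarts only when the first
    run fails to converge cleanly."""
    best = None
    for i, t0 in enumerate((theta0, theta0 + 0.5, theta0 - 0.5)):
        res = optimize.minimize(
            objective, t0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
        if i == 0 and res.success and res.fun < 1e11:
            break
    return best


def fit_ipd(
    times: Sequence[float],
    events: Sequence[int],
    family: Family | str,
    ) -> FitResult:
    """Maximum-likelihood fit of individual event/censoring times."""
    family = Family(family)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("times and events must be 1-D and matched")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if e.sum() == 0:
        raise FitError("no events: likelihood is unbounded")
    med = float(np.median(t))

    def nll(theta: np.ndarray) -> float:
        try:
            dist = ParametricSurvival(family, _to_natural(family, theta))
        except (ValueError, OverflowError):
            return 1e12
        with np.errstate(all="ignore"):
            ll = np.where(e == 1, log_density(dist, t), np.log(survival_at(dist, t)))
        if not np.all(np.isfinite(ll)):
            return 1e12
        return -float(ll.sum())

    theta0 = _initial_theta(family, med)
    best = _multistart(nll, theta0)
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise FitError(f"MLE failed for family {family.value}")
    dist = ParametricSurvival(family, _to_natural(family, best.x))
    k = N_PARAMS[family]
    ll = -best.fun
    n = len(t)
    return FitResult(dist, ll, 2 * k - 2 * ll, k * math.log(n) - 2 * ll,
                     n, int(e.sum()), "mle")


def _reconstruct_interval_ipd(curve: KMCurve) -> tuple[np.ndarray, np.ndarray]:
    """Approximate event/censoring times from curve coordinates plus numbers
    at risk: interval event counts follow from the survival drop, censorings
    from the residual decline in the risk set; events are placed at interval
    midpoints, censorings at interval ends."""
    t = curve.time
    s = curve.survival
    n = curve.n_at_risk
    times: list[float] = []
    events: list[int] = []
    s_prev = 1.0
    for j in range(len(t)):
        if s_prev <= 0:
            break
        # events at this point: the product-limit drop against the risk set
        d = int(round(n[j] * (1.0 - s[j] / s_prev)))
        n_next = n[j + 1] if j + 1 < len(n) else 0.0
        c = int(max(round(n[j] - d - n_next), 0))
        t_cens = 0.5 * (t[j] + t[j + 1]) if j + 1 < len(t) else t[j]
        times += [t[j]] * d + [t_cens] * c
        events += [1] * d + [0] * c
        s_prev = s[j]
    return np.asarray(times), np.asarray(events)


def fit_parametric(
    curve: KMCurve,
    family: Family | str,
    method: str = "auto",
) -> FitResult:
    """Fit a parametric family to a (digitized) survival curve.

    ``method``:

    * ``"auto"`` -- MLE on reconstructed interval data when the curve carries
      numbers at risk, otherwise least squares;
    * ``"mle"`` -- require at-risk numbers;
    * ``"wls"`` -- weighted least squares on log(-log S) coordinates, with
      at-risk numbers (when present) as weights.
    """
    family = Family(family)
    clean = curve.cleaned()
    usable = (clean.survival > 0) & (clean.survival < 1) & (clean.time > 0)
    if usable.sum() < 2 * N_PARAMS[family]:
        raise FitError(
            "degenerate curve: need at least "
            f"{2 * N_PARAMS[family]} points with survival in (0, 1), "
            f"got {int(usable.sum())}"
        )
    if method == "auto":
        method = "mle" if clean.n_at_risk is not None else "wls"
    if method == "mle":
        if clean.n_at_risk is None:
            raise FitError("MLE fitting needs numbers at risk on the curve")
        times, events = _reconstruct_interval_ipd(clean)
        if len(times) == 0 or events.sum() == 0:
            raise FitError("at-risk reconstruction produced no events")
        return fit_ipd(times, events, family)
    if method != "wls":
        raise ValueError(f"unknown fitting method {method!r}")

    t = clean.time[usable]
    s = clean.survival[usable]
    if clean.n_at_risk is not None:
        w = clean.n_at_risk[usable]
    else:
        # inverse-variance weights for the cloglog transform of a
        # product-limit estimate (Greenwood-style): Var[log(-log S)] is
        # approximately (1-S) / (S (ln S)^2) up to the at-risk count
        w = s * np.log(s) ** 2 / np.clip(1.0 - s, 1e-6, None)
    w = w / w.sum()
    y = np.log(-np.log(s))

    def rss(theta: np.ndarray) -> float:
        try:
            dist = ParametricSurvival(family, _to_natural(family, theta))
        except (ValueError, OverflowError):
            return 1e12
        with np.errstate(all="ignore"):
            sm = survival_at(dist, t)
            yh = np.log(-np.log(np.clip(sm, 1e-300, 1 - 1e-12)))
        if not np.all(np.isfinite(yh)):
            return 1e12
        return float(np.sum(w * (y - yh) ** 2))

    theta0 = _initial_theta(family, float(np.interp(0.5, s[::-1], t[::-1])))
    best = _multistart(rss, theta0)
    if best is None or best.fun >= 1e11:
        raise FitError(f"WLS failed for family {family.value}")
    dist = ParametricSurvival(family, _to_natural(family, best.x))
    # Gaussian pseudo-likelihood of the transformed residuals, so AIC/BIC
    # remain comparable across families fitted on the same points.
    n = len(t)
    sigma2 = max(float(best.fun), 1e-300)
    ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    k = N_PARAMS[family]
    return FitResult(dist, ll, 2 * k - 2 * ll, k * math.log(n) - 2 * ll,
                     n, None, "wls")


def rank_fits(results: Sequence[FitResult]) -> list[FitResult]:
    """Ascending AIC; ties broken by BIC, then by fewer parameters."""
    if not results:
        raise ValueError("rank_fits needs at least one FitResult")
    return sorted(
        results,
        key=lambda r: (round(r.aic, 9), round(r.bic, 9), N_PARAMS[r.dist.family]),
    )
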