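"""Synthetic inputs with known ground truth.

The one model input that is not a printed number is the pair of digitized
Kaplan-Meier curves the survival fits were estimated from. This module
emulates that input end to end: simulate individual event/censoring times
from a known parametric law (inverse-transform sampling), estimate the
product-limit curve, and sample jittered coordinates the way a graph
digitizer would produce them. Fitting can then be validated full circle
against the generating parameters.

Default censoring mimics trial-like follow-up -- administrative censoring
at 25 months plus 5%/year random dropout. These are fixture conventions
with explicit seeds, not claims about any particular trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .survival import KMCurve, ParametricSurvival

__all__ = ["SimulatedIPD", "simulate_ipd", "km_estimate", "emulate_digitization"]

DEFAULT_ADMIN_CENSOR_MONTHS = 25.0
DEFAULT_ANNUAL_DROPOUT = 0.05


@dataclass
class SimulatedIPD:
    """Individual event/censoring times with their generating truth."""

    time: np.ndarray
    event: np.ndarray
    dist: ParametricSurvival
    seed: int
    admin_censor_months: float
    annual_dropout: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must be matched")
        if np.any(self.time < 0):
            raise ValueError("times must be non-negative")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")

    @property
    def censoring_fraction(self) -> float:
        return float(1.0 - self.event.mean())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time": self.time, "event": self.event}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(
        cls, path: str | Path, dist: ParametricSurvival, seed: int = 0
    ) -> "SimulatedIPD":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["event"].to_numpy(), dist, seed,
                   float("nan"), float("nan"))


def simulate_ipd(
    dist: ParametricSurvival,
    n: int,
    seed: int,
    admin_censor_months: float | None = DEFAULT_ADMIN_CENSOR_MONTHS,
    annual_dropout: float = DEFAULT_ANNUAL_DROPOUT,
) -> SimulatedIPD:
    """Draw ``n`` subjects; censor at min(event, dropout, admin cut-off).

    Event times come from inverse-transform sampling: with u ~ U(0, 1),
    ``t = S^{-1}(u)`` (for the log-logistic, t = (1/u - 1)^{1/gamma} /
    lambda). Random dropout is exponential with the given annual rate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    t_event = np.asarray(dist.quantile(u), dtype=float)
    t_cens = np.full(n, np.inf)
    if admin_censor_months is not None:
        t_cens = np.minimum(t_cens, admin_censor_months)
    if annual_dropout > 0:
        monthly_rate = -np.log1p(-annual_dropout) / 12.0
        t_cens = np.minimum(t_cens, rng.exponential(1.0 / monthly_rate, size=n))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return SimulatedIPD(
        time, event, dist, seed,
        float("inf") if admin_censor_months is None else admin_censor_months,
        annual_dropout,
    )


def km_estimate(ipd: SimulatedIPD) -> KMCurve:
    """Product-limit estimate of the survival curve, with numbers at risk."""
    if ipd.event.sum() == 0:
        raise ValueError("cannot estimate a curve from all-censored data")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    sf = kmf.survival_function_.iloc[:, 0]
    at_risk = kmf.event_table["at_risk"].reindex(sf.index)
    mask = sf.index > 0
    return KMCurve(
        sf.index.to_numpy()[mask],
        sf.to_numpy()[mask],
        at_risk.to_numpy(dtype=float)[mask],
    )


def emulate_digitization(
    curve: KMCurve,
    n_points: int = 40,
    jitter_sd: float = 0.0,
    seed: int = 0,
    t_max: float | None = None,
) -> KMCurve:
    """Coordinates as a graph digitizer would sample them.

    Takes ``n_points`` on an even time grid across the plotted window,
    reads the step function there, perturbs the survival reading with
    truncated Gaussian noise, and re-monotonizes. Numbers at risk are
    dropped: a digitized figure does not carry them.

    ``t_max`` emulates the figure's time axis; by default it stops where
    the curve first falls below 2.5% (published axes rarely extend into
    the exhausted tail, and for heavy-tailed data the last event time can
    lie far beyond any plot).
    """
    if n_points < 2:
        raise ValueError("need at least two points")
    rng = np.random.default_rng(seed)
    if t_max is None:
        below = np.nonzero(curve.survival <= 0.025)[0]
        t_max = curve.time[below[0]] if below.size else curve.time[-1]
    grid = np.linspace(curve.time[0], t_max, n_points)
    # step-function lookup (right-continuous, S=1 before the first event)
    idx = np.searchsorted(curve.time, grid, side="right") - 1
    s = np.where(idx >= 0, curve.survival[np.clip(idx, 0, None)], 1.0)
    if jitter_sd > 0:
        s = np.clip(s + rng.normal(0.0, jitter_sd, size=n_points), 0.0, 1.0)
    grid, keep = np.unique(grid, return_index=True)
    return KMCurve(grid, s[keep]).cleaned()
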