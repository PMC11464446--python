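"""One-way and probabilistic sensitivity analysis, CEAC, price threshold.

One-way analysis re-runs the full model twice per parameter (at its range
ends, everything else at base) and reports the ICER spread for a tornado
diagram. Probabilistic analysis draws every uncertain parameter from its
assigned family -- Beta for probabilities and utilities, Gamma for costs,
Normal (zero-truncated) for anthropometrics -- with moments matched to the
base value and an SD of (high - low)/3.92, i.e. the printed range read as a
95% interval. Survival parameters carry no published uncertainty and are
held fixed, a documented limitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    ParamRange,
    RunConfig,
    apply_params,
    get_param,
    run_model,
)

__all__ = [
    "TornadoEntry", "PSASample", "PSAResult",
    "run_owsa", "sample_psa", "run_psa", "ceac", "threshold_price",
    "ThresholdResult",
]


@dataclass
class TornadoEntry:
    path: str
    base: float
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _icer_or_nan(cmp) -> float:
    return float("nan") if cmp.icer is None else cmp.icer


def run_owsa(
    cfg: RunConfig, ranges: list[ParamRange] | None = None
) -> list[TornadoEntry]:
    """Tornado table: one entry per parameter, sorted by spread descending."""
    if ranges is None:
        ranges = cfg.sensitivity
    if not ranges:
        raise ValueError("no sensitivity ranges given")
    entries = []
    for r in ranges:
        base = get_param(cfg, r.path)
        lo = run_model(cfg, {r.path: r.low})
        hi = run_model(cfg, {r.path: r.high})
        entries.append(
            TornadoEntry(r.path, base, r.low, r.high,
                         _icer_or_nan(lo), _icer_or_nan(hi))
        )
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"parameter": e.path, "base": e.base, "low": e.low, "high": e.high,
             "icer_low": e.icer_low, "icer_high": e.icer_high, "spread": e.spread}
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PSASample:
    index: int
    params: dict[str, float]
    cost_intervention: float
    qalys_intervention: float
    cost_comparator: float
    qalys_comparator: float

    @property
    def delta_cost(self) -> float:
        return self.cost_intervention - self.cost_comparator

    @property
    def delta_qalys(self) -> float:
        return self.qalys_intervention - self.qalys_comparator

    def nmb_gain(self, wtp: float) -> float:
        return wtp * self.delta_qalys - self.delta_cost


def _draw_column(
    rng: np.random.Generator, base: float, r: ParamRange, n: int
) -> tuple[np.ndarray, bool]:
    """n draws for one parameter; second value flags a moment-match
    fallback (range-preserving Beta) having been used."""
    sd = (r.high - r.low) / 3.92
    if r.dist == "fixed" or sd == 0.0:
        return np.full(n, base), False
    if r.dist == "gamma":
        if base <= 0:
            return np.full(n, base), False
        shape = (base / sd) ** 2
        scale = sd ** 2 / base
        return rng.gamma(shape, scale, size=n), False
    if r.dist == "beta":
        if not 0.0 < base < 1.0:
            return np.full(n, base), False
        nu = base * (1.0 - base) / sd ** 2 - 1.0
        if nu <= 0:  # SD too large for the Beta support: keep the range
            m = (base - r.low) / (r.high - r.low)
            c = 6.0
            x = rng.beta(max(m * c, 1e-6), max((1.0 - m) * c, 1e-6), size=n)
            return r.low + (r.high - r.low) * x, True
        return rng.beta(base * nu, (1.0 - base) * nu, size=n), False
    if r.dist == "normal":
        floor = max(0.1 * base, 0.0)
        out = rng.normal(base, sd, size=n)
        bad = out <= floor
        while np.any(bad):  # truncation by redraw
            out[bad] = rng.normal(base, sd, size=int(bad.sum()))
            bad = out <= floor
        return out, False
    raise ValueError(f"unknown distribution {r.dist!r}")


def sample_psa(
    cfg: RunConfig,
    n: int = 1000,
    seed: int | None = None,
    ranges: list[ParamRange] | None = None,
) -> pd.DataFrame:
    """Draw ``n`` parameter vectors; one column per parameter path."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if ranges is None:
        ranges = cfg.sensitivity
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    cols, fallbacks = {}, []
    for r in ranges:
        base = get_param(cfg, r.path)
        cols[r.path], fb = _draw_column(rng, base, r, n)
        if fb:
            fallbacks.append(r.path)
    df = pd.DataFrame(cols)
    df.attrs["fallback_parameterizations"] = fallbacks
    return df


@dataclass
class PSAResult:
    samples: list[PSASample]
    wtp: float
    seed: int | None = None

    def prob_cost_effective(self, wtp: float | None = None) -> float:
        w = self.wtp if wtp is None else wtp
        return float(np.mean([s.nmb_gain(w) > 0 for s in self.samples]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"draw": s.index,
                 "cost_intervention": s.cost_intervention,
                 "qalys_intervention": s.qalys_intervention,
                 "cost_comparator": s.cost_comparator,
                 "qalys_comparator": s.qalys_comparator,
                 "delta_cost": s.delta_cost,
                 "delta_qalys": s.delta_qalys}
                for s in self.samples
            ]
        )

    def scatter_frame(self) -> pd.DataFrame:
        return self.to_frame()[["draw", "delta_qalys", "delta_cost"]]

    @property
    def summary(self) -> dict:
        df = self.to_frame()
        return {
            "n_draws": len(self.samples),
            "mean_delta_cost": float(df["delta_cost"].mean()),
            "mean_delta_qalys": float(df["delta_qalys"].mean()),
            "prob_cost_effective_at_wtp": self.prob_cost_effective(),
            "wtp": self.wtp,
            "seed": self.seed,
        }


def run_psa(
    cfg: RunConfig,
    n: int = 1000,
    seed: int | None = None,
    samples: pd.DataFrame | None = None,
    model=run_model,
) -> PSAResult:
    """Evaluate the full model per draw and summarise the cloud.

    ``model`` is the evaluation function ``(cfg, overrides) -> Comparison``;
    the default is the base-case pipeline, but e.g. a subgroup run can be
    passed instead.
    """
    if samples is None:
        samples = sample_psa(cfg, n=n, seed=seed)
    out = []
    for i, row in enumerate(samples.itertuples(index=False)):
        values = dict(zip(samples.columns, row))
        cmp = model(cfg, values)
        out.append(
            PSASample(
                index=i,
                params=values,
                cost_intervention=cmp.intervention.cost,
                qalys_intervention=cmp.intervention.qalys,
                cost_comparator=cmp.comparator.cost,
                qalys_comparator=cmp.comparator.qalys,
            )
        )
    return PSAResult(out, wtp=cfg.settings.wtp,
                     seed=cfg.seed if seed is None else seed)


def ceac(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty WTP grid")
    de = np.array([s.delta_qalys for s in psa.samples])
    dc = np.array([s.delta_cost for s in psa.samples])
    prob = [(w * de - dc > 0).mean() for w in grid]
    return pd.DataFrame({"wtp": grid, "prob_cost_effective": prob})


# ---------------------------------------------------------------------------
# simultaneous price-threshold search


@dataclass
class ThresholdResult:
    feasible: bool
    multiplier: float | None
    prices: dict[str, float]
    icer: float | None
    wtp: float


def threshold_price(
    cfg: RunConfig,
    drugs: tuple[str, ...] = ("enfortumab_vedotin", "pembrolizumab"),
    wtp: float | None = None,
    tol: float = 1.0,
) -> ThresholdResult:
    """Joint price multiplier at which the ICER meets the WTP threshold.

    Both drug prices are scaled by the same multiplier m; because cost is
    linear (and increasing) in prices, the ICER is increasing in m and the
    crossing is found by bisection to ``|ICER - wtp| < tol`` dollars.
    """
    w = cfg.settings.wtp if wtp is None else wtp
    base_prices = {d: get_param(cfg, f"drug_price.{d}") for d in drugs}

    def icer_at(m: float) -> float:
        cmp = run_model(
            cfg, {f"drug_price.{d}": p * m for d, p in base_prices.items()}
        )
        if cmp.icer is None:  # dominant at very low prices
            return -math.inf if cmp.dominance == "dominant" else math.inf
        return cmp.icer

    hi = 1.0
    f_hi = icer_at(hi)
    if f_hi <= w:
        return ThresholdResult(True, 1.0, base_prices, f_hi, w)
    lo = 1e-6
    if icer_at(lo) > w:
        return ThresholdResult(False, None, {}, None, w)
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        f_mid = icer_at(mid)
        if abs(f_mid - w) < tol:
            lo = hi = mid
            break
        if f_mid > w:
            hi = mid
        else:
            lo = mid
    m = 0.5 * (lo + hi)
    return ThresholdResult(
        True, m, {d: p * m for d, p in base_prices.items()}, icer_at(m), w
    )
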