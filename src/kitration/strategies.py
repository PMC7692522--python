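"""Week-by-week kit-consumption recursions for strategies I, M, S1 and S2.

All strategies share one bookkeeping convention: ``W_t`` is the unused-kit
stock at the start of week ``t``; the recursion is active for weeks
``t = t0..T`` (default ``t0 = 5``, so the first strategy-dependent stock is
``W_6``); kits used in week ``t`` equal ``W_t - W_{t+1}`` and never exceed
that week's patients or the remaining stock.  There is no resupply and kits
do not expire.

* Strategy I ("ideal"): hindsight benchmark; the rate is the stock divided
  by the *true* future patient total, spreading kits evenly over remaining
  demand.
* Strategy M: the same rule with the future total replaced by rolling
  curve forecasts — the deployable, prediction-based strategy.
* Strategy S1: spend up to half the remaining stock each week.
* Strategy S2: spread the remaining stock evenly over the remaining weeks.

Consumption is deterministic expected-value flooring by default
(``floor(rate * patients)``); an explicitly optional stochastic mode draws
``Binomial(patients, rate)`` instead.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Callable, Literal

import numpy as np

from .forecast import ForecastMatrix, future_demand
from .series_io import WeeklySeries

__all__ = [
    "StockTrajectory",
    "apply_week",
    "run_ideal",
    "run_main",
    "run_s1",
    "run_s2",
    "DEFAULT_T0",
]

#: Default activation week: strategies are defined from the sixth week, so
#: the stock is initialised at week 5 (W_5 = W_init).
DEFAULT_T0 = 5

ConsumptionMode = Literal["deterministic", "stochastic"]


@dataclasses.dataclass(frozen=True)
class StockTrajectory:
    """Stock and consumption-rate trajectory of one strategy on one series.

    ``stock[i]`` is ``W_{t0 + i}`` for ``i = 0 .. T - t0 + 1`` (so the last
    entry is the post-season stock ``W_{T+1}``); ``rates``, ``kits_used``
    and ``patients`` are indexed by active week ``t = t0..T``.
    """

    strategy: str
    institution_id: str
    season: str
    W_init: int
    t0: int
    T: int
    stock: np.ndarray
    rates: np.ndarray
    kits_used: np.ndarray
    patients: np.ndarray

    def __post_init__(self) -> None:
        n_active = self.T - self.t0 + 1
        if len(self.stock) != n_active + 1:
            raise ValueError("stock must cover weeks t0..T+1")
        if not (len(self.rates) == len(self.kits_used) == len(self.patients) == n_active):
            raise ValueError("rates/kits_used/patients must cover weeks t0..T")
        if self.stock[0] != self.W_init:
            raise ValueError("W_{t0} must equal W_init")

    def W(self, t: int) -> int:
        """Unused kits at the start of week ``t`` (t0 <= t <= T+1)."""
        if not self.t0 <= t <= self.T + 1:
            raise IndexError(f"week {t} outside {self.t0}..{self.T + 1}")
        return int(self.stock[t - self.t0])

    def rate(self, t: int) -> float:
        if not self.t0 <= t <= self.T:
            raise IndexError(f"week {t} outside {self.t0}..{self.T}")
        return float(self.rates[t - self.t0])

    @property
    def final_stock(self) -> int:
        return int(self.stock[-1])

    @property
    def total_used(self) -> int:
        return int(self.kits_used.sum())


def apply_week(
    stock: int,
    rate: float,
    patients: int,
    mode: ConsumptionMode = "deterministic",
    rng: np.random.Generator | None = None,
) -> tuple[int, int]:
    """Consume kits for one week at consumption rate ``rate``.

    Deterministic mode uses expected-value flooring,
    ``kits_used = min(floor(rate * patients), stock)``; stochastic mode
    draws ``Binomial(patients, rate)`` (each suspected patient receives a
    kit with probability ``rate``), capped at the stock.

    Returns ``(kits_used, new_stock)``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    if stock < 0 or patients < 0:
        raise ValueError("stock and patients must be non-negative")
    if mode == "deterministic":
        demand = math.floor(rate * patients)
    elif mode == "stochastic":
        if rng is None:
            raise ValueError("stochastic mode requires a seeded Generator")
        demand = int(rng.binomial(patients, rate))
    else:
        raise ValueError(f"unknown consumption mode {mode!r}")
    kits_used = min(demand, stock)
    return kits_used, stock - kits_used


def _run_rate_rule(
    series: WeeklySeries,
    strategy: str,
    rate_fn: Callable[[int, int], float],
    W_init: int,
    t0: int,
    mode: ConsumptionMode,
    rng: np.random.Generator | None,
) -> StockTrajectory:
    """Run a rate-based recursion: rate_fn(t, current_stock) -> r_t."""
    if W_init < 1:
        raise ValueError("W_init must be >= 1 (loss normalisation divides by it)")
    T = series.T
    if not 1 <= t0 <= T:
        raise ValueError(f"t0={t0} outside 1..{T}")
    stock = [W_init]
    rates, used_list, pats = [], [], []
    W = W_init
    for t in range(t0, T + 1):
        r = rate_fn(t, W)
        P = series.count(t)
        used, W = apply_week(W, r, P, mode=mode, rng=rng)
        stock.append(W)
        rates.append(r)
        used_list.append(used)
        pats.append(P)
    return StockTrajectory(
        strategy=strategy,
        institution_id=series.institution_id,
        season=series.season,
        W_init=W_init,
        t0=t0,
        T=T,
        stock=np.asarray(stock, dtype=int),
        rates=np.asarray(rates, dtype=float),
        kits_used=np.asarray(used_list, dtype=int),
        patients=np.asarray(pats, dtype=int),
    )


def run_ideal(
    series: WeeklySeries,
    W_init: int,
    t0: int = DEFAULT_T0,
    mode: ConsumptionMode = "deterministic",
    rng: np.random.Generator | None = None,
) -> StockTrajectory:
    """Hindsight benchmark: ``r_t = min(W_t / sum_{s>t} P_s, 1)``.

    Requires the full-season counts (it is an after-the-fact reference);
    a zero future total gives rate 1.
    """

    def rate(t: int, W: int) -> float:
        fut = series.future_total(t)
        return 1.0 if fut == 0 else min(W / fut, 1.0)

    return _run_rate_rule(series, "I", rate, W_init, t0, mode, rng)


def run_main(
    series: WeeklySeries,
    forecasts: ForecastMatrix,
    W_init: int,
    t0: int = DEFAULT_T0,
    mode: ConsumptionMode = "deterministic",
    rng: np.random.Generator | None = None,
) -> StockTrajectory:
    """Prediction-based strategy: the ideal rule with the true future total
    replaced by the rolling forecast ``sum_{s>t} P̂_s(t)``.

    With a perfect predictor (forecasts equal to the observed future) the
    trajectory coincides with :func:`run_ideal` week for week.
    """
    T = series.T
    for t in range(t0, T):
        if t not in forecasts.rows:
            raise ValueError(f"strategy M: missing forecast row for week {t}")

    def rate(t: int, W: int) -> float:
        demand = future_demand(forecasts, t) if t < T else 0.0
        return 1.0 if demand <= 0.0 else min(W / demand, 1.0)

    return _run_rate_rule(series, "M", rate, W_init, t0, mode, rng)


def _run_amount_rule(
    series: WeeklySeries,
    strategy: str,
    amount_fn: Callable[[int, int], int],
    W_init: int,
    t0: int,
) -> StockTrajectory:
    if W_init < 1:
        raise ValueError("W_init must be >= 1 (loss normalisation divides by it)")
    T = series.T
    if not 1 <= t0 <= T:
        raise ValueError(f"t0={t0} outside 1..{T}")
    stock = [W_init]
    rates, used_list, pats = [], [], []
    W = W_init
    for t in range(t0, T + 1):
        P = series.count(t)
        used = min(amount_fn(t, W), P, W)
        # realised rate: share of this week's patients who received a kit
        rates.append(used / P if P > 0 else 0.0)
        W -= used
        stock.append(W)
        used_list.append(used)
        pats.append(P)
    return StockTrajectory(
        strategy=strategy,
        institution_id=series.institution_id,
        season=series.season,
        W_init=W_init,
        t0=t0,
        T=T,
        stock=np.asarray(stock, dtype=int),
        rates=np.asarray(rates, dtype=float),
        kits_used=np.asarray(used_list, dtype=int),
        patients=np.asarray(pats, dtype=int),
    )


def run_s1(series: WeeklySeries, W_init: int, t0: int = DEFAULT_T0) -> StockTrajectory:
    """Simple strategy 1: spend up to half the remaining stock each week,
    ``W_{t+1} = W_t - min(floor(W_t / 2), P_t)``."""
    return _run_amount_rule(series, "S1", lambda t, W: W // 2, W_init, t0)


def run_s2(series: WeeklySeries, W_init: int, t0: int = DEFAULT_T0) -> StockTrajectory:
    """Simple strategy 2: spread the remaining stock evenly over the
    remaining weeks, ``W_{t+1} = W_t - min(floor(W_t / (T - t)), P_t)``;
    in the final week (divisor zero) spend ``min(W_T, P_T)``."""
    T = series.T

    def amount(t: int, W: int) -> int:
        return W if t == T else W // (T - t)

    return _run_amount_rule(series, "S2", amount, W_init, t0)


STRATEGY_RUNNERS = {"I": run_ideal, "M": run_main, "S1": run_s1, "S2": run_s2}
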