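"""Loss metric against the ideal distribution and filling-rate sweeps.

A strategy X is scored by the time-averaged absolute deviation of its
unused-kit trajectory from the ideal benchmark,

    E^X = 1 / ((T - 5) * W_init) * sum_{t=6..T} |W^X_t - W^I_t| ,

which is 0 for the ideal itself and grows towards 1/2 as a strategy
over-spends early (shortage) or hoards (waste).  The severity of the
shortage is described by the filling rate f = W_init / sum_t P_t: f = 1
means exactly one kit per patient.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .forecast import ForecastMatrix, ParamBounds, rolling_forecasts
from .series_io import WeeklySeries, assign_groups
from .strategies import (
    DEFAULT_T0,
    StockTrajectory,
    run_ideal,
    run_main,
    run_s1,
    run_s2,
)

__all__ = [
    "LossResult",
    "SweepResult",
    "MinLossFill",
    "loss",
    "filling_to_stock",
    "sweep_filling_rates",
    "find_min_loss_fill",
]


@dataclasses.dataclass(frozen=True)
class LossResult:
    strategy: str
    E: float
    filling_rate: float
    W_init: int
    institution_id: str
    season: str


@dataclasses.dataclass(frozen=True)
class MinLossFill:
    """Grid argmin of loss over the filling rate for one institution/strategy."""

    f: float
    E: float
    interior: bool  # True iff f* is strictly inside the grid range
    tie: bool  # True iff another grid point attains the same minimum


def loss(candidate: StockTrajectory, ideal: StockTrajectory) -> float:
    """Loss of ``candidate`` against the ideal trajectory.

    Sums |W^X_t - W^I_t| over the strategy-dependent weeks (t0+1 .. T) and
    normalises by (T - 5) * W_init; with the default activation week t0 = 5
    this is exactly the sum over weeks 6..T.
    """
    for attr in ("W_init", "T", "t0"):
        if getattr(candidate, attr) != getattr(ideal, attr):
            raise ValueError(
                f"trajectories disagree on {attr}: "
                f"{getattr(candidate, attr)} vs {getattr(ideal, attr)}"
            )
    t0, T = candidate.t0, candidate.T
    diff = sum(abs(candidate.W(t) - ideal.W(t)) for t in range(t0 + 1, T + 1))
    return diff / ((T - 5) * candidate.W_init)


def filling_to_stock(f: float, series: WeeklySeries) -> int:
    """Initial stock implied by filling rate ``f``:
    ``W_init = round(f * season total)``, at least 1."""
    if f <= 0:
        raise ValueError(f"filling rate must be positive, got {f}")
    total = series.total
    if total <= 0:
        raise ValueError(
            f"institution {series.institution_id!r}: zero-total season, "
            "filling rate undefined"
        )
    return max(1, math.floor(f * total + 0.5))


_QUANTILE_KEYS = ("mean", "median", "q1", "q3", "min", "max")


@dataclasses.dataclass(frozen=True)
class SweepResult:
    """Per-cell losses of a filling-rate sweep plus group-level summaries.

    ``records`` has one row per (institution, strategy, f); ``failures``
    lists cells that could not be computed, with the reason.
    """

    f_grid: tuple[float, ...]
    strategies: tuple[str, ...]
    records: pd.DataFrame
    groups: Mapping[str, str]
    failures: tuple[tuple[str, str, float, str], ...] = ()

    def losses(self, institution_id: str, strategy: str) -> pd.DataFrame:
        sel = self.records[
            (self.records["institution_id"] == institution_id)
            & (self.records["strategy"] == strategy)
        ]
        return sel.sort_values("f")

    def group_summary(self) -> pd.DataFrame:
        """Box-plot style summary per (group, strategy, f): mean, median,
        linear-interpolation quartiles, min, max and the count of outliers
        beyond 1.5x IQR from the quartiles."""
        rows = []
        rec = self.records.copy()
        rec["group"] = rec["institution_id"].map(self.groups)
        for (group, strategy, f), sub in rec.groupby(["group", "strategy", "f"]):
            e = sub["E"].to_numpy()
            q1, med, q3 = np.percentile(e, [25, 50, 75])
            iqr = q3 - q1
            out_mask = (e < q1 - 1.5 * iqr) | (e > q3 + 1.5 * iqr)
            rows.append(
                {
                    "group": group,
                    "strategy": strategy,
                    "f": f,
                    "n": len(e),
                    "mean": e.mean(),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "min": e.min(),
                    "max": e.max(),
                    "n_outliers": int(out_mask.sum()),
                }
            )
        return pd.DataFrame(rows).sort_values(["group", "strategy", "f"]).reset_index(
            drop=True
        )


def sweep_filling_rates(
    series: Sequence[WeeklySeries],
    strategies: Sequence[str] = ("M", "S1", "S2"),
    f_grid: Iterable[float] = (0.4, 0.55, 0.7, 0.85, 1.0),
    t0: int = DEFAULT_T0,
    bounds: ParamBounds | None = None,
    forecasts: Mapping[str, ForecastMatrix] | None = None,
    groups: Mapping[str, str] | None = None,
) -> SweepResult:
    """Run every strategy at every filling rate for every institution.

    For each cell the initial stock is derived from ``f``, the ideal
    benchmark and the strategy trajectory are run, and the loss recorded.
    Rolling forecasts for strategy M are fitted once per institution (or
    supplied precomputed via ``forecasts``).  Per-cell failures are recorded
    and the sweep continues.
    """
    f_grid = tuple(float(f) for f in f_grid)
    if not f_grid:
        raise ValueError("empty filling-rate grid")
    strategies = tuple(strategies)
    unknown = set(strategies) - {"I", "M", "S1", "S2"}
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")
    if groups is None:
        groups = assign_groups(series)

    fm_cache: dict[str, ForecastMatrix] = dict(forecasts or {})
    rows = []
    failures: list[tuple[str, str, float, str]] = []
    for s in series:
        if "M" in strategies and s.institution_id not in fm_cache:
            fm_cache[s.institution_id] = rolling_forecasts(s, bounds=bounds)
        for f in f_grid:
            try:
                W_init = filling_to_stock(f, s)
                ideal = run_ideal(s, W_init, t0)
            except ValueError as exc:
                for X in strategies:
                    failures.append((s.institution_id, X, f, str(exc)))
                continue
            for X in strategies:
                try:
                    if X == "I":
                        traj = ideal
                    elif X == "M":
                        traj = run_main(s, fm_cache[s.institution_id], W_init, t0)
                    elif X == "S1":
                        traj = run_s1(s, W_init, t0)
                    else:
                        traj = run_s2(s, W_init, t0)
                    rows.append(
                        {
                            "institution_id": s.institution_id,
                            "season": s.season,
                            "strategy": X,
                            "f": f,
                            "W_init": W_init,
                            "E": loss(traj, ideal),
                        }
                    )
                except ValueError as exc:
                    failures.append((s.institution_id, X, f, str(exc)))
    records = pd.DataFrame(
        rows, columns=["institution_id", "season", "strategy", "f", "W_init", "E"]
    )
    return SweepResult(
        f_grid=f_grid,
        strategies=strategies,
        records=records,
        groups=dict(groups),
        failures=tuple(failures),
    )


def find_min_loss_fill(
    sweep: SweepResult, institution_id: str, strategy: str
) -> MinLossFill:
    """Grid argmin of the loss over the filling rate.

    Ties go to the smallest f (flagged); ``interior`` is True iff the
    minimiser lies strictly inside the swept range — the regime where the
    strategy lets a clinic stock *fewer* kits than patients at minimal loss.
    """
    cells = sweep.losses(institution_id, strategy)
    if len(cells) < 3:
        raise ValueError(
            f"need >= 3 grid points for {institution_id}/{strategy}, "
            f"got {len(cells)}"
        )
    e = cells["E"].to_numpy()
    fs = cells["f"].to_numpy()
    best = float(e.min())
    hits = fs[np.isclose(e, best, rtol=0.0, atol=1e-12)]
    f_star = float(hits.min())
    return MinLossFill(
        f=f_star,
        E=best,
        interior=bool(fs.min() < f_star < fs.max()),
        tie=len(hits) > 1,
    )
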