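"""Single-peak epidemic incidence curve fitting and rolling forecasts.

The weekly incidence implied by the classical SIR model near its peak is
well approximated by the Kermack–McKendrick bell

    P(t) = A * sech^2(b*t + c) + p ,

where ``A`` is the peak height above baseline (patients/week), ``b`` the
epidemic growth/decay rate (1/week), ``c`` a (negative) phase shift so the
peak sits at week ``-c/b``, and ``p`` a small additive baseline.  Negative
predictions are clamped to zero before use.

Fits are bounded least squares over a prefix of the season, started from a
fixed coarse grid of initial guesses, so they are fully deterministic.
Rolling forecasts re-fit on weeks ``1..t`` and predict weeks ``t+1..T``,
mimicking in-season use where the future is unknown.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .series_io import WeeklySeries

__all__ = [
    "CurveParams",
    "ParamBounds",
    "FitResult",
    "ForecastMatrix",
    "evaluate_curve",
    "fit_curve",
    "rolling_forecasts",
    "future_demand",
    "DEFAULT_FIRST_FIT_WEEK",
]

#: Earliest week a fit may be based on: the prediction-based strategy needs
#: the data from the initial five weeks.
DEFAULT_FIRST_FIT_WEEK = 5

# Fixed multi-start grid over (b, c); A starts at the prefix maximum, p at 0.
_B_STARTS = (0.15, 0.3, 0.5, 0.8, 1.3)
_C_STARTS = (-9.0, -6.5, -4.5, -2.5, -1.0)


@dataclasses.dataclass(frozen=True)
class CurveParams:
    """Fitted incidence-curve parameters.

    ``r0_estimate`` (basic reproduction number implied by the underlying SIR
    fit) is an optional derived quantity; it is ``None`` unless supplied by
    the caller.
    """

    A: float
    b: float
    c: float
    p: float
    r0_estimate: float | None = None

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"A must be positive, got {self.A}")
        if not self.b > 0:
            raise ValueError(f"b must be positive, got {self.b}")
        if self.c > 0:
            raise ValueError(f"c must be <= 0, got {self.c}")
        if not -1.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [-1, 1], got {self.p}")

    @property
    def peak_week(self) -> float:
        """Real-valued week at which the un-clamped curve is maximal."""
        return -self.c / self.b

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.b, self.c, self.p], dtype=float)


@dataclasses.dataclass(frozen=True)
class ParamBounds:
    """Box constraints (lower, upper) for each of A, b, c, p."""

    A: tuple[float, float] = (1e-6, 300.0)
    b: tuple[float, float] = (0.1, 2.0)
    c: tuple[float, float] = (-10.0, 0.0)
    p: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("A", "b", "c", "p"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bounds for {name}: lower {lo} !< upper {hi}")

    @classmethod
    def for_counts(cls, counts: Sequence[int] | np.ndarray) -> "ParamBounds":
        """Default bounds with the scale cap tied to the observed maximum,
        A in (0, 3*max count]."""
        peak = float(max(np.max(np.asarray(counts, dtype=float)), 1.0))
        return cls(A=(1e-6, 3.0 * peak))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[float]]) -> "ParamBounds":
        kwargs = {k: (float(v[0]), float(v[1])) for k, v in mapping.items()}
        return cls(**kwargs)

    def lower(self) -> np.ndarray:
        return np.array([self.A[0], self.b[0], self.c[0], self.p[0]])

    def upper(self) -> np.ndarray:
        return np.array([self.A[1], self.b[1], self.c[1], self.p[1]])

    def contains(self, params: CurveParams, atol: float = 1e-9) -> bool:
        x = params.as_array()
        return bool(
            np.all(x >= self.lower() - atol) and np.all(x <= self.upper() + atol)
        )


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Outcome of one bounded least-squares fit on weeks ``1..n_weeks_used``."""

    params: CurveParams
    sse: float
    n_weeks_used: int
    converged: bool
    degenerate: bool = False


def _curve(x: np.ndarray, weeks: np.ndarray) -> np.ndarray:
    A, b, c, p = x
    return np.maximum(A / np.cosh(b * weeks + c) ** 2 + p, 0.0)


def _curve_jac(x: np.ndarray, weeks: np.ndarray) -> np.ndarray:
    """Jacobian of the clamped curve w.r.t. (A, b, c, p); rows where the raw
    curve is clamped at zero have zero gradient."""
    A, b, c, p = x
    u = b * weeks + c
    sech2 = 1.0 / np.cosh(u) ** 2
    raw = A * sech2 + p
    active = (raw > 0.0).astype(float)
    dA = sech2
    dc = -2.0 * A * sech2 * np.tanh(u)
    db = dc * weeks
    dp = np.ones_like(weeks)
    return np.column_stack([dA, db, dc, dp]) * active[:, None]


def evaluate_curve(params: CurveParams, week: int | float | np.ndarray) -> float | np.ndarray:
    """Predicted patients in ``week``: max(0, A*sech^2(b*week + c) + p).

    Vectorised over ``week``; weeks must be >= 1.
    """
    week_arr = np.asarray(week, dtype=float)
    if np.any(week_arr < 1):
        raise ValueError("weeks are 1-based; got week < 1")
    out = _curve(params.as_array(), week_arr)
    return float(out) if np.isscalar(week) or week_arr.ndim == 0 else out


def _coerce_counts(series: WeeklySeries | Sequence[float]) -> np.ndarray:
    if isinstance(series, WeeklySeries):
        return series.counts_array()
    return np.asarray(series, dtype=float)


def fit_curve(
    series: WeeklySeries | Sequence[float],
    s: int | None = None,
    bounds: ParamBounds | None = None,
) -> FitResult:
    """Bounded least-squares fit of the incidence curve to weeks ``1..s``.

    Minimises ``sum_t (P_t - curve(t))^2`` under the box constraints,
    starting from a fixed coarse grid over (b, c); the best start wins, so
    the result is deterministic.  Float-valued observations are accepted so
    that noiseless model curves can be fitted exactly.

    Parameters
    ----------
    series : WeeklySeries or sequence of float
        Observed weekly counts (the full season; only the prefix is fitted).
    s : int, optional
        Number of leading weeks to fit on (default: all).  Must be >= 5:
        the prediction-based strategy requires the data from the initial
        five weeks.
    bounds : ParamBounds, optional
        Box constraints; default ties the scale cap to the *full* series
        maximum, mirroring ranges pre-determined from whole-season fits.
    """
    y_full = _coerce_counts(series)
    T = len(y_full)
    if s is None:
        s = T
    if s < DEFAULT_FIRST_FIT_WEEK:
        raise ValueError(
            f"fitting requires the data from the initial five weeks (s={s})"
        )
    if s > T:
        raise ValueError(f"s={s} exceeds available weeks T={T}")
    if bounds is None:
        bounds = ParamBounds.for_counts(y_full)

    y = y_full[:s]
    weeks = np.arange(1, s + 1, dtype=float)
    lo, hi = bounds.lower(), bounds.upper()

    if not np.any(y > 0):
        # No signal: boundary fit at the smallest admissible scale.
        x = np.array([lo[0], lo[1], hi[2], float(np.clip(0.0, lo[3], hi[3]))])
        resid = _curve(x, weeks) - y
        return FitResult(
            params=CurveParams(*map(float, x)),
            sse=float(resid @ resid),
            n_weeks_used=int(s),
            converged=True,
            degenerate=True,
        )

    A0 = float(np.clip(np.max(y), lo[0], hi[0]))
    p0 = float(np.clip(0.0, lo[3], hi[3]))
    best_x: np.ndarray | None = None
    best_cost = np.inf
    best_success = False
    for b0 in _B_STARTS:
        for c0 in _C_STARTS:
            x0 = np.clip(np.array([A0, b0, c0, p0]), lo, hi)
            res = least_squares(
                lambda x: _curve(x, weeks) - y,
                x0,
                jac=lambda x: _curve_jac(x, weeks),
                bounds=(lo, hi),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=400,
            )
            if res.cost < best_cost - 1e-15:
                best_cost = res.cost
                best_x = res.x
                best_success = bool(res.success)
    assert best_x is not None
    resid = _curve(best_x, weeks) - y
    params = CurveParams(*(float(v) for v in best_x))
    return FitResult(
        params=params,
        sse=float(resid @ resid),
        n_weeks_used=int(s),
        converged=best_success,
    )


@dataclasses.dataclass(frozen=True)
class ForecastMatrix:
    """Rolling predictions: row ``t`` holds forecasts for weeks ``t+1..T``
    made from data observed through week ``t``."""

    T: int
    rows: Mapping[int, np.ndarray]  # t -> array of length T - t, all >= 0
    fits: Mapping[int, FitResult] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, row in self.rows.items():
            if len(row) != self.T - t:
                raise ValueError(
                    f"row {t}: expected {self.T - t} forecasts, got {len(row)}"
                )
            if np.any(np.asarray(row) < 0):
                raise ValueError(f"row {t}: negative forecast")

    def row(self, t: int) -> np.ndarray:
        if t not in self.rows:
            raise KeyError(f"no forecasts fitted through week {t}")
        return np.asarray(self.rows[t], dtype=float)

    def predict(self, s: int, t: int) -> float:
        """Forecast for week ``s`` made from data through week ``t`` (s > t)."""
        if s <= t or s > self.T:
            raise KeyError(f"forecast P̂_{s}({t}) undefined (need t < s <= T)")
        return float(self.row(t)[s - t - 1])

    @classmethod
    def from_truth(cls, series: WeeklySeries, first_fit_week: int = DEFAULT_FIRST_FIT_WEEK) -> "ForecastMatrix":
        """Oracle matrix whose 'forecasts' are the observed future counts —
        the hypothetical perfect predictor."""
        T = series.T
        rows = {
            t: np.asarray(series.counts[t:], dtype=float)
            for t in range(first_fit_week, T)
        }
        return cls(T=T, rows=rows)


def rolling_forecasts(
    series: WeeklySeries,
    bounds: ParamBounds | None = None,
    first_fit_week: int = DEFAULT_FIRST_FIT_WEEK,
) -> ForecastMatrix:
    """Fit on weeks ``1..t`` and forecast weeks ``t+1..T``, for each
    ``t = first_fit_week .. T-1``.  Forecasts are clamped at zero."""
    if first_fit_week < DEFAULT_FIRST_FIT_WEEK:
        raise ValueError(
            f"first_fit_week must be >= {DEFAULT_FIRST_FIT_WEEK}, got {first_fit_week}"
        )
    T = series.T
    if bounds is None:
        bounds = ParamBounds.for_counts(series.counts)
    rows: dict[int, np.ndarray] = {}
    fits: dict[int, FitResult] = {}
    for t in range(first_fit_week, T):
        try:
            fit = fit_curve(series, s=t, bounds=bounds)
        except ValueError as exc:
            raise ValueError(f"rolling fit failed at week {t}: {exc}") from exc
        future_weeks = np.arange(t + 1, T + 1, dtype=float)
        rows[t] = _curve(fit.params.as_array(), future_weeks)
        fits[t] = fit
    return ForecastMatrix(T=T, rows=rows, fits=fits)


def future_demand(fm: ForecastMatrix, t: int) -> float:
    """Total predicted patients for weeks ``t+1..T`` based on data through
    ``t``; the empty sum at ``t = T`` is 0."""
    if t == fm.T:
        return 0.0
    return float(np.sum(fm.row(t)))
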