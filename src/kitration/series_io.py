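"""Weekly incidence series: container, delimited-text I/O, grouping, summaries.

The unit of observation is one medical institution over one epidemic season:
an ordered vector of non-negative integer weekly case counts ``P_t`` for
weeks ``t = 1..T``.  Institutions are ranked by season total and split into
volume groups A (largest), B and C, the convention used throughout the
evaluation module for reporting losses by institution size.
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Minimum season length. Strategies activate at week 5 and the loss is
#: summed over weeks 6..T, so at least two post-activation weeks are needed.
MIN_WEEKS = 7

REQUIRED_COLUMNS = ("institution_id", "season", "week", "cases")

GROUP_LABELS = ("A", "B", "C")


@dataclasses.dataclass(frozen=True)
class WeeklySeries:
    """One institution-season of observed weekly patient counts.

    Parameters
    ----------
    institution_id : str
        Opaque identifier of the medical institution.
    season : str
        Season label (free-form, e.g. ``"2018"``).
    counts : sequence of int
        Observed new suspected patients per week, weeks ``1..T``.
    """

    institution_id: str
    season: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if any(float(orig) != new for orig, new in zip(self.counts, counts)):
            raise ValueError(
                f"institution {self.institution_id!r}: non-integer case count"
            )
        if any(c < 0 for c in counts):
            raise ValueError(
                f"institution {self.institution_id!r}: negative case count"
            )
        if len(counts) < MIN_WEEKS:
            raise ValueError(
                f"institution {self.institution_id!r}: season has "
                f"{len(counts)} weeks, need at least {MIN_WEEKS}"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def T(self) -> int:
        """Number of weeks in the season."""
        return len(self.counts)

    @property
    def total(self) -> int:
        """Season total of patients."""
        return int(sum(self.counts))

    def count(self, week: int) -> int:
        """Observed count in 1-based ``week``."""
        if not 1 <= week <= self.T:
            raise IndexError(f"week {week} outside 1..{self.T}")
        return self.counts[week - 1]

    def future_total(self, week: int) -> int:
        """Sum of observed counts for weeks ``week+1 .. T`` (0 at ``week >= T``)."""
        return int(sum(self.counts[week:]))

    def counts_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics of season totals for one group (or all)."""

    group: str  # "A", "B", "C" or "Total"
    n: int
    mean: float
    sd: float
    max: int
    min: int
    sd_degenerate: bool = False  # True when n == 1 and sd is reported as 0


def load_series(path: str | Path, season: str | None = None) -> list[WeeklySeries]:
    """Load a collection of weekly series from a delimited text file.

    The file must have a header with columns
    ``institution_id, season, week, cases`` (comma-separated, UTF-8; lines
    starting with ``#`` are ignored).  Weeks of each institution must form a
    contiguous range ``1..T``.

    Parameters
    ----------
    path : path
        Input file.
    season : str, optional
        If given, keep only rows of this season.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype={"institution_id": str, "season": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if season is not None:
        df = df[df["season"] == season]
        if df.empty:
            raise ValueError(f"{path}: no rows for season {season!r}")

    bad = df["cases"].apply(lambda v: float(v) < 0 or float(v) != int(v))
    if bad.any():
        row = df[bad].iloc[0]
        raise ValueError(
            f"{path}: institution {row['institution_id']!r} week "
            f"{int(row['week'])}: cases must be a non-negative integer, "
            f"got {row['cases']!r}"
        )

    out: list[WeeklySeries] = []
    for (inst, seas), grp in df.groupby(["institution_id", "season"], sort=True):
        weeks = grp["week"].astype(int).to_numpy()
        if len(np.unique(weeks)) != len(weeks):
            dup = int(weeks[pd.Series(weeks).duplicated().to_numpy()][0])
            raise ValueError(
                f"{path}: institution {inst!r}: duplicate week {dup}"
            )
        expected = np.arange(1, len(weeks) + 1)
        present = np.sort(weeks)
        if not np.array_equal(present, expected):
            gap = int(np.setdiff1d(expected, present)[0]) if len(
                np.setdiff1d(expected, present)
            ) else int(present[0])
            raise ValueError(
                f"{path}: institution {inst!r}: weeks must form 1..T "
                f"with no gaps (missing week {gap})"
            )
        ordered = grp.sort_values("week")
        out.append(
            WeeklySeries(
                institution_id=str(inst),
                season=str(seas),
                counts=tuple(int(c) for c in ordered["cases"]),
            )
        )
    if not out:
        raise ValueError(f"{path}: no series found")
    return out


def series_to_frame(series: Iterable[WeeklySeries]) -> pd.DataFrame:
    """Long-format DataFrame (one row per institution-week), sorted by id."""
    rows = []
    for s in sorted(series, key=lambda s: (s.institution_id, s.season)):
        for week, cases in enumerate(s.counts, start=1):
            rows.append((s.institution_id, s.season, week, cases))
    if not rows:
        raise ValueError("empty series collection")
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def save_series(
    series: Iterable[WeeklySeries],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """Write a collection to delimited text such that :func:`load_series`
    round-trips it exactly.  ``header_lines`` are emitted as ``#`` comments."""
    df = series_to_frame(series)
    _write_with_header(df, path, header_lines)


def save_table(
    table: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    """Write a result table as delimited text, floats at 6 significant digits."""
    if table.empty:
        raise ValueError("refusing to write an empty table")
    _write_with_header(table, path, header_lines, float_format="%.6g")


def _write_with_header(
    df: pd.DataFrame,
    path: str | Path,
    header_lines: Sequence[str],
    float_format: str | None = None,
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format=float_format)


def assign_groups(series: Sequence[WeeklySeries]) -> dict[str, str]:
    """Rank institutions by descending season total into groups A, B, C.

    The first ``ceil(N/3)`` institutions form group A, the next
    ``ceil((N-|A|)/2)`` group B, the rest group C (at N=38: 13/13/12).
    Ties in the totals are broken by institution id, ascending.
    """
    series = list(series)
    if len(series) < 3:
        raise ValueError(f"need at least 3 institutions, got {len(series)}")
    ids = [s.institution_id for s in series]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate institution ids in collection")
    ranked = sorted(series, key=lambda s: (-s.total, s.institution_id))
    n = len(ranked)
    n_a = math.ceil(n / 3)
    n_b = math.ceil((n - n_a) / 2)
    groups: dict[str, str] = {}
    for i, s in enumerate(ranked):
        groups[s.institution_id] = "A" if i < n_a else ("B" if i < n_a + n_b else "C")
    return groups


def summarize_groups(
    series: Sequence[WeeklySeries], groups: Mapping[str, str]
) -> list[GroupSummary]:
    """Per-group and overall mean/sd/max/min of season totals.

    ``sd`` is the sample standard deviation (denominator ``n - 1``); a
    single-member group reports sd 0 with ``sd_degenerate=True``.
    """
    missing = [s.institution_id for s in series if s.institution_id not in groups]
    if missing:
        raise ValueError(f"institutions without a group: {missing}")
    totals = {g: [] for g in GROUP_LABELS}
    for s in series:
        totals[groups[s.institution_id]].append(s.total)
    out: list[GroupSummary] = []
    for label in (*GROUP_LABELS, "Total"):
        vals = (
            [t for g in GROUP_LABELS for t in totals[g]]
            if label == "Total"
            else totals[label]
        )
        if not vals:
            continue
        arr = np.asarray(vals, dtype=float)
        degenerate = len(vals) == 1
        out.append(
            GroupSummary(
                group=label,
                n=len(vals),
                mean=float(arr.mean()),
                sd=0.0 if degenerate else float(arr.std(ddof=1)),
                max=int(arr.max()),
                min=int(arr.min()),
                sd_degenerate=degenerate,
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])
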