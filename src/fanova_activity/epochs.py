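"""From raw per-epoch counts to one complete daily profile per child.

The inclusion rules: a day is kept when the device was worn for at least
600 minutes between 07:00 and 22:00; a kept day yields a profile only when
all 660 one-minute epochs of the common 08:30-19:30 window are present
(functional analysis needs a common observation grid with no missing
data); and one eligible day is sampled uniformly per child so daily
profiles are independent across the cohort.

A minute counts as worn only when all of its sub-epochs are present;
missingness is absent rows in the input (nonwear detection is out of
scope and can be plugged in upstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timegrid import (
    COMMON_END,
    COMMON_START,
    MIN_WEAR_MINUTES,
    MINUTE_GRID,
    N_GRID,
    WEAR_END,
    WEAR_START,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("child_id", "date", "time", "epoch_seconds", "counts")


class EpochParseError(ValueError):
    """Raised when an epoch CSV violates the interface contract."""


@dataclass
class EpochSeries:
    """One child-day of counts at a uniform epoch length.

    ``starts`` are epoch start times in seconds since midnight, strictly
    increasing.  For minute-level series produced by
    :func:`aggregate_to_minutes`, only complete minutes appear.
    """

    child_id: str
    date: str
    starts: np.ndarray  # int seconds since midnight
    epoch_seconds: int
    counts: np.ndarray  # nonnegative ints

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.starts.size != self.counts.size:
            raise ValueError("starts and counts differ in length")
        if np.any(np.diff(self.starts) <= 0):
            raise ValueError(f"epoch starts not strictly increasing for {self.child_id} {self.date}")
        if np.any(self.counts < 0):
            raise ValueError(f"negative counts for {self.child_id} {self.date}")


@dataclass
class DailyProfile:
    """A complete 660-point one-minute count vector on the 08:30-19:30 grid."""

    child_id: str
    date: str
    counts: np.ndarray  # shape (660,)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_GRID,):
            raise ValueError(f"profile must have exactly {N_GRID} values")

    @property
    def grid(self) -> np.ndarray:
        return MINUTE_GRID


@dataclass
class FunctionalDataset:
    """One profile per child, joined with covariates and weights."""

    child_ids: list[str]
    profiles: np.ndarray  # shape (n, 660)
    covariates: pd.DataFrame  # indexed like child_ids
    weights: np.ndarray  # shape (n,), positive

    def __post_init__(self) -> None:
        n = len(self.child_ids)
        if self.profiles.shape != (n, N_GRID):
            raise ValueError("profiles shape does not match child list")
        if self.weights.shape != (n,) or np.any(self.weights <= 0):
            raise ValueError("weights must be positive, one per child")

    @property
    def n(self) -> int:
        return len(self.child_ids)


def parse_epoch_csv(path) -> list[EpochSeries]:
    """Read and validate an epoch CSV into one series per (child, date)."""
    frame = pd.read_csv(path, dtype={"child_id": str, "date": str, "time": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise EpochParseError(f"missing column(s): {', '.join(missing)}")

    counts = pd.to_numeric(frame["counts"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise EpochParseError(f"row {row + 2}: counts must be a nonnegative integer, got {frame['counts'].iloc[row]!r}")
    frame["counts"] = counts.astype(np.int64)

    try:
        parts = frame["time"].str.split(":", expand=True).astype(int)
    except (ValueError, TypeError) as exc:
        raise EpochParseError(f"unparseable time value: {exc}") from exc
    frame["_sec"] = parts[0] * 3600 + parts[1] * 60 + (parts[2] if parts.shape[1] > 2 else 0)

    dup = frame.duplicated(subset=["child_id", "date", "_sec"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise EpochParseError(
            f"row {row + 2}: duplicate epoch for child {frame['child_id'].iloc[row]!r} at "
            f"{frame['date'].iloc[row]} {frame['time'].iloc[row]}"
        )

    series = []
    for (child, date), group in frame.groupby(["child_id", "date"], sort=True):
        group = group.sort_values("_sec")
        lengths = group["epoch_seconds"].unique()
        if lengths.size != 1:
            raise EpochParseError(f"mixed epoch lengths for child {child!r} on {date}")
        series.append(
            EpochSeries(
                child_id=str(child),
                date=str(date),
                starts=group["_sec"].to_numpy(),
                epoch_seconds=int(lengths[0]),
                counts=group["counts"].to_numpy(),
            )
        )
    return series


def aggregate_to_minutes(series: EpochSeries) -> EpochSeries:
    """Sum sub-epochs into one-minute epochs.

    A minute needs its full complement of sub-epochs (e.g. four 15-s
    epochs) to be emitted; incomplete minutes are dropped, i.e. missing.
    Already-minute input is returned unchanged.
    """
    if 60 % series.epoch_seconds:
        raise ValueError(f"epoch length {series.epoch_seconds}s does not divide 60s")
    if series.epoch_seconds == 60:
        return series
    need = 60 // series.epoch_seconds
    minute = series.starts // 60
    uniq, inverse, counts_per = np.unique(minute, return_inverse=True, return_counts=True)
    sums = np.zeros(uniq.size, dtype=np.int64)
    np.add.at(sums, inverse, series.counts)
    complete = counts_per == need
    return EpochSeries(
        child_id=series.child_id,
        date=series.date,
        starts=uniq[complete] * 60,
        epoch_seconds=60,
        counts=sums[complete],
    )


def wear_time_filter(minute_series: EpochSeries) -> tuple[bool, int]:
    """Keep a day iff >= 600 worn minutes start within [07:00, 22:00)."""
    if minute_series.epoch_seconds != 60:
        raise ValueError("wear_time_filter expects a minute-level series")
    mins = minute_series.starts // 60
    worn = int(np.count_nonzero((mins >= WEAR_START) & (mins < WEAR_END)))
    return worn >= MIN_WEAR_MINUTES, worn


def standardize_window(minute_series: EpochSeries) -> DailyProfile | None:
    """Extract the 660 minutes of [08:30, 19:30); reject if any is missing."""
    if minute_series.epoch_seconds != 60:
        raise ValueError("standardize_window expects a minute-level series")
    mins = minute_series.starts // 60
    inside = (mins >= COMMON_START) & (mins < COMMON_END)
    if int(np.count_nonzero(inside)) != N_GRID:
        return None
    return DailyProfile(
        child_id=minute_series.child_id,
        date=minute_series.date,
        counts=minute_series.counts[inside].astype(float),
    )


def qc_days(series_list: list[EpochSeries]) -> tuple[list[DailyProfile], pd.DataFrame]:
    """Run aggregation, wear-time and window filters over all child-days.

    Returns eligible profiles plus a QC report with one row per day:
    ``child_id, date, minutes_worn, eligible, reason``.
    """
    profiles: list[DailyProfile] = []
    rows = []
    for series in series_list:
        minute = aggregate_to_minutes(series)
        keep, worn = wear_time_filter(minute)
        if not keep:
            rows.append((series.child_id, series.date, worn, False, "insufficient_wear_time"))
            continue
        profile = standardize_window(minute)
        if profile is None:
            rows.append((series.child_id, series.date, worn, False, "incomplete_common_window"))
            continue
        profiles.append(profile)
        rows.append((series.child_id, series.date, worn, True, ""))
    report = pd.DataFrame(rows, columns=["child_id", "date", "minutes_worn", "eligible", "reason"])
    return profiles, report


def sample_one_profile_per_child(
    profiles: list[DailyProfile],
    covariates: pd.DataFrame,
    seed: int,
    weight_col: str = "weight",
) -> FunctionalDataset:
    """Pick one eligible day per child uniformly at random and join covariates.

    Children present in the covariate table but with zero eligible days are
    excluded (logged); children with profiles but no covariate row raise.
    """
    by_child: dict[str, list[DailyProfile]] = {}
    for p in profiles:
        by_child.setdefault(p.child_id, []).append(p)

    cov = covariates.set_index("child_id", drop=False)
    missing_cov = sorted(set(by_child) - set(cov.index))
    if missing_cov:
        raise ValueError(f"profiled children without covariates: {missing_cov[:5]}")
    skipped = sorted(set(cov.index) - set(by_child))
    if skipped:
        logger.info("excluding %d children with no eligible day: %s%s",
                    len(skipped), skipped[:5], "..." if len(skipped) > 5 else "")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    child_ids = sorted(by_child)
    chosen = []
    for child in child_ids:
        days = sorted(by_child[child], key=lambda p: p.date)
        chosen.append(days[int(rng.integers(len(days)))])

    return FunctionalDataset(
        child_ids=child_ids,
        profiles=np.vstack([p.counts for p in chosen]),
        covariates=cov.loc[child_ids].reset_index(drop=True),
        weights=cov.loc[child_ids, weight_col].to_numpy(dtype=float),
    )
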