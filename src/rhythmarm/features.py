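"""Hourly feature extraction from raw smartphone sensor streams.

Raw inputs are Beiwe-style CSV streams: accelerometer samples (epoch
timestamp plus per-axis acceleration in m/s^2) and screen-on / unlock
event logs (epoch timestamp).  Both are reduced to an hourly grid in
participant-local time:

* ``X(t)`` — mean accelerometer magnitude ``sqrt(ax^2+ay^2+az^2)`` over
  the hour, missing when the hour contains no samples (phone off, no
  signal, airplane mode);
* ``Y(t)`` — screen-on count over the hour, zero when no events fired
  (an event log encodes absence as zero, not as a gap).

Hour bins are half-open ``[h, h+1)`` and each record is labeled by the
clock hour at the *end* of the bin.  Daily self-reported bed / wake
clock times are cleaned with a window-plus-duration rule that undoes
AM/PM entry slips, and per-participant EMA summaries (mean sleep
duration, bed/wake-time SDs, mean mood) are computed on a continuous
time axis so that post-midnight bedtimes do not inflate the SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOURS_PER_DAY = 24

#: Acceptable bedtime window, hours on a wrapped axis: [17:00, 28:00) == 5 PM .. 4 AM.
BED_WINDOW = (17.0, 28.0)
#: Acceptable wake window: [4:00, 15:00) == 4 AM .. 3 PM.
WAKE_WINDOW = (4.0, 15.0)
#: Implied sleep durations outside this range are treated as entry errors.
REALISTIC_SLEEP_HOURS = (1.0, 16.0)


@dataclass(frozen=True)
class CsvDialect:
    """Column layout of the raw Beiwe-style CSV streams."""

    timestamp_col: str = "timestamp"
    timestamp_unit: str = "ms"  # "ms" | "s"
    x_col: str = "x"
    y_col: str = "y"
    z_col: str = "z"
    event_col: str = "event"


@dataclass
class EmaResponse:
    """One daily self-report: sleep duration, bed/wake clock times, mood (1-7)."""

    date: str | None = None
    sleep_hours: float | None = None
    bed_time: float | None = None  # clock hour in [0, 24)
    wake_time: float | None = None
    mood: int | None = None

    def __post_init__(self) -> None:
        if self.mood is not None and self.mood not in range(1, 8):
            raise ValueError(f"mood must be in 1..7, got {self.mood}")
        if self.sleep_hours is not None and self.sleep_hours < 0:
            raise ValueError("sleep_hours must be non-negative")


@dataclass
class EmaSummary:
    """Per-participant EMA aggregates entering the association stage."""

    mean_sleep_hours: float | None = None
    sd_bed_time_hours: float | None = None
    sd_wake_time_hours: float | None = None
    mean_mood: float | None = None
    n_responses: int = 0


@dataclass
class HourlySeries:
    """Contiguous hourly feature series for one participant.

    ``data`` columns: ``t`` (consecutive hour index), ``hour_of_day``
    (0-23, end-of-bin label, participant-local), ``X`` (mean accel
    magnitude, NaN = missing), ``Y`` (screen-on count), ``imputed``
    (True where X was filled in downstream).
    """

    participant_id: str
    data: pd.DataFrame
    start_hour_epoch: int | None = None  # local epoch-hour of the first bin

    def __post_init__(self) -> None:
        required = {"t", "hour_of_day", "X", "Y", "imputed"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"HourlySeries data missing columns {sorted(missing)}")
        t = self.data["t"].to_numpy()
        if len(t) and not np.array_equal(t, np.arange(t[0], t[0] + len(t))):
            raise ValueError("hour index t must be consecutive integers")
        y = self.data["Y"].to_numpy()
        if np.any(y < 0):
            raise ValueError("screen-on counts must be non-negative")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> np.ndarray:
        """True where X is missing or was imputed (i.e. not directly observed)."""
        return (self.data["X"].isna() | self.data["imputed"]).to_numpy()

    def copy(self) -> "HourlySeries":
        return replace(self, data=self.data.copy())


def _magnitude(df: pd.DataFrame, dialect: CsvDialect) -> np.ndarray:
    cols = [dialect.x_col, dialect.y_col, dialect.z_col]
    arr = df[cols].to_numpy(dtype=float)
    return np.sqrt(np.sum(arr * arr, axis=1))


def _epoch_hours(ts: pd.Series, dialect: CsvDialect, tz_offset_hours: float) -> np.ndarray:
    """Convert epoch timestamps to fractional participant-local epoch hours."""
    scale = {"ms": 3_600_000.0, "s": 3600.0}[dialect.timestamp_unit]
    vals = pd.to_numeric(ts, errors="coerce").to_numpy(dtype=float)
    return vals / scale + tz_offset_hours


def bin_hourly(
    accel: pd.DataFrame | None,
    screens: pd.DataFrame | None,
    participant_id: str = "p",
    hour_range: tuple[int, int] | None = None,
    tz_offset_hours: float = 0.0,
    dialect: CsvDialect = CsvDialect(),
) -> HourlySeries:
    """Bin raw accelerometer samples and screen events onto the hourly grid.

    Parameters
    ----------
    accel, screens
        Raw streams in the given CSV dialect; either may be empty.
    hour_range
        Half-open ``(start, end)`` span of local epoch-hours to emit.  When
        omitted it is inferred as the smallest span covering all samples.
    tz_offset_hours
        Offset added to UTC timestamps to obtain participant-local time.

    Rows with non-finite timestamps or accelerations are dropped and counted
    in the log rather than raising.
    """
    accel = accel if accel is not None else pd.DataFrame(
        columns=[dialect.timestamp_col, dialect.x_col, dialect.y_col, dialect.z_col]
    )
    screens = screens if screens is not None else pd.DataFrame(columns=[dialect.timestamp_col])

    accel_hours = _epoch_hours(accel[dialect.timestamp_col], dialect, tz_offset_hours) if len(accel) else np.empty(0)
    mags = _magnitude(accel, dialect) if len(accel) else np.empty(0)
    ok = np.isfinite(accel_hours) & np.isfinite(mags)
    n_rejected = int((~ok).sum())
    accel_hours, mags = accel_hours[ok], mags[ok]

    screen_hours = _epoch_hours(screens[dialect.timestamp_col], dialect, tz_offset_hours) if len(screens) else np.empty(0)
    ok_s = np.isfinite(screen_hours)
    n_rejected += int((~ok_s).sum())
    screen_hours = screen_hours[ok_s]
    if n_rejected:
        logger.warning("bin_hourly(%s): rejected %d malformed rows", participant_id, n_rejected)

    if hour_range is None:
        all_h = np.concatenate([accel_hours, screen_hours])
        if len(all_h) == 0:
            raise ValueError("cannot infer hour range from empty streams")
        hour_range = (int(np.floor(all_h.min())), int(np.floor(all_h.max())) + 1)
    start, end = hour_range
    if end <= start:
        raise ValueError(f"empty hour range {hour_range}")
    n = end - start

    accel_bin = np.floor(accel_hours).astype(int) - start
    in_range = (accel_bin >= 0) & (accel_bin < n)
    x_sum = np.bincount(accel_bin[in_range], weights=mags[in_range], minlength=n)
    x_cnt = np.bincount(accel_bin[in_range], minlength=n)
    with np.errstate(invalid="ignore"):
        x = np.where(x_cnt > 0, x_sum / np.maximum(x_cnt, 1), np.nan)

    screen_bin = np.floor(screen_hours).astype(int) - start
    in_range_s = (screen_bin >= 0) & (screen_bin < n)
    y = np.bincount(screen_bin[in_range_s], minlength=n).astype(int)

    data = pd.DataFrame(
        {
            "t": np.arange(n),
            # bin [h, h+1) carries the label of the hour at its end
            "hour_of_day": (np.arange(start, end) + 1) % HOURS_PER_DAY,
            "X": x,
            "Y": y,
            "imputed": False,
        }
    )
    return HourlySeries(participant_id=participant_id, data=data, start_hour_epoch=start)


# ---------------------------------------------------------------------------
# Self-report cleaning
# ---------------------------------------------------------------------------


def _in_bed_window(bed: float) -> bool:
    axis = bed + HOURS_PER_DAY if bed < 12.0 else bed
    return BED_WINDOW[0] <= axis < BED_WINDOW[1]


def _in_wake_window(wake: float) -> bool:
    return WAKE_WINDOW[0] <= wake < WAKE_WINDOW[1]


def _implied_duration(bed: float, wake: float) -> float:
    return (wake - bed) % HOURS_PER_DAY


def correct_selfreport_times(bed: float, wake: float) -> tuple[float, float]:
    """Undo AM/PM slips in self-reported bed and wake clock times.

    A reported time is corrected (shifted by 12 h) only when it falls
    outside its plausible window — bedtimes 5 PM-4 AM, wake times
    4 AM-3 PM — *and* the implied sleep duration is unrealistic
    (< 1 h or > 16 h), *and* the 12 h flip actually repairs both
    conditions.  The function is total and idempotent.
    """
    for v, name in ((bed, "bed"), (wake, "wake")):
        if not (0.0 <= v < 24.0):
            raise ValueError(f"{name} time must be a clock hour in [0, 24), got {v}")

    def realistic(b: float, w: float) -> bool:
        lo, hi = REALISTIC_SLEEP_HOURS
        return lo <= _implied_duration(b, w) <= hi

    if realistic(bed, wake):
        return bed, wake

    cand_bed = bed if _in_bed_window(bed) else (bed + 12.0) % 24.0
    cand_wake = wake if _in_wake_window(wake) else (wake + 12.0) % 24.0
    # try flipping the offending value(s); keep a candidate only if it repairs
    for b, w in ((cand_bed, wake), (bed, cand_wake), (cand_bed, cand_wake)):
        if (b, w) != (bed, wake) and _in_bed_window(b) and _in_wake_window(w) and realistic(b, w):
            return b, w
    return bed, wake


def bed_time_axis(bed: float) -> float:
    """Map a bedtime clock hour onto a continuous axis: post-midnight times get +24 h."""
    return bed + HOURS_PER_DAY if bed < 12.0 else bed


def summarize_ema(responses: Sequence[EmaResponse]) -> EmaSummary:
    """Aggregate daily EMA responses into the per-participant summary.

    Bed times are mapped to a continuous axis (post-midnight +24 h) before
    taking the SD; wake times use the raw clock axis.  SDs use n-1 in the
    denominator and need at least two responses; with fewer, the field is
    left missing rather than raising.
    """
    sleep = [r.sleep_hours for r in responses if r.sleep_hours is not None]
    moods = [r.mood for r in responses if r.mood is not None]
    beds = [bed_time_axis(r.bed_time) for r in responses if r.bed_time is not None]
    wakes = [r.wake_time for r in responses if r.wake_time is not None]

    out = EmaSummary(n_responses=len(responses))
    if sleep:
        out.mean_sleep_hours = float(np.mean(sleep))
    if moods:
        out.mean_mood = float(np.mean(moods))
    if len(beds) >= 2:
        out.sd_bed_time_hours = float(np.std(beds, ddof=1))
    if len(wakes) >= 2:
        out.sd_wake_time_hours = float(np.std(wakes, ddof=1))
    return out


# ---------------------------------------------------------------------------
# Tidy CSV round trip
# ---------------------------------------------------------------------------


def write_hourly_csv(series: HourlySeries, path: str | Path) -> None:
    df = series.data.copy()
    df.insert(0, "participant_id", series.participant_id)
    df["X_missing"] = df["X"].isna()
    if series.start_hour_epoch is not None:
        df["hour_start_epoch"] = series.start_hour_epoch + df["t"]
    df.to_csv(path, index=False)


def read_hourly_csv(path: str | Path) -> HourlySeries:
    df = pd.read_csv(path)
    pid = str(df["participant_id"].iloc[0]) if len(df) else "p"
    start = int(df["hour_start_epoch"].iloc[0]) if "hour_start_epoch" in df.columns and len(df) else None
    keep = [c for c in ["t", "hour_of_day", "X", "Y", "imputed", "dormant"] if c in df.columns]
    data = df[keep].copy()
    data["imputed"] = data["imputed"].astype(bool)
    data["Y"] = data["Y"].astype(int)
    return HourlySeries(participant_id=pid, data=data.reset_index(drop=True), start_hour_epoch=start)


def read_sensor_csvs(paths: Iterable[str | Path]) -> pd.DataFrame:
    """Concatenate a participant's raw CSV chunks (Beiwe writes one file per hour)."""
    frames = [pd.read_csv(p) for p in paths]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
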