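"""Ingest: raw movement counts -> nightly activity -> analysis panel.

Raw data are per-animal, minute-resolution movement counts from infrared
sensors.  Because rats are nocturnal, "daily activity" is defined as the
cumulative number of movements during the night window 18:00-06:00; the
window is half-open ``[18:00, 06:00)`` and a night is labelled by the
calendar date on which it *starts*.  Nightly totals are log10-transformed
and assembled into a tidy panel with one row per (animal, day), the day
index taken relative to the irradiation date (day 0 = irradiation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, time, datetime, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "MovementCountSeries",
    "read_movement_counts",
    "write_movement_counts",
    "nightly_activity",
    "to_log_activity",
    "assemble_panel",
    "validate_panel",
    "read_panel",
    "write_panel",
    "PANEL_COLUMNS",
]

PANEL_COLUMNS = ("animal_id", "dose_gy", "day", "log_activity")

NIGHT_START = time(18, 0)
NIGHT_END = time(6, 0)


@dataclass
class MovementCountSeries:
    """Per-animal time series of movement counts at fixed resolution.

    ``timestamps`` must be strictly increasing with uniform spacing and
    ``counts`` non-negative integers (movements per interval).
    """

    animal_id: str
    timestamps: pd.DatetimeIndex
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.counts = np.asarray(self.counts)
        if len(self.timestamps) != len(self.counts):
            raise ValueError(
                f"animal {self.animal_id}: {len(self.timestamps)} timestamps "
                f"but {len(self.counts)} counts"
            )
        if len(self.timestamps) == 0:
            raise ValueError(f"animal {self.animal_id}: empty series")
        diffs = np.diff(self.timestamps.asi8)
        if len(diffs) and not np.all(diffs > 0):
            bad = int(np.argmax(diffs <= 0)) + 1
            raise ValueError(
                f"animal {self.animal_id}: timestamps not strictly increasing "
                f"at position {bad} ({self.timestamps[bad]})"
            )
        if len(diffs) and not np.all(diffs == diffs[0]):
            bad = int(np.argmax(diffs != diffs[0])) + 1
            raise ValueError(
                f"animal {self.animal_id}: non-uniform timestamp spacing at "
                f"position {bad} ({self.timestamps[bad]})"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts, dtype=float)
            if not np.all(np.isfinite(as_int)) or np.any(as_int != np.round(as_int)):
                raise ValueError(
                    f"animal {self.animal_id}: counts must be integer-valued"
                )
            self.counts = as_int.astype(np.int64)
        if np.any(self.counts < 0):
            bad = int(np.argmax(self.counts < 0))
            raise ValueError(
                f"animal {self.animal_id}: negative count at position {bad} "
                f"({self.timestamps[bad]})"
            )

    @property
    def interval(self) -> pd.Timedelta:
        if len(self.timestamps) < 2:
            return pd.Timedelta(minutes=1)
        return pd.Timedelta(self.timestamps[1] - self.timestamps[0])

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MovementCountSeries)
            and self.animal_id == other.animal_id
            and self.timestamps.equals(other.timestamps)
            and np.array_equal(self.counts, other.counts)
        )


def read_movement_counts(
    path,
    animal_col: str = "animal_id",
    time_col: str = "timestamp",
    count_col: str = "count",
    timestamp_format: str | None = None,
    sep: str = ",",
    decimal: str = ".",
) -> list[MovementCountSeries]:
    """Read a raw-counts CSV into one :class:`MovementCountSeries` per animal.

    The file holds long-format rows ``animal_id, timestamp, count`` (ISO
    8601 timestamps unless ``timestamp_format`` is given).  Validation
    errors name the offending file row (1-based, excluding the header).
    """
    df = pd.read_csv(path, sep=sep, decimal=decimal)
    missing = [c for c in (animal_col, time_col, count_col) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    try:
        ts = pd.to_datetime(df[time_col], format=timestamp_format)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable timestamp ({exc})") from exc
    counts = pd.to_numeric(df[count_col], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        row = int(np.argmax(bad.to_numpy())) + 1
        raise ValueError(
            f"{path}: invalid count {df[count_col].iloc[row - 1]!r} at data "
            f"row {row} (animal {df[animal_col].iloc[row - 1]!r})"
        )
    dup = df.duplicated(subset=[animal_col, time_col])
    if dup.any():
        row = int(np.argmax(dup.to_numpy())) + 1
        raise ValueError(
            f"{path}: duplicated timestamp at data row {row} "
            f"(animal {df[animal_col].iloc[row - 1]!r}, "
            f"time {df[time_col].iloc[row - 1]!r})"
        )
    out = []
    work = df.assign(_ts=ts, _ct=counts.astype(np.int64))
    for animal, grp in work.groupby(animal_col, sort=True):
        grp = grp.sort_values("_ts")
        out.append(
            MovementCountSeries(
                animal_id=str(animal),
                timestamps=pd.DatetimeIndex(grp["_ts"]),
                counts=grp["_ct"].to_numpy(),
            )
        )
    return out


def write_movement_counts(series_list, path, sep: str = ",") -> None:
    """Write series to the long CSV dialect read by :func:`read_movement_counts`."""
    frames = [
        pd.DataFrame(
            {
                "animal_id": s.animal_id,
                "timestamp": s.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
                "count": s.counts,
            }
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def _night_of(ts: pd.Timestamp, night_start: time, night_end: time) -> date | None:
    """Calendar date of the night a timestamp belongs to, or None (daytime).

    The window crosses midnight: [night_start, 24:00) belongs to the night
    starting that date, [00:00, night_end) to the night starting the
    previous date.
    """
    t = ts.time()
    if t >= night_start:
        return ts.date()
    if t < night_end:
        return (ts - pd.Timedelta(days=1)).date()
    return None


def nightly_activity(
    series: MovementCountSeries,
    night_start: time = NIGHT_START,
    night_end: time = NIGHT_END,
) -> pd.DataFrame:
    """Total movements per night window, night labelled by its start date.

    Returns a frame with columns ``night`` (date), ``total`` (int),
    ``n_intervals`` and ``complete``.  A night is complete when every
    interval of the window is present in the series; incomplete nights are
    flagged so the caller can exclude them.  A series too short to contain
    one full window yields an empty frame with a warning.
    """
    if night_start <= night_end:
        raise ValueError(
            "night window must cross midnight (night_start > night_end as "
            f"clock times); got {night_start}-{night_end}"
        )
    step = series.interval
    window_minutes = (
        (24 * 60 - (night_start.hour * 60 + night_start.minute))
        + night_end.hour * 60
        + night_end.minute
    )
    expected = int(round(window_minutes * 60 / step.total_seconds()))

    nights = [_night_of(ts, night_start, night_end) for ts in series.timestamps]
    mask = np.array([n is not None for n in nights])
    if not mask.any():
        warnings.warn(
            f"animal {series.animal_id}: series contains no night-window "
            "intervals; returning empty result"
        )
        return pd.DataFrame(columns=["night", "total", "n_intervals", "complete"])
    df = pd.DataFrame(
        {
            "night": [n for n in nights if n is not None],
            "count": series.counts[mask],
        }
    )
    agg = df.groupby("night", sort=True)["count"].agg(["sum", "size"]).reset_index()
    agg.columns = ["night", "total", "n_intervals"]
    agg["complete"] = agg["n_intervals"] == expected
    full = agg[agg["complete"]]
    if full.empty:
        warnings.warn(
            f"animal {series.animal_id}: no complete night window "
            f"({expected} intervals expected)"
        )
    if (full["total"] == 0).any():
        warnings.warn(
            f"animal {series.animal_id}: zero total movements on "
            f"{int((full['total'] == 0).sum())} night(s); these cannot be "
            "log-transformed"
        )
    return agg


def to_log_activity(totals, log_base: float = 10.0) -> np.ndarray:
    """Log-transform nightly totals (base 10 by default).

    Zero or negative totals are an error: the caller must exclude or
    impute degenerate nights explicitly.
    """
    totals = np.asarray(totals, dtype=float)
    if np.any(totals <= 0):
        bad = int(np.argmax(totals <= 0))
        raise ValueError(
            f"non-positive nightly total ({totals[bad]}) at position {bad}: "
            "exclude or impute before log transform"
        )
    return np.log(totals) / np.log(log_base)


def assemble_panel(
    nightly: dict[str, pd.DataFrame],
    dose_map: dict[str, float],
    irradiation_date: date | str,
    log_base: float = 10.0,
    drop_incomplete: bool = True,
) -> pd.DataFrame:
    """Build the analysis panel from per-animal nightly totals.

    ``nightly`` maps animal id -> frame as returned by
    :func:`nightly_activity`; ``dose_map`` maps animal id -> dose in Gy;
    ``day`` is the night's start date minus the irradiation date, so the
    night beginning on the irradiation date is day 0.  Incomplete nights
    are excluded (flagged at ingest; no rescaling is applied).  The result
    is order-invariant: rows are sorted by (animal_id, day).
    """
    if isinstance(irradiation_date, str):
        irradiation_date = date.fromisoformat(irradiation_date)
    rows = []
    for animal in sorted(nightly):
        if animal not in dose_map:
            raise ValueError(f"animal {animal!r} has no dose assigned")
        table = nightly[animal]
        if drop_incomplete and "complete" in table.columns:
            table = table[table["complete"]]
        for _, rec in table.iterrows():
            day = (rec["night"] - irradiation_date).days
            rows.append(
                {
                    "animal_id": str(animal),
                    "dose_gy": float(dose_map[animal]),
                    "day": int(day),
                    "log_activity": float(
                        to_log_activity([rec["total"]], log_base=log_base)[0]
                    ),
                }
            )
    panel = pd.DataFrame(rows, columns=list(PANEL_COLUMNS))
    return validate_panel(panel)


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise an activity panel.

    Checks the panel invariants: required columns, unique (animal, day)
    cells, a single non-negative dose per animal, finite log activities.
    Returns a copy sorted by (animal_id, day).
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel missing column(s) {missing}")
    panel = panel.loc[:, list(PANEL_COLUMNS)].copy()
    panel["animal_id"] = panel["animal_id"].astype(str)
    panel["dose_gy"] = panel["dose_gy"].astype(float)
    panel["day"] = panel["day"].astype(int)
    panel["log_activity"] = panel["log_activity"].astype(float)
    if panel.empty:
        raise ValueError("panel is empty")
    dup = panel.duplicated(subset=["animal_id", "day"])
    if dup.any():
        rec = panel[dup].iloc[0]
        raise ValueError(
            f"duplicate cell: animal {rec['animal_id']!r}, day {rec['day']}"
        )
    doses = panel.groupby("animal_id")["dose_gy"].nunique()
    if (doses > 1).any():
        raise ValueError(
            f"animal {doses.idxmax()!r} has more than one dose"
        )
    if (panel["dose_gy"] < 0).any():
        raise ValueError("negative dose in panel")
    if not np.all(np.isfinite(panel["log_activity"])):
        raise ValueError("non-finite log_activity in panel")
    return panel.sort_values(["animal_id", "day"], ignore_index=True)


def read_panel(path, sep: str = ",", decimal: str = ".") -> pd.DataFrame:
    """Read a panel CSV (columns animal_id, dose_gy, day, log_activity)."""
    try:
        df = pd.read_csv(path, sep=sep, decimal=decimal)
        return validate_panel(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_panel(panel: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a panel to the CSV dialect read by :func:`read_panel`."""
    validate_panel(panel).to_csv(path, sep=sep, index=False)
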