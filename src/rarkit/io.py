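"""Reading, validating and day-aligning epoch-level actigraphy recordings.

An Actiwatch-class device exports one row per epoch (30 s or 60 s): a local
timestamp and a nonnegative integer activity count.  Analysis operates on
midnight-aligned full days, so recordings are trimmed: epochs before the first
midnight at or after the start, and at or after the last midnight within the
recording, are discarded, leaving an integer number of full days.

Timestamps are naive local clock time; daylight-saving transitions are not
modeled (a 23/25-hour civil day shows up as irregular spacing and is
rejected).  Missing or negative counts are hard errors — the metrics below
assume gap-free series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Config, IOConfig

_TIMESTAMP_FMT = "%Y-%m-%d %H:%M:%S"


@dataclass
class EpochSeries:
    """A subject's uniformly sampled activity-count series."""

    subject_id: str
    start: pd.Timestamp
    epoch_seconds: int
    counts: np.ndarray  # 1-D nonnegative int array

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.counts = np.asarray(self.counts)
        if self.epoch_seconds not in (30, 60):
            raise ValueError(f"epoch_seconds must be 30 or 60, got {self.epoch_seconds}")
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = np.asarray(self.counts, dtype=float)
            if np.any(~np.isfinite(as_float)) or np.any(as_float != np.round(as_float)):
                raise ValueError("invalid counts: non-integer or missing values")
            self.counts = as_float.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("invalid counts: negative values")

    @property
    def n_epochs(self) -> int:
        return int(self.counts.size)

    @property
    def end(self) -> pd.Timestamp:
        """Timestamp one epoch past the last recorded epoch."""
        return self.start + pd.Timedelta(seconds=self.epoch_seconds * self.n_epochs)


@dataclass
class DayMatrix:
    """Midnight-to-midnight day-aligned counts, one row per retained day."""

    subject_id: str
    epoch_seconds: int
    values: np.ndarray  # days x (86400 // epoch_seconds)
    start: pd.Timestamp  # first retained midnight

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.start = pd.Timestamp(self.start)
        per_day = 86400 // self.epoch_seconds
        if self.values.ndim != 2 or self.values.shape[1] != per_day:
            raise ValueError(
                f"values must be days x {per_day} for {self.epoch_seconds}s epochs"
            )
        if self.values.shape[0] < 1:
            raise ValueError("recording too short: 0 retained days")
        if np.any(self.values < 0):
            raise ValueError("invalid counts: negative values")

    @property
    def days(self) -> int:
        return int(self.values.shape[0])

    @property
    def epochs_per_day(self) -> int:
        return 86400 // self.epoch_seconds

    def flatten(self) -> np.ndarray:
        """Concatenated chronological epoch series of the retained days."""
        return self.values.reshape(-1)

    def to_csv(self, path: str | Path) -> None:
        """One row per day, for inspection."""
        pd.DataFrame(self.values).to_csv(path, index=False, header=False)


@dataclass
class CohortManifest:
    """Maps subject IDs to epoch files and group labels."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)  # (id, path, group)

    def __post_init__(self) -> None:
        ids = [sid for sid, _, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id in manifest")

    @classmethod
    def read_csv(cls, path: str | Path) -> "CohortManifest":
        df = pd.read_csv(path, dtype=str)
        required = {"subject_id", "path", "group"}
        if not required.issubset(df.columns):
            raise ValueError(f"manifest must have columns {sorted(required)}")
        base = Path(path).parent
        entries = []
        for row in df.itertuples(index=False):
            p = Path(row.path)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"manifest entry {row.subject_id}: {p} not found")
            entries.append((row.subject_id, str(p), row.group))
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.entries, columns=["subject_id", "path", "group"]).to_csv(
            path, index=False
        )


def read_epoch_csv(
    path: str | Path,
    epoch_seconds_hint: int | None = None,
    subject_id: str | None = None,
    config: Config | None = None,
) -> EpochSeries:
    """Parse a per-subject epoch CSV into an :class:`EpochSeries`.

    The file must carry a header row with a timestamp column and a counts
    column (names configurable through :class:`IOConfig`).  Epoch length is
    inferred from consecutive timestamp deltas unless a hint is given; any
    irregular spacing is an error.
    """
    iocfg: IOConfig = (config or Config()).io
    df = pd.read_csv(path)
    for col in (iocfg.timestamp_column, iocfg.counts_column):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    ts = pd.to_datetime(df[iocfg.timestamp_column], format="mixed")
    counts = df[iocfg.counts_column].to_numpy()
    if pd.isna(counts.astype(object)).any():
        raise ValueError("invalid counts: missing values")
    if len(ts) >= 2:
        deltas = np.diff(ts.to_numpy()).astype("timedelta64[s]").astype(int)
        uniq = np.unique(deltas)
        if uniq.size != 1:
            raise ValueError(f"irregular epochs: spacings {uniq.tolist()} s in {path}")
        epoch_seconds = int(uniq[0])
        if epoch_seconds_hint is not None and epoch_seconds != epoch_seconds_hint:
            raise ValueError(
                f"irregular epochs: spacing {epoch_seconds}s != hint {epoch_seconds_hint}s"
            )
    elif epoch_seconds_hint is not None:
        epoch_seconds = epoch_seconds_hint
    else:
        raise ValueError("ambiguous epoch inference: single row, pass epoch_seconds_hint")
    if epoch_seconds not in (30, 60):
        raise ValueError(f"irregular epochs: unsupported spacing {epoch_seconds}s")
    sid = subject_id if subject_id is not None else Path(path).stem
    return EpochSeries(sid, ts.iloc[0], epoch_seconds, counts)


def write_epoch_csv(series: EpochSeries, path: str | Path, config: Config | None = None) -> None:
    """Write the CSV dialect :func:`read_epoch_csv` reads (round-trip safe)."""
    iocfg: IOConfig = (config or Config()).io
    ts = pd.date_range(
        series.start, periods=series.n_epochs, freq=f"{series.epoch_seconds}s"
    )
    df = pd.DataFrame(
        {
            iocfg.timestamp_column: ts.strftime(_TIMESTAMP_FMT),
            iocfg.counts_column: series.counts,
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


def trim_to_full_days(series: EpochSeries) -> DayMatrix:
    """Discard partial-day tails, keeping midnight-to-midnight full days."""
    eps = series.epoch_seconds
    per_day = 86400 // eps
    start, end = series.start, series.end
    first_mid = start.normalize()
    if first_mid < start:
        first_mid += pd.Timedelta(days=1)
    last_mid = end.normalize()
    n_days = (last_mid - first_mid).days
    if n_days < 1:
        raise ValueError("recording too short: fewer than 1 complete day")
    offset_s = (first_mid - start).total_seconds()
    if offset_s % eps:
        raise ValueError("irregular epochs: start not aligned to epoch grid")
    i0 = int(offset_s) // eps
    values = series.counts[i0 : i0 + n_days * per_day].reshape(n_days, per_day)
    return DayMatrix(series.subject_id, eps, values, first_mid)


def hourly_totals(dm: DayMatrix) -> np.ndarray:
    """Per-clock-hour count sums, chronological, length 24 * days."""
    per_hour = 3600 // dm.epoch_seconds
    return dm.values.reshape(dm.days * 24, per_hour).sum(axis=1)
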