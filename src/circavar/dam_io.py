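"""Reading, writing and annotation of DAM2-style activity monitor files.

The DAM2 dialect used here is the common DAMSystem3 text layout: 42
tab-separated columns per row — record index, date ("D Mon YY"), time
("HH:MM:SS"), a status code (1 = valid), five pass-through auxiliary
columns, a light-sensor flag, and 32 per-channel beam-crossing counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

N_CHANNELS = 32
N_COLUMNS = 42

_MONTHS = [
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
]


class DamParseError(ValueError):
    """Raised when a monitor file violates the DAM2 dialect."""


class CoverageError(ValueError):
    """Raised when a series does not span the requested time window."""


@dataclass(frozen=True)
class PhotoRegime:
    """Light schedule of an experiment: LD entrainment followed by DD.

    ``lights_on`` / ``lights_off`` are clock hours in [0, 24).  Analysis
    day counts default to the 3 LD + 5 DD days used throughout the
    pipeline and must not exceed the recorded day counts.
    """

    lights_on: float
    lights_off: float
    n_ld_days: int
    n_dd_days: int
    ld_analysis_days: int = 3
    dd_analysis_days: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.lights_on < 24 and 0 <= self.lights_off < 24):
            raise ValueError("lights_on and lights_off must lie in [0, 24)")
        if self.lights_on == self.lights_off:
            raise ValueError("lights_on must differ from lights_off")
        if self.ld_analysis_days > self.n_ld_days:
            raise ValueError("ld_analysis_days exceeds recorded LD days")
        if self.dd_analysis_days > self.n_dd_days:
            raise ValueError("dd_analysis_days exceeds recorded DD days")

    @property
    def photoperiod_hours(self) -> float:
        return (self.lights_off - self.lights_on) % 24


@dataclass
class ActivitySeries:
    """One fly's binned beam-crossing counts with light-regime annotation.

    ``zt`` is Zeitgeber time in LD and circadian time (projected from the
    last actual lights-on) in DD; both live in [0, 24).  ``segment`` is
    "LD" or "DD" per bin; ``light`` is "L" or "D".
    """

    fly_id: str
    genotype: str
    bin_width: int  # minutes
    t0: datetime
    counts: np.ndarray
    light: np.ndarray | None = None
    zt: np.ndarray | None = None
    segment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def times(self) -> np.ndarray:
        """Bin start times as hours since t0."""
        return np.arange(len(self.counts)) * self.bin_width / 60.0

    def annotated(self) -> bool:
        return self.zt is not None

    def day_slice(self, segment: str, day: int) -> slice:
        """Bin-index slice of the day-th (1-based) 24-h cycle of a segment.

        Days are counted from the first bin belonging to the segment.
        """
        if self.segment is None:
            raise ValueError("series is not annotated")
        idx = np.flatnonzero(self.segment == segment)
        if idx.size == 0:
            raise CoverageError(f"series has no {segment} bins")
        per_day = (24 * 60) // self.bin_width
        start = idx[0] + (day - 1) * per_day
        stop = start + per_day
        if stop > idx[-1] + 1:
            raise CoverageError(
                f"{segment} day {day} not fully recorded (needs bins "
                f"{start}..{stop - 1}, segment ends at {idx[-1]})"
            )
        return slice(start, stop)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-bin table (fly_id, genotype, t, zt, segment, light, count)."""
        return pd.DataFrame(
            {
                "fly_id": self.fly_id,
                "genotype": self.genotype,
                "t": self.times,
                "zt": self.zt if self.zt is not None else np.nan,
                "segment": self.segment if self.segment is not None else "",
                "light": self.light if self.light is not None else "",
                "count": self.counts,
            }
        )


@dataclass
class MonitorFile:
    """Parsed DAM2 monitor file: timestamps, status, and a (T, 32) count matrix."""

    timestamps: list[datetime]
    status: np.ndarray
    light_sensor: np.ndarray
    counts: np.ndarray  # shape (T, 32)
    aux: np.ndarray = field(default=None)  # pass-through columns 5-9

    def __post_init__(self) -> None:
        if self.aux is None:
            self.aux = np.zeros((len(self.timestamps), 5), dtype=int)

    @property
    def n_rows(self) -> int:
        return len(self.timestamps)

    @property
    def minutes_per_row(self) -> float:
        if self.n_rows < 2:
            return 1.0
        delta = self.timestamps[1] - self.timestamps[0]
        return delta.total_seconds() / 60.0


def _format_date(ts: datetime) -> str:
    return f"{ts.day} {_MONTHS[ts.month - 1]} {ts.year % 100:02d}"


def _parse_timestamp(date_str: str, time_str: str, line_no: int) -> datetime:
    try:
        day_s, mon_s, yy_s = date_str.split()
        month = _MONTHS.index(mon_s) + 1
        hh, mm, ss = (int(x) for x in time_str.split(":"))
        return datetime(2000 + int(yy_s), month, int(day_s), hh, mm, ss)
    except (ValueError, IndexError) as exc:
        raise DamParseError(f"line {line_no}: bad timestamp {date_str!r} {time_str!r}") from exc


def read_dam_monitor(path) -> MonitorFile:
    """Parse a DAM2 monitor file.

    Rows with a status code other than 1 are kept and flagged via the
    ``status`` array, not dropped.  Raises :class:`DamParseError` naming
    the offending line for malformed rows and a non-monotone timestamp
    ordering error.
    """
    timestamps: list[datetime] = []
    status, light, aux, counts = [], [], [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != N_COLUMNS:
                raise DamParseError(
                    f"line {line_no}: expected {N_COLUMNS} tab-separated "
                    f"columns, found {len(fields)}"
                )
            timestamps.append(_parse_timestamp(fields[1], fields[2], line_no))
            try:
                status.append(int(fields[3]))
                aux.append([int(x) for x in fields[4:9]])
                light.append(int(fields[9]))
                row = [int(x) for x in fields[10:]]
            except ValueError as exc:
                raise DamParseError(f"line {line_no}: non-integer field") from exc
            if any(c < 0 for c in row):
                raise DamParseError(f"line {line_no}: negative channel count")
            counts.append(row)
    for i in range(1, len(timestamps)):
        if timestamps[i] <= timestamps[i - 1]:
            raise DamParseError(
                f"non-monotone timestamps at row {i + 1}: "
                f"{timestamps[i]} after {timestamps[i - 1]}"
            )
    return MonitorFile(
        timestamps=timestamps,
        status=np.array(status, dtype=int),
        light_sensor=np.array(light, dtype=int),
        counts=np.array(counts, dtype=int).reshape(len(timestamps), N_CHANNELS),
        aux=np.array(aux, dtype=int).reshape(len(timestamps), 5),
    )


def write_dam_monitor(series_set: list[ActivitySeries], path,
                      light_sensor: np.ndarray | None = None) -> None:
    """Write up to 32 series sharing a time base as one DAM2 file.

    Channels beyond the provided series are zero-filled; the row cadence
    equals the series' bin width (per-minute series round-trip exactly).
    """
    if len(series_set) > N_CHANNELS:
        raise ValueError(f"at most {N_CHANNELS} series per monitor file")
    if not series_set:
        raise ValueError("no series to write")
    ref = series_set[0]
    for s in series_set[1:]:
        if s.bin_width != ref.bin_width or s.t0 != ref.t0 or len(s) != len(ref):
            raise ValueError("all series in a monitor file must share a time base")
    n = len(ref)
    matrix = np.zeros((n, N_CHANNELS), dtype=int)
    for ch, s in enumerate(series_set):
        matrix[:, ch] = s.counts
    if light_sensor is None:
        if ref.light is not None:
            light_sensor = (ref.light == "L").astype(int)
        else:
            light_sensor = np.zeros(n, dtype=int)
    step = timedelta(minutes=ref.bin_width)
    with open(path, "w") as fh:
        for i in range(n):
            ts = ref.t0 + i * step
            row = [
                str(i + 1),
                _format_date(ts),
                ts.strftime("%H:%M:%S"),
                "1", "0", "0", "0", "0", "0",
                str(int(light_sensor[i])),
            ] + [str(int(c)) for c in matrix[i]]
            fh.write("\t".join(row) + "\n")


def bin_counts(monitor: MonitorFile, channel: int, bin_width: int,
               fly_id: str | None = None, genotype: str = "",
               fill_gaps: bool = False) -> ActivitySeries:
    """Aggregate one channel of raw per-row counts into fixed-width bins.

    ``bin_width`` (minutes) must divide 60 or be a multiple of 60 that
    divides 24 h.  Total counts are conserved; a trailing partial bin is
    dropped.  Missing rows inside the record raise unless ``fill_gaps``
    zero-fills them.
    """
    if bin_width <= 0 or (60 % bin_width != 0 and bin_width % 60 != 0):
        raise ValueError("bin_width must divide 60 min or be a whole number of hours")
    if not 1 <= channel <= N_CHANNELS:
        raise ValueError(f"channel must be in 1..{N_CHANNELS}")
    raw = monitor.counts[:, channel - 1]
    step = monitor.minutes_per_row
    expected = [monitor.timestamps[0] + timedelta(minutes=step * i)
                for i in range(int(round(
                    (monitor.timestamps[-1] - monitor.timestamps[0]).total_seconds()
                    / 60.0 / step)) + 1)]
    if len(expected) != monitor.n_rows:
        if not fill_gaps:
            raise ValueError(
                f"record has gaps: expected {len(expected)} rows at "
                f"{step:g}-min cadence, found {monitor.n_rows}; "
                "pass fill_gaps=True to zero-fill"
            )
        lookup = {ts: raw[i] for i, ts in enumerate(monitor.timestamps)}
        raw = np.array([lookup.get(ts, 0) for ts in expected], dtype=int)
    rows_per_bin = bin_width / step
    if rows_per_bin < 1 or rows_per_bin != int(rows_per_bin):
        raise ValueError(
            f"bin_width {bin_width} min is not a multiple of the "
            f"{step:g}-min row cadence"
        )
    rows_per_bin = int(rows_per_bin)
    n_bins = len(raw) // rows_per_bin
    if n_bins < 1:
        raise ValueError("recording shorter than one bin")
    binned = raw[: n_bins * rows_per_bin].reshape(n_bins, rows_per_bin).sum(axis=1)
    return ActivitySeries(
        fly_id=fly_id if fly_id is not None else f"ch{channel}",
        genotype=genotype,
        bin_width=bin_width,
        t0=monitor.timestamps[0],
        counts=binned,
    )


def annotate_regime(series: ActivitySeries, regime: PhotoRegime) -> ActivitySeries:
    """Populate light / zt / segment per bin from a photoperiod description.

    zt = 0 at lights-on; in DD the same 24-h clock is projected forward
    from the last actual lights-on.  The LD→DD boundary is the first
    projected lights-on after the final LD day.  The recording is assumed
    to start within 12 h either side of the lights-on that opens LD day 1.
    """
    hours = series.times  # hours since t0
    t0_clock = series.t0.hour + series.t0.minute / 60.0 + series.t0.second / 3600.0
    # signed offset of t0 from the lights-on that starts LD day 1
    since_on0 = (t0_clock - regime.lights_on) % 24
    if since_on0 > 12:
        since_on0 -= 24
    ld_span = regime.n_ld_days * 24.0
    needed = ld_span + regime.n_dd_days * 24.0 - since_on0
    if hours[-1] + series.bin_width / 60.0 < needed - 1e-9:
        raise CoverageError(
            f"series spans {hours[-1] + series.bin_width / 60.0:.1f} h after t0 "
            f"but the regime requires {needed:.1f} h"
        )
    t_cycle = since_on0 + hours  # hours since lights-on of LD day 1
    zt = t_cycle % 24
    segment = np.where(t_cycle < ld_span, "LD", "DD")
    photo = regime.photoperiod_hours
    light = np.where((segment == "LD") & (zt < photo), "L", "D")
    return replace(series, zt=zt, light=light, segment=segment)


def series_set_to_frame(series_set: list[ActivitySeries]) -> pd.DataFrame:
    return pd.concat([s.to_frame() for s in series_set], ignore_index=True)
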