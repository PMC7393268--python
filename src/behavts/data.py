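"""Temporal data types for behavioral time series and the conversions among them.

Three representations cover the data produced in behavioral studies:

``EventSequence``
    annotation-style records (onset, offset, code) on a real time axis —
    the natural output of human video/audio coding;
``NominalTimeSeries``
    a regularly sampled stream of integer category codes (0 = background),
    the input to cross-recurrence analysis;
``BinarySpikeTrain``
    a 0/1 stream marking event *onsets* (point-process data), the input to
    burstiness and Granger-causality analysis.

Conventions (applied uniformly): samples are 0-based; sample ``i`` covers the
half-open interval ``[i/rate, (i+1)/rate)``; a sample's category is decided at
its midpoint. These choices make the event↔timeseries round trip an identity
for sample-aligned, non-overlapping events.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

#: onsets at or above this many seconds are treated as Unix epoch timestamps
#: and shifted to session-relative time (sensor exports).
EPOCH_THRESHOLD = 1e8

_HMS_RE = re.compile(r"^(?:(\d+):)?(\d{1,2}):(\d{1,2}(?:\.\d+)?)$")


def parse_timestamp(value) -> float:
    """Parse a timestamp to seconds.

    Accepts plain numbers (seconds, including Unix epoch seconds) and
    ``hh:mm:ss(.fff)`` / ``mm:ss`` strings.
    """
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    text = str(value).strip()
    m = _HMS_RE.match(text)
    if m:
        hours = int(m.group(1)) if m.group(1) else 0
        return hours * 3600.0 + int(m.group(2)) * 60.0 + float(m.group(3))
    try:
        return float(text)
    except ValueError as exc:
        raise InvalidInputError(f"unparseable timestamp: {value!r}") from exc


@dataclass
class EventRecord:
    """A single annotated behavior: ``[onset, offset)`` in seconds plus a code."""

    onset: float
    offset: float
    code: int | str

    def __post_init__(self):
        if not self.offset > self.onset:
            raise InvalidInputError(
                f"offset must exceed onset (got {self.onset}..{self.offset})"
            )
        if self.code is None or self.code == "":
            raise InvalidInputError("event code must be non-empty")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class EventSequence:
    """An ordered, by-default non-overlapping stream of :class:`EventRecord`."""

    records: list[EventRecord] = field(default_factory=list)
    label: str = ""
    allow_overlap: bool = False
    code_labels: dict[int, str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: (r.onset, r.offset))
        if not self.allow_overlap:
            for prev, cur in zip(self.records, self.records[1:]):
                if cur.onset < prev.offset - 1e-12:
                    raise InvalidInputError(
                        f"overlapping events at t={cur.onset:.6g} in "
                        f"sequence {self.label!r} (pass allow_overlap=True "
                        "to permit)"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def duration(self) -> float:
        """End of the last event (0 for an empty sequence)."""
        return max((r.offset for r in self.records), default=0.0)

    def codes(self) -> list:
        return sorted({r.code for r in self.records}, key=str)

    def encoded(self) -> "EventSequence":
        """Return a copy with string codes mapped to integers 1..K.

        Integer codes are passed through unchanged; the mapping is stored in
        ``code_labels``.
        """
        labels = sorted({r.code for r in self.records if isinstance(r.code, str)})
        table = {lab: i + 1 for i, lab in enumerate(labels)}
        records = [
            EventRecord(r.onset, r.offset, table.get(r.code, r.code))
            for r in self.records
        ]
        return EventSequence(
            records,
            label=self.label,
            allow_overlap=self.allow_overlap,
            code_labels={v: k for k, v in table.items()},
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.onset, r.offset, r.code) for r in self.records],
            columns=["onset", "offset", "code"],
        )


@dataclass
class NominalTimeSeries:
    """A regularly sampled stream of integer category codes (0 = background)."""

    values: np.ndarray
    rate: float
    start_time: float = 0.0
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=int)
        if self.values.ndim != 1:
            raise InvalidInputError("values must be one-dimensional")
        if not self.rate > 0:
            raise InvalidInputError("sampling rate must be positive")
        if (self.values < 0).any():
            raise InvalidInputError("category codes must be >= 0")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n(self) -> int:
        return len(self.values)

    def times(self) -> np.ndarray:
        """Left edge of every sample interval."""
        return self.start_time + np.arange(self.n) / self.rate


@dataclass
class BinarySpikeTrain:
    """A 0/1 stream where 1 marks the onset of an event within a sample."""

    values: np.ndarray
    rate: float
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=int)
        if self.values.ndim != 1:
            raise InvalidInputError("values must be one-dimensional")
        if not self.rate > 0:
            raise InvalidInputError("sampling rate must be positive")
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            raise InvalidInputError("spike train values must be 0 or 1")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_onsets(self) -> int:
        return int(self.values.sum())

    def onset_indices(self) -> np.ndarray:
        return np.flatnonzero(self.values)


@dataclass
class IntervalSet:
    """A collection of positive inter-onset intervals with summary statistics.

    The standard deviation uses the n−1 (sample) normalization.
    """

    intervals: np.ndarray
    unit: str = "seconds"

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise InvalidInputError("intervals must be one-dimensional")
        if (self.intervals <= 0).any():
            raise InvalidInputError("intervals must be strictly positive")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def n(self) -> int:
        return len(self.intervals)

    @property
    def mean(self) -> float:
        return float(np.mean(self.intervals))

    @property
    def std(self) -> float:
        return float(np.std(self.intervals, ddof=1))


# ---------------------------------------------------------------------------
# conversions


def import_annotation_table(
    rows: pd.DataFrame | Iterable[Sequence],
    column_map: Mapping[str, str | int] | None = None,
    label: str = "",
    encode_labels: bool = False,
    allow_overlap: bool = False,
) -> EventSequence:
    """Import a tabular annotation export into a clean :class:`EventSequence`.

    Parameters
    ----------
    rows
        A DataFrame, or any iterable of row tuples.
    column_map
        Maps the keys ``onset``, ``offset``, ``code`` to column names (or
        positional indices for tuple input). Defaults to the first three
        columns / the identically named columns.
    encode_labels
        Map string codes to integers 1..K via a label table stored on the
        result.

    Rows with missing fields are dropped with a logged count; rows with
    ``offset <= onset`` are excluded and counted in ``meta['dropped_invalid']``.
    Unix-epoch timestamps are shifted to session-relative seconds.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    cmap = dict(column_map or {})
    for key, default in (("onset", 0), ("offset", 1), ("code", 2)):
        if key not in cmap:
            cmap[key] = key if key in rows.columns else default
    for key, col in cmap.items():
        if col not in rows.columns:
            raise ConfigurationError(
                f"column {col!r} (mapped to {key!r}) not found in table "
                f"with columns {list(rows.columns)}"
            )

    table = rows[[cmap["onset"], cmap["offset"], cmap["code"]]].copy()
    table.columns = ["onset", "offset", "code"]
    n_total = len(table)
    table = table.replace("", np.nan).dropna()
    n_missing = n_total - len(table)
    if n_missing:
        logger.warning("dropped %d rows with missing fields", n_missing)

    records: list[EventRecord] = []
    n_invalid = 0
    for _, row in table.iterrows():
        onset = parse_timestamp(row["onset"])
        offset = parse_timestamp(row["offset"])
        if offset <= onset:
            n_invalid += 1
            continue
        records.append(EventRecord(onset, offset, row["code"]))
    if n_invalid:
        logger.warning("excluded %d rows with offset <= onset", n_invalid)

    if records and min(r.onset for r in records) >= EPOCH_THRESHOLD:
        shift = min(r.onset for r in records)
        records = [EventRecord(r.onset - shift, r.offset - shift, r.code) for r in records]
        logger.info("Unix-epoch timestamps shifted by %.0f s to session time", shift)

    seq = EventSequence(
        records,
        label=label,
        allow_overlap=allow_overlap,
        meta={"dropped_missing": n_missing, "dropped_invalid": n_invalid},
    )
    return seq.encoded() if encode_labels else seq


def _require_int_codes(seq: EventSequence):
    if any(isinstance(r.code, str) for r in seq.records):
        raise InvalidInputError(
            "string codes present; call EventSequence.encoded() first"
        )


def events_to_timeseries(
    seq: EventSequence,
    rate: float,
    duration: float | None = None,
    last_onset_wins: bool = False,
) -> NominalTimeSeries:
    """Sample an event sequence onto a regular grid of category codes.

    Sample ``i`` carries the code of the event overlapping its midpoint
    ``(i + 0.5)/rate``; background samples carry 0. Overlapping events at a
    sampled instant raise unless ``last_onset_wins`` is set, in which case the
    later-onset event takes the sample.
    """
    _require_int_codes(seq)
    if not rate > 0:
        raise InvalidInputError("rate must be positive")
    if duration is None:
        duration = seq.duration
    if duration < seq.duration:
        raise InvalidInputError("duration shorter than the last event offset")
    n = int(round(duration * rate))
    values = np.zeros(n, dtype=int)
    assigned = np.zeros(n, dtype=bool)
    for rec in seq.records:  # sorted by onset; later onsets overwrite
        i0 = max(0, math.ceil(rec.onset * rate - 0.5 - 1e-9))
        i1 = min(n, math.ceil(rec.offset * rate - 0.5 - 1e-9))
        if i1 <= i0:
            continue
        clash = assigned[i0:i1]
        if clash.any() and not last_onset_wins:
            raise InvalidInputError(
                f"events overlap at sampled instants near t={i0 / rate:.6g} s "
                "(set last_onset_wins=True to resolve)"
            )
        values[i0:i1] = rec.code
        assigned[i0:i1] = True
    return NominalTimeSeries(values, rate=rate, label=seq.label)


def timeseries_to_events(
    ts: NominalTimeSeries, background: int = 0
) -> EventSequence:
    """Run-length encode a nominal series back into events.

    Maximal runs of equal non-background code become events with half-open
    ``[start/rate, end/rate)`` extents.
    """
    v = ts.values
    records = []
    if len(v):
        change = np.flatnonzero(np.diff(v) != 0)
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [len(v)]))
        for s, e in zip(starts, ends):
            if v[s] != background:
                records.append(
                    EventRecord(
                        ts.start_time + s / ts.rate,
                        ts.start_time + e / ts.rate,
                        int(v[s]),
                    )
                )
    return EventSequence(records, label=ts.label)


def events_to_spike_train(
    seq: EventSequence,
    rate: float,
    duration: float | None = None,
) -> BinarySpikeTrain:
    """Mark each event *onset* with a 1 on a regular grid.

    Two onsets falling into the same sample collapse to a single 1; the number
    of collisions is logged and stored in the result's label-free ``meta`` —
    use the returned train's spike count vs. ``len(seq)`` to detect collapse.
    """
    if not rate > 0:
        raise InvalidInputError("rate must be positive")
    if duration is None:
        duration = seq.duration
    values = np.zeros(int(math.ceil(duration * rate - 1e-9)), dtype=int)
    collisions = 0
    for rec in seq.records:
        i = int(math.floor(rec.onset * rate + 1e-9))
        if i >= len(values):
            values = np.append(values, np.zeros(i - len(values) + 1, dtype=int))
        if values[i]:
            collisions += 1
        values[i] = 1
    if collisions:
        logger.warning("%d onset collisions collapsed within single samples", collisions)
    return BinarySpikeTrain(values, rate=rate, label=seq.label)


def presence_resample(
    seq: EventSequence,
    bin_width: float,
    codes: Iterable,
    duration: float | None = None,
) -> dict:
    """Resample events into per-code presence/absence bins.

    Bin ``b`` of code ``c``'s train is 1 iff any event with that code overlaps
    the half-open window ``[b*w, (b+1)*w)``. This is the standard reduction of
    region-of-interest annotations to multivariate spike trains (e.g. at a
    333 ms bin width). Returns ``{code: BinarySpikeTrain}``.
    """
    codes = list(codes)
    if not codes:
        raise ConfigurationError("presence_resample requires a non-empty code filter")
    if not bin_width > 0:
        raise InvalidInputError("bin width must be positive")
    if duration is None:
        duration = seq.duration
    n_bins = max(int(math.ceil(duration / bin_width - 1e-9)), 0)
    out = {}
    for code in codes:
        values = np.zeros(n_bins, dtype=int)
        for rec in seq.records:
            if rec.code != code:
                continue
            b0 = max(0, int(math.floor(rec.onset / bin_width + 1e-9)))
            b1 = min(n_bins, int(math.ceil(rec.offset / bin_width - 1e-9)))
            values[b0:b1] = 1
        out[code] = BinarySpikeTrain(values, rate=1.0 / bin_width, label=str(code))
    return out


def inter_onset_intervals(train: BinarySpikeTrain) -> IntervalSet:
    """Compute the inter-onset interval distribution of a spike train.

    τ_k is the time (in seconds) between consecutive 1s; a train with fewer
    than two onsets has no interval distribution.
    """
    onsets = train.onset_indices()
    if len(onsets) < 2:
        raise InsufficientDataError(
            f"need >= 2 onsets to form intervals, got {len(onsets)}"
        )
    return IntervalSet(np.diff(onsets) / train.rate)
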