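"""Reading, validation and survey pairing for smartphone tapping sessions.

The tapping task asks a participant to lay the phone on a flat surface and
alternately tap two stationary targets with two fingers of one hand for
20 seconds.  The phone logs one record per screen tap: a timestamp ``t``
(seconds) and the tap position ``(x, y)`` in pixels (origin top-left, y
growing downward).  This module turns raw tap logs into :class:`TapSession`
objects, screens out sessions too short to support the tapping features,
and pairs each questionnaire record with the tapping session recorded
closest in time for the same participant.
"""

from __future__ import annotations

import csv
import io
import json
import math
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence, Union

import numpy as np

__all__ = [
    "TapEvent",
    "TapSession",
    "SurveyRecord",
    "PairedSample",
    "SessionRejection",
    "ParseError",
    "parse_tap_sessions",
    "serialize_sessions",
    "validate_session",
    "filter_sessions",
    "pair_records",
    "read_surveys",
]

# Score ceilings of the 16-item questionnaire subset administered by the
# mobile study (6 Part-I items x 4 points, 10 Part-II items x 4 points) and
# the 8-item quality-of-life short form.
UPDRS1_MAX = 24
UPDRS2_MAX = 40
PDQ8_MAX = 32


class ParseError(ValueError):
    """Malformed input record; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TapEvent(NamedTuple):
    t: float
    x: float
    y: float


@dataclass(frozen=True)
class TapSession:
    """One 20-second tapping task for one participant.

    Events are stored as parallel numpy arrays sorted stably by time;
    duplicate timestamps are legal (zero inter-tap intervals).
    """

    participant_id: str
    recorded_at: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @classmethod
    def from_events(
        cls, participant_id: str, recorded_at: float, events: Iterable[TapEvent]
    ) -> "TapSession":
        ev = list(events)
        t = np.asarray([e.t for e in ev], dtype=float)
        x = np.asarray([e.x for e in ev], dtype=float)
        y = np.asarray([e.y for e in ev], dtype=float)
        if not participant_id:
            raise ValueError("participant_id must be non-empty")
        if t.size and (np.any(t < 0) or not np.all(np.isfinite(t))):
            raise ValueError("timestamps must be finite and non-negative")
        if t.size and not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("coordinates must be finite")
        order = np.argsort(t, kind="stable")
        return cls(participant_id, float(recorded_at), t[order], x[order], y[order])

    @property
    def n_taps(self) -> int:
        return int(self.t.size)

    @property
    def events(self) -> list[TapEvent]:
        return [TapEvent(float(a), float(b), float(c)) for a, b, c in zip(self.t, self.x, self.y)]

    def shifted(self, dt: float = 0.0, dx: float = 0.0, dy: float = 0.0) -> "TapSession":
        """Copy with all timestamps and/or positions translated."""
        return TapSession(self.participant_id, self.recorded_at, self.t + dt, self.x + dx, self.y + dy)


@dataclass(frozen=True)
class SurveyRecord:
    """Questionnaire totals: Part-I/II subset scores plus optional PDQ-8."""

    participant_id: str
    recorded_at: float
    updrs1: int
    updrs2: int
    pdq8: Optional[int] = None

    def __post_init__(self):
        if not self.participant_id:
            raise ValueError("participant_id must be non-empty")
        if not (0 <= self.updrs1 <= UPDRS1_MAX):
            raise ValueError(f"updrs1 out of range 0..{UPDRS1_MAX}: {self.updrs1}")
        if not (0 <= self.updrs2 <= UPDRS2_MAX):
            raise ValueError(f"updrs2 out of range 0..{UPDRS2_MAX}: {self.updrs2}")
        if self.pdq8 is not None and not (0 <= self.pdq8 <= PDQ8_MAX):
            raise ValueError(f"pdq8 out of range 0..{PDQ8_MAX}: {self.pdq8}")

    @property
    def total(self) -> int:
        return self.updrs1 + self.updrs2


class PairedSample(NamedTuple):
    session: TapSession
    survey: SurveyRecord


@dataclass(frozen=True)
class SessionRejection:
    participant_id: str
    recorded_at: float
    reason: str


# default field map for the "mpower" dialect; the hosted schema is
# configurable because field names vary across releases
MPOWER_FIELDS = {
    "participant_id": "healthCode",
    "recorded_at": "createdOn",
    "samples": "tapping_results",
    "time": "TapTimeStamp",
    "coordinate": "TapCoordinate",
}


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            yield from fh
    elif hasattr(source, "read"):
        yield from source
    else:  # iterable of lines
        yield from source


def _parse_jsonl(source) -> list[tuple[str, float, TapEvent]]:
    recs = []
    for lineno, line in enumerate(_iter_lines(source), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
            pid = str(obj["pid"])
            rec_at = float(obj.get("recorded_at", 0.0))
            ev = TapEvent(float(obj["t"]), float(obj["x"]), float(obj["y"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"malformed tap record ({exc})", lineno) from exc
        recs.append((pid, rec_at, ev))
    return recs


def _parse_csv(source) -> list[tuple[str, float, TapEvent]]:
    text = "".join(_iter_lines(source))
    reader = csv.DictReader(io.StringIO(text))
    recs = []
    for lineno, row in enumerate(reader, start=2):  # header is line 1
        try:
            pid = row["pid"]
            if not pid:
                raise ValueError("empty pid")
            rec_at = float(row.get("recorded_at") or 0.0)
            ev = TapEvent(float(row["t"]), float(row["x"]), float(row["y"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"malformed tap record ({exc})", lineno) from exc
        recs.append((pid, rec_at, ev))
    return recs


def _parse_mpower(source, fields: dict) -> list[TapSession]:
    # one JSON document per line, one document per session
    sessions = []
    for lineno, line in enumerate(_iter_lines(source), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
            pid = str(obj[fields["participant_id"]])
            rec_at = float(obj[fields["recorded_at"]])
            events = []
            for s in obj[fields["samples"]]:
                t = float(s[fields["time"]])
                coord = s[fields["coordinate"]]
                if isinstance(coord, str):
                    xy = coord.strip().strip("{}").split(",")
                    x, y = float(xy[0]), float(xy[1])
                else:
                    x, y = float(coord[0]), float(coord[1])
                events.append(TapEvent(t, x, y))
            sessions.append(TapSession.from_events(pid, rec_at, events))
        except (KeyError, IndexError, TypeError, ValueError) as exc:
            raise ParseError(f"malformed session document ({exc})", lineno) from exc
    return sessions


def parse_tap_sessions(source, dialect: str = "jsonl", mpower_fields: Optional[dict] = None) -> list[TapSession]:
    """Parse raw tap logs into sessions grouped by (participant, recording time).

    Parameters
    ----------
    source
        Path, open text file, or iterable of lines.
    dialect
        ``"jsonl"`` (one tap per line with keys pid/recorded_at/t/x/y),
        ``"csv"`` (same columns with a header), or ``"mpower"`` (one JSON
        document per line holding a whole session; field names adjustable
        via *mpower_fields*).
    """
    if dialect == "mpower":
        fields = dict(MPOWER_FIELDS)
        if mpower_fields:
            fields.update(mpower_fields)
        sessions = _parse_mpower(source, fields)
    elif dialect in ("jsonl", "csv"):
        recs = _parse_jsonl(source) if dialect == "jsonl" else _parse_csv(source)
        groups: dict[tuple[str, float], list[TapEvent]] = {}
        for pid, rec_at, ev in recs:
            groups.setdefault((pid, rec_at), []).append(ev)
        sessions = [TapSession.from_events(pid, rec_at, evs) for (pid, rec_at), evs in groups.items()]
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    sessions.sort(key=lambda s: (s.participant_id, s.recorded_at))
    return sessions


def serialize_sessions(sessions: Sequence[TapSession], path=None) -> str:
    """Write sessions as canonical JSON-lines (one tap per line, fixed key order).

    ``parse → serialize → parse → serialize`` is byte-stable.
    """
    lines = []
    for s in sorted(sessions, key=lambda s: (s.participant_id, s.recorded_at)):
        for t, x, y in zip(s.t, s.x, s.y):
            lines.append(json.dumps(
                {"pid": s.participant_id, "recorded_at": s.recorded_at,
                 "t": float(t), "x": float(x), "y": float(y)}))
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def validate_session(s: TapSession, min_taps: int = 4) -> Union[TapSession, SessionRejection]:
    """Screen a session for the minimum structure the tapping features need.

    Rejects sessions with fewer than *min_taps* events, or with fewer than
    two taps on either side of the mean-x split (drift statistics need at
    least two points per side; interval statistics need at least two taps).
    Rejection is a return state, not an exception.
    """
    if s.n_taps < min_taps:
        return SessionRejection(s.participant_id, s.recorded_at, "too few taps")
    mean_x = float(np.mean(s.x))
    n_left = int(np.sum(s.x < mean_x))
    n_right = s.n_taps - n_left
    if n_left == 0:
        return SessionRejection(s.participant_id, s.recorded_at, "empty left side")
    if n_left < 2:
        return SessionRejection(s.participant_id, s.recorded_at, "too few left-side taps")
    if n_right < 2:
        return SessionRejection(s.participant_id, s.recorded_at, "too few right-side taps")
    return s


def filter_sessions(
    sessions: Iterable[TapSession], min_taps: int = 4
) -> tuple[list[TapSession], list[SessionRejection]]:
    accepted, rejected = [], []
    for s in sessions:
        out = validate_session(s, min_taps=min_taps)
        (accepted if isinstance(out, TapSession) else rejected).append(out)
    return accepted, rejected


def pair_records(
    sessions: Sequence[TapSession], surveys: Sequence[SurveyRecord]
) -> list[PairedSample]:
    """Pair each survey with the same participant's nearest-in-time session.

    Participants missing either a session or a survey are dropped.  Ties in
    |session time − survey time| break toward the earlier session, which is
    deterministic and independent of input order.
    """
    by_pid: dict[str, list[TapSession]] = {}
    for s in sessions:
        by_pid.setdefault(s.participant_id, []).append(s)
    for lst in by_pid.values():
        lst.sort(key=lambda s: s.recorded_at)
    out = []
    for sv in surveys:
        cands = by_pid.get(sv.participant_id)
        if not cands:
            continue
        best = min(cands, key=lambda s: (abs(s.recorded_at - sv.recorded_at), s.recorded_at))
        out.append(PairedSample(best, sv))
    return out


def read_surveys(source) -> list[SurveyRecord]:
    """Read survey records from CSV with columns pid, recorded_at, updrs1, updrs2, pdq8.

    An empty pdq8 cell means the participant did not complete the
    quality-of-life questionnaire.
    """
    text = "".join(_iter_lines(source))
    reader = csv.DictReader(io.StringIO(text))
    out = []
    for lineno, row in enumerate(reader, start=2):
        try:
            pdq8_raw = row.get("pdq8", "")
            pdq8 = int(pdq8_raw) if pdq8_raw not in (None, "", "NA") else None
            out.append(SurveyRecord(
                participant_id=row["pid"],
                recorded_at=float(row.get("recorded_at") or 0.0),
                updrs1=int(row["updrs1"]),
                updrs2=int(row["updrs2"]),
                pdq8=pdq8,
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"malformed survey record ({exc})", lineno) from exc
    return out
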